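"""Least-squares model fitting, AICc model selection and parameter-space maps.

A fit minimizes the sum of squared residuals (SSR) between an observed
relative-volume record and the forward-Euler simulation of one transport
model evaluated at the observation times ("model-dependent fit": the ODE
constraints are enforced by construction).  Positive permeability-like
parameters are searched in log10 space with bounded Nelder-Mead from
multiple deterministic starts; the best start is polished by a second,
tighter Nelder-Mead run.

Fitted models on the same record are compared with the small-sample
corrected Akaike information criterion

    AICc = n * ln(SSR / n) + 2 k + 2 k (k + 1) / (n - k - 1),

where ``k`` counts the model's free parameters plus one for the error
variance.  Ties are broken in favour of the model with fewer parameters.

The WS parameter-space map evaluates the steady relative volume on a
(Pf, Ps) grid through the closed form (it depends on Pf/Ps only), with
optional spot checks against long-time Euler integration.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize

from .model_core import (
    DEFAULT_CONSTANTS,
    MODEL_IDS,
    MODEL_N_PARAMS,
    IntegrationError,
    ModelParameters,
    OsmoticProtocol,
    PhysicalConstants,
    VacuoleGeometry,
    simulate,
    ws_steady_state,
)

logger = logging.getLogger("vacuodyn")

__all__ = [
    "VolumeRecord",
    "FitResult",
    "ParameterSpaceMap",
    "DEFAULT_BOUNDS",
    "fit_model",
    "fit_all_models",
    "aicc",
    "compare_models",
    "explore_parameter_space",
]

#: Default search bounds; Pf/Ps in cm/s, Vb as a fraction of V0 and the WME
#: elastic modulus eps = V0 * eps_star in MPa.  They bracket all fitted
#: values reported for beetroot vacuoles with about two decades of margin.
DEFAULT_BOUNDS = {
    "Pf": (1e-5, 1e-1),
    "Ps": (1e-6, 1e-2),
    "vb_frac": (0.0, 0.999),
    "eps_mpa": (1e-4, 100.0),
}

_MPA_TO_DYN_CM2 = 1e7


@dataclass
class VolumeRecord:
    """Sampled relative-volume observations of one vacuole.

    ``times`` are absolute experiment times (s, strictly increasing,
    typically every 30 s from the solution switch) and ``rel_volume`` the
    measured V/V0 with the first observation as the unit reference.
    """

    times: np.ndarray
    rel_volume: np.ndarray
    protocol: OsmoticProtocol
    geometry: VacuoleGeometry
    label: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.rel_volume = np.asarray(self.rel_volume, dtype=float)
        if self.times.shape != self.rel_volume.shape or self.times.ndim != 1:
            raise ValueError("times and rel_volume must be 1-D and equally long")
        if self.times.size < 1:
            raise ValueError("record is empty")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.rel_volume <= 0):
            raise ValueError("relative volumes must be positive")

    @property
    def n_obs(self) -> int:
        return int(self.times.size)

    def to_csv(self, path) -> None:
        """Write `time_s,relative_volume` CSV with `#`-prefixed metadata."""
        p, g = self.protocol, self.geometry
        meta = [
            f"label = {self.label}",
            f"C0 = {p.C0}",
            f"t_switch = {p.t_switch}",
            f"B = {p.B}",
            f"t_star = {p.t_star}",
            f"Ce_star = {p.Ce_star}",
            f"t_end = {p.t_end}",
            f"direction = {p.direction}",
            f"diameter_um = {g.diameter_um}",
            f"area_mode = {g.area_mode}",
        ]
        with open(path, "w", encoding="utf-8", newline="") as fh:
            for line in meta:
                fh.write(f"# {line}\n")
            pd.DataFrame(
                {"time_s": self.times, "relative_volume": self.rel_volume}
            ).to_csv(fh, index=False)

    @classmethod
    def from_csv(cls, path) -> "VolumeRecord":
        meta: dict[str, str] = {}
        with open(path, encoding="utf-8") as fh:
            lines = fh.readlines()
        for line in lines:
            if line.startswith("#") and "=" in line:
                key, _, val = line.lstrip("# ").partition("=")
                meta[key.strip()] = val.strip()
        body = [ln for ln in lines if not ln.startswith("#") and ln.strip()]
        if not body:
            raise ValueError(f"no data rows in {path}")
        from io import StringIO

        df = pd.read_csv(StringIO("".join(body)))
        if not {"time_s", "relative_volume"} <= set(df.columns):
            raise ValueError("record CSV needs columns time_s, relative_volume")

        def fget(key, default):
            return float(meta[key]) if key in meta else default

        protocol = OsmoticProtocol(
            C0=fget("C0", 450.0),
            t_switch=fget("t_switch", 300.0),
            B=fget("B", 731.5),
            t_star=fget("t_star", 237.2),
            Ce_star=fget("Ce_star", 258.8),
            t_end=fget("t_end", 900.0),
            direction=meta.get("direction", "hypo"),  # type: ignore[arg-type]
        )
        geometry = VacuoleGeometry.from_diameter_um(
            fget("diameter_um", 40.0), meta.get("area_mode", "recomputed")
        )
        return cls(
            times=df["time_s"].to_numpy(),
            rel_volume=df["relative_volume"].to_numpy(),
            protocol=protocol,
            geometry=geometry,
            label=meta.get("label", ""),
        )


@dataclass
class FitResult:
    """Best fit of one model to one record."""

    model_id: str
    best_params: ModelParameters
    ssr: float
    n_obs: int
    n_params: int
    aic: float
    converged: bool
    n_starts_used: int

    def params_dict(self) -> dict[str, float]:
        return self.best_params.free_values()


@dataclass
class ParameterSpaceMap:
    """Steady relative volume on a (Pf, Ps) grid; rows follow ``Pf_grid``."""

    Pf_grid: np.ndarray
    Ps_grid: np.ndarray
    Vf_over_V0: np.ndarray

    def __post_init__(self) -> None:
        if self.Vf_over_V0.shape != (self.Pf_grid.size, self.Ps_grid.size):
            raise ValueError("matrix shape must be |Pf_grid| x |Ps_grid|")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.Vf_over_V0, index=self.Pf_grid, columns=self.Ps_grid)

    def to_csv(self, matrix_path, pf_axis_path=None, ps_axis_path=None) -> None:
        np.savetxt(matrix_path, self.Vf_over_V0, delimiter=",")
        if pf_axis_path is not None:
            np.savetxt(pf_axis_path, self.Pf_grid, delimiter=",")
        if ps_axis_path is not None:
            np.savetxt(ps_axis_path, self.Ps_grid, delimiter=",")

    def plot(self, path=None):
        """Simple log-log heatmap of the steady-volume map."""
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(5, 4))
        mesh = ax.pcolormesh(self.Ps_grid, self.Pf_grid, self.Vf_over_V0, shading="auto")
        ax.set_xscale("log")
        ax.set_yscale("log")
        ax.set_xlabel("Ps (cm/s)")
        ax.set_ylabel("Pf (cm/s)")
        fig.colorbar(mesh, ax=ax, label="Vf / V0")
        if path is not None:
            fig.savefig(path, dpi=150, bbox_inches="tight")
            plt.close(fig)
        return fig


# --------------------------------------------------------------------------
# parameter transforms
# --------------------------------------------------------------------------

# free-parameter layout per model in the transformed search space
_LAYOUT = {
    "W": ("log_Pf",),
    "WNOV": ("log_Pf", "vb_frac"),
    "WME": ("log_Pf", "log_eps_mpa"),
    "WS": ("log_Pf", "log_Ps"),
    "WSNOV": ("log_Pf", "log_Ps", "vb_frac"),
}


def _transformed_bounds(model_id: str, bounds: Mapping[str, tuple[float, float]]):
    out = []
    for name in _LAYOUT[model_id]:
        if name == "log_Pf":
            lo, hi = bounds["Pf"]
            out.append((math.log10(lo), math.log10(hi)))
        elif name == "log_Ps":
            lo, hi = bounds["Ps"]
            out.append((math.log10(lo), math.log10(hi)))
        elif name == "log_eps_mpa":
            lo, hi = bounds["eps_mpa"]
            out.append((math.log10(lo), math.log10(hi)))
        else:  # vb_frac, linear
            out.append(tuple(bounds["vb_frac"]))
    return out


def _to_params(x: np.ndarray, model_id: str, V0: float) -> ModelParameters:
    vals = dict(zip(_LAYOUT[model_id], x))
    kwargs: dict[str, float] = {"Pf": 10.0 ** vals["log_Pf"]}
    if "log_Ps" in vals:
        kwargs["Ps"] = 10.0 ** vals["log_Ps"]
    if "vb_frac" in vals:
        kwargs["Vb"] = vals["vb_frac"] * V0
    if "log_eps_mpa" in vals:
        kwargs["eps_star"] = 10.0 ** vals["log_eps_mpa"] * _MPA_TO_DYN_CM2 / V0
    return ModelParameters(model_id=model_id, **kwargs)


# --------------------------------------------------------------------------
# fitting
# --------------------------------------------------------------------------


def _ssr(record: VolumeRecord, params: ModelParameters, dt: float) -> float:
    t_end = max(record.protocol.t_end, float(record.times[-1]))
    try:
        traj = simulate(
            params,
            record.protocol,
            record.geometry,
            dt=dt,
            t_end=t_end,
        )
    except (IntegrationError, ValueError):
        return np.inf
    sim_rel = np.interp(record.times, traj.times, traj.rel_volume)
    resid = sim_rel - record.rel_volume
    return float(resid @ resid)


def fit_model(
    record: VolumeRecord,
    model_id: str,
    bounds: Mapping[str, tuple[float, float]] | None = None,
    n_starts: int = 8,
    seed: int = 0,
    dt: float = 0.1,
) -> FitResult:
    """Fit one transport model to a volume record by SSR minimization.

    Multi-start bounded Nelder-Mead in the transformed parameter space
    (log10 for Pf, Ps and the elastic modulus; linear for the non-osmotic
    volume fraction), deterministic for a given ``seed``.  The first start
    sits at the centre of the bounds; the remaining ``n_starts - 1`` are
    drawn uniformly in the transformed space.  Trials whose simulation blows
    up are discarded with a log entry; if no start converges the result is
    flagged, not raised.
    """
    if model_id not in MODEL_IDS:
        raise ValueError(f"unknown model_id {model_id!r}")
    if n_starts < 1:
        raise ValueError("n_starts must be >= 1")
    merged = dict(DEFAULT_BOUNDS)
    if bounds:
        merged.update(bounds)
    for key, (lo, hi) in merged.items():
        if not (np.isfinite(lo) and np.isfinite(hi) and hi > lo >= 0):
            raise ValueError(f"invalid bounds for {key}: {(lo, hi)}")
    tb = _transformed_bounds(model_id, merged)
    lows = np.array([b[0] for b in tb])
    highs = np.array([b[1] for b in tb])
    V0 = record.geometry.V0

    def objective(x: np.ndarray) -> float:
        val = _ssr(record, _to_params(x, model_id, V0), dt)
        return val if np.isfinite(val) else 1e6

    rng = np.random.default_rng(seed)
    starts = [0.5 * (lows + highs)]
    for _ in range(n_starts - 1):
        starts.append(lows + rng.random(lows.size) * (highs - lows))

    best_x = None
    best_val = np.inf
    converged = False
    for i, x0 in enumerate(starts):
        res = optimize.minimize(
            objective,
            x0,
            method="Nelder-Mead",
            bounds=tb,
            options={"maxiter": 2000, "xatol": 1e-8, "fatol": 1e-14},
        )
        if res.fun >= 1e6:
            logger.info(
                "fit %s start %d ended in a non-physical region; discarded",
                model_id,
                i,
            )
            continue
        converged = converged or bool(res.success)
        if res.fun < best_val:
            best_val = float(res.fun)
            best_x = np.asarray(res.x)
    if best_x is None:  # every start blew up
        center = 0.5 * (lows + highs)
        params = _to_params(center, model_id, V0)
        return FitResult(
            model_id=model_id,
            best_params=params,
            ssr=float("inf"),
            n_obs=record.n_obs,
            n_params=MODEL_N_PARAMS[model_id],
            aic=float("inf"),
            converged=False,
            n_starts_used=n_starts,
        )
    # derivative-free polish around the best start
    polish = optimize.minimize(
        objective,
        best_x,
        method="Nelder-Mead",
        bounds=tb,
        options={"maxiter": 4000, "xatol": 1e-10, "fatol": 1e-16},
    )
    if polish.fun <= best_val:
        best_val = float(polish.fun)
        best_x = np.asarray(polish.x)
        converged = converged or bool(polish.success)
    params = _to_params(best_x, model_id, V0)
    k = MODEL_N_PARAMS[model_id]
    return FitResult(
        model_id=model_id,
        best_params=params,
        ssr=best_val,
        n_obs=record.n_obs,
        n_params=k,
        aic=aicc(best_val, record.n_obs, k),
        converged=converged,
        n_starts_used=n_starts,
    )


def fit_all_models(
    record: VolumeRecord,
    model_ids: Sequence[str] = MODEL_IDS,
    bounds: Mapping[str, tuple[float, float]] | None = None,
    n_starts: int = 8,
    seed: int = 0,
    dt: float = 0.1,
) -> list[FitResult]:
    """Fit every requested model to the same record (one seed for all)."""
    return [
        fit_model(record, mid, bounds=bounds, n_starts=n_starts, seed=seed, dt=dt)
        for mid in model_ids
    ]


# --------------------------------------------------------------------------
# AICc model comparison
# --------------------------------------------------------------------------


def aicc(ssr: float, n: int, n_params: int) -> float:
    """Small-sample corrected Akaike score of a least-squares fit.

    ``k = n_params + 1`` counts the error-variance parameter.  A perfect fit
    (``ssr == 0``) maps to ``-inf``: it outranks everything.
    """
    k = n_params + 1
    if n - k - 1 <= 0:
        raise ValueError(f"AICc undefined for n = {n}, k = {k} (n - k - 1 <= 0)")
    if ssr < 0:
        raise ValueError("ssr must be non-negative")
    if ssr == 0.0:
        return float("-inf")
    return n * math.log(ssr / n) + 2 * k + 2 * k * (k + 1) / (n - k - 1)


def compare_models(fits: Sequence[FitResult]) -> pd.DataFrame:
    """Rank fitted models of one record by AICc.

    Returns a DataFrame sorted by ascending AICc (ties broken by fewer
    parameters) with columns ``model, n_params, ssr, aic, delta_aic,
    weight``; Akaike weights are normalized to one.
    """
    if not fits:
        raise ValueError("no fits to compare")
    n_obs = {f.n_obs for f in fits}
    if len(n_obs) != 1:
        raise ValueError("all fits must refer to the same record (equal n_obs)")
    df = pd.DataFrame(
        {
            "model": [f.model_id for f in fits],
            "n_params": [f.n_params for f in fits],
            "ssr": [f.ssr for f in fits],
            "aic": [f.aic for f in fits],
        }
    ).sort_values(["aic", "n_params"], kind="stable")
    best = df["aic"].iloc[0]
    if np.isneginf(best):
        # perfect fits dominate; split the weight among them
        exact = np.isneginf(df["aic"].to_numpy())
        df["delta_aic"] = np.where(exact, 0.0, np.inf)
        df["weight"] = np.where(exact, 1.0 / exact.sum(), 0.0)
    else:
        df["delta_aic"] = df["aic"] - best
        rel = np.exp(-0.5 * df["delta_aic"].to_numpy())
        df["weight"] = rel / rel.sum()
    return df.reset_index(drop=True)


# --------------------------------------------------------------------------
# WS parameter-space exploration
# --------------------------------------------------------------------------


def _steady_by_simulation(
    Pf: float,
    Ps: float,
    C0: float,
    Ce_final: float,
    geometry: VacuoleGeometry,
    constants: PhysicalConstants,
    dt: float = 0.1,
    rel_tol: float = 1e-12,
    max_chunks: int = 200,
) -> float:
    """Long-time Euler integration of WS under constant ``Ce_final``.

    Brute-force oracle for :func:`ws_steady_state`; integrates in chunks
    until the relative volume stops changing.
    """
    # chunked restarts (10^4 s per chunk): carry (V, M) forward by hand
    from .model_core import MOSM_TO_MOL_CM3, _MODEL_CODE, _euler_loop

    n = int(round(10_000.0 / dt)) + 1
    Ce = np.full(n, Ce_final * MOSM_TO_MOL_CM3)
    V0 = geometry.V0
    v, m = V0, V0 * C0 * MOSM_TO_MOL_CM3
    for _ in range(max_chunks):
        V, M, fail = _euler_loop(
            Ce,
            float(dt),
            v,
            m,
            Pf,
            Ps,
            0.0,
            0.0,
            constants.Vw,
            constants.RT,
            geometry.area_mode == "fixed",
            _MODEL_CODE["WS"],
        )
        if fail >= 0:
            raise IntegrationError("steady-state simulation became non-physical")
        if abs(V[-1] / v - 1.0) < rel_tol:
            return float(V[-1] / V0)
        v, m = float(V[-1]), float(M[-1])
    return float(v / V0)


def explore_parameter_space(
    Pf_grid,
    Ps_grid,
    protocol: OsmoticProtocol = None,
    geometry: VacuoleGeometry | None = None,
    constants: PhysicalConstants = DEFAULT_CONSTANTS,
    spot_check: int = 0,
    seed: int = 0,
    spot_check_tol: float = 1e-4,
) -> ParameterSpaceMap:
    """Map the WS steady relative volume over a (Pf, Ps) grid.

    Each cell is the closed-form steady state for the protocol's final
    osmolality; it depends on (Pf, Ps) only through Pf/Ps, so a 1000 x 1000
    grid (a million cells) is immediate.  With ``spot_check > 0`` that many
    randomly chosen cells are verified against long-time Euler integration
    within ``spot_check_tol`` relative.
    """
    if protocol is None:
        protocol = OsmoticProtocol()
    Pf_grid = np.asarray(Pf_grid, dtype=float)
    Ps_grid = np.asarray(Ps_grid, dtype=float)
    for grid, name in ((Pf_grid, "Pf_grid"), (Ps_grid, "Ps_grid")):
        if np.any(grid <= 0):
            raise ValueError(f"{name} must be positive")
        if np.any(np.diff(grid) <= 0):
            raise ValueError(f"{name} must be sorted ascending")
    ratio = Pf_grid[:, None] / Ps_grid[None, :]
    vf = ws_steady_state(ratio, protocol.C0, protocol.Ce_star, constants)
    if spot_check > 0:
        if geometry is None:
            geometry = VacuoleGeometry.from_diameter_um()
        rng = np.random.default_rng(seed)
        for _ in range(spot_check):
            i = int(rng.integers(Pf_grid.size))
            j = int(rng.integers(Ps_grid.size))
            sim_vf = _steady_by_simulation(
                Pf_grid[i], Ps_grid[j], protocol.C0, protocol.Ce_star, geometry, constants
            )
            if abs(sim_vf / vf[i, j] - 1.0) > spot_check_tol:
                raise AssertionError(
                    f"closed form and simulation disagree at cell ({i}, {j}): "
                    f"{vf[i, j]:.8f} vs {sim_vf:.8f}"
                )
    return ParameterSpaceMap(Pf_grid=Pf_grid, Ps_grid=Ps_grid, Vf_over_V0=vf)
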