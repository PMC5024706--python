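"""Membrane-transport models for the osmotic volume dynamics of isolated vacuoles.

An isolated vacuole, idealized as a sphere bounded by the tonoplast, is
perfused with a solution whose osmolality changes gradually after a solution
switch.  Five competing hypotheses about what shapes the volume response are
encoded as forced ODE systems in the state ``(V, M)`` — vacuole volume (cm^3)
and intravacuolar solute amount (mol):

``W``
    water flux only, driven by the osmotic gradient (one parameter, *Pf*);
``WNOV``
    water flux with a non-osmotic (osmotically inactive) volume *Vb*;
``WME``
    water flux opposed by membrane elasticity: swelling builds a hydrostatic
    pressure ``dP = eps_star * (V - V0)`` that subtracts ``dP / (R*T)`` from
    the osmotic driving force;
``WS``
    simultaneous water and solute fluxes through independent pathways
    (*Pf* and *Ps*), the solute leaving the vacuole down its gradient;
``WSNOV``
    the WS fluxes acting on the osmotically active volume ``V - Vb``.

All models share the phenomenological law of osmosis

    Jv = A * Pf * Vw * (C_in - Ce(t)),      dV/dt = Jv

with ``C_in = M / (V - Vb)`` and, for the solute models,

    Js = -A * Ps * (C_in - Ce(t)),          dM/dt = Js.

The forcing ``Ce(t)`` is the measured external osmolality: an iso-osmotic
plateau ``C0`` followed, after the solution switch, by a single-exponential
decay ``B * exp(-t / t_star) + Ce_star`` evaluated on global experiment time
and clamped to the interval spanned by ``C0`` and ``Ce_star``.

Internal units are mol, cm, s and dyn; osmolalities are supplied in
mOsmol/Kgw and converted at 1 mOsmol/Kgw = 1e-6 mol/cm^3 (unit solution
density).  Trajectories are integrated by forward Euler with a 0.1 s step,
which is well inside the stability region of these stiff-free systems; a
closed-form WS steady state is provided as an independent oracle.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np

logger = logging.getLogger("vacuodyn")

__all__ = [
    "MOSM_TO_MOL_CM3",
    "MODEL_IDS",
    "MODEL_N_PARAMS",
    "PhysicalConstants",
    "OsmoticProtocol",
    "VacuoleGeometry",
    "ModelParameters",
    "Trajectory",
    "IntegrationError",
    "external_osmolality",
    "area_from_volume",
    "model_rhs",
    "simulate",
    "ws_steady_state",
    "mean_solute_mass_flow",
    "DEFAULT_CONSTANTS",
    "DEFAULT_HYPO_PROTOCOL",
    "DEFAULT_HYPER_PROTOCOL",
]

# 1 mOsmol/Kgw == 1e-6 osmol/cm^3 (solution density ~ 1 g/cm^3)
MOSM_TO_MOL_CM3 = 1e-6

#: Identifiers of the five transport models, ordered by increasing structure.
MODEL_IDS = ("W", "WNOV", "WME", "WS", "WSNOV")

#: Number of free parameters per model (used by the AICc comparison).
MODEL_N_PARAMS = {"W": 1, "WNOV": 2, "WME": 2, "WS": 2, "WSNOV": 3}

_MODEL_CODE = {"W": 0, "WNOV": 1, "WME": 2, "WS": 3, "WSNOV": 4}

# surface of a sphere of volume V is _SPHERE_COEF * V**(2/3)
_SPHERE_COEF = (36.0 * math.pi) ** (1.0 / 3.0)

AVOGADRO = 6.02214076e23


class IntegrationError(RuntimeError):
    """The Euler trajectory reached a non-physical state (V <= Vb or V <= 0)."""


# --------------------------------------------------------------------------
# domain types
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class PhysicalConstants:
    """Fixed physical constants, in cgs-style units.

    Attributes
    ----------
    Vw : partial molar volume of water, cm^3/mol.
    R : gas constant, dyn*cm/(K*mol).
    T : absolute temperature, K.
    """

    Vw: float = 18.0
    R: float = 8.31e7
    T: float = 293.0

    def __post_init__(self) -> None:
        if not (self.Vw > 0 and self.R > 0 and self.T > 0):
            raise ValueError("physical constants must be strictly positive")

    @property
    def RT(self) -> float:
        return self.R * self.T


@dataclass(frozen=True)
class OsmoticProtocol:
    """External-osmolality time course of a perfusion experiment.

    The chamber holds an iso-osmotic solution of osmolality ``C0`` until
    ``t_switch``; from then on the measured osmolality follows
    ``B * exp(-t / t_star) + Ce_star`` (global experiment time), clamped to
    the interval between ``C0`` and ``Ce_star``.  All osmolalities in
    mOsmol/Kgw, times in s.
    """

    C0: float = 450.0
    t_switch: float = 300.0
    B: float = 731.5
    t_star: float = 237.2
    Ce_star: float = 258.8
    t_end: float = 900.0
    direction: Literal["hypo", "hyper"] = "hypo"

    def __post_init__(self) -> None:
        if self.t_star <= 0:
            raise ValueError("t_star must be positive")
        if not (self.t_end > self.t_switch >= 0):
            raise ValueError("need t_end > t_switch >= 0")
        if self.C0 <= 0 or self.Ce_star <= 0:
            raise ValueError("osmolalities must be positive")
        if self.direction == "hypo" and not self.Ce_star < self.C0:
            raise ValueError("hypo-osmotic protocol requires Ce_star < C0")
        if self.direction == "hyper" and not self.Ce_star > self.C0:
            raise ValueError("hyper-osmotic protocol requires Ce_star > C0")
        if self.direction not in ("hypo", "hyper"):
            raise ValueError(f"unknown direction {self.direction!r}")

    @classmethod
    def hyper(
        cls,
        Ce_star: float = 660.0,
        C0: float = 450.0,
        t_switch: float = 300.0,
        t_star: float = 237.2,
        t_end: float = 900.0,
    ) -> "OsmoticProtocol":
        """Hyper-osmotic variant of the protocol.

        The decay constant mirrors the measured hypo-osmotic one and the
        (negative) amplitude is set so the exponential passes through ``C0``
        at the switch; both are placeholders for a measured hyper-osmotic
        time course.
        """
        B = (C0 - Ce_star) / math.exp(-t_switch / t_star)
        return cls(
            C0=C0,
            t_switch=t_switch,
            B=B,
            t_star=t_star,
            Ce_star=Ce_star,
            t_end=t_end,
            direction="hyper",
        )


@dataclass(frozen=True)
class VacuoleGeometry:
    """Initial volume of the spherical vacuole and the surface-area convention.

    ``area_mode="recomputed"`` re-evaluates the sphere surface from the
    current volume at every integration step; ``"fixed"`` freezes it at its
    initial value (the two give indistinguishable results for the small
    relative volume changes seen here, which is itself a tested claim).
    """

    V0: float
    area_mode: Literal["recomputed", "fixed"] = "recomputed"

    def __post_init__(self) -> None:
        if self.V0 <= 0:
            raise ValueError("V0 must be positive")
        if self.area_mode not in ("recomputed", "fixed"):
            raise ValueError(f"unknown area_mode {self.area_mode!r}")

    @classmethod
    def from_diameter_um(
        cls, diameter_um: float = 40.0, area_mode: str = "recomputed"
    ) -> "VacuoleGeometry":
        """Geometry of a sphere of the given diameter in micrometres."""
        r_cm = 0.5 * diameter_um * 1e-4
        return cls(V0=4.0 / 3.0 * math.pi * r_cm**3, area_mode=area_mode)  # type: ignore[arg-type]

    @property
    def diameter_um(self) -> float:
        return 2.0 * (3.0 * self.V0 / (4.0 * math.pi)) ** (1.0 / 3.0) * 1e4


@dataclass(frozen=True)
class ModelParameters:
    """Free parameters of one transport model.

    Only the parameters used by ``model_id`` may be non-zero:
    ``Ps`` (cm/s) for WS/WSNOV, ``Vb`` (cm^3) for WNOV/WSNOV and the elastic
    coefficient ``eps_star`` (dyn/cm^5, pressure change per volume change)
    for WME.  The volumetric elastic modulus reported for a WME trajectory is
    ``eps = V * eps_star``.
    """

    model_id: str
    Pf: float
    Ps: float = 0.0
    Vb: float = 0.0
    eps_star: float = 0.0

    def __post_init__(self) -> None:
        if self.model_id not in MODEL_IDS:
            raise ValueError(f"unknown model_id {self.model_id!r}")
        if self.Pf < 0 or self.Ps < 0 or self.Vb < 0 or self.eps_star < 0:
            raise ValueError("parameters must be non-negative")
        uses = {
            "Ps": self.model_id in ("WS", "WSNOV"),
            "Vb": self.model_id in ("WNOV", "WSNOV"),
            "eps_star": self.model_id == "WME",
        }
        for name, used in uses.items():
            if not used and getattr(self, name) != 0.0:
                raise ValueError(f"{name} is not a parameter of the {self.model_id} model")

    @property
    def n_free(self) -> int:
        return MODEL_N_PARAMS[self.model_id]

    def free_values(self) -> dict[str, float]:
        """Mapping of the free-parameter names to their values."""
        names = {
            "W": ("Pf",),
            "WNOV": ("Pf", "Vb"),
            "WME": ("Pf", "eps_star"),
            "WS": ("Pf", "Ps"),
            "WSNOV": ("Pf", "Ps", "Vb"),
        }[self.model_id]
        return {n: getattr(self, n) for n in names}


@dataclass
class Trajectory:
    """A simulated time course on a uniform grid.

    ``V`` is volume (cm^3), ``M`` solute amount (mol), ``Ce`` the external
    osmolality (mOsmol/Kgw), ``Jv`` the volume flux (cm^3/s), ``Js`` the
    solute flux (mol/s, zero for water-only models) and ``dP`` the
    hydrostatic pressure difference (dyn/cm^2, non-zero only for WME).
    """

    times: np.ndarray
    V: np.ndarray
    M: np.ndarray
    Ce: np.ndarray
    Jv: np.ndarray
    Js: np.ndarray
    dP: np.ndarray
    params: ModelParameters
    V0: float
    M0: float
    dt: float

    @property
    def rel_volume(self) -> np.ndarray:
        return self.V / self.V0

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "time_s": self.times,
                "relative_volume": self.rel_volume,
                "volume_cm3": self.V,
                "solute_mol": self.M,
                "external_mosm": self.Ce,
            }
        )

    def to_csv(self, path, header_lines: list[str] | None = None) -> None:
        """Write the trajectory as UTF-8 CSV ('.' decimal separator)."""
        with open(path, "w", encoding="utf-8", newline="") as fh:
            for line in header_lines or []:
                fh.write(f"# {line}\n")
            self.to_frame().to_csv(fh, index=False)


DEFAULT_CONSTANTS = PhysicalConstants()
DEFAULT_HYPO_PROTOCOL = OsmoticProtocol()
DEFAULT_HYPER_PROTOCOL = OsmoticProtocol.hyper()


# --------------------------------------------------------------------------
# forcing and geometry
# --------------------------------------------------------------------------


def external_osmolality(t, protocol: OsmoticProtocol = DEFAULT_HYPO_PROTOCOL):
    """External osmolality (mOsmol/Kgw) at time ``t`` (s, scalar or array).

    Returns ``C0`` on the iso-osmotic plateau (``t < t_switch``) and the
    exponential ``B * exp(-t / t_star) + Ce_star`` afterwards, evaluated on
    global experiment time and clamped to the closed interval spanned by
    ``C0`` and ``Ce_star``.
    """
    arr = np.asarray(t, dtype=float)
    if np.any(arr < 0):
        raise ValueError("time must be non-negative")
    decay = protocol.B * np.exp(-arr / protocol.t_star) + protocol.Ce_star
    lo = min(protocol.C0, protocol.Ce_star)
    hi = max(protocol.C0, protocol.Ce_star)
    out = np.where(arr < protocol.t_switch, protocol.C0, np.clip(decay, lo, hi))
    return float(out) if np.isscalar(t) or arr.ndim == 0 else out


def area_from_volume(V, geometry: VacuoleGeometry):
    """Surface area (cm^2) of the spherical vacuole of volume ``V`` (cm^3).

    In ``fixed`` mode the area of the initial sphere is returned regardless
    of ``V``.
    """
    arr = np.asarray(V, dtype=float)
    if np.any(arr <= 0):
        raise ValueError("volume must be positive")
    if geometry.area_mode == "fixed":
        a = np.full_like(arr, _SPHERE_COEF * geometry.V0 ** (2.0 / 3.0))
    else:
        a = _SPHERE_COEF * arr ** (2.0 / 3.0)
    return float(a) if np.isscalar(V) or arr.ndim == 0 else a


# --------------------------------------------------------------------------
# right-hand sides
# --------------------------------------------------------------------------


def model_rhs(
    state: tuple[float, float],
    t: float,
    params: ModelParameters,
    protocol: OsmoticProtocol = DEFAULT_HYPO_PROTOCOL,
    geometry: VacuoleGeometry | None = None,
    constants: PhysicalConstants = DEFAULT_CONSTANTS,
    V0: float | None = None,
) -> tuple[float, float]:
    """Time derivative ``(dV/dt, dM/dt)`` of the chosen model at ``state``.

    ``V0`` (reference volume of the WME pressure term) defaults to the
    geometry's initial volume.  Concentrations are handled in mol/cm^3.
    """
    V, M = state
    if geometry is None:
        geometry = VacuoleGeometry.from_diameter_um()
    if V0 is None:
        V0 = geometry.V0
    if V <= 0:
        raise IntegrationError("volume must be positive")
    if V <= params.Vb:
        raise IntegrationError("singular state: V <= Vb")
    A = area_from_volume(V, geometry)
    Ce = external_osmolality(t, protocol) * MOSM_TO_MOL_CM3
    grad = M / (V - params.Vb) - Ce
    if params.model_id == "WME":
        grad = grad - params.eps_star * (V - V0) / constants.RT
    dV = A * params.Pf * constants.Vw * grad
    dM = -A * params.Ps * grad if params.model_id in ("WS", "WSNOV") else 0.0
    return dV, dM


# --------------------------------------------------------------------------
# Euler integration
# --------------------------------------------------------------------------


def _euler_loop(Ce, dt, V0, M0, Pf, Ps, Vb, eps_star, Vw, RT, fixed_area, code):
    # Forward Euler over the whole grid; Ce is already in mol/cm^3.
    # Returns (V, M, i_fail) with i_fail = -1 on success.  Both state
    # equations share the same gradient evaluation, which makes the WS
    # conservation line Ps*(V-V0) + Pf*Vw*(M-M0) = 0 exact per step.
    n = Ce.shape[0]
    V = np.empty(n)
    M = np.empty(n)
    V[0] = V0
    M[0] = M0
    a0 = _SPHERE_COEF_ * V0 ** (2.0 / 3.0)
    v = V0
    m = M0
    for i in range(n - 1):
        a = a0 if fixed_area else _SPHERE_COEF_ * v ** (2.0 / 3.0)
        grad = m / (v - Vb) - Ce[i]
        if code == 2:
            grad = grad - eps_star * (v - V0) / RT
        v = v + a * Pf * Vw * grad * dt
        if code >= 3:
            m = m - a * Ps * grad * dt
        if v <= 0.0 or v <= Vb:
            return V, M, i
        V[i + 1] = v
        M[i + 1] = m
    return V, M, -1


_SPHERE_COEF_ = _SPHERE_COEF  # module-global visible to the jitted kernel

try:  # pragma: no cover - exercised implicitly
    from numba import njit as _njit

    _euler_loop = _njit(cache=False)(_euler_loop)
except Exception:  # numba unavailable: pure-Python kernel, same arithmetic
    logger.info("numba not available; using the pure-Python Euler kernel")


def simulate(
    params: ModelParameters,
    protocol: OsmoticProtocol = DEFAULT_HYPO_PROTOCOL,
    geometry: VacuoleGeometry | None = None,
    constants: PhysicalConstants = DEFAULT_CONSTANTS,
    dt: float = 0.1,
    t_end: float | None = None,
) -> Trajectory:
    """Integrate one model by forward Euler from the iso-osmotic rest state.

    The initial condition is the vacuole equilibrated with the iso-osmotic
    bath: ``V(0) = V0`` and ``M(0) = M0 = (V0 - Vb) * C0`` (in mol, with
    ``C0`` converted to mol/cm^3), so the osmotically active compartment
    starts at concentration ``C0`` and the pre-switch plateau is a true rest
    state; for models without a non-osmotic volume this is ``M0 = V0 * C0``.
    ``t_end`` defaults to the protocol's record length.

    Raises
    ------
    IntegrationError
        If the state becomes non-physical (``V <= Vb`` or ``V <= 0``).
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if geometry is None:
        geometry = VacuoleGeometry.from_diameter_um()
    if params.Vb >= geometry.V0:
        raise ValueError("Vb must be smaller than V0")
    end = protocol.t_end if t_end is None else t_end
    n = int(round(end / dt)) + 1
    times = np.arange(n) * dt
    Ce_mosm = external_osmolality(times, protocol)
    Ce = Ce_mosm * MOSM_TO_MOL_CM3
    V0 = geometry.V0
    M0 = (V0 - params.Vb) * protocol.C0 * MOSM_TO_MOL_CM3
    V, M, fail = _euler_loop(
        Ce,
        float(dt),
        V0,
        M0,
        params.Pf,
        params.Ps,
        params.Vb,
        params.eps_star,
        constants.Vw,
        constants.RT,
        geometry.area_mode == "fixed",
        _MODEL_CODE[params.model_id],
    )
    if fail >= 0:
        raise IntegrationError(
            f"{params.model_id} trajectory became non-physical at "
            f"t = {times[fail]:.1f} s (V <= max(0, Vb))"
        )
    A = area_from_volume(V, geometry)
    grad = M / (V - params.Vb) - Ce
    dP = np.zeros(n)
    if params.model_id == "WME":
        dP = params.eps_star * (V - V0)
        grad = grad - dP / constants.RT
    Jv = A * params.Pf * constants.Vw * grad
    Js = -A * params.Ps * grad if params.model_id in ("WS", "WSNOV") else np.zeros(n)
    return Trajectory(
        times=times,
        V=V,
        M=M,
        Ce=Ce_mosm,
        Jv=Jv,
        Js=Js,
        dP=dP,
        params=params,
        V0=V0,
        M0=M0,
        dt=float(dt),
    )


# --------------------------------------------------------------------------
# WS closed-form steady state (internal oracle)
# --------------------------------------------------------------------------


def ws_steady_state(
    ratio,
    C0: float = 450.0,
    Ce_final: float = 258.8,
    constants: PhysicalConstants = DEFAULT_CONSTANTS,
):
    """Steady relative volume of the WS model under a constant final osmolality.

    At steady state both fluxes vanish (``M/V = Ce``) and the exact Euler
    conservation line ``Ps*(V - V0) + Pf*Vw*(M - M0) = 0`` pins the volume::

        Vf / V0 = (1 + k * C0) / (1 + k * Ce_final),   k = (Pf/Ps) * Vw

    with osmolalities converted to mol/cm^3.  Depends on ``Pf`` and ``Ps``
    only through their ratio; accepts scalar or array ``ratio``.
    """
    r = np.asarray(ratio, dtype=float)
    if np.any(r < 0):
        raise ValueError("ratio must be non-negative")
    if C0 <= 0 or Ce_final <= 0:
        raise ValueError("osmolalities must be positive")
    k = r * constants.Vw
    out = (1.0 + k * C0 * MOSM_TO_MOL_CM3) / (1.0 + k * Ce_final * MOSM_TO_MOL_CM3)
    return float(out) if np.isscalar(ratio) or r.ndim == 0 else out


def mean_solute_mass_flow(traj: Trajectory) -> float:
    """Mean magnitude of the solute flow along a trajectory, particles/s.

    Reported for comparison with literature transport rates; the value
    scales with the (unmeasured) vacuole surface area.
    """
    return float(np.mean(np.abs(traj.Js)) * AVOGADRO)
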