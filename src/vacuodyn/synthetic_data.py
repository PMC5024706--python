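"""Synthetic single-vacuole records and osmolality series.

The generator emulates what the video-microscopy pipeline actually
measures: the diameter of a spherical vacuole, read off an image every 30 s
for 10 min after the solution switch.  A ground-truth trajectory is
simulated, sampled at the observation times, converted to diameter,
optionally quantized to the pixel grid, perturbed with Gaussian diameter
noise and converted back to relative volume with the first observation as
the unit reference — exactly the reduction applied to the real images.
External-osmolality aliquot series are generated the same way from the
protocol's forcing function.

Cohorts couple the per-record Pf and Ps draws through the Pf/Ps ratio
(log-normal spreads on Pf and on the ratio, Ps derived), because observed
per-vacuole ratios scatter far less than independent permeability draws
would allow.  All randomness is controlled by integer seeds; per-record
seeds derive deterministically from the cohort seed via
``numpy.random.SeedSequence``.
"""

from __future__ import annotations

import json
import logging
import math
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize

from .fitting import VolumeRecord
from .model_core import (
    DEFAULT_HYPO_PROTOCOL,
    ModelParameters,
    OsmoticProtocol,
    VacuoleGeometry,
    external_osmolality,
    simulate,
)

logger = logging.getLogger("vacuodyn")

__all__ = [
    "NoiseModel",
    "CohortSpec",
    "generate_record",
    "generate_osmolality_series",
    "fit_osmolality_decay",
    "generate_cohort",
    "write_cohort",
]


@dataclass(frozen=True)
class NoiseModel:
    """Measurement noise applied to the observed diameter (micrometres).

    ``pixel_scale`` is the image scaling factor in um/pixel; a positive
    value rounds each diameter to the pixel grid (the printed range of the
    acquisition system is 2.98-3.50 um/pixel), while 0 disables quantization
    and models sub-pixel diameter measurement.  ``diameter_sd`` is the
    Gaussian noise on the measured diameter.
    """

    pixel_scale: float = 3.24
    diameter_sd: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.diameter_sd < 0:
            raise ValueError("diameter_sd must be non-negative")
        if self.pixel_scale != 0.0 and not (2.98 <= self.pixel_scale <= 3.50):
            raise ValueError(
                "pixel_scale must be 0 (no quantization) or within the "
                "calibrated range 2.98-3.50 um/pixel"
            )


def _volume_to_diameter_um(V: np.ndarray) -> np.ndarray:
    return 2.0 * (3.0 * V / (4.0 * math.pi)) ** (1.0 / 3.0) * 1e4


def generate_record(
    params: ModelParameters,
    protocol: OsmoticProtocol = DEFAULT_HYPO_PROTOCOL,
    geometry: VacuoleGeometry | None = None,
    noise: NoiseModel = NoiseModel(),
    sampling_interval: float = 30.0,
    duration: float = 600.0,
    dt: float = 0.1,
    label: str = "",
) -> VolumeRecord:
    """One noisy single-vacuole record sampled after the solution switch.

    Observation times are ``t_switch + {0, sampling_interval, ...,
    duration}``.  Deterministic for a given ``noise.seed``.  If the noise
    drives a diameter non-positive the whole record is resampled (with a
    warning), aborting after 100 attempts.
    """
    if geometry is None:
        geometry = VacuoleGeometry.from_diameter_um()
    t_obs = protocol.t_switch + np.arange(0.0, duration + 0.5 * sampling_interval, sampling_interval)
    traj = simulate(params, protocol, geometry, dt=dt, t_end=float(t_obs[-1]))
    V_true = np.interp(t_obs, traj.times, traj.V)
    d_true = _volume_to_diameter_um(V_true)
    if noise.pixel_scale > 0:
        d_true = np.round(d_true / noise.pixel_scale) * noise.pixel_scale
    rng = np.random.default_rng(noise.seed)
    for attempt in range(100):
        d = d_true + rng.normal(0.0, noise.diameter_sd, size=d_true.shape)
        if np.all(d > 0):
            break
        warnings.warn("noise produced a non-positive diameter; resampling")
    else:
        raise RuntimeError("could not draw a physical record in 100 attempts")
    rel = (d / d[0]) ** 3
    return VolumeRecord(
        times=t_obs,
        rel_volume=rel,
        protocol=protocol,
        geometry=geometry,
        label=label,
    )


def generate_osmolality_series(
    protocol: OsmoticProtocol = DEFAULT_HYPO_PROTOCOL,
    sampling_interval: float = 30.0,
    measurement_sd: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Aliquot series of the external osmolality over the whole record.

    Samples the forcing function every ``sampling_interval`` seconds from
    t = 0 to the protocol end and adds Gaussian measurement noise
    (mOsmol/Kgw).  Columns: ``time_s, osmolality_mosm``.
    """
    if sampling_interval <= 0:
        raise ValueError("sampling_interval must be positive")
    times = np.arange(0.0, protocol.t_end + 0.5 * sampling_interval, sampling_interval)
    values = external_osmolality(times, protocol)
    if measurement_sd > 0:
        rng = np.random.default_rng(seed)
        values = values + rng.normal(0.0, measurement_sd, size=times.shape)
    return pd.DataFrame({"time_s": times, "osmolality_mosm": values})


def fit_osmolality_decay(
    times,
    values,
    t_switch: float = 300.0,
) -> dict[str, float]:
    """Recover (B, t_star, Ce_star) from an aliquot series.

    Fits the single exponential to the samples strictly after the switch
    (the plateau and the clamped instant carry no information about the
    decay).  Exact round-trip on a noiseless generated series.
    """
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    mask = times > t_switch
    if mask.sum() < 3:
        raise ValueError("need at least 3 post-switch samples")
    t, v = times[mask], values[mask]

    def model(x, B, t_star, Ce_star):
        return B * np.exp(-x / t_star) + Ce_star

    ce0 = float(v[-1])
    ts0 = max((t[-1] - t[0]) / 3.0, 1.0)
    b0 = float((v[0] - ce0) * math.exp(t[0] / ts0))
    popt, _ = optimize.curve_fit(model, t, v, p0=[b0, ts0, ce0], maxfev=20000)
    return {"B": float(popt[0]), "t_star": float(popt[1]), "Ce_star": float(popt[2])}


@dataclass(frozen=True)
class CohortSpec:
    """Specification of a synthetic cohort of single-vacuole experiments.

    Per-record generating parameters are sampled log-normally around the
    condition means: ``Pf`` with coefficient of variation ``cv_pf`` and the
    ``Pf/Ps`` ratio with ``cv_ratio`` (``Ps`` derived), preserving the means
    and the tight per-vacuole coupling of the two permeabilities.  Vacuole
    diameters are drawn normally (um).  ``cv_* = 0`` fixes the parameters.
    """

    n_records: int
    params: ModelParameters
    protocol: OsmoticProtocol = DEFAULT_HYPO_PROTOCOL
    noise: NoiseModel = NoiseModel()
    seed: int = 0
    diameter_um_mean: float = 40.0
    diameter_um_sd: float = 0.0
    cv_pf: float = 0.0
    cv_ratio: float = 0.0
    label: str = ""

    def __post_init__(self) -> None:
        if self.n_records < 1:
            raise ValueError("n_records must be >= 1")
        if self.diameter_um_mean <= 0:
            raise ValueError("diameters must be positive")
        if self.cv_pf < 0 or self.cv_ratio < 0:
            raise ValueError("coefficients of variation must be non-negative")


def _lognormal_factor(rng: np.random.Generator, cv: float) -> float:
    # unit-mean log-normal multiplier with coefficient of variation cv
    if cv == 0:
        return 1.0
    sigma2 = math.log(1.0 + cv * cv)
    return float(rng.lognormal(-0.5 * sigma2, math.sqrt(sigma2)))


def generate_cohort(
    spec: CohortSpec,
) -> tuple[list[VolumeRecord], list[dict[str, float]]]:
    """Generate ``n_records`` independent records plus their ground truth.

    Per-record seeds are spawned from ``SeedSequence(spec.seed)``, so two
    cohorts with identical specs are identical.  Returns the records and a
    manifest of generating parameters (Pf, Ps, diameter, seed) per record.
    """
    ss = np.random.SeedSequence(spec.seed)
    children = ss.spawn(spec.n_records)
    records: list[VolumeRecord] = []
    truth: list[dict[str, float]] = []
    for i, child in enumerate(children):
        child_seed = int(child.generate_state(1)[0] % (2**31))
        rng = np.random.default_rng(child_seed)
        pf = spec.params.Pf * _lognormal_factor(rng, spec.cv_pf)
        kwargs: dict[str, float] = {"Pf": pf}
        if spec.params.model_id in ("WS", "WSNOV"):
            ratio = spec.params.Pf / spec.params.Ps
            ratio_i = ratio * _lognormal_factor(rng, spec.cv_ratio)
            kwargs["Ps"] = pf / ratio_i
        d_um = spec.diameter_um_mean
        if spec.diameter_um_sd > 0:
            d_um = float(rng.normal(spec.diameter_um_mean, spec.diameter_um_sd))
            if d_um <= 0:
                raise ValueError("sampled a non-positive diameter; narrow the spread")
        geometry = VacuoleGeometry.from_diameter_um(d_um)
        if spec.params.Vb > 0:
            # keep the non-osmotic fraction, not the absolute volume
            nominal_v0 = VacuoleGeometry.from_diameter_um(spec.diameter_um_mean).V0
            kwargs["Vb"] = spec.params.Vb / nominal_v0 * geometry.V0
        if spec.params.model_id == "WME":
            kwargs["eps_star"] = spec.params.eps_star
        params_i = ModelParameters(model_id=spec.params.model_id, **kwargs)
        record_seed = int(rng.integers(0, 2**31))
        record = generate_record(
            params_i,
            spec.protocol,
            geometry,
            replace(spec.noise, seed=record_seed),
            label=f"{spec.label}#{i}" if spec.label else f"record-{i}",
        )
        records.append(record)
        truth.append(
            {
                "index": i,
                "Pf": params_i.Pf,
                "Ps": params_i.Ps,
                "Vb": params_i.Vb,
                "eps_star": params_i.eps_star,
                "diameter_um": d_um,
                "seed": record_seed,
            }
        )
    return records, truth


def write_cohort(
    records: Sequence[VolumeRecord],
    truth: Sequence[dict[str, float]],
    out_dir,
    manifest_name: str = "manifest.json",
) -> Path:
    """Write per-record CSVs plus a JSON manifest with the ground truth."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    entries = []
    for i, (rec, info) in enumerate(zip(records, truth)):
        path = out / f"record_{i:03d}.csv"
        rec.to_csv(path)
        entries.append({"path": path.name, **info})
    manifest = out / manifest_name
    manifest.write_text(json.dumps({"records": entries}, indent=2), encoding="utf-8")
    return manifest
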