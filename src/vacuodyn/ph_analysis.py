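"""Cross-condition analyses of the fitted WS permeabilities.

The WS model reduces each record to a pair (Pf, Ps); per pH condition these
are summarized as mean +/- SEM, with the permeability ratio averaged over
per-record ratios (not taken as the ratio of means).  Two relationships are
then quantified:

* ``Pf/Ps`` versus pH follows a saturating exponential
  ``ratio = A * exp(-(pH - pH*) / pH') + ratio*`` with the reference pH*
  fixed (default 6.6, the most acidic condition);
* the steady relative volume ``Vf/V0`` is linear in ``Pf/Ps`` over the
  observed range, anchored near 1 at ratio 0 (no net water movement).

Both fits are unweighted by default (SEM weighting available by flag) and
report asymptotic 95% confidence intervals.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize, stats

from .fitting import FitResult, VolumeRecord

__all__ = [
    "ConditionSummary",
    "ExponentialPhFit",
    "LinearRatioFit",
    "summarize_conditions",
    "summaries_to_frame",
    "fit_ratio_vs_ph",
    "fit_vf_vs_ratio",
]


@dataclass
class ConditionSummary:
    """Per-pH summary of WS fits (mean +/- SEM; SEM is NaN when N = 1)."""

    ph: float
    pf_mean: float
    pf_sem: float
    ps_mean: float
    ps_sem: float
    ratio_mean: float
    ratio_sem: float
    vf_v0_mean: float
    vf_v0_sem: float
    n: int


@dataclass
class ExponentialPhFit:
    """Saturating-exponential fit of Pf/Ps versus pH (pH* held fixed)."""

    amplitude: float
    ph_prime: float
    ratio_star: float
    ph_star: float
    r2: float
    amplitude_ci95: float
    ph_prime_ci95: float
    ratio_star_ci95: float
    converged: bool


@dataclass
class LinearRatioFit:
    """OLS line of Vf/V0 versus Pf/Ps with 95% CI half-widths."""

    intercept: float
    slope: float
    r2: float
    intercept_ci95: float
    slope_ci95: float


def _mean_sem(values: np.ndarray) -> tuple[float, float]:
    n = values.size
    mean = float(np.mean(values))
    sem = float(np.std(values, ddof=1) / math.sqrt(n)) if n > 1 else float("nan")
    return mean, sem


def summarize_conditions(
    grouped: Mapping[float, Sequence[tuple[FitResult, VolumeRecord]]],
) -> list[ConditionSummary]:
    """Summarize WS fits grouped by condition (e.g. pH).

    ``grouped`` maps each condition value to its (fit, record) pairs.  The
    ratio column averages the per-record Pf/Ps values and the steady volume
    is each record's final observed relative volume.
    """
    out = []
    for ph in sorted(grouped):
        pairs = grouped[ph]
        if not pairs:
            raise ValueError(f"empty group for condition {ph}")
        pf = np.array([f.best_params.Pf for f, _ in pairs])
        ps = np.array([f.best_params.Ps for f, _ in pairs])
        ratio = pf / ps
        vf = np.array([r.rel_volume[-1] for _, r in pairs])
        pf_m, pf_s = _mean_sem(pf)
        ps_m, ps_s = _mean_sem(ps)
        ra_m, ra_s = _mean_sem(ratio)
        vf_m, vf_s = _mean_sem(vf)
        out.append(
            ConditionSummary(
                ph=float(ph),
                pf_mean=pf_m,
                pf_sem=pf_s,
                ps_mean=ps_m,
                ps_sem=ps_s,
                ratio_mean=ra_m,
                ratio_sem=ra_s,
                vf_v0_mean=vf_m,
                vf_v0_sem=vf_s,
                n=len(pairs),
            )
        )
    return out


def summaries_to_frame(summaries: Sequence[ConditionSummary]) -> pd.DataFrame:
    """Condition table with the canonical column layout."""
    return pd.DataFrame(
        [
            {
                "ph": s.ph,
                "pf_mean": s.pf_mean,
                "pf_sem": s.pf_sem,
                "ps_mean": s.ps_mean,
                "ps_sem": s.ps_sem,
                "ratio_mean": s.ratio_mean,
                "ratio_sem": s.ratio_sem,
                "vf_v0_mean": s.vf_v0_mean,
                "vf_v0_sem": s.vf_v0_sem,
                "n": s.n,
            }
            for s in summaries
        ]
    )


def fit_ratio_vs_ph(
    ph,
    ratio,
    ph_star: float = 6.6,
    sem=None,
    weighted: bool = False,
) -> ExponentialPhFit:
    """Fit ``ratio = A * exp(-(pH - pH*) / pH') + ratio*`` with pH* fixed.

    Unweighted nonlinear least squares by default; pass ``weighted=True``
    with per-point SEMs to weight residuals by 1/SEM.  Confidence intervals
    are asymptotic (t-based, 95%).

    Raises
    ------
    ValueError
        With fewer than 3 points, or if ``ph_star`` exceeds the smallest pH.
    """
    ph = np.asarray(ph, dtype=float)
    ratio = np.asarray(ratio, dtype=float)
    if ph.size < 3:
        raise ValueError("need at least 3 (pH, ratio) points")
    if ph_star > ph.min():
        raise ValueError("ph_star must not exceed the smallest pH")
    sigma = None
    if weighted:
        if sem is None:
            raise ValueError("weighted fit requires per-point SEMs")
        sigma = np.asarray(sem, dtype=float)

    def model(x, A, ph_prime, ratio_star):
        return A * np.exp(-(x - ph_star) / ph_prime) + ratio_star

    span = float(ph.max() - ph.min())
    if np.ptp(ratio) < 1e-12 * max(1.0, abs(ratio[0])):
        # constant data: amplitude 0, decay scale unidentifiable
        return ExponentialPhFit(
            amplitude=0.0,
            ph_prime=span / 3 if span > 0 else 1.0,
            ratio_star=float(np.mean(ratio)),
            ph_star=ph_star,
            r2=1.0,
            amplitude_ci95=0.0,
            ph_prime_ci95=float("nan"),
            ratio_star_ci95=0.0,
            converged=True,
        )
    p0 = [float(ratio[np.argmin(ph)] - ratio.max()), max(span / 3, 0.1), float(ratio.max())]
    try:
        popt, pcov = optimize.curve_fit(
            model, ph, ratio, p0=p0, sigma=sigma, maxfev=20000
        )
        converged = np.all(np.isfinite(pcov))
    except RuntimeError:
        popt, pcov = np.array(p0), np.full((3, 3), np.nan)
        converged = False
    resid = ratio - model(ph, *popt)
    ss_tot = float(np.sum((ratio - ratio.mean()) ** 2))
    r2 = 1.0 - float(resid @ resid) / ss_tot if ss_tot > 0 else 1.0
    dof = max(ph.size - 3, 1)
    tval = stats.t.ppf(0.975, dof)
    se = np.sqrt(np.diag(pcov))
    return ExponentialPhFit(
        amplitude=float(popt[0]),
        ph_prime=float(popt[1]),
        ratio_star=float(popt[2]),
        ph_star=ph_star,
        r2=max(min(r2, 1.0), 0.0),
        amplitude_ci95=float(tval * se[0]),
        ph_prime_ci95=float(tval * se[1]),
        ratio_star_ci95=float(tval * se[2]),
        converged=bool(converged),
    )


def fit_vf_vs_ratio(ratio, vf_v0) -> LinearRatioFit:
    """Ordinary least-squares line of steady volume versus Pf/Ps ratio."""
    x = np.asarray(ratio, dtype=float)
    y = np.asarray(vf_v0, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 points")
    if np.ptp(x) == 0:
        raise ValueError("identical x-values: the line is singular")
    res = sm.OLS(y, sm.add_constant(x)).fit()
    ci = res.conf_int(alpha=0.05)
    return LinearRatioFit(
        intercept=float(res.params[0]),
        slope=float(res.params[1]),
        r2=float(res.rsquared),
        intercept_ci95=float((ci[0, 1] - ci[0, 0]) / 2),
        slope_ci95=float((ci[1, 1] - ci[1, 0]) / 2),
    )
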