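"""Water-vapor ¹⁸O equilibration: dosing volumes and soil-water enrichment curves.

In vapor-equilibration qSIP the isotope label reaches the soil through the gas
phase: a reservoir of ¹⁸O-enriched water placed next to the sample equilibrates
with the soil water without changing its amount.  Two computations support this
design:

1. How much enriched water to place in the headspace so that, at full
   equilibration, the soil water reaches a target atom% ¹⁸O.  This is a simple
   two-component isotope mass balance solved for the added volume.
2. The *mean* soil-water enrichment over the incubation, obtained by fitting a
   saturating exponential ``e(t) = a·(1 − exp(−k·t))`` to a calibration time
   series and integrating it analytically over the incubation window.  The mean
   (not the plateau) is what enters taxon growth-rate denominators, because DNA
   synthesized early in the incubation saw a less-enriched water pool.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .errors import (
    CurveFitError,
    DegenerateSpecError,
    EmptyMixtureError,
    InfeasibleTargetError,
    InsufficientDataError,
)

__all__ = [
    "EquilibrationSpec",
    "EnrichmentCurve",
    "water_volume_for_target",
    "mix_enrichment",
    "fit_enrichment_curve",
    "fit_enrichment_curves",
    "mean_enrichment",
]

#: Natural abundance of ¹⁸O in water, atom percent.
NATURAL_ABUNDANCE_AT_PCT = 0.2


@dataclass(frozen=True)
class EquilibrationSpec:
    """One dosing problem: soil water volume and the three enrichments.

    Parameters
    ----------
    v_soil_water
        Volume of water already in the soil sample, µl.
    at_pct_target
        Desired soil-water enrichment at equilibrium, atom% ¹⁸O.
    at_pct_added
        Enrichment of the water placed in the headspace, atom% ¹⁸O.
    at_pct_na
        Natural-abundance enrichment of the soil water, atom% ¹⁸O.
    """

    v_soil_water: float
    at_pct_target: float
    at_pct_added: float
    at_pct_na: float = NATURAL_ABUNDANCE_AT_PCT

    def __post_init__(self):
        if self.v_soil_water < 0:
            raise ValueError("soil water volume must be non-negative")
        for name in ("at_pct_na", "at_pct_target", "at_pct_added"):
            v = getattr(self, name)
            if not (0.0 <= v <= 100.0):
                raise ValueError(f"{name}={v} outside [0, 100] atom%")


def water_volume_for_target(spec: EquilibrationSpec) -> float:
    """Volume (µl) of enriched water needed to bring soil water to the target.

    Solves the mass balance
    ``V = V_sw · (at%_NA − at%_target) / (at%_target − at%_added)``.

    Raises
    ------
    DegenerateSpecError
        If the added water has exactly the target enrichment (no finite volume
        can move the mixture there, or any volume keeps it there).
    InfeasibleTargetError
        If the solution is negative, i.e. the target lies outside the interval
        spanned by the soil water and the added water.
    """
    if spec.at_pct_added == spec.at_pct_target:
        raise DegenerateSpecError(
            "added water enrichment equals the target; dosing volume undefined"
        )
    v = (
        spec.v_soil_water
        * (spec.at_pct_na - spec.at_pct_target)
        / (spec.at_pct_target - spec.at_pct_added)
    )
    # exact hit of the starting enrichment yields 0 up to sign of rounding
    if v < 0 and not np.isclose(v, 0.0, atol=1e-12):
        raise InfeasibleTargetError(
            f"target {spec.at_pct_target} atom% unreachable with added water at "
            f"{spec.at_pct_added} atom% (negative volume {v:.4g} µl)"
        )
    return max(v, 0.0)


def mix_enrichment(v1: float, e1: float, v2: float, e2: float) -> float:
    """Enrichment (atom%) of a mixture of two water volumes.

    Volume-weighted mean; serves as the independent mass-balance check of
    :func:`water_volume_for_target`.
    """
    if v1 < 0 or v2 < 0:
        raise ValueError("volumes must be non-negative")
    total = v1 + v2
    if total <= 0:
        raise EmptyMixtureError("cannot mix two zero volumes")
    return (v1 * e1 + v2 * e2) / total


def mean_enrichment(plateau: float, rate: float, duration: float) -> float:
    """Time-averaged enrichment of ``a·(1 − exp(−k·t))`` over ``[0, T]``.

    Closed form ``a·(1 − (1 − exp(−kT))/(kT))``; small ``kT`` is evaluated by
    the series ``a·(kT/2 − (kT)²/6)`` to avoid catastrophic cancellation, and
    ``k = ∞`` (instantaneous equilibration) returns the plateau.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    if np.isinf(rate):
        return plateau
    kt = rate * duration
    if kt < 1e-6:
        return plateau * (kt / 2.0 - kt**2 / 6.0)
    return plateau * (1.0 + np.expm1(-kt) / kt)


@dataclass(frozen=True)
class EnrichmentCurve:
    """A fitted soil-water enrichment trajectory and its incubation mean."""

    times: np.ndarray
    values: np.ndarray
    plateau: float
    rate: float
    mean_enrichment: float
    duration: float
    residual_ss: float = field(default=0.0)

    def __call__(self, t):
        """Evaluate the fitted curve at time(s) ``t`` (hours)."""
        if np.isinf(self.rate):
            return np.full_like(np.asarray(t, dtype=float), self.plateau)
        return self.plateau * (1.0 - np.exp(-self.rate * np.asarray(t, dtype=float)))


def fit_enrichment_curve(times, values, duration: float) -> EnrichmentCurve:
    """Fit ``e(t) = a·(1 − exp(−k·t))`` and integrate it over the incubation.

    Parameters
    ----------
    times
        Sampling times in hours, strictly increasing, ≥ 0.
    values
        Measured atom% ¹⁸O at those times (excess above zero; the natural
        abundance baseline of ~0.2 atom% is small enough to ignore here and the
        curve is fitted without an offset).
    duration
        Incubation length T in hours over which the mean is taken.

    Returns
    -------
    EnrichmentCurve
        With fitted plateau ``a``, rate ``k`` (1/h) and the closed-form mean
        ``a·(1 − (1 − exp(−kT))/(kT))``.
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(values, dtype=float)
    if t.size < 3:
        raise InsufficientDataError(
            f"need at least 3 calibration points, got {t.size}"
        )
    if np.any(np.diff(t) <= 0):
        raise ValueError("times must be strictly increasing")
    if np.any(t < 0):
        raise ValueError("times must be non-negative")
    if np.any(y < 0):
        raise ValueError("enrichment values must be non-negative")

    if np.allclose(y, 0.0):
        return EnrichmentCurve(t, y, 0.0, 0.0, 0.0, duration, float(np.sum(y**2)))
    if np.allclose(y, y[0]):
        # flat non-zero series: instantaneous equilibration, k -> inf
        return EnrichmentCurve(t, y, float(y[0]), np.inf, float(y[0]), duration, 0.0)

    def model(tt, a, k):
        return a * (1.0 - np.exp(-k * tt))

    a0 = float(np.max(y))
    k0 = 1.0 / float(np.median(t[t > 0])) if np.any(t > 0) else 1.0
    try:
        popt, _ = curve_fit(
            model, t, y, p0=[a0, k0], bounds=([0.0, 0.0], [100.0, np.inf]),
            maxfev=10000,
        )
    except RuntimeError as exc:  # pragma: no cover - scipy convergence failure
        resid = y - model(t, a0, k0)
        raise CurveFitError(f"enrichment curve fit failed: {exc}", residuals=resid)
    a, k = float(popt[0]), float(popt[1])
    resid = y - model(t, a, k)
    return EnrichmentCurve(
        t, y, a, k, mean_enrichment(a, k, duration), duration,
        float(np.sum(resid**2)),
    )


def fit_enrichment_curves(
    calibration: pd.DataFrame,
    duration: float,
    group_col: str = "group",
    time_col: str = "time_h",
    value_col: str = "atom_pct_18O",
) -> pd.DataFrame:
    """Fit one enrichment curve per group of a calibration table.

    The grouping key is configurable so a single calibration sample per
    treatment (the study design) or one per tube both work.

    Returns a frame indexed by group with columns ``plateau``, ``rate``,
    ``mean_enrichment``, ``residual_ss``, ``n_points``.
    """
    rows = {}
    for group, sub in calibration.groupby(group_col, sort=True):
        sub = sub.sort_values(time_col)
        curve = fit_enrichment_curve(sub[time_col], sub[value_col], duration)
        rows[group] = {
            "plateau": curve.plateau,
            "rate": curve.rate,
            "mean_enrichment": curve.mean_enrichment,
            "residual_ss": curve.residual_ss,
            "n_points": len(sub),
        }
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = group_col
    return out
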