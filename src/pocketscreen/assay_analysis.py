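"""Quantification of the wet-lab validation assays.

Covers four readouts used to validate taxane-site binders:

* fluorescence tubulin-polymerization kinetics, normalized so that the
  paclitaxel reference end-point reads 100% and the global minimum 0%,
  summarized as Vmax (steepest 3-point slope, %/min) and MEP (the 30-min
  end-point, %), with fold changes against the DMSO control;
* microtubule-phenotype scoring (total abnormality count per cell);
* nocodazole-challenge polymer-state proportions;
* potency estimation — EC50 of growth-rate halving by log-linear
  interpolation of per-dose regression slopes, and EC50 of cell death at a
  fixed time by a four-parameter logistic (4PL) fit. "Not assigned" is an
  explicit outcome whenever the data cannot support an estimate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy.optimize import curve_fit
from scipy.stats import linregress

__all__ = [
    "PolymerizationCurve",
    "CurveStats",
    "PhenotypeCounts",
    "EC50Estimate",
    "PotencyResult",
    "normalize_polymerization",
    "curve_stats",
    "fold_changes",
    "phenotype_score",
    "polymer_state_proportions",
    "growth_ec50",
    "death_ec50",
]


@dataclass
class PolymerizationCurve:
    """One condition's fluorescence time course (times in minutes)."""

    condition: str
    times: np.ndarray
    readings: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.readings = np.asarray(self.readings, dtype=float)
        if self.times.shape != self.readings.shape:
            raise ValueError(f"{self.condition}: times and readings differ in length")
        if not np.all(np.diff(self.times) > 0):
            raise ValueError(f"{self.condition}: times must be strictly increasing")


@dataclass
class CurveStats:
    """Summary of one normalized polymerization curve."""

    condition: str
    vmax: float  # %/min
    mep: float  # % at final time point
    fc_vmax: Optional[float] = None
    fc_mep: Optional[float] = None
    classification: Optional[str] = None


@dataclass
class PhenotypeCounts:
    """Per-category microtubule abnormality counts for one condition.

    A cell may contribute to several categories, so the score can exceed 1.
    """

    condition: str
    counts: dict[str, int]
    n_cells: int

    def __post_init__(self) -> None:
        if self.n_cells <= 0:
            raise ValueError(f"{self.condition}: n_cells must be positive")
        if any(c < 0 for c in self.counts.values()):
            raise ValueError(f"{self.condition}: negative abnormality count")


@dataclass
class EC50Estimate:
    """An EC50 in µM, or an explicit not-assigned state with its reason."""

    value: Optional[float]
    reason: Optional[str] = None
    diagnostics: dict = field(default_factory=dict)

    @property
    def assigned(self) -> bool:
        return self.value is not None


@dataclass
class PotencyResult:
    """The three potency readouts of one compound."""

    condition: str
    ec50_p: EC50Estimate
    ec50_d24: EC50Estimate
    ec50_d48: EC50Estimate


# ---------------------------------------------------------------------------
# tubulin polymerization


def normalize_polymerization(
    curves: Sequence[PolymerizationCurve], tax_reference: str
) -> dict[str, PolymerizationCurve]:
    """Normalize a run of raw fluorescence curves to percent polymerization.

    The lowest reading across *all* curves of the run maps to 0% and the
    reference (paclitaxel) curve's final reading to 100%::

        norm(t) = 100 * (F(t) - F_min) / (F_ref(t_end) - F_min)
    """
    by_condition = {c.condition: c for c in curves}
    if tax_reference not in by_condition:
        raise ValueError(f"reference condition {tax_reference!r} not in run")
    f_min = min(float(c.readings.min()) for c in curves)
    ref_end = float(by_condition[tax_reference].readings[-1])
    span = ref_end - f_min
    if span <= 0:
        raise ValueError(
            "degenerate normalization: reference end-point equals the run minimum"
        )
    return {
        c.condition: PolymerizationCurve(
            condition=c.condition,
            times=c.times.copy(),
            readings=100.0 * (c.readings - f_min) / span,
        )
        for c in curves
    }


def curve_stats(norm_curve: PolymerizationCurve, window: int = 3) -> CurveStats:
    """Vmax (steepest least-squares slope over ``window`` consecutive points,
    %/min) and MEP (the final normalized value, %)."""
    n = len(norm_curve.times)
    if n < window:
        raise ValueError(
            f"{norm_curve.condition}: need at least {window} points, got {n}"
        )
    slopes = []
    for i in range(n - window + 1):
        t = norm_curve.times[i : i + window]
        y = norm_curve.readings[i : i + window]
        slope = np.polyfit(t, y, 1)[0]
        slopes.append(slope)
    return CurveStats(
        condition=norm_curve.condition,
        vmax=float(max(slopes)),
        mep=float(norm_curve.readings[-1]),
    )


def fold_changes(
    stats: CurveStats, dmso: CurveStats, threshold: float = 1.0
) -> CurveStats:
    """Fold changes of Vmax and MEP over the DMSO control, and the resulting
    classification: "enhancer" iff both FCs exceed the threshold,
    "suppressor" iff both are below it, otherwise "mixed"."""
    if dmso.vmax <= 0 or dmso.mep <= 0:
        raise ValueError("DMSO reference statistics must be positive")
    fc_vmax = stats.vmax / dmso.vmax
    fc_mep = stats.mep / dmso.mep
    if fc_vmax > threshold and fc_mep > threshold:
        cls = "enhancer"
    elif fc_vmax < threshold and fc_mep < threshold:
        cls = "suppressor"
    else:
        cls = "mixed"
    return CurveStats(
        condition=stats.condition,
        vmax=stats.vmax,
        mep=stats.mep,
        fc_vmax=float(fc_vmax),
        fc_mep=float(fc_mep),
        classification=cls,
    )


# ---------------------------------------------------------------------------
# cell phenotypes


def phenotype_score(counts: PhenotypeCounts) -> float:
    """Average abnormalities per cell: total category counts / cells scored."""
    return float(sum(counts.counts.values()) / counts.n_cells)


def polymer_state_proportions(n_polymerized: int, n_total: int) -> tuple[float, float]:
    """(polymerized, soluble) cell fractions after a depolymerization challenge."""
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    if not 0 <= n_polymerized <= n_total:
        raise ValueError("n_polymerized must lie in [0, n_total]")
    p = n_polymerized / n_total
    return (p, 1.0 - p)


# ---------------------------------------------------------------------------
# potency


def _series_slope(times: np.ndarray, values: np.ndarray) -> float:
    if len(times) < 2:
        raise ValueError("need at least two time points per series")
    return float(linregress(times, values).slope)


def growth_ec50(
    series: Mapping[float, tuple[Sequence[float], Sequence[float]]],
    vehicle: tuple[Sequence[float], Sequence[float]],
) -> EC50Estimate:
    """EC50 of proliferation inhibition from confluence time series.

    Each dose's growth rate is its least-squares confluence slope; the EC50
    is the concentration at which the rate crosses half the vehicle rate,
    interpolated linearly in log10 concentration between the bracketing
    doses. Not assigned when the vehicle rate is non-positive or no dose
    pair brackets the half rate.
    """
    if len(series) < 2:
        return EC50Estimate(None, reason="fewer than two concentrations")
    v_slope = _series_slope(np.asarray(vehicle[0], float), np.asarray(vehicle[1], float))
    if v_slope <= 0:
        return EC50Estimate(None, reason="vehicle growth rate is non-positive",
                            diagnostics={"vehicle_slope": v_slope})
    target = 0.5 * v_slope
    concs = sorted(series)
    slopes = {
        c: _series_slope(np.asarray(series[c][0], float), np.asarray(series[c][1], float))
        for c in concs
    }
    diags = {"vehicle_slope": v_slope, "slopes": slopes, "target": target}
    for c_lo, c_hi in zip(concs, concs[1:]):
        s_lo, s_hi = slopes[c_lo], slopes[c_hi]
        if s_lo >= target >= s_hi and s_lo != s_hi:
            frac = (s_lo - target) / (s_lo - s_hi)
            log_ec50 = np.log10(c_lo) + frac * (np.log10(c_hi) - np.log10(c_lo))
            return EC50Estimate(float(10 ** log_ec50), diagnostics=diags)
    return EC50Estimate(None, reason="no dose pair brackets the half growth rate",
                        diagnostics=diags)


def _four_pl(log_c: np.ndarray, floor: float, ceil: float, log_ec50: float, hill: float) -> np.ndarray:
    return floor + (ceil - floor) / (1.0 + 10 ** (hill * (log_ec50 - log_c)))


def death_ec50(
    concentrations: Sequence[float],
    dead_fractions: Sequence[float],
    min_span: float = 0.1,
) -> EC50Estimate:
    """EC50 of cell death at a fixed time from dose–response fractions.

    Least-squares 4PL fit on log10 concentration with the floor constrained
    non-negative; the estimate is the fitted midpoint. Not assigned with
    fewer than 4 doses, on non-convergence, or when the fitted response
    span (ceiling - floor) is below ``min_span`` (10% of the full [0, 1]
    response range by default, i.e. effectively flat data).
    """
    c = np.asarray(concentrations, dtype=float)
    y = np.asarray(dead_fractions, dtype=float)
    if c.shape != y.shape:
        raise ValueError("concentrations and responses differ in length")
    if len(np.unique(c)) < 4:
        return EC50Estimate(None, reason="fewer than 4 distinct concentrations")
    if np.any(c <= 0):
        raise ValueError("concentrations must be positive")
    if np.any((y < 0) | (y > 1)):
        raise ValueError("dead fractions must lie in [0, 1]")
    log_c = np.log10(c)
    p0 = [max(float(y.min()), 0.0), min(float(y.max()), 1.0), float(np.median(log_c)), 1.0]
    if p0[1] - p0[0] < 1e-6:
        p0[1] = p0[0] + 0.1
    try:
        popt, _ = curve_fit(
            _four_pl,
            log_c,
            y,
            p0=p0,
            bounds=([0.0, 0.0, log_c.min() - 3, 0.05], [1.0, 1.5, log_c.max() + 3, 10.0]),
            maxfev=20000,
            xtol=1e-14,
            ftol=1e-14,
            gtol=1e-14,
        )
    except (RuntimeError, ValueError) as exc:
        return EC50Estimate(None, reason=f"4PL fit failed: {exc}")
    floor, ceil, log_ec50, hill = (float(v) for v in popt)
    diags = {"floor": floor, "ceiling": ceil, "hill": hill}
    if ceil - floor < min_span:
        return EC50Estimate(None, reason="fitted response span below 10% of range",
                            diagnostics=diags)
    return EC50Estimate(float(10 ** log_ec50), diagnostics=diags)
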