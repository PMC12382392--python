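"""Dose-response curve fitting and optimal-dosage aggregation.

Each smartphone-derived feature (or measured trait) is regressed on nitrogen
dosage with an ordinary-least-squares quadratic in u = √dose; the square-root
transform normalizes the right-skewed dose design (20–800 ppm). A concave fit
with its vertex inside the observed dose range yields an interior peak dose
(back-transformed as peak_u²). Peaks are averaged within the spectral and the
structural feature group, and the overall optimal dosage is the mean of the
two group means.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "DoseResponseFit", "OptimalDoseResult",
    "fit_curve", "aggregate_optimal", "compare_polynomial_orders",
]

_INTERIOR_TYPES = ("interior-max", "interior-min")


@dataclass(frozen=True)
class DoseResponseFit:
    """Quadratic fit y = a·u² + b·u + c with u = √dose, plus its peak.

    ``peak_type`` is "interior-max" (concave, vertex in range),
    "interior-min" (convex vertex in range, only reported when the caller
    asks for extrema of either sign — inverse indices such as ExR),
    "boundary" (vertex outside the dose range, clamped and flagged, never
    extrapolated), or "non-concave".
    """

    feature: str
    a: float
    b: float
    c: float
    r2: float
    se: float
    peak_u: float
    peak_dose_ppm: float
    peak_type: str

    @property
    def interior(self) -> bool:
        return self.peak_type in _INTERIOR_TYPES


@dataclass(frozen=True)
class OptimalDoseResult:
    """Group-mean peak dosages and their overall mean (the optimum)."""

    group_peaks: Mapping[str, float]
    optimal_dose_ppm: float
    contributing: Mapping[str, tuple[str, ...]]
    excluded: tuple[str, ...]


def fit_curve(
    doses: Sequence[float],
    values: Sequence[float],
    feature: str = "",
    extremum: str = "max",
) -> DoseResponseFit:
    """OLS quadratic of a response on √dose with peak location.

    With ``extremum="max"`` (default) only a concave fit can report an
    interior peak; ``extremum="either"`` also reports the vertex of a convex
    fit as "interior-min" (the vertex location of y and −y coincide), which
    lets inversely-responding indices contribute a dose optimum.

    Raises
    ------
    ValueError
        if fewer than 3 distinct dose levels are present (rank-deficient).
    """
    doses = np.asarray(doses, dtype=float)
    values = np.asarray(values, dtype=float)
    if doses.shape != values.shape or doses.size == 0:
        raise ValueError("doses and values must be equal-length, nonempty")
    if np.any(doses < 0) or not np.all(np.isfinite(values)):
        raise ValueError("doses must be non-negative and values finite")
    if extremum not in ("max", "either"):
        raise ValueError("extremum must be 'max' or 'either'")
    u = np.sqrt(doses)
    if len(np.unique(u)) < 3:
        raise ValueError("rank-deficient fit: need at least 3 distinct dose levels")

    # polynomial.polyfit returns ascending coefficients (c, b, a)
    c, b, a = np.polynomial.polynomial.polyfit(u, values, 2)
    fitted = a * u**2 + b * u + c
    resid = values - fitted
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((values - values.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else (1.0 if ss_res == 0 else float("nan"))
    dof = len(values) - 3
    se = float(np.sqrt(ss_res / dof)) if dof > 0 else float("nan")

    u_min, u_max = float(u.min()), float(u.max())
    peak_u = peak_dose = float("nan")
    if a < 0 or (a > 0 and extremum == "either"):
        vertex = -b / (2.0 * a)
        if u_min <= vertex <= u_max:
            peak_u = float(vertex)
            peak_dose = peak_u**2
            peak_type = "interior-max" if a < 0 else "interior-min"
        elif a < 0:
            peak_u = float(np.clip(vertex, u_min, u_max))
            peak_dose = peak_u**2
            peak_type = "boundary"
        else:
            peak_type = "non-concave"
    else:
        peak_type = "non-concave"

    return DoseResponseFit(
        feature=feature, a=float(a), b=float(b), c=float(c), r2=float(r2),
        se=se, peak_u=peak_u, peak_dose_ppm=peak_dose, peak_type=peak_type,
    )


def aggregate_optimal(
    fits: Sequence[DoseResponseFit],
    groups: Mapping[str, str],
) -> OptimalDoseResult:
    """Average interior peak dosages within groups, then across group means.

    ``groups`` maps feature name → group label (e.g. "spectral" /
    "structural"). Fits without an interior extremum are excluded and listed.

    Raises
    ------
    ValueError
        if any group contributes no interior peak.
    """
    by_group: dict[str, list[float]] = {g: [] for g in dict.fromkeys(groups.values())}
    contributing: dict[str, list[str]] = {g: [] for g in by_group}
    excluded: list[str] = []
    for fit in fits:
        if fit.feature not in groups:
            continue
        g = groups[fit.feature]
        if fit.interior:
            by_group[g].append(fit.peak_dose_ppm)
            contributing[g].append(fit.feature)
        else:
            excluded.append(fit.feature)

    empty = [g for g, peaks in by_group.items() if not peaks]
    if empty:
        raise ValueError(f"no interior dose-response peak in group(s): {empty}")

    group_peaks = {g: float(np.mean(p)) for g, p in by_group.items()}
    optimum = float(np.mean(list(group_peaks.values())))
    return OptimalDoseResult(
        group_peaks=group_peaks,
        optimal_dose_ppm=optimum,
        contributing={g: tuple(v) for g, v in contributing.items()},
        excluded=tuple(excluded),
    )


def compare_polynomial_orders(
    doses: Sequence[float],
    values: Sequence[float],
    orders: Sequence[int] = (1, 2, 3),
) -> dict[int, float]:
    """Small-sample-corrected AIC of polynomial fits in u = √dose, per order.

    AICc = n·log(RSS/n) + 2k + 2k(k+1)/(n−k−1) with k = order + 1
    parameters; lower is better. Used to check that a quadratic generating
    curve is indeed selected over linear and cubic alternatives.
    """
    doses = np.asarray(doses, dtype=float)
    values = np.asarray(values, dtype=float)
    u = np.sqrt(doses)
    n = len(values)
    scores: dict[int, float] = {}
    for order in orders:
        k = order + 1
        if n - k - 1 <= 0:
            scores[order] = float("inf")
            continue
        coef = np.polynomial.polynomial.polyfit(u, values, order)
        fitted = np.polynomial.polynomial.polyval(u, coef)
        rss = float(np.sum((values - fitted) ** 2))
        rss = max(rss, 1e-300)  # guard log(0) for exact fits
        scores[order] = n * np.log(rss / n) + 2 * k + 2 * k * (k + 1) / (n - k - 1)
    return scores
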