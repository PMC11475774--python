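"""Gaussian signal-detection-theory primitives for diagnostic morphometry.

This module implements the binormal ideal-observer toolkit used throughout
the package: the detectability index ``d_a`` (the standardized separation
between a signal group, e.g. AD patients, and a background group, e.g.
normal controls, on one imaging biomarker), its closed-form relation to the
area under the ROC curve, the likelihood-ratio (ideal-observer) cut-off at
the crossing of the two class densities, criterion-level sensitivity and
specificity, and a tie-aware empirical ROC.

Conventions
-----------
* ``d_a = (mu_background - mu_signal) / sqrt((sigma_s^2 + sigma_b^2) / 2)``.
  The sign is kept (atrophy markers give positive ``d_a`` when the signal
  group has the smaller mean; ventricle dilation gives negative ``d_a``),
  while AUC is computed from the magnitude so any informative feature has
  AUC >= 0.5.
* AUC under the binormal model is ``1/2 + 1/2 * erf(|d_a| / 2)``, i.e. the
  standard-normal CDF at ``|d_a| / sqrt(2)``.
* Percent change between group means defaults to the symmetric convention
  ``100 * (comparison - reference) / mean(comparison, reference)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy import special, stats

__all__ = [
    "GroupStats",
    "GaussianPair",
    "DetectabilityResult",
    "RocCurve",
    "detectability_index",
    "auc_from_d",
    "d_from_auc",
    "percent_change",
    "ideal_observer_cutoff",
    "criterion_performance",
    "cutoff_for_sensitivity",
    "empirical_roc",
    "cumulative_distribution",
]

Direction = Literal["low", "high"]
_SQRT2 = math.sqrt(2.0)


@dataclass(frozen=True)
class GroupStats:
    """Mean, standard deviation and optional size of one diagnostic group.

    Units follow the underlying feature (mm for thickness, mm^2 for surface
    area, mm^3 for volume). ``sd`` must be strictly positive; ``n``, when
    given, must be at least 2 (a single subject has no spread).
    """

    mean: float
    sd: float
    n: int | None = None

    def __post_init__(self) -> None:
        if not math.isfinite(self.mean):
            raise ValueError(f"group mean must be finite, got {self.mean!r}")
        if not (self.sd > 0) or not math.isfinite(self.sd):
            raise ValueError(f"group sd must be finite and > 0, got {self.sd!r}")
        if self.n is not None and self.n < 2:
            raise ValueError(f"group n must be >= 2 when given, got {self.n!r}")


@dataclass(frozen=True)
class GaussianPair:
    """A signal/background pair of Gaussian class models on one biomarker.

    ``signal`` is the diseased group (e.g. AD), ``background`` the reference
    group (e.g. NC). The likelihood ratio of the two densities drives the
    ideal-observer cut-off.
    """

    signal: GroupStats
    background: GroupStats
    decision_variable: str = ""
    units: str = ""


@dataclass(frozen=True)
class DetectabilityResult:
    """Detectability of one feature for one ordered group pair.

    ``d_a`` keeps the (background - signal) sign; ``auc`` is computed from
    its magnitude. ``cutoff`` is the ideal-observer criterion (NaN when the
    two class densities never cross between the means).
    """

    feature: str
    pair: str
    d_a: float
    auc: float
    percent_change: float
    cutoff: float


@dataclass(frozen=True)
class RocCurve:
    """An empirical ROC step curve with its trapezoidal area.

    ``points`` runs from (0, 0) to (1, 1), non-decreasing in both
    coordinates; ``auc`` equals the trapezoidal area of the points and, by
    construction, the tie-corrected Mann-Whitney concordance probability.
    """

    points: np.ndarray
    auc: float

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        object.__setattr__(self, "points", pts)


def detectability_index(signal: GroupStats, background: GroupStats) -> float:
    """Detectability index ``d_a`` of a signal group against background.

    ``d_a = (mu_b - mu_s) / sqrt((sigma_s^2 + sigma_b^2) / 2)`` — the mean
    separation in units of the root-mean-square class SD. Antisymmetric
    under swapping the groups.

    Examples
    --------
    >>> ad = GroupStats(2.743, 0.458)   # entorhinal thickness, AD
    >>> nc = GroupStats(3.370, 0.278)   # entorhinal thickness, NC
    >>> round(detectability_index(ad, nc), 3)
    1.655
    """
    rms_sd = math.sqrt(0.5 * signal.sd**2 + 0.5 * background.sd**2)
    return (background.mean - signal.mean) / rms_sd


def auc_from_d(d_a: float) -> float:
    """Binormal AUC implied by a detectability index.

    ``AUC = 1/2 + 1/2 * erf(d_a / 2)``, the standard-normal CDF at
    ``d_a / sqrt(2)``; strictly increasing, with ``auc_from_d(0) = 0.5``.
    Pass ``abs(d_a)`` for the direction-free diagnostic accuracy.
    """
    if not math.isfinite(d_a):
        raise ValueError(f"d_a must be finite, got {d_a!r}")
    return 0.5 + 0.5 * special.erf(d_a / 2.0)


def d_from_auc(auc: float) -> float:
    """Inverse of :func:`auc_from_d`: ``d_a = 2 * erfinv(2 * AUC - 1)``."""
    if not 0.0 < auc < 1.0:
        raise ValueError(f"auc must lie strictly in (0, 1), got {auc!r}")
    return 2.0 * special.erfinv(2.0 * auc - 1.0)


def percent_change(
    reference: GroupStats,
    comparison: GroupStats,
    *,
    convention: Literal["symmetric", "plain"] = "symmetric",
) -> float:
    """Signed percent change of ``comparison`` relative to ``reference``.

    The default symmetric convention divides by the midpoint of the two
    means, ``100 * (c - r) / ((c + r) / 2)``, and is antisymmetric under
    swapping the groups; ``convention="plain"`` divides by the reference
    mean instead.
    """
    r, c = reference.mean, comparison.mean
    if convention == "plain":
        if r <= 0:
            raise ValueError("plain percent change needs a positive reference mean")
        return 100.0 * (c - r) / r
    denom = 0.5 * (c + r)
    if denom <= 0:
        raise ValueError("symmetric percent change needs mean(c, r) > 0")
    return 100.0 * (c - r) / denom


def _density_crossings(s: GroupStats, b: GroupStats) -> np.ndarray:
    """Roots of ln f_signal(t) - ln f_background(t) = 0, ascending."""
    if math.isclose(s.sd, b.sd, rel_tol=1e-12):
        if math.isclose(s.mean, b.mean, rel_tol=0, abs_tol=1e-300):
            raise ValueError(
                "identical class distributions: every criterion is equivalent, "
                "no unique ideal-observer cut-off exists"
            )
        return np.array([0.5 * (s.mean + b.mean)])
    # unequal variances: quadratic a t^2 + b t + c = 0
    a = 1.0 / (2.0 * b.sd**2) - 1.0 / (2.0 * s.sd**2)
    lin = s.mean / s.sd**2 - b.mean / b.sd**2
    const = b.mean**2 / (2.0 * b.sd**2) - s.mean**2 / (2.0 * s.sd**2) - math.log(
        s.sd / b.sd
    )
    disc = lin**2 - 4.0 * a * const
    if disc < 0:
        raise ValueError("class densities have no real crossing")
    sq = math.sqrt(disc)
    return np.sort(np.array([(-lin - sq) / (2 * a), (-lin + sq) / (2 * a)]))


def ideal_observer_cutoff(pair: GaussianPair) -> float:
    """Likelihood-ratio cut-off: the density crossing between the two means.

    The ideal observer classifies at ``f_signal(t) = f_background(t)``
    (equivalently ``ln f_s - ln f_b = 0``), which maximizes dichotomous
    accuracy under equal priors. With unequal class SDs the crossing
    equation is quadratic; the root lying strictly between the two means is
    the clinically meaningful criterion and is returned. The other root sits
    in both far tails.

    Examples
    --------
    >>> pair = GaussianPair(GroupStats(2.743, 0.458), GroupStats(3.370, 0.278))
    >>> round(ideal_observer_cutoff(pair), 2)
    3.04
    """
    s, b = pair.signal, pair.background
    roots = _density_crossings(s, b)
    lo, hi = sorted((s.mean, b.mean))
    between = [t for t in roots if lo < t < hi]
    if not between:
        raise ValueError(
            "no density crossing strictly between the group means; "
            f"crossings at {roots.tolist()} for means ({s.mean}, {b.mean})"
        )
    return float(between[0])


def criterion_performance(
    pair: GaussianPair, cutoff: float, direction: Direction = "low"
) -> tuple[float, float, float]:
    """Sensitivity, specificity and balanced accuracy at a given criterion.

    ``direction="low"`` means low values indicate signal (atrophy markers:
    thinner cortex / smaller volume in disease); ``"high"`` the reverse
    (ventricle dilation). Sensitivity is the Gaussian mass of the signal
    class on the signal side of the cut-off, specificity the background
    mass on the other side; balanced accuracy is their mean.
    """
    s, b = pair.signal, pair.background
    if direction == "low":
        sens = stats.norm.cdf(cutoff, s.mean, s.sd)
        spec = stats.norm.sf(cutoff, b.mean, b.sd)
    elif direction == "high":
        sens = stats.norm.sf(cutoff, s.mean, s.sd)
        spec = stats.norm.cdf(cutoff, b.mean, b.sd)
    else:  # pragma: no cover - guarded by typing
        raise ValueError(f"direction must be 'low' or 'high', got {direction!r}")
    return float(sens), float(spec), float(0.5 * (sens + spec))


def cutoff_for_sensitivity(
    signal: GroupStats, target_sensitivity: float, direction: Direction = "low"
) -> float:
    """Criterion achieving an exact target sensitivity under the signal model.

    For ``direction="low"`` this is the ``target``-quantile of the signal
    Gaussian; e.g. a 95% sensitivity criterion sits at
    ``mean + 1.6449 * sd``.
    """
    if not 0.0 < target_sensitivity < 1.0:
        raise ValueError("target sensitivity must lie strictly in (0, 1)")
    if direction == "low":
        return float(stats.norm.ppf(target_sensitivity, signal.mean, signal.sd))
    return float(stats.norm.isf(target_sensitivity, signal.mean, signal.sd))


def empirical_roc(
    scores: Sequence[float],
    labels: Sequence[int],
    direction: Direction = "high",
) -> RocCurve:
    """Empirical ROC curve and tie-corrected AUC from scored subjects.

    ``labels`` are binary (1 = signal class); ``direction="high"`` means
    larger scores indicate signal. Tied scores receive half credit, so the
    AUC equals the Mann-Whitney concordance probability
    ``(#{s > b} + 0.5 * #{s = b}) / (n1 * n0)`` and the curve walks tie
    groups diagonally. Invariant under strictly monotone score transforms.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValueError("scores and labels must be equal-length 1-D sequences")
    pos = labels == 1
    n1, n0 = int(pos.sum()), int((~pos).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("empirical ROC needs both classes non-empty")
    if direction == "low":
        scores = -scores
    # walk distinct scores from most to least signal-like
    order = np.argsort(-scores, kind="mergesort")
    sorted_scores = scores[order]
    sorted_pos = pos[order].astype(float)
    # indices where a new distinct score block ends
    distinct = np.nonzero(np.r_[np.diff(sorted_scores) != 0, True])[0]
    tp = np.cumsum(sorted_pos)[distinct]
    fp = (distinct + 1) - tp
    tpr = np.r_[0.0, tp / n1]
    fpr = np.r_[0.0, fp / n0]
    auc = float(np.trapezoid(tpr, fpr))
    return RocCurve(points=np.column_stack([fpr, tpr]), auc=auc)


def cumulative_distribution(
    values: Sequence[float],
    grid: Sequence[float],
    normalized: bool = False,
) -> np.ndarray:
    """Cumulative case counts (or empirical CDF) over an ascending grid.

    Returns, for each grid point ``g``, the number of values ``<= g`` —
    the sigmoid-shaped cumulative case-number curve whose slope is
    inversely proportional to the group SD. With ``normalized=True`` the
    counts are divided by the total, giving the empirical CDF on the grid.
    """
    values = np.asarray(values, dtype=float)
    grid = np.asarray(grid, dtype=float)
    if values.size == 0:
        raise ValueError("cumulative_distribution needs at least one value")
    if np.any(np.diff(grid) < 0):
        raise ValueError("grid must be sorted ascending")
    counts = np.searchsorted(np.sort(values), grid, side="right").astype(float)
    if normalized:
        counts /= values.size
    return counts
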