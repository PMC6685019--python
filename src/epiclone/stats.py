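"""Clone-size statistics for neutrality inference.

The central object is the first incomplete moment of the clone-size
distribution,

    mu1(n) = sum_{m >= n} m * P_m / sum_{m >= 1} m * P_m,

where ``P_m`` is the proportion of surviving clones of size ``m``: mu1(n) is
the fraction of all mutant cells residing in clones of size n or larger.
Normalising by the mean clone size makes mu1 equal to 1 at and below the
smallest observed size ``m``.  Under neutral drift the clone-size
distribution is asymptotically exponential, so the log first incomplete
moment (LFIM) is a straight line; departure from straightness is quantified
with a coefficient of determination R² for a line constrained through the
anchor point (m, 1) — i.e. (m, 0) in log space.  Because of the constraint,
R² can be negative.

The module also provides the simulation dN/dS (observed non-neutral to
neutral clone counts, normalised by the known intake ratio), ROC/AUC
evaluation of R² as a neutrality classifier, curve averaging across
replicate simulations, one-sided rank-sum comparisons, and the composition
of clone-size intervals by mutation label.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn import metrics as skm


@dataclass(frozen=True)
class IncompleteMomentCurve:
    """First incomplete moment evaluated on the observed size support."""

    n: np.ndarray  # ascending clone sizes (distinct observed values)
    mu1: np.ndarray  # mu1 at each support point, in (0, 1]
    m: int  # smallest observed clone size

    def __post_init__(self):
        if self.n.size == 0:
            raise ValueError("empty incomplete-moment curve")

    def at(self, sizes: np.ndarray) -> np.ndarray:
        """Step-function evaluation: mu1(x) = mu1 at the largest support
        point <= x; 1 below the support, 0 beyond the largest clone."""
        sizes = np.asarray(sizes)
        idx = np.searchsorted(self.n, sizes, side="right") - 1
        out = np.ones(sizes.shape, dtype=float)
        inside = idx >= 0
        out[inside] = self.mu1[idx[inside]]
        out[sizes > self.n[-1]] = 0.0
        return out


@dataclass(frozen=True)
class FitResult:
    """Constrained straight-line fit of the LFIM.

    The line is anchored at (m, 0) in (size, log mu1) space; ``slope`` has
    units 1/cells.  ``r2`` uses SS_tot about the mean of the fitted points
    and may be negative.  ``fraction_used`` < 1 restricts the fit to the
    smallest fraction of the clone multiset.
    """

    slope: float
    m: int
    r2: float
    fraction_used: float = 1.0
    n_points: int = 0

    def predict_log(self, sizes: np.ndarray) -> np.ndarray:
        return self.slope * (np.asarray(sizes, dtype=float) - self.m)


@dataclass(frozen=True)
class RocResult:
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float


def first_incomplete_moment(sizes) -> IncompleteMomentCurve:
    """First incomplete moment of a clone-size multiset.

    ``sizes`` are surviving clone sizes — positive, in any unit (cells for
    simulated tissue, mm² for cohort data).  The curve is evaluated at each
    distinct observed size; mu1 at the smallest size is exactly 1.
    """
    sizes = np.asarray(sizes, dtype=float)
    if sizes.size == 0:
        raise ValueError("cannot compute incomplete moment of no clones")
    if np.any(sizes <= 0):
        raise ValueError("clone sizes must be positive")
    support, counts = np.unique(sizes, return_counts=True)
    mass = support * counts  # sum of cells in clones of each size
    tail = np.cumsum(mass[::-1])[::-1]
    mu1 = tail / tail[0]
    return IncompleteMomentCurve(n=support, mu1=mu1, m=int(support[0]))


def constrained_lfim_r2(
    sizes,
    fraction_used: float = 1.0,
    weight_by_counts: bool = False,
) -> FitResult:
    """Straight-line fit of log mu1 constrained through (m, 0).

    One point per distinct observed clone size enters the fit by default;
    ``weight_by_counts`` weights each point by its clone count instead.
    ``fraction_used`` < 1 fits only support points at or below the
    ``fraction_used`` quantile of the clone-size multiset (e.g. the smallest
    75% of clones).

    Least squares through the anchor: slope = sum(w x y) / sum(w x²) with
    x = n − m, y = log mu1.  R² = 1 − SS_res/SS_tot with SS_tot about the
    (weighted) mean of the fitted y values, hence possibly negative.
    """
    sizes = np.asarray(sizes, dtype=float)
    curve = first_incomplete_moment(sizes)
    n, mu1 = curve.n, curve.mu1
    if not 0 < fraction_used <= 1:
        raise ValueError("fraction_used must lie in (0, 1]")
    if fraction_used < 1.0:
        cutoff = np.quantile(sizes, fraction_used)
        keep = n <= cutoff
        if keep.sum() < 2:  # degenerate restriction: fall back to full support
            keep = np.ones(n.size, dtype=bool)
        n, mu1 = n[keep], mu1[keep]
    if n.size < 2:
        raise ValueError("constrained fit requires >= 2 distinct clone sizes")
    x = n - curve.m
    y = np.log(mu1)
    if weight_by_counts:
        support, counts = np.unique(sizes, return_counts=True)
        w = counts[np.searchsorted(support, n)].astype(float)
    else:
        w = np.ones_like(x)
    slope = float(np.sum(w * x * y) / np.sum(w * x * x))
    resid = y - slope * x
    ss_res = float(np.sum(w * resid**2))
    ybar = float(np.sum(w * y) / np.sum(w))
    ss_tot = float(np.sum(w * (y - ybar) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return FitResult(
        slope=slope, m=curve.m, r2=float(r2),
        fraction_used=float(fraction_used), n_points=int(n.size),
    )


def lfim_tail_deviation(
    sizes, fraction_used: float = 0.75, min_size: float = 0.0
) -> float:
    """RMS deviation of the (visible) LFIM from the straight line fitted to
    its smallest clones.

    Clones below ``min_size`` (the detection limit) are discarded; a
    constrained line is fitted to the smallest ``fraction_used`` of the
    remaining clones and the root-mean-square residual of log mu1 about that
    line is computed over the whole visible support.  Early in a non-neutral
    tissue only the fast-growing clones are visible and the statistic is
    small; it grows once slower clones cross the detection limit and bend
    the curve.
    """
    sizes = np.asarray(sizes, dtype=float)
    vis = sizes[sizes >= min_size]
    if np.unique(vis).size < 2:
        raise ValueError("need >= 2 distinct visible clone sizes")
    fit = constrained_lfim_r2(vis, fraction_used=fraction_used)
    curve = first_incomplete_moment(vis)
    resid = np.log(curve.mu1) - fit.predict_log(curve.n)
    return float(np.sqrt(np.mean(resid**2)))


def average_curves(curves: list[IncompleteMomentCurve]) -> IncompleteMomentCurve:
    """Pointwise mean of incomplete-moment curves on the union of supports.

    Each curve is extended to the common grid as a step function (1 below
    its support, 0 beyond its largest clone), mirroring how replicate
    simulations with different size ranges are averaged into one curve.
    """
    if not curves:
        raise ValueError("no curves to average")
    grid = np.unique(np.concatenate([c.n for c in curves]))
    mean = np.mean([c.at(grid) for c in curves], axis=0)
    return IncompleteMomentCurve(n=grid, mu1=mean, m=int(grid[0]))


def dnds_ratio(n_observed_n: int, n_observed_s: int, a: float) -> float:
    """Simulation dN/dS: observed non-neutral over neutral clone counts,
    normalised by the known intake ratio ``a`` = (introduced N)/(introduced S).

    Equals 1 when labels are exchangeable with respect to survival; > 1 when
    non-neutral clones are over-represented among observed clones.
    """
    if a <= 0:
        raise ValueError("intake ratio a must be positive")
    if n_observed_s <= 0:
        raise ValueError("dN/dS undefined with no observed neutral clones")
    return float(n_observed_n) / (a * float(n_observed_s))


def roc_auc(scores_class0, scores_class1, lower_is_class1: bool = True) -> RocResult:
    """ROC analysis of a score separating two groups of simulations.

    ``scores_class0`` come from the negative class (e.g. neutral R² values),
    ``scores_class1`` from the positive class (non-neutral).  By default a
    *lower* score votes for class 1, matching the use of LFIM R² as a
    straightness score.  The trapezoidal AUC equals the rank-based
    (Mann–Whitney) probability estimate, with ties counting one half.
    """
    s0 = np.asarray(scores_class0, dtype=float)
    s1 = np.asarray(scores_class1, dtype=float)
    if s0.size == 0 or s1.size == 0:
        raise ValueError("both score lists must be non-empty")
    y = np.concatenate([np.zeros(s0.size), np.ones(s1.size)])
    s = np.concatenate([s0, s1])
    if lower_is_class1:
        s = -s
    fpr, tpr, thr = skm.roc_curve(y, s, drop_intermediate=False)
    return RocResult(fpr=fpr, tpr=tpr, thresholds=thr, auc=float(skm.auc(fpr, tpr)))


def rank_sum_one_sided(group_a, group_b) -> float:
    """One-sided Mann–Whitney p-value for the alternative ``a > b``.

    Exact when both groups are small and tie-free; otherwise the normal
    approximation with tie correction.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    return float(sps.mannwhitneyu(a, b, alternative="greater").pvalue)


def size_interval_composition(table: pd.DataFrame, breakpoints) -> pd.DataFrame:
    """Fraction of non-neutral clones per half-open size interval.

    ``table`` needs ``size_cells`` and ``label`` columns; intervals are
    ``[b_i, b_{i+1})`` from the ascending ``breakpoints``.  Empty intervals
    report a missing fraction.
    """
    bp = np.asarray(breakpoints, dtype=float)
    if bp.size < 2 or np.any(np.diff(bp) <= 0):
        raise ValueError("breakpoints must be ascending with >= 2 values")
    cats = pd.cut(table["size_cells"], bins=bp, right=False)
    grouped = table.groupby(cats, observed=False)
    out = grouped["label"].agg(
        n_clones="size",
        non_neutral_fraction=lambda s: (s == "non_neutral").mean() if len(s) else np.nan,
    )
    return out.reset_index(names="size_interval")
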