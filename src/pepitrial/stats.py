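"""Meta-analysis statistics for measured-vs-predicted response rates.

The comparison battery: Pearson correlation with its Student-t p-value,
orthogonal (perpendicular) trend fitting with bootstrap bands, the "n−1"
chi-squared test for pairs of independent proportions, ROC/AUC evaluation of
the predictor over trial-success thresholds, rank/mean group-location tests,
and the cohort-representativeness operations (per-position binder frequencies
and mean epitope counts).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from scipy import stats as _sps

from .epitopes import Antigen, BindingTable, count_binding_alleles, scan_peptides
from .hla import ModelPopulation
from .trial import RatePoint

__all__ = [
    "DataPair",
    "CorrelationResult",
    "PerpFit",
    "Chi2Result",
    "RocResult",
    "pearson_with_p",
    "perpendicular_fit",
    "chi2_nminus1",
    "pairwise_match_summary",
    "roc_for_threshold",
    "auc_sweep",
    "group_location_test",
    "per_position_binder_frequency",
    "mean_epitope_count",
]


@dataclass(frozen=True)
class DataPair:
    """One trial's measured response rate paired with its in silico prediction."""

    label: str
    measured: RatePoint
    predicted: RatePoint


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    p: float
    n: int

    @property
    def df(self) -> int:
        return self.n - 2


def pearson_with_p(xs: Sequence[float], ys: Sequence[float]) -> CorrelationResult:
    """Pearson product-moment correlation with its two-sided t-test p-value.

    t = r * sqrt((n-2) / (1 - r^2)); p is the two-sided tail of Student's t
    with n - 2 degrees of freedom.  Requires n >= 3 and non-degenerate
    variance in both variables.
    """
    x = np.asarray(xs, dtype=float)
    y = np.asarray(ys, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("xs and ys must be equal-length 1-D sequences")
    n = x.size
    if n < 3:
        raise ValueError("correlation needs at least 3 pairs")
    xc = x - x.mean()
    yc = y - y.mean()
    sxx = float(xc @ xc)
    syy = float(yc @ yc)
    if sxx == 0.0 or syy == 0.0:
        raise ValueError("correlation undefined: zero variance in an input")
    r = float(xc @ yc) / math.sqrt(sxx * syy)
    r = max(-1.0, min(1.0, r))
    if abs(r) == 1.0:
        p = 0.0
    else:
        t = r * math.sqrt((n - 2) / (1.0 - r * r))
        p = 2.0 * float(_sps.t.sf(abs(t), df=n - 2))
    return CorrelationResult(r=r, p=p, n=n)


@dataclass(frozen=True)
class PerpFit:
    """Orthogonal-regression (total least squares) trend line.

    The fitted line minimizes the summed squared perpendicular distances to
    the points, treating both variables as error-bearing — the symmetric
    choice when neither the measured nor the predicted rate is a noise-free
    regressor.  ``vertical`` marks the degenerate best-fit x = intercept.
    Band half-widths (level 0.95 by default) come from a seeded
    pairs-bootstrap, evaluated at ``band_x``.
    """

    slope: float
    intercept: float
    perp_rss: float
    n: int
    vertical: bool = False
    level: float = 0.95
    band_x: tuple[float, ...] = ()
    confidence_halfwidth: tuple[float, ...] = ()
    prediction_halfwidth: tuple[float, ...] = ()

    def predict(self, x: float) -> float:
        if self.vertical:
            raise ValueError("vertical fit: y is not a function of x")
        return self.slope * x + self.intercept


def _tls_line(x: np.ndarray, y: np.ndarray) -> tuple[float, float, bool]:
    """Closed-form orthogonal fit on centered second moments.

    slope = (s_yy - s_xx + sqrt((s_yy - s_xx)^2 + 4 s_xy^2)) / (2 s_xy);
    with s_xy = 0 the line is horizontal (s_xx >= s_yy) or vertical.
    Returns (slope, intercept, vertical); for a vertical line the intercept
    holds the x-location.
    """
    xm, ym = x.mean(), y.mean()
    xc, yc = x - xm, y - ym
    sxx = float(xc @ xc)
    syy = float(yc @ yc)
    sxy = float(xc @ yc)
    if sxy == 0.0:
        if syy > sxx:
            return math.inf, xm, True
        return 0.0, ym, False
    slope = (syy - sxx + math.hypot(syy - sxx, 2.0 * sxy)) / (2.0 * sxy)
    return slope, ym - slope * xm, False


def _perp_rss(x: np.ndarray, y: np.ndarray, slope: float, intercept: float,
              vertical: bool) -> float:
    if vertical:
        return float(((x - intercept) ** 2).sum())
    return float(((y - slope * x - intercept) ** 2).sum() / (1.0 + slope * slope))


def perpendicular_fit(
    xs: Sequence[float],
    ys: Sequence[float],
    level: float = 0.95,
    band_x: Sequence[float] = (),
    n_boot: int = 2000,
    seed: int = 0,
) -> PerpFit:
    """Fit the perpendicular (orthogonal, equal-error-variance) trend line.

    Band scheme, documented rather than inherited: resample the (x, y) pairs
    with replacement ``n_boot`` times, refit, and take the percentile interval
    of the fitted value at each requested abscissa (confidence band); the
    prediction band additionally adds a resampled vertical residual of the
    original fit to each bootstrap value.  Bootstrap replicates that come out
    vertical are skipped for band purposes.
    """
    x = np.asarray(xs, dtype=float)
    y = np.asarray(ys, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 3:
        raise ValueError("perpendicular fit needs >= 3 (x, y) pairs")
    if np.allclose(x, x[0]) and np.allclose(y, y[0]):
        raise ValueError("all points coincident: no trend line")
    slope, intercept, vertical = _tls_line(x, y)
    rss = _perp_rss(x, y, slope, intercept, vertical)

    band_x = tuple(float(b) for b in band_x)
    conf_hw: tuple[float, ...] = ()
    pred_hw: tuple[float, ...] = ()
    if band_x and not vertical:
        rng = np.random.default_rng(seed)
        residuals = y - (slope * x + intercept)
        bx = np.asarray(band_x)
        boot_line = np.empty((n_boot, bx.size))
        boot_pred = np.empty((n_boot, bx.size))
        kept = 0
        for _ in range(n_boot):
            idx = rng.integers(0, x.size, size=x.size)
            b, a, vert = _tls_line(x[idx], y[idx])
            if vert:
                continue
            vals = b * bx + a
            boot_line[kept] = vals
            boot_pred[kept] = vals + rng.choice(residuals, size=bx.size)
            kept += 1
        if kept < 2:
            raise ValueError("bootstrap degenerate: nearly vertical cloud")
        alpha = (1.0 - level) / 2.0
        qs = [100.0 * alpha, 100.0 * (1.0 - alpha)]
        lo_c, hi_c = np.percentile(boot_line[:kept], qs, axis=0)
        lo_p, hi_p = np.percentile(boot_pred[:kept], qs, axis=0)
        conf_hw = tuple((hi_c - lo_c) / 2.0)
        pred_hw = tuple((hi_p - lo_p) / 2.0)

    return PerpFit(
        slope=slope,
        intercept=intercept,
        perp_rss=rss,
        n=x.size,
        vertical=vertical,
        level=level,
        band_x=band_x,
        confidence_halfwidth=conf_hw,
        prediction_halfwidth=pred_hw,
    )


@dataclass(frozen=True)
class Chi2Result:
    statistic: float
    p_value: float
    n: int  # total count across both proportions


def chi2_nminus1(p1: RatePoint, p2: RatePoint) -> Chi2Result:
    """The "n−1" chi-squared test for two independent proportions.

    The Pearson chi-squared statistic of the 2x2 responders/non-responders
    table is multiplied by (N−1)/N (N = total subjects), the small-sample
    correction recommended over both the uncorrected Pearson test and the
    continuity-corrected one; the p-value is the upper tail of chi-squared
    with 1 df.  A zero margin (e.g. both rates 0 or both 1) is a perfect
    match by convention: statistic 0, p = 1.
    """
    a, b = p1.numerator, p1.denominator - p1.numerator
    c, d = p2.numerator, p2.denominator - p2.numerator
    n = a + b + c + d
    row1, row2 = a + b, c + d
    col1, col2 = a + c, b + d
    if col1 == 0 or col2 == 0:
        return Chi2Result(statistic=0.0, p_value=1.0, n=n)
    pearson = n * (a * d - b * c) ** 2 / (row1 * row2 * col1 * col2)
    stat = pearson * (n - 1) / n
    p = float(_sps.chi2.sf(stat, df=1))
    return Chi2Result(statistic=float(stat), p_value=p, n=n)


def pairwise_match_summary(
    pairs: Sequence[DataPair], mode: str = "p_gt_0.05"
) -> float:
    """Fraction of measured/predicted pairs that "match".

    mode="p_gt_0.05": no significant difference under the "n−1" chi-squared
    test.  mode="within_10pct": absolute rate difference <= 10 percentage
    points (inclusive boundary).
    """
    if not pairs:
        raise ValueError("no data pairs")
    if mode == "p_gt_0.05":
        hits = sum(
            1 for p in pairs if chi2_nminus1(p.measured, p.predicted).p_value > 0.05
        )
    elif mode == "within_10pct":
        hits = sum(
            1
            for p in pairs
            if abs(p.measured.rate - p.predicted.rate) <= 0.10 + 1e-12
        )
    else:
        raise ValueError(f"unknown match mode {mode!r}")
    return hits / len(pairs)


@dataclass(frozen=True)
class RocResult:
    """ROC curve of the in silico predictor against a trial-success label.

    A trial is labelled a success when its measured rate reaches
    ``success_threshold`` (percent).  The predicted rate is the score; the
    curve sweeps cutoffs over the distinct scores (ties grouped into a single
    vertex).  ``auc`` is the trapezoidal area; ``None`` when only one label
    class is present (degenerate)."""

    success_threshold: float
    points: tuple[tuple[float, float], ...]  # (1 - specificity, sensitivity)
    auc: Optional[float]
    counts: tuple[tuple[int, int, int, int], ...]  # (TP, FP, TN, FN) per cutoff
    cutoffs: tuple[float, ...]
    n_pos: int
    n_neg: int

    @property
    def degenerate(self) -> bool:
        return self.auc is None


def roc_for_threshold(
    pairs: Sequence[DataPair], success_threshold: float
) -> RocResult:
    """Build the ROC curve at one trial-success threshold (percent).

    Labels: measured rate >= threshold.  Scores: predicted rate.  At each
    score cutoff c, trials with predicted rate >= c are test-positive;
    sensitivity = TP/(TP+FN) and specificity = TN/(TN+FP) come from the 2x2
    table; the curve runs from (0, 0) (cutoff above every score) to (1, 1).
    """
    if not pairs:
        raise ValueError("no data pairs")
    thr = success_threshold / 100.0
    labels = np.array([p.measured.rate >= thr for p in pairs])
    scores = np.array([p.predicted.rate for p in pairs])
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos

    cutoffs = sorted(set(scores), reverse=True)
    points: list[tuple[float, float]] = [(0.0, 0.0)]
    counts: list[tuple[int, int, int, int]] = []
    if n_pos == 0 or n_neg == 0:
        return RocResult(
            success_threshold=success_threshold,
            points=tuple(points),
            auc=None,
            counts=(),
            cutoffs=tuple(cutoffs),
            n_pos=n_pos,
            n_neg=n_neg,
        )
    for c in cutoffs:
        test_pos = scores >= c
        tp = int((test_pos & labels).sum())
        fp = int((test_pos & ~labels).sum())
        tn = n_neg - fp
        fn = n_pos - tp
        counts.append((tp, fp, tn, fn))
        points.append((fp / n_neg, tp / n_pos))
    pts = np.array(points)
    auc = float(np.trapezoid(pts[:, 1], pts[:, 0]))
    return RocResult(
        success_threshold=success_threshold,
        points=tuple(map(tuple, points)),
        auc=auc,
        counts=tuple(counts),
        cutoffs=tuple(cutoffs),
        n_pos=n_pos,
        n_neg=n_neg,
    )


def auc_sweep(
    pairs: Sequence[DataPair],
    thresholds: Iterable[float] = range(30, 81, 5),
) -> dict[float, float]:
    """AUC at each trial-success threshold (default 30–80%, step 5).

    Degenerate thresholds (single label class) are skipped.  The sweep over
    the balanced middle of the threshold range avoids judging the predictor
    on hopelessly imbalanced labellings.
    """
    out: dict[float, float] = {}
    for t in thresholds:
        roc = roc_for_threshold(pairs, float(t))
        if roc.auc is not None:
            out[float(t)] = roc.auc
    return out


def _mann_whitney_p(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sided Mann–Whitney p by normal approximation with tie correction
    (no continuity correction)."""
    n1, n2 = a.size, b.size
    combined = np.concatenate([a, b])
    ranks = _sps.rankdata(combined)
    u1 = float(ranks[:n1].sum()) - n1 * (n1 + 1) / 2.0
    mu = n1 * n2 / 2.0
    n = n1 + n2
    _, tie_counts = np.unique(combined, return_counts=True)
    tie_term = float(((tie_counts**3 - tie_counts)).sum()) / (n * (n - 1))
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if var <= 0:
        return 1.0  # all values identical across both groups
    z = (u1 - mu) / math.sqrt(var)
    return 2.0 * float(_sps.norm.sf(abs(z)))


def group_location_test(
    a: Sequence[float], b: Sequence[float], kind: str = "rank"
) -> float:
    """Two-sided comparison of the location of two independent groups.

    kind="rank": Mann–Whitney U by normal approximation with tie correction —
    the distribution-free choice for skewed rate data.  kind="mean": Welch's
    unequal-variance t-test.  The choice between them is configuration, not
    inference.
    """
    x = np.asarray(a, dtype=float)
    y = np.asarray(b, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each group needs at least 2 observations")
    if kind == "rank":
        return _mann_whitney_p(x, y)
    if kind == "mean":
        if np.ptp(np.concatenate([x, y])) == 0.0:
            return 1.0
        res = _sps.ttest_ind(x, y, equal_var=False)
        return float(res.pvalue)
    raise ValueError(f"unknown test kind {kind!r}")


def per_position_binder_frequency(
    population: ModelPopulation,
    antigen: Antigen,
    n: int,
    table: BindingTable,
    k: int = 9,
) -> np.ndarray:
    """Per start position, the fraction of subjects predicted to bind the
    k-mer starting there with >= n of their own alleles.

    The resulting length-(L−k+1) vector is the cohort's epitope-binding
    fingerprint of the antigen; correlating two cohorts' vectors (via
    :func:`pearson_with_p`) is the representativeness check between a small
    model population and a large reference cohort.
    """
    windows = scan_peptides(antigen, k=k)
    subjects = list(population)
    out = np.empty(len(windows))
    for i, w in enumerate(windows):
        hits = sum(
            1
            for s in subjects
            if count_binding_alleles(w.peptide, s.genotype, table) >= n
        )
        out[i] = hits / len(subjects)
    return out


def mean_epitope_count(
    population: ModelPopulation,
    antigen: Antigen,
    n: int,
    table: BindingTable,
    k: int = 9,
) -> float:
    """Mean number of windows per subject binding >= n autologous alleles.

    Equals the sum of the per-position binder frequencies (exchange of
    summation over subjects and positions)."""
    windows = scan_peptides(antigen, k=k)
    subjects = list(population)
    total = sum(
        1
        for s in subjects
        for w in windows
        if count_binding_alleles(w.peptide, s.genotype, table) >= n
    )
    return total / len(subjects)
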