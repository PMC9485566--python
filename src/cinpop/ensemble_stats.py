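"""Population statistics on activity rasters.

Given the binary R x C raster, this module computes the per-frame coactivity
(summed column vectors), its Monte-Carlo significance threshold from
per-cell surrogate rasters, the rate of activity accumulation (slope of a
linear fit to the running sum of coactivity), cumulative distribution
functions of per-neuron percent-active frames and of inter-event intervals
(IISIs), and the nonparametric group comparisons used throughout:
Wilcoxon signed-rank (paired), Mann-Whitney U (unpaired), Friedman /
Kruskal-Wallis with Dunn's post hoc (several samples), Kolmogorov-Smirnov
with Bonferroni correction (CDFs), and the 2x2 chi-square for proportions.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .containers import EventRaster
from .imaging_events import percent_active

SURROGATE_METHODS = ("circular_shift", "permute")


# ---------------------------------------------------------------------------
# Coactivity and its Monte-Carlo null
# ---------------------------------------------------------------------------

def coactivity(raster: EventRaster) -> np.ndarray:
    """Per-frame number of coactive cells: counts[t] = sum_i A[i, t]."""
    return raster.A.sum(axis=0).astype(int)


@dataclass
class CoactivityProfile:
    """Coactivity counts with their Monte-Carlo significance threshold."""

    counts: np.ndarray
    threshold: int | None
    significant_frames: np.ndarray
    alpha: float
    n_surrogates: int
    surrogate_method: str
    seed: int | None
    surrogate_tail_p: np.ndarray = field(default_factory=lambda: np.empty(0))
    empty: bool = False

    @property
    def n_significant_frames(self) -> int:
        return int(self.significant_frames.sum())

    @property
    def n_significant_peaks(self) -> int:
        """Runs of adjacent significant frames counted as single peaks."""
        s = self.significant_frames
        if not s.any():
            return 0
        starts = s & ~np.concatenate([[False], s[:-1]])
        return int(starts.sum())


def _surrogate_count_histogram(raster: EventRaster, n_surrogates: int,
                               method: str, rng: np.random.Generator
                               ) -> np.ndarray:
    """Histogram over {0..R} of per-frame coactivity pooled over surrogates.

    Rows are represented by their event-frame indices; a circular shift adds
    a per-cell uniform offset mod C, preserving each cell's event count and
    within-cell interval structure.  ``permute`` redraws each cell's event
    frames uniformly without replacement (count-preserving only).
    """
    R, C = raster.n_cells, raster.n_frames
    rows = [raster.event_frames(i) for i in range(R)]
    lens = np.array([len(r) for r in rows])
    flat = np.concatenate(rows) if lens.sum() else np.empty(0, dtype=int)
    cell_of = np.repeat(np.arange(R), lens)
    hist = np.zeros(R + 1, dtype=np.int64)
    for _ in range(n_surrogates):
        if method == "circular_shift":
            shifts = rng.integers(0, C, size=R)
            ev = (flat + shifts[cell_of]) % C
        elif method == "permute":
            ev = np.concatenate([rng.choice(C, size=k, replace=False)
                                 for k in lens]) if lens.sum() else flat
        else:
            raise ValueError(f"unknown surrogate method {method!r}")
        counts = np.bincount(ev, minlength=C)
        hist += np.bincount(counts, minlength=R + 1)
    return hist


def mc_threshold(raster: EventRaster, n_surrogates: int = 1000,
                 alpha: float = 0.05, method: str = "circular_shift",
                 seed: int | None = None) -> CoactivityProfile:
    """Monte-Carlo significance threshold for coactivity peaks.

    Surrogate rasters preserve each cell's event count (circular shifts also
    preserve its interval structure); the pooled per-frame coactivity
    distribution across all surrogates defines the null.  The threshold (the
    dashed line under the raster) is the smallest integer count c whose null
    tail probability P(coactivity >= c) is below ``alpha``; frames at or
    above it are flagged significant.
    """
    if raster.n_cells < 2:
        raise ValueError("need at least 2 cells")
    if raster.n_frames < 2:
        raise ValueError("need at least 2 frames")
    counts = coactivity(raster)
    if raster.total_events() == 0:
        warnings.warn("raster has no events; coactivity threshold undefined",
                      stacklevel=2)
        return CoactivityProfile(counts, None, np.zeros(len(counts), bool),
                                 alpha, n_surrogates, method, seed,
                                 empty=True)
    rng = np.random.default_rng(seed)
    hist = _surrogate_count_histogram(raster, n_surrogates, method, rng)
    total = hist.sum()
    tail = hist[::-1].cumsum()[::-1] / total  # tail[c] = P(count >= c)
    candidates = np.flatnonzero(tail < alpha)
    thr = int(candidates[0]) if candidates.size else raster.n_cells + 1
    thr = max(thr, 1)
    sig = counts >= thr
    return CoactivityProfile(counts, thr, sig, alpha, n_surrogates, method,
                             seed, surrogate_tail_p=tail)


# ---------------------------------------------------------------------------
# Rate of activity accumulation
# ---------------------------------------------------------------------------

@dataclass
class AccumulationFit:
    """OLS line through the running sum of coactivity over frames."""

    cumulative: np.ndarray
    slope: float            # events per frame
    slope_per_s: float      # events per second
    intercept: float
    r_squared: float


def accumulation_slope(counts: np.ndarray, fps: float) -> AccumulationFit:
    """Rate of activity accumulation: fit cumulative coactivity vs frame."""
    counts = np.asarray(counts, dtype=float)
    if len(counts) < 2:
        raise ValueError("need at least 2 frames")
    cumulative = np.cumsum(counts)
    x = np.arange(len(counts), dtype=float)
    res = stats.linregress(x, cumulative)
    r2 = res.rvalue ** 2 if np.isfinite(res.rvalue) else 1.0
    return AccumulationFit(cumulative, float(res.slope),
                           float(res.slope * fps), float(res.intercept),
                           float(r2))


# ---------------------------------------------------------------------------
# CDFs of percent-active frames
# ---------------------------------------------------------------------------

@dataclass
class CdfComparison:
    """Two-sample Kolmogorov-Smirnov comparison of pooled per-neuron values."""

    name_a: str
    name_b: str
    sample_a: np.ndarray
    sample_b: np.ndarray
    ks_D: float
    p_value: float
    bonferroni_alpha: float
    n_a: int
    n_b: int

    @property
    def significant(self) -> bool:
        return self.p_value < self.bonferroni_alpha


def pooled_percent_active(rasters) -> np.ndarray:
    """Per-neuron percent-active frames pooled across recordings."""
    if isinstance(rasters, EventRaster):
        rasters = [rasters]
    vals = [percent_active(r) for r in rasters]
    if not vals:
        raise ValueError("empty group")
    return np.concatenate(vals)


def activity_cdf(groups: dict, comparisons: list[tuple[str, str]] | None = None,
                 alpha: float = 0.05) -> list[CdfComparison]:
    """KS comparisons of percent-active CDFs between condition groups.

    ``groups`` maps condition name to an EventRaster, a list of rasters
    (neurons pooled across experiments), or a precomputed 1-D value array.
    ``comparisons`` lists the planned pairs (default: all pairs); the
    Bonferroni-adjusted alpha is ``alpha / n_comparisons``.
    """
    samples = {}
    for name, g in groups.items():
        if isinstance(g, EventRaster) or (isinstance(g, (list, tuple)) and g
                                          and isinstance(g[0], EventRaster)):
            arr = pooled_percent_active(g)
        else:
            arr = np.asarray(g, dtype=float)
        if arr.size < 2:
            raise ValueError(f"group {name!r} needs at least 2 neurons")
        samples[name] = arr
    if comparisons is None:
        comparisons = list(itertools.combinations(samples, 2))
    if not comparisons:
        raise ValueError("no comparisons requested")
    b_alpha = alpha / len(comparisons)
    out = []
    for a, b in comparisons:
        res = stats.ks_2samp(samples[a], samples[b], method="asymp")
        out.append(CdfComparison(a, b, samples[a], samples[b],
                                 float(res.statistic), float(res.pvalue),
                                 b_alpha, len(samples[a]), len(samples[b])))
    return out


def empirical_cdf(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Sorted values and their empirical CDF (reaching exactly 1)."""
    v = np.sort(np.asarray(values, dtype=float))
    return v, np.arange(1, len(v) + 1) / len(v)


# ---------------------------------------------------------------------------
# Inter-event intervals
# ---------------------------------------------------------------------------

@dataclass
class IntervalSet:
    """Per-cell inter-event intervals (s); cells with < 2 events contribute
    nothing."""

    per_cell: list[np.ndarray]
    condition_tag: str = ""

    @property
    def pooled(self) -> np.ndarray:
        arrs = [a for a in self.per_cell if a.size]
        return np.concatenate(arrs) if arrs else np.empty(0)


def iisi_extract(raster: EventRaster) -> IntervalSet:
    """Successive differences of per-cell event frame times, in seconds.

    Intended for collapse-to-event rasters (one mark per transient), so the
    intervals are the silences between inferred events.
    """
    per_cell = [np.diff(raster.event_frames(i)) / raster.fps
                for i in range(raster.n_cells)]
    return IntervalSet(per_cell, raster.condition_tag)


DEFAULT_SCALES = ((0.0, 1.0), (1.0, 60.0), (60.0, 120.0))


@dataclass
class IisiHistograms:
    """Per-scale histograms plus the pooled interval CDF."""

    scales: tuple
    bin_edges: list[np.ndarray]
    counts: list[np.ndarray]
    cdf_x: np.ndarray
    cdf_y: np.ndarray


def iisi_histograms(intervals: IntervalSet,
                    scales=DEFAULT_SCALES,
                    bins_per_scale: int = 20) -> IisiHistograms:
    """Histogram the skewed IISI distribution at several scales.

    The distribution has a long tail, so it is shown split (by default
    < 1 s, 1-60 s, and 60-120 s); counts per scale sum to the number of
    intervals falling in that range.  The pooled CDF lumps all intervals.
    """
    pooled = intervals.pooled
    if pooled.size == 0:
        raise ValueError("empty interval set")
    edges_list, counts_list = [], []
    for lo, hi in scales:
        edges = np.linspace(lo, hi, bins_per_scale + 1)
        counts, _ = np.histogram(pooled[(pooled >= lo) & (pooled < hi)],
                                 bins=edges)
        edges_list.append(edges)
        counts_list.append(counts)
    x, y = empirical_cdf(pooled)
    return IisiHistograms(tuple(scales), edges_list, counts_list, x, y)


# ---------------------------------------------------------------------------
# Rank-based group comparisons
# ---------------------------------------------------------------------------

@dataclass
class PairwiseResult:
    group_a: str
    group_b: str
    statistic: float
    p_value: float
    p_adjusted: float


@dataclass
class GroupTestReport:
    test_name: str
    statistic: float
    p_value: float
    n_per_group: list[int]
    group_names: list[str]
    posthoc: list[PairwiseResult] = field(default_factory=list)
    note: str = ""


def _dunn_kruskal(samples: list[np.ndarray], names: list[str]
                  ) -> list[PairwiseResult]:
    """Dunn's post hoc after Kruskal-Wallis: pooled-midrank z tests with the
    tie correction, Bonferroni-adjusted two-sided p-values."""
    pooled = np.concatenate(samples)
    N = len(pooled)
    ranks = stats.rankdata(pooled)
    splits = np.cumsum([len(s) for s in samples])[:-1]
    rank_groups = np.split(ranks, splits)
    means = [r.mean() for r in rank_groups]
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = (tie_counts ** 3 - tie_counts).sum() / (12.0 * (N - 1))
    var_base = N * (N + 1) / 12.0 - tie_term
    pairs = list(itertools.combinations(range(len(samples)), 2))
    m = len(pairs)
    out = []
    for i, j in pairs:
        se = np.sqrt(var_base * (1 / len(samples[i]) + 1 / len(samples[j])))
        z = (means[i] - means[j]) / se if se > 0 else 0.0
        p = 2 * stats.norm.sf(abs(z))
        out.append(PairwiseResult(names[i], names[j], float(z), float(p),
                                  float(min(1.0, p * m))))
    return out


def _dunn_friedman(samples: list[np.ndarray], names: list[str]
                   ) -> list[PairwiseResult]:
    """Dunn-type comparisons on within-block ranks after Friedman's test."""
    data = np.column_stack(samples)
    n, k = data.shape
    ranks = np.apply_along_axis(stats.rankdata, 1, data)
    mean_ranks = ranks.mean(axis=0)
    se = np.sqrt(k * (k + 1) / (6.0 * n))
    pairs = list(itertools.combinations(range(k), 2))
    m = len(pairs)
    out = []
    for i, j in pairs:
        z = (mean_ranks[i] - mean_ranks[j]) / se
        p = 2 * stats.norm.sf(abs(z))
        out.append(PairwiseResult(names[i], names[j], float(z), float(p),
                                  float(min(1.0, p * m))))
    return out


def group_compare(samples, design: str,
                  names: list[str] | None = None) -> GroupTestReport:
    """Dispatch the appropriate nonparametric test for the study design.

    * ``paired`` — Wilcoxon signed-rank (two matched samples, e.g. before
      and after drug administration);
    * ``unpaired`` — Mann-Whitney U (e.g. control vs DA-depleted neurons);
    * ``k_paired`` — Friedman ANOVA with Dunn-type post hoc;
    * ``k_unpaired`` — Kruskal-Wallis ANOVA with Dunn's post hoc.

    Ties are handled by midranks; p-values use the normal approximation with
    continuity correction for larger samples and exact distributions where
    scipy supports them at small n.
    """
    samples = [np.asarray(s, dtype=float) for s in samples]
    if names is None:
        names = [f"group{i}" for i in range(len(samples))]
    ns = [len(s) for s in samples]
    if any(n < 3 for n in ns):
        raise ValueError("each sample needs at least 3 observations")

    if design == "paired":
        if len(samples) != 2:
            raise ValueError("paired design takes exactly 2 samples")
        a, b = samples
        if len(a) != len(b):
            raise ValueError("paired samples must have equal length")
        if np.all(a == b):
            return GroupTestReport("wilcoxon", float("nan"), 1.0, ns, names,
                                   note="all paired differences are zero")
        stat, p = stats.wilcoxon(a, b)
        return GroupTestReport("wilcoxon", float(stat), float(p), ns, names)
    if design == "unpaired":
        if len(samples) != 2:
            raise ValueError("unpaired design takes exactly 2 samples")
        big = max(ns) > 20
        stat, p = stats.mannwhitneyu(
            *samples, alternative="two-sided",
            method="asymptotic" if big else "exact")
        return GroupTestReport("mann-whitney", float(stat), float(p), ns,
                               names)
    if design == "k_unpaired":
        if len(samples) < 3:
            raise ValueError("k-group design needs at least 3 samples")
        try:
            stat, p = stats.kruskal(*samples)
        except ValueError:  # all values identical
            stat, p = 0.0, 1.0
        return GroupTestReport("kruskal-wallis", float(stat), float(p), ns,
                               names, posthoc=_dunn_kruskal(samples, names))
    if design == "k_paired":
        if len(samples) < 3:
            raise ValueError("k-group design needs at least 3 samples")
        if len(set(ns)) != 1:
            raise ValueError("paired samples must have equal length")
        try:
            stat, p = stats.friedmanchisquare(*samples)
        except ValueError:
            stat, p = 0.0, 1.0
        return GroupTestReport("friedman", float(stat), float(p), ns, names,
                               posthoc=_dunn_friedman(samples, names))
    raise ValueError(f"unknown design {design!r}")


@dataclass
class ProportionTest:
    chi2: float
    p_value: float
    df: int
    k1: int
    n1: int
    k2: int
    n2: int


def proportion_compare(k1: int, n1: int, k2: int, n2: int) -> ProportionTest:
    """2x2 chi-square (df = 1, no continuity correction) on two proportions,
    e.g. the percentage of neurons with spontaneous firing, or of indented
    phase plots, in two conditions."""
    if n1 <= 0 or n2 <= 0:
        raise ValueError("totals must be positive")
    if not (0 <= k1 <= n1 and 0 <= k2 <= n2):
        raise ValueError("counts must lie between 0 and their totals")
    table = np.array([[k1, n1 - k1], [k2, n2 - k2]], dtype=float)
    if np.any(table.sum(axis=0) == 0):
        chi2, p = 0.0, 1.0
    else:
        chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
    return ProportionTest(float(chi2), float(p), 1, k1, n1, k2, n2)
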