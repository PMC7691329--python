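"""Statistical primitives shared by every pipeline stage.

Self-contained implementations of the statistics the analysis relies on:
a log-space two-sided Fisher exact test (usable when p-values underflow
double precision), exact binomial confidence intervals, the rank-statistic
AUROC, label-shuffle significance machinery, the within-animal permutation
test for optogenetic effects, Wilcoxon rank tests with normal-approximation
z statistics, and anatomical count normalization.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.special import logsumexp
from statsmodels.stats.proportion import proportion_confint

from ._rng import rng_from_seed

__all__ = [
    "ContingencyTable2x2",
    "PermutationResult",
    "ShuffleNullResult",
    "fisher_exact_two_sided",
    "binomial_ci",
    "auroc",
    "shuffle_significance",
    "permutation_test_laser",
    "rank_tests",
    "normalized_cell_counts",
    "bonferroni_alpha",
]

# Relative slack in log-probability when deciding whether a table is "as or
# more extreme" than the observed one; guards against floating-point ties
# (same convention as common exact-test implementations).
_LOG_REL_EPS = 1e-7


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts for two populations (rows) split into two preference classes.

    Layout::

        [[a, b],
         [c, d]]
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        counts = (self.a, self.b, self.c, self.d)
        if any(int(x) != x or x < 0 for x in counts):
            raise ValueError("counts must be non-negative integers")
        if sum(counts) == 0:
            raise ValueError("empty table")

    @classmethod
    def from_array(cls, table) -> "ContingencyTable2x2":
        t = np.asarray(table)
        if t.shape != (2, 2):
            raise ValueError("expected a 2x2 table")
        return cls(int(t[0, 0]), int(t[0, 1]), int(t[1, 0]), int(t[1, 1]))

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=np.int64)


@dataclass(frozen=True)
class PermutationResult:
    """Outcome of a within-animal label-permutation test."""

    observed_effect: float
    null_samples: np.ndarray
    p_two_sided: float
    n_permutations: int
    seed: int
    #: smallest attainable nonzero p (1 / n_permutations); the test reports
    #: p = 0 when no null draw is as extreme as the observed effect
    resolution: float = field(default=np.nan)

    def __post_init__(self) -> None:
        object.__setattr__(self, "null_samples", np.asarray(self.null_samples, dtype=float))
        if len(self.null_samples) != self.n_permutations:
            raise ValueError("null_samples length must equal n_permutations")
        if not 0.0 <= self.p_two_sided <= 1.0:
            raise ValueError("p must lie in [0, 1]")
        if np.isnan(self.resolution):
            object.__setattr__(self, "resolution", 1.0 / self.n_permutations)

    def to_json_record(self) -> dict:
        return {
            "statistic": float(self.observed_effect),
            "p": float(self.p_two_sided),
            "n": int(self.n_permutations),
            "resolution": float(self.resolution),
            "seed": int(self.seed),
        }


@dataclass(frozen=True)
class ShuffleNullResult:
    """Observed score against the central interval of a label-shuffle null."""

    observed: float
    null_lo: float
    null_hi: float
    significant: bool
    n_shuffles: int

    def __post_init__(self) -> None:
        if self.null_lo > self.null_hi:
            raise ValueError("null_lo must not exceed null_hi")


def fisher_exact_two_sided(table) -> float:
    """Two-sided Fisher exact test, returned as log10 of the p-value.

    The two-sided p is the point-probability definition: the sum of
    probabilities of all tables with the observed margins whose
    hypergeometric probability does not exceed that of the observed table.
    Working entirely in log space keeps p-values far below the double
    underflow threshold (~1e-308) representable.

    Parameters
    ----------
    table
        A :class:`ContingencyTable2x2` or any 2x2 array-like of counts.

    Returns
    -------
    float
        ``log10(p)`` (always <= 0).
    """
    t = table if isinstance(table, ContingencyTable2x2) else ContingencyTable2x2.from_array(table)
    a, b, c, d = t.a, t.b, t.c, t.d
    n = a + b + c + d
    row1 = a + b
    col1 = a + c
    # support of the [0,0] cell given fixed margins
    k_lo = max(0, col1 - (n - row1))
    k_hi = min(row1, col1)
    ks = np.arange(k_lo, k_hi + 1)
    logp = sps.hypergeom.logpmf(ks, n, row1, col1)
    log_obs = logp[a - k_lo]
    keep = logp <= log_obs + _LOG_REL_EPS * abs(log_obs)
    log_p_two = logsumexp(logp[keep])
    return float(min(log_p_two / np.log(10.0), 0.0))


def binomial_ci(successes: int, n: int, level: float = 0.95) -> tuple[float, float]:
    """Exact (Clopper–Pearson tail-inversion) binomial confidence interval.

    Returns ``(lo, hi)`` bounding ``successes / n`` at the given level.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    if not 0 <= successes <= n:
        raise ValueError("successes must lie in [0, n]")
    lo, hi = proportion_confint(successes, n, alpha=1.0 - level, method="beta")
    return float(lo), float(hi)


def auroc(positives: Sequence[float], negatives: Sequence[float]) -> float:
    """Probability that a random positive exceeds a random negative.

    Rank-statistic definition: the fraction of (positive, negative) pairs
    with positive > negative, ties counted as half.
    """
    pos = np.asarray(positives, dtype=float)
    neg = np.asarray(negatives, dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both groups must be non-empty")
    ranks = sps.rankdata(np.concatenate([pos, neg]))
    u = ranks[: pos.size].sum() - pos.size * (pos.size + 1) / 2.0
    return float(u / (pos.size * neg.size))


def shuffle_significance(
    values_a: Sequence[float],
    values_b: Sequence[float],
    score_fn: Callable[[np.ndarray, np.ndarray], float],
    n_shuffles: int = 1000,
    central: float = 0.95,
    seed: int | np.random.Generator | None = None,
) -> ShuffleNullResult:
    """Test a two-group score against a label-shuffle null.

    The null pools both groups, randomly re-partitions the pooled values
    into groups of the original sizes ``n_shuffles`` times, and recomputes
    ``score_fn``. The observed score is significant when it falls outside
    the central ``central`` fraction of the null (empirical percentiles).
    """
    if n_shuffles < 1:
        raise ValueError("n_shuffles must be >= 1")
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    observed = float(score_fn(a, b))
    pooled = np.concatenate([a, b])
    rng = rng_from_seed(seed)
    null = np.empty(n_shuffles)
    for i in range(n_shuffles):
        perm = rng.permutation(pooled)
        null[i] = score_fn(perm[: a.size], perm[a.size :])
    tail = (1.0 - central) / 2.0 * 100.0
    lo, hi = np.percentile(null, [tail, 100.0 - tail])
    return ShuffleNullResult(
        observed=observed,
        null_lo=float(lo),
        null_hi=float(hi),
        significant=bool(observed < lo or observed > hi),
        n_shuffles=n_shuffles,
    )


def _as_column_table(trials) -> dict[str, np.ndarray]:
    if isinstance(trials, pd.DataFrame):
        return {k: np.asarray(trials[k].to_numpy()) for k in trials.columns}
    return {k: np.asarray(v) for k, v in trials.items()}


def permutation_test_laser(
    per_animal_trials: Sequence,
    metric_fn: Callable[[Mapping[str, np.ndarray], np.ndarray], float],
    n_perm: int = 1000,
    seed: int | np.random.Generator | None = None,
) -> PermutationResult:
    """Within-animal permutation test of a laser-induced change.

    Each permutation round shuffles the laser labels independently within
    each animal (preserving that animal's laser-trial count), concatenates
    all animals, and recomputes the pooled laser-induced change.

    Parameters
    ----------
    per_animal_trials
        One trial table per animal (DataFrame or mapping of column name to
        array). Each must carry a boolean ``laser`` column.
    metric_fn
        ``metric_fn(columns, laser_mask) -> float`` where ``columns`` maps
        column names to pooled numpy arrays (laser column excluded) and
        ``laser_mask`` is the pooled boolean laser assignment. Called once
        with the real labels and once per permutation.
    n_perm
        Number of label permutations.
    seed
        Seed for the permutation stream.

    Returns
    -------
    PermutationResult
        Two-sided p = fraction of null draws with \\|null\\| >= \\|observed\\|
        (null centered at 0); no +1 smoothing, so p has resolution
        ``1/n_perm``.
    """
    if len(per_animal_trials) == 0:
        raise ValueError("need at least one animal")
    tables = [_as_column_table(t) for t in per_animal_trials]
    lasers = []
    for i, tab in enumerate(tables):
        if "laser" not in tab:
            raise ValueError("each trial table must carry a 'laser' column")
        las = np.asarray(tab["laser"], dtype=bool)
        if las.all() or not las.any():
            raise ValueError(f"animal {i} lacks laser or non-laser trials")
        lasers.append(las)
    keys = [k for k in tables[0] if k != "laser"]
    pooled = {k: np.concatenate([tab[k] for tab in tables]) for k in keys}
    sizes = [las.size for las in lasers]
    offsets = np.cumsum([0] + sizes)
    pooled_laser = np.concatenate(lasers)

    observed = float(metric_fn(pooled, pooled_laser))

    seed_int = seed if isinstance(seed, (int, np.integer)) else -1
    rng = rng_from_seed(seed)
    null = np.empty(n_perm)
    work = pooled_laser.copy()
    for r in range(n_perm):
        for i, las in enumerate(lasers):
            work[offsets[i] : offsets[i + 1]] = rng.permutation(las)
        null[r] = metric_fn(pooled, work)
    p = float(np.mean(np.abs(null) >= abs(observed)))
    return PermutationResult(
        observed_effect=observed,
        null_samples=null,
        p_two_sided=p,
        n_permutations=n_perm,
        seed=int(seed_int),
    )


def _ranksum_z(x: np.ndarray, y: np.ndarray) -> float:
    """Normal-approximation z for the rank-sum statistic with tie correction."""
    n1, n2 = x.size, y.size
    ranks = sps.rankdata(np.concatenate([x, y]))
    r1 = ranks[:n1].sum()
    n = n1 + n2
    mu = n1 * (n + 1) / 2.0
    _, counts = np.unique(np.concatenate([x, y]), return_counts=True)
    tie_term = np.sum(counts**3 - counts) / (n * (n - 1.0))
    sigma2 = n1 * n2 / 12.0 * (n + 1 - tie_term)
    if sigma2 <= 0:
        raise ValueError("degenerate data: all values tied")
    return float((r1 - mu) / np.sqrt(sigma2))


def _signed_rank_z(d: np.ndarray) -> float:
    """Normal-approximation z for the signed-rank statistic with tie correction."""
    n = d.size
    ranks = sps.rankdata(np.abs(d))
    w_pos = ranks[d > 0].sum()
    mu = n * (n + 1) / 4.0
    _, counts = np.unique(np.abs(d), return_counts=True)
    sigma2 = n * (n + 1) * (2 * n + 1) / 24.0 - np.sum(counts**3 - counts) / 48.0
    if sigma2 <= 0:
        raise ValueError("degenerate data: all differences tied")
    return float((w_pos - mu) / np.sqrt(sigma2))


def rank_tests(
    x: Sequence[float],
    y: Sequence[float],
    paired: bool,
    alternative: str = "two-sided",
) -> tuple[float, float]:
    """Wilcoxon rank tests with a normal-approximation z.

    Paired mode is the signed-rank test with zero differences dropped
    (classical convention); unpaired mode is the rank-sum test. The p-value
    is computed by scipy (exact for small tie-free samples, asymptotic
    otherwise) for the requested ``alternative``; the returned z is the
    tie-corrected normal approximation and flips sign when x and y are
    swapped.

    Returns
    -------
    (p, z)
    """
    xv = np.asarray(x, dtype=float)
    yv = np.asarray(y, dtype=float)
    if paired:
        if xv.size != yv.size:
            raise ValueError("paired test requires equal lengths")
        d = xv - yv
        d = d[d != 0]
        if d.size < 2:
            raise ValueError("fewer than 2 usable (nonzero) differences")
        res = sps.wilcoxon(d, zero_method="wilcox", alternative=alternative, method="auto")
        z = _signed_rank_z(d)
        return float(res.pvalue), z
    if xv.size < 2 or yv.size < 2:
        raise ValueError("fewer than 2 observations in a group")
    res = sps.mannwhitneyu(xv, yv, alternative=alternative, method="auto")
    z = _ranksum_z(xv, yv)
    return float(res.pvalue), z


def normalized_cell_counts(
    cells: pd.DataFrame,
    bin_width: float = 0.5,
    normalization_range: tuple[float, float] = (0.0, 3.0),
    position_col: str = "ap_mm",
    group_cols: Sequence[str] = (),
) -> pd.DataFrame:
    """Bin labeled-cell positions and normalize by the in-range total.

    Counts of back-labeled cells per anteroposterior bin (default width
    0.5 mm), divided by the total number of cells whose position falls in
    ``normalization_range``. Cells outside the range still appear in the
    binned numerators, so proportions over in-range bins sum to 1 and
    out-of-range bins report their fraction relative to the same
    denominator.

    Parameters
    ----------
    cells
        Table with a finite position column and optional grouping columns
        (e.g. region or fluorophore tags).
    group_cols
        Extra columns to split counts by before normalizing; the
        denominator is computed per group.
    """
    lo, hi = normalization_range
    if not hi > lo:
        raise ValueError("normalization range must be non-empty")
    pos = cells[position_col].to_numpy(dtype=float)
    if not np.all(np.isfinite(pos)):
        raise ValueError("positions must be finite")
    edges_lo = np.floor(pos.min() / bin_width) * bin_width
    edges_hi = np.ceil(pos.max() / bin_width) * bin_width
    n_bins = max(int(round((edges_hi - edges_lo) / bin_width)), 1)
    edges = edges_lo + bin_width * np.arange(n_bins + 1)

    def _one(df: pd.DataFrame) -> pd.DataFrame:
        p = df[position_col].to_numpy(dtype=float)
        denom = int(np.sum((p >= lo) & (p <= hi)))
        if denom == 0:
            raise ValueError("zero cells in normalization range")
        counts, _ = np.histogram(p, bins=edges)
        return pd.DataFrame(
            {
                "bin_lo": edges[:-1],
                "bin_hi": edges[1:],
                "count": counts,
                "proportion": counts / denom,
            }
        )

    if group_cols:
        out = (
            cells.groupby(list(group_cols), group_keys=True)
            .apply(_one, include_groups=False)
            .reset_index(level=list(range(len(group_cols))))
            .reset_index(drop=True)
        )
        return out
    return _one(cells)


def bonferroni_alpha(alpha: float = 0.05, n_comparisons: int = 2) -> float:
    """Bonferroni-adjusted per-comparison threshold (0.05/2 = 0.025 for the
    right/left cue pair)."""
    if n_comparisons < 1:
        raise ValueError("n_comparisons must be >= 1")
    return alpha / n_comparisons
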