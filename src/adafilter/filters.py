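"""Count filters: the basic filter plus five parametric filter families.

All filters operate on raw counts and are blinded to the group labels, with
the exception of the Jaccard filter which uses within-condition replicate
pairs (but is symmetric in the two conditions). Every family except ``none``
is composed with the basic filter: genes with only zero counts are removed
first, and percentile cutoffs / Jaccard indices are computed on the basic
survivors only.

``proportion_filtered`` is reported relative to the basic survivors for all
families, and relative to all m genes for the basic filter itself.
"""

from __future__ import annotations

import numpy as np
from statsmodels.nonparametric.smoothers_lowess import lowess

from .containers import CountMatrix, FilterSpec, FilterResult
from .de import cpm as _cpm

__all__ = [
    "basic_filter",
    "mean_filter",
    "max_filter",
    "cpm_filter",
    "zero_filter",
    "jaccard_pair_index",
    "jaccard_threshold",
    "jaccard_filter",
    "apply_filter",
]


def _as_counts(counts) -> np.ndarray:
    if isinstance(counts, CountMatrix):
        return counts.counts
    return np.asarray(counts)


def basic_filter(counts) -> FilterResult:
    """Keep genes with at least one non-zero count across all samples."""
    c = _as_counts(counts)
    keep = (c > 0).any(axis=1)
    prop = 1.0 - keep.sum() / c.shape[0]
    return FilterResult(FilterSpec("basic"), keep, prop, realized_threshold=0.0)


def _percentile_filter(counts, percentile: float, statistic: str) -> FilterResult:
    if not (0 < percentile < 100):
        raise ValueError("percentile must lie in (0, 100)")
    c = _as_counts(counts)
    base = basic_filter(c).keep
    n_base = base.sum()
    if n_base == 0:
        raise ValueError("no genes survive the basic filter")
    stat = c.mean(axis=1) if statistic == "mean" else c.max(axis=1)
    cutoff = float(np.percentile(stat[base], percentile))  # linear interpolation
    # removal is strict (stat < cutoff); the relative tolerance keeps exact
    # ties at the cutoff, which interpolation rounding can otherwise break
    keep = base & (stat >= cutoff * (1.0 - 1e-9) - 1e-12)
    prop = 1.0 - keep.sum() / n_base
    return FilterResult(FilterSpec(statistic, percentile), keep, prop, cutoff)


def mean_filter(counts, percentile: float) -> FilterResult:
    """Remove basic survivors whose mean raw count falls strictly below the
    given empirical percentile of mean counts."""
    return _percentile_filter(counts, percentile, "mean")


def max_filter(counts, percentile: float) -> FilterResult:
    """Remove basic survivors whose maximum raw count (over both conditions)
    falls strictly below the given empirical percentile of maximum counts."""
    return _percentile_filter(counts, percentile, "max")


def cpm_filter(counts, c_threshold: float, n1: int | None = None,
               n2: int | None = None, cpm_matrix=None) -> FilterResult:
    """Remove genes whose CPM is below c in more than min(n1, n2) samples.

    CPM for filtering uses raw library sizes (no TMM factors).
    """
    if c_threshold <= 0:
        raise ValueError("cpm threshold c must be positive")
    c = _as_counts(counts)
    if n1 is None or n2 is None:
        if not isinstance(counts, CountMatrix):
            raise ValueError("n1/n2 are required for array input")
        n1, n2 = counts.n1, counts.n2
    if cpm_matrix is None:
        cpm_matrix = _cpm(c)
    base = basic_filter(c).keep
    n_base = base.sum()
    n_below = (np.asarray(cpm_matrix) < c_threshold).sum(axis=1)
    keep = base & (n_below <= min(n1, n2))
    prop = 1.0 - keep.sum() / n_base if n_base else 0.0
    return FilterResult(FilterSpec("cpm", c_threshold), keep, prop, c_threshold)


def zero_filter(counts, u: int) -> FilterResult:
    """Remove genes with more than u zero counts (strict; composed with the
    basic filter, which equals this family in the limit u = n - 1)."""
    if int(u) != u or u < 1:
        raise ValueError("u must be an integer >= 1")
    c = _as_counts(counts)
    base = basic_filter(c).keep
    n_base = base.sum()
    n_zero = (c == 0).sum(axis=1)
    keep = base & (n_zero <= u)
    prop = 1.0 - keep.sum() / n_base if n_base else 0.0
    return FilterResult(FilterSpec("zero", int(u)), keep, prop, float(u))


def jaccard_pair_index(x, y, v: float) -> float:
    """Jaccard similarity of two replicates dichotomised at cutoff v.

    |{i: x_i > v and y_i > v}| / |{i: x_i > v or y_i > v}|, defined as 0 when
    the denominator is empty.
    """
    x = np.asarray(x)
    y = np.asarray(y)
    if x.shape != y.shape:
        raise ValueError("replicates must have the same length")
    bx, by = x > v, y > v
    denom = (bx | by).sum()
    if denom == 0:
        return 0.0
    return float((bx & by).sum() / denom)


def _default_grid(c: np.ndarray, max_points: int = 50) -> np.ndarray:
    """Candidate cutoffs: distinct observed counts up to the 95th percentile
    of non-zero counts, capped at ``max_points`` quantile-spaced values."""
    nz = c[c > 0]
    if nz.size == 0:
        return np.array([0.0])
    hi = np.percentile(nz, 95)
    vals = np.unique(c[c <= hi].astype(float))
    if vals.size > max_points:
        qs = np.quantile(vals, np.linspace(0, 1, max_points))
        vals = np.unique(np.floor(qs))
    return vals


def jaccard_threshold(counts, groups=None, candidate_grid=None,
                      span: float = 0.5) -> float:
    """Count-scale cutoff v* maximising the loess-smoothed global Jaccard index.

    The global index at cutoff v is the simple average of the pairwise index
    over all within-condition replicate pairs, pooled across both conditions.
    Ties in the smoothed maximum are broken toward the smallest v. Computed on
    basic-filter survivors.
    """
    cm = counts if isinstance(counts, CountMatrix) else None
    c = _as_counts(counts)
    if groups is None:
        if cm is None:
            raise ValueError("groups are required for array input")
        groups = cm.groups
    groups = np.asarray(groups)
    for g in (1, 2):
        if (groups == g).sum() < 2:
            raise ValueError("each condition needs at least two replicates")
    base = basic_filter(c).keep
    cb = c[base]
    if candidate_grid is None:
        candidate_grid = _default_grid(cb)
    grid = np.asarray(candidate_grid, dtype=float)
    if grid.size == 0:
        raise ValueError("candidate grid must be non-empty")
    grid = np.unique(grid)

    # all within-condition replicate pairs, pooled across both conditions
    pa, pb = [], []
    for g in (1, 2):
        idx = np.flatnonzero(groups == g)
        ia, ib = np.triu_indices(len(idx), k=1)
        pa.append(idx[ia])
        pb.append(idx[ib])
    pa = np.concatenate(pa)
    pb = np.concatenate(pb)
    scores = np.empty(grid.size)
    for i, v in enumerate(grid):
        b = (cb > v).astype(np.int64)
        both = b.T @ b  # pairwise co-exceedance counts
        n_above = np.diag(both)
        inter = both[pa, pb]
        union = n_above[pa] + n_above[pb] - inter
        with np.errstate(divide="ignore", invalid="ignore"):
            pair_idx = np.where(union > 0, inter / np.maximum(union, 1), 0.0)
        scores[i] = pair_idx.mean()
    if grid.size >= 4 and np.ptp(grid) > 0:
        sm = lowess(scores, grid, frac=span, it=0, return_sorted=True)[:, 1]
    else:
        sm = scores
    best = np.flatnonzero(sm == sm.max())[0]  # smallest v on ties
    return float(grid[best])


def jaccard_filter(counts, groups=None, candidate_grid=None,
                   span: float = 0.5) -> FilterResult:
    """Max-based filter at the Jaccard-selected cutoff v*: keep basic
    survivors whose maximum count exceeds v* (matching the ``> v``
    dichotomisation of the index itself)."""
    c = _as_counts(counts)
    v_star = jaccard_threshold(counts, groups, candidate_grid, span)
    base = basic_filter(c).keep
    n_base = base.sum()
    keep = base & (c.max(axis=1) > v_star)
    prop = 1.0 - keep.sum() / n_base if n_base else 0.0
    return FilterResult(FilterSpec("jaccard"), keep, prop, v_star)


def apply_filter(spec: FilterSpec, counts, groups=None, n1=None, n2=None,
                 cpm_matrix=None) -> FilterResult:
    """Dispatch a FilterSpec to its implementation."""
    c = _as_counts(counts)
    if spec.family == "none":
        keep = np.ones(c.shape[0], dtype=bool)
        return FilterResult(spec, keep, 0.0)
    if spec.family == "basic":
        return basic_filter(counts)
    if spec.family == "mean":
        return mean_filter(counts, spec.threshold)
    if spec.family == "max":
        return max_filter(counts, spec.threshold)
    if spec.family == "cpm":
        return cpm_filter(counts, spec.threshold, n1=n1, n2=n2,
                          cpm_matrix=cpm_matrix)
    if spec.family == "zero":
        return zero_filter(counts, int(spec.threshold))
    if spec.family == "jaccard":
        return jaccard_filter(counts, groups)
    raise ValueError(f"unknown filter family {spec.family!r}")
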