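"""Normalisation and differential-expression testing core.

Implements trimmed-mean-of-M-values (TMM) scale factors, counts-per-million,
a voom-style log2-CPM transform with observation-level precision weights from
a fitted mean-variance trend, and a moderated weighted two-group t-test with
empirical-Bayes variance shrinkage.

TMM follows the published reference construction exactly: upper-quartile
reference-sample rule, 30% trimming of M-values and 5% of A-values, and
inverse asymptotic-variance weights, with factors rescaled to geometric
mean 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import special, stats
from scipy.stats import rankdata
from statsmodels.nonparametric.smoothers_lowess import lowess

from .containers import CountMatrix

__all__ = [
    "NormalizedData",
    "TestResult",
    "tmm_factors",
    "cpm",
    "voom_transform",
    "moderated_test",
]


@dataclass(frozen=True)
class NormalizedData:
    """voom-style normalised data: log2-CPM plus precision weights."""

    lib_sizes: np.ndarray
    tmm_factors: np.ndarray
    log_cpm: np.ndarray
    weights: np.ndarray

    def __post_init__(self):
        if np.any(~np.isfinite(self.log_cpm)):
            raise ValueError("log_cpm must be finite")
        if np.any(self.weights <= 0) or np.any(~np.isfinite(self.weights)):
            raise ValueError("weights must be positive and finite")


@dataclass(frozen=True)
class TestResult:
    """Per-gene two-sided moderated-t results."""

    p_values: np.ndarray
    test_statistics: np.ndarray
    df: np.ndarray
    prior_df: float
    prior_var: float

    def __post_init__(self):
        finite = np.isfinite(self.p_values)
        if np.any((self.p_values[finite] < 0) | (self.p_values[finite] > 1)):
            raise ValueError("p-values must lie in [0, 1]")


def _as_counts(counts) -> np.ndarray:
    if isinstance(counts, CountMatrix):
        return counts.counts
    return np.asarray(counts, dtype=float)


def _tmm_pair(obs, ref, log_ratio_trim=0.3, sum_trim=0.05):
    """TMM factor of one sample against the reference column (log2 scale)."""
    obs = np.asarray(obs, dtype=float)
    ref = np.asarray(ref, dtype=float)
    n_o, n_r = obs.sum(), ref.sum()
    with np.errstate(divide="ignore", invalid="ignore"):
        log_r = np.log2((obs / n_o) / (ref / n_r))
        abs_e = (np.log2(obs / n_o) + np.log2(ref / n_r)) / 2.0
        v = (n_o - obs) / (n_o * obs) + (n_r - ref) / (n_r * ref)
    fin = np.isfinite(log_r) & np.isfinite(abs_e)
    log_r, abs_e, v = log_r[fin], abs_e[fin], v[fin]
    if log_r.size == 0 or np.max(np.abs(log_r)) < 1e-6:
        return 1.0
    n = log_r.size
    lo_l = np.floor(n * log_ratio_trim) + 1
    hi_l = n + 1 - lo_l
    lo_s = np.floor(n * sum_trim) + 1
    hi_s = n + 1 - lo_s
    rank_r = rankdata(log_r)
    rank_e = rankdata(abs_e)
    keep = ((rank_r >= lo_l) & (rank_r <= hi_l)
            & (rank_e >= lo_s) & (rank_e <= hi_s))
    if not np.any(keep):
        return 1.0
    f = np.sum(log_r[keep] / v[keep]) / np.sum(1.0 / v[keep])
    if not np.isfinite(f):
        return 1.0
    return float(2.0 ** f)


def tmm_factors(counts) -> np.ndarray:
    """Per-sample TMM normalisation factors, rescaled to geometric mean 1.

    The reference sample is the one whose upper-quartile count fraction is
    closest to the mean upper-quartile across samples.
    """
    c = _as_counts(counts)
    lib = c.sum(axis=0)
    if np.any(lib <= 0):
        raise ValueError("every sample must have a positive library size")
    q75 = np.quantile(c / lib, 0.75, axis=0)
    ref_idx = int(np.argmin(np.abs(q75 - q75.mean())))
    factors = np.array([_tmm_pair(c[:, j], c[:, ref_idx]) for j in range(c.shape[1])])
    factors /= np.exp(np.mean(np.log(factors)))
    return factors


def cpm(counts, lib_sizes=None, factors=None) -> np.ndarray:
    """Counts per million on effective library sizes (lib_size * factor)."""
    c = _as_counts(counts)
    if lib_sizes is None:
        lib_sizes = c.sum(axis=0)
    lib_sizes = np.asarray(lib_sizes, dtype=float)
    if factors is None:
        factors = np.ones_like(lib_sizes)
    eff = lib_sizes * np.asarray(factors, dtype=float)
    if np.any(eff <= 0):
        raise ValueError("effective library sizes must be positive")
    return c / eff * 1e6


def _design(groups) -> np.ndarray:
    groups = np.asarray(groups)
    return np.column_stack([np.ones(groups.size), (groups == 2).astype(float)])


def _wls_group_fit(y, w, groups):
    """Vectorised per-gene weighted group-means fit.

    Returns (coef2, fitted, sigma2, se_unscaled, df_resid) where coef2 is the
    group-2 minus group-1 contrast and se_unscaled its standard-error factor.
    """
    g2 = np.asarray(groups) == 2
    w1, w2 = w[:, ~g2], w[:, g2]
    y1, y2 = y[:, ~g2], y[:, g2]
    sw1, sw2 = w1.sum(axis=1), w2.sum(axis=1)
    mu1 = (w1 * y1).sum(axis=1) / sw1
    mu2 = (w2 * y2).sum(axis=1) / sw2
    fitted = np.empty_like(y)
    fitted[:, ~g2] = mu1[:, None]
    fitted[:, g2] = mu2[:, None]
    resid = y - fitted
    rss = (w * resid ** 2).sum(axis=1)
    df = y.shape[1] - 2
    sigma2 = rss / df
    se_unscaled = np.sqrt(1.0 / sw1 + 1.0 / sw2)
    return mu2 - mu1, fitted, sigma2, se_unscaled, df


def voom_transform(counts, factors=None, groups=None, span: float = 0.5) -> NormalizedData:
    """log2-CPM with precision weights from the fitted mean-variance trend.

    log_cpm_ij = log2((c_ij + 0.5) / (lib_j * factor_j + 1) * 1e6). A gene-wise
    group-means model is fitted by ordinary least squares, a lowess trend of
    sqrt(residual sd) versus average log2 count is fitted across genes, the
    trend is interpolated at the fitted log2 counts, and the precision weight
    of each observation is the predicted sd to the power -4 (predicted
    quarter-root sds are clamped at the trend boundary values).
    """
    cm = counts if isinstance(counts, CountMatrix) else None
    c = _as_counts(counts)
    if c.shape[0] < 2:
        raise ValueError("at least two genes are required to fit the trend")
    if c.shape[1] < 3:
        raise ValueError("at least three samples are required (residual df)")
    if groups is None:
        if cm is None:
            raise ValueError("groups are required for array input")
        groups = cm.groups
    lib = c.sum(axis=0)
    if factors is None:
        factors = tmm_factors(c)
    factors = np.asarray(factors, dtype=float)
    eff = lib * factors
    log_cpm = np.log2((c + 0.5) / (eff + 1.0)[None, :] * 1e6)
    ones = np.ones_like(log_cpm)
    _, fitted, sigma2, _, _ = _wls_group_fit(log_cpm, ones, groups)
    sqrt_sd = sigma2 ** 0.25
    # mean log2 count of each gene, on the same scale as the fitted values
    a_mean = log_cpm.mean(axis=1) + np.mean(np.log2(eff + 1.0)) - np.log2(1e6)
    ok = np.isfinite(sqrt_sd)
    xs, ys = a_mean[ok], sqrt_sd[ok]
    if xs.size >= 2 and np.ptp(xs) > 0 and np.any(ys > 0):
        delta = 0.01 * np.ptp(xs)
        trend = lowess(ys, xs, frac=span, it=3, delta=delta, return_sorted=True)
        tx, ty = trend[:, 0], trend[:, 1]
        tx, uniq = np.unique(tx, return_index=True)
        ty = ty[uniq]
    else:  # degenerate: flat trend
        tx = np.array([0.0, 1.0])
        ty = np.full(2, ys.mean() if ys.size else 0.0)
    fitted_logcount = fitted + np.mean(np.log2(eff + 1.0)) - np.log2(1e6)
    pred = np.interp(fitted_logcount, tx, ty, left=ty[0], right=ty[-1])
    pred = np.maximum(pred, 1e-6)  # guard all-constant data (sd identically 0)
    weights = pred ** -4
    return NormalizedData(lib, factors, log_cpm, weights)


def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x for y > 0 (Newton on 1/trigamma, standard trick)."""
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y += dif
        if abs(dif) < 1e-8 * y:
            break
    return float(y)


def _fit_f_dist(sigma2: np.ndarray, df: float) -> tuple[float, float]:
    """Moment-match log residual variances to a scaled inverse-chi-square prior.

    Returns (prior_df d0, prior variance s0^2); d0 = inf means full shrinkage.
    """
    ok = np.isfinite(sigma2) & (sigma2 > 0)
    s2 = sigma2[ok]
    if s2.size < 2:
        return np.inf, float(np.median(sigma2[ok])) if ok.any() else 1.0
    z = np.log(s2)
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    emean = e.mean()
    evar = e.var(ddof=1) - special.polygamma(1, df / 2.0)
    if evar > 0:
        d0 = 2.0 * _trigamma_inverse(evar)
        s0_2 = np.exp(emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0))
    else:
        d0 = np.inf
        s0_2 = np.exp(emean)
    return float(d0), float(s0_2)


def moderated_test(normalized: NormalizedData, groups, prior_df: float | None = None) -> TestResult:
    """Empirical-Bayes moderated weighted t-test for the two-group contrast.

    Residual variances are shrunk towards the ensemble prior
    ((d0*s0^2 + d*s^2)/(d0 + d)); the moderated t uses d + d0 degrees of
    freedom. ``prior_df=0`` disables shrinkage and reduces to the ordinary
    weighted two-sample t-test.
    """
    groups = np.asarray(groups)
    if (groups == 1).sum() < 1 or (groups == 2).sum() < 1:
        raise ValueError("both groups need at least one sample")
    y, w = normalized.log_cpm, normalized.weights
    coef, _, sigma2, se_unscaled, df = _wls_group_fit(y, w, groups)
    if df < 1:
        raise ValueError("at least one residual degree of freedom is required")
    if prior_df is None:
        d0, s0_2 = _fit_f_dist(sigma2, df)
    elif prior_df == 0:
        d0, s0_2 = 0.0, 1.0
    else:
        d0 = float(prior_df)
        _, s0_2 = _fit_f_dist(sigma2, df)
    if np.isinf(d0):
        post_var = np.full_like(sigma2, s0_2)
        total_df = np.full_like(sigma2, np.inf)
    else:
        post_var = (d0 * s0_2 + df * sigma2) / (d0 + df)
        total_df = np.full_like(sigma2, df + d0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = coef / (np.sqrt(post_var) * se_unscaled)
    p = 2.0 * stats.t.sf(np.abs(t), total_df)
    return TestResult(p, t, total_df, d0, s0_2)
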