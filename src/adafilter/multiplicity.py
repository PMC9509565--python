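"""Multiple-testing adjustment: BH step-up and Grenander-based local FDR.

The local-FDR estimator models the p-values as a two-group mixture
f(p) = eta0 * 1 + (1 - eta0) * g(p) with a uniform null and a nonincreasing
alternative density g. eta0 is estimated from the censored upper tail of the
p-value distribution under a truncated-uniform null; g is estimated by the
Grenander estimator (derivative of the least concave majorant of the ECDF)
applied to the alternative component of the mixture, which enforces
f_hat >= eta0 and makes the fitted density integrate to exactly 1.
lfdr(p) = min(1, eta0 / f_hat(p)); hypotheses with lfdr strictly below alpha
are rejected.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import isotonic_regression

__all__ = ["AdjustedResult", "bh_reject", "estimate_lfdr", "adjust", "reject",
           "grenander_density"]


@dataclass(frozen=True)
class AdjustedResult:
    """Adjusted p-values (BH) or lfdr values, with the rejection mask."""

    method: str
    adjusted: np.ndarray
    rejected: np.ndarray
    alpha: float
    eta0: float | None = None

    def __post_init__(self):
        adj = np.asarray(self.adjusted, dtype=float)
        if adj.size and (adj.min() < 0 or adj.max() > 1):
            raise ValueError("adjusted values must lie in [0, 1]")
        object.__setattr__(self, "adjusted", adj)
        object.__setattr__(self, "rejected",
                           np.asarray(self.rejected, dtype=bool))

    @property
    def n_rejected(self) -> int:
        return int(self.rejected.sum())


def _check_pvals(pvals) -> np.ndarray:
    p = np.asarray(pvals, dtype=float)
    if p.ndim != 1:
        raise ValueError("p-values must be a 1-d vector")
    if p.size and (np.any(~np.isfinite(p)) or p.min() < 0 or p.max() > 1):
        raise ValueError("p-values must be finite and lie in [0, 1]")
    return p


def bh_reject(pvals, alpha: float = 0.05) -> AdjustedResult:
    """Benjamini-Hochberg step-up at level alpha.

    k* = max{k : p_(k) <= k * alpha / M}; the k* smallest p-values are
    rejected (none when no such k exists). Adjusted values are the usual
    monotone BH-adjusted p-values, so rejected <=> adjusted <= alpha.
    """
    p = _check_pvals(pvals)
    m = p.size
    if m == 0:
        return AdjustedResult("bh", np.empty(0), np.empty(0, dtype=bool), alpha)
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    adj_sorted = np.minimum(adj_sorted, 1.0)
    adjusted = np.empty(m)
    adjusted[order] = adj_sorted
    passed = np.flatnonzero(p[order] <= np.arange(1, m + 1) * alpha / m)
    rejected = np.zeros(m, dtype=bool)
    if passed.size:
        k_star = passed[-1] + 1
        rejected[order[:k_star]] = True
    return AdjustedResult("bh", adjusted, rejected, alpha)


def _pava_decreasing_slopes(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Left derivative of the least concave majorant through (x, y).

    The LCM slopes equal the antitonic (nonincreasing) regression of the raw
    chord slopes with the x-increments as weights; computed with PAVA.
    Returns one slope per interval (x[i-1], x[i]].
    """
    dx = np.diff(x)
    dy = np.diff(y)
    raw = dy / dx
    fitted = isotonic_regression(raw, weights=dx, increasing=False).x
    return np.maximum(fitted, 0.0)


def grenander_density(pvals):
    """Plain Grenander density estimate of the p-value distribution on [0, 1].

    Returns (breaks, slopes): breaks of length K+1 starting at 0 and ending
    at 1, and K nonincreasing piecewise-constant density values. The density
    integrates to exactly 1.
    """
    p = _check_pvals(pvals)
    ps = np.unique(p)
    ecdf = np.searchsorted(np.sort(p), ps, side="right") / p.size
    x = np.concatenate([[0.0], ps])
    y = np.concatenate([[0.0], ecdf])
    if x[-1] < 1.0:
        x = np.append(x, 1.0)
        y = np.append(y, 1.0)
    else:
        y[-1] = 1.0
    slopes = _pava_decreasing_slopes(x, y)
    return x, slopes


def _eta0_cutoff(p_sorted: np.ndarray, max_candidates: int = 200):
    """Censored truncated-uniform estimate of the null proportion eta0.

    Candidate censoring cutoffs are quantile points of the distinct p-values
    between their median and 90th percentile (the censored window keeps at
    least ~10% of the mass, so the fit is stable). For each cutoff t the
    truncated-uniform estimate is #{p > t} / (M (1 - t)); the retained cutoff
    is the one whose censored sample looks most null (largest estimate, i.e.
    the smallest estimated fraction of alternatives hidden above the cutoff),
    clipped to [0, 1]. A conservative over-estimate of eta0 inflates the lfdr,
    which is the safe direction for FDR control.
    """
    m = p_sorted.size
    distinct = np.unique(p_sorted)
    if distinct.size < 2:
        return 1.0, float(distinct[0]) if distinct.size else 1.0
    lo, hi = np.quantile(distinct, [0.5, 0.9])
    cand = distinct[(distinct >= lo) & (distinct <= hi) & (distinct < 1.0)]
    if cand.size == 0:
        cand = distinct[distinct < 1.0]
        if cand.size == 0:
            return 1.0, 1.0
    if cand.size > max_candidates:
        cand = np.unique(np.quantile(cand, np.linspace(0, 1, max_candidates)))
    n_above = m - np.searchsorted(p_sorted, cand, side="right")
    with np.errstate(divide="ignore"):
        eta0_t = n_above / (m * (1.0 - cand))
    best = int(np.argmax(eta0_t))
    return float(min(1.0, eta0_t[best])), float(cand[best])


def estimate_lfdr(pvals, alpha: float = 0.05) -> AdjustedResult:
    """Local FDR via the two-component Grenander construction (see module
    docstring). Rejects hypotheses with lfdr strictly below alpha."""
    p = _check_pvals(pvals)
    m = p.size
    if m < 2:
        raise ValueError("at least two p-values are required")
    order = np.argsort(p, kind="stable")
    p_sorted = p[order]
    eta0, _cutoff = _eta0_cutoff(p_sorted)
    if eta0 >= 1.0 or np.all(p_sorted == p_sorted[0]):
        lfdr = np.ones(m)
        return AdjustedResult("lfdr", lfdr, lfdr < alpha, alpha, eta0=1.0)

    # alternative-component CDF: (F_n(p) - eta0 p) / (1 - eta0), monotonised
    ps = np.unique(p_sorted)
    ecdf = np.searchsorted(p_sorted, ps, side="right") / m
    f_alt = (ecdf - eta0 * ps) / (1.0 - eta0)
    f_alt = np.clip(np.maximum.accumulate(np.clip(f_alt, 0.0, 1.0)), 0.0, 1.0)
    x = np.concatenate([[0.0], ps])
    y = np.concatenate([[0.0], f_alt])
    if x[-1] < 1.0:
        x = np.append(x, 1.0)
        y = np.append(y, 1.0)
    else:
        y[-1] = 1.0
    slopes = _pava_decreasing_slopes(x, y)
    # left-continuous evaluation: p in (x[k-1], x[k]] takes slope k
    seg = np.clip(np.searchsorted(x, p_sorted, side="left"), 1, slopes.size) - 1
    g_hat = slopes[seg]
    f_hat = eta0 + (1.0 - eta0) * g_hat
    lfdr_sorted = np.minimum(1.0, eta0 / f_hat)
    lfdr = np.empty(m)
    lfdr[order] = lfdr_sorted
    return AdjustedResult("lfdr", lfdr, lfdr < alpha, alpha, eta0=eta0)


def adjust(pvals, method: str, alpha: float = 0.05) -> AdjustedResult:
    """Dispatch to bh_reject or estimate_lfdr."""
    if method == "bh":
        return bh_reject(pvals, alpha)
    if method == "lfdr":
        return estimate_lfdr(pvals, alpha)
    raise ValueError(f"unknown adjustment method {method!r}")


def reject(adjusted: AdjustedResult) -> int:
    """Number of rejected hypotheses R (genes removed by a filter are never
    part of the adjusted vector, so they are never rejected)."""
    return adjusted.n_rejected
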