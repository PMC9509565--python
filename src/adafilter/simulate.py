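"""Two-group negative-binomial count simulation with known truth labels.

The generator emulates two NB-based strategies: fixed gene-wise parameters
(every null gene shares one mean/dispersion) and distributed parameters
(per-gene mean/dispersion pairs resampled jointly from a parameter table,
optionally with a fraction of structurally-zero genes). Counts are drawn
independently per gene and sample; the NB variance is parameterised as
mu + phi * mu**2 with dispersion phi.
"""

from __future__ import annotations

import math

import numpy as np

from .containers import CountMatrix, NBParamTable, TruthLabels, ConfigError

__all__ = [
    "simulate_nb_fixed",
    "simulate_nb_distributed",
    "simulate_low_count_null_mixture",
    "scale_to_depth",
    "synthetic_param_generator",
]


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, phi: np.ndarray,
             n_cols: int) -> np.ndarray:
    """Draw an (m, n_cols) NB matrix, mean mu_i, variance mu_i + phi_i mu_i^2.

    phi = 0 degenerates to Poisson; mu = 0 yields structural zeros.
    """
    mu = np.asarray(mu, dtype=float)
    phi = np.broadcast_to(np.asarray(phi, dtype=float), mu.shape)
    out = np.zeros((mu.size, n_cols), dtype=np.int64)
    pos = mu > 0
    if not np.any(pos):
        return out
    mu_p, phi_p = mu[pos], phi[pos]
    pois = phi_p == 0
    block = np.empty((pos.sum(), n_cols), dtype=np.int64)
    if np.any(pois):
        block[pois] = rng.poisson(mu_p[pois][:, None], size=(pois.sum(), n_cols))
    nb = ~pois
    if np.any(nb):
        # size r = 1/phi, p = r / (r + mu)
        r = 1.0 / phi_p[nb]
        p = r / (r + mu_p[nb])
        block[nb] = rng.negative_binomial(r[:, None], p[:, None],
                                          size=(nb.sum(), n_cols))
    out[pos] = block
    return out


def _split_truth(m: int, pi0: float, rng: np.random.Generator):
    """Return (is_null, up_mask) with exactly ceil(pi0*m) null genes.

    DE genes are split half up-, half down-regulated (odd remainder goes to
    the up-regulated side); DE positions are drawn at random.
    """
    if not (0.0 <= pi0 <= 1.0):
        raise ConfigError("pi0 must lie in [0, 1]")
    m0 = math.ceil(pi0 * m)
    is_null = np.ones(m, dtype=bool)
    de_idx = rng.choice(m, size=m - m0, replace=False)
    is_null[de_idx] = False
    up = np.zeros(m, dtype=bool)
    n_de = m - m0
    n_up = (n_de + 1) // 2
    up[de_idx[:n_up]] = True
    return is_null, up


def simulate_nb_fixed(m: int, n1: int, n2: int, pi0: float, mu0: float = 10.0,
                      fold_change: float = 2.0, dispersion: float = 0.1,
                      seed=0) -> tuple[CountMatrix, TruthLabels]:
    """Fixed-parameter NB simulation.

    All null genes have mean mu0 in both groups; DE genes keep mu0 in group 1
    and get mu0*fold_change (up) or mu0/fold_change (down) in group 2, applied
    symmetrically so mean library size stays roughly balanced across groups.
    """
    if mu0 <= 0 or fold_change <= 0:
        raise ConfigError("mu0 and fold_change must be positive")
    if dispersion < 0:
        raise ConfigError("dispersion must be non-negative")
    rng = _rng(seed)
    is_null, up = _split_truth(m, pi0, rng)
    mu1 = np.full(m, float(mu0))
    mu2 = np.full(m, float(mu0))
    mu2[~is_null & up] = mu0 * fold_change
    mu2[~is_null & ~up] = mu0 / fold_change
    phi = np.full(m, float(dispersion))
    counts = np.hstack([_nb_draw(rng, mu1, phi, n1), _nb_draw(rng, mu2, phi, n2)])
    cm = CountMatrix(
        counts,
        [f"gene{i + 1}" for i in range(m)],
        [f"sample{j + 1}" for j in range(n1 + n2)],
        [1] * n1 + [2] * n2,
    )
    return cm, TruthLabels(is_null, mu1, mu2, phi)


def simulate_nb_distributed(param_table: NBParamTable, m: int, n1: int, n2: int,
                            pi0: float, fold_change: float = 2.0,
                            seed=0) -> tuple[CountMatrix, TruthLabels]:
    """Distributed-parameter NB simulation.

    Per-gene (mean, dispersion) pairs are resampled jointly with replacement
    from ``param_table`` (preserving their empirical dependence). A
    ``zero_fraction`` of genes gets mean 0 in both groups. DE genes receive
    the symmetric fold change as in :func:`simulate_nb_fixed`.
    """
    if fold_change <= 0:
        raise ConfigError("fold_change must be positive")
    rng = _rng(seed)
    idx = rng.integers(0, len(param_table), size=m)
    base_mu = param_table.means[idx].copy()
    phi = param_table.dispersions[idx].copy()
    if param_table.zero_fraction > 0:
        n_zero = int(round(param_table.zero_fraction * m))
        zero_idx = rng.choice(m, size=n_zero, replace=False)
        base_mu[zero_idx] = 0.0
    is_null, up = _split_truth(m, pi0, rng)
    mu1 = base_mu.copy()
    mu2 = base_mu.copy()
    mu2[~is_null & up] = base_mu[~is_null & up] * fold_change
    mu2[~is_null & ~up] = base_mu[~is_null & ~up] / fold_change
    # a DE label on a structurally-zero gene is vacuous: mu1 == mu2 == 0
    is_null = mu1 == mu2
    counts = np.hstack([_nb_draw(rng, mu1, phi, n1), _nb_draw(rng, mu2, phi, n2)])
    cm = CountMatrix(
        counts,
        [f"gene{i + 1}" for i in range(m)],
        [f"sample{j + 1}" for j in range(n1 + n2)],
        [1] * n1 + [2] * n2,
    )
    return cm, TruthLabels(is_null, mu1, mu2, phi)


def simulate_low_count_null_mixture(m: int, n1: int, n2: int,
                                    low_fraction: float = 0.3,
                                    pi0: float = 0.8, mu_low: float = 2.0,
                                    mu_high: float = 50.0,
                                    fold_change: float = 2.0,
                                    dispersion: float = 0.1,
                                    seed=0) -> tuple[CountMatrix, TruthLabels]:
    """Two-block scenario: a block of low-count null genes plus a regular
    block carrying all the DE signal.

    ``low_fraction`` of the genes are nulls with mean ``mu_low`` (candidates
    a count filter should remove); the remaining genes have mean ``mu_high``
    with a within-block null proportion chosen so the overall proportion of
    true nulls is ``pi0``. Useful for studying how aggressive filtering first
    helps (removing uninformative low-count genes) and then hurts (removing
    detectable DE genes).
    """
    m_low = int(round(low_fraction * m))
    m_high = m - m_low
    if pi0 * m < m_low:
        raise ConfigError("pi0 too small: the low-count block alone exceeds it")
    pi0_high = (pi0 * m - m_low) / m_high
    s1, s2 = np.random.SeedSequence(seed).spawn(2)
    low_cm, low_truth = simulate_nb_fixed(m_low, n1, n2, pi0=1.0, mu0=mu_low,
                                          dispersion=dispersion,
                                          seed=np.random.default_rng(s1))
    high_cm, high_truth = simulate_nb_fixed(m_high, n1, n2, pi0=pi0_high,
                                            mu0=mu_high,
                                            fold_change=fold_change,
                                            dispersion=dispersion,
                                            seed=np.random.default_rng(s2))
    counts = np.vstack([low_cm.counts, high_cm.counts])
    cm = CountMatrix(counts, [f"gene{i + 1}" for i in range(m)],
                     low_cm.sample_ids, low_cm.groups)
    truth = TruthLabels(np.r_[low_truth.is_null, high_truth.is_null],
                        np.r_[low_truth.mu1, high_truth.mu1],
                        np.r_[low_truth.mu2, high_truth.mu2],
                        np.r_[low_truth.dispersion, high_truth.dispersion])
    return cm, truth


def scale_to_depth(param_table: NBParamTable, depth: float) -> NBParamTable:
    """Rescale means so their sum (expected per-sample total) equals depth."""
    if depth <= 0:
        raise ConfigError("depth must be positive")
    total = param_table.means.sum()
    if total <= 0:
        raise ConfigError("cannot scale a table whose means are all zero")
    return NBParamTable(param_table.means * (depth / total),
                        param_table.dispersions.copy(),
                        param_table.zero_fraction)


def synthetic_param_generator(m: int, seed=0, log_mean_location: float = 2.0,
                              log_mean_scale: float = 1.5,
                              dispersion_shape: float = 2.0,
                              dispersion_rate: float = 10.0,
                              zero_fraction: float = 0.0) -> NBParamTable:
    """Synthetic stand-in for real-data-derived NB parameter tables.

    Means are log-normal (natural-log location/scale), dispersions are
    gamma(shape, rate), drawn independently. Deterministic given the seed.
    """
    if log_mean_scale < 0 or dispersion_shape <= 0 or dispersion_rate <= 0:
        raise ConfigError("scale must be >= 0 and shape/rate positive")
    rng = _rng(seed)
    means = rng.lognormal(mean=log_mean_location, sigma=log_mean_scale, size=m)
    disps = rng.gamma(shape=dispersion_shape, scale=1.0 / dispersion_rate, size=m)
    return NBParamTable(means, disps, zero_fraction)
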