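"""Core domain containers for two-group RNA-seq count data and scenarios.

Counts are stored genes x samples (the dominant file convention for DE
matrices); group labels take values 1 and 2.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CountMatrix",
    "TruthLabels",
    "NBParamTable",
    "FilterSpec",
    "FilterResult",
    "ScenarioConfig",
    "ConfigError",
    "FormatError",
    "table2_battery",
]

FILTER_FAMILIES = ("none", "basic", "mean", "max", "cpm", "jaccard", "zero")

#: Table-2 percentile grid used by the mean- and max-based filter families.
PERCENTILE_GRID = (1, 2, 3, 4, 5, 8, 11, 14, 17, 20, 23, 26, 29, 32, 35, 38,
                   41, 44, 47, 50, 55, 60, 65, 70, 75, 80, 85, 90)
#: CPM thresholds c of the CPM-based filter family.
CPM_GRID = (1, 2, 5, 25, 50, 100)


class ConfigError(ValueError):
    """Invalid scenario or filter configuration."""


class FormatError(ValueError):
    """Malformed count matrix or metadata file."""


@dataclass(frozen=True)
class CountMatrix:
    """An m-gene x n-sample integer count matrix with group labels.

    Parameters
    ----------
    counts : (m, n) array of non-negative integers
    gene_ids : m unique identifiers
    sample_ids : n unique identifiers
    groups : n labels in {1, 2}, both groups non-empty
    """

    counts: np.ndarray
    gene_ids: np.ndarray
    sample_ids: np.ndarray
    groups: np.ndarray

    def __post_init__(self):
        counts = np.asarray(self.counts)
        if counts.ndim != 2:
            raise FormatError("counts must be a 2-d matrix (genes x samples)")
        if not np.issubdtype(counts.dtype, np.number):
            raise FormatError("counts must be numeric")
        if np.any(counts < 0):
            raise FormatError("negative counts are not allowed")
        if not np.all(counts == np.floor(counts)):
            raise FormatError("counts must be integral")
        object.__setattr__(self, "counts", counts.astype(np.int64))
        gene_ids = np.asarray(self.gene_ids, dtype=object)
        sample_ids = np.asarray(self.sample_ids, dtype=object)
        groups = np.asarray(self.groups, dtype=np.int64)
        m, n = counts.shape
        if gene_ids.shape != (m,):
            raise FormatError(f"expected {m} gene ids, got {gene_ids.shape}")
        if sample_ids.shape != (n,) or groups.shape != (n,):
            raise FormatError("sample_ids/groups must match the number of columns")
        if len(set(gene_ids)) != m:
            raise FormatError("gene ids must be unique")
        if len(set(sample_ids)) != n:
            raise FormatError("sample ids must be unique")
        if not set(np.unique(groups)) <= {1, 2}:
            raise FormatError("group labels must be 1 or 2")
        if (groups == 1).sum() == 0 or (groups == 2).sum() == 0:
            raise FormatError("both groups must be non-empty")
        object.__setattr__(self, "gene_ids", gene_ids)
        object.__setattr__(self, "sample_ids", sample_ids)
        object.__setattr__(self, "groups", groups)

    @property
    def m(self) -> int:
        return self.counts.shape[0]

    @property
    def n(self) -> int:
        return self.counts.shape[1]

    @property
    def n1(self) -> int:
        return int((self.groups == 1).sum())

    @property
    def n2(self) -> int:
        return int((self.groups == 2).sum())

    def lib_sizes(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    def subset_genes(self, keep: np.ndarray) -> "CountMatrix":
        keep = np.asarray(keep, dtype=bool)
        return CountMatrix(self.counts[keep], self.gene_ids[keep],
                           self.sample_ids, self.groups)

    def to_xy(self):
        """Return (X, y) in scikit-learn orientation: samples x genes."""
        return self.counts.T.copy(), self.groups.copy()

    @classmethod
    def from_xy(cls, X, y, gene_ids=None, sample_ids=None) -> "CountMatrix":
        X = np.asarray(X)
        n, m = X.shape
        if gene_ids is None:
            gene_ids = [f"gene{i + 1}" for i in range(m)]
        if sample_ids is None:
            sample_ids = [f"sample{j + 1}" for j in range(n)]
        return cls(X.T, np.asarray(gene_ids, dtype=object),
                   np.asarray(sample_ids, dtype=object), np.asarray(y))


@dataclass(frozen=True)
class TruthLabels:
    """Per-gene simulation truth: null status, group means and dispersions."""

    is_null: np.ndarray
    mu1: np.ndarray
    mu2: np.ndarray
    dispersion: np.ndarray

    def __post_init__(self):
        is_null = np.asarray(self.is_null, dtype=bool)
        mu1 = np.asarray(self.mu1, dtype=float)
        mu2 = np.asarray(self.mu2, dtype=float)
        disp = np.asarray(self.dispersion, dtype=float)
        if not (is_null.shape == mu1.shape == mu2.shape == disp.shape):
            raise ValueError("truth label fields must share one shape")
        if np.any(mu1 < 0) or np.any(mu2 < 0) or np.any(disp < 0):
            raise ValueError("means and dispersions must be non-negative")
        if not np.array_equal(is_null, mu1 == mu2):
            raise ValueError("is_null must be equivalent to mu1 == mu2")
        object.__setattr__(self, "is_null", is_null)
        object.__setattr__(self, "mu1", mu1)
        object.__setattr__(self, "mu2", mu2)
        object.__setattr__(self, "dispersion", disp)

    @property
    def n_de(self) -> int:
        return int((~self.is_null).sum())


@dataclass(frozen=True)
class NBParamTable:
    """Per-gene negative-binomial (mean, dispersion) pairs.

    ``zero_fraction`` optionally marks a proportion of genes whose mean is
    forced to 0 in both groups when simulating (emulating libraries with many
    genes having zero counts only).
    """

    means: np.ndarray
    dispersions: np.ndarray
    zero_fraction: float = 0.0

    def __post_init__(self):
        means = np.atleast_1d(np.asarray(self.means, dtype=float))
        disp = np.atleast_1d(np.asarray(self.dispersions, dtype=float))
        if means.shape != disp.shape or means.ndim != 1:
            raise ValueError("means and dispersions must be 1-d and aligned")
        if means.size == 0:
            raise ValueError("parameter table must be non-empty")
        if np.any(means < 0) or np.any(disp < 0):
            raise ValueError("means and dispersions must be non-negative")
        if not (0.0 <= self.zero_fraction < 1.0):
            raise ValueError("zero_fraction must lie in [0, 1)")
        object.__setattr__(self, "means", means)
        object.__setattr__(self, "dispersions", disp)

    def __len__(self) -> int:
        return self.means.size

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"mean": self.means, "dispersion": self.dispersions})


@dataclass(frozen=True)
class FilterSpec:
    """A filter family plus its family-specific threshold.

    threshold meaning: percentile percentage for mean/max, c for cpm,
    u for zero; None for none/basic/jaccard.
    """

    family: str
    threshold: float | int | None = None

    def __post_init__(self):
        if self.family not in FILTER_FAMILIES:
            raise ConfigError(f"unknown filter family: {self.family!r}")
        t = self.threshold
        if self.family in ("none", "basic", "jaccard"):
            if t is not None:
                raise ConfigError(f"{self.family} filter takes no threshold")
        elif self.family in ("mean", "max"):
            if t is None or not (0 < t < 100):
                raise ConfigError("percentile percentage must lie in (0, 100)")
        elif self.family == "cpm":
            if t is None or t <= 0:
                raise ConfigError("cpm threshold c must be positive")
        elif self.family == "zero":
            if t is None or int(t) != t or t < 1:
                raise ConfigError("zero threshold u must be an integer >= 1")

    @property
    def name(self) -> str:
        if self.threshold is None:
            return self.family
        return f"{self.family}_{self.threshold:g}"

    def __str__(self) -> str:  # pragma: no cover
        return self.name


@dataclass(frozen=True)
class FilterResult:
    """Boolean keep-mask induced by a filter, with bookkeeping.

    ``proportion_filtered`` is the fraction removed among the basic-filter
    survivors (for the basic filter itself: among all m genes).
    ``realized_threshold`` is the count-scale cutoff actually applied,
    if any.
    """

    spec: FilterSpec
    keep: np.ndarray
    proportion_filtered: float
    realized_threshold: float | None = None

    def __post_init__(self):
        keep = np.asarray(self.keep, dtype=bool)
        object.__setattr__(self, "keep", keep)
        if not (0.0 <= self.proportion_filtered <= 1.0):
            raise ValueError("proportion_filtered must lie in [0, 1]")

    @property
    def n_kept(self) -> int:
        return int(self.keep.sum())


def table2_battery(n1: int, n2: int, *, include_none: bool = True,
                   include_basic: bool = True) -> list[FilterSpec]:
    """Full default battery: every filter family at every default threshold.

    mean/max at the 28 percentile percentages, CPM at c in {1,2,5,25,50,100},
    one Jaccard filter, and the zero-based filter at u = n-4, ..., 1 (for
    n = 20 samples this is u = 16..1), plus the no-filter and basic options.
    """
    n = n1 + n2
    battery: list[FilterSpec] = []
    if include_none:
        battery.append(FilterSpec("none"))
    if include_basic:
        battery.append(FilterSpec("basic"))
    battery += [FilterSpec("mean", p) for p in PERCENTILE_GRID]
    battery += [FilterSpec("max", p) for p in PERCENTILE_GRID]
    battery += [FilterSpec("cpm", c) for c in CPM_GRID]
    battery.append(FilterSpec("jaccard"))
    u_max = max(n - 4, 1)
    battery += [FilterSpec("zero", u) for u in range(u_max, 0, -1)]
    return battery


@dataclass(frozen=True)
class ScenarioConfig:
    """A simulation scenario: data-generating settings plus analysis knobs."""

    m: int = 10000
    n1: int = 10
    n2: int = 10
    pi0: float = 0.8
    alpha: float = 0.05
    adjustment: str = "lfdr"
    order: str = "a"
    filter_battery: tuple[FilterSpec, ...] | None = None
    l: int = 5
    reference: FilterSpec = field(default_factory=lambda: FilterSpec("jaccard"))
    nb_params: dict = field(default_factory=dict)
    n_reps: int = 1000
    seed: int = 0

    def __post_init__(self):
        if self.m < 2:
            raise ConfigError("m must be at least 2")
        if self.n1 < 1 or self.n2 < 1:
            raise ConfigError("both group sizes must be positive")
        if not (0.0 <= self.pi0 <= 1.0):
            raise ConfigError("pi0 must lie in [0, 1]")
        if not (0.0 < self.alpha < 1.0):
            raise ConfigError("alpha must lie in (0, 1)")
        if self.adjustment not in ("bh", "lfdr"):
            raise ConfigError("adjustment must be 'bh' or 'lfdr'")
        if self.order not in ("a", "b"):
            raise ConfigError("order must be 'a' or 'b'")
        if self.l < 0:
            raise ConfigError("filter parameter l must be >= 0")
        if self.n_reps < 1:
            raise ConfigError("n_reps must be >= 1")
        battery = self.filter_battery
        if battery is None:
            battery = tuple(table2_battery(self.n1, self.n2))
        else:
            battery = tuple(battery)
            if len(battery) == 0:
                raise ConfigError("filter_battery must contain at least one filter")
        if self.reference not in battery:
            battery = battery + (self.reference,)
        object.__setattr__(self, "filter_battery", battery)

    @property
    def reference_index(self) -> int:
        return self.filter_battery.index(self.reference)

    def with_(self, **kwargs) -> "ScenarioConfig":
        return replace(self, **kwargs)
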