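"""Adaptive filter selection: run a filter battery, count rejections per
filter, and pick the filter with the largest rejection count, falling back to
a pre-declared reference filter when the maximum is too small.

Pre-processing orders:
  (a) normalise and test once on the basic-filter survivors, then for each
      filter restrict the p-value vector to its survivors and adjust;
  (b) for each filter, reduce the raw count matrix first, then normalise,
      test and adjust on the reduced matrix.
The keep-masks themselves are identical between the orders (filters operate
on raw counts); what changes is the data the normalisation and the
mean-variance trend see.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .containers import CountMatrix, FilterSpec, FilterResult, ScenarioConfig
from .de import cpm, tmm_factors, voom_transform, moderated_test
from .filters import apply_filter
from .multiplicity import AdjustedResult, adjust

__all__ = ["AdaptiveSelection", "BatteryResult", "run_battery", "select",
           "adaptive_analyze"]

logger = logging.getLogger("adafilter")


@dataclass(frozen=True)
class BatteryResult:
    """Per-filter outcome of one battery run."""

    battery: tuple[FilterSpec, ...]
    filter_results: tuple[FilterResult, ...]
    adjusted: tuple[AdjustedResult, ...]
    R: np.ndarray                      # rejection counts R_1..R_F
    rejection_masks: tuple[np.ndarray, ...]  # gene-level, length m each


@dataclass(frozen=True)
class AdaptiveSelection:
    """The adaptive decision: R vector, chosen index k and fallback flag."""

    R: np.ndarray
    k: int
    fallback_fired: bool
    chosen: FilterSpec
    rejected_genes: np.ndarray

    def __post_init__(self):
        if not self.fallback_fired and self.R[self.k] != self.R.max():
            raise ValueError("chosen filter must attain the maximum R")

    @property
    def n_rejected(self) -> int:
        return int(self.rejected_genes.sum())


def _test_pvalues(counts: CountMatrix) -> np.ndarray:
    """TMM + voom + moderated t on a (sub)matrix; returns per-gene p-values."""
    factors = tmm_factors(counts)
    norm = voom_transform(counts, factors=factors, groups=counts.groups)
    return moderated_test(norm, counts.groups).p_values


def run_battery(counts: CountMatrix, battery, alpha: float = 0.05,
                adjustment: str = "lfdr", order: str = "a") -> BatteryResult:
    """Apply every filter of the battery and adjust per filter.

    A filter that leaves no testable genes reports R_f = 0 with a warning
    instead of raising.
    """
    battery = tuple(battery)
    if len(battery) == 0:
        raise ValueError("battery must contain at least one filter")
    if order not in ("a", "b"):
        raise ValueError("order must be 'a' or 'b'")
    m = counts.m
    raw_cpm = cpm(counts.counts)
    basic_keep = (counts.counts > 0).any(axis=1)

    filter_results = tuple(
        apply_filter(spec, counts, groups=counts.groups,
                     n1=counts.n1, n2=counts.n2, cpm_matrix=raw_cpm)
        for spec in battery
    )

    if order == "a":
        pvals = np.full(m, np.nan)
        if basic_keep.sum() >= 2:
            pvals[basic_keep] = _test_pvalues(counts.subset_genes(basic_keep))

    adjusted_list: list[AdjustedResult] = []
    masks: list[np.ndarray] = []
    R = np.zeros(len(battery), dtype=np.int64)
    for f, (spec, fres) in enumerate(zip(battery, filter_results)):
        keep = fres.keep
        if order == "b":
            pvals = np.full(m, np.nan)
            testable = keep & basic_keep  # all-zero genes are never testable
            if testable.sum() >= 2:
                pvals[testable] = _test_pvalues(counts.subset_genes(testable))
        sel = keep & np.isfinite(pvals)
        if sel.sum() < 2:
            logger.warning("filter %s leaves %d testable genes; R set to 0",
                           spec.name, int(sel.sum()))
            adj = AdjustedResult(adjustment, np.empty(0),
                                 np.empty(0, dtype=bool), alpha)
            mask = np.zeros(m, dtype=bool)
        else:
            adj = adjust(pvals[sel], adjustment, alpha)
            mask = np.zeros(m, dtype=bool)
            mask[np.flatnonzero(sel)] = adj.rejected
        adjusted_list.append(adj)
        masks.append(mask)
        R[f] = mask.sum()
    return BatteryResult(battery, filter_results, tuple(adjusted_list), R,
                         tuple(masks))


def select(R, l: int, reference_index: int, strict: bool = False):
    """Choose k = argmax_f R_f with the declared tie rule, then apply the
    reference fallback.

    Ties at the maximum go to the reference filter if it attains the maximum,
    otherwise to the earliest filter in battery order. The fallback fires when
    R_k <= l (matching the operational "5 or less rejections" rule for l = 5);
    ``strict=True`` restores the literal R_k < l condition.
    """
    R = np.asarray(R)
    if R.size == 0:
        raise ValueError("R must be non-empty")
    if not (0 <= reference_index < R.size):
        raise ValueError("reference_index out of range")
    max_R = R.max()
    if R[reference_index] == max_R:
        k = int(reference_index)
    else:
        k = int(np.argmax(R))
    fallback = (max_R < l) if strict else (max_R <= l)
    if fallback:
        k = int(reference_index)
    return k, bool(fallback)


def adaptive_analyze(counts: CountMatrix, config: ScenarioConfig,
                     battery_result: BatteryResult | None = None,
                     strict: bool = False) -> AdaptiveSelection:
    """Full adaptive analysis: battery run + selection rule.

    A precomputed ``battery_result`` may be supplied (the benchmark harness
    reuses one run for per-filter and adaptive metrics).
    """
    if battery_result is None:
        battery_result = run_battery(counts, config.filter_battery,
                                     alpha=config.alpha,
                                     adjustment=config.adjustment,
                                     order=config.order)
    k, fallback = select(battery_result.R, config.l, config.reference_index,
                         strict=strict)
    chosen = battery_result.battery[k]
    selection = AdaptiveSelection(battery_result.R, k, fallback, chosen,
                                  battery_result.rejection_masks[k])
    logger.info("adaptive choice: %s (R=%d, fallback=%s, filtered %.3f)",
                chosen.name, selection.n_rejected, fallback,
                battery_result.filter_results[k].proportion_filtered)
    return selection
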