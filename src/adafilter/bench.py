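"""Monte-Carlo harness: power, FDR and proportion-filtered estimates per
filter (including the adaptive filter) over replicated NB scenarios.

Per-replicate seeds are spawned deterministically from the scenario seed so
every filter sees identical data within a replicate (paired comparison) and
results are reproducible and parallelisable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import ScenarioConfig, NBParamTable, ConfigError
from .simulate import simulate_nb_fixed, simulate_nb_distributed, scale_to_depth
from .adaptive import run_battery, adaptive_analyze

__all__ = ["power_fdp", "run_scenario", "scenario_grid", "MetricsTable",
           "plot_power_vs_filtered"]

ADAPTIVE_ROW = "adaptive"


@dataclass(frozen=True)
class MetricsTable:
    """Per-(scenario, filter) estimates with Monte-Carlo standard errors."""

    table: pd.DataFrame

    def row(self, filter_name: str) -> pd.Series:
        return self.table.loc[self.table["filter"] == filter_name].iloc[0]

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def power_fdp(truth, rejected) -> tuple[float, float]:
    """(multiple power, false discovery proportion) of one rejection mask.

    Power = |rejected & DE| / |DE| (NaN when there are no DE genes);
    FDP = |rejected & null| / |rejected| with the 0/0 := 0 convention.
    """
    is_null = np.asarray(truth.is_null if hasattr(truth, "is_null") else truth,
                         dtype=bool)
    rejected = np.asarray(rejected, dtype=bool)
    if is_null.shape != rejected.shape:
        raise ValueError("truth and rejection masks must have equal length")
    n_de = (~is_null).sum()
    n_rej = rejected.sum()
    true_pos = (rejected & ~is_null).sum()
    false_pos = (rejected & is_null).sum()
    power = true_pos / n_de if n_de > 0 else np.nan
    fdp = false_pos / n_rej if n_rej > 0 else 0.0
    return float(power), float(fdp)


def _simulate(config: ScenarioConfig, seed) -> tuple:
    nb = dict(config.nb_params)
    strategy = nb.pop("strategy", "fixed")
    depth = nb.pop("depth", None)
    if strategy == "fixed":
        if depth is not None:
            nb["mu0"] = depth / config.m
        return simulate_nb_fixed(config.m, config.n1, config.n2, config.pi0,
                                 seed=seed, **nb)
    if strategy == "distributed":
        table = nb.pop("param_table")
        if not isinstance(table, NBParamTable):
            table = NBParamTable(**table)
        if depth is not None:
            table = scale_to_depth(table, depth)
        return simulate_nb_distributed(table, config.m, config.n1, config.n2,
                                       config.pi0, seed=seed, **nb)
    raise ConfigError(f"unknown simulation strategy {strategy!r}")


def run_scenario(config: ScenarioConfig, scenario_name: str = "scenario",
                 strict: bool = False, check_invariants: bool = True) -> MetricsTable:
    """Estimate power/FDR/proportion filtered for every battery filter and
    the adaptive rule, averaging over ``config.n_reps`` replicates.

    ``check_invariants`` asserts on every replicate that the adaptive
    rejection count equals max_f R_f when that max clears l, and the
    reference count otherwise.
    """
    names = [spec.name for spec in config.filter_battery] + [ADAPTIVE_ROW]
    n_filters = len(names)
    power = np.full((config.n_reps, n_filters), np.nan)
    fdp = np.zeros((config.n_reps, n_filters))
    rejections = np.zeros((config.n_reps, n_filters))
    prop_filtered = np.full((config.n_reps, n_filters), np.nan)
    fallback = np.zeros(config.n_reps, dtype=bool)

    child_seeds = np.random.SeedSequence(config.seed).spawn(config.n_reps)
    for rep, child in enumerate(child_seeds):
        rng = np.random.default_rng(child)
        counts, truth = _simulate(config, rng)
        battery_result = run_battery(counts, config.filter_battery,
                                     alpha=config.alpha,
                                     adjustment=config.adjustment,
                                     order=config.order)
        for f in range(len(config.filter_battery)):
            mask = battery_result.rejection_masks[f]
            power[rep, f], fdp[rep, f] = power_fdp(truth, mask)
            rejections[rep, f] = battery_result.R[f]
            prop_filtered[rep, f] = battery_result.filter_results[f].proportion_filtered
        selection = adaptive_analyze(counts, config,
                                     battery_result=battery_result,
                                     strict=strict)
        if check_invariants:
            expected = (battery_result.R[config.reference_index]
                        if selection.fallback_fired else battery_result.R.max())
            if selection.n_rejected != expected:
                raise AssertionError("adaptive rejection-count invariant violated")
        a = n_filters - 1
        power[rep, a], fdp[rep, a] = power_fdp(truth, selection.rejected_genes)
        rejections[rep, a] = selection.n_rejected
        prop_filtered[rep, a] = battery_result.filter_results[selection.k].proportion_filtered
        fallback[rep] = selection.fallback_fired

    def _mean_se(mat):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN slices
            mean = np.nanmean(mat, axis=0)
            if config.n_reps > 1:
                se = np.nanstd(mat, axis=0, ddof=1) / np.sqrt(config.n_reps)
            else:
                se = np.full(mat.shape[1], np.nan)
        return mean, se

    pw, pw_se = _mean_se(power)
    fd, fd_se = _mean_se(fdp)
    rj, rj_se = _mean_se(rejections)
    pf, _ = _mean_se(prop_filtered)
    table = pd.DataFrame({
        "scenario": scenario_name,
        "filter": names,
        "power": pw, "power_se": pw_se,
        "fdr": fd, "fdr_se": fd_se,
        "mean_rejections": rj, "rejections_se": rj_se,
        "mean_proportion_filtered": pf,
        "n_reps": config.n_reps,
    })
    table["fallback_rate"] = np.nan
    table.loc[table["filter"] == ADAPTIVE_ROW, "fallback_rate"] = fallback.mean()
    return MetricsTable(table)


def scenario_grid(base_config: ScenarioConfig, axis: str, values) -> list[ScenarioConfig]:
    """Scenario configs differing only along one axis (pi0, m, n, depth).

    All configs share the base seed: replicate r of every scenario uses the
    r-th spawned stream, so scenarios are compared on matched noise.
    """
    configs = []
    for v in values:
        if axis == "pi0":
            configs.append(base_config.with_(pi0=v))
        elif axis == "m":
            configs.append(base_config.with_(m=int(v)))
        elif axis == "n":
            configs.append(base_config.with_(n1=int(v), n2=int(v)))
        elif axis == "depth":
            nb = dict(base_config.nb_params)
            nb["depth"] = float(v)
            configs.append(base_config.with_(nb_params=nb))
        else:
            raise ConfigError(f"unknown grid axis {axis!r}")
    return configs


def plot_power_vs_filtered(metrics: MetricsTable, ax=None):
    """Power of each filter as a function of its mean proportion of removed
    genes (matplotlib optional; parameterised families drawn as curves,
    fixed-threshold filters as points)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    table = metrics.table
    families = table["filter"].str.split("_").str[0]
    for family, sub in table.groupby(families):
        sub = sub.sort_values("mean_proportion_filtered")
        if len(sub) > 1:
            ax.plot(sub["mean_proportion_filtered"], sub["power"],
                    marker=".", label=family)
        else:
            ax.scatter(sub["mean_proportion_filtered"], sub["power"],
                       label=family, zorder=3)
    ax.set_xlabel("mean proportion of filtered genes")
    ax.set_ylabel("multiple power")
    ax.legend(fontsize="small")
    return ax
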