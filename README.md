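# adafilter

Adaptive count filtering for two-group RNA-seq differential-expression
testing.

Filtering low-count genes before multiplicity adjustment can raise the power
of an RNA-seq study — fewer hypotheses mean a less stringent correction — but
*too aggressive* filtering throws away detectable genes, and no single filter
(mean-, max-, CPM-, Jaccard- or zero-count-based, at any threshold) is
optimal across data-generating scenarios. `adafilter` implements the
**adaptive filter**: run a battery of F filters, adjust the analysis on each
filter's survivor set, record the rejection counts R_1..R_F and select

    k = argmax_f R_f ,

falling back to a pre-declared *reference filter* whenever R_k <= l (default
l = 5, reference = Jaccard). The fallback is what protects the false
discovery rate under the global null, where an unguarded argmax over many
filters would cherry-pick noise. The package provides:

- the filter battery (basic, mean, max, CPM, Jaccard, zero-count families);
- a testing core: TMM normalisation, voom-style log2-CPM transform with
  precision weights, empirical-Bayes moderated t-tests;
- multiplicity control by Benjamini-Hochberg or a Grenander-based local FDR
  (two-group mixture f(p) = eta0 + (1-eta0) g(p), lfdr = eta0 / f_hat(p));
- a negative-binomial simulation harness estimating multiple power
  (|rejected & DE| / |DE|) and FDR (mean false-discovery proportion) per
  filter and for the adaptive rule.

See `docs/methods.md` for the model, estimators and numerical choices.

## Worked example

```python
from adafilter import simulate_nb_fixed, AdaptiveFilterDE

# 2000 genes, 10 vs 10 samples, 20% DE at fold change 2
cm, truth = simulate_nb_fixed(m=2000, n1=10, n2=10, pi0=0.8, mu0=10,
                              fold_change=2.0, dispersion=0.1, seed=1)
X, y = cm.to_xy()                     # sklearn orientation: samples x genes
model = AdaptiveFilterDE(adjustment="lfdr", l=5, reference="jaccard").fit(X, y)
print("chosen filter:   ", model.chosen_.name)
print("rejections:      ", model.n_rejected_, "= max(R) =", model.R_.max())
print("fallback fired:  ", model.fallback_fired_)
rej = model.predict()
tp = (rej & ~truth.is_null).sum(); fp = (rej & truth.is_null).sum()
print(f"true/false pos:   {tp} / {fp}  (realized FDP {fp/rej.sum():.3f})")
```

prints

```
chosen filter:    max_2
rejections:       209 = max(R) = 209
fallback fired:   False
true/false pos:   206 / 3  (realized FDP 0.014)
```

The battery's best filter here is the max-based filter at the 2nd
percentile; it rejects 209 genes of which 206 are truly differentially
expressed — a realized false-discovery proportion of 1.4% at nominal level
alpha = 0.05. `model.R_` holds the full rejection-count vector, one entry
per battery filter, and `model.battery_result_` the per-filter keep-masks
and adjusted values.

The same machinery is available as plain functions (`run_battery`, `select`,
`adaptive_analyze`, `run_scenario`) and from the shell:

```sh
adafilter analyze --counts counts.tsv --groups groups.tsv \
    --adjust lfdr --alpha 0.05 --l 5 --reference jaccard --order a
adafilter benchmark --config scenario.yaml --out metrics.tsv
adafilter simulate --config scenario.yaml --out sim_counts.tsv
```

`CountFilter` is a scikit-learn feature selector (`fit`/`transform`/
`get_support`), so individual filters compose with sklearn pipelines.

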