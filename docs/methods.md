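# Methods

## Problem and model

An RNA-seq experiment compares two groups of independent samples
(sizes n1, n2, n = n1 + n2) over m genes. The count of gene i in sample j is
C_ij; for each gene the two-sided hypothesis H0i: mu_1i = mu_2i is tested
against H1i: mu_1i != mu_2i, where mu_gi is the expected count in group g.
Low-count genes carry little evidence and inflate the multiple-testing
burden, so a *filter* removes a subset of genes before the adjustment;
with fewer hypotheses the adjustment is less stringent and power increases —
unless the filter also removes detectable DE genes.

Because no single filter is optimal across data-generating scenarios, the
package implements an *adaptive* filter: a battery of F filters is applied,
the analysis is adjusted separately on each filter's survivor set, the
per-filter rejection counts R_1..R_F are recorded, and the filter

    k = argmax_f R_f

is selected. If the best filter rejects too few hypotheses (R_k <= l for a
pre-declared integer l), the procedure falls back to a pre-declared
*reference filter* instead; without this safeguard the selection step can
inflate the FDR under the global null, because with no signal the argmax
over many filters cherry-picks noise.

## Analysis pipeline

1. **Basic filter** — genes with zero counts in every sample are removed.
2. **TMM normalisation** — per-sample scale factors from weighted, doubly
   trimmed mean of gene-wise log2 fold changes against a reference sample
   (the sample whose upper-quartile count fraction is closest to the mean
   upper-quartile). Trim fractions: 30% on M-values, 5% on A-values;
   weights are inverse asymptotic (delta-method) variances; factors are
   rescaled to geometric mean 1. This reproduces the published reference
   implementation to ~1e-10 (frozen oracle test).
3. **voom transform** — log2 CPM with offsets,
   `log2((c + 0.5) / (eff_lib + 1) * 1e6)`; an unweighted gene-wise
   group-means fit gives residual sds; a lowess trend (span 0.5, 3
   robustifying iterations, delta = 1% of the x-range) of sqrt(sd) versus
   average log2 count is interpolated at the fitted log-counts; precision
   weights are predicted sd^-4, with constant extrapolation beyond the trend
   range and a 1e-6 floor on the predicted quarter-root sd so that
   all-constant data yield equal weights instead of dividing by zero.
4. **Moderated t** — per-gene weighted least squares of log2 CPM on the
   group indicator; residual variances are shrunk by empirical Bayes:
   log variances are moment-matched to a scaled inverse-chi-square prior
   (prior df d0 via a trigamma inverse, prior variance s0^2), the posterior
   variance is (d0 s0^2 + d s^2)/(d0 + d) and the moderated t has d + d0
   degrees of freedom. `prior_df=0` disables shrinkage and reduces exactly
   to the ordinary weighted two-sample t-test (tested to 1e-10). On a frozen
   fixture the whole pipeline agrees with the reference voom/limma pipeline
   to a log-p correlation > 0.999; residual differences trace to the lowess
   implementations.
5. **Multiplicity** — BH step-up or local FDR (below) at alpha = 0.05;
   rejection uses `adjusted <= alpha` for BH and the strict `lfdr < alpha`
   for the local FDR.

Two pre-processing orders are supported. Order (a): normalise and test once
on the basic survivors, then restrict the p-value vector to each filter's
survivors before adjusting. Order (b): reduce the raw count matrix per
filter, then normalise and test on the reduced matrix. Keep-masks are
computed from raw counts in both orders and are identical between them; what
changes is the data seen by the normalisation and the mean-variance trend.
Under order (a) the `none` option adjusts over the basic survivors (genes
with all-zero counts have no defined test); on data without all-zero genes
`none` and `basic` coincide exactly.

## Filter families

All filter statistics are computed on raw counts (CPM uses raw library
sizes, without TMM factors — filtering precedes or parallels normalisation);
every family except `none` is composed with the basic filter, and percentile
cutoffs / Jaccard indices are computed among basic survivors only.

- **mean / max** — remove genes whose mean (max) count lies strictly below
  the linear-interpolation empirical percentile of the mean (max) counts.
  Strict removal makes tied statistics stay in the analysis, so the realized
  removal proportion can fall below the nominal percentage under ties. A
  relative tolerance of 1e-9 on the cutoff keeps exact ties that percentile
  interpolation rounding would otherwise break.
- **cpm** — remove genes with CPM < c in more than min(n1, n2) samples;
  default grid c in {1, 2, 5, 25, 50, 100}.
- **zero** — remove genes with more than u zero counts (strict). Under this
  convention the basic filter is the u = n - 1 member of the family. Default
  grid u = n-4, ..., 1 (u = 16..1 at n = 20).
- **jaccard** — for each within-condition replicate pair and cutoff v,
  the index |both > v| / |either > v| (0 when the union is empty); the
  global index at v is the simple average over all within-condition pairs
  pooled across both conditions. A lowess curve (span 0.5) is fitted through
  (v, global index) over a candidate grid (distinct observed counts up to
  the 95th percentile of non-zero counts, at most 50 quantile-spaced
  points), and v* is the grid point maximising the smoothed curve, ties
  going to the smallest v. v* is then applied as a max-based cutoff:
  keep genes with max count > v*, matching the `> v` dichotomisation of the
  index itself.

The full default battery at n = 20 has F = 81 members: 28 mean + 28 max +
6 cpm + 1 jaccard + 16 zero + basic + none.

## Local FDR estimator

The p-values are modelled as the two-group mixture
f(p) = eta0 + (1 - eta0) g(p) with uniform null and nonincreasing
alternative density g; lfdr(p) = min(1, eta0 / f(p)).

- **eta0** — censored truncated-uniform estimate
  eta0(t) = #{p > t} / (M (1 - t)) over a cutoff grid t of distinct
  p-values between their median and 90th percentile (so the censored window
  always keeps enough mass for a stable fit; at most 200 quantile points).
  The retained cutoff is the one whose censored window looks most null,
  i.e. with the largest eta0(t) (equivalently, the smallest estimated
  fraction of alternatives hidden above the cutoff), clipped to [0, 1].
  Each candidate already over-estimates eta0 in expectation (alternatives
  leaking above the cutoff count as nulls), so the envelope is deliberately
  conservative: an over-estimated eta0 inflates every lfdr, which is the
  safe direction for FDR control. Under a pure-uniform null the envelope
  clips to 1 in almost every realisation, making the estimator strongly
  specific (essentially never rejecting under the global null). The cost is
  conservatism at small M, where the estimate often saturates at 1 and the
  lfdr rule rejects nothing — the adaptive procedure then falls back to the
  reference filter.
- **density** — when eta0 < 1, the alternative CDF is estimated as the
  monotonised, clipped (F_n(p) - eta0 p)/(1 - eta0) and its Grenander
  estimate (left derivative of the least concave majorant, computed as the
  antitonic PAVA regression of the chord slopes weighted by the x
  increments) gives g_hat; f_hat = eta0 + (1 - eta0) g_hat. This enforces
  f_hat >= eta0 *and* makes the fitted density integrate to exactly 1 —
  flooring the marginal Grenander estimate at eta0 would do neither.
  The density is evaluated left-continuously at the observed p-values, so
  lfdr is a nondecreasing step function of p. When eta0 = 1 the fitted
  density is identically 1 and no hypothesis is rejected; all-identical
  p-values likewise return eta0 = 1 with no rejections.

## Adaptive selection details

- Fallback condition: the operational rule is R_k <= l ("l or fewer
  rejections fall back"); a strict-mode switch restores R_k < l. The two
  readings differ only when R_k = l exactly.
- Tie-breaking at the maximum: the reference filter wins ties it
  participates in; otherwise the earliest filter in battery order wins.
  Preferring the reference at ties is the conservative choice.
- Defaults: reference = Jaccard, l = 5, lfdr adjustment, order (a).

## Synthetic data generator

`simulate_nb_fixed` draws counts independently per gene and sample from a
negative binomial with variance mu + phi mu^2 (phi = dispersion; phi = 0
degenerates to Poisson). Exactly ceil(pi0 * m) genes are null with mean mu0
in both groups; DE genes keep mu0 in group 1 and get mu0 * fc (half,
up-regulated) or mu0 / fc (half, down) in group 2, so mean library size
stays roughly balanced between groups. Defaults: mu0 = 10 (a sequencing
depth of 10m reads spread over m genes, the middle of the 5m/10m/50m depth
range the depth axis exposes), phi = 0.1 and fc = 2 (typical bulk RNA-seq
magnitudes). These are explicit knobs, not published values.

`simulate_nb_distributed` resamples per-gene (mean, dispersion) pairs
jointly with replacement from a parameter table, preserving their empirical
dependence, with an optional fraction of structurally-zero genes (emulating
libraries where many genes never produce a read); the table can come from a
file or from `synthetic_param_generator` (log-normal means, gamma
dispersions), and `scale_to_depth` rescales its means to a fixed expected
per-sample total. `simulate_low_count_null_mixture` stacks a block of
low-count null genes onto a regular block carrying the DE signal, the
configuration in which moderate filtering helps and aggressive filtering
hurts.

What the generator does *not* emulate: gene-gene correlation, real-data
dispersion-mean trends, library-size variation between samples beyond the
NB noise itself, and resampling of real count columns. Passing tests
therefore demonstrate the procedure's behaviour under independent NB genes,
not under arbitrary real-data dependence; with correlated genes the BH and
lfdr guarantees themselves weaken.

## Benchmark harness and problem sizes

`run_scenario` spawns one child seed per replicate from the scenario seed,
so all filters are compared on identical data (paired comparison), and
reruns with the same config are byte-identical. Per replicate it runs the
battery once (order (a) tests once and re-adjusts per filter), records
power = |rejected & DE| / |DE| (missing when there are no DE genes, never
0), FDP = |rejected & null| / |rejected| (0/0 := 0), rejections and the
proportion filtered (relative to basic survivors; for the basic filter,
relative to m). The FDR estimate is the mean FDP across replicates with its
Monte-Carlo standard error.

The packaged FDR studies use m = 2500 with 500 replicates and
m in {100, 500} with 1000 replicates (n1 = n2 = 10, pi0 in {0.8, 1.0}, full
battery, lfdr, l = 5, Jaccard reference); these sizes put each study at a
few CPU-minutes while keeping Monte-Carlo standard errors of the FDR
estimate near 0.001-0.004. The default `ScenarioConfig` keeps the study
design's m = 10000 and n_reps = 1000 for users who want the full-scale run.

## Numerical choices and degenerate inputs

- TMM: samples that are exact scalar multiples of the reference give factor
  1 (all M-values below 1e-6 short-circuit); a zero-library sample is an
  error. TMM factors are only approximately invariant to rescaling one
  sample's counts, because the precision weights depend on depth — the
  behaviour of the reference implementation, against which factors are
  checked.
- voom needs at least 2 genes (trend) and 3 samples (residual df);
  moderated_test requires at least one residual df and both groups
  non-empty.
- A filter that leaves fewer than two testable genes reports R_f = 0 with a
  warning instead of crashing.
- BH on an empty vector returns zero rejections without error.
- Jaccard requires two replicates per condition; with identical replicates
  the score curve ties at 1 and the smallest candidate cutoff is chosen.

## Known limitations

- The lfdr estimator is deliberately conservative; its rejection counts lie
  below BH's on matched data, markedly so at small M. FDR control is the
  design goal, power is secondary.
- Order (b) re-normalises and re-tests per filter and is therefore ~F times
  slower than order (a); benchmarks default to order (a).
- Only two-group designs (intercept + group indicator) are supported, and
  only the filter families listed above.
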