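# Methods

## Model and procedure

**Ranking index.** Each miRNA's differential-expression result is
reduced to `r = -sign(statistic) * ln(p)`. The natural logarithm is
used throughout; `sign(0) := 0`, so a zero statistic gives `r = 0`
regardless of p, and `p = 1` likewise gives 0. Any upstream test that
produces a signed statistic and a p-value is acceptable — the index only
assumes that p-values are comparable across miRNAs and that the sign
encodes direction (positive = overexpressed in cases). Zero p-values
(possible with aggressive upstream rounding) are clamped to the smallest
positive normal double (≈2.2e-308, i.e. |r| ≤ ~708) with a warning,
since the transform is undefined at 0.

**Transfer.** The gene-level score is the weighted sum of the ranking
indexes of all miRNAs targeting the gene, `t_i = Σ_{j∈G_i} w_ij r_j`,
with `w = 1` unless a weight column is supplied (weights are a
per-pair multiplicative factor encoding target-prediction confidence).
miRNAs present in the target map but absent from the ranking contribute
nothing (warned, with a count); a target map sharing no miRNA with the
ranking is an error. Duplicate (miRNA, gene) pairs are collapsed at load
time keeping the maximum weight, because a pair is a membership
relation. If an expressed-gene list is supplied, genes outside it have
`t` forced to 0 (no transcript, no miRNA-mediated contrast) but keep
their targeted flag. Contributions are summed in a fixed
(gene, miRNA, weight) order so the result is bitwise independent of
input row order.

**Universe.** Only genes targeted by at least one miRNA enter the
set-level analysis. Genes whose score is 0 through cancellation or the
expressed-gene rule remain in the universe; genes absent from the
target map never do. Untargeted genes would contribute structural zeros
that carry no information about the contrast and would only dilute the
membership model.

**Set-level model.** For each set F, membership of universe genes is
regressed on `t` by maximum-likelihood logistic regression
(`logit P(g∈F) = κ + α t_g`, statsmodels Newton). Significance of the
slope is a two-sided Wald test; a likelihood-ratio test would behave
near-identically for a single scalar slope and is not provided.
Adjusted p-values are computed jointly across all tested sets by
Benjamini-Hochberg (default) or Benjamini-Yekutieli step-up.
Classification: adjusted p below the significance level and `α > 0` →
`inhibited_in_cases`; below level and `α < 0` → `deregulated_in_cases`
(the set is enriched in genes inhibited in controls); anything else,
including a failed fit, → `not_significant`.

## Parameters and defaults

| parameter | default | meaning / rationale |
|---|---|---|
| `min_set_size`, `max_set_size` | 10, 500 | bounds on annotated genes *within the universe*; standard gene-set-analysis practice — tiny sets are unstable, huge sets uninformative |
| `fdr_method` | BH | BY available for arbitrary dependence |
| `significance_level` | 0.05 | applied to adjusted p-values |
| `normalize_index` | on | rank-based inverse-normal transform (quantiles at rank/(n+1), average ranks on ties) of the targeted genes' scores before fitting |
| permutations (`null`) | 20 | enough to estimate a mean significant fraction at desk scale |

`normalize_index` deserves a note: transferred scores are sums of
signed log-p values and are strongly heavy-tailed (a single p ≈ 1e-30
contributes |r| ≈ 69). A handful of extreme-leverage genes can dominate
or destabilise the logistic MLE. The rank-INT is strictly monotone, so
it preserves the ranking semantics while giving the covariate a fixed
standard-normal scale; it also makes the null distribution of the Wald
p-values accurately uniform (verified in the calibration tests). The
flag can be switched off to fit on the raw scale.

**Degenerate fits.** Perfect separation (in one covariate: the two
classes split by a threshold) and non-convergence are flagged
`converged = false`; the record is retained with NA estimates and
classified not significant, never silently dropped. A universe lacking
members or non-members is a caller error, distinct from
non-convergence. A set covering the entire universe carries no contrast
and is skipped with a warning.

## Permutation null model

The type-I-error experiment permutes the *gene column* of the target
table: each (miRNA, gene) row keeps its miRNA (and weight slot) and
receives a uniformly permuted gene. This preserves the per-miRNA target
counts and the gene-id multiset — hence the annotation structure —
while destroying every biological miRNA–gene association. Duplicate
pairs arising by chance are kept (deduplication would alter the
preserved degree sequence). The full pipeline (transfer + set-level
fit + FDR) is rerun per permutation and the fraction of sets with
adjusted p below the level is recorded; per-permutation random streams
are spawned deterministically from the single experiment seed.

## Synthetic data

The generator emulates the statistical structure of the pipeline's
inputs, not any particular cohort. Defaults: 300 miRNAs, 2000 genes,
each miRNA targeting 2–10 distinct genes uniformly at random, 200
candidate sets of 20–100 genes, one planted set with effect δ = 1.5,
unit noise. Null statistics are drawn from Normal(0, σ) with two-sided
p-values from the same reference, so the ranking index is exactly
recoverable from the emitted table (round-trip to 1e-12, by
construction). Effects are planted at the **miRNA level**: every miRNA
targeting at least one member gene of a planted set has δ added to its
statistic before the p-value is computed. Detection therefore exercises
the entire transfer mechanism — the member genes' scores shift only
because their regulators' statistics shift — rather than just the
set-level fit.

What the generator does *not* emulate: count data and the upstream
differential-expression test, paired designs, correlated miRNA
behaviour, the empirical (much heavier-tailed) degree distribution of
real target databases, or annotation overlap between sets. Passing
tests therefore demonstrate the correctness and calibration of the
transfer + set-level machinery under clean conditions, not robustness
to the pathologies of real target predictions.

A small hand-built fixture probes the two signature regimes with frozen
numbers: a gene targeted by two miRNAs with ranking indexes +67.34 and
−66.61 (reverse-engineered p = exp(−|r|)), whose transferred score
collapses to 0.73; and a gene targeted by 16 individually weak miRNAs
(each |r| < 10) whose indexes sum to −53.65.

## Numerical choices

* Ties in the rank-INT use average ranks; all-tied inputs map to 0.
* FDR adjustment passes missing p-values (failed fits) through as
  missing without counting them as tests.
* Results are serialised to 6 significant digits with `NA` for missing;
  stats/target tables are written at full (17 significant digit)
  precision so file round-trips are exact.
* Identifier matching is exact-string and case-sensitive; id aliasing
  belongs upstream.
* All randomness (generator, permutations) flows from explicit seeds;
  per-permutation streams are spawned from a `SeedSequence`, so results
  are reproducible and independent of execution order.

## Problem sizes used in the checks

The acceptance checks run the permutation experiment at 20 permutations
of the default scenario (~4000 set-level fits), the null calibration on
1000 random sets over one 2000-gene universe, and the recovery check on
50 generated studies (100 sets each, planted set of 50 genes, δ = 1.5).
Measured behaviour at these sizes: mean significant fraction under
permutation ≈ 0.1% (bound: 5%), raw null p-values uniform by KS test,
planted-set recovery 50/50 seeds with the correct slope sign.

## Known limitations

* Target-prediction noise propagates directly into `t`; weights can
  mitigate but not remove it.
* Sets are tested marginally; overlapping sets are not deconvolved, and
  no multidimensional (joint miRNA + mRNA) model is provided.
* The logistic model treats genes as independent observations; genes
  co-targeted by the same miRNAs have correlated scores, which the
  Wald test ignores (the permutation experiment is the empirical check
  that this does not inflate type-I error at the tested scales).
* Wald p-values for very small universes or very small sets are
  approximate; the size filter is the practical guard.
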