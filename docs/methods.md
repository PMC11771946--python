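# Methods

## The analysis model

The pipeline scores label-free peptide intensities from a proximity-labeling
panel: one negative-control condition expressing the unfused biotin ligase
and several bait-fusion conditions, each in *n* = 3 biological replicates.
The quantity of interest for protein group *g* in bait condition *c*,
replicate *r*, is the ratio

    R(g, c, r) = P(g, sample(c, r)) / P(g, sample(control, r))

of trimmed-mean-normalized, summed protein intensities, tested on the log2
scale. The implicit model is multiplicative: intensities are log-normal,
replicate noise and instrument/sample loading effects act as per-cell and
per-column scale factors, and a true interactor shifts its bait intensities
by a constant factor. Under that model the replicate log2 ratios of a
non-interactor are i.i.d. with mean 0, so a one-sample t-test (df = n−1) is
exact, and the geometric mean of the ratios estimates the fold enrichment.

### Stage conventions and degenerate cases

**Razor assignment.** Candidate counts are taken in a single pass over the
input (each accession's count = number of peptides listing it), and each
shared peptide goes to the candidate with the largest count; equal counts
break to the lexicographically smallest accession. Re-counting iteratively
after each assignment would be an alternative dialect; the single pass is
deterministic and equivalent except on adversarial inputs.

**Coverage.** Peptide positions are unavailable in intensity tables, so
coverage is the summed length of the distinct assigned peptide sequences,
capped at the protein length, over the protein length. Masters are the
argmax of coverage, ties again lexicographic.

**Missingness filter.** A peptide is retained iff some condition group has
≥ `min_observed` (default 2) observed replicates. The alternative reading —
≥ 2 observations anywhere — is available as `filter_scope="global"`; the
group reading is the default because the imputation rules that follow are
defined per condition group.

**Imputation.** Per peptide per condition group: one missing value is
replaced by the arithmetic mean of the observed ones (deterministic,
seed-independent); two or more missing values (including a fully missing
group of a peptide retained through another condition) are each drawn
independently and uniformly from `[min_s, Q_s(q)]`, where `min_s` and
`Q_s(q)` are the minimum and the `q` = 0.02 linear-interpolation empirical
quantile of sample *s*'s observed values *before any imputation*. The
per-sample scoping respects sample-specific detection limits; the uniform
draw is the least-informative choice on the stated interval. If every
observed value of a sample equals a constant the interval collapses and the
imputed value is that constant. A sample with zero observed values has no
detectable-signal distribution and is a fatal input error. All draws come
from one seeded generator, so a fixed seed reproduces the output exactly.

**Trimmed-mean normalization.** With `trim` = 0.10, each column discards its
lowest and highest `floor(trim·n)` entries (rank-based; ties keep insertion
order) and the remaining values are averaged; column *s* is scaled by
`M / m(s)` with `M` the grand mean of the per-column trimmed means. The
target `M` preserves the overall intensity scale. A data-dependent target
cannot make the *matrix* exactly invariant to rescaling one column — the
global constant `M` moves — but the constant cancels in every downstream
ratio, so control-relative ratios, p-values and all calls are exactly
invariant to per-column rescaling; the test suite checks both facts (ratio
invariance at 1e−9, matrix equality up to one global factor). The operation
is idempotent to 1e−9. Requires at least `ceil(1/(1−2·trim))` rows.

**Ratios.** Control normalization is replicate-matched (bait replicate *r*
over control replicate *r*), because each biological trial produced one
replicate of every condition from the same cell pool; a condition-mean
option (`replicate_matched=False`) is provided. The same replicate-matched
rule produces the second-level mutant-over-WT ratios, computed only for
each mutant's significant hits.

**Testing.** Default: two-sided one-sample t on replicate log2 ratios vs 0.
Rationale: the ratios are the stated normalized quantity, their logs
symmetrize the multiplicative noise, and n = 3 gives df = 2. Zero-variance
rows are pinned (p = 1 if the mean log ratio is 0, else p = 0) so mean
imputation of duplicated values cannot produce undefined p-values. A Welch
two-sample variant on log2 normalized intensities (`test_kind="two_sample"`)
and a linear-scale variant (`test_scale="linear"`) exist for sensitivity
analysis, as does optional Benjamini–Hochberg adjustment — off by default,
since the headline calling rule thresholds the raw p at α = 0.05 jointly
with fold change > 1.5.

**Set partition.** "Unique" interactors of a condition are those absent
from every other bait condition, wild type included; the percent-unique
denominator is that condition's full significant set (0 when empty). A
mutants-only denominator is available (`unique_denominator="mutants"`).
Severity labels (severe/mild/reference) are configuration, so the partition
applies to any bait panel. Venn regions are exact exclusive-region counts
and always sum to the union size.

## The synthetic generator

`generate_experiment` emulates the features the analysis is sensitive to:

- **Abundances**: protein *i* gets `A_i ~ LogNormal(μ=16, σ=1.5)` (natural
  log), spanning the ~4 decades typical of label-free intensities.
- **Peptides**: 2–6 peptides per protein, with fixed Dirichlet(5) fractional
  yields of the protein abundance, so summation roll-up recovers protein
  effects exactly in expectation.
- **Planted effects**: selected proteins in bait conditions are multiplied
  by `2^effect_log2fc` (default 3); the negative control is never planted.
  Planted sets are drawn per condition, or pinned explicitly to create
  cross-condition structure.
- **Noise**: multiplicative log-normal replicate noise with CV 0.2 (a
  typical between-replicate spread for affinity-purification LFQ), optional
  per-sample scale biases.
- **Missingness**: cells below the per-sample 20% intensity quantile are
  censored with probability 0.4 — missing-not-at-random, concentrated at
  low abundance, which is the regime the bottom-2% imputation rule assumes.
  Censoring uses a seed stream independent of generation, so missingness
  settings can vary without changing the underlying intensities (and the
  missing-cell count is monotone in the censoring probability).
- **Shared peptides**: a fraction (default 5%) of peptides carries a second
  candidate accession to exercise razor assignment.

Noise level, missingness rates and abundance spread are not published for
the target experiment; the defaults above are field-typical choices and are
deliberately not tuned. What passing tests show is therefore that the
*procedure* is correct and calibrated under its stated model — exact
multiplicative effects, independent log-normal noise, quantile-censored
missingness. Real data add peptide-level interference, correlated noise,
ionization nonlinearity and FDR-filtered identifications, none of which the
generator models; recovery rates on synthetic data are upper bounds, not
forecasts.

## Problem sizes and numerical choices

Null calibration uses 2,000 proteins (≈10,000 group × condition tests), at
which 3 binomial standard errors around α = 0.05 is ±0.015. Truth-recovery
runs use 200–2,000 proteins; the full suite and the acceptance script each
run in well under a minute on one CPU. Quantiles are linear-interpolation
empirical quantiles throughout (pandas default), pinned because the 2%
quantile of 18-sample columns is convention-sensitive. Matrix states are
enforced as a one-way chain (raw → trimmed_normalized → control_relative →
wt_relative) to make transformation order a type-level invariant.
Fold change and log2fc are stored redundantly and checked against each
other at 1e−9.

## Known limitations

- Protein inference implements razor + identical-set grouping only; no
  parsimony/ILP inference, no isoform resolution.
- Coverage without peptide positions over-estimates when peptides overlap.
- No model-based imputation (kNN, left-censored ML); the two fixed rules
  are intentional for fidelity to the target workflow.
- The t-test flavor applied by the original quantification software is not
  recoverable from its description; both plausible variants are implemented
  and neither intent is asserted.
- With three replicates, df = 2: p-values are heavy-tail sensitive and the
  fold-change arm of the conjunction does most of the filtering for noisy
  groups.
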