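# proxidiff

Differential interactome analysis for proximity-labeling (TurboID/BioID)
label-free proteomics.

Proximity labeling fuses a promiscuous biotin ligase to a bait protein,
biotinylating everything in the bait's neighborhood; streptavidin capture
followed by quantitative mass spectrometry then lists candidate interactors.
Because the ligase also biotinylates bystanders, every bait condition must
be scored against an unfused-ligase negative control, and when the panel
contains several bait variants (here: wild-type DDX3X and four missense
variants, two clinically severe and two mild, in neural progenitor cells)
the interesting biology is in the *set structure* — which interactors are
shared by the whole panel, which are gained only by variants, which track
clinical severity, and which are variant-specific.

`proxidiff` takes peptide-level intensity tables (tab-delimited exports of
the quantification software) plus a design table and runs:

1. **Protein inference** — razor assignment (a shared peptide goes to the
   candidate protein with the most identified peptides), grouping of
   accessions with identical peptide sets, master selection by % sequence
   coverage.
2. **Missingness filter** — a peptide is kept only if observed in ≥2
   replicates of at least one condition.
3. **Imputation** — one missing replicate in a group of three is replaced by
   the mean of the other two; two or more missing are drawn uniformly from
   the bottom 2% of that sample's detected intensities (left-censored
   missingness).
4. **Quantification** — peptide intensities are summed per protein group;
   samples are rescaled so their 10%-trimmed means agree; each bait sample
   is divided by its replicate-matched control.
5. **Enrichment calling** — per protein group and bait condition, the fold
   change is the geometric mean of replicate ratios
   `FC_g = 2^(mean_r log2 R_{g,r})` and the p-value a two-sided one-sample
   t-test of the log2 ratios against 0 (df = n−1). A hit requires
   `FC > 1.5` **and** `p < 0.05`. Mutant hits are additionally re-expressed
   relative to the wild-type bait.
6. **Set partition** — the shared core (∩ of all baits), severity-shared
   sets ((∩ severe) \ WT, (∩ mild) \ WT), all Venn regions of the mutant
   sets with WT members removed, and per-condition unique interactors with
   their percentages.

A synthetic-data generator (`proxidiff.simulate`) produces peptide tables
with the same statistical structure — log-normal abundances, planted
enrichment, shared peptides, per-sample scale biases, intensity-dependent
censoring — together with ground truth, so the whole chain is testable
without any mass-spectrometry download.

## Worked example

```python
from proxidiff import (SimulationConfig, design_for, generate_experiment,
                       run_from_tables)

cfg = SimulationConfig(n_proteins=200, n_planted_per_condition=20, seed=7)
table, truth = generate_experiment(cfg)          # peptides + ground truth
res = run_from_tables(table, design_for(cfg))    # full pipeline in memory
part = res["partition"]

print({c: len(s) for c, s in sorted(part.per_condition.items())})
print(len(part.core), len(part.severe_shared))
```

prints

```
{'R326H': 21, 'R376C': 22, 'R488H': 20, 'T532M': 23, 'WT': 22}
0 2
```

Each condition had 20 proteins planted at log2 fold change 3; the pipeline
calls 20–23 significant interactors per condition (the planted ones — 95 to
100% recovered per condition at this seed — plus a couple of false
positives). Because the planted sets were drawn independently per condition,
no protein is shared by all five baits (`core = 0`) and two proteins happen
to fall in both severe conditions but not WT (`severe_shared = 2`). The
enrichment table itself looks like:

```
 group condition  fold_change   log2fc  p_value  significant
P00002        WT     6.427642 2.684290 0.002011         True
P00011        WT     5.863108 2.551666 0.002784         True
P00024        WT     5.528900 2.466992 0.001564         True
```

The same analysis runs from the shell on TSV inputs:

```sh
proxidiff simulate --outdir demo --n-proteins 200 --n-planted 20 --seed 7
proxidiff run --peptides demo/peptides.tsv --design demo/design.tsv \
              --lengths demo/lengths.tsv --outdir demo/out
```

writing the protein-group table, every matrix state, both enrichment
tables, the partition JSON and Venn region counts under `demo/out/`.

Re-analysis of an already-normalized protein-level matrix (e.g. a published
supplementary table) is available as
`proxidiff.pipeline.reproduce_from_normalized`, which forms control
ratios, calls enrichment and returns the headline partition counts.

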