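"""End-to-end orchestration: peptides in, interactome partition out.

``run_from_tables`` executes the full in-memory chain —
protein inference -> missingness filter -> imputation -> roll-up ->
trimmed-mean normalization -> control-relative ratios -> enrichment ->
reference-relative enrichment -> set partition — and returns every
intermediate.  ``run_pipeline`` wraps it with file IO and provenance
headers; identical configuration and inputs give byte-identical outputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, fields as dc_fields
from pathlib import Path

from . import io as pio
from .enrichment import ThresholdConfig, enrich, enrich_vs_reference, significant_sets
from .errors import InputError
from .inference import assign_razor, group_proteins
from .normalize import control_relative, rollup, trimmed_mean_normalize, wt_relative
from .partition import (
    DEFAULT_SEVERITY_MAP,
    build_partition,
    partition_to_json,
    venn_counts,
)
from .preprocess import audit_frame, filter_peptides, impute
from .types import DesignTable, PeptideTable

log = logging.getLogger("proxidiff")


@dataclass
class PipelineConfig:
    """All stage parameters plus input/output paths for a pipeline run."""

    peptides: str | Path | None = None
    design: str | Path | None = None
    lengths: str | Path | None = None
    outdir: str | Path = "proxidiff_out"
    dialect: str = "generic"
    control: str = "TurboID"
    reference: str = "WT"
    min_observed: int = 2
    filter_scope: str = "group"
    low_quantile: float = 0.02
    trim: float = 0.10
    fc_threshold: float = 1.5
    alpha: float = 0.05
    test_kind: str = "one_sample_log_ratio"
    test_scale: str = "log2"
    bh_correct: bool = False
    replicate_matched: bool = True
    unique_denominator: str = "all"
    severity_map: dict[str, str] = field(
        default_factory=lambda: dict(DEFAULT_SEVERITY_MAP)
    )
    seed: int = 0

    @classmethod
    def from_dict(cls, mapping: dict) -> "PipelineConfig":
        known = {f.name for f in dc_fields(cls)}
        unknown = set(mapping) - known
        if unknown:
            raise InputError(f"unknown configuration keys: {sorted(unknown)}")
        return cls(**mapping)

    def thresholds(self) -> ThresholdConfig:
        return ThresholdConfig(
            fc_threshold=self.fc_threshold,
            alpha=self.alpha,
            test_scale=self.test_scale,
            test_kind=self.test_kind,
            bh_correct=self.bh_correct,
        )


def run_from_tables(
    peptides: PeptideTable,
    design: DesignTable,
    config: PipelineConfig | None = None,
    protein_lengths: dict[str, int] | None = None,
) -> dict:
    """Run the full analysis in memory; returns all intermediates keyed by stage."""
    config = config or PipelineConfig()
    lengths = protein_lengths or peptides.protein_lengths
    if lengths is None:
        raise InputError("protein lengths required (table metadata or argument)")

    assignment = assign_razor(peptides)
    groups = group_proteins(peptides, assignment, lengths)
    log.info("inference: %d peptides -> %d protein groups",
             len(peptides.data), len(groups.groups))

    filtered = filter_peptides(peptides, design, config.min_observed, config.filter_scope)
    log.info("filter: %d -> %d peptides", len(peptides.data), len(filtered.data))
    # groups are re-derived on the filtered table so razor counts reflect
    # only peptides that survive the missingness filter
    assignment = assign_razor(filtered)
    groups = group_proteins(filtered, assignment, lengths)

    audit: list = []
    imputed = impute(filtered, design, config.low_quantile, config.seed, audit)
    log.info("imputation: %d cells filled", len(audit))

    raw = rollup(imputed, groups)
    normalized = trimmed_mean_normalize(raw, config.trim)
    ratios = control_relative(normalized, design, config.replicate_matched)

    thresholds = config.thresholds()
    enrichment = enrich(ratios, design, thresholds, normalized=normalized)
    hits = significant_sets(enrichment)
    for cond in design.bait_conditions:
        hits.setdefault(cond, set())
    log.info("enrichment: %s",
             {c: len(hits[c]) for c in design.bait_conditions})

    restrict = {c: hits[c] for c in design.mutant_conditions}
    wt_ratios = wt_relative(ratios, design, restrict)
    enrichment_wt = enrich_vs_reference(wt_ratios, design, thresholds)

    severity_map = {c: s for c, s in config.severity_map.items()
                    if c in design.bait_conditions}
    part = build_partition(enrichment, severity_map, config.unique_denominator)

    return {
        "assignment": assignment,
        "groups": groups,
        "filtered": filtered,
        "imputed": imputed,
        "imputation_audit": audit_frame(audit),
        "matrix_raw": raw,
        "matrix_normalized": normalized,
        "matrix_control_relative": ratios,
        "matrix_wt_relative": wt_ratios,
        "enrichment": enrichment,
        "enrichment_wt": enrichment_wt,
        "partition": part,
        "venn": venn_counts(part),
    }


def run_pipeline(config: PipelineConfig) -> dict:
    """File-based run: read inputs per config, write every artifact to outdir."""
    if config.peptides is None or config.design is None:
        raise InputError("config must set 'peptides' and 'design' paths")
    design = pio.read_design(config.design, config.control, config.reference)
    peptides = pio.read_peptide_table(config.peptides, design, config.dialect)
    lengths = pio.read_lengths(config.lengths) if config.lengths else None
    if lengths is None:
        raise InputError("config must set 'lengths' (accession/length TSV)")

    results = run_from_tables(peptides, design, config, protein_lengths=lengths)

    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    digests = [f"input {Path(p).name} sha256:{pio.file_digest(p)}"
               for p in (config.peptides, config.design, config.lengths)]

    pio.write_groups(results["groups"], outdir / "protein_groups.tsv")
    for key, name in (("matrix_raw", "matrix_raw.tsv"),
                      ("matrix_normalized", "matrix_trimmed_normalized.tsv"),
                      ("matrix_control_relative", "matrix_control_relative.tsv")):
        pio.write_matrix(results[key], outdir / name, extra=digests)
    thresholds = config.thresholds()
    pio.write_enrichment(results["enrichment"], outdir / "enrichment_vs_control.tsv",
                         thresholds)
    pio.write_enrichment(results["enrichment_wt"], outdir / "enrichment_vs_reference.tsv",
                         thresholds)
    results["imputation_audit"].to_csv(outdir / "imputation_audit.tsv",
                                       sep="\t", index=False)
    pio.write_partition(partition_to_json(results["partition"]),
                        outdir / "partition.json")
    for name, table in results["venn"].items():
        table.to_csv(outdir / f"venn_{name}.tsv", sep="\t", index=False)
    pio.write_membership_matrix(results["partition"].per_condition,
                                outdir / "membership.tsv")
    return results


def reproduce_from_normalized(
    normalized_values,
    design: DesignTable,
    thresholds: ThresholdConfig | None = None,
    severity_map: dict[str, str] | None = None,
) -> dict:
    """Recompute enrichment and partition counts from a normalized protein matrix.

    Entry point for re-analyzing a published normalized protein-level table
    (rows = proteins, columns = design samples): forms control-relative
    ratios, calls enrichment, builds the partition, and returns the headline
    counts (per-condition significant totals, shared core, severity-shared
    sets, percent unique).
    """
    from .types import ProteinMatrix

    thresholds = thresholds or ThresholdConfig()
    severity_map = severity_map or {
        c: DEFAULT_SEVERITY_MAP.get(c, "mild") for c in design.bait_conditions
    }
    matrix = ProteinMatrix(normalized_values, "trimmed_normalized",
                           ["supplied normalized values"])
    ratios = control_relative(matrix, design)
    enrichment = enrich(ratios, design, thresholds)
    part = build_partition(enrichment, severity_map)
    return {
        "enrichment": enrichment,
        "partition": part,
        "n_significant": {c: len(s) for c, s in part.per_condition.items()},
        "core_count": len(part.core),
        "severe_shared_count": len(part.severe_shared),
        "mild_shared_count": len(part.mild_shared),
        "percent_unique": part.percent_unique,
    }
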