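"""Protein roll-up, trimmed-mean normalization, and ratio formation.

Peptide intensities are summed into one intensity per protein group.  Each
sample column is then rescaled so that its 10%-trimmed mean (lowest and
highest ``floor(trim * n)`` entries discarded) equals the grand mean of the
per-sample trimmed means — a robust per-sample scale correction that leaves
the overall intensity scale unchanged.  Bait intensities are finally
expressed as replicate-matched ratios to the negative control, and
optionally to the reference (wild-type) bait for mutant-vs-reference
comparisons.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .errors import InputError, InternalError
from .types import DesignTable, PeptideTable, ProteinGroupSet, ProteinMatrix


def rollup(peptides: PeptideTable, groups: ProteinGroupSet) -> ProteinMatrix:
    """Sum peptide intensities per protein group (rows = master accession)."""
    if peptides.n_missing():
        raise InputError("roll-up requires a complete (imputed) peptide table")
    pep_to_master = groups.peptide_to_master()
    uncovered = set(peptides.data.index) - set(pep_to_master)
    if uncovered:
        raise InternalError(f"peptides not covered by any group: {sorted(uncovered)[:5]}")
    masters = peptides.data.index.map(pep_to_master)
    values = peptides.intensities.groupby(masters).sum()
    values.index.name = "group"
    return ProteinMatrix(values, "raw", [f"rollup of {len(peptides.data)} peptides"])


def trimmed_column_means(values: pd.DataFrame, trim: float) -> pd.Series:
    """Per-column mean after discarding floor(trim*n) entries from each tail."""
    n = len(values)
    k = math.floor(trim * n)
    if n < math.ceil(1 / (1 - 2 * trim)) or n - 2 * k < 1:
        raise InputError(f"too few rows ({n}) for trim={trim}")
    arr = np.sort(values.to_numpy(dtype=float), axis=0)
    trimmed = arr[k: n - k if k else n]
    return pd.Series(trimmed.mean(axis=0), index=values.columns)


def trimmed_mean_normalize(matrix: ProteinMatrix, trim: float = 0.10) -> ProteinMatrix:
    """Equalize per-sample trimmed means, rescaled to their grand mean."""
    matrix.require_state("raw")
    if not 0.0 <= trim < 0.5:
        raise InputError(f"trim must lie in [0, 0.5), got {trim!r}")
    m = trimmed_column_means(matrix.values, trim)
    grand = float(m.mean())
    scaled = matrix.values * (grand / m)
    return matrix.advanced(
        scaled, "trimmed_normalized",
        f"trimmed-mean normalization (trim={trim}, target={grand:.6g})",
    )


def control_relative(matrix: ProteinMatrix, design: DesignTable,
                     replicate_matched: bool = True) -> ProteinMatrix:
    """Express every bait sample as a ratio to the negative control.

    ``replicate_matched=True`` divides by the same biological replicate's
    control sample (each trial transduced every lentivirus into the same
    pooled cells); otherwise by the control condition mean.
    """
    matrix.require_state("trimmed_normalized")
    blocks = {}
    control_cols = design.samples_for(design.control)
    control_mean = matrix.values[control_cols].mean(axis=1)
    for cond in design.bait_conditions:
        if replicate_matched:
            for bait_col, ctrl_col in design.replicate_pairs(cond, design.control):
                blocks[bait_col] = matrix.values[bait_col] / matrix.values[ctrl_col]
        else:
            for bait_col in design.samples_for(cond):
                blocks[bait_col] = matrix.values[bait_col] / control_mean
    ratios = pd.DataFrame(blocks, index=matrix.values.index)
    mode = "replicate-matched" if replicate_matched else "condition-mean"
    return matrix.advanced(
        ratios, "control_relative",
        f"ratios to negative control {design.control!r} ({mode})",
    )


def wt_relative(matrix: ProteinMatrix, design: DesignTable,
                restrict_to: dict[str, set[str]]) -> ProteinMatrix:
    """Replicate-matched ratios of each mutant bait to the reference bait.

    ``restrict_to`` maps each mutant condition to the protein groups whose
    ratios should be computed (typically that mutant's significant hits
    against the control); the returned matrix covers the union of those
    groups and records the per-condition restriction in ``restricted``.
    """
    matrix.require_state("control_relative")
    unknown_conds = set(restrict_to) - set(design.mutant_conditions)
    if unknown_conds:
        raise InputError(f"restrict_to names non-mutant conditions: {sorted(unknown_conds)}")
    known_groups = set(matrix.values.index)
    for cond, groups in restrict_to.items():
        bad = set(groups) - known_groups
        if bad:
            raise InputError(
                f"restrict_to[{cond!r}] contains unknown groups: {sorted(bad)[:5]}"
            )

    union = sorted(set().union(*restrict_to.values())) if restrict_to else []
    blocks = {}
    for cond in design.mutant_conditions:
        if cond not in restrict_to:
            continue
        for mut_col, ref_col in design.replicate_pairs(cond, design.reference):
            blocks[mut_col] = (matrix.values[mut_col] / matrix.values[ref_col]).loc[union]
    ratios = pd.DataFrame(blocks, index=pd.Index(union, name="group"), dtype=float)
    if ratios.empty:
        ratios = pd.DataFrame(index=pd.Index(union, name="group"))
    out = matrix.advanced(
        ratios if len(union) else pd.DataFrame(np.empty((0, 0))),
        "wt_relative",
        f"ratios to reference bait {design.reference!r}",
    )
    out.restricted = {c: set(g) for c, g in restrict_to.items()}
    return out
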