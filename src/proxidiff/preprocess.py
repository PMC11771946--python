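"""Peptide missingness filtering and left-censored imputation.

Filtering keeps a peptide only if it was measured often enough; the default
scope (``group``) requires at least ``min_observed`` non-missing replicates
within at least one condition, the reading consistent with the per-group
imputation rules that follow.  A ``global`` scope (>= ``min_observed``
observations anywhere) is available for sensitivity analysis.

Imputation then completes the matrix per peptide per condition group:

* one missing replicate: the arithmetic mean of the observed ones (rule 1,
  deterministic);
* two or more missing (including a fully-missing group of a peptide retained
  through another condition): each missing cell is an independent uniform
  draw between the sample's observed minimum and its low-intensity quantile
  (default the bottom 2% of detectable signals), reflecting below-detection
  censoring (rule 2, seeded).

Quantiles are linear-interpolation empirical quantiles of each sample's
observed values *before* any imputation.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import InputError
from .types import DesignTable, PeptideTable


def filter_peptides(
    peptides: PeptideTable,
    design: DesignTable,
    min_observed: int = 2,
    scope: str = "group",
) -> PeptideTable:
    """Drop peptides not measured in at least ``min_observed`` samples.

    With ``scope='group'`` the requirement must be met within a single
    condition group; with ``scope='global'`` across all samples.
    """
    if scope not in ("group", "global"):
        raise InputError(f"filter scope must be 'group' or 'global', got {scope!r}")
    if scope == "group" and min_observed > design.n_replicates:
        raise InputError(
            f"min_observed={min_observed} exceeds the group size {design.n_replicates}"
        )
    observed = peptides.intensities.notna()
    if scope == "global":
        keep = observed.sum(axis=1) >= min_observed
    else:
        per_cond = pd.DataFrame({
            c: observed[design.samples_for(c)].sum(axis=1) for c in design.conditions
        })
        keep = (per_cond >= min_observed).any(axis=1)
    return PeptideTable(
        peptides.data.loc[keep].copy(), list(peptides.samples),
        dict(peptides.protein_lengths) if peptides.protein_lengths else None,
    )


def impute(
    peptides: PeptideTable,
    design: DesignTable,
    low_quantile: float = 0.02,
    seed: int = 0,
    audit: list | None = None,
) -> PeptideTable:
    """Complete a filtered peptide table by the two imputation rules.

    Pass a list as ``audit`` to collect provenance records
    ``(peptide_id, sample_id, rule, imputed_value)``.
    """
    if not 0.0 <= low_quantile <= 1.0:
        raise InputError(f"low_quantile must lie in [0, 1], got {low_quantile!r}")
    rng = np.random.default_rng(seed)
    data = peptides.data.copy()
    inten = data[peptides.samples]

    # per-sample bottom-quantile interval from pre-imputation observed values
    bounds: dict[str, tuple[float, float]] = {}
    for s in peptides.samples:
        obs = inten[s].dropna()
        if obs.empty:
            raise InputError(f"sample {s!r} has no observed values; cannot define "
                             "detectable signals for imputation")
        bounds[s] = (float(obs.min()), float(obs.quantile(low_quantile)))

    for cond in design.conditions:
        cols = design.samples_for(cond)
        block = data[cols].to_numpy(dtype=float)
        miss = np.isnan(block)
        n_miss = miss.sum(axis=1)

        # rule 1: exactly one missing -> mean of the observed replicates
        one = n_miss == 1
        if one.any():
            means = np.nanmean(block[one], axis=1)
            for row_i, m in zip(np.flatnonzero(one), means):
                col_j = int(np.flatnonzero(miss[row_i])[0])
                block[row_i, col_j] = m
                if audit is not None:
                    audit.append((data.index[row_i], cols[col_j], "mean_of_observed", float(m)))

        # rule 2: two or more missing -> independent bottom-quantile draws
        many = n_miss >= 2
        for row_i in np.flatnonzero(many):
            for col_j in np.flatnonzero(miss[row_i]):
                lo, hi = bounds[cols[col_j]]
                val = float(rng.uniform(lo, hi)) if hi > lo else lo
                block[row_i, col_j] = val
                if audit is not None:
                    audit.append((data.index[row_i], cols[col_j], "low_quantile_draw", val))

        data[cols] = block

    out = PeptideTable(
        data, list(peptides.samples),
        dict(peptides.protein_lengths) if peptides.protein_lengths else None,
    )
    if out.n_missing():
        raise InputError("imputation left missing cells; was the table filtered?")
    return out


def audit_frame(audit: list) -> pd.DataFrame:
    """Imputation audit records as a DataFrame."""
    return pd.DataFrame(audit, columns=["peptide_id", "sample_id", "rule", "imputed_value"])
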