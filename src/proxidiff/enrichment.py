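"""Significant-interactor calling from replicate ratio matrices.

For each protein group and bait condition the fold change is the geometric
mean of the replicate ratios and the p-value a two-sided one-sample t-test
of the replicate log2 ratios against 0 (df = n - 1).  A hit is significant
iff fold change exceeds ``fc_threshold`` (default 1.5) *and* p is below
``alpha`` (default 0.05) — a conjunction, so a large fold change with a
noisy p, or a tiny but precise shift, is not called.

Zero-variance rows (possible after mean imputation of duplicated values) are
pinned: p = 1 when the mean log-ratio is 0, else p = 0.  A two-sample Welch
test on log2 normalized intensities and Benjamini-Hochberg adjustment are
available behind flags for sensitivity analysis; both default off.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InputError
from .types import (
    DesignTable,
    ENRICHMENT_COLUMNS,
    ProteinMatrix,
    empty_enrichment_table,
    validate_enrichment_table,
)


@dataclass
class ThresholdConfig:
    """Significance thresholds and test variant selection."""

    fc_threshold: float = 1.5
    alpha: float = 0.05
    test_scale: str = "log2"          # "log2" | "linear"
    test_kind: str = "one_sample_log_ratio"  # | "two_sample"
    bh_correct: bool = False

    def __post_init__(self) -> None:
        if self.fc_threshold <= 0:
            raise InputError(f"fc_threshold must be positive, got {self.fc_threshold!r}")
        if not 0.0 < self.alpha < 1.0:
            raise InputError(f"alpha must lie in (0, 1), got {self.alpha!r}")
        if self.test_scale not in ("log2", "linear"):
            raise InputError(f"unknown test_scale {self.test_scale!r}")
        if self.test_kind not in ("one_sample_log_ratio", "two_sample"):
            raise InputError(f"unknown test_kind {self.test_kind!r}")


def _one_sample_p(values: np.ndarray, null: float) -> np.ndarray:
    """Row-wise two-sided one-sample t-test p-values with pinned degenerate rows."""
    n = values.shape[1]
    if n < 2:
        raise InputError("t-test needs >=2 replicates per condition; supply more")
    mean = values.mean(axis=1)
    sd = values.std(axis=1, ddof=1)
    p = np.empty(len(values))
    degenerate = sd == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (mean - null) / (sd / np.sqrt(n))
    p[~degenerate] = 2 * stats.t.sf(np.abs(t[~degenerate]), df=n - 1)
    p[degenerate] = np.where(mean[degenerate] == null, 1.0, 0.0)
    return p


def _finalize(rows: list[pd.DataFrame], thresholds: ThresholdConfig) -> pd.DataFrame:
    if not rows:
        return empty_enrichment_table()
    table = pd.concat(rows, ignore_index=True)
    if thresholds.bh_correct:
        from statsmodels.stats.multitest import multipletests
        table["p_value"] = multipletests(table["p_value"], method="fdr_bh")[1]
    table["significant"] = (
        (table["fold_change"] > thresholds.fc_threshold)
        & (table["p_value"] < thresholds.alpha)
    )
    validate_enrichment_table(table)
    return table[ENRICHMENT_COLUMNS]


def _condition_rows(
    ratios: pd.DataFrame, condition: str, cols: list[str], thresholds: ThresholdConfig
) -> pd.DataFrame:
    log2r = np.log2(ratios[cols].to_numpy(dtype=float))
    log2fc = log2r.mean(axis=1)
    if thresholds.test_scale == "log2":
        p = _one_sample_p(log2r, 0.0)
    else:
        p = _one_sample_p(ratios[cols].to_numpy(dtype=float), 1.0)
    return pd.DataFrame({
        "group": ratios.index,
        "condition": condition,
        "fold_change": np.exp2(log2fc),
        "log2fc": log2fc,
        "p_value": p,
    })


def enrich(
    ratios: ProteinMatrix,
    design: DesignTable,
    thresholds: ThresholdConfig | None = None,
    normalized: ProteinMatrix | None = None,
) -> pd.DataFrame:
    """Call enrichment per bait condition from control-relative ratios.

    ``normalized`` (the trimmed-normalized matrix) is required only for
    ``test_kind='two_sample'``, which Welch-tests bait vs control log2
    intensities instead of testing ratios against 0.
    """
    thresholds = thresholds or ThresholdConfig()
    ratios.require_state("control_relative")
    rows = []
    for cond in design.bait_conditions:
        cols = design.samples_for(cond)
        block = _condition_rows(ratios.values, cond, cols, thresholds)
        if thresholds.test_kind == "two_sample":
            if normalized is None:
                raise InputError("test_kind='two_sample' needs the normalized matrix")
            normalized.require_state("trimmed_normalized")
            bait = np.log2(normalized.values[cols].to_numpy(dtype=float))
            ctrl = np.log2(
                normalized.values[design.samples_for(design.control)].to_numpy(dtype=float)
            )
            res = stats.ttest_ind(bait, ctrl, axis=1, equal_var=False)
            p = np.where(np.isnan(res.pvalue),
                         (bait.mean(axis=1) == ctrl.mean(axis=1)).astype(float), res.pvalue)
            block["p_value"] = p
        rows.append(block)
    return _finalize(rows, thresholds)


def enrich_vs_reference(
    wt_ratios: ProteinMatrix,
    design: DesignTable,
    thresholds: ThresholdConfig | None = None,
) -> pd.DataFrame:
    """Second-level calls: each mutant's control hits tested against the reference bait."""
    thresholds = thresholds or ThresholdConfig()
    wt_ratios.require_state("wt_relative")
    restricted: dict[str, set[str]] = getattr(wt_ratios, "restricted", {})
    rows = []
    for cond in design.mutant_conditions:
        groups = sorted(restricted.get(cond, set()))
        if not groups:
            continue
        cols = design.samples_for(cond)
        rows.append(
            _condition_rows(wt_ratios.values.loc[groups], cond, cols, thresholds)
        )
    return _finalize(rows, thresholds)


def significant_sets(table: pd.DataFrame) -> dict[str, set[str]]:
    """Map each condition in an enrichment table to its significant groups."""
    out: dict[str, set[str]] = {}
    for cond, sub in table.groupby("condition"):
        out[str(cond)] = set(sub.loc[sub["significant"], "group"])
    return out
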