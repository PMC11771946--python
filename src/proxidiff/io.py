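"""Tab-delimited readers and writers for every pipeline artifact.

The canonical dialect is TSV, UTF-8, ``.`` decimal.  Peptide tables use
columns ``peptide_id``, ``sequence``, ``accessions`` (semicolon-separated)
followed by one intensity column per design sample; empty cells, ``0`` and
``NA`` all mean "not detected".  A ``pd_export`` dialect adapts vendor-style
exports whose intensity columns are named ``Abundance: <sample>``.

Matrix and enrichment writers prepend ``#``-comment provenance headers
(package version, input digests, transformation chain); readers skip them.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .errors import InputError
from .types import DesignTable, PeptideTable, ProteinGroupSet, ProteinMatrix

_MISSING_SENTINELS = {"", "NA", "NaN", "nan", "0", "0.0"}


def file_digest(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]


def provenance_lines(extra: list[str] | None = None) -> list[str]:
    lines = [f"# proxidiff {__version__}"]
    if extra:
        lines += [f"# {line}" for line in extra]
    return lines


def read_design(path, control: str, reference: str) -> DesignTable:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "condition": str})
    return DesignTable(df, control=control, reference=reference)


def write_design(design: DesignTable, path) -> None:
    design.data.to_csv(path, sep="\t", index=False)


def read_lengths(path) -> dict[str, int]:
    df = pd.read_csv(path, sep="\t", dtype={"accession": str})
    if not {"accession", "length"}.issubset(df.columns):
        raise InputError("lengths file needs columns: accession, length")
    return dict(zip(df["accession"], df["length"].astype(int)))


def write_lengths(lengths: dict[str, int], path) -> None:
    pd.DataFrame(
        sorted(lengths.items()), columns=["accession", "length"]
    ).to_csv(path, sep="\t", index=False)


def _parse_intensity(raw, row, col) -> float:
    text = str(raw).strip()
    if pd.isna(raw) or text in _MISSING_SENTINELS:
        return np.nan
    try:
        value = float(text)
    except ValueError:
        raise InputError(f"non-numeric intensity {raw!r} at row {row!r}, column {col!r}")
    return np.nan if value == 0 else value


def read_peptide_table(path, design: DesignTable, dialect: str = "generic") -> PeptideTable:
    """Read a peptide TSV in the ``generic`` or ``pd_export`` dialect."""
    if dialect not in ("generic", "pd_export"):
        raise InputError(f"unknown peptide-table dialect {dialect!r}")
    df = pd.read_csv(path, sep="\t", dtype=str)
    if dialect == "pd_export":
        renames = {}
        for col in df.columns:
            if col.startswith("Abundance:"):
                renames[col] = col.split(":", 1)[1].strip()
        for vendor, ours in (("Annotated Sequence", "sequence"),
                             ("Sequence", "sequence"),
                             ("Protein Accessions", "accessions"),
                             ("Master Protein Accessions", "accessions"),
                             ("Peptide ID", "peptide_id")):
            if vendor in df.columns and ours not in renames.values():
                renames[vendor] = ours
        df = df.rename(columns=renames)
        if "peptide_id" not in df.columns:
            df.insert(0, "peptide_id", [f"pep{i+1:06d}" for i in range(len(df))])

    for required in ("peptide_id", "sequence", "accessions"):
        if required not in df.columns:
            raise InputError(f"peptide table missing column {required!r}")
    absent = [s for s in design.samples if s not in df.columns]
    if absent:
        raise InputError(f"design samples absent from peptide table header: {absent}")

    df = df.set_index("peptide_id")
    for s in design.samples:
        df[s] = [
            _parse_intensity(v, pid, s) for pid, v in zip(df.index, df[s])
        ]
    df["accessions"] = [
        tuple(sorted(a.strip() for a in str(accs).split(";") if a.strip()))
        for accs in df["accessions"]
    ]
    keep = ["sequence", "accessions"] + design.samples
    return PeptideTable(df[keep], samples=list(design.samples))


def write_peptide_table(table: PeptideTable, path) -> None:
    df = table.data.copy()
    df["accessions"] = [";".join(a) for a in df["accessions"]]
    df.to_csv(path, sep="\t", na_rep="", index=True, index_label="peptide_id")


def write_groups(groups: ProteinGroupSet, path) -> None:
    rows = []
    for i, g in enumerate(groups.groups, start=1):
        rows.append({
            "group_id": i,
            "master": g.master,
            "members": ";".join(sorted(g.members)),
            "master_coverage": g.coverage[g.master],
            "n_peptides": len(g.peptide_ids),
        })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_matrix(matrix: ProteinMatrix, path, extra: list[str] | None = None) -> None:
    header = provenance_lines([f"state: {matrix.state}", *matrix.provenance,
                               *(extra or [])])
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\n".join(header) + "\n")
        matrix.values.to_csv(fh, sep="\t", index=True, index_label="group")


def read_matrix(path, state: str) -> ProteinMatrix:
    df = pd.read_csv(path, sep="\t", comment="#", index_col="group")
    return ProteinMatrix(df, state, [f"read from {Path(path).name}"])


def write_enrichment(table: pd.DataFrame, path, thresholds=None) -> None:
    extra = []
    if thresholds is not None:
        extra.append(
            f"thresholds: fc>{thresholds.fc_threshold}, p<{thresholds.alpha}, "
            f"test={thresholds.test_kind}/{thresholds.test_scale}, "
            f"bh={thresholds.bh_correct}"
        )
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\n".join(provenance_lines(extra)) + "\n")
        table.to_csv(fh, sep="\t", index=False)


def read_enrichment(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#")
    df["significant"] = df["significant"].astype(bool)
    return df


def write_partition(partition_json: dict, path) -> None:
    Path(path).write_text(json.dumps(partition_json, indent=2, sort_keys=True) + "\n")


def write_membership_matrix(per_condition: dict[str, set[str]], path) -> None:
    """0/1 membership matrix (group x condition) for upset-style plotting."""
    union = sorted(set().union(*per_condition.values())) if per_condition else []
    df = pd.DataFrame(
        {c: [int(g in s) for g in union] for c, s in per_condition.items()},
        index=pd.Index(union, name="group"),
    )
    df.to_csv(path, sep="\t")
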