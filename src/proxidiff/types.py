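"""Core in-memory containers for the pipeline.

All tabular data is held in :class:`pandas.DataFrame` objects wrapped in thin
dataclasses that pin the column contract and carry stage metadata (experimental
design, protein lengths, normalization state).  Missing intensities are NaN.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InputError, InternalError

#: Columns of a peptide table that are not per-sample intensities.
PEPTIDE_META_COLUMNS = ("sequence", "accessions")


@dataclass
class PeptideTable:
    """Peptide-level intensities with candidate protein accessions.

    ``data`` is indexed by peptide id and holds a ``sequence`` column, an
    ``accessions`` column (tuple of candidate accessions, non-empty) and one
    float column per sample; NaN marks a missing (non-detected) intensity.
    ``protein_lengths`` optionally maps accession to residue count so sequence
    coverage can be computed without a sequence database.
    """

    data: pd.DataFrame
    samples: list[str]
    protein_lengths: dict[str, int] | None = None

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.data.index.has_duplicates:
            dupes = self.data.index[self.data.index.duplicated()].tolist()
            raise InputError(f"duplicate peptide ids: {dupes[:5]}")
        missing_cols = [c for c in self.samples if c not in self.data.columns]
        if missing_cols:
            raise InputError(f"sample columns absent from peptide table: {missing_cols}")
        for pid, acc in self.data["accessions"].items():
            if not acc:
                raise InputError(f"peptide {pid!r} has an empty candidate accession set")
        vals = self.data[self.samples].to_numpy(dtype=float)
        if np.any(vals[np.isfinite(vals)] <= 0):
            raise InputError("peptide intensities must be strictly positive where present")

    @property
    def intensities(self) -> pd.DataFrame:
        """The per-sample intensity block (peptides x samples)."""
        return self.data[self.samples]

    def n_missing(self) -> int:
        return int(self.intensities.isna().to_numpy().sum())

    def copy(self) -> "PeptideTable":
        return PeptideTable(
            self.data.copy(), list(self.samples),
            dict(self.protein_lengths) if self.protein_lengths else None,
        )


@dataclass
class DesignTable:
    """Maps sample columns to (condition, replicate) and names the two anchors.

    ``control`` is the negative-control condition (unfused biotin-ligase
    background); ``reference`` is the reference bait (wild type) used for the
    second-level, bait-vs-bait comparison.
    """

    data: pd.DataFrame  # columns: sample_id, condition, replicate
    control: str
    reference: str

    def __post_init__(self) -> None:
        required = {"sample_id", "condition", "replicate"}
        if not required.issubset(self.data.columns):
            raise InputError(f"design table needs columns {sorted(required)}")
        if self.data["sample_id"].duplicated().any():
            raise InputError("duplicate sample ids in design table")
        counts = self.data.groupby("condition")["replicate"].count()
        if counts.nunique() != 1:
            raise InputError(f"unequal replicate counts per condition: {counts.to_dict()}")
        for name, label in (("control", self.control), ("reference", self.reference)):
            if label not in set(self.data["condition"]):
                raise InputError(f"{name} condition {label!r} not present in design")
        if self.control == self.reference:
            raise InputError("control and reference conditions must differ")

    @property
    def conditions(self) -> list[str]:
        """Condition labels in first-appearance order (control included)."""
        return list(dict.fromkeys(self.data["condition"]))

    @property
    def bait_conditions(self) -> list[str]:
        """All conditions except the negative control."""
        return [c for c in self.conditions if c != self.control]

    @property
    def mutant_conditions(self) -> list[str]:
        """Bait conditions other than the reference bait."""
        return [c for c in self.bait_conditions if c != self.reference]

    @property
    def n_replicates(self) -> int:
        return int(self.data.groupby("condition")["replicate"].count().iloc[0])

    @property
    def samples(self) -> list[str]:
        return list(self.data["sample_id"])

    def samples_for(self, condition: str) -> list[str]:
        """Sample ids of one condition, ordered by replicate index."""
        sub = self.data[self.data["condition"] == condition]
        return list(sub.sort_values("replicate")["sample_id"])

    def replicate_pairs(self, condition: str, other: str) -> list[tuple[str, str]]:
        """Replicate-matched (condition, other) sample-id pairs."""
        a = self.data[self.data["condition"] == condition].set_index("replicate")["sample_id"]
        b = self.data[self.data["condition"] == other].set_index("replicate")["sample_id"]
        if set(a.index) != set(b.index):
            raise InputError(
                f"replicate indices differ between {condition!r} and {other!r}"
            )
        return [(a[r], b[r]) for r in sorted(a.index)]


@dataclass(frozen=True)
class ProteinGroup:
    """Accessions indistinguishable by their assigned peptide set."""

    members: frozenset[str]
    peptide_ids: frozenset[str]
    master: str
    coverage: dict[str, float] = field(hash=False)


@dataclass
class ProteinGroupSet:
    """Razor assignment plus identical-peptide-set protein groups."""

    assignment: dict[str, str]  # peptide_id -> accession
    groups: list[ProteinGroup]

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for g in self.groups:
            if g.master not in g.members:
                raise InternalError(f"master {g.master} outside its group members")
            if g.peptide_ids & seen:
                raise InternalError("protein groups share peptide ids")
            seen |= g.peptide_ids
        if seen != set(self.assignment):
            raise InternalError("groups do not partition the assigned peptides")

    @property
    def masters(self) -> list[str]:
        return [g.master for g in self.groups]

    def group_of(self, accession: str) -> ProteinGroup:
        for g in self.groups:
            if accession in g.members:
                return g
        raise KeyError(accession)

    def peptide_to_master(self) -> dict[str, str]:
        """Map each peptide id to the master accession of its group."""
        out: dict[str, str] = {}
        for g in self.groups:
            for pid in g.peptide_ids:
                out[pid] = g.master
        return out


#: Legal normalization states of a protein matrix, in pipeline order.
MATRIX_STATES = ("raw", "trimmed_normalized", "control_relative", "wt_relative")


@dataclass
class ProteinMatrix:
    """Protein-group x sample intensity (or ratio) matrix with a state flag.

    Rows are indexed by master accession.  ``state`` advances only along
    raw -> trimmed_normalized -> control_relative -> wt_relative; each
    transformation appends a line to ``provenance``.
    """

    values: pd.DataFrame
    state: str
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.state not in MATRIX_STATES:
            raise InternalError(f"unknown matrix state {self.state!r}")
        vals = self.values.to_numpy(dtype=float)
        if np.any(~np.isfinite(vals)) or np.any(vals <= 0):
            raise InternalError(
                f"protein matrix in state {self.state!r} must be finite and positive"
            )

    def require_state(self, expected: str) -> None:
        if self.state != expected:
            raise InputError(
                f"matrix in state {self.state!r}; operation requires {expected!r}"
            )

    def advanced(self, values: pd.DataFrame, new_state: str, note: str) -> "ProteinMatrix":
        """Return a copy advanced one state with a provenance note."""
        if MATRIX_STATES.index(new_state) != MATRIX_STATES.index(self.state) + 1:
            raise InternalError(f"illegal state transition {self.state} -> {new_state}")
        return ProteinMatrix(values, new_state, self.provenance + [note])


ENRICHMENT_COLUMNS = ["group", "condition", "fold_change", "log2fc", "p_value", "significant"]


def empty_enrichment_table() -> pd.DataFrame:
    return pd.DataFrame(columns=ENRICHMENT_COLUMNS)


def validate_enrichment_table(table: pd.DataFrame) -> None:
    missing = [c for c in ENRICHMENT_COLUMNS if c not in table.columns]
    if missing:
        raise InputError(f"enrichment table missing columns: {missing}")
    if len(table) and not np.allclose(
        table["fold_change"], np.exp2(table["log2fc"]), rtol=0, atol=1e-9
    ):
        raise InternalError("fold_change and log2fc disagree beyond 1e-9")
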