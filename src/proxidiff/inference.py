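"""Razor-peptide assignment, protein grouping, and master-protein selection.

A peptide matching several candidate proteins is assigned exclusively to the
candidate with the most identified peptides (counting every peptide that
lists the candidate, in one pass over the input; ties break to the
lexicographically smallest accession so outputs are reproducible).
Accessions with identical assigned-peptide sets are merged into one protein
group, represented by the member with the highest sequence coverage.

Coverage is approximated as the summed lengths of the distinct assigned
peptide sequences, capped at the protein length, divided by the protein
length — intensity-table inputs carry no peptide positions.
"""

from __future__ import annotations

from collections import Counter, defaultdict

from .errors import InputError
from .types import PeptideTable, ProteinGroup, ProteinGroupSet


def assign_razor(peptides: PeptideTable) -> dict[str, str]:
    """Assign each peptide to exactly one accession by the razor rule."""
    counts: Counter[str] = Counter()
    for pid, accs in peptides.data["accessions"].items():
        if not accs:
            raise InputError(f"peptide {pid!r} has no candidate accessions")
        counts.update(accs)

    assignment: dict[str, str] = {}
    for pid, accs in peptides.data["accessions"].items():
        # max count, ties to lexicographically smallest accession
        assignment[pid] = min(accs, key=lambda a: (-counts[a], a))
    return assignment


def group_proteins(
    peptides: PeptideTable,
    assignment: dict[str, str],
    protein_lengths: dict[str, int],
) -> ProteinGroupSet:
    """Merge accessions with identical assigned-peptide sets; pick masters."""
    missing = set(assignment) - set(peptides.data.index)
    if missing:
        raise InputError(f"assignment covers unknown peptides: {sorted(missing)[:5]}")
    unassigned = set(peptides.data.index) - set(assignment)
    if unassigned:
        raise InputError(f"peptides without assignment: {sorted(unassigned)[:5]}")

    by_accession: dict[str, set[str]] = defaultdict(set)
    for pid, acc in assignment.items():
        by_accession[acc].add(pid)

    no_length = sorted(set(by_accession) - set(protein_lengths))
    if no_length:
        raise InputError(f"no protein length for assigned accessions: {no_length[:5]}")

    sequences = peptides.data["sequence"]
    by_pepset: dict[frozenset[str], list[str]] = defaultdict(list)
    for acc, pids in by_accession.items():
        by_pepset[frozenset(pids)].append(acc)

    groups: list[ProteinGroup] = []
    for pepset, members in sorted(by_pepset.items(), key=lambda kv: sorted(kv[1])):
        covered = sum(len(s) for s in set(sequences.loc[list(pepset)]))
        coverage = {}
        for acc in members:
            length = protein_lengths[acc]
            if length <= 0:
                raise InputError(f"non-positive protein length for {acc!r}")
            coverage[acc] = min(covered, length) / length
        master = min(members, key=lambda a: (-coverage[a], a))
        groups.append(
            ProteinGroup(
                members=frozenset(members),
                peptide_ids=pepset,
                master=master,
                coverage=coverage,
            )
        )
    return ProteinGroupSet(assignment=assignment, groups=groups)


def infer_proteins(peptides: PeptideTable) -> ProteinGroupSet:
    """Razor assignment followed by grouping, using the table's own lengths."""
    if peptides.protein_lengths is None:
        raise InputError("peptide table carries no protein lengths; supply them")
    assignment = assign_razor(peptides)
    return group_proteins(peptides, assignment, peptides.protein_lengths)
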