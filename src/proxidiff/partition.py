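"""Set algebra over per-condition significant interactors.

Partitions the significant sets of a five-bait panel (reference bait plus
four variants) into the categories used to compare variant interactomes:

* ``core`` — interactors shared by the reference and every variant;
* ``mutants_only`` — every region of the 4-set Venn diagram of the variant
  sets after removing reference-bait interactors;
* ``severe_shared`` / ``mild_shared`` — interactors common to all baits of a
  severity class but absent from the reference set;
* ``unique[c]`` — interactors of condition ``c`` found in no other bait
  condition (reference included), with ``percent_unique`` relative to that
  condition's full significant set.

Severity labels are configuration, not hard-coded gene knowledge, so the
partition generalizes to any bait panel.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import pandas as pd

from .errors import InputError
from .enrichment import significant_sets

#: severity classes of the default bait panel
DEFAULT_SEVERITY_MAP = {
    "WT": "reference",
    "R326H": "severe",
    "T532M": "severe",
    "R376C": "mild",
    "R488H": "mild",
}


@dataclass
class InteractomePartition:
    """Named set partitions over per-condition significant interactors."""

    per_condition: dict[str, set[str]]
    core: set[str]
    mutants_only: dict[frozenset[str], set[str]]
    severe_shared: set[str]
    mild_shared: set[str]
    unique: dict[str, set[str]]
    percent_unique: dict[str, float]
    severity_map: dict[str, str]
    reference: str = field(default="")

    def __post_init__(self) -> None:
        for cond, s in self.per_condition.items():
            if not self.core <= s:
                raise InputError(f"core not contained in {cond!r} significant set")
        for c in self.unique:
            for other in self.unique:
                if other != c and self.unique[c] & self.per_condition[other]:
                    raise InputError(f"unique[{c!r}] overlaps {other!r}")


def build_partition(
    enrichment: pd.DataFrame,
    severity_map: dict[str, str],
    unique_denominator: str = "all",
) -> InteractomePartition:
    """Partition significant interactors by the configured severity classes.

    ``unique_denominator`` controls which panel members count against
    uniqueness: ``"all"`` (default — every other bait, reference included)
    or ``"mutants"`` (variant baits only).
    """
    if unique_denominator not in ("all", "mutants"):
        raise InputError(f"unknown unique_denominator {unique_denominator!r}")
    sets = significant_sets(enrichment)
    missing = set(severity_map) - set(sets)
    if missing:
        raise InputError(f"conditions absent from enrichment table: {sorted(missing)}")
    sets = {c: sets[c] for c in severity_map}

    references = [c for c, s in severity_map.items() if s == "reference"]
    if len(references) != 1:
        raise InputError(f"severity map must name exactly one reference, got {references}")
    reference = references[0]
    mutants = [c for c in severity_map if c != reference]
    severe = [c for c in mutants if severity_map[c] == "severe"]
    mild = [c for c in mutants if severity_map[c] == "mild"]
    unknown = {c: s for c, s in severity_map.items()
               if s not in ("reference", "severe", "mild")}
    if unknown:
        raise InputError(f"unknown severity labels: {unknown}")

    core = set.intersection(*sets.values())
    ref_set = sets[reference]

    def class_shared(members: list[str]) -> set[str]:
        if not members:
            return set()
        return set.intersection(*(sets[c] for c in members)) - ref_set

    # 4-set Venn regions of the mutant sets, reference members removed first
    stripped = {c: sets[c] - ref_set for c in mutants}
    mutants_only: dict[frozenset[str], set[str]] = {}
    for r in range(1, len(mutants) + 1):
        for combo in combinations(mutants, r):
            inside = set.intersection(*(stripped[c] for c in combo))
            outside = set().union(*(stripped[c] for c in mutants if c not in combo)) \
                if len(combo) < len(mutants) else set()
            region = inside - outside
            if region:
                mutants_only[frozenset(combo)] = region

    unique: dict[str, set[str]] = {}
    percent_unique: dict[str, float] = {}
    panel = list(severity_map) if unique_denominator == "all" else mutants
    for c in panel:
        others = set().union(*(sets[o] for o in panel if o != c)) if len(panel) > 1 else set()
        unique[c] = sets[c] - others
        percent_unique[c] = len(unique[c]) / len(sets[c]) if sets[c] else 0.0

    return InteractomePartition(
        per_condition=sets,
        core=core,
        mutants_only=mutants_only,
        severe_shared=class_shared(severe),
        mild_shared=class_shared(mild),
        unique=unique,
        percent_unique=percent_unique,
        severity_map=dict(severity_map),
        reference=reference,
    )


def venn_regions(sets: dict[str, set[str]]) -> pd.DataFrame:
    """Exclusive-region counts of an n-set Venn decomposition.

    One row per non-empty membership pattern; ``region`` lists the member
    conditions joined by ``&``.  Region counts sum to the union cardinality.
    """
    conds = list(sets)
    rows = []
    for r in range(1, len(conds) + 1):
        for combo in combinations(conds, r):
            inside = set.intersection(*(sets[c] for c in combo))
            outside = set().union(*(sets[c] for c in conds if c not in combo)) \
                if len(combo) < len(conds) else set()
            region = inside - outside
            rows.append({"region": "&".join(combo), "n_sets": r, "count": len(region)})
    return pd.DataFrame(rows, columns=["region", "n_sets", "count"])


def venn_counts(partition: InteractomePartition) -> dict[str, pd.DataFrame]:
    """Region counts for the full panel and the reference-excluded variants."""
    mutants = [c for c in partition.severity_map if c != partition.reference]
    stripped = {
        c: partition.per_condition[c] - partition.per_condition[partition.reference]
        for c in mutants
    }
    return {
        "all_conditions": venn_regions(partition.per_condition),
        "mutants_wt_excluded": venn_regions(stripped),
    }


def partition_to_json(partition: InteractomePartition) -> dict:
    """JSON-serializable view of a partition (sorted member lists)."""
    return {
        "reference": partition.reference,
        "severity_map": partition.severity_map,
        "per_condition": {c: sorted(s) for c, s in partition.per_condition.items()},
        "core": sorted(partition.core),
        "severe_shared": sorted(partition.severe_shared),
        "mild_shared": sorted(partition.mild_shared),
        "mutants_only": {
            "&".join(sorted(k)): sorted(v) for k, v in partition.mutants_only.items()
        },
        "unique": {c: sorted(s) for c, s in partition.unique.items()},
        "percent_unique": partition.percent_unique,
    }
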