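"""Synthetic peptide-level proximity-labeling experiments with ground truth.

The generator emulates the statistical structure the downstream analysis
assumes: a panel of bait conditions measured against an unfused-ligase
negative control in a fixed number of biological replicates, log-normal
protein abundances, peptides drawn as fixed fractions of their protein's
abundance (so summation roll-up is exact in expectation), multiplicative
replicate noise, per-sample scale biases, a fraction of peptides shared
between two candidate accessions (to exercise razor assignment), and
left-censored missingness concentrated below a per-sample intensity
quantile.

Two independent seeded streams are used — one for abundances/noise, one for
censoring — so the missingness rate can be varied without perturbing the
underlying intensities.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InputError
from .types import DesignTable, PeptideTable

_AMINO_ACIDS = np.array(list("ACDEFGHIKLMNPQRSTVWY"))

DEFAULT_CONDITIONS = ("TurboID", "WT", "R326H", "R376C", "R488H", "T532M")


@dataclass
class SimulationConfig:
    """Parameters of one synthetic experiment.

    The defaults mirror the study design the pipeline targets: six conditions
    (negative control first) in three biological replicates.  ``effect_log2fc``
    is the planted enrichment of a true interactor over the background, in
    log2 units; ``replicate_cv`` the coefficient of variation of the
    multiplicative replicate noise; intensities falling below the
    ``missingness_quantile`` of their sample are censored with probability
    ``missing_prob_low``.
    """

    n_proteins: int = 300
    n_planted_per_condition: int = 30
    peptides_per_protein: tuple[int, int] = (2, 6)
    shared_peptide_fraction: float = 0.05
    conditions: tuple[str, ...] = DEFAULT_CONDITIONS
    n_replicates: int = 3
    baseline_log_mean: float = 16.0  # natural-log scale of raw LFQ intensities
    baseline_log_sd: float = 1.5
    effect_log2fc: float = 3.0
    replicate_cv: float = 0.2
    missingness_quantile: float = 0.2
    missing_prob_low: float = 0.4
    sample_scale_factors: dict[str, float] | None = None
    seed: int = 0
    # Optional explicit planted sets (condition -> protein accessions); when
    # None, planted proteins are drawn at random per condition.
    planted: dict[str, set[str]] | None = None

    def __post_init__(self) -> None:
        for name in ("n_proteins", "n_planted_per_condition", "n_replicates"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 0 or (name != "n_planted_per_condition" and v == 0):
                raise InputError(f"{name} must be a positive count, got {v!r}")
        if self.n_planted_per_condition > self.n_proteins:
            raise InputError("n_planted_per_condition exceeds n_proteins")
        lo, hi = self.peptides_per_protein
        if lo < 1 or hi < lo:
            raise InputError(f"peptides_per_protein range invalid: {self.peptides_per_protein}")
        for name in ("shared_peptide_fraction", "missingness_quantile", "missing_prob_low"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise InputError(f"{name} must lie in [0, 1], got {v!r}")
        if len(self.conditions) < 2:
            raise InputError("conditions must list the negative control plus >=1 bait")
        if len(set(self.conditions)) != len(self.conditions):
            raise InputError("conditions contains duplicates")
        if self.replicate_cv < 0:
            raise InputError(f"replicate_cv must be non-negative, got {self.replicate_cv!r}")
        if self.baseline_log_sd < 0:
            raise InputError(f"baseline_log_sd must be non-negative, got {self.baseline_log_sd!r}")
        if self.planted is not None:
            bad = set(self.planted) - set(self.conditions[1:])
            if bad:
                raise InputError(f"planted names non-bait conditions: {sorted(bad)}")

    @property
    def control(self) -> str:
        return self.conditions[0]

    @property
    def sample_ids(self) -> list[str]:
        return [f"{c}_{r}" for c in self.conditions for r in range(1, self.n_replicates + 1)]


@dataclass
class SyntheticTruth:
    """Planted interactor identities and their log2 effects per condition."""

    planted: dict[str, set[str]]
    effect_log2fc: dict[tuple[str, str], float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for cond, prots in self.planted.items():
            for p in prots:
                if (cond, p) not in self.effect_log2fc:
                    raise InputError(f"planted ({cond}, {p}) has no recorded effect")

    def all_planted(self) -> set[str]:
        out: set[str] = set()
        for s in self.planted.values():
            out |= s
        return out


def design_for(config: SimulationConfig) -> DesignTable:
    """The design table matching a simulation config (control first, WT reference)."""
    rows = [
        {"sample_id": f"{c}_{r}", "condition": c, "replicate": r}
        for c in config.conditions
        for r in range(1, config.n_replicates + 1)
    ]
    reference = config.conditions[1]
    return DesignTable(pd.DataFrame(rows), control=config.control, reference=reference)


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(_AMINO_ACIDS, size=length))


def generate_experiment(config: SimulationConfig) -> tuple[PeptideTable, SyntheticTruth]:
    """Simulate one experiment; returns the peptide table and its ground truth.

    Protein abundances are log-normal; each protein is split into peptides
    with fixed (per-protein, Dirichlet-drawn) fractional yields; planted
    proteins are multiplied by ``2**effect_log2fc`` in their condition's
    samples; replicate noise is multiplicative log-normal with the requested
    CV; censoring is applied last, from an independent stream, to cells whose
    intensity falls below the per-sample ``missingness_quantile``.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0]))
    cens_rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))

    n_prot = config.n_proteins
    proteins = [f"P{i:05d}" for i in range(1, n_prot + 1)]

    # planted sets (negative control never planted)
    baits = list(config.conditions[1:])
    if config.planted is not None:
        unknown = {p for s in config.planted.values() for p in s} - set(proteins)
        if unknown:
            raise InputError(f"planted references unknown proteins: {sorted(unknown)[:5]}")
        planted = {c: set(config.planted.get(c, set())) for c in baits}
    else:
        planted = {
            c: set(rng.choice(proteins, size=config.n_planted_per_condition, replace=False))
            for c in baits
        }
    effects = {
        (c, p): float(config.effect_log2fc) for c in baits for p in planted[c]
    }
    truth = SyntheticTruth(planted=planted, effect_log2fc=effects)

    lo, hi = config.peptides_per_protein
    n_peps = rng.integers(lo, hi + 1, size=n_prot)
    abundance = np.exp(rng.normal(config.baseline_log_mean, config.baseline_log_sd, size=n_prot))

    samples = config.sample_ids
    sample_cond = {s: s.rsplit("_", 1)[0] for s in samples}
    scales = config.sample_scale_factors or {}
    scale_vec = np.array([float(scales.get(s, 1.0)) for s in samples])
    # sd of log-normal noise giving the requested CV on the natural scale
    noise_sd = np.sqrt(np.log1p(config.replicate_cv**2))

    rows = []
    pep_counter = 0
    for i, prot in enumerate(proteins):
        k = int(n_peps[i])
        fractions = rng.dirichlet(np.full(k, 5.0))
        # per-sample planted multiplier for this protein
        mult = np.array([
            2.0 ** effects.get((sample_cond[s], prot), 0.0) for s in samples
        ])
        for j in range(k):
            pep_counter += 1
            base = abundance[i] * fractions[j]
            noise = np.exp(rng.normal(0.0, noise_sd, size=len(samples)))
            inten = base * mult * scale_vec * noise
            rows.append({
                "peptide_id": f"pep{pep_counter:06d}",
                "sequence": _random_sequence(rng, int(rng.integers(8, 21))),
                "protein": prot,
                "intensity": inten,
            })

    # share a fraction of peptides with a second candidate accession
    n_shared = int(round(config.shared_peptide_fraction * len(rows))) if n_prot > 1 else 0
    shared_idx = set(rng.choice(len(rows), size=n_shared, replace=False)) if n_shared else set()
    records = []
    for idx, row in enumerate(rows):
        acc = [row["protein"]]
        if idx in shared_idx:
            other = proteins[int(rng.integers(n_prot))]
            while other == row["protein"]:
                other = proteins[int(rng.integers(n_prot))]
            acc = sorted([row["protein"], other])
        records.append((row["peptide_id"], row["sequence"], tuple(acc), row["intensity"]))

    inten_mat = np.vstack([r[3] for r in records])

    # left-censored missingness: below the per-sample quantile, drop w.p. missing_prob_low
    if config.missingness_quantile > 0:
        thresholds = np.quantile(inten_mat, config.missingness_quantile, axis=0)
    else:
        thresholds = np.full(len(samples), -np.inf)
    u = cens_rng.random(inten_mat.shape)
    censored = (inten_mat < thresholds) & (u < config.missing_prob_low)
    inten_mat = np.where(censored, np.nan, inten_mat)

    data = pd.DataFrame(inten_mat, columns=samples)
    data.insert(0, "accessions", [r[2] for r in records])
    data.insert(0, "sequence", [r[1] for r in records])
    data.index = pd.Index([r[0] for r in records], name="peptide_id")

    # residue counts: covered residues plus ~30% uncovered slack, deterministic
    lengths: dict[str, int] = {}
    seq_len = data["sequence"].str.len()
    own_protein = pd.Series([r["protein"] for r in rows], index=data.index)
    for prot, grp in seq_len.groupby(own_protein):
        lengths[prot] = int(np.ceil(grp.sum() * 1.3))

    table = PeptideTable(data, samples=samples, protein_lengths=lengths)
    return table, truth


def write_truth(truth: SyntheticTruth, path) -> None:
    """Write planted effects as TSV (condition, protein, log2 effect)."""
    rows = [
        {"condition": c, "protein": p, "effect_log2fc": truth.effect_log2fc[(c, p)]}
        for c in sorted(truth.planted)
        for p in sorted(truth.planted[c])
    ]
    pd.DataFrame(rows, columns=["condition", "protein", "effect_log2fc"]).to_csv(
        path, sep="\t", index=False
    )


def read_truth(path) -> SyntheticTruth:
    """Read a truth file written by :func:`write_truth`."""
    df = pd.read_csv(path, sep="\t", dtype={"condition": str, "protein": str})
    planted: dict[str, set[str]] = {}
    effects: dict[tuple[str, str], float] = {}
    for row in df.itertuples(index=False):
        planted.setdefault(row.condition, set()).add(row.protein)
        effects[(row.condition, row.protein)] = float(row.effect_log2fc)
    return SyntheticTruth(planted=planted, effect_log2fc=effects)
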