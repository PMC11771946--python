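import numpy as np
import pandas as pd
import pytest

from proxidiff.types import DesignTable, PeptideTable


def make_design(conditions=("CTRL", "WT", "M1", "M2"), n_replicates=3,
                control=None, reference=None) -> DesignTable:
    rows = [
        {"sample_id": f"{c}_{r}", "condition": c, "replicate": r}
        for c in conditions for r in range(1, n_replicates + 1)
    ]
    return DesignTable(
        pd.DataFrame(rows),
        control=control or conditions[0],
        reference=reference or conditions[1],
    )


def make_peptides(rows, samples, lengths=None) -> PeptideTable:
    """rows: list of (peptide_id, sequence, accessions, intensities)."""
    data = pd.DataFrame(
        {s: [r[3][i] for r in rows] for i, s in enumerate(samples)},
        index=pd.Index([r[0] for r in rows], name="peptide_id"),
    )
    data.insert(0, "accessions", [tuple(r[2]) for r in rows])
    data.insert(0, "sequence", [r[1] for r in rows])
    return PeptideTable(data, samples=list(samples), protein_lengths=lengths)


@pytest.fixture
def design6():
    """Study-shaped design: negative control + five baits, three replicates."""
    return make_design(("TurboID", "WT", "R326H", "R376C", "R488H", "T532M"))


@pytest.fixture
def small_design():
    return make_design(("CTRL", "WT", "M1"), n_replicates=3)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
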