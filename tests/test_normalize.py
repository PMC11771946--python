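"""Roll-up, trimmed-mean normalization, and ratio formation."""

import numpy as np
import pandas as pd
import pytest

from proxidiff import (
    assign_razor,
    control_relative,
    group_proteins,
    rollup,
    trimmed_mean_normalize,
    wt_relative,
)
from proxidiff.errors import InputError
from proxidiff.normalize import trimmed_column_means
from proxidiff.types import ProteinMatrix

from conftest import make_design, make_peptides


def matrix_from(values: dict, state="raw") -> ProteinMatrix:
    return ProteinMatrix(pd.DataFrame(values), state)


def complete_table(design, rows):
    return make_peptides(
        [(f"p{i}", "ACDEFGHIK", (acc,), vals) for i, (acc, vals) in enumerate(rows)],
        design.samples,
        lengths={acc: 100 for acc, _ in rows},
    )


def groups_for(table):
    assignment = assign_razor(table)
    return group_proteins(table, assignment, table.protein_lengths)


class TestRollup:
    def test_sums_peptides_of_a_group(self, small_design):
        table = complete_table(small_design, [
            ("P1", [5.0] * 9), ("P1", [7.0] * 9), ("P2", [2.0] * 9),
        ])
        mat = rollup(table, groups_for(table))
        assert mat.values.loc["P1", "CTRL_1"] == 12.0
        assert mat.values.loc["P2", "CTRL_1"] == 2.0

    def test_single_peptide_group_is_identity(self, small_design):
        table = complete_table(small_design, [("P1", [3.0] * 9)])
        mat = rollup(table, groups_for(table))
        assert (mat.values.loc["P1"] == 3.0).all()

    def test_conserves_per_sample_totals(self, small_design, rng):
        rows = [(f"P{i}", list(rng.uniform(1, 100, 9))) for i in range(20)]
        table = complete_table(small_design, rows)
        mat = rollup(table, groups_for(table))
        np.testing.assert_allclose(
            mat.values.sum(axis=0).to_numpy(),
            table.intensities.sum(axis=0).to_numpy(),
            rtol=1e-12,
        )

    def test_missing_cells_rejected(self, small_design):
        table = complete_table(small_design, [("P1", [3.0] * 9)])
        table.data.loc["p0", "CTRL_1"] = np.nan
        with pytest.raises(InputError, match="complete"):
            rollup(table, groups_for(table))


class TestTrimmedNormalize:
    def test_hand_computed_trimmed_mean(self):
        col = pd.DataFrame({"s": np.arange(1.0, 11.0)})
        assert trimmed_column_means(col, 0.10)["s"] == pytest.approx(5.5)

    def test_identical_columns_are_fixed_point(self):
        vals = {f"s{j}": np.arange(1.0, 21.0) for j in range(4)}
        mat = matrix_from(vals)
        out = trimmed_mean_normalize(mat)
        pd.testing.assert_frame_equal(out.values, mat.values)

    def test_equalizes_trimmed_means(self, rng):
        vals = {f"s{j}": rng.lognormal(3, 1, 50) * (j + 1) for j in range(4)}
        out = trimmed_mean_normalize(matrix_from(vals))
        m = trimmed_column_means(out.values, 0.10)
        np.testing.assert_allclose(m, m.iloc[0], rtol=1e-12)

    def test_idempotent_to_1e9(self, rng):
        vals = {f"s{j}": rng.lognormal(3, 1, 50) * (j + 1) for j in range(4)}
        once = trimmed_mean_normalize(matrix_from(vals))
        twice = trimmed_mean_normalize(ProteinMatrix(once.values, "raw"))
        np.testing.assert_allclose(
            twice.values.to_numpy(), once.values.to_numpy(), rtol=1e-9)

    def test_column_rescaling_changes_nothing_but_global_factor(self, rng):
        vals = {f"s{j}": rng.lognormal(3, 1, 50) for j in range(4)}
        base = trimmed_mean_normalize(matrix_from(vals)).values
        scaled_in = {k: (np.asarray(v) * (17.0 if k == "s2" else 1.0))
                     for k, v in vals.items()}
        scaled = trimmed_mean_normalize(matrix_from(scaled_in)).values
        factor = scaled.to_numpy() / base.to_numpy()
        np.testing.assert_allclose(factor, factor.flat[0], rtol=1e-9)

    def test_trim_half_rejected(self):
        with pytest.raises(InputError, match="trim"):
            trimmed_mean_normalize(matrix_from({"s": [1.0, 2.0]}), trim=0.5)

    def test_too_few_rows_rejected(self):
        with pytest.raises(InputError, match="rows"):
            trimmed_mean_normalize(matrix_from({"s": [1.0]}), trim=0.4)


class TestControlRelative:
    def _norm(self, values):
        return ProteinMatrix(pd.DataFrame(values), "trimmed_normalized")

    def test_ratio_arithmetic(self, small_design):
        vals = {s: [10.0 if s.startswith("CTRL") else 30.0]
                for s in small_design.samples}
        out = control_relative(self._norm(vals), small_design)
        assert (out.values.loc[0] == 3.0).all()

    def test_null_interactor_has_unit_ratio(self, small_design):
        vals = {s: [8.0] for s in small_design.samples}
        out = control_relative(self._norm(vals), small_design)
        assert (out.values.loc[0] == 1.0).all()
        assert np.log2(out.values.loc[0]).sum() == 0.0

    def test_control_columns_dropped(self, small_design):
        vals = {s: [2.0] for s in small_design.samples}
        out = control_relative(self._norm(vals), small_design)
        assert not any(c.startswith("CTRL") for c in out.values.columns)

    def test_replicate_matched_uses_same_replicate(self, small_design):
        vals = {f"CTRL_{r}": [float(r)] for r in (1, 2, 3)}
        vals.update({f"WT_{r}": [10.0 * r] for r in (1, 2, 3)})
        vals.update({f"M1_{r}": [1.0] for r in (1, 2, 3)})
        out = control_relative(self._norm(vals), small_design)
        assert (out.values[["WT_1", "WT_2", "WT_3"]].loc[0] == 10.0).all()

    def test_condition_mean_mode(self, small_design):
        vals = {f"CTRL_{r}": [float(r)] for r in (1, 2, 3)}  # mean 2
        vals.update({f"WT_{r}": [4.0] for r in (1, 2, 3)})
        vals.update({f"M1_{r}": [2.0] for r in (1, 2, 3)})
        out = control_relative(self._norm(vals), small_design,
                               replicate_matched=False)
        assert (out.values[["WT_1", "WT_2", "WT_3"]].loc[0] == 2.0).all()


class TestWtRelative:
    def _ratios(self, small_design, values):
        bait_cols = [s for s in small_design.samples if not s.startswith("CTRL")]
        return ProteinMatrix(pd.DataFrame(values, columns=bait_cols),
                             "control_relative")

    def test_mutant_equal_to_reference_gives_one(self, small_design):
        ratios = self._ratios(small_design, [[2.0] * 6])
        out = wt_relative(ratios, small_design, {"M1": {0}})
        assert (out.values.loc[0, ["M1_1", "M1_2", "M1_3"]] == 1.0).all()

    def test_empty_restriction_gives_empty_matrix(self, small_design):
        ratios = self._ratios(small_design, [[2.0] * 6])
        out = wt_relative(ratios, small_design, {"M1": set()})
        assert out.values.empty
        assert out.state == "wt_relative"

    def test_unknown_groups_listed(self, small_design):
        ratios = self._ratios(small_design, [[2.0] * 6])
        with pytest.raises(InputError, match="ghost"):
            wt_relative(ratios, small_design, {"M1": {"ghost"}})

    def test_state_machine_enforced(self, small_design):
        raw = matrix_from({s: [1.0, 2.0] for s in small_design.samples})
        with pytest.raises(InputError, match="state"):
            control_relative(raw, small_design)
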