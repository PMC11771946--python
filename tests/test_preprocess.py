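"""Missingness filter and the two imputation rules."""

import numpy as np
import pytest
from scipy import stats

from proxidiff import filter_peptides, impute
from proxidiff.errors import InputError
from proxidiff.preprocess import audit_frame

from conftest import make_design, make_peptides

NA = np.nan


def pt(rows, design):
    return make_peptides(
        [(f"p{i}", "ACDEFGHIK", ("P1",), vals) for i, vals in enumerate(rows)],
        design.samples,
    )


class TestFilter:
    def test_two_of_three_in_one_condition_retained(self, small_design):
        # observed twice in CTRL, nowhere else
        table = pt([[5.0, 6.0, NA, NA, NA, NA, NA, NA, NA]], small_design)
        assert len(filter_peptides(table, small_design).data) == 1

    def test_single_observation_everywhere_removed(self, small_design):
        table = pt([[5.0, NA, NA, 6.0, NA, NA, 7.0, NA, NA]], small_design)
        assert len(filter_peptides(table, small_design).data) == 0

    def test_complete_table_is_noop(self, small_design):
        table = pt([[float(i + 1)] * 9 for i in range(4)], small_design)
        out = filter_peptides(table, small_design)
        assert out.data.equals(table.data)

    def test_global_scope_counts_across_conditions(self, small_design):
        table = pt([[5.0, NA, NA, 6.0, NA, NA, 7.0, NA, NA]], small_design)
        assert len(filter_peptides(table, small_design, scope="global").data) == 1

    def test_idempotent(self, small_design):
        table = pt([
            [5.0, 6.0, NA, NA, NA, NA, NA, NA, NA],
            [5.0, NA, NA, NA, 6.0, NA, NA, NA, 7.0],
        ], small_design)
        once = filter_peptides(table, small_design)
        twice = filter_peptides(once, small_design)
        assert once.data.equals(twice.data)

    def test_min_observed_above_group_size_rejected(self, small_design):
        table = pt([[1.0] * 9], small_design)
        with pytest.raises(InputError, match="group size"):
            filter_peptides(table, small_design, min_observed=4)


class TestImpute:
    def test_rule1_mean_of_other_two(self, small_design):
        table = pt([[10.0, 12.0, NA] + [1.0] * 6,
                    [2.0] * 9], small_design)
        out = impute(table, small_design, seed=0)
        assert out.data.loc["p0", "CTRL_3"] == pytest.approx(11.0)

    def test_complete_group_unchanged(self, small_design):
        table = pt([[5.0, 6.0, 7.0] + [2.0] * 6], small_design)
        out = impute(table, small_design, seed=0)
        assert out.data[small_design.samples].equals(
            table.data[small_design.samples])

    def test_rule1_is_seed_independent(self, small_design):
        table = pt([[10.0, 12.0, NA] + [1.0] * 6,
                    [2.0] * 9], small_design)
        a = impute(table, small_design, seed=1).data.loc["p0", "CTRL_3"]
        b = impute(table, small_design, seed=99).data.loc["p0", "CTRL_3"]
        assert a == b == 11.0

    def test_degenerate_constant_sample_imputes_constant(self, small_design):
        # every observed CTRL_2/CTRL_3 intensity equals 3.0, so the bottom-2%
        # interval collapses and rule 2 imputes exactly 3.0
        rows = [[3.0, NA, NA] + [1.0] * 6 for _ in range(5)]
        rows.append([3.0] * 3 + [1.0] * 6)
        table = pt(rows, small_design)
        out = impute(table, small_design, seed=0)
        block = out.data[["CTRL_2", "CTRL_3"]].to_numpy()
        assert np.all(block == 3.0)

    def test_output_complete_and_reproducible(self, small_design):
        rows = [[6.0, 7.0, NA, NA, NA, 9.0, 4.0, NA, NA] for _ in range(6)]
        rows.append([5.0] * 9)
        table = pt(rows, small_design)
        out1 = impute(table, small_design, seed=5)
        out2 = impute(table, small_design, seed=5)
        assert out1.n_missing() == 0
        assert out1.data.equals(out2.data)

    def test_rule2_draws_lie_in_bottom_quantile_and_are_uniform(self, small_design):
        rng = np.random.default_rng(3)
        n = 5000
        # CTRL_2/CTRL_3 missing -> rule 2 for every row; observed values in
        # those samples come from extra complete rows defining the quantile
        missing_rows = [[10.0, NA, NA] + [5.0] * 6 for _ in range(n)]
        anchor_rows = [[10.0, float(v), float(v)] + [5.0] * 6
                       for v in rng.uniform(1.0, 100.0, size=200)]
        table = pt(missing_rows + anchor_rows, small_design)
        audit = []
        impute(table, small_design, low_quantile=0.02, seed=7, audit=audit)
        frame = audit_frame(audit)
        draws = frame.loc[frame["sample_id"] == "CTRL_2", "imputed_value"].to_numpy()
        observed = table.data["CTRL_2"].dropna()
        lo, hi = observed.min(), observed.quantile(0.02)
        assert len(draws) == n
        assert draws.max() <= hi and draws.min() >= lo
        ks = stats.kstest(draws, stats.uniform(loc=lo, scale=hi - lo).cdf)
        assert ks.pvalue > 0.01

    def test_fully_missing_group_uses_rule2(self, small_design):
        rows = [[6.0, 7.0, 8.0, NA, NA, NA, 1.0, 2.0, 3.0],
                [1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0, 8.0, 9.0]]
        table = pt(rows, small_design)
        audit = []
        out = impute(table, small_design, seed=0, audit=audit)
        assert out.n_missing() == 0
        rules = audit_frame(audit)["rule"].unique().tolist()
        assert rules == ["low_quantile_draw"]

    def test_sample_with_no_observations_is_fatal(self, small_design):
        rows = [[6.0, 7.0, 8.0, NA, 5.0, 5.0, 1.0, 2.0, 3.0]]
        table = pt(rows, small_design)
        with pytest.raises(InputError, match="WT_1"):
            impute(table, small_design)

    def test_audit_records_every_filled_cell(self, small_design):
        rows = [[6.0, 7.0, NA, NA, NA, 9.0, 4.0, 5.0, 6.0],
                [5.0] * 9]
        table = pt(rows, small_design)
        audit = []
        impute(table, small_design, seed=0, audit=audit)
        frame = audit_frame(audit)
        assert len(frame) == 3
        assert set(frame["rule"]) == {"mean_of_observed", "low_quantile_draw"}
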