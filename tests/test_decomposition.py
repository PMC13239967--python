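"""Fraction-positive statistics, the Kitagawa split, and paired tests."""

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp
import scipy.stats
from hypothesis import given, settings
from hypothesis import strategies as st

from kerastate.decomposition import (
    build_fraction_table,
    donor_paired_summary,
    fraction_positive,
    kitagawa_decompose,
    paired_t_test,
)
from kerastate.errors import KerastateError
from tests.conftest import random_fraction_table


def two_state_example_table():
    """Pooled pi/p: normal (.5,.5)/(.4,.2); LE (.3,.7)/(.3,.1)."""
    return pd.DataFrame(
        [
            ("D1", "normal", "K0", 500, 200),
            ("D1", "normal", "K1", 500, 100),
            ("D1", "LE", "K0", 300, 90),
            ("D1", "LE", "K1", 700, 70),
        ],
        columns=["donor", "condition", "state", "n_cells", "n_positive"],
    )


class TestFractionPositive:
    def test_counts_greater_than_zero(self):
        col = np.array([0, 0, 1, 3, 0, 2, 0, 0, 0, 5])
        counts = sp.csr_matrix(col[:, None])
        assert fraction_positive(counts, np.arange(10), 0) == pytest.approx(0.4)

    @pytest.mark.parametrize("col,expected", [(np.zeros(6), 0.0), (np.arange(1, 7), 1.0)])
    def test_degenerate_columns(self, col, expected):
        counts = sp.csr_matrix(col[:, None])
        assert fraction_positive(counts, np.ones(6, bool), 0) == expected

    def test_empty_subset_raises(self):
        counts = sp.csr_matrix(np.ones((4, 2)))
        with pytest.raises(KerastateError, match="empty"):
            fraction_positive(counts, np.zeros(4, bool), 0)


class TestFractionTable:
    def test_single_group(self):
        cells = pd.DataFrame(
            {
                "donor": ["D1"] * 4,
                "condition": ["normal"] * 4,
                "state": ["K0"] * 4,
                "positive": [True, False, False, False],
            }
        )
        table = build_fraction_table(cells)
        assert len(table) == 1
        assert table.loc[0, "n_cells"] == 4 and table.loc[0, "n_positive"] == 1

    def test_permutation_invariant(self, tiny_cohort):
        cells = tiny_cohort.cells.copy()
        cells["state"] = cells["true_state"]
        cells["positive"] = np.asarray(tiny_cohort.counts[:, 0].todense()).ravel() > 0
        shuffled = cells.sample(frac=1.0, random_state=3).reset_index(drop=True)
        pd.testing.assert_frame_equal(build_fraction_table(cells), build_fraction_table(shuffled))

    def test_matches_nested_loop_tally(self):
        rng = np.random.default_rng(11)
        n = 500
        cells = pd.DataFrame(
            {
                "donor": rng.choice(["D1", "D2", "D3"], n),
                "condition": rng.choice(["normal", "LE"], n),
                "state": rng.choice(["K0", "K1"], n),
                "positive": rng.random(n) < 0.3,
            }
        )
        table = build_fraction_table(cells).set_index(["donor", "condition", "state"])
        for d in ["D1", "D2", "D3"]:
            for c in ["normal", "LE"]:
                for s in ["K0", "K1"]:
                    sub = cells[
                        (cells.donor == d) & (cells.condition == c) & (cells.state == s)
                    ]
                    row = table.loc[(d, c, s)]
                    assert row["n_cells"] == len(sub)
                    assert row["n_positive"] == int(sub["positive"].sum())

    def test_missing_key_raises(self):
        cells = pd.DataFrame(
            {"donor": ["D1", None], "condition": ["normal"] * 2, "state": ["K0"] * 2, "positive": [True, False]}
        )
        with pytest.raises(KerastateError, match="donor"):
            build_fraction_table(cells)


class TestKitagawa:
    def test_hand_enumerated_two_state_example(self):
        res = kitagawa_decompose(two_state_example_table(), "normal", "LE")
        assert res.delta_total == pytest.approx(-0.14, abs=1e-12)
        assert res.composition_component == pytest.approx(-0.04, abs=1e-12)
        assert res.within_component == pytest.approx(-0.10, abs=1e-12)

    def test_identical_conditions_all_zero(self):
        table = two_state_example_table()
        table.loc[table.condition == "LE", ["n_cells", "n_positive"]] = (
            table.loc[table.condition == "normal", ["n_cells", "n_positive"]].to_numpy()
        )
        res = kitagawa_decompose(table, "normal", "LE")
        assert res.delta_total == res.within_component == res.composition_component == 0.0

    def test_antisymmetry(self):
        table = two_state_example_table()
        fwd = kitagawa_decompose(table, "normal", "LE")
        rev = kitagawa_decompose(table, "LE", "normal")
        assert rev.delta_total == pytest.approx(-fwd.delta_total, abs=1e-12)
        assert rev.within_component == pytest.approx(-fwd.within_component, abs=1e-12)
        assert rev.composition_component == pytest.approx(-fwd.composition_component, abs=1e-12)

    @pytest.mark.parametrize("mode", ["pooled", "per_donor"])
    def test_additivity_random_tables(self, mode):
        rng = np.random.default_rng(5)
        for _ in range(50):
            table = random_fraction_table(rng)
            # every donor/condition needs cells for both modes to be defined
            table.loc[table.groupby(["donor", "condition"])["n_cells"].transform("sum") == 0, "n_cells"] = 1
            res = kitagawa_decompose(table, "normal", "LE", mode=mode)
            assert res.within_component + res.composition_component == pytest.approx(
                res.delta_total, abs=1e-12
            )

    def test_state_missing_in_one_condition(self):
        table = pd.DataFrame(
            [
                ("D1", "normal", "K0", 100, 40),
                ("D1", "normal", "K1", 0, 0),
                ("D1", "LE", "K0", 50, 10),
                ("D1", "LE", "K1", 50, 30),
            ],
            columns=["donor", "condition", "state", "n_cells", "n_positive"],
        )
        res = kitagawa_decompose(table, "normal", "LE")
        # missing state: pi = 0 in normal, p borrowed from LE; identity exact
        assert res.within_component + res.composition_component == pytest.approx(
            res.delta_total, abs=1e-12
        )
        row = res.per_state.set_index("state").loc["K1"]
        assert row["pi_a"] == 0.0 and row["p_a"] == row["p_b"] == 0.6

    def test_empty_condition_raises(self):
        table = two_state_example_table()
        table.loc[table.condition == "LE", "n_cells"] = 0
        with pytest.raises(KerastateError, match="zero cells"):
            kitagawa_decompose(table, "normal", "LE")

    def test_null_invariance(self):
        # equal compositions => composition component 0; equal rates => within 0
        table = pd.DataFrame(
            [
                ("D1", "normal", "K0", 400, 100),
                ("D1", "normal", "K1", 600, 300),
                ("D1", "LE", "K0", 200, 80),
                ("D1", "LE", "K1", 300, 60),
            ],
            columns=["donor", "condition", "state", "n_cells", "n_positive"],
        )
        res = kitagawa_decompose(table, "normal", "LE")  # pi equal (.4,.6)
        assert res.composition_component == pytest.approx(0.0, abs=1e-12)
        table2 = pd.DataFrame(
            [
                ("D1", "normal", "K0", 400, 100),
                ("D1", "normal", "K1", 600, 300),
                ("D1", "LE", "K0", 600, 150),
                ("D1", "LE", "K1", 400, 200),
            ],
            columns=["donor", "condition", "state", "n_cells", "n_positive"],
        )
        res2 = kitagawa_decompose(table2, "normal", "LE")  # p equal (.25,.5)
        assert res2.within_component == pytest.approx(0.0, abs=1e-12)


class TestPairedT:
    def test_identical_inputs(self):
        res = paired_t_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.t_statistic == 0.0 and res.p_value == 1.0

    def test_closed_form_df2(self):
        res = paired_t_test([1, 2, 3], [2, 4, 6])
        assert res.t_statistic == pytest.approx(3.4641, abs=1e-4)
        assert res.df == 2
        # exact df=2 CDF: p = 1 - t/sqrt(t^2 + 2)
        t = res.t_statistic
        assert res.p_value == pytest.approx(1.0 - t / np.sqrt(t * t + 2.0), abs=1e-12)
        assert res.p_value == pytest.approx(0.0742, abs=5e-4)

    def test_sign_flip(self):
        a, b = [0.1, 0.4, 0.3, 0.9], [0.2, 0.3, 0.5, 1.0]
        fwd, rev = paired_t_test(a, b), paired_t_test(b, a)
        assert rev.t_statistic == pytest.approx(-fwd.t_statistic, abs=1e-14)
        assert rev.p_value == pytest.approx(fwd.p_value, abs=1e-14)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=30, deadline=None)
    def test_agrees_with_scipy(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 12))
        x, y = rng.normal(size=n), rng.normal(size=n)
        res = paired_t_test(x, y)
        ref = scipy.stats.ttest_rel(y, x)
        assert res.t_statistic == pytest.approx(ref.statistic, abs=1e-10)
        assert res.p_value == pytest.approx(ref.pvalue, abs=1e-10)

    def test_zero_variance_nonzero_difference_degenerate(self):
        res = paired_t_test([1.0, 2.0], [2.0, 3.0])
        assert res.degenerate and res.p_value == 0.0


class TestDonorPairedSummary:
    def test_identical_donors_p_one(self):
        table = pd.DataFrame(
            [
                (d, c, "K0", 100, 30)
                for d in ("D1", "D2", "D3")
                for c in ("normal", "LE")
            ],
            columns=["donor", "condition", "state", "n_cells", "n_positive"],
        )
        per_donor, test = donor_paired_summary(table, "normal", "LE")
        assert test.mean_difference == 0.0 and test.p_value == 1.0

    def test_pooled_means_match_tally(self):
        rng = np.random.default_rng(2)
        table = random_fraction_table(rng)
        table["n_cells"] += 1  # every donor/condition populated
        per_donor, _ = donor_paired_summary(table, "normal", "LE")
        for cond, key in (("normal", "pooled_a"), ("LE", "pooled_b")):
            sub = table[table.condition == cond]
            assert per_donor.attrs[key] == pytest.approx(
                sub.n_positive.sum() / sub.n_cells.sum(), abs=1e-15
            )
        # per-donor fraction equals that donor's tally
        for _, row in per_donor.iterrows():
            sub = table[(table.donor == row.donor) & (table.condition == "normal")]
            assert row["fraction_normal"] == pytest.approx(
                sub.n_positive.sum() / sub.n_cells.sum(), abs=1e-15
            )

    def test_missing_condition_names_donor(self):
        table = two_state_example_table()
        table = table[~((table.donor == "D1") & (table.condition == "LE"))]
        with pytest.raises(KerastateError, match="D1"):
            donor_paired_summary(table, "normal", "LE")
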