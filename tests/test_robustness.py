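"""Tests for signal-set construction, normalisation and robustness testing."""

import numpy as np
import pandas as pd
import pytest

import radrobust as rr
from radrobust.robustness import condition_pairs
from radrobust.tables import SchemaError

from _oracles import bs_brute, ns_brute, pooled_t_brute, robustness_brute


class TestBiologicalSignal:
    def test_enumerates_all_cross_group_pairs(self):
        bs = rr.biological_signal([0.0, 1.0], [2.0])
        assert sorted(bs.values.tolist()) == [1.0, 2.0]

    def test_identical_singleton_groups_give_zero(self):
        bs = rr.biological_signal([3.0], [3.0])
        assert bs.values.tolist() == [0.0]

    def test_default_cohort_sizes_give_520_pairs(self):
        rng = np.random.default_rng(0)
        bs = rr.biological_signal(rng.normal(size=20), rng.normal(size=26))
        assert len(bs) == 20 * 26

    def test_invariant_under_group_label_swap(self):
        rng = np.random.default_rng(1)
        w, m = rng.normal(size=5), rng.normal(size=7)
        a = np.sort(rr.biological_signal(w, m).values)
        b = np.sort(rr.biological_signal(m, w).values)
        assert np.array_equal(a, b)

    def test_empty_group_is_an_error(self):
        with pytest.raises(ValueError):
            rr.biological_signal([], [1.0])


class TestNoiseSignal:
    @staticmethod
    def _phantom(values_by_condition):
        rows = []
        for cond, vals in values_by_condition.items():
            for i, v in enumerate(vals):
                rows.append({"lesion_id": f"lesion_{i}", "condition_id": cond, "f": v})
        return pd.DataFrame(rows)

    def test_identical_conditions_give_all_zeros(self):
        phantom = self._phantom({"c1": [1.0, 2.0], "c2": [1.0, 2.0]})
        ns = rr.noise_signal(phantom, "f", "c1", "c2")
        assert ns.values.tolist() == [0.0, 0.0]

    def test_per_lesion_matched_subtraction(self):
        phantom = self._phantom({"c1": [1.0, 2.0], "c2": [3.0, 2.0]})
        ns = rr.noise_signal(phantom, "f", "c1", "c2")
        assert sorted(ns.values.tolist()) == [0.0, 2.0]

    def test_size_equals_lesion_count_and_symmetric_in_conditions(self, phantom_table):
        ns_ij = rr.noise_signal(phantom_table, "f_strong", "scanner1-395mA", "scanner2-65mA")
        ns_ji = rr.noise_signal(phantom_table, "f_strong", "scanner2-65mA", "scanner1-395mA")
        assert len(ns_ij) == 24
        assert np.array_equal(ns_ij.values, ns_ji.values)

    def test_missing_lesion_is_incomplete_design(self):
        phantom = self._phantom({"c1": [1.0, 2.0], "c2": [3.0, 2.0]})
        with pytest.raises(ValueError, match="incomplete design"):
            rr.noise_signal(phantom.iloc[:-1], "f", "c1", "c2")


class TestNormalization:
    def test_population_convention_hand_case(self):
        # BS {2, 1}: mu = 1.5, sigma = 0.5 (1/n) -> denominator 2.0
        bs = rr.SignalSet("biological", [2.0, 1.0], ("w", "m"), ddof=0)
        bs_norm, _ = rr.normalize_signals(bs, [])
        assert sorted(bs_norm.values.tolist()) == pytest.approx([0.5, 1.0])

    def test_sample_convention_hand_case(self):
        # BS {2, 1}: mu = 1.5, sigma ~ 0.7071 (1/(n-1)) -> denominator ~ 2.2071
        bs = rr.SignalSet("biological", [2.0, 1.0], ("w", "m"), ddof=1)
        bs_norm, _ = rr.normalize_signals(bs, [])
        assert sorted(bs_norm.values.tolist()) == pytest.approx([0.4531, 0.9062], abs=1e-4)

    def test_constant_nonzero_signal_normalises_to_one(self):
        bs = rr.SignalSet("biological", [1.0, 1.0], ("w", "m"))
        bs_norm, _ = rr.normalize_signals(bs, [])
        assert bs_norm.values.tolist() == [1.0, 1.0]

    def test_all_zero_signal_is_degenerate(self):
        bs = rr.SignalSet("biological", [0.0, 0.0], ("w", "m"))
        with pytest.raises(ValueError, match="degenerate"):
            rr.normalize_signals(bs, [])

    def test_mean_identity_and_shared_denominator(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            bs = rr.SignalSet("biological", np.abs(rng.normal(size=50)), ("w", "m"))
            ns = rr.SignalSet("noise", np.abs(rng.normal(size=24)), ("c1", "c2"))
            bs_norm, [ns_norm] = rr.normalize_signals(bs, [ns])
            denom = bs.mu + bs.sigma
            assert bs_norm.mu == pytest.approx(bs.mu / denom, abs=1e-12)
            assert np.allclose(ns_norm.values, ns.values / denom)


class TestCompareSignals:
    def test_identical_sets_are_not_robust(self):
        s = rr.SignalSet("noise", [1.0, 2.0, 3.0], ("c1", "c2"))
        cmp = rr.compare_signals(s, s)
        assert cmp.t == pytest.approx(0.0) and cmp.p == pytest.approx(1.0)
        assert not cmp.robust

    def test_pooled_t_closed_form(self):
        a = rr.SignalSet("noise", [1.0, 2.0, 3.0], ("c1", "c2"))
        b = rr.SignalSet("biological", [5.0, 6.0, 7.0], ("w", "m"))
        cmp = rr.compare_signals(a, b)  # a as "biology", b as noise
        assert cmp.t == pytest.approx(-4.898979, abs=1e-5)
        assert cmp.p == pytest.approx(0.0080499, abs=1e-5)  # 2*sf(4.899, df=4)
        assert not cmp.robust  # significant but biology below noise
        cmp2 = rr.compare_signals(b, a)  # now biology above noise
        assert cmp2.robust

    def test_direction_rule_blocks_significant_noise_dominance(self):
        rng = np.random.default_rng(3)
        bs = rr.SignalSet("biological", np.abs(rng.normal(0.2, 0.05, 100)), ("w", "m"))
        ns = rr.SignalSet("noise", np.abs(rng.normal(2.0, 0.05, 100)), ("c1", "c2"))
        cmp = rr.compare_signals(bs, ns)
        assert cmp.p < 0.05 and not cmp.robust

    def test_degenerate_zero_variance_sets(self):
        a = rr.SignalSet("biological", [1.0, 1.0], ("w", "m"))
        b = rr.SignalSet("noise", [1.0, 1.0], ("c1", "c2"))
        assert rr.compare_signals(a, b).p == 1.0
        c = rr.SignalSet("noise", [2.0, 2.0], ("c1", "c2"))
        assert rr.compare_signals(a, c).p == 0.0


class TestRobustnessMatrix:
    def test_8_conditions_give_28_cells(self, cohort_table, phantom_table):
        matrix = rr.robustness_matrix("f_strong", cohort_table, phantom_table)
        assert matrix.n_cells == 28
        pairs = set(zip(matrix.cells["condition_i"], matrix.cells["condition_j"]))
        assert len(pairs) == 28

    def test_two_conditions_give_one_cell(self, cohort_table):
        base = pd.DataFrame({"f_strong": np.arange(5.0), "f_null": np.zeros(5)})
        phantom = rr.generate_phantom_table(5, ["c1", "c2"], base, 0.1, seed=0)
        matrix = rr.robustness_matrix("f_strong", cohort_table, phantom)
        assert matrix.n_cells == 1

    def test_strong_separation_makes_every_cell_robust(self):
        cohort = rr.generate_cohort_table(
            rr.CohortConfig(20, 26, {"f": rr.FeatureSpec(0.0, 10.0, 1.0)}, seed=4)
        )
        base = pd.DataFrame({"f": np.random.default_rng(5).normal(0, 1, 24)})
        phantom = rr.generate_phantom_table(
            24, rr.default_scan_conditions(), base, 0.1, seed=6
        )
        matrix = rr.robustness_matrix("f", cohort, phantom)
        assert matrix.n_robust == 28
        overall, fraction = rr.aggregate_robustness(matrix)
        assert overall and fraction == 1.0

    def test_agrees_with_brute_force_micro_instance(self):
        """Full-procedure agreement with an independent double-loop script on a
        5-lesion, 3-condition instance."""
        rng = np.random.default_rng(7)
        w, m = rng.normal(0, 1, 4), rng.normal(1, 1, 6)
        cohort = pd.DataFrame(
            {
                "sample_id": [f"s{i}" for i in range(10)],
                "group": ["wildtype"] * 4 + ["mutant"] * 6,
                "f": np.r_[w, m],
            }
        )
        wide = {c: rng.normal(0, 0.5, 5).tolist() for c in ["c1", "c2", "c3"]}
        rows = []
        for cond, vals in wide.items():
            for i, v in enumerate(vals):
                rows.append({"lesion_id": f"l{i}", "condition_id": cond, "f": v})
        phantom = pd.DataFrame(rows)
        matrix = rr.robustness_matrix("f", cohort, phantom)
        mean_bs, expected = robustness_brute(w.tolist(), m.tolist(), wide)
        assert matrix.mean_bs == pytest.approx(mean_bs, abs=1e-12)
        assert matrix.n_cells == 3
        for _, row in matrix.cells.iterrows():
            mean_ns, t, p, robust = expected[(row["condition_i"], row["condition_j"])]
            assert row["mean_ns"] == pytest.approx(mean_ns, abs=1e-12)
            assert row["t"] == pytest.approx(t, abs=1e-10)
            assert row["p"] == pytest.approx(p, abs=1e-10)
            assert row["robust"] == robust


class TestModelResults:
    def test_fit_produces_grids_aggregate_and_summary(self, cohort_table, phantom_table):
        model = rr.RobustnessModel(cohort_table, phantom_table)
        results = model.fit()
        agg = results.aggregate().set_index("feature")
        assert set(agg.index) == {"f_strong", "f_null"}
        assert (agg["n_cells"] == 28).all()
        long = results.to_frame()
        assert len(long) == 2 * 28
        text = results.summary()
        assert "f_strong" in text and "alpha = 0.05" in text
        grid = results.grid("f_strong", "mean_ns")
        assert grid.shape == (8, 8)
        arr = grid.to_numpy()
        assert np.allclose(arr, arr.T, equal_nan=True)

    def test_feature_missing_from_either_table_is_schema_error(
        self, cohort_table, phantom_table
    ):
        with pytest.raises(SchemaError):
            rr.RobustnessModel(cohort_table, phantom_table, features=["nope"])

    def test_bonferroni_option_never_increases_robust_count(
        self, cohort_table, phantom_table
    ):
        plain = rr.RobustnessModel(cohort_table, phantom_table).fit()
        adj = rr.RobustnessModel(cohort_table, phantom_table, p_adjust="bonferroni").fit()
        for f in plain.matrices:
            assert adj.matrices[f].n_robust <= plain.matrices[f].n_robust

    def test_welch_option_runs(self, cohort_table, phantom_table):
        results = rr.RobustnessModel(cohort_table, phantom_table, equal_var=False).fit()
        assert np.isfinite(results.to_frame()["p"]).all()


class TestAggregation:
    def test_strict_majority_rule(self):
        from radrobust.robustness import RobustnessMatrix

        def matrix(n_robust, n_cells=28):
            cells = pd.DataFrame(
                {
                    "condition_i": [f"i{k}" for k in range(n_cells)],
                    "condition_j": [f"j{k}" for k in range(n_cells)],
                    "mean_ns": 0.1,
                    "t": 1.0,
                    "p": 0.01,
                    "robust": [k < n_robust for k in range(n_cells)],
                }
            )
            return RobustnessMatrix("f", 0.5, cells)

        assert rr.aggregate_robustness(matrix(28)) == (True, 1.0)
        overall, frac = rr.aggregate_robustness(matrix(3))
        assert not overall and frac == pytest.approx(3 / 28)
        assert rr.aggregate_robustness(matrix(14))[0] is False  # boundary: not strict majority
        assert rr.aggregate_robustness(matrix(15))[0] is True

    def test_condition_pairs_count(self):
        assert len(condition_pairs([f"c{i}" for i in range(8)])) == 28
        assert len(condition_pairs(["a", "b"])) == 1
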