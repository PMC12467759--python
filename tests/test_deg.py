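import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from _oracles import bh_bruteforce, ranksum_permutation_p
from dicoex import synthetic_data as sd
from dicoex.deg import (
    adjust_pvalues,
    bonferroni_threshold,
    intersect_deg,
    run_deg,
    wilcoxon_rank_sum,
)


class TestWilcoxonRankSum:
    def test_exact_enumeration_fully_separated(self):
        # all 20 labelings of 6 values; observed rank-sum is the most extreme
        w, p = wilcoxon_rank_sum([1, 2, 3], [4, 5, 6], mode="exact")
        assert w == 15.0
        assert p == pytest.approx(0.1)

    def test_all_values_identical_is_degenerate(self):
        _, p = wilcoxon_rank_sum([5, 5, 5], [5, 5, 5])
        assert p == 1.0

    def test_approx_close_to_permutation_at_n30(self):
        rng = np.random.default_rng(42)
        x, y = rng.normal(size=30), rng.normal(size=30)
        _, p_approx = wilcoxon_rank_sum(x, y)
        p_perm = ranksum_permutation_p(x, y, n_perm=100_000, seed=7)
        assert abs(p_approx - p_perm) < 0.02

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(0)
        x, y = rng.normal(size=15), rng.normal(size=20) + 0.5
        _, p1 = wilcoxon_rank_sum(x, y)
        _, p2 = wilcoxon_rank_sum(np.exp(x), np.exp(y))
        assert p1 == pytest.approx(p2, rel=1e-12)

    def test_group_swap_preserves_p(self):
        rng = np.random.default_rng(1)
        x, y = rng.normal(size=12), rng.normal(size=9)
        _, p1 = wilcoxon_rank_sum(x, y)
        _, p2 = wilcoxon_rank_sum(y, x)
        assert p1 == pytest.approx(p2, rel=1e-12)

    def test_exact_mode_size_limit(self):
        with pytest.raises(ValueError, match="exact"):
            wilcoxon_rank_sum(np.arange(10), np.arange(10), mode="exact")


class TestAdjustPvalues:
    @pytest.mark.parametrize(
        "p,method,m,expected",
        [
            ([0.01], "bonferroni", 5, [0.05]),
            ([0.2], "bonferroni", 10, [1.0]),
            ([0.01, 0.02, 0.03, 0.04], "bh", 4, [0.04, 0.04, 0.04, 0.04]),
        ],
    )
    def test_examples(self, p, method, m, expected):
        np.testing.assert_allclose(adjust_pvalues(p, method, m), expected)

    def test_bh_matches_bruteforce_definition(self):
        rng = np.random.default_rng(123)
        for _ in range(50):
            n = rng.integers(1, 40)
            p = rng.random(n)
            m = n + int(rng.integers(0, 20))
            np.testing.assert_allclose(
                adjust_pvalues(p, "bh", m), bh_bruteforce(p, m), rtol=1e-12
            )

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=30))
    def test_bh_dominates_raw_p_and_preserves_order(self, p):
        adj = adjust_pvalues(p, "bh")
        assert np.all(adj >= np.asarray(p) - 1e-15)
        order = np.argsort(p, kind="stable")
        assert np.all(np.diff(adj[order]) >= -1e-15)

    def test_rejects_bad_inputs(self):
        with pytest.raises(ValueError):
            adjust_pvalues([1.5], "bh")
        with pytest.raises(ValueError):
            adjust_pvalues([0.1, 0.2], "bh", m=1)


class TestBonferroniThreshold:
    @pytest.mark.parametrize(
        "alpha,m,expected",
        [
            (0.05, 20511, 2.44e-6),  # printed large-cohort threshold
            (0.05, 29377, 1.70e-6),  # printed small-cohort threshold
            (0.05, 1, 0.05),
        ],
    )
    def test_printed_thresholds(self, alpha, m, expected):
        assert bonferroni_threshold(alpha, m) == pytest.approx(expected, rel=5e-3)

    def test_zero_tests_is_error(self):
        with pytest.raises(ValueError):
            bonferroni_threshold(0.05, 0)


class TestRunDeg:
    def test_planted_de_sensitivity_at_cohort_scale(self, platform_pair, deg_pair):
        _, _, truth_a, _, _ = platform_pair
        deg_a, _ = deg_pair
        called = set(deg_a.loc[deg_a["significant"], "gene"])
        sens, _ = sd.recovery_metrics(truth_a.de_set(), called)
        assert sens >= 0.9

    def test_null_dataset_rarely_yields_bh_hits(self):
        hits = 0
        for rep in range(100):
            cfg = sd.SimulationConfig(seed=1000 + rep, n_genes=50, n_wt=40, n_mut=40)
            ds, _ = sd.simulate_dataset(cfg, "null")
            res = run_deg(ds, method="bh", alpha=0.05)
            hits += int(res["significant"].any())
        assert hits <= 5  # 0 significant in >= 95% of replicates

    def test_null_per_gene_type_i_error_within_binomial_band(self):
        cfg = sd.SimulationConfig(seed=77, n_genes=2000, n_wt=40, n_mut=40)
        ds, _ = sd.simulate_dataset(cfg, "null")
        res = run_deg(ds)
        rate = float((res["p"] < 0.05).mean())
        half = 2.576 * np.sqrt(0.05 * 0.95 / 2000)
        assert abs(rate - 0.05) < half

    def test_single_gene_family(self):
        cfg = sd.SimulationConfig(seed=0, n_genes=1, n_wt=10, n_mut=10)
        ds, _ = sd.simulate_dataset(cfg, "p")
        res = run_deg(ds)
        assert res.loc[0, "p_bonf"] == pytest.approx(res.loc[0, "p"])

    def test_label_swap_flips_direction(self):
        cfg = sd.SimulationConfig(
            seed=4, n_genes=5, n_wt=20, n_mut=20, de_spec=[sd.DeGene(0, 2.0, 1)]
        )
        ds, _ = sd.simulate_dataset(cfg, "p")
        from dicoex.dataio import ExpressionDataset

        flipped = ExpressionDataset(
            ds.platform_id, ds.genes, ds.samples, ds.values,
            ["MUT" if l == "WT" else "WT" for l in ds.labels],
        )
        a, b = run_deg(ds), run_deg(flipped)
        np.testing.assert_allclose(a["p"], b["p"], rtol=1e-9)
        assert a.loc[0, "direction"] == "UP" and b.loc[0, "direction"] == "DOWN"


class TestIntersectDeg:
    @staticmethod
    def frame(rows):
        return pd.DataFrame(
            rows, columns=["gene", "direction", "p", "significant"]
        )

    def test_same_direction_rule(self):
        a = self.frame([("G1", "UP", 0.01, True), ("G2", "DOWN", 0.01, True)])
        b = self.frame([("G1", "UP", 0.02, True), ("G2", "UP", 0.02, True)])
        assert list(intersect_deg(a, b)["gene"]) == ["G1"]

    def test_flag_off_keeps_discordant(self):
        a = self.frame([("G1", "UP", 0.01, True), ("G2", "DOWN", 0.01, True)])
        b = self.frame([("G1", "UP", 0.02, True), ("G2", "UP", 0.02, True)])
        out = intersect_deg(a, b, require_same_direction=False)
        assert list(out["gene"]) == ["G1", "G2"]

    def test_disjoint_sets_give_empty(self):
        a = self.frame([("G1", "UP", 0.01, True)])
        b = self.frame([("G2", "UP", 0.02, True)])
        assert intersect_deg(a, b).empty

    def test_replication_recovers_shared_truth(self, platform_pair, deg_pair):
        _, _, truth_a, _, truth_b = platform_pair
        common = intersect_deg(*deg_pair)
        shared = truth_a.de_set() & truth_b.de_set()
        sens, fdp = sd.recovery_metrics(shared, common["gene"])
        assert sens >= 0.9
        assert fdp <= 0.05
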