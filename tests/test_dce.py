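import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from _oracles import dce_permutation_p
from dicoex import synthetic_data as sd
from dicoex.dataio import ExpressionDataset
from dicoex.dce import (
    bonferroni_pair_threshold,
    dce_z_statistic,
    direction_consistent_pairs,
    fisher_z,
    genes_from_pairs,
    overlap_pairs,
    run_dce,
    variance_filter,
)


class TestFisherZ:
    def test_zero_maps_to_zero(self):
        assert fisher_z(0.0) == 0.0

    def test_reference_value(self):
        assert fisher_z(0.75) == pytest.approx(0.9730, abs=1e-4)
        assert fisher_z(-0.75) == pytest.approx(-0.9730, abs=1e-4)

    def test_boundary_is_clamped_finite(self):
        assert np.isfinite(fisher_z(1.0))
        assert np.isfinite(fisher_z(-1.0))

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(st.floats(-0.999, 0.999))
    def test_tanh_inverts(self, r):
        assert np.tanh(fisher_z(r)) == pytest.approx(r, abs=1e-12)

    def test_strictly_increasing(self):
        r = np.linspace(-0.99, 0.99, 500)
        assert np.all(np.diff(fisher_z(r)) > 0)


class TestDceZStatistic:
    def test_null_identity(self):
        z, p = dce_z_statistic(0.4, 50, 0.4, 80)
        assert z == 0.0
        assert p == 1.0

    def test_large_cohort_reference_pair(self):
        # rounded printed correlations of the strongest replicated pair
        z, p = dce_z_statistic(0.93, 93, 0.75, 415)
        assert z == pytest.approx(5.89, abs=0.01)
        assert p == pytest.approx(3.9e-9, rel=0.05)

    def test_small_cohort_reference_pair(self):
        z, _ = dce_z_statistic(0.97, 14, 0.62, 166)
        assert z == pytest.approx(4.39, abs=0.01)

    def test_antisymmetric_under_group_swap(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            r1, r2 = rng.uniform(-0.95, 0.95, 2)
            n1, n2 = rng.integers(5, 300, 2)
            z_ab, p_ab = dce_z_statistic(r1, n1, r2, n2)
            z_ba, p_ba = dce_z_statistic(r2, n2, r1, n1)
            assert z_ab == pytest.approx(-z_ba, rel=1e-12)
            assert p_ab == pytest.approx(p_ba, rel=1e-12)

    def test_small_groups_are_error(self):
        with pytest.raises(ValueError):
            dce_z_statistic(0.5, 3, 0.1, 100)

    def test_extreme_tail_stays_accurate(self):
        _, p = dce_z_statistic(0.999999, 10000, -0.999999, 10000)
        assert 0.0 <= p < 1e-300 or p == 0.0

    def test_agrees_with_permutation_null_in_aggregate(self):
        # the permutation null is conditional on each sample, so agreement
        # holds in aggregate: mean signed difference ~ 0 across datasets
        diffs = []
        for seed in range(20, 30):
            cfg = sd.SimulationConfig(
                seed=seed, n_genes=2, n_wt=40, n_mut=40,
                dce_spec=[sd.DceBlock((0, 1), 0.3, 0.3)],
            )
            ds, _ = sd.simulate_dataset(cfg, "perm")
            x, y = ds.values[0], ds.values[1]
            labels = ds.group_mask("WT")
            r1 = np.corrcoef(x[labels], y[labels])[0, 1]
            r2 = np.corrcoef(x[~labels], y[~labels])[0, 1]
            _, p_analytic = dce_z_statistic(r1, 40, r2, 40)
            p_perm = dce_permutation_p(x, y, labels, n_perm=20_000, seed=seed)
            diffs.append(p_analytic - p_perm)
        diffs = np.asarray(diffs)
        se = diffs.std(ddof=1) / np.sqrt(diffs.size)
        assert abs(diffs.mean()) < 3 * max(se, 0.005)


class TestVarianceFilter:
    @staticmethod
    def dataset(values, genes=None):
        values = np.asarray(values, dtype=float)
        n = values.shape[1]
        return ExpressionDataset(
            "p",
            genes or [f"G{i}" for i in range(values.shape[0])],
            [f"S{i}" for i in range(n)],
            values,
            ["WT"] * (n // 2) + ["MUT"] * (n - n // 2),
        )

    def test_printed_panel_size_at_cohort_gene_count(self):
        rng = np.random.default_rng(0)
        ds = self.dataset(rng.normal(size=(20511, 8)))
        assert len(variance_filter(ds, 0.25).selected) == 5128

    def test_quarter_of_eight_rounds_up_to_two(self):
        rng = np.random.default_rng(1)
        ds = self.dataset(rng.normal(size=(8, 6)))
        assert len(variance_filter(ds, 0.25).selected) == 2

    def test_tie_break_by_symbol(self):
        ds = self.dataset(np.tile([0.0, 1.0, 0.0, 1.0], (4, 1)), ["D", "C", "B", "A"])
        assert variance_filter(ds, 0.25).selected == ["A"]

    def test_selected_variances_dominate_excluded(self):
        rng = np.random.default_rng(2)
        ds = self.dataset(rng.normal(size=(40, 10)) * rng.uniform(0.5, 3, (40, 1)))
        res = variance_filter(ds, 0.25)
        sel = set(res.selected)
        v = res.variances
        assert v[list(sel)].min() >= v[[g for g in ds.genes if g not in sel]].max()

    def test_all_zero_variance_is_error(self):
        ds = self.dataset(np.ones((5, 6)))
        with pytest.raises(ValueError):
            variance_filter(ds)


class TestPairThreshold:
    @pytest.mark.parametrize(
        "m,expected",
        [(5128, 3.80e-9), (6988, 2.05e-9), (2, 0.05)],
    )
    def test_printed_thresholds(self, m, expected):
        assert bonferroni_pair_threshold(0.05, m) == pytest.approx(expected, rel=5e-3)

    def test_single_gene_is_error(self):
        with pytest.raises(ValueError):
            bonferroni_pair_threshold(0.05, 1)


class TestRunDce:
    def test_full_fraction_on_five_genes_gives_ten_pairs(self):
        cfg = sd.SimulationConfig(seed=0, n_genes=5, n_wt=10, n_mut=10)
        ds, _ = sd.simulate_dataset(cfg, "p")
        res = run_dce(ds, fraction=1.0)
        assert len(res) == 10
        assert (res["gene_a"] < res["gene_b"]).all()

    def test_planted_pair_bonferroni_significant(self):
        cfg = sd.SimulationConfig(
            seed=9, n_genes=200, n_wt=93, n_mut=415,
            dce_spec=[sd.DceBlock((0, 1), 0.9, 0.0)],
        )
        ds, truth = sd.simulate_dataset(cfg, "p")
        res = run_dce(ds, fraction=1.0, method="bonferroni", alpha=0.05)
        sig = set(zip(res.loc[res["significant"], "gene_a"],
                      res.loc[res["significant"], "gene_b"]))
        assert truth.pair_set() <= sig

    def test_null_rejection_rate_at_nominal_alpha(self):
        # pooled over replicates: pair statistics sharing a gene are
        # dependent within one dataset, so a single-replicate binomial band
        # is misspecified
        n_rej = n_tests = 0
        for rep in range(20):
            cfg = sd.SimulationConfig(seed=3000 + rep, n_genes=50, n_wt=40, n_mut=40)
            ds, _ = sd.simulate_dataset(cfg, "null")
            res = run_dce(ds, fraction=1.0)
            n_rej += int((res["p"] < 0.05).sum())
            n_tests += len(res)
        rate = n_rej / n_tests
        half = 2.576 * np.sqrt(0.05 * 0.95 / n_tests)
        assert abs(rate - 0.05) < half

    def test_bonferroni_respects_family_size(self):
        cfg = sd.SimulationConfig(seed=8, n_genes=12, n_wt=20, n_mut=20)
        ds, _ = sd.simulate_dataset(cfg, "p")
        res = run_dce(ds, fraction=1.0)
        m = 12 * 11 // 2
        np.testing.assert_allclose(
            res["p_bonf"], np.minimum(1.0, res["p"] * m), rtol=1e-12
        )

    def test_too_few_samples_is_error(self):
        values = np.random.default_rng(0).normal(size=(5, 7))
        ds = ExpressionDataset(
            "p", [f"G{i}" for i in range(5)], [f"S{i}" for i in range(7)],
            values, ["WT"] * 3 + ["MUT"] * 4,
        )
        with pytest.raises(ValueError, match="more than 3"):
            run_dce(ds, fraction=1.0)


def pair_frame(rows):
    return pd.DataFrame(
        rows,
        columns=["gene_a", "gene_b", "r_wt", "r_mut", "p", "p_adj",
                 "delta_direction", "significant"],
    )


class TestOverlapAndConsistency:
    def test_overlap_canonicalises_pair_order(self):
        a = pair_frame([("X", "Y", 0.9, 0.1, 1e-9, 1e-5, "LOSS", True)])
        b = pair_frame([("Y", "X", 0.8, 0.2, 1e-8, 1e-4, "LOSS", True)])
        out = overlap_pairs(a, b)
        assert len(out) == 1
        assert out.loc[0, "gene_a"] == "X"

    def test_disjoint_pairs_give_empty_overlap(self):
        a = pair_frame([("A", "B", 0.9, 0.1, 1e-9, 1e-5, "LOSS", True)])
        b = pair_frame([("C", "D", 0.8, 0.2, 1e-8, 1e-4, "LOSS", True)])
        assert overlap_pairs(a, b).empty

    def test_shared_planted_pairs_recovered_at_adequate_n(self):
        # both platforms at the large design so the replication has power
        de = [sd.DeGene(i, 2.0, 1) for i in range(10)]
        dce = [sd.DceBlock((2 * j, 2 * j + 1), 0.9, 0.0) for j in range(5)]
        cfg = sd.SimulationConfig(
            seed=13, n_genes=100, n_wt=93, n_mut=415, de_spec=de, dce_spec=dce,
            shared_fraction=1.0, n_wt_second=93, n_mut_second=415,
        )
        (ds_a, ta), (ds_b, tb) = sd.simulate_pair_of_platforms(cfg)
        res_a = run_dce(ds_a, fraction=1.0)
        res_b = run_dce(ds_b, fraction=1.0)
        out = overlap_pairs(res_a, res_b)
        recovered = set(zip(out["gene_a"], out["gene_b"]))
        assert len(recovered & ta.pair_set()) >= 4

    @pytest.mark.parametrize(
        "row_a,row_b,kept",
        [
            # gain in both, corrected-significant in a, nominal in b -> kept
            (("A", "B", 0.1, 0.9, 1e-9, 1e-6, "GAIN", True),
             ("A", "B", 0.2, 0.8, 0.01, 0.3, "GAIN", False), True),
            # opposite directions -> dropped even if both significant
            (("A", "B", 0.1, 0.9, 1e-9, 1e-6, "GAIN", True),
             ("A", "B", 0.9, 0.1, 1e-9, 1e-6, "LOSS", True), False),
            # corrected-significant in a but not nominal in b -> dropped
            (("A", "B", 0.1, 0.9, 1e-9, 1e-6, "GAIN", True),
             ("A", "B", 0.2, 0.8, 0.2, 0.6, "GAIN", False), False),
        ],
    )
    def test_direction_consistency_rules(self, row_a, row_b, kept):
        out = direction_consistent_pairs(
            pair_frame([row_a]), pair_frame([row_b]), strict_alpha=0.05
        )
        assert len(out) == (1 if kept else 0)


class TestGenesFromPairs:
    def test_union_of_members(self):
        assert genes_from_pairs([("A", "B"), ("B", "C")]) == ["A", "B", "C"]

    def test_empty(self):
        assert genes_from_pairs([]) == []
        assert genes_from_pairs(pd.DataFrame(columns=["gene_a", "gene_b"])) == []

    def test_disjoint_pairs_count(self):
        pairs = [(f"A{i}", f"B{i}") for i in range(7)]
        assert len(genes_from_pairs(pairs)) == 14
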