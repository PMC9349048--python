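from fractions import Fraction
from math import comb

import numpy as np
import pandas as pd
import pytest

from cellatlas import composition, synthetic
from cellatlas.core import CompositionTable


def make_table(counts, phenotypes, clusters=None):
    counts = np.asarray(counts)
    clusters = clusters or [f"c{j}" for j in range(counts.shape[1])]
    samples = [f"s{i}" for i in range(counts.shape[0])]
    return CompositionTable(
        pd.DataFrame(counts, index=samples, columns=clusters),
        pd.Series(phenotypes, index=samples),
    )


class TestRelativeAbundance:
    def test_single_phenotype_percentages(self):
        t = make_table([[30, 70]], ["w"])
        rel = composition.relative_abundance(t, "pooled")
        assert rel.loc["w"].tolist() == [30.0, 70.0]

    def test_pooled_equals_per_replicate_for_identical_replicates(self):
        t = make_table([[10, 30], [10, 30]], ["w", "w"])
        pooled = composition.relative_abundance(t, "pooled")
        per_rep = composition.relative_abundance(t, "per_replicate")
        assert np.allclose(pooled.loc["w"], per_rep.iloc[0])
        assert np.allclose(pooled.loc["w"], per_rep.iloc[1])

    def test_rows_sum_to_100(self, small_atlas):
        _, table, _ = small_atlas
        for mode in ("pooled", "per_replicate"):
            rel = composition.relative_abundance(table, mode)
            assert np.allclose(rel.sum(axis=1), 100.0, atol=1e-9)

    def test_pooled_is_weighted_mean_of_per_replicate(self):
        t = make_table([[10, 90], [40, 60], [20, 20]], ["w", "w", "q"])
        pooled = composition.relative_abundance(t, "pooled")
        per_rep = composition.relative_abundance(t, "per_replicate")
        weights = t.counts.sum(axis=1)
        for ph in ("w", "q"):
            idx = t.phenotype == ph
            expected = (per_rep[idx].mul(weights[idx], axis=0)).sum() / weights[idx].sum()
            assert np.allclose(pooled.loc[ph], expected)

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError, match="unknown mode"):
            composition.relative_abundance(make_table([[1, 1]], ["w"]), "bogus")


class TestRadarNormalize:
    def test_means_divided_by_max(self):
        # phenotype means (%) of cluster c0: w=2, q=4, g=1, m=3
        counts = [[2, 98], [4, 96], [1, 99], [3, 97]]
        t = make_table(counts, ["w", "q", "g", "m"])
        prof = composition.radar_normalize(t)
        assert prof.loc["c0", ["w", "q", "g", "m"]].tolist() == [0.5, 1.0, 0.25, 0.75]

    def test_cluster_in_single_phenotype(self):
        t = make_table([[5, 95], [0, 100]], ["w", "q"])
        prof = composition.radar_normalize(t)
        assert prof.loc["c0", "w"] == 1.0
        assert prof.loc["c0", "q"] == 0.0

    def test_invariant_to_global_count_rescale(self):
        counts = np.array([[3, 7], [6, 4]])
        t1 = make_table(counts, ["w", "q"])
        t2 = make_table(counts * 10, ["w", "q"])
        assert np.allclose(
            composition.radar_normalize(t1).to_numpy(),
            composition.radar_normalize(t2).to_numpy(),
        )

    def test_absent_cluster_yields_nan_with_warning(self):
        t = make_table([[5, 0], [7, 0]], ["w", "q"])
        with pytest.warns(UserWarning, match="absent"):
            prof = composition.radar_normalize(t)
        assert prof.loc["c1"].isna().all()


class TestFoldChange:
    def test_two_vs_one_percent(self):
        fc = composition.fold_change(
            pd.Series({"c0": 2.0}), pd.Series({"c0": 1.0})
        )
        assert fc.loc["c0", "fold"] == pytest.approx(2.0)
        assert fc.loc["c0", "direction"] == 1

    def test_equal_abundances(self):
        fc = composition.fold_change(pd.Series({"c0": 3.0}), pd.Series({"c0": 3.0}))
        assert fc.loc["c0", "fold"] == 1.0
        assert fc.loc["c0", "direction"] == 0

    def test_complete_absence_is_infinite_fold(self):
        # mirrors a cluster entirely missing from one group
        fc = composition.fold_change(pd.Series({"c0": 0.0}), pd.Series({"c0": 6.0}))
        assert np.isinf(fc.loc["c0", "fold"])
        assert fc.loc["c0", "direction"] == -1

    def test_both_zero_undefined(self):
        fc = composition.fold_change(pd.Series({"c0": 0.0}), pd.Series({"c0": 0.0}))
        assert np.isnan(fc.loc["c0", "fold"])
        assert fc.loc["c0", "direction"] == 0


def fisher_oracle(a, b, c, d):
    """Exact two-sided Fisher p as a Fraction, by full hypergeometric
    enumeration over the margin-fixed tables."""
    n = a + b + c + d
    r1, c1 = a + b, a + c
    lo, hi = max(0, r1 + c1 - n), min(r1, c1)
    obs = Fraction(comb(c1, a) * comb(n - c1, r1 - a), comb(n, r1))
    total = Fraction(0)
    for k in range(lo, hi + 1):
        p_k = Fraction(comb(c1, k) * comb(n - c1, r1 - k), comb(n, r1))
        if p_k <= obs:
            total += p_k
    return total


class TestFisherExact:
    def test_identical_proportions_p_one(self):
        assert composition.fisher_exact_two_sided([[5, 5], [5, 5]]) == 1.0

    def test_diagonal_table_value(self):
        # (5,0;0,5): 2 of the 252 margin-fixed tables are as extreme
        p = composition.fisher_exact_two_sided([[5, 0], [0, 5]])
        assert p == pytest.approx(2 / 252, abs=1e-15)

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_fraction_oracle_on_random_tables(self, seed):
        rng = np.random.default_rng(seed)
        for _ in range(25):
            a, b, c, d = rng.integers(0, 16, size=4)
            ours = composition.fisher_exact_two_sided([[a, b], [c, d]])
            assert ours == pytest.approx(float(fisher_oracle(a, b, c, d)), abs=1e-12)

    def test_consistent_with_scipy_convention(self):
        from scipy.stats import fisher_exact

        rng = np.random.default_rng(9)
        for _ in range(50):
            a, b, c, d = rng.integers(0, 25, size=4)
            ours = composition.fisher_exact_two_sided([[a, b], [c, d]])
            ref = fisher_exact([[a, b], [c, d]], alternative="two-sided")[1]
            assert ours == pytest.approx(ref, rel=1e-6, abs=1e-12)

    def test_rejects_negative_entries(self):
        with pytest.raises(ValueError):
            composition.fisher_exact_two_sided([[1, -1], [0, 2]])


class TestFisherAbundanceTest:
    def test_planted_shift_flagged(self):
        counts_a = pd.Series({"c0": 500, "c1": 500, "c2": 1000})
        counts_b = pd.Series({"c0": 200, "c1": 800, "c2": 1000})
        res = composition.fisher_abundance_test(counts_a, counts_b)
        assert bool(res.loc["c0", "significant"])
        assert res.loc["c0", "direction"] == 1
        assert not bool(res.loc["c2", "significant"])

    def test_fold_gate_blocks_small_shift(self):
        # significant p but fold ≤ 1.3 must not pass
        counts_a = pd.Series({"c0": 5500, "c1": 4500})
        counts_b = pd.Series({"c0": 4500, "c1": 5500})
        res = composition.fisher_abundance_test(counts_a, counts_b)
        assert res.loc["c0", "p_value"] < 0.001
        assert res.loc["c0", "fold"] < 1.3
        assert not res["significant"].any()

    def test_zero_total_group_rejected(self):
        with pytest.raises(ValueError, match="at least one cell"):
            composition.fisher_abundance_test(
                pd.Series({"c0": 0}), pd.Series({"c0": 5})
            )


class TestDmCompositionTest:
    def test_identical_samples_give_zero_statistics(self):
        t = make_table([[100, 200, 300, 400]] * 6, ["w"] * 3 + ["q"] * 3)
        res = composition.dm_composition_test(t, ("w", "q"))
        stats = res["statistic"].dropna()
        assert (stats.abs() < 1e-3).all()
        assert not res["significant"].any()

    def test_depth_rescaling_creates_no_effect(self):
        # compositional: multiplying one sample's counts through all
        # clusters equally must not produce significant clusters
        rng = np.random.default_rng(11)
        base = rng.multinomial(2000, np.full(8, 0.125), size=8)
        counts = base.copy()
        counts[0] *= 5
        counts[4] *= 3
        t = make_table(counts, ["w"] * 4 + ["q"] * 4)
        res = composition.dm_composition_test(t, ("w", "q"))
        assert not res["significant"].any()

    def test_planted_threefold_shift_recovered(self):
        eff = {"c1": {"q": 3.0}, "c7": {"q": 3.0}}
        cfg = synthetic.AtlasSimConfig(
            n_species=1, n_clusters=10, n_genes=40, n_marker_genes_per_cluster=2,
            cells_per_replicate=2000, phenotypes={"w": 4, "q": 4},
            planted_effects=eff, seed=41,
        )
        _, table, truth = synthetic.simulate_atlas(cfg)
        res = composition.dm_composition_test(table, ("w", "q"))
        flagged = set(res.index[res["significant"]])
        assert truth.affected_clusters <= flagged

    def test_null_flags_rarely(self):
        rng = np.random.default_rng(13)
        flagged = 0
        tested = 0
        for _ in range(10):
            comp = rng.dirichlet(np.full(10, 20.0))
            counts = np.vstack(
                [rng.multinomial(2000, rng.dirichlet(400 * comp)) for _ in range(8)]
            )
            counts += 1  # keep every cluster detected
            t = make_table(counts, ["w"] * 4 + ["q"] * 4)
            res = composition.dm_composition_test(t, ("w", "q"))
            flagged += int(res["significant"].sum())
            tested += int(res["statistic"].notna().sum())
        assert flagged / tested <= 2 * 0.2

    def test_auto_reference_minimises_cv(self):
        rng = np.random.default_rng(15)
        totals = np.array([400, 800, 600, 1000, 500, 700])
        counts = np.empty((6, 4), dtype=int)
        counts[:, 2] = totals // 4  # constant 25% relative abundance
        for i, total in enumerate(totals):
            rest = total - counts[i, 2]
            split = rng.multinomial(rest, [0.2, 0.5, 0.3])
            counts[i, [0, 1, 3]] = split + 1
        t = make_table(counts, ["w"] * 3 + ["q"] * 3)
        assert composition.auto_reference(t) == "c2"

    def test_explicit_reference_must_be_ubiquitous(self):
        counts = [[10, 0, 90], [10, 5, 85], [10, 5, 85], [10, 5, 85]]
        t = make_table(counts, ["w", "w", "q", "q"])
        with pytest.raises(ValueError, match="not detected"):
            composition.dm_composition_test(t, ("w", "q"), reference="c1")

    def test_too_few_replicates_rejected(self):
        t = make_table([[5, 5], [5, 5], [5, 5]], ["w", "q", "q"])
        with pytest.raises(ValueError, match="at least two samples"):
            composition.dm_composition_test(t, ("w", "q"))


class TestConvergenceCall:
    def _calls(self, entries):
        return pd.DataFrame(entries).set_index("cluster")

    def test_consistent_direction_is_convergent(self):
        calls_a = self._calls([{"cluster": "c0", "significant": True, "direction": 1}])
        calls_b = self._calls([{"cluster": "k0", "significant": True, "direction": 1}])
        edges = pd.DataFrame([{"source": "c0", "target": "k0"}])
        assert composition.convergence_call(calls_a, calls_b, edges) == {("c0", "k0")}

    def test_opposite_directions_not_convergent(self):
        calls_a = self._calls([{"cluster": "c0", "significant": True, "direction": 1}])
        calls_b = self._calls([{"cluster": "k0", "significant": True, "direction": -1}])
        edges = pd.DataFrame([{"source": "c0", "target": "k0"}])
        assert composition.convergence_call(calls_a, calls_b, edges) == set()

    def test_nonsignificant_side_not_convergent(self):
        calls_a = self._calls([{"cluster": "c0", "significant": True, "direction": 1}])
        calls_b = self._calls([{"cluster": "k0", "significant": False, "direction": 1}])
        edges = pd.DataFrame([{"source": "c0", "target": "k0"}])
        assert composition.convergence_call(calls_a, calls_b, edges) == set()

    def test_missing_cluster_skipped_with_warning(self):
        calls_a = self._calls([{"cluster": "c0", "significant": True, "direction": 1}])
        calls_b = self._calls([{"cluster": "k0", "significant": True, "direction": 1}])
        edges = pd.DataFrame([{"source": "c9", "target": "k0"}])
        with pytest.warns(UserWarning, match="skipped"):
            assert composition.convergence_call(calls_a, calls_b, edges) == set()


class TestReportFraction:
    def test_paper_style_rounding(self):
        assert composition.report_fraction(35, 43) == 81.4

    def test_zero_and_full(self):
        assert composition.report_fraction(0, 43) == 0.0
        assert composition.report_fraction(43, 43) == 100.0

    def test_half_away_from_zero(self):
        assert composition.report_fraction(1, 16, decimals=0) == 6.0  # 6.25 → 6
        assert composition.report_fraction(1, 8, decimals=1) == 12.5
        assert composition.report_fraction(5, 8, decimals=1) == 62.5
        assert composition.report_fraction(1, 1600, decimals=1) == 0.1  # 0.0625

    def test_integer_rendering(self):
        assert composition.format_fraction(30, 43, decimals=0) == "70%"
        assert composition.format_fraction(35, 43) == "81.4%"

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            composition.report_fraction(1, 0)
        with pytest.raises(ValueError):
            composition.report_fraction(5, 4)
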