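import itertools

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp
from scipy.special import comb

from spotmosaic.io import CountsMatrix, HomologRecord
from spotmosaic.qc import log_normalize
from spotmosaic.registration import (
    GroupExpressionStats,
    group_expression_stats,
    heritability_genesets,
    map_orthologs,
    one_vs_all_t,
    over_representation,
    pseudobulk_aggregate,
    registration_correlation,
    select_markers,
)
from spotmosaic.simulate import SimulationConfig, simulate_nuclei


class TestPseudobulk:
    def test_hand_checked_sums(self):
        dense = np.arange(12).reshape(2, 6)
        counts = CountsMatrix(
            sp.csr_matrix(dense), ["g1", "g2"], [f"b{i}" for i in range(6)]
        )
        groups = ["c1", "c1", "c1", "c2", "c2", "c2"]
        units = ["u1", "u1", "u2", "u1", "u1", "u2"]
        pb, meta = pseudobulk_aggregate(
            counts, groups, units, min_spots=1, min_detected_genes=0, min_samples_per_group=0
        )
        assert pb.shape == (2, 4)
        # (c1,u1) sums columns 0,1; (c1,u2) column 2; etc.
        np.testing.assert_array_equal(pb[:, 0], dense[:, [0, 1]].sum(axis=1))
        np.testing.assert_array_equal(pb[:, 1], dense[:, [2]].sum(axis=1))

    def test_small_samples_dropped(self):
        dense = np.ones((3, 100))
        counts = CountsMatrix(
            sp.csr_matrix(dense), ["g1", "g2", "g3"], [f"b{i}" for i in range(100)]
        )
        groups = ["c1"] * 40 + ["c2"] * 60
        units = ["u"] * 100
        pb, meta = pseudobulk_aggregate(
            counts, groups, units, min_spots=50, min_detected_genes=0, min_samples_per_group=0
        )
        assert meta["group"].tolist() == ["c2"]

    def test_single_group_unit_equals_row_sums(self):
        dense = np.arange(8).reshape(2, 4)
        counts = CountsMatrix(sp.csr_matrix(dense), ["g1", "g2"], list("abcd"))
        pb, _ = pseudobulk_aggregate(
            counts, ["c"] * 4, ["u"] * 4, min_spots=1, min_detected_genes=0,
            min_samples_per_group=0,
        )
        np.testing.assert_array_equal(pb[:, 0], dense.sum(axis=1))


class TestOneVsAllT:
    def test_closed_form(self):
        stats = GroupExpressionStats(
            genes=["g"], groups=["c"],
            mean_in=np.array([[2.0]]), mean_out=np.array([[0.0]]),
            var_in=np.array([[1.0]]), var_out=np.array([[1.0]]),
            n_in=np.array([4]),
        )
        de = one_vs_all_t(stats)
        assert de["t"].iloc[0] == pytest.approx(4.0)  # 2 / sqrt(2/8)
        assert de["logFC"].iloc[0] == 2.0

    def test_equal_means_zero(self):
        stats = GroupExpressionStats(
            genes=["g"], groups=["c"],
            mean_in=np.array([[1.5]]), mean_out=np.array([[1.5]]),
            var_in=np.array([[1.0]]), var_out=np.array([[2.0]]),
            n_in=np.array([5]),
        )
        assert one_vs_all_t(stats)["t"].iloc[0] == 0.0

    def test_matches_direct_formula_oracle(self):
        rng = np.random.default_rng(0)
        expr = rng.normal(size=(10, 30))
        labels = np.array(["a"] * 10 + ["b"] * 12 + ["c"] * 8)
        stats = group_expression_stats(expr, labels, [f"g{i}" for i in range(10)])
        de = one_vs_all_t(stats)
        for grp in "abc":
            sel = labels == grp
            n_c = sel.sum()
            for gi in range(10):
                m_in, m_out = expr[gi, sel].mean(), expr[gi, ~sel].mean()
                v_in = expr[gi, sel].var(ddof=1)
                v_out = expr[gi, ~sel].var(ddof=1)
                expected = (m_in - m_out) / np.sqrt((v_in + v_out) / (2 * n_c))
                got = de[(de.group == grp) & (de.gene == f"g{gi}")]["t"].iloc[0]
                assert got == pytest.approx(expected, abs=1e-12)

    def test_sign_matches_mean_difference(self):
        rng = np.random.default_rng(1)
        expr = rng.normal(size=(20, 40))
        labels = np.array(["a"] * 20 + ["b"] * 20)
        de = one_vs_all_t(group_expression_stats(expr, labels, [f"g{i}" for i in range(20)]))
        assert ((de["t"] == 0) | (np.sign(de["t"]) == np.sign(de["logFC"]))).all()

    def test_welch_differs_for_unbalanced_groups(self):
        rng = np.random.default_rng(2)
        expr = rng.normal(size=(5, 100))
        labels = np.array(["a"] * 10 + ["b"] * 90)
        stats = group_expression_stats(expr, labels, [f"g{i}" for i in range(5)])
        printed = one_vs_all_t(stats, welch=False)
        welch = one_vs_all_t(stats, welch=True)
        assert not np.allclose(printed["t"], welch["t"])


class TestBHProperty:
    def test_step_up_enumeration(self):
        from statsmodels.stats.multitest import multipletests

        p = np.array([0.01, 0.02, 0.03, 0.04])
        fdr = multipletests(p, method="fdr_bh")[1]
        np.testing.assert_allclose(fdr, [0.04, 0.04, 0.04, 0.04])
        # generic step-up oracle on random p-values
        rng = np.random.default_rng(3)
        p = np.sort(rng.uniform(size=12))
        expected = np.minimum.accumulate((p * 12 / np.arange(1, 13))[::-1])[::-1]
        np.testing.assert_allclose(multipletests(p, method="fdr_bh")[1], expected)


class TestSelectMarkers:
    def test_stated_filters_and_order(self):
        de = pd.DataFrame(
            {
                "gene": [f"g{i}" for i in range(1, 6)],
                "group": "c",
                "fdr": [0.01, 0.2, 0.01, 0.04, 0.01],
                "logFC": [2.0, 3.0, -1.0, 1.0, 0.5],
                "t": [1] * 5,
                "p": [0.01] * 5,
            }
        )
        per_group, union = select_markers(de, top_n=250)
        assert per_group["c"] == ["g1", "g4", "g5"]

    def test_top_n_one(self):
        de = pd.DataFrame(
            {"gene": ["a", "b"], "group": "c", "fdr": [0.01, 0.01],
             "logFC": [1.0, 2.0], "t": [1, 1], "p": [0.01, 0.01]}
        )
        per_group, _ = select_markers(de, top_n=1)
        assert per_group["c"] == ["b"]

    def test_nothing_passes(self):
        de = pd.DataFrame(
            {"gene": ["a"], "group": "c", "fdr": [0.5], "logFC": [1.0], "t": [1], "p": [0.5]}
        )
        with pytest.warns(UserWarning, match="no marker"):
            per_group, union = select_markers(de)
        assert per_group["c"] == [] and union == []


class TestMapOrthologs:
    def _homologs(self):
        return [
            HomologRecord("A", "a", "human", "rat"),
            HomologRecord("B", "b", "human", "rat"),
            HomologRecord("C", "c", "human", "rat"),
        ]

    def test_translation_and_report(self):
        lists = {"l1": ["A", "B", "X"], "l2": ["C"]}
        out, report = map_orthologs(lists, self._homologs())
        assert out == {"l1": ["a", "b"], "l2": ["c"]}
        assert report.set_index("list").loc["l1", "n_dropped"] == 1

    def test_five_gene_toy_count(self):
        out, report = map_orthologs({"l": ["A", "B", "C", "Y", "Z"]}, self._homologs())
        assert report["n_mapped"].iloc[0] == 3
        assert report["n_dropped"].iloc[0] == 2


class TestRegistrationCorrelation:
    def test_self_registration_diagonal_one(self):
        rng = np.random.default_rng(4)
        t = pd.DataFrame(
            rng.normal(size=(200, 4)), columns=list("abcd"),
            index=[f"g{i}" for i in range(200)],
        )
        R = registration_correlation(t, t)
        np.testing.assert_allclose(np.diag(R), 1.0, atol=1e-12)

    def test_sign_flip_gives_minus_one(self):
        rng = np.random.default_rng(5)
        t = pd.DataFrame(
            rng.normal(size=(200, 3)), columns=list("abc"),
            index=[f"g{i}" for i in range(200)],
        )
        R = registration_correlation(-t, t)
        np.testing.assert_allclose(np.diag(R), -1.0, atol=1e-12)

    def test_explicit_universe_and_size_guard(self):
        rng = np.random.default_rng(6)
        t = pd.DataFrame(
            rng.normal(size=(50, 2)), columns=list("ab"),
            index=[f"g{i}" for i in range(50)],
        )
        R = registration_correlation(t, t, gene_universe=[f"g{i}" for i in range(10)])
        assert R.shape == (2, 2)
        with pytest.raises(ValueError, match="too small"):
            registration_correlation(t, t, gene_universe=["g1", "g2"])

    def test_split_half_correspondence(self):
        """t-statistic profiles computed on disjoint halves of the same
        nuclei place the true cell-type correspondence on the row argmax."""
        cfg = SimulationConfig(seed=20, n_nuclei=1600, marker_fold_change=4.0)
        counts, labels, _ = simulate_nuclei(cfg)
        norm = log_normalize(counts)
        expr = np.asarray(norm.matrix.todense())
        ct = labels.loc[norm.barcodes, "cell_type"].to_numpy()
        rng = np.random.default_rng(0)
        half = rng.random(expr.shape[1]) < 0.5
        t_tables = []
        for sel in (half, ~half):
            stats = group_expression_stats(expr[:, sel], ct[sel], norm.genes)
            de = one_vs_all_t(stats)
            t_tables.append(de.pivot(index="gene", columns="group", values="t"))
        R = registration_correlation(t_tables[0], t_tables[1])
        for grp in R.index:
            assert R.loc[grp].idxmax() == grp


class TestOverRepresentation:
    def test_worked_table_and_odds_ratio(self):
        universe = [f"g{i}" for i in range(100)]
        degs = {"c": set(universe[:20])}
        gene_list = universe[10:40]  # overlap 10
        out = over_representation(gene_list, degs, universe)
        row = out.iloc[0]
        assert (row.a, row.b, row.c, row.d) == (10, 20, 10, 60)
        assert row.odds_ratio == pytest.approx(3.0)
        # p from hypergeometric tail enumeration
        N, K, n = 100, 20, 30
        p_oracle = sum(
            comb(K, k, exact=True) * comb(N - K, n - k, exact=True)
            for k in range(10, 21)
        ) / comb(N, n, exact=True)
        assert row.p == pytest.approx(p_oracle, rel=1e-10)

    def test_exact_3113_table(self):
        universe = [f"g{i}" for i in range(8)]
        degs = {"c": set(universe[:4])}
        gene_list = universe[1:4] + [universe[7]]  # a=3, b=1, c=1, d=3
        out = over_representation(gene_list, degs, universe, min_list=1)
        assert out["p"].iloc[0] == pytest.approx(17 / 70, rel=1e-12)

    def test_disjoint_list_not_enriched(self):
        universe = [f"g{i}" for i in range(100)]
        degs = {"c": set(universe[:20])}
        out = over_representation(universe[20:60], degs, universe)
        assert out["odds_ratio"].iloc[0] <= 1.0
        assert out["p"].iloc[0] >= 0.5

    def test_short_list_skipped(self):
        universe = [f"g{i}" for i in range(100)]
        with pytest.warns(UserWarning, match="skipped"):
            out = over_representation(universe[:5], {"c": set(universe[:20])}, universe)
        assert out.empty

    def test_fisher_matches_enumeration_all_small_tables(self):
        # exhaustive check against the hypergeometric tail for all tables N <= 30
        from scipy.stats import fisher_exact

        for N in (8, 12, 30):
            for K in range(1, N):
                for n in range(1, N):
                    a_min, a_max = max(0, K + n - N), min(K, n)
                    for a in range(a_min, a_max + 1):
                        table = [[a, n - a], [K - a, N - K - n + a]]
                        p = fisher_exact(table, alternative="greater")[1]
                        oracle = sum(
                            comb(K, k, exact=True) * comb(N - K, n - k, exact=True)
                            for k in range(a, a_max + 1)
                        ) / comb(N, n, exact=True)
                        assert p == pytest.approx(oracle, rel=1e-9)


class TestHeritabilityGenesets:
    def _coords(self):
        return pd.DataFrame(
            {
                "gene": [f"g{i}" for i in range(10)],
                "chrom": ["chr1"] * 8 + ["chrX", "chr2"],
                "start": [1_000_001 + i * 10_000 for i in range(10)],
                "end": [1_005_000 + i * 10_000 for i in range(10)],
            }
        )

    def test_top_fraction_ceiling(self):
        pb = np.ones((10, 1))
        pb[3, 0] = 100.0
        out, _ = heritability_genesets(
            pb, [f"g{i}" for i in range(10)], ["c"], self._coords(), top_fraction=0.10
        )
        assert [iv.name for iv in out["c"]] == ["g3"]

    def test_flank_arithmetic(self):
        coords = pd.DataFrame(
            {"gene": ["G"], "chrom": ["chr1"], "start": [1_000_001], "end": [1_005_000]}
        )
        pb = np.array([[5.0]])
        out, _ = heritability_genesets(pb, ["G"], ["c"], coords, top_fraction=1.0)
        iv = out["c"][0]
        assert (iv.start, iv.end) == (900_000, 1_105_000)

    def test_start_clipped_at_zero(self):
        coords = pd.DataFrame(
            {"gene": ["G"], "chrom": ["chr1"], "start": [50_001], "end": [55_000]}
        )
        out, _ = heritability_genesets(np.array([[1.0]]), ["G"], ["c"], coords, top_fraction=1.0)
        assert out["c"][0].start == 0

    def test_excluded_chromosomes_and_missing_coords(self):
        pb = np.ones((10, 1))
        pb[8, 0] = 100.0  # top gene on chrX -> excluded
        coords = self._coords().iloc[:-1]  # g9 has no coordinates
        out, report = heritability_genesets(
            pb, [f"g{i}" for i in range(10)], ["c"], coords, top_fraction=1.0
        )
        assert report["n_excluded_chrom"].iloc[0] == 1
        assert report["n_missing_coords"].iloc[0] == 1
        assert len(out["c"]) == 8
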