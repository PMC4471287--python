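import numpy as np
import pandas as pd
import pytest
from scipy import stats

from _oracles import clusters_by_pairwise_linkage
from convergeomics.methylation import (
    CpGCluster,
    GeneModel,
    call_clusters,
    cluster_overlap,
    cluster_state_correlation,
    common_positions,
    filter_sites,
    map_clusters_to_genes,
    read_bismark_coverage,
    significant_clusters,
)
from convergeomics.methylation import test_cluster as run_cluster_test
from convergeomics.methylation import test_clusters as run_cluster_table
from convergeomics.simulate import SimConfig, simulate_methylome


def sites(rows):
    """rows: (chrom, pos, coverage, n_meth)"""
    df = pd.DataFrame(rows, columns=["chrom", "pos", "coverage", "n_meth"])
    df["freq"] = df["n_meth"] / df["coverage"]
    return df


class TestBismarkIO:
    def test_one_based_conversion(self, tmp_path):
        p = tmp_path / "s.cov"
        p.write_text("chr1\t100\t100\t50.0\t5\t5\nchr1\t150\t150\t100.0\t8\t0\n")
        df = read_bismark_coverage(p)
        assert df["pos"].tolist() == [99, 149]
        assert df["coverage"].tolist() == [10, 8]
        assert df["freq"].tolist() == [0.5, 1.0]

    def test_malformed_file_names_path_and_dialect(self, tmp_path):
        p = tmp_path / "bad.cov"
        p.write_text("chr1\t100\toops\n")
        with pytest.raises(ValueError, match="bad.cov"):
            read_bismark_coverage(p)


class TestFilterSites:
    def test_coverage_floor_is_strict(self):
        s = sites([("chr1", 10, 3, 1), ("chr1", 20, 6, 3), ("chr1", 30, 10, 5)])
        out = filter_sites({"s": s}, min_coverage_exclusive=5, top_coverage_fraction=0)
        assert out["s"]["coverage"].tolist() == [6, 10]

    @pytest.mark.parametrize("n_kept,n_removed", [(1000, 1), (999, 1), (2000, 2), (2001, 3)])
    def test_ceiling_rule(self, n_kept, n_removed):
        rows = [("chr1", 10 * i, 6 + (i % 7), 3) for i in range(n_kept)]
        out = filter_sites({"s": sites(rows)}, top_coverage_fraction=0.001)
        assert len(out["s"]) == n_kept - n_removed

    def test_top_removal_targets_highest_coverage(self):
        rows = [("chr1", 10 * i, 6, 3) for i in range(999)] + [("chr1", 99990, 500, 10)]
        out = filter_sites({"s": sites(rows)})
        assert 99990 not in set(out["s"]["pos"])

    def test_ties_broken_by_descending_position(self):
        # all coverages equal: the removed site is the right-most one
        rows = [("chr1", 10 * i, 6, 3) for i in range(1000)]
        out = filter_sites({"s": sites(rows)})
        assert 9990 not in set(out["s"]["pos"])
        assert len(out["s"]) == 999

    def test_blacklist_applied_to_all_samples(self):
        s1 = sites([("chr1", 10, 8, 4), ("chr1", 20, 8, 4)])
        s2 = sites([("chr1", 10, 9, 4), ("chr1", 20, 9, 4)])
        out = filter_sites(
            {"a": s1, "b": s2}, top_coverage_fraction=0, blacklist={("chr1", 10)}
        )
        assert set(out["a"]["pos"]) == {20}
        assert set(out["b"]["pos"]) == {20}

    def test_toy_fixture_kept_counts(self, toy_coverage_path):
        df = read_bismark_coverage(toy_coverage_path)
        assert len(df) == 1000
        out = filter_sites({"s": df})["s"]
        # 1 site fails the >5x floor, then 1 of the 999 kept is removed
        assert len(out) == 998
        assert out["coverage"].max() < 300  # the unique max went out


class TestCallClusters:
    def test_spec_examples(self):
        assert call_clusters({"chr1": [100]}) == []
        cl = call_clusters({"chr1": [100, 130, 175, 300, 340]})
        assert [c.positions for c in cl] == [(100, 130, 175), (300, 340)]
        assert call_clusters({"chr1": [100, 151]}) == []  # gap 51 > 50
        assert len(call_clusters({"chr1": [100, 150]})) == 1  # gap 50 joins

    def test_span_covers_sites(self):
        (c,) = call_clusters({"chr1": [100, 130]})
        assert (c.start, c.end) == (100, 131)

    def test_unsorted_raises(self):
        with pytest.raises(ValueError):
            call_clusters({"chr1": [100, 90]})

    def test_matches_pairwise_linkage_oracle(self):
        rng = np.random.default_rng(0)
        for trial in range(60):
            if trial % 2 == 0:
                pos = np.unique(rng.integers(0, 3000, size=60))
            else:  # clumped placement
                centers = rng.integers(0, 5000, size=8)
                pos = np.unique(
                    np.concatenate([c + rng.integers(0, 120, 10) for c in centers])
                )
            ours = call_clusters({"chr1": pos.tolist()})
            ref = clusters_by_pairwise_linkage(pos.tolist())
            assert [c.positions for c in ours] == ref

    def test_partition_property(self):
        rng = np.random.default_rng(1)
        pos = np.unique(rng.integers(0, 2000, size=80))
        clusters = call_clusters({"chr1": pos.tolist()})
        covered = [p for c in clusters for p in c.positions]
        assert len(covered) == len(set(covered))  # each site in at most one

    def test_commutes_with_chromosome_partition(self):
        rng = np.random.default_rng(2)
        both = {
            "chr1": np.unique(rng.integers(0, 2000, 70)).tolist(),
            "chr2": np.unique(rng.integers(0, 2000, 70)).tolist(),
        }
        whole = call_clusters(both)
        parts = call_clusters({"chr1": both["chr1"]}) + call_clusters(
            {"chr2": both["chr2"]}
        )
        assert [(c.chrom, c.positions) for c in whole] == sorted(
            (c.chrom, c.positions) for c in parts
        )


class TestClusterTesting:
    def make_groups(self, freq_a, freq_b, positions=(100, 120)):
        samples = {}
        for i, f in enumerate(freq_a):
            samples[f"a{i}"] = sites(
                [("chr1", p, 10, int(round(10 * f))) for p in positions]
            )
        for i, f in enumerate(freq_b):
            samples[f"b{i}"] = sites(
                [("chr1", p, 10, int(round(10 * f))) for p in positions]
            )
        cluster = CpGCluster("chr1", positions[0], positions[-1] + 1, tuple(positions))
        a = [k for k in samples if k.startswith("a")]
        b = [k for k in samples if k.startswith("b")]
        return cluster, samples, a, b

    def test_separated_groups(self):
        cluster, samples, a, b = self.make_groups(
            [0.8, 0.7, 0.9, 0.8], [0.2, 0.3, 0.1, 0.2]
        )
        res = run_cluster_test(cluster, samples, a, b)
        assert res.p < 1e-3
        assert res.delta == pytest.approx(0.6, abs=0.05)

    def test_identical_groups(self):
        cluster, samples, a, b = self.make_groups([0.5] * 3, [0.5] * 3)
        res = run_cluster_test(cluster, samples, a, b)
        assert res.t == 0.0 and res.p == 1.0

    def test_insufficient_observations_skipped(self):
        cluster, samples, a, b = self.make_groups([0.5, 0.6], [0.5])
        assert run_cluster_test(cluster, samples, a, b[:1]) is None

    def test_vectorised_matches_scalar(self):
        cfg = SimConfig(seed=41, n_cpg_sites=200, frac_de=0.3)
        samples, _, _ = simulate_methylome(cfg)
        names_a = [s for s in samples if s.startswith("kd")]
        names_b = [s for s in samples if s.startswith("ntp")]
        uni = common_positions(samples, names_a + names_b)
        clusters = call_clusters(uni)
        table = run_cluster_table(samples, clusters, names_a, names_b,
                              positions_by_chrom=uni)
        for i in (0, len(clusters) // 2, len(clusters) - 1):
            ref = run_cluster_test(clusters[i], samples, names_a, names_b)
            row = table[table["cluster_id"] == clusters[i].id].iloc[0]
            assert row["t"] == pytest.approx(ref.t, rel=1e-9)
            assert row["p"] == pytest.approx(ref.p, rel=1e-9)
            assert row["delta"] == pytest.approx(ref.delta, rel=1e-9)


class TestSignificantClusters:
    def test_bonferroni_boundary(self):
        res = pd.DataFrame(
            {"cluster_id": [f"c{i}" for i in range(100)], "p": [1.0] * 100}
        )
        res.loc[0, "p"] = 4e-4
        res.loc[1, "p"] = 6e-4
        out = significant_clusters(res, method="bonferroni", alpha=0.05)
        assert bool(out.loc[0, "genome_wide_significant"])
        assert not out.loc[1, "genome_wide_significant"]

    def test_all_unit_p_flags_nothing(self):
        res = pd.DataFrame({"cluster_id": ["a", "b"], "p": [1.0, 1.0]})
        for method in ("bonferroni", "bh"):
            out = significant_clusters(res, method=method)
            assert not out["genome_wide_significant"].any()

    def test_bh_mode_adds_q(self):
        res = pd.DataFrame(
            {"cluster_id": ["a", "b", "c"], "p": [0.001, 0.02, 0.9]}
        )
        out = significant_clusters(res, method="bh", alpha=0.05)
        assert "q" in out.columns
        assert bool(out.loc[0, "genome_wide_significant"])


class TestClusterOverlap:
    def test_identical_sets_fully_overlap(self):
        cl = [("chr1", 100, 160), ("chr1", 400, 450), ("chr2", 10, 90)]
        res = cluster_overlap(cl, cl, 50)
        assert res.intersection_size == 3

    def test_disjoint_intervals(self):
        a = [("chr1", 100, 160)]
        b = [("chr1", 160, 200)]  # half-open: no shared bp
        res = cluster_overlap(a, b, 50)
        assert res.intersection_size == 0 and res.p_hyper == 1.0

    def test_one_bp_overlap_counts(self):
        a = [("chr1", 100, 161)]
        b = [("chr1", 160, 200)]
        assert cluster_overlap(a, b, 50).intersection_size == 1

    def test_exact_tail_matches_reference(self):
        a = [("chr1", i * 1000, i * 1000 + 50) for i in range(10)]
        b = [("chr1", i * 1000, i * 1000 + 50) for i in range(5)] + [
            ("chr2", i * 1000, i * 1000 + 50) for i in range(5)
        ]
        res = cluster_overlap(a, b, 100)
        expected = stats.hypergeom.sf(4, 100, 10, 10)  # 6.72e-4 by enumeration
        assert res.p_hyper == pytest.approx(expected, rel=1e-9)


class TestGeneMapping:
    def test_plus_strand_window(self):
        gene = GeneModel("chr1", 10_000, 12_000, "+", "G1")
        assert map_clusters_to_genes([("chr1", 4900, 4960)], [gene]) == []
        assert map_clusters_to_genes([("chr1", 5000, 5050)], [gene]) == [
            ("chr1:5000-5050", "G1")
        ]

    def test_minus_strand_window(self):
        gene = GeneModel("chr1", 10_000, 12_000, "-", "G1")
        assert map_clusters_to_genes([("chr1", 16_900, 16_950)], [gene]) == [
            ("chr1:16900-16950", "G1")
        ]
        assert map_clusters_to_genes([("chr1", 17_000, 17_050)], [gene]) == []

    def test_cluster_can_link_multiple_genes(self):
        genes = [
            GeneModel("chr1", 10_000, 12_000, "+", "G1"),
            GeneModel("chr1", 11_000, 13_000, "+", "G2"),
        ]
        links = map_clusters_to_genes([("chr1", 11_500, 11_560)], genes)
        assert {g for _, g in links} == {"G1", "G2"}


class TestStateCorrelation:
    def test_reference_identity_orders_correlations(self):
        rng = np.random.default_rng(3)
        kd = rng.uniform(0.2, 0.8, 20)
        ref_a = rng.uniform(0.2, 0.8, 20)
        r_a, r_b = cluster_state_correlation(kd, ref_a, kd)
        assert r_b == pytest.approx(1.0)
        assert r_b > r_a

    def test_constant_kd_flagged(self):
        r_a, r_b = cluster_state_correlation([0.5] * 5, [0.1, 0.2, 0.3, 0.4, 0.5],
                                             [0.5, 0.4, 0.3, 0.2, 0.1])
        assert r_a is None and r_b is None

    def test_too_few_clusters_flagged(self):
        r_a, r_b = cluster_state_correlation([0.1, 0.9], [0.1, 0.9], [0.9, 0.1])
        assert r_a is None and r_b is None

    def test_mismatched_lengths_raise(self):
        with pytest.raises(ValueError):
            cluster_state_correlation([0.1], [0.1, 0.2], [0.1, 0.2])
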