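"""Bin matrices, TF-IDF, reduction/clustering, markers, overlap coefficients."""

import itertools

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp
from sklearn.metrics import adjusted_rand_score

from ptjoint import clustering
from ptjoint.io import CountMatrix, GeneRecord
from .conftest import make_fragments


class TestBinMatrix:
    def test_midpoint_assignment(self):
        # fragment (4998, 5004): midpoint 5001 -> bin chr1:5000-10000
        frags = make_fragments([("chr1", 4998, 5004, "A")], deduplicated=True)
        bins = clustering.build_bin_matrix(frags, bin_size=5000)
        col = bins.values.toarray()[0].argmax()
        assert bins.col_labels[col] == "chr1:5000-10000"

    def test_row_sums_equal_fragment_counts(self, small_sim):
        from ptjoint.io import FragmentSet, deduplicate

        pooled = pd.concat(
            [fs.data for fs in small_sim.fragments["active"].values()],
            ignore_index=True,
        )
        frags = deduplicate(FragmentSet(pooled, dict(small_sim.config.chrom_sizes)))
        bins = clustering.build_bin_matrix(frags)
        row_sums = np.asarray(bins.values.sum(axis=1)).ravel()
        counts = frags.data["barcode"].value_counts()
        for bc, total in zip(bins.row_labels, row_sums):
            assert counts[bc] == total

    def test_empty_input(self):
        bins = clustering.build_bin_matrix(
            make_fragments([], deduplicated=True)
        )
        assert bins.shape[0] == 0


class TestTfidf:
    def make(self, arr):
        return CountMatrix(
            sp.csr_matrix(np.asarray(arr)),
            [f"c{i}" for i in range(len(arr))],
            [f"b{j}" for j in range(len(arr[0]))],
        )

    def test_depth_invariance_exact(self):
        a = self.make([[1, 2, 0], [3, 0, 1]])
        b = self.make([[5, 10, 0], [3, 0, 1]])  # first cell scaled by 5
        np.testing.assert_allclose(clustering.tfidf(a), clustering.tfidf(b))

    def test_two_by_two_hand_computed(self):
        # TF = [[.5,.5],[1,0]]; IDF = [2/3, 2/2]; out = log1p(1e4*TF*IDF)
        mat = self.make([[1, 1], [2, 0]])
        expected = np.log1p(
            1e4
            * np.array([[0.5 * 2 / 3, 0.5 * 1.0], [1.0 * 2 / 3, 0.0]])
        )
        np.testing.assert_allclose(clustering.tfidf(mat), expected)

    def test_rare_bin_upweighted(self):
        mat = self.make([[1, 1], [1, 0], [1, 0]])
        out = clustering.tfidf(mat)
        assert out[0, 1] > out[0, 0]

    def test_zero_cell_rejected(self):
        with pytest.raises(ValueError, match="filter"):
            clustering.tfidf(self.make([[0, 0], [1, 2]]))


class TestSelectTopBins:
    def make(self, totals):
        return CountMatrix(
            sp.csr_matrix(np.asarray([totals])),
            ["c0"],
            [f"b{j}" for j in range(len(totals))],
        )

    def test_fraction_count(self):
        mat = self.make(list(range(100)))
        assert len(clustering.select_top_bins(mat, 0.85)) == 85

    def test_identity_at_one(self):
        mat = self.make([5, 1, 3])
        assert list(clustering.select_top_bins(mat, 1.0)) == [0, 1, 2]

    def test_ties_break_by_genomic_order(self):
        mat = self.make([2, 2, 2, 2])
        assert list(clustering.select_top_bins(mat, 0.5)) == [0, 1]


class TestReduceCluster:
    def test_rank_two_matrix_captured(self, rng):
        u = rng.normal(size=(80, 2))
        v = rng.normal(size=(2, 30))
        mat = u @ v
        emb = clustering.reduce_dimensions(mat, n_components=2, seed=0)
        recon_var = (emb.scores**2).sum()
        total_var = (mat**2).sum()
        assert recon_var / total_var > 0.99

    def test_seeded_determinism(self, rng):
        mat = rng.normal(size=(50, 20))
        a = clustering.reduce_dimensions(mat, 5, seed=3)
        b = clustering.reduce_dimensions(mat, 5, seed=3)
        np.testing.assert_array_equal(a.scores, b.scores)

    def test_rank_deficiency_warns_and_reduces(self, rng, caplog):
        mat = rng.normal(size=(6, 4))
        emb = clustering.reduce_dimensions(mat, n_components=35, seed=0)
        assert emb.scores.shape[1] <= 3

    def test_blobs_recovered_exactly(self, rng):
        centers = np.array([[0, 0], [20, 0], [0, 20]])
        labels_true = np.repeat([0, 1, 2], 50)
        pts = centers[labels_true] + rng.normal(scale=0.5, size=(150, 2))
        emb = clustering.Embedding(pts, [f"c{i}" for i in range(150)], "raw")
        labels = clustering.cluster_cells(emb, k=3, seed=0)
        pred = [labels[f"c{i}"] for i in range(150)]
        assert adjusted_rand_score(labels_true, pred) == 1.0

    def test_k_one_single_label(self, rng):
        emb = clustering.Embedding(
            rng.normal(size=(10, 2)), [f"c{i}" for i in range(10)], "raw"
        )
        assert set(clustering.cluster_cells(emb, k=1).values()) == {"c0"}

    def test_k_exceeds_cells(self, rng):
        emb = clustering.Embedding(
            rng.normal(size=(3, 2)), ["a", "b", "c"], "raw"
        )
        with pytest.raises(ValueError):
            clustering.cluster_cells(emb, k=5)


class TestRnaNormalization:
    def test_all_genes_kept_when_n_top_large(self, rng):
        counts = CountMatrix(
            sp.csr_matrix(rng.poisson(5, size=(20, 10)) + 1),
            [f"c{i}" for i in range(20)],
            [f"g{j}" for j in range(10)],
        )
        _, variable = clustering.normalize_select_rna(counts, n_top=100)
        assert len(variable) == 10

    def test_depth_invariance(self):
        arr = np.array([[1, 2, 3], [2, 4, 6]])
        counts = CountMatrix(sp.csr_matrix(arr), ["a", "b"], ["g1", "g2", "g3"])
        norm, _ = clustering.normalize_select_rna(counts)
        np.testing.assert_allclose(norm[0], norm[1])

    def test_markers_rank_variable(self, small_sim):
        norm, variable = clustering.normalize_select_rna(small_sim.rna, n_top=8)
        planted_markers = {
            g for genes in small_sim.truth.markers.values() for g in genes
        }
        recall = len(planted_markers & set(variable)) / len(planted_markers)
        assert recall >= 0.5  # markers are among the most dispersed genes


class TestMarkerGenes:
    def test_planted_markers_recovered(self, small_sim):
        truth = small_sim.truth
        norm, _ = clustering.normalize_select_rna(small_sim.rna)
        labels = truth.cells["cell_type"].to_dict()
        table = clustering.marker_genes(
            norm, small_sim.rna.col_labels, labels, small_sim.rna.row_labels
        )
        for cell_type, markers in truth.markers.items():
            top = set(
                table.loc[table["cluster"] == cell_type].head(
                    len(markers) + 2
                )["gene"]
            )
            hits = len(set(markers) & top)
            assert hits / len(markers) >= 0.5

    def test_identical_distribution_excluded(self, rng):
        norm = np.tile(rng.normal(size=(1, 5)), (20, 1))
        labels = {f"c{i}": "a" if i < 10 else "b" for i in range(20)}
        table = clustering.marker_genes(
            norm, [f"g{j}" for j in range(5)], labels, list(labels)
        )
        assert table.empty

    def test_threshold_zero_is_superset(self, rng):
        norm = rng.normal(loc=1.0, scale=0.3, size=(30, 8)) ** 2
        labels = {f"c{i}": "a" if i < 15 else "b" for i in range(30)}
        ids = [f"g{j}" for j in range(8)]
        strict = clustering.marker_genes(norm, ids, labels, list(labels), 0.25)
        loose = clustering.marker_genes(norm, ids, labels, list(labels), 0.0)
        strict_pairs = set(zip(strict["cluster"], strict["gene"]))
        loose_pairs = set(zip(loose["cluster"], loose["gene"]))
        assert strict_pairs <= loose_pairs

    def test_single_cluster_rejected(self, rng):
        norm = rng.normal(size=(10, 3))
        labels = {f"c{i}": "only" for i in range(10)}
        with pytest.raises(ValueError):
            clustering.marker_genes(norm, ["g1", "g2", "g3"], labels, list(labels))


class TestGeneActivity:
    GENES = [GeneRecord("g1", "chr1", "+", 10_000, 20_000)]

    def count(self, rows):
        frags = make_fragments(rows, deduplicated=True)
        return clustering.gene_activity(frags, self.GENES).values.toarray()

    def test_body_fragment_counted(self):
        assert self.count([("chr1", 15_000, 15_200, "A")])[0, 0] == 1

    def test_promoter_window_counted(self):
        # 1.5 kb upstream of the + strand TSS
        assert self.count([("chr1", 8_400, 8_600, "A")])[0, 0] == 1

    def test_far_upstream_not_counted(self):
        assert self.count([("chr1", 6_900, 7_000, "A")])[0, 0] == 0

    def test_minus_strand_mirrored(self):
        genes = [GeneRecord("gm", "chr1", "-", 10_000, 20_000)]
        frags = make_fragments([("chr1", 21_000, 21_200, "A")], deduplicated=True)
        out = clustering.gene_activity(frags, genes).values.toarray()
        assert out[0, 0] == 1


class TestAnnotateEpigenome:
    def test_plurality(self):
        epi = {f"c{i}": "e1" for i in range(10)}
        rna = {f"c{i}": "X" if i < 6 else "Y" for i in range(10)}
        assert clustering.annotate_epigenome_clusters(epi, rna) == {"e1": "X"}

    def test_tie_breaks_to_larger_cluster(self):
        epi = {f"c{i}": "e1" for i in range(4)}
        rna = {"c0": "X", "c1": "X", "c2": "Y", "c3": "Y"}
        # X is globally bigger
        rna.update({f"x{i}": "X" for i in range(5)})
        assert clustering.annotate_epigenome_clusters(epi, rna)["e1"] == "X"

    def test_no_overlap_unassigned(self):
        epi = {"a": "e1"}
        rna = {"b": "X"}
        assert clustering.annotate_epigenome_clusters(epi, rna)["e1"] == "unassigned"


def brute_force_o_i(a, b):
    """Exhaustive contingency enumeration for the two-modality overlap."""
    shared = sorted(set(a) & set(b))
    out = {}
    for ai in sorted(set(a[x] for x in shared)):
        cells = [x for x in shared if a[x] == ai]
        best = 0.0
        for bx in set(b[x] for x in shared):
            inter = sum(1 for x in cells if b[x] == bx)
            best = max(best, inter / len(cells))
        out[ai] = best
    return out


def brute_force_o_ij(a, b, c):
    out = {}
    for ai in sorted(set(a.values())):
        a_cells = [x for x in a if a[x] == ai and x in c]
        for bj in sorted(set(b.values())):
            b_cells = [x for x in b if b[x] == bj and x in c]
            best = 0.0
            for ck in set(c.values()):
                fa = sum(1 for x in a_cells if c[x] == ck) / len(a_cells)
                fb = sum(1 for x in b_cells if c[x] == ck) / len(b_cells)
                best = max(best, min(fa, fb))
            out[(ai, bj)] = best
    return out


class TestOverlapCoefficients:
    def test_identical_partitions_all_one(self):
        labels = {f"c{i}": f"k{i % 4}" for i in range(40)}
        assert (clustering.overlap_two_modality(labels, labels) == 1.0).all()

    def test_six_four_split(self):
        a = {f"c{i}": "A1" for i in range(10)}
        b = {f"c{i}": "B1" if i < 6 else "B2" for i in range(10)}
        assert clustering.overlap_two_modality(a, b)["A1"] == 0.6

    def test_single_epigenome_cluster_degenerate(self):
        a = {f"c{i}": f"k{i % 3}" for i in range(30)}
        b = {f"c{i}": "only" for i in range(30)}
        assert (clustering.overlap_two_modality(a, b) == 1.0).all()

    def test_matches_brute_force_on_random_partitions(self, rng):
        for _ in range(100):
            n = 200
            a = {f"c{i}": f"a{rng.integers(0, 6)}" for i in range(n)}
            b = {f"c{i}": f"b{rng.integers(0, 5)}" for i in range(n)}
            ours = clustering.overlap_two_modality(a, b)
            expected = brute_force_o_i(a, b)
            for key, val in expected.items():
                assert ours[key] == val

    def test_integration_full_agreement(self):
        a = {f"q{i}": "A1" for i in range(10)}
        b = {f"r{i}": "B1" for i in range(10)}
        c = {**{f"q{i}": "C1" for i in range(10)}, **{f"r{i}": "C1" for i in range(10)}}
        out = clustering.overlap_integration(a, b, c)
        assert out.loc["A1", "B1"] == 1.0

    def test_integration_disjoint_coembedding(self):
        a = {f"q{i}": "A1" for i in range(5)}
        b = {f"r{i}": "B1" for i in range(5)}
        c = {**{f"q{i}": "C1" for i in range(5)}, **{f"r{i}": "C2" for i in range(5)}}
        assert clustering.overlap_integration(a, b, c).loc["A1", "B1"] == 0.0

    def test_integration_partial(self):
        a = {f"q{i}": "A1" for i in range(10)}
        b = {f"r{i}": "B1" for i in range(10)}
        c = {f"q{i}": "C1" if i < 5 else "C2" for i in range(10)}
        c.update({f"r{i}": "C1" if i < 8 else "C3" for i in range(10)})
        assert clustering.overlap_integration(a, b, c).loc["A1", "B1"] == 0.5

    def test_integration_matches_brute_force(self, rng):
        for _ in range(20):
            a = {f"q{i}": f"a{rng.integers(0, 3)}" for i in range(40)}
            b = {f"r{i}": f"b{rng.integers(0, 3)}" for i in range(40)}
            c = {x: f"c{rng.integers(0, 4)}" for x in list(a) + list(b)}
            ours = clustering.overlap_integration(a, b, c)
            expected = brute_force_o_ij(a, b, c)
            for (ai, bj), val in expected.items():
                assert ours.loc[ai, bj] == pytest.approx(val)

    def test_integration_rejects_shared_barcodes(self):
        with pytest.raises(ValueError):
            clustering.overlap_integration({"x": "A"}, {"x": "B"}, {"x": "C"})
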