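"""Coverage smoothing, peak calling/merging, RPKM, profiles, saturation."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from ptjoint import signal
from ptjoint.io import FragmentSet, GenomicInterval
from .conftest import make_fragments

MB = {"chr1": 1_000_000}


def uniform_background(rng, n=10_000, chrom_len=1_000_000, barcode="A"):
    starts = rng.integers(0, chrom_len - 200, size=n)
    return [("chr1", int(s), int(s) + 150, barcode) for s in starts]


class TestPseudobulk:
    def test_partition_and_identity(self):
        frags = make_fragments(
            [("chr1", 0, 100, "a"), ("chr1", 200, 300, "b")], deduplicated=True
        )
        groups = signal.pseudobulk(frags, {"a": "g1", "b": "g2"})
        assert len(groups["g1"]) + len(groups["g2"]) == 2
        single = signal.pseudobulk(frags, {"a": "all", "b": "all"})
        assert len(single["all"]) == 2

    def test_unlabeled_dropped(self):
        frags = make_fragments(
            [("chr1", 0, 100, "a"), ("chr1", 200, 300, "x")], deduplicated=True
        )
        groups = signal.pseudobulk(frags, {"a": "g1"})
        assert len(groups["g1"]) == 1


class TestInsertionCoverage:
    def test_support_matches_shift_extension_arithmetic(self):
        # fragment (1000, 1200): insertions at 1000 and 1199, windows
        # [925,1075) and [1124,1274)
        frags = make_fragments([("chr1", 1000, 1200, "A")], deduplicated=True)
        track = signal.insertion_coverage(frags, extsize=150, shift=-75, step=1)
        cov = track.values["chr1"]
        support = np.where(cov > 0)[0]
        assert support.min() == 925
        assert support.max() == 1273
        assert set(np.where(np.diff(support) > 1)[0]) == {1075 - 925 - 1}

    def test_mass_conservation(self, rng):
        frags = make_fragments(
            [
                ("chr1", int(s), int(s) + 100, "A")
                for s in rng.integers(500, 90_000, size=200)
            ],
            deduplicated=True,
        )
        track = signal.insertion_coverage(frags, extsize=150, step=10)
        assert track.total_mass == pytest.approx(2 * 200 * 150 / 10, rel=1e-6)

    def test_zero_fragments_zero_track(self):
        frags = make_fragments([], deduplicated=True)
        track = signal.insertion_coverage(frags)
        assert track.total_mass == 0.0

    def test_linearity(self):
        rows = [("chr1", 100 + 30 * i, 300 + 30 * i, "A") for i in range(20)]
        t1 = signal.insertion_coverage(make_fragments(rows, deduplicated=True))
        t2 = signal.insertion_coverage(
            make_fragments(rows * 2, deduplicated=True)
        )
        np.testing.assert_allclose(2 * t1.values["chr1"], t2.values["chr1"])


class TestCallPeaks:
    def test_flat_background_no_peaks(self):
        # deterministic constant-rate track: nothing exceeds its own mean
        track = signal.CoverageTrack(
            step=10,
            values={"chr1": np.full(10_000, 3.0)},
            chrom_sizes={"chr1": 100_000},
            total_insertions=2000,
            extsize=150,
        )
        assert len(signal.call_peaks(track)) == 0

    def test_single_enriched_site_detected_exactly_once(self):
        rng = np.random.default_rng(42)
        rows = uniform_background(rng, n=10_000)
        # 20x the background rate concentrated on a 500-bp site
        lam_bg_insertions = 10_000 * 2 / 1_000_000  # per bp
        n_sig = int(20 * lam_bg_insertions * 500 / 2)
        sig_starts = 500_000 + rng.integers(0, 450, size=n_sig)
        rows += [("chr1", int(s), int(s) + 50, "A") for s in sig_starts]
        frags = FragmentSet(
            pd.DataFrame(rows, columns=["chrom", "start", "end", "barcode"]).assign(
                count=1
            ),
            MB,
            True,
        )
        call = signal.call_peaks(signal.insertion_coverage(frags))
        assert len(call) == 1
        peak = call.peaks.iloc[0]
        overlap = min(peak.end, 500_500) - max(peak.start, 500_000)
        assert overlap >= 0.8 * 500
        assert 500_000 <= peak.summit < 500_500
        # independent Poisson-tail oracle at the site
        k_site = n_sig * 2 * 150 / 10  # expected mass in site bins
        lam = 10_000 * 2 * 150 / 1_000_000
        assert stats.poisson.sf(int(k_site / 50), lam) < 1e-20

    def test_broad_gap_merges_narrow_keeps_separate(self):
        rng = np.random.default_rng(3)
        rows = uniform_background(rng, n=5_000)
        for site in (400_000, 400_800):
            starts = site + rng.integers(0, 150, size=400)
            rows += [("chr1", int(s), int(s) + 60, "A") for s in starts]
        frags = FragmentSet(
            pd.DataFrame(rows, columns=["chrom", "start", "end", "barcode"]).assign(
                count=1
            ),
            MB,
            True,
        )
        track = signal.insertion_coverage(frags)
        narrow = signal.call_peaks(track, mode="narrow")
        broad = signal.call_peaks(track, mode="broad", broad_merge_gap=1000)
        assert len(narrow) == 2
        assert len(broad) == 1


def _call(peaks, replicate, qvalues=None):
    qvalues = qvalues or [1e-4] * len(peaks)
    return signal.PeakCall(
        peaks=pd.DataFrame(
            dict(
                chrom=[p[0] for p in peaks],
                start=[p[1] for p in peaks],
                end=[p[2] for p in peaks],
                summit=[(p[1] + p[2]) // 2 for p in peaks],
                qvalue=qvalues,
            )
        ),
        mode="narrow",
        replicate=replicate,
    )


class TestMergeReproducible:
    def test_two_replicate_retention(self):
        calls = [
            _call([("chr1", 1000, 1400)], 0),
            _call([("chr1", 1100, 1500)], 1),
            _call([("chr1", 90_000, 90_300)], 2),
        ]
        merged = signal.merge_reproducible(calls, min_replicates=2, width=500)
        assert len(merged) == 1
        (iv,) = merged
        assert iv.end - iv.start == 500
        assert 1000 <= iv.summit <= 1500

    def test_singleton_dropped(self):
        calls = [
            _call([("chr1", 1000, 1400)], 0),
            _call([("chr1", 1000, 1400)], 1),
            _call([("chr1", 50_000, 50_400)], 2),
        ]
        merged = signal.merge_reproducible(calls, min_replicates=2)
        assert all(iv.start < 2000 for iv in merged)

    def test_collapse_keeps_best_q(self):
        # two retained summits 200 bp apart -> one 500-bp interval whose
        # summit comes from the smaller q-value
        calls = [
            _call([("chr1", 1000, 1300), ("chr1", 1200, 1500)], 0, [1e-6, 1e-3]),
            _call([("chr1", 1000, 1300), ("chr1", 1200, 1500)], 1, [1e-6, 1e-3]),
        ]
        merged = signal.merge_reproducible(calls, min_replicates=2, width=500)
        assert len(merged) == 1
        assert merged[0].summit == 1150  # summit of the q=1e-6 call
        assert merged[0].end - merged[0].start == 500

    def test_requires_enough_replicates(self):
        with pytest.raises(ValueError):
            signal.merge_reproducible([_call([("chr1", 0, 100)], 0)], 2)

    def test_width_exact_away_from_edges(self):
        calls = [
            _call([("chr1", 10_000, 10_400)], 0),
            _call([("chr1", 10_100, 10_500)], 1),
        ]
        for iv in signal.merge_reproducible(calls, 2, 500, {"chr1": 100_000}):
            assert iv.end - iv.start == 500


class TestRpkm:
    def test_closed_form(self):
        rows = [("chr1", 10_000 + i, 10_400 + i, "A") for i in range(10)]
        rows += [
            ("chr1", 200_000 + 50 * i, 200_100 + 50 * i, "A")
            for i in range(999_990)
        ]
        frags = FragmentSet(
            pd.DataFrame(rows, columns=["chrom", "start", "end", "barcode"]).assign(
                count=1
            ),
            {"chr1": 300_000_000},
            True,
        )
        rpkm = signal.quantify_rpkm(
            {"g": frags}, [GenomicInterval("chr1", 10_000, 10_500)]
        )
        assert rpkm.iloc[0, 0] == pytest.approx(20.0)

    def test_no_overlap_zero(self):
        frags = make_fragments([("chr1", 0, 100, "A")], deduplicated=True)
        rpkm = signal.quantify_rpkm(
            {"g": frags}, [GenomicInterval("chr1", 50_000, 50_500)]
        )
        assert rpkm.iloc[0, 0] == 0.0

    def test_depth_invariance(self):
        rows = [("chr1", 100 * i, 100 * i + 80, "A") for i in range(100)]
        f1 = make_fragments(rows, deduplicated=True)
        f2 = make_fragments(
            rows + [(c, s + 7, e + 7, b) for c, s, e, b in rows],
            deduplicated=True,
        )
        iv = [GenomicInterval("chr1", 0, 5_000)]
        r1 = signal.quantify_rpkm({"g": f1}, iv)
        r2 = signal.quantify_rpkm({"g": f2}, iv)
        assert r1.iloc[0, 0] == pytest.approx(r2.iloc[0, 0], rel=0.01)

    def test_group_permutation_equivariance(self, rng):
        frag_sets = {}
        for g in ("x", "y", "z"):
            frag_sets[g] = make_fragments(
                [
                    ("chr1", int(s), int(s) + 100, "A")
                    for s in rng.integers(0, 90_000, size=50)
                ],
                deduplicated=True,
            )
        ivs = [GenomicInterval("chr1", 1000 * i, 1000 * i + 500) for i in range(10)]
        direct = signal.quantify_rpkm(frag_sets, ivs)
        renamed = signal.quantify_rpkm(
            {"z": frag_sets["x"], "x": frag_sets["y"], "y": frag_sets["z"]}, ivs
        )
        np.testing.assert_allclose(direct["x"], renamed["z"])
        np.testing.assert_allclose(direct["y"], renamed["x"])

    def test_zero_group_warns_zero_column(self, caplog):
        empty = make_fragments([], deduplicated=True)
        rpkm = signal.quantify_rpkm(
            {"g": empty}, [GenomicInterval("chr1", 0, 500)]
        )
        assert (rpkm["g"] == 0).all()


class TestProfileAndSizes:
    def test_central_enrichment(self):
        anchors = [GenomicInterval("chr1", 49_750, 50_250)]
        rows = [("chr1", 49_990, 50_010, "A")] * 50
        mat, _ = signal.profile_matrix(
            make_fragments(rows, deduplicated=True), anchors
        )
        assert mat[0].argmax() in (len(mat[0]) // 2 - 1, len(mat[0]) // 2)

    def test_uniform_fragments_flat_profile(self, rng):
        rows = [
            ("chr1", int(s), int(s) + 100, "A")
            for s in rng.integers(0, 99_000, size=40_000)
        ]
        anchors = [
            GenomicInterval("chr1", c - 250, c + 250)
            for c in range(10_000, 90_000, 5_000)
        ]
        _, norm = signal.profile_matrix(
            make_fragments(rows, deduplicated=True), anchors
        )
        assert np.all(np.abs(norm - 1.0) < 0.25)

    def test_minus_strand_mirrors(self):
        from ptjoint.io import GeneRecord

        rows = [("chr1", 50_500, 50_600, "A")] * 10  # downstream of + TSS
        frags = make_fragments(rows, deduplicated=True)
        plus = [GeneRecord("gp", "chr1", "+", 50_000, 52_000)]
        minus = [GeneRecord("gm", "chr1", "-", 48_001, 50_001)]
        mp, _ = signal.profile_matrix(frags, plus)
        mm, _ = signal.profile_matrix(frags, minus)
        np.testing.assert_array_equal(mp[0], mm[0][::-1])

    def test_band_fractions(self):
        frags = make_fragments(
            [
                ("chr1", 0, 100, "A"),
                ("chr1", 0, 200, "A"),
                ("chr1", 0, 400, "A"),
                ("chr1", 0, 600, "A"),
            ],
            deduplicated=True,
        )
        stats_ = signal.fragment_size_stats(frags)
        f = stats_["fractions"]
        assert f["subnucleosomal"] == f["mono"] == f["di"] == f["tri"] == 0.25
        assert sum(f.values()) == pytest.approx(1.0)

    def test_all_mono(self):
        frags = make_fragments([("chr1", 0, 200, "A")] * 5, deduplicated=True)
        assert signal.fragment_size_stats(frags)["fractions"]["mono"] == 1.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            signal.fragment_size_stats(make_fragments([], deduplicated=True))


class TestPeakOverlap:
    A = [GenomicInterval("chr1", i * 1000, i * 1000 + 500) for i in range(4)]

    def test_identical(self):
        frac, n, total = signal.peak_overlap(self.A, self.A)
        assert frac == 1.0 and n == total == 4

    def test_disjoint(self):
        b = [GenomicInterval("chr2", 0, 100)]
        assert signal.peak_overlap(self.A, b)[0] == 0.0

    def test_partial(self):
        b = [GenomicInterval("chr1", 0, 2600)]  # touches peaks 0,1,2 only
        frac, n, total = signal.peak_overlap(self.A, b)
        assert frac == 0.75 and n == 3


@pytest.fixture(scope="module")
def frag_pool():
    rng = np.random.default_rng(11)
    rows = []
    for i in range(60):
        bc = f"c{i}"
        for site in range(100_000, 900_000, 100_000):
            for _ in range(6):
                s = site + int(rng.integers(0, 450))
                rows.append(("chr1", s, s + 50, bc))
        starts = rng.integers(0, 999_000, size=60)
        rows += [("chr1", int(s), int(s) + 100, bc) for s in starts]
    return FragmentSet(
        pd.DataFrame(rows, columns=["chrom", "start", "end", "barcode"]).assign(
            count=1
        ),
        MB,
        True,
    )


class TestSaturation:
    def test_full_depth_recovers_everything(self, frag_pool):
        full = signal.call_peaks(signal.insertion_coverage(frag_pool)).intervals()
        curve = signal.downsample_saturation(frag_pool, full, [60], seed=0)
        assert curve.table["fraction_recovered"].iloc[-1] == 1.0

    def test_zero_target_cutoff_is_smallest_grid_point(self, frag_pool):
        full = signal.call_peaks(signal.insertion_coverage(frag_pool)).intervals()
        curve = signal.downsample_saturation(
            frag_pool, full, [10, 30, 60], recovery_target=0.0, seed=0
        )
        assert curve.cutoff_nuclei == 10

    def test_grid_clipped_with_warning(self, frag_pool):
        full = signal.call_peaks(signal.insertion_coverage(frag_pool)).intervals()
        curve = signal.downsample_saturation(frag_pool, full, [500], seed=0)
        assert curve.table["n_nuclei"].iloc[0] == 60
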