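import logging

import numpy as np
import pytest

from tfreloc.genomic_io import CoverageTrack, GeneModel, GenomicInterval, Peak
from tfreloc.profiles import (
    anchored_matrix,
    average_profile,
    genomic_location,
    location_fractions,
    metagene,
)

from conftest import random_peaks


def peak(start, end, chrom="chr1", summit=None, name=None):
    return Peak(GenomicInterval(chrom, start, end),
                name=name or f"{chrom}:{start}", summit=summit)


def gene(gid, start, end, strand="+", chrom="chr1"):
    return GeneModel(gid, GenomicInterval(chrom, start, end, strand), strand)


class TestAnchoredMatrix:
    def test_constant_track_fills_every_cell(self):
        track = CoverageTrack({"chr1": np.full(10_000, 3.0, np.float32)})
        m = anchored_matrix(track, [peak(4000, 4400)], flank=1000,
                            bin_size=10, normalized=False)
        np.testing.assert_allclose(m.values, 3.0)

    def test_unit_impulse_lands_in_central_bin(self):
        arr = np.zeros(10_000, np.float32)
        arr[5000] = 1.0
        track = CoverageTrack({"chr1": arr})
        m = anchored_matrix(track, [peak(4800, 5200)], flank=1000,
                            bin_size=10, normalized=False)
        # anchor center = midpoint 5000; bin 0 starts at offset 0
        central = np.flatnonzero(m.values[0])
        assert list(central) == [100]  # offset 0 bin
        assert m.values[0, 100] == pytest.approx(1 / 10)

    def test_flank_must_be_multiple_of_bin_size(self):
        track = CoverageTrack({"chr1": np.zeros(100, np.float32)})
        with pytest.raises(ValueError):
            anchored_matrix(track, [peak(40, 60)], flank=105, bin_size=10)

    def test_matches_per_base_oracle(self):
        rng = np.random.default_rng(4)
        arr = rng.random(60_000).astype(np.float32)
        track = CoverageTrack({"chr1": arr}, library_size=1e6)
        anchors = random_peaks(rng, 60, chroms=("chr1",), max_pos=58_000,
                               with_summits=True)
        flank, bs = 500, 25
        m = anchored_matrix(track, anchors, flank=flank, bin_size=bs)
        for i, p in enumerate(anchors):
            c = p.center
            for j in range(2 * flank // bs):
                lo = c - flank + j * bs
                vals = [float(arr[k]) if 0 <= k < len(arr) else 0.0
                        for k in range(lo, lo + bs)]
                expected = sum(vals) / bs  # library 1e6 makes scale 1
                assert m.values[i, j] == pytest.approx(expected, abs=1e-9)

    def test_rows_clipped_at_chromosome_start_fill_zero(self):
        track = CoverageTrack({"chr1": np.ones(2000, np.float32)})
        m = anchored_matrix(track, [peak(0, 200)], flank=1000, bin_size=100,
                            normalized=False)
        assert m.values[0, 0] == 0.0  # fully off the end
        assert m.values[0, -1] == 1.0


class TestAverageProfile:
    def _matrix(self, rng, n=20, bins=40):
        track = CoverageTrack(
            {"chr1": rng.random(100_000).astype(np.float32)},
            library_size=1e6)
        anchors = random_peaks(rng, n, chroms=("chr1",), max_pos=90_000)
        return anchored_matrix(track, anchors, flank=200, bin_size=10)

    def test_single_row_profile_is_that_row(self):
        m = self._matrix(np.random.default_rng(0))
        np.testing.assert_allclose(average_profile(m, [m.row_order[3]]),
                                   m.values[3])

    def test_empty_subset_rejected(self):
        m = self._matrix(np.random.default_rng(0))
        with pytest.raises(ValueError):
            average_profile(m, np.zeros(len(m.row_order), dtype=bool))

    def test_symmetric_coverage_gives_symmetric_profile(self):
        arr = np.zeros(10_000, np.float32)
        centers = [2000, 5000, 8000]
        for c in centers:
            # triangle symmetric about the bin-grid mirror point c - 0.5
            for d in range(300):
                arr[c - 1 - d] += 300 - d
                arr[c + d] += 300 - d
        track = CoverageTrack({"chr1": arr})
        anchors = [peak(c - 100, c + 100) for c in centers]
        m = anchored_matrix(track, anchors, flank=400, bin_size=10,
                            normalized=False)
        prof = average_profile(m)
        np.testing.assert_allclose(prof, prof[::-1], atol=1e-9)

    def test_group_profiles_recombine_to_whole(self):
        m = self._matrix(np.random.default_rng(7))
        groups = np.array([0] * 8 + [1] * 12)
        pa = average_profile(m, groups == 0)
        pb = average_profile(m, groups == 1)
        whole = average_profile(m)
        np.testing.assert_allclose((8 * pa + 12 * pb) / 20, whole, atol=1e-12)


class TestMetagene:
    def test_uniform_track_gives_flat_profile(self):
        track = CoverageTrack({"chr1": np.full(50_000, 2.0, np.float32)})
        genes = [gene("a", 10_000, 16_000), gene("b", 30_000, 33_000, "-")]
        mp = metagene(track, genes, normalized=False)
        np.testing.assert_allclose(mp.values, 2.0)

    def test_signal_only_in_bodies_leaves_flanks_zero(self):
        arr = np.zeros(50_000, np.float32)
        arr[10_000:16_000] = 1.0
        arr[30_000:33_000] = 1.0
        track = CoverageTrack({"chr1": arr})
        genes = [gene("a", 10_000, 16_000), gene("b", 30_000, 33_000, "-")]
        mp = metagene(track, genes, normalized=False)
        fb = mp.flank_bins
        np.testing.assert_allclose(mp.values[:fb], 0.0)
        np.testing.assert_allclose(mp.values[-fb:], 0.0)
        np.testing.assert_allclose(mp.values[fb:-fb], 1.0)

    def test_length_invariant_rescaling(self):
        """Two genes of different lengths carrying the same per-scaled-
        position signal produce a group profile equal to that signal."""
        body_bins = 10
        arr = np.zeros(100_000, np.float32)
        pattern = np.arange(1.0, 11.0)  # value per scaled bin
        layouts = [(10_000, 15_000), (40_000, 52_000)]  # 5 kb and 12 kb
        genes = []
        for gi, (s, e) in enumerate(layouts):
            cuts = s + np.round(np.linspace(0, e - s, body_bins + 1)).astype(int)
            for j in range(body_bins):
                arr[cuts[j] : cuts[j + 1]] = pattern[j]
            genes.append(gene(f"g{gi}", s, e))
        track = CoverageTrack({"chr1": arr})
        mp = metagene(track, genes, body_bins=body_bins, flank=1000,
                      flank_bins=10, normalized=False)
        fb = mp.flank_bins
        np.testing.assert_allclose(mp.values[fb:-fb], pattern, atol=1e-9)

    def test_minus_strand_gene_profile_is_reversed(self):
        arr = np.zeros(50_000, np.float32)
        arr[10_000:10_500] = 5.0  # 5' end of a + strand gene
        track = CoverageTrack({"chr1": arr})
        plus = metagene(track, [gene("a", 10_000, 16_000, "+")],
                        normalized=False)
        minus = metagene(track, [gene("a", 10_000, 16_000, "-")],
                         normalized=False)
        np.testing.assert_allclose(minus.values, plus.values[::-1])

    def test_short_gene_skipped_with_warning(self, caplog):
        track = CoverageTrack({"chr1": np.ones(10_000, np.float32)})
        genes = [gene("tiny", 100, 150), gene("ok", 3000, 9000)]
        with caplog.at_level(logging.WARNING):
            mp = metagene(track, genes, body_bins=200)
        assert mp.gene_ids == ["ok"]
        assert any("tiny" in r.message for r in caplog.records)


class TestCofactorRelocationSignal:
    def test_cofactor_profile_rises_at_relocated_to_sites_on_induction(
            self, small_scenario, small_tracks):
        """The co-factor's average profile at relocated-to sites gains
        signal at the anchor center from the un-induced to the induced
        condition (the co-factor follows the relocating complex)."""
        tracks, _ = small_tracks
        st = small_scenario.truth.site_table
        rows = st[st["relocated_to"]]
        anchors = [peak(r.start, r.end, chrom=r.chrom, name=r.site_id)
                   for r in rows.itertuples(index=False)]
        profs = {}
        for cond in ("noDox", "Dox"):
            m = anchored_matrix(tracks[("CDK9", cond)], anchors,
                                flank=500, bin_size=10)
            profs[cond] = average_profile(m)
        center = len(profs["Dox"]) // 2
        assert profs["Dox"][center] > 5 * max(profs["noDox"][center], 1e-12)


class TestGenomicLocation:
    GENES = [gene("g1", 10_000, 20_000, "+"), gene("g2", 50_000, 60_000, "-")]

    def test_peak_near_tss_is_promoter(self):
        df = genomic_location([peak(10_400, 10_600)], self.GENES)
        assert df.loc[0, "location"] == "promoter"
        assert bool(df.loc[0, "proximal"])

    def test_peak_inside_gene_body_is_intragenic(self):
        df = genomic_location([peak(15_000, 15_200)], self.GENES)
        assert df.loc[0, "location"] == "intragenic"
        assert not bool(df.loc[0, "proximal"])

    def test_far_peak_is_distal_intergenic(self):
        df = genomic_location([peak(110_000, 110_200)], self.GENES)
        assert df.loc[0, "location"] == "intergenic"
        assert df.loc[0, "proximal_distal"] == "distal"

    def test_minus_strand_tss_is_gene_end(self):
        # TSS of g2 is at 59,999; a peak near the gene *start* is not
        # proximal
        near_end = genomic_location([peak(59_000, 59_400)], self.GENES)
        near_start = genomic_location([peak(46_000, 46_400)], self.GENES)
        assert bool(near_end.loc[0, "proximal"])
        assert not bool(near_start.loc[0, "proximal"])

    def test_matches_brute_force(self):
        rng = np.random.default_rng(12)
        genes = []
        for i in range(40):
            s = int(rng.integers(0, 180_000))
            e = s + int(rng.integers(500, 8000))
            strand = "+" if rng.random() < 0.5 else "-"
            genes.append(gene(f"g{i}", s, e, strand,
                              chrom=f"chr{1 + i % 2}"))
        peaks = random_peaks(rng, 300, max_pos=200_000)
        df = genomic_location(peaks, genes, promoter_window=2000)
        for p, row in zip(peaks, df.itertuples(index=False)):
            c = p.center
            same = [g for g in genes if g.chrom == p.chrom]
            prox = any(abs(c - g.tss) <= 2000 for g in same)
            intra = any(g.interval.start <= c < g.interval.end for g in same)
            expected = ("promoter" if prox
                        else "intragenic" if intra else "intergenic")
            assert row.location == expected
            assert row.proximal == prox

    def test_fractions_sum_to_one(self):
        rng = np.random.default_rng(3)
        peaks = random_peaks(rng, 100, max_pos=150_000)
        df = genomic_location(peaks, self.GENES)
        fr = location_fractions(df)
        assert fr["proximal"] + fr["distal"] == pytest.approx(1.0)
        assert (fr["promoter"] + fr["intragenic"] + fr["intergenic"]
                == pytest.approx(1.0))
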