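import itertools
import math

import numpy as np
import pytest

from tfreloc.genomic_io import PWM, GenomicInterval, Peak, load_bundled_motifs
from tfreloc.motifs import (
    density_profile,
    group_enrichment,
    hypergeom_pvalue,
    log_odds,
    max_score,
    scan,
)

from conftest import brute_pwm_score, brute_scan_threshold, revcomp


def simple_pwm(consensus, dominant=0.85, name="M"):
    idx = {"A": 0, "C": 1, "G": 2, "T": 3}
    m = np.full((len(consensus), 4), (1 - dominant) / 3)
    for i, b in enumerate(consensus):
        m[i, idx[b]] = dominant
    return PWM(name, m)


class TestLogOdds:
    def test_uniform_pwm_scores_zero(self):
        pwm = PWM("u", np.full((5, 4), 0.25))
        np.testing.assert_allclose(log_odds(pwm), 0.0)

    def test_deterministic_column_after_pseudocount(self):
        # counts column (1,0,0,0), per-cell pseudocount 0.25:
        # p = (1 + 0.25) / (1 + 1) = 0.625 -> hand-checked log-odds
        p = np.array([[1.25 / 2, 0.25 / 2, 0.25 / 2, 0.25 / 2]])
        pwm = PWM("d", p)
        S = log_odds(pwm)
        assert S[0, 0] == pytest.approx(math.log2(0.625 / 0.25))
        assert S[0, 1] == pytest.approx(math.log2(0.125 / 0.25))

    def test_max_score_is_sum_of_position_maxima(self):
        pwm = load_bundled_motifs()["RUNX"]
        S = log_odds(pwm)
        assert max_score(pwm) == pytest.approx(S.max(axis=1).sum())

    def test_zero_probability_rejected(self):
        pwm = PWM("z", np.array([[1.0, 0.0, 0.0, 0.0]]))
        with pytest.raises(ValueError, match="pseudocount"):
            log_odds(pwm)


class TestScan:
    PWM6 = simple_pwm("ACGTAG")

    def test_consensus_hits_once_at_max_score(self):
        seq = "TTTTT" + "ACGTAG" + "TTTTT"
        hits = scan(seq, self.PWM6, threshold_fraction=1.0)
        assert len(hits) == 1
        (h,) = hits
        assert (h.position, h.strand) == (5, "+")
        assert h.score == pytest.approx(max_score(self.PWM6))

    def test_reverse_complement_hit_reported_on_forward_coords(self):
        seq = "TTTTT" + revcomp("ACGTAG") + "TTTTT"
        hits = scan(seq, self.PWM6, threshold_fraction=1.0)
        assert len(hits) == 1
        assert (hits[0].position, hits[0].strand) == (5, "-")

    def test_sequence_shorter_than_pwm_rejected(self):
        with pytest.raises(ValueError, match="shorter"):
            scan("ACG", self.PWM6)

    def test_exhaustive_kmer_oracle(self):
        """Hit set over all 4^6 6-mers equals brute-force scoring of every
        k-mer on both strands."""
        pwm = self.PWM6
        thr = brute_scan_threshold(pwm, 0.8)
        for kmer in map("".join, itertools.product("ACGT", repeat=6)):
            hits = scan(kmer, pwm, threshold_fraction=0.8, collapse=False)
            expect = set()
            if brute_pwm_score(kmer, pwm) >= thr - 1e-9:
                expect.add("+")
            if brute_pwm_score(revcomp(kmer), pwm) >= thr - 1e-9:
                expect.add("-")
            assert {h.strand for h in hits} == expect, kmer
            for h in hits:
                assert h.position == 0
                ref = kmer if h.strand == "+" else revcomp(kmer)
                assert h.score == pytest.approx(brute_pwm_score(ref, pwm))

    def test_overlapping_same_strand_hits_collapse_to_best(self):
        pwm = simple_pwm("AAAAAA")
        seq = "A" * 20
        collapsed = scan(seq, pwm, threshold_fraction=0.9)
        raw = scan(seq, pwm, threshold_fraction=0.9, collapse=False)
        plus_c = [h for h in collapsed if h.strand == "+"]
        plus_r = [h for h in raw if h.strand == "+"]
        assert len(plus_r) == 15
        # kept hits are pairwise >= one PWM length apart
        pos = [h.position for h in plus_c]
        assert all(b - a >= 6 for a, b in zip(pos, pos[1:]))

    def test_strand_symmetry_of_genome_scan(self):
        rng = np.random.default_rng(8)
        seq = "".join("ACGT"[i] for i in rng.integers(0, 4, 4000))
        pwm = load_bundled_motifs()["GATA"]
        fwd = scan(seq, pwm, collapse=False)
        rc = scan(revcomp(seq), pwm, collapse=False)
        L = len(pwm)
        mirrored = {(len(seq) - h.position - L,
                     "+" if h.strand == "-" else "-") for h in rc}
        assert {(h.position, h.strand) for h in fwd} == mirrored


class TestDensityProfile:
    def _anchors(self, centers, chrom="chr1"):
        return [Peak(GenomicInterval(chrom, c - 100, c + 100), name=f"a{c}")
                for c in centers]

    def test_planted_motif_peaks_in_its_bin(self):
        rng = np.random.default_rng(5)
        codes = rng.integers(0, 4, 30_000)
        pwm = load_bundled_motifs()["RUNX"]
        cons = pwm.consensus
        centers = list(range(2000, 28_000, 2000))
        seq = list("ACGT"[i] for i in codes)
        offset = -35  # hit start relative to anchor center
        for c in centers:
            seq[c + offset : c + offset + len(cons)] = list(cons)
        genome = {"chr1": "".join(seq)}
        dp = density_profile(self._anchors(centers), genome, pwm,
                             flank=200, bin_size=10, row_window=5)
        col = dp.counts.sum(axis=0)
        assert dp.offsets[int(col.argmax())] == pytest.approx(-40, abs=10)

    def test_no_motifs_gives_zero_profile(self):
        genome = {"chr1": "AC" * 20_000}
        pwm = simple_pwm("GGGGGGGG", dominant=0.97)
        dp = density_profile(self._anchors([5000, 9000]), genome, pwm,
                             flank=200, bin_size=10)
        assert dp.counts.sum() == 0
        assert np.all(dp.values == 0)

    def test_raw_counts_integrate_to_mean_hits_per_peak(self):
        rng = np.random.default_rng(9)
        genome = {"chr1": "".join("ACGT"[i]
                                  for i in rng.integers(0, 4, 50_000))}
        pwm = load_bundled_motifs()["ETS"]
        anchors = self._anchors(list(range(3000, 48_000, 3000)))
        dp = density_profile(anchors, genome, pwm, flank=300, bin_size=10)
        integral = (dp.counts / dp.bin_size).sum(axis=1) * dp.bin_size
        assert integral.sum() / len(anchors) == pytest.approx(
            dp.mean_hits_per_peak
        )

    def test_matches_brute_force_histogram(self):
        rng = np.random.default_rng(10)
        genome = {"chr1": "".join("ACGT"[i]
                                  for i in rng.integers(0, 4, 20_000))}
        pwm = load_bundled_motifs()["AP1"]
        anchors = self._anchors([4000, 8000, 12_000, 16_000])
        flank, bs = 250, 25
        dp = density_profile(anchors, genome, pwm, flank=flank, bin_size=bs)
        L = len(pwm)
        for i, a in enumerate(anchors):
            c = a.center
            window = genome["chr1"][c - flank - L + 1 : c + flank + L - 1]
            hits = scan(window, pwm)
            hist = np.zeros(2 * flank // bs)
            for h in hits:
                off = h.position + (c - flank - L + 1) - c
                if -flank <= off < flank:
                    hist[(off + flank) // bs] += 1
            np.testing.assert_allclose(dp.counts[i], hist)


class TestEnrichment:
    def test_exact_p_matches_enumeration_for_small_totals(self):
        """Two-sided hypergeometric p equals direct enumeration with
        math.comb for all configurations with N <= 30."""
        for N in (5, 11, 18, 30):
            for K in range(0, N + 1, max(1, N // 4)):
                for n in range(1, N + 1, max(1, N // 3)):
                    for k in range(max(0, n + K - N), min(n, K) + 1):
                        p_obs = (math.comb(K, k) * math.comb(N - K, n - k)
                                 / math.comb(N, n))
                        total = 0.0
                        for j in range(max(0, n + K - N), min(n, K) + 1):
                            pj = (math.comb(K, j) * math.comb(N - K, n - j)
                                  / math.comb(N, n))
                            if pj <= p_obs * (1 + 1e-9):
                                total += pj
                        assert hypergeom_pvalue(k, n, K, N) == pytest.approx(
                            min(1.0, total), rel=1e-9), (k, n, K, N)

    def test_fraction_and_fold_arithmetic(self):
        # group: 100 peaks, all with a hit; background: 10 of 100 with a hit
        pwm = simple_pwm("ACGTACGT", dominant=0.97)
        cons = pwm.consensus
        rng = np.random.default_rng(2)
        chunks, peaks = [], []
        pos = 0
        for i in range(200):
            filler = "".join("AC"[j] for j in rng.integers(0, 2, 30))
            body = cons if (i < 100 or i % 10 == 0) else "A" * len(cons)
            s = filler + body + filler
            peaks.append(Peak(GenomicInterval("chr1", pos, pos + len(s)),
                              name=f"p{i}"))
            chunks.append(s)
            pos += len(s)
        genome = {"chr1": "".join(chunks)}
        res = group_enrichment(peaks[:100], peaks[100:], genome, pwm)
        assert res.fraction_with_hit == 1.0
        assert res.fold_vs_background == pytest.approx(10.0)
        assert res.p_value < 1e-10

    def test_group_and_background_must_be_disjoint(self):
        pwm = simple_pwm("ACGTAC")
        p = Peak(GenomicInterval("chr1", 0, 50), name="p")
        genome = {"chr1": "A" * 100}
        with pytest.raises(ValueError, match="disjoint"):
            group_enrichment([p], [p], genome, pwm)

    def test_composite_density_higher_at_relocated_to_sites(
            self, small_scenario):
        """ETS::RUNX composite hits concentrate at relocated-to sites,
        not at the sites the factor left."""
        pwms = load_bundled_motifs()
        genome = small_scenario.genome()
        st = small_scenario.truth.site_table

        def anchors(mask):
            rows = st[mask]
            return [Peak(GenomicInterval(r.chrom, r.start, r.end),
                         name=r.site_id)
                    for r in rows.itertuples(index=False)]

        to_sites = anchors(st["relocated_to"])
        from_sites = anchors(st["relocating"])
        dp_to = density_profile(to_sites, genome, pwms["ETS_RUNX"],
                                flank=200, bin_size=10)
        dp_from = density_profile(from_sites, genome, pwms["ETS_RUNX"],
                                  flank=200, bin_size=10)
        assert dp_to.mean_hits_per_peak > 5 * max(
            dp_from.mean_hits_per_peak, 0.02
        )
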