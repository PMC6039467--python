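"""PWM scanning, motif-density profiles along ranked anchors, and per-group
motif enrichment.

Scores are log2 odds against the PWM background.  The scan threshold is
expressed as a fraction of the score *range* (min..max attainable score),
which keeps one threshold usable across PWMs of different lengths and
information content.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.ndimage import uniform_filter1d

from .genomic_io import BASES, PWM, Peak

logger = logging.getLogger(__name__)

__all__ = [
    "MotifHit",
    "MotifDensityProfile",
    "EnrichmentResult",
    "log_odds",
    "scan",
    "density_profile",
    "group_enrichment",
    "hypergeom_pvalue",
]

_CODE = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate(BASES):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i


def encode_sequence(seq: str) -> np.ndarray:
    """ACGT -> 0..3 int8 codes; anything else becomes -1 (never matched)."""
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


@dataclass(frozen=True)
class MotifHit:
    """One PWM match.  `position` is the match start on the + genome strand
    regardless of which strand matched."""

    name: str
    position: int
    strand: str
    score: float


@dataclass
class MotifDensityProfile:
    """Positional hit-start density around ranked anchors.

    `counts` holds the raw per-anchor, per-bin hit counts; `values` holds
    the display matrix after a rolling mean over `row_window` ranked rows,
    expressed as hits per bp per peak.  Statistics should use `counts`.
    """

    pwm_name: str
    row_order: list[str]
    offsets: np.ndarray  # bin left edges relative to anchor center (bp)
    counts: np.ndarray  # (n_rows, n_bins) raw hit counts
    values: np.ndarray  # (n_rows, n_bins) smoothed density (hits/bp/peak)
    bin_size: int
    flank: int
    row_window: int

    @property
    def mean_hits_per_peak(self) -> float:
        return float(self.counts.sum() / self.counts.shape[0])


@dataclass(frozen=True)
class EnrichmentResult:
    pwm_name: str
    n_group: int
    n_background: int
    hits_group: int
    hits_background: int
    fraction_with_hit: float
    background_fraction: float
    fold_vs_background: float
    p_value: float


def log_odds(pwm: PWM) -> np.ndarray:
    """Position score matrix: score(pos, base) = log2(p / background)."""
    if np.any(pwm.matrix <= 0) or np.any(pwm.background <= 0):
        raise ValueError(
            f"PWM {pwm.name} has zero probabilities; apply a pseudocount "
            "when reading the PFM"
        )
    return np.log2(pwm.matrix / pwm.background[None, :])


def _score_threshold(S: np.ndarray, threshold_fraction: float) -> float:
    smin = float(S.min(axis=1).sum())
    smax = float(S.max(axis=1).sum())
    return smin + threshold_fraction * (smax - smin)


def _window_scores(codes: np.ndarray, S: np.ndarray) -> np.ndarray:
    """Score of every window start; windows containing non-ACGT get -inf."""
    L = S.shape[0]
    n = codes.size - L + 1
    if n <= 0:
        return np.empty(0)
    scores = np.zeros(n, dtype=np.float64)
    bad = np.zeros(n, dtype=bool)
    for j in range(L):
        cj = codes[j : j + n]
        invalid = cj < 0
        bad |= invalid
        scores += S[j, np.where(invalid, 0, cj)]
    scores[bad] = -np.inf
    return scores


def _collapse_hits(positions, scores, length):
    """Greedy suppression of overlapping hits on one strand: keep the best,
    drop others starting within < PWM length; ties go to the leftmost."""
    order = np.lexsort((positions, -scores))
    keep = []
    taken = []
    for idx in order:
        p = positions[idx]
        if all(abs(p - q) >= length for q in taken):
            keep.append(idx)
            taken.append(p)
    keep.sort(key=lambda i: positions[i])
    return keep


def scan(sequence: str, pwm: PWM, threshold_fraction: float = 0.8,
         collapse: bool = True) -> list[MotifHit]:
    """Scan both strands; report hits with score >= threshold.

    Reverse-strand hits are reported at their forward-strand match start
    (the leftmost base of the window).  Overlapping same-strand hits within
    one PWM length are collapsed to the best-scoring one unless
    `collapse=False`.
    """
    if not (0 < threshold_fraction <= 1):
        raise ValueError("threshold_fraction must be in (0, 1]")
    L = len(pwm)
    if len(sequence) < L:
        raise ValueError(
            f"sequence of length {len(sequence)} shorter than PWM {pwm.name} "
            f"({L} bp)"
        )
    S = log_odds(pwm)
    thr = _score_threshold(S, threshold_fraction)
    codes = encode_sequence(sequence)
    # reverse strand: score the reverse complement of each window, i.e. scan
    # with the reverse-complemented matrix at the same forward coordinates
    S_rc = S[::-1, ::-1]
    hits: list[MotifHit] = []
    for strand, mat in (("+", S), ("-", S_rc)):
        scores = _window_scores(codes, mat)
        idx = np.flatnonzero(scores >= thr - 1e-9)
        if idx.size and collapse:
            keep = _collapse_hits(idx, scores[idx], L)
            idx = idx[keep]
        hits.extend(
            MotifHit(pwm.name, int(p), strand, float(scores[p])) for p in idx
        )
    hits.sort(key=lambda h: (h.position, h.strand))
    return hits


def max_score(pwm: PWM) -> float:
    return float(log_odds(pwm).max(axis=1).sum())


# ---------------------------------------------------------------------------
# density profiles along ranked anchors


def density_profile(anchors: list[Peak], genome: dict[str, str], pwm: PWM,
                    flank: int = 1000, bin_size: int = 10,
                    row_window: int = 100,
                    threshold_fraction: float = 0.8) -> MotifDensityProfile:
    """Hit-start density around anchor centers, rows in the given (ranked)
    anchor order — the same row coordinates as the signal heatmaps.

    A hit is counted in the bin containing its forward-strand start offset
    relative to the anchor center, offsets in [-flank, flank).
    """
    if flank % bin_size:
        raise ValueError("flank must be a multiple of bin_size")
    L = len(pwm)
    n_bins = 2 * flank // bin_size
    counts = np.zeros((len(anchors), n_bins), dtype=np.float64)
    for i, peak in enumerate(anchors):
        seq = genome[peak.chrom]
        center = peak.center
        # widen so that hits *starting* anywhere in [-flank, flank) are seen
        lo = max(0, center - flank)
        hi = min(len(seq), center + flank + L - 1)
        window = seq[lo:hi]
        if len(window) < L:
            continue
        for hit in scan(window, pwm, threshold_fraction):
            off = hit.position + lo - center
            if -flank <= off < flank:
                counts[i, (off + flank) // bin_size] += 1
    density = counts / bin_size  # hits per bp per peak
    if len(anchors) > 1 and row_window > 1:
        values = uniform_filter1d(density, size=min(row_window, len(anchors)),
                                  axis=0, mode="nearest")
    else:
        values = density.copy()
    offsets = np.arange(-flank, flank, bin_size)
    row_order = [p.name for p in anchors]
    return MotifDensityProfile(pwm.name, row_order, offsets, counts, values,
                               bin_size, flank, row_window)


# ---------------------------------------------------------------------------
# enrichment


def hypergeom_pvalue(k: int, n_draws: int, K_success: int, N_total: int) -> float:
    """Exact two-sided hypergeometric p: the total probability of outcomes
    no more likely than the observed one (minimum-likelihood definition)."""
    if not (0 <= k <= n_draws <= N_total and 0 <= K_success <= N_total):
        raise ValueError("inconsistent hypergeometric counts")
    support = np.arange(max(0, n_draws + K_success - N_total),
                        min(n_draws, K_success) + 1)
    pmf = stats.hypergeom.pmf(support, N_total, K_success, n_draws)
    p_obs = stats.hypergeom.pmf(k, N_total, K_success, n_draws)
    p = float(pmf[pmf <= p_obs * (1 + 1e-9)].sum())
    return min(1.0, p)


def peaks_with_hit(peaks: list[Peak], genome: dict[str, str], pwm: PWM,
                   threshold_fraction: float = 0.8) -> np.ndarray:
    """Boolean vector: does each peak's span contain >=1 hit."""
    out = np.zeros(len(peaks), dtype=bool)
    for i, p in enumerate(peaks):
        seq = genome[p.chrom][p.start : p.end]
        if len(seq) < len(pwm):
            continue
        out[i] = bool(scan(seq, pwm, threshold_fraction, collapse=False))
    return out


def group_enrichment(group_peaks: list[Peak], background_peaks: list[Peak],
                     genome: dict[str, str], pwm: PWM,
                     threshold_fraction: float = 0.8) -> EnrichmentResult:
    """Fraction of group peaks carrying >=1 motif hit, fold over the
    background fraction, and an exact two-sided hypergeometric p-value.

    The background is the set of peaks *not* in the group; the two sets must
    be disjoint (checked by coordinates).
    """
    if not group_peaks or not background_peaks:
        raise ValueError("group and background must be nonempty")
    group_keys = {(p.chrom, p.start, p.end) for p in group_peaks}
    bg_keys = {(p.chrom, p.start, p.end) for p in background_peaks}
    if group_keys & bg_keys:
        raise ValueError("group and background peak sets must be disjoint")
    g_hit = peaks_with_hit(group_peaks, genome, pwm, threshold_fraction)
    b_hit = peaks_with_hit(background_peaks, genome, pwm, threshold_fraction)
    k, n = int(g_hit.sum()), len(group_peaks)
    Kb, Nb = int(b_hit.sum()), len(background_peaks)
    fraction = k / n
    bg_fraction = Kb / Nb
    fold = fraction / bg_fraction if bg_fraction > 0 else np.inf
    p = hypergeom_pvalue(k, n, k + Kb, n + Nb)
    return EnrichmentResult(pwm.name, n, Nb, k, Kb, fraction, bg_fraction,
                            float(fold), p)


def hits_to_bed_rows(hits: list[MotifHit], chrom: str, pwm_length: int):
    """BED6 rows for exporting hits; score = bits * 100, integer."""
    return [
        (chrom, h.position, h.position + pwm_length, h.name,
         int(round(h.score * 100)), h.strand)
        for h in hits
    ]
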