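"""Pairwise quantitative comparison of a factor's binding between two
conditions: union peaks, window counts, CPM normalisation, >2-fold
specificity classes and the fold-difference ranking that fixes the shared
row order for all downstream heatmaps.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .genomic_io import CoverageTrack, GenomicInterval, Peak

__all__ = [
    "union_peaks",
    "merge_peaks",
    "quantify",
    "normalize_cpm",
    "classify_specificity",
    "rank_by_fold",
    "compare_binding",
    "GROUP_A_SPECIFIC",
    "GROUP_SHARED",
    "GROUP_B_SPECIFIC",
]

GROUP_A_SPECIFIC = "A_specific"  # Group 1
GROUP_SHARED = "shared"  # Group 2
GROUP_B_SPECIFIC = "B_specific"  # Group 3
GROUP_NUMBER = {GROUP_A_SPECIFIC: 1, GROUP_SHARED: 2, GROUP_B_SPECIFIC: 3}


def merge_peaks(*peak_sets: list[Peak]) -> list[Peak]:
    """Merge any number of peak sets into union loci.

    Overlapping or bookended intervals merge.  The merged peak keeps the
    summit of the highest-scoring contributor carrying one (ties: first in
    sorted order); when no contributor has a summit the merged summit is the
    midpoint (left as None, since Peak.center falls back to the midpoint).
    """
    peaks = sorted(
        (p for ps in peak_sets for p in ps),
        key=lambda p: (p.chrom, p.start, p.end),
    )
    if not peaks:
        return []
    merged: list[Peak] = []
    cur = peaks[0]
    cur_start, cur_end = cur.start, cur.end
    best = cur  # best-scoring contributor with a summit, if any
    members = [cur]

    def _finish():
        with_summit = [p for p in members if p.summit is not None]
        summit = None
        score = max(p.score for p in members)
        if with_summit:
            top = max(with_summit, key=lambda p: p.score)
            summit = top.start + top.summit - cur_start
        iv = GenomicInterval(cur.chrom, cur_start, cur_end)
        name = f"{cur.chrom}:{cur_start}-{cur_end}"
        merged.append(Peak(iv, name=name, score=score, summit=summit))

    for p in peaks[1:]:
        if p.chrom == cur.chrom and p.start <= cur_end:  # overlap or bookend
            cur_end = max(cur_end, p.end)
            members.append(p)
        else:
            _finish()
            cur = p
            cur_start, cur_end = p.start, p.end
            members = [p]
    _finish()
    return merged


def union_peaks(peaks_a: list[Peak], peaks_b: list[Peak]) -> list[Peak]:
    """Union loci of two peak sets (sorted, overlap/bookend-merged)."""
    return merge_peaks(peaks_a, peaks_b)


def quantify(track: CoverageTrack, intervals: list[Peak],
             halfwidth: int = 200) -> np.ndarray:
    """Raw signal sum in a summit-centred window of +/- halfwidth around
    each peak, clipped at chromosome ends."""
    if halfwidth < 0:
        raise ValueError("halfwidth must be >= 0")
    out = np.empty(len(intervals), dtype=np.float64)
    for i, p in enumerate(intervals):
        if p.chrom not in track.data:
            raise KeyError(f"chromosome {p.chrom!r} absent from track")
        c = p.center
        out[i] = track.window_sum(p.chrom, c - halfwidth, c + halfwidth)
    return out


def normalize_cpm(raw, library_size: float):
    """Counts per million: raw * 1e6 / library_size."""
    if library_size <= 0:
        raise ValueError("library_size must be > 0")
    return np.asarray(raw, dtype=np.float64) * 1e6 / library_size


def classify_specificity(cpm_a, cpm_b, fold_threshold: float = 2.0,
                         pseudocount: float = 0.5):
    """Fold = (cpm_a + pc) / (cpm_b + pc); > threshold -> A-specific,
    < 1/threshold -> B-specific, else shared.

    The pseudocount gives absent peaks (cpm 0) a finite fold, so
    ">2-fold reduced" and "absent" land in the same specific class.
    Returns (fold, group) arrays (or scalars for scalar input).
    """
    if fold_threshold <= 1:
        raise ValueError("fold_threshold must be > 1")
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    a = np.asarray(cpm_a, dtype=np.float64)
    b = np.asarray(cpm_b, dtype=np.float64)
    if np.any(a < 0) or np.any(b < 0):
        raise ValueError("cpm must be >= 0")
    fold = (a + pseudocount) / (b + pseudocount)
    group = np.where(
        fold > fold_threshold, GROUP_A_SPECIFIC,
        np.where(fold < 1.0 / fold_threshold, GROUP_B_SPECIFIC, GROUP_SHARED),
    )
    if np.isscalar(cpm_a) and np.isscalar(cpm_b):
        return float(fold), str(group)
    return fold, group


def rank_by_fold(records: pd.DataFrame) -> pd.DataFrame:
    """Order by descending fold; ties broken by (cpm_a + cpm_b) descending,
    then genomic position.  Adds a 1..N `rank` column.  This ordering is the
    shared row coordinate for every heatmap built from the comparison."""
    df = records.copy()
    df["_cpmsum"] = df["cpm_a"] + df["cpm_b"]
    df = df.sort_values(
        ["fold", "_cpmsum", "chrom", "start", "end"],
        ascending=[False, False, True, True, True],
        kind="mergesort",
    ).drop(columns="_cpmsum")
    df["rank"] = np.arange(1, len(df) + 1)
    return df.reset_index(drop=True)


def compare_binding(peaks_a: list[Peak], peaks_b: list[Peak],
                    track_a: CoverageTrack, track_b: CoverageTrack,
                    halfwidth: int = 200, fold_threshold: float = 2.0,
                    pseudocount: float = 0.5) -> pd.DataFrame:
    """Full pairwise comparison: union loci, CPM in both conditions,
    fold, specificity group, and the fold rank.

    Returns a DataFrame with one row per union peak, ordered by rank, with
    columns: name, chrom, start, end, summit, cpm_a, cpm_b, fold, group,
    group_number, rank.
    """
    union = union_peaks(peaks_a, peaks_b)
    raw_a = quantify(track_a, union, halfwidth)
    raw_b = quantify(track_b, union, halfwidth)
    cpm_a = normalize_cpm(raw_a, track_a.library_size)
    cpm_b = normalize_cpm(raw_b, track_b.library_size)
    fold, group = classify_specificity(cpm_a, cpm_b, fold_threshold,
                                       pseudocount)
    df = pd.DataFrame(
        {
            "name": [p.name for p in union],
            "chrom": [p.chrom for p in union],
            "start": [p.start for p in union],
            "end": [p.end for p in union],
            "summit": [p.summit if p.summit is not None else -1
                       for p in union],
            "cpm_a": cpm_a,
            "cpm_b": cpm_b,
            "fold": fold,
            "group": group,
        }
    )
    df["group_number"] = df["group"].map(GROUP_NUMBER)
    return rank_by_fold(df)


def peaks_from_comparison(df: pd.DataFrame) -> list[Peak]:
    """Union peaks in ranked order, for use as heatmap anchors."""
    peaks = []
    for row in df.itertuples(index=False):
        summit = None if row.summit < 0 else int(row.summit)
        peaks.append(
            Peak(GenomicInterval(row.chrom, int(row.start), int(row.end)),
                 name=row.name, score=float(max(row.cpm_a, row.cpm_b)),
                 summit=summit)
        )
    return peaks
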