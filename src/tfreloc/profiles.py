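"""Anchor-centred signal matrices, average profiles, scaled gene-body
metagene profiles, and genomic-location classification of peaks.
"""

from __future__ import annotations

import gzip
import json
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genomic_io import CoverageTrack, GeneModel, Peak

logger = logging.getLogger(__name__)

__all__ = [
    "AnchorMatrix",
    "MetageneProfile",
    "anchored_matrix",
    "average_profile",
    "metagene",
    "genomic_location",
    "smooth_rows",
]


@dataclass
class AnchorMatrix:
    """Peaks x positional bins signal matrix with a fixed ranked row order.

    Every matrix built from one comparison shares the identical row order,
    so heatmaps of different tracks line up "along the same coordinates".
    Values are mean per-bp signal per bin (CPM-scaled when `normalized`).
    """

    row_order: list[str]
    offsets: np.ndarray  # bin left edges relative to anchor center (bp)
    values: np.ndarray  # (n_rows, n_bins)
    bin_size: int
    flank: int

    @property
    def n_bins(self) -> int:
        return self.values.shape[1]

    def row_index(self, row_ids) -> np.ndarray:
        lookup = {r: i for i, r in enumerate(self.row_order)}
        try:
            return np.array([lookup[r] for r in row_ids], dtype=int)
        except KeyError as exc:
            raise KeyError(f"row {exc.args[0]!r} not in matrix") from exc

    def to_tsv(self, path, sidecar_path=None, params: dict | None = None):
        """Gzipped TSV of the matrix plus a JSON sidecar recording row
        order, bin offsets and parameters."""
        df = pd.DataFrame(self.values, index=self.row_order,
                          columns=self.offsets)
        opener = gzip.open if str(path).endswith(".gz") else open
        with opener(path, "wt") as fh:
            df.to_csv(fh, sep="\t", index_label="row")
        if sidecar_path is not None:
            meta = {
                "row_order": list(self.row_order),
                "offsets": [int(o) for o in self.offsets],
                "bin_size": self.bin_size,
                "flank": self.flank,
            }
            if params:
                meta["params"] = params
            with open(sidecar_path, "w") as fh:
                json.dump(meta, fh, sort_keys=True, indent=1)


@dataclass
class MetageneProfile:
    """Mean signal over genes rescaled to a fixed bin layout: `flank_bins`
    upstream bins at fixed bp resolution, `body_bins` bins spanning the gene
    body regardless of its length, `flank_bins` downstream bins."""

    values: np.ndarray  # (n_bins,) group mean
    per_gene: np.ndarray  # (n_genes, n_bins)
    gene_ids: list[str]
    body_bins: int
    flank_bins: int
    flank: int

    @property
    def n_bins(self) -> int:
        return 2 * self.flank_bins + self.body_bins


def anchored_matrix(track: CoverageTrack, anchors: list[Peak],
                    flank: int = 1000, bin_size: int = 10,
                    normalized: bool = True) -> AnchorMatrix:
    """Signal matrix centred on each anchor's center (summit when present,
    else midpoint), +/- `flank` bp in `bin_size` bp bins.

    Bins falling off a chromosome end are filled with 0.  Row order follows
    the given anchor order (callers pass rank_by_fold / strength-ranked
    anchors).
    """
    if flank % bin_size:
        raise ValueError("flank must be a multiple of bin_size")
    n_bins = 2 * flank // bin_size
    values = np.zeros((len(anchors), n_bins), dtype=np.float64)
    scale = 1e6 / track.library_size if normalized else 1.0
    rel = np.arange(-flank, flank)
    for i, p in enumerate(anchors):
        arr = track.values(p.chrom)
        idx = p.center + rel
        valid = (idx >= 0) & (idx < len(arr))
        vals = np.zeros(2 * flank, dtype=np.float64)
        vals[valid] = arr[idx[valid]]
        values[i] = vals.reshape(n_bins, bin_size).mean(axis=1)
    values *= scale
    offsets = np.arange(-flank, flank, bin_size)
    return AnchorMatrix([p.name for p in anchors], offsets, values,
                        bin_size, flank)


def average_profile(matrix: AnchorMatrix, rows=None) -> np.ndarray:
    """Column means over a row subset (all rows when `rows is None`).

    `rows` may be row ids, integer indices, or a boolean mask.  Subsetting
    by specificity group gives the per-group average profiles."""
    if rows is None:
        sub = matrix.values
    else:
        rows = np.asarray(rows)
        if rows.dtype == bool:
            if rows.size != len(matrix.row_order):
                raise ValueError("boolean mask length mismatch")
            sub = matrix.values[rows]
        elif np.issubdtype(rows.dtype, np.integer):
            sub = matrix.values[rows]
        else:
            sub = matrix.values[matrix.row_index(rows)]
    if sub.shape[0] == 0:
        raise ValueError("empty row subset")
    return sub.mean(axis=0)


def smooth_rows(values: np.ndarray, window: int = 50) -> np.ndarray:
    """Display-only rolling mean over ranked rows (never used in
    statistics)."""
    from scipy.ndimage import uniform_filter1d

    return uniform_filter1d(values, size=min(window, values.shape[0]),
                            axis=0, mode="nearest")


def _scaled_body_bins(arr: np.ndarray, start: int, end: int,
                      body_bins: int) -> np.ndarray:
    """Mean per-bp signal of [start, end) linearly rescaled onto
    `body_bins` bins."""
    L = end - start
    cuts = start + np.round(np.linspace(0, L, body_bins + 1)).astype(int)
    cum = np.concatenate(([0.0], np.cumsum(arr[start:end], dtype=np.float64)))
    lo = cuts - start
    sums = cum[lo[1:]] - cum[lo[:-1]]
    widths = np.diff(cuts)
    return sums / widths


def metagene(track: CoverageTrack, genes: list[GeneModel],
             body_bins: int = 100, flank: int = 2000, flank_bins: int = 20,
             normalized: bool = True) -> MetageneProfile:
    """Strand-aware metagene profile: fixed-resolution flanks around a gene
    body rescaled to `body_bins` bins; the group profile is the mean over
    genes.

    Genes shorter than `body_bins` bp are skipped with a logged warning.
    Flank bins beyond chromosome ends read as 0.
    """
    if flank % flank_bins:
        raise ValueError("flank must be a multiple of flank_bins")
    fb = flank // flank_bins
    scale = 1e6 / track.library_size if normalized else 1.0
    rows, kept = [], []
    for g in genes:
        L = g.interval.length
        if L < body_bins:
            logger.warning("gene %s (%d bp) shorter than body_bins=%d; skipped",
                           g.gene_id, L, body_bins)
            continue
        arr = track.values(g.chrom)
        n = len(arr)

        def flank_vals(lo):
            idx = lo + np.arange(flank)
            valid = (idx >= 0) & (idx < n)
            v = np.zeros(flank, dtype=np.float64)
            v[valid] = arr[idx[valid]]
            return v.reshape(flank_bins, fb).mean(axis=1)

        up = flank_vals(g.interval.start - flank)
        body = _scaled_body_bins(arr, g.interval.start, g.interval.end,
                                 body_bins)
        down = flank_vals(g.interval.end)
        prof = np.concatenate([up, body, down])
        if g.strand == "-":
            prof = prof[::-1]
        rows.append(prof * scale)
        kept.append(g.gene_id)
    per_gene = (np.array(rows) if rows
                else np.empty((0, 2 * flank_bins + body_bins)))
    mean = (per_gene.mean(axis=0) if len(rows)
            else np.zeros(2 * flank_bins + body_bins))
    return MetageneProfile(mean, per_gene, kept, body_bins, flank_bins, flank)


def genomic_location(peaks: list[Peak], genes: list[GeneModel],
                     promoter_window: int = 2000) -> pd.DataFrame:
    """Per-peak location labels and the proximal/distal split.

    proximal (= promoter): peak center within +/- promoter_window of any
    TSS; else intragenic if the center lies inside any gene span, else
    intergenic.  distal = not proximal.
    """
    tss_by_chrom: dict[str, np.ndarray] = {}
    spans_by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for g in genes:
        tss_by_chrom.setdefault(g.chrom, []).append(g.tss)
        spans_by_chrom.setdefault(g.chrom, []).append(
            (g.interval.start, g.interval.end)
        )
    tss_by_chrom = {c: np.sort(np.array(v)) for c, v in tss_by_chrom.items()}
    spans_sorted = {}
    for c, v in spans_by_chrom.items():
        starts = np.array(sorted(s for s, _ in v))
        # max end among genes with start <= x, via running max on sorted starts
        order = np.argsort([s for s, _ in v], kind="mergesort")
        ends = np.array([v[i][1] for i in order])
        run_max_end = np.maximum.accumulate(ends)
        spans_sorted[c] = (starts, run_max_end)

    records = []
    for p in peaks:
        c = p.center
        proximal = False
        if p.chrom in tss_by_chrom:
            tss = tss_by_chrom[p.chrom]
            j = np.searchsorted(tss, c)
            dmin = min(
                abs(c - tss[j - 1]) if j > 0 else np.inf,
                abs(tss[j] - c) if j < len(tss) else np.inf,
            )
            proximal = dmin <= promoter_window
        if proximal:
            location = "promoter"
        else:
            intragenic = False
            if p.chrom in spans_sorted:
                starts, run_max_end = spans_sorted[p.chrom]
                j = np.searchsorted(starts, c, side="right")
                intragenic = j > 0 and run_max_end[j - 1] > c
            location = "intragenic" if intragenic else "intergenic"
        records.append((p.name, p.chrom, c, proximal, location))
    df = pd.DataFrame(
        records, columns=["name", "chrom", "center", "proximal", "location"]
    )
    df["proximal_distal"] = np.where(df["proximal"], "proximal", "distal")
    return df


def location_fractions(location_df: pd.DataFrame) -> dict[str, float]:
    n = len(location_df)
    if n == 0:
        return {}
    out = {"proximal": float(location_df["proximal"].mean()),
           "distal": float(1 - location_df["proximal"].mean())}
    for label in ("promoter", "intragenic", "intergenic"):
        out[label] = float((location_df["location"] == label).mean())
    return out
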