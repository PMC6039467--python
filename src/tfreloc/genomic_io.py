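"""Readers and writers for the genomic formats the pipeline touches.

All coordinates are 0-based half-open internally.  Conversion to 1-based
happens only at report boundaries (none of the formats here need it:
BED/bedGraph are already 0-based half-open).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import SeqIO, motifs as bio_motifs
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "GenomicInterval",
    "Peak",
    "GeneModel",
    "CoverageTrack",
    "PWM",
    "read_bed",
    "write_bed",
    "read_bedgraph",
    "write_bedgraph",
    "read_fasta",
    "write_fasta",
    "read_gene_table",
    "write_gene_table",
    "read_pfm",
]

BASES = "ACGT"


class FileFormatError(ValueError):
    """Raised for malformed input files; message names file and line."""


@dataclass(frozen=True)
class GenomicInterval:
    """A half-open genomic span: [start, end) on `chrom`."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self):
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class Peak:
    """A ChIP-seq peak: an interval with optional summit and a score.

    `summit` is a bp offset from `interval.start`; the peak *center* used by
    anchor-centred analyses is the summit when present, else the midpoint.
    """

    interval: GenomicInterval
    name: str = "."
    score: float = 0.0
    summit: int | None = None

    def __post_init__(self):
        if self.score < 0:
            raise ValueError("peak score must be nonnegative")
        if self.summit is not None and not (
            0 <= self.summit < self.interval.length
        ):
            raise ValueError(
                f"summit {self.summit} outside peak of length "
                f"{self.interval.length}"
            )

    @property
    def center(self) -> int:
        if self.summit is not None:
            return self.interval.start + self.summit
        return self.interval.midpoint

    @property
    def chrom(self) -> str:
        return self.interval.chrom

    @property
    def start(self) -> int:
        return self.interval.start

    @property
    def end(self) -> int:
        return self.interval.end


@dataclass(frozen=True)
class GeneModel:
    """A gene span with a strand-aware transcription start site."""

    gene_id: str
    interval: GenomicInterval
    strand: str

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene strand must be + or -, got {self.strand!r}")

    @property
    def tss(self) -> int:
        return self.interval.start if self.strand == "+" else self.interval.end - 1

    @property
    def chrom(self) -> str:
        return self.interval.chrom


@dataclass
class CoverageTrack:
    """Per-chromosome base-resolution signal with a library size.

    `library_size` is the total raw fragment count used for CPM scaling;
    when unknown (e.g. a bedGraph of unknown provenance) it defaults to the
    total signal, which preserves relative comparisons between tracks
    normalised the same way.
    """

    data: dict[str, np.ndarray]
    resolution: int = 1
    library_size: float | None = None

    def __post_init__(self):
        for chrom, arr in self.data.items():
            if np.any(arr < 0):
                raise ValueError(f"negative signal on {chrom}")
        if self.library_size is None:
            self.library_size = float(
                sum(float(a.sum()) for a in self.data.values())
            )
        if self.library_size <= 0:
            self.library_size = 1.0  # empty track; CPM stays 0 everywhere

    def chroms(self) -> list[str]:
        return list(self.data)

    def chrom_length(self, chrom: str) -> int:
        return int(len(self.data[chrom]) * self.resolution)

    def values(self, chrom: str) -> np.ndarray:
        if chrom not in self.data:
            raise KeyError(f"chromosome {chrom!r} absent from track")
        return self.data[chrom]

    def window_sum(self, chrom: str, start: int, end: int) -> float:
        """Sum of signal in [start, end), clipped at chromosome ends."""
        arr = self.values(chrom)
        lo = max(0, start)
        hi = min(len(arr), end)
        if hi <= lo:
            return 0.0
        return float(arr[lo:hi].sum(dtype=np.float64))

    @property
    def total_signal(self) -> float:
        return float(sum(float(a.sum()) for a in self.data.values()))


@dataclass(frozen=True)
class PWM:
    """A position probability matrix over A, C, G, T with a background."""

    name: str
    matrix: np.ndarray  # (length, 4) probabilities
    background: np.ndarray = field(
        default_factory=lambda: np.full(4, 0.25)
    )

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[1] != 4:
            raise ValueError("PWM matrix must be (length, 4)")
        if not np.allclose(m.sum(axis=1), 1.0, atol=1e-6):
            raise ValueError(f"PWM {self.name}: rows must sum to 1")
        bg = np.asarray(self.background, dtype=float)
        if not np.isclose(bg.sum(), 1.0, atol=1e-6):
            raise ValueError("background must sum to 1")
        object.__setattr__(self, "matrix", m)
        object.__setattr__(self, "background", bg)

    def __len__(self) -> int:
        return self.matrix.shape[0]

    @property
    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.matrix.argmax(axis=1))


# ---------------------------------------------------------------------------
# BED / narrowPeak


def read_bed(path) -> list[Peak]:
    """Read BED3/BED6/narrowPeak into Peaks.

    narrowPeak (10 columns) supplies the summit from the 10th column
    (-1 means no summit).
    """
    peaks: list[Peak] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FileFormatError(f"{path}:{lineno}: expected >=3 columns")
            try:
                chrom = fields[0]
                start, end = int(fields[1]), int(fields[2])
                name = fields[3] if len(fields) > 3 else "."
                score = float(fields[4]) if len(fields) > 4 else 0.0
                strand = fields[5] if len(fields) > 5 else "."
                summit = None
                if len(fields) >= 10:
                    s = int(fields[9])
                    summit = s if s >= 0 else None
                peaks.append(
                    Peak(GenomicInterval(chrom, start, end, strand),
                         name=name, score=score, summit=summit)
                )
            except (ValueError, IndexError) as exc:
                raise FileFormatError(f"{path}:{lineno}: {exc}") from exc
    return peaks


def _fmt_score(score: float) -> str:
    return str(int(score)) if float(score).is_integer() else repr(float(score))


def write_bed(peaks, path, narrowpeak: bool = False) -> None:
    """Write BED6 (or narrowPeak when `narrowpeak`, preserving summits)."""
    with open(path, "w") as fh:
        for p in peaks:
            cols = [p.chrom, str(p.start), str(p.end), p.name,
                    _fmt_score(p.score), p.interval.strand]
            if narrowpeak:
                cols += ["0", "-1", "-1",
                         str(p.summit if p.summit is not None else -1)]
            fh.write("\t".join(cols) + "\n")


# ---------------------------------------------------------------------------
# bedGraph


def read_bedgraph(path, chrom_sizes: dict[str, int] | None = None,
                  library_size: float | None = None) -> CoverageTrack:
    """Read a bedGraph into a base-resolution CoverageTrack.

    Gaps read as 0.  Overlapping intervals are an error (a bedGraph is a
    function of position, not a pile-up).
    """
    spans: dict[str, list[tuple[int, int, float]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise FileFormatError(f"{path}:{lineno}: expected 4 columns")
            try:
                chrom, start, end, value = (
                    fields[0], int(fields[1]), int(fields[2]), float(fields[3])
                )
            except ValueError as exc:
                raise FileFormatError(f"{path}:{lineno}: {exc}") from exc
            if end <= start:
                raise FileFormatError(f"{path}:{lineno}: end <= start")
            spans.setdefault(chrom, []).append((start, end, value))

    data: dict[str, np.ndarray] = {}
    for chrom, items in spans.items():
        items.sort()
        last_end = -1
        for start, end, _ in items:
            if start < last_end:
                raise FileFormatError(
                    f"{path}: overlapping bedGraph intervals on {chrom} "
                    f"at {start}"
                )
            last_end = end
        length = items[-1][1]
        if chrom_sizes and chrom in chrom_sizes:
            length = max(length, chrom_sizes[chrom])
        arr = np.zeros(length, dtype=np.float32)
        for start, end, value in items:
            arr[start:end] = value
        data[chrom] = arr
    if chrom_sizes:
        for chrom, size in chrom_sizes.items():
            if chrom not in data:
                data[chrom] = np.zeros(size, dtype=np.float32)
    return CoverageTrack(data, library_size=library_size)


def write_bedgraph(track: CoverageTrack, path) -> None:
    """Write a CoverageTrack as bedGraph, run-length encoded, zeros omitted."""
    if track.resolution != 1:
        raise ValueError("only base-resolution tracks are written as bedGraph")
    with open(path, "w") as fh:
        for chrom in track.chroms():
            arr = np.asarray(track.values(chrom), dtype=np.float64)
            if arr.size == 0:
                continue
            change = np.flatnonzero(np.diff(arr)) + 1
            starts = np.concatenate(([0], change))
            ends = np.concatenate((change, [arr.size]))
            vals = arr[starts]
            for s, e, v in zip(starts, ends, vals):
                if v != 0.0:
                    fh.write(f"{chrom}\t{s}\t{e}\t{v:g}\n")


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: dict[str, str], path, width: int = 60) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="")
        for name, seq in sequences.items()
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


# ---------------------------------------------------------------------------
# Gene tables (TSV with header)

GENE_TABLE_COLUMNS = ["gene_id", "chrom", "start", "end", "strand", "tss"]


def read_gene_table(path) -> list[GeneModel]:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in GENE_TABLE_COLUMNS[:5] if c not in df.columns]
    if missing:
        raise FileFormatError(f"{path}: missing columns {missing}")
    genes = []
    for row in df.itertuples(index=False):
        gene = GeneModel(
            str(row.gene_id),
            GenomicInterval(str(row.chrom), int(row.start), int(row.end),
                            str(row.strand)),
            str(row.strand),
        )
        if hasattr(row, "tss") and int(row.tss) != gene.tss:
            raise FileFormatError(
                f"{path}: gene {gene.gene_id} tss column inconsistent with "
                f"strand convention (expected {gene.tss})"
            )
        genes.append(gene)
    return genes


def write_gene_table(genes, path) -> None:
    df = pd.DataFrame(
        [
            (g.gene_id, g.chrom, g.interval.start, g.interval.end,
             g.strand, g.tss)
            for g in genes
        ],
        columns=GENE_TABLE_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# JASPAR PFMs

PFM_PSEUDOCOUNT = 0.25  # per cell, added before normalisation


def read_pfm(path, pseudocount: float = PFM_PSEUDOCOUNT,
             background=None) -> list[PWM]:
    """Read JASPAR-format PFM text into probability PWMs.

    Counts are converted with a per-cell pseudocount:
    p = (c + pseudocount) / (col_total + 4 * pseudocount), which keeps every
    probability strictly positive so log-odds scores stay finite.
    """
    with open(path) as fh:
        return _parse_pfm_text(fh.read(), pseudocount, background)


def load_bundled_motifs(pseudocount: float = PFM_PSEUDOCOUNT) -> dict[str, PWM]:
    """The PFMs shipped with the package (RUNX, ETS, GATA, AP1, TEAD and the
    ETS::RUNX composite), keyed by name."""
    from importlib.resources import files

    text = files("tfreloc.data").joinpath("motifs.jaspar").read_text()
    return {p.name: p for p in _parse_pfm_text(text, pseudocount, None)}


def _parse_pfm_text(text: str, pseudocount: float, background) -> list[PWM]:
    bg = np.full(4, 0.25) if background is None else np.asarray(background, float)
    with io.StringIO(text) as fh:
        records = bio_motifs.parse(fh, "jaspar")
    pwms = []
    for rec in records:
        counts = np.array([rec.counts[b] for b in BASES], dtype=float).T
        totals = counts.sum(axis=1, keepdims=True)
        probs = (counts + pseudocount) / (totals + 4 * pseudocount)
        pwms.append(PWM(name=rec.name or rec.matrix_id, matrix=probs,
                        background=bg))
    return pwms
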