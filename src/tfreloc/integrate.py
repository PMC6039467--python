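"""Three-set peak-overlap grouping (Venn Groups 1-5), nearest-TSS peak-to-
gene assignment, cross-tabulation with expression responses, and the
relocation estimate.

The three sets are, in the relocation analysis: A = the mobile factor
(FLI1-like) before induction, B = the same factor after induction, C = the
induced factor (RUNX1-like) after induction — all restricted to distal
peaks.  Venn regions are computed on merged union loci so one genomic locus
counts once however many raw peaks cover it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genomic_io import GeneModel, Peak
from .peak_compare import merge_peaks

__all__ = [
    "DEFAULT_GROUP_MAP",
    "VennResult",
    "venn_groups",
    "assign_genes",
    "cross_tab",
    "relocation_estimate",
]

# region pattern "abc" (1 = locus overlaps that set) -> group label
DEFAULT_GROUP_MAP = {
    "100": "G1",  # A only: binding lost on induction
    "110": "G2",  # A and B, no C: retained, independent of the induced factor
    "111": "G3",  # all three: retained and joined by the induced factor
    "011": "G4",  # B and C, no A: de novo binding at induced-factor sites
    "001": "G5",  # C only: induced factor alone
    "101": "A_C_unlabelled",  # residual regions, reported but unlabelled
    "010": "B_unlabelled",
}

GROUPS_1_TO_5 = ("G1", "G2", "G3", "G4", "G5")


@dataclass
class VennResult:
    loci: pd.DataFrame  # one row per union locus
    group_map: dict[str, str]
    set_names: tuple[str, str, str]

    def members(self, group: str) -> pd.DataFrame:
        return self.loci[self.loci["group"] == group]

    @property
    def counts(self) -> dict[str, int]:
        c = {g: 0 for g in set(self.group_map.values())}
        c.update(self.loci["group"].value_counts().to_dict())
        return c

    def member_peaks(self, group: str) -> list[Peak]:
        from .genomic_io import GenomicInterval

        return [
            Peak(GenomicInterval(r.chrom, int(r.start), int(r.end)),
                 name=r.name)
            for r in self.members(group).itertuples(index=False)
        ]


def _overlaps_any(loci: list[Peak], peaks: list[Peak]) -> np.ndarray:
    """Boolean per locus: does it intersect (>=1 bp) any peak in the set."""
    out = np.zeros(len(loci), dtype=bool)
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for p in peaks:
        by_chrom.setdefault(p.chrom, []).append((p.start, p.end))
    merged_by_chrom = {}
    for chrom, ivs in by_chrom.items():
        ivs.sort()
        starts = np.array([s for s, _ in ivs])
        run_max_end = np.maximum.accumulate(np.array([e for _, e in ivs]))
        merged_by_chrom[chrom] = (starts, run_max_end)
    for i, locus in enumerate(loci):
        if locus.chrom not in merged_by_chrom:
            continue
        starts, run_max_end = merged_by_chrom[locus.chrom]
        j = np.searchsorted(starts, locus.end, side="left")
        out[i] = j > 0 and run_max_end[j - 1] > locus.start
    return out


def venn_groups(peaks_a: list[Peak], peaks_b: list[Peak],
                peaks_c: list[Peak],
                group_map: dict[str, str] | None = None,
                set_names: tuple[str, str, str] = ("A", "B", "C"),
                ) -> VennResult:
    """Three-set Venn on merged union loci; overlap = >= 1 bp intersection.

    Each union locus gets a membership pattern over the three input sets and
    the group label the (configurable) mapping assigns to that pattern.
    """
    gmap = dict(DEFAULT_GROUP_MAP if group_map is None else group_map)
    loci = merge_peaks(peaks_a, peaks_b, peaks_c)
    in_a = _overlaps_any(loci, peaks_a)
    in_b = _overlaps_any(loci, peaks_b)
    in_c = _overlaps_any(loci, peaks_c)
    patterns = [
        f"{int(a)}{int(b)}{int(c)}" for a, b, c in zip(in_a, in_b, in_c)
    ]
    df = pd.DataFrame(
        {
            "name": [p.name for p in loci],
            "chrom": [p.chrom for p in loci],
            "start": [p.start for p in loci],
            "end": [p.end for p in loci],
            "in_a": in_a,
            "in_b": in_b,
            "in_c": in_c,
            "pattern": patterns,
        }
    )
    df["group"] = df["pattern"].map(gmap)
    return VennResult(df, gmap, set_names)


def assign_genes(peaks: list[Peak], genes: list[GeneModel],
                 max_distance: int = 100_000) -> pd.DataFrame:
    """Assign each peak to the gene with the nearest TSS (center-to-TSS
    distance) within `max_distance`; ties go to the lexicographically
    smaller gene_id.  Unassigned peaks carry gene_id None."""
    by_chrom: dict[str, list[tuple[int, str]]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append((g.tss, g.gene_id))
    sorted_by_chrom = {
        c: sorted(v) for c, v in by_chrom.items()
    }
    records = []
    for p in peaks:
        best_gene, best_d = None, None
        entries = sorted_by_chrom.get(p.chrom)
        if entries:
            tss = np.array([t for t, _ in entries])
            c = p.center
            j = np.searchsorted(tss, c)
            candidates = []
            if j > 0:
                candidates.append(j - 1)
            if j < len(tss):
                candidates.append(j)
            # widen to catch equidistant neighbours with equal TSS values
            dists = {k: abs(int(tss[k]) - c) for k in candidates}
            dmin = min(dists.values())
            tied = [entries[k][1] for k, d in dists.items() if d == dmin]
            # equal-TSS duplicates around j
            lo = np.searchsorted(tss, c - dmin, side="left")
            hi = np.searchsorted(tss, c + dmin, side="right")
            tied = [entries[k][1] for k in range(lo, hi)
                    if abs(int(tss[k]) - c) == dmin]
            if dmin <= max_distance:
                best_gene = min(tied)
                best_d = dmin
        records.append((p.name, p.chrom, p.center, best_gene, best_d))
    return pd.DataFrame(
        records, columns=["name", "chrom", "center", "gene_id", "distance"]
    )


def cross_tab(venn: VennResult, assignment: pd.DataFrame,
              codes: dict[str, str], differential: set[str],
              groups=GROUPS_1_TO_5) -> pd.DataFrame:
    """Per Venn group: member peak count, assigned genes (deduplicated —
    a gene counts once per group however many member peaks map to it),
    differential-gene count, and a histogram of response codes.

    Genes may appear in several groups (peaks at one gene can fall in more
    than one Venn region)."""
    gene_of = dict(zip(assignment["name"], assignment["gene_id"]))
    rows = []
    all_codes = sorted({c for c in codes.values()})
    for grp in groups:
        members = venn.members(grp)
        genes = {
            gene_of.get(n) for n in members["name"]
        } - {None, np.nan}
        genes = {g for g in genes if isinstance(g, str)}
        n_diff = len(genes & differential)
        hist = {f"code_{c}": 0 for c in all_codes}
        for g in genes:
            code = codes.get(g)
            if code is not None:
                hist[f"code_{code}"] += 1
        rows.append({"group": grp, "n_peaks": int(len(members)),
                     "n_genes": len(genes),
                     "n_differential_genes": n_diff, **hist})
    return pd.DataFrame(rows)


def relocation_estimate(venn: VennResult) -> dict[str, float]:
    """Estimate the fraction of the mobile factor's pre-induction sites
    whose occupancy moved to induced-factor sites.

    Two truth-free views of the same quantity:
      loss-based  |G1| / (|G1| + |G2|) — fraction of the factor's own sites
                  (never co-bound by the induced factor) that it left;
      gain-based  |G4| / (|G4| + |G2|) — de novo sites at induced-factor
                  loci against the retained own sites.
    The reported estimate is their mean.
    """
    c = venn.counts
    g1, g2, g4 = c.get("G1", 0), c.get("G2", 0), c.get("G4", 0)
    loss = g1 / (g1 + g2) if (g1 + g2) else float("nan")
    gain = g4 / (g4 + g2) if (g4 + g2) else float("nan")
    est = float(np.nanmean([loss, gain]))
    return {"loss_based": loss, "gain_based": gain, "estimate": est}
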