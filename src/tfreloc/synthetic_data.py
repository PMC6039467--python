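"""Synthetic factor-relocation scenario with known ground truth.

The generator builds a toy genome carrying regulatory sites of five classes
(ETS+GATA enhancers, ETS+RUNX composite enhancers, RUNX-only sites, TEAD
sites and constitutive promoters), plants consensus motif instances at each
site, and simulates four-condition ChIP coverage for four tracks:

* FLI1  — the mobile ETS factor.  Bound at ETS/GATA enhancers before
  induction; on induction of RUNX1 a configurable fraction of those sites
  lose FLI1 and the displaced occupancy appears de novo at ETS::RUNX
  composite sites (the relocation the pipeline must recover).  The BET
  inhibitor (JQ1) condition blocks relocation.
* RUNX1 — the induced factor; absent in un-induced conditions, bound at
  RUNX-motif sites when induced; with JQ1 it loses the relocated-to sites
  and gains TEAD sites (the aberrant state).
* CDK9  — a co-factor that follows FLI1/RUNX1 co-occupancy, plus a weak
  basal presence at promoters.
* H3K79me2 — an elongation mark over gene bodies, scaled per condition by
  the gene's true expression level.

Gene expression follows negative-binomial counts whose condition means
realise a known two-character 0/1/2 response code per gene.  Everything is
a pure function of the seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genomic_io import (
    BASES,
    CoverageTrack,
    GeneModel,
    GenomicInterval,
    Peak,
    load_bundled_motifs,
)

logger = logging.getLogger(__name__)

__all__ = [
    "ScenarioConfig",
    "ScenarioTruth",
    "Scenario",
    "SizingError",
    "build_genome",
    "simulate_tracks",
    "simulate_expression",
    "CONDITIONS",
    "FACTORS",
]

CONDITIONS = ("noDox", "Dox", "noDox_JQ1", "Dox_JQ1")
FACTORS = ("FLI1", "RUNX1", "CDK9", "H3K79me2")
TF_FACTORS = ("FLI1", "RUNX1", "CDK9")

DEFAULT_CLASS_FRACTIONS = {
    "ETS_GATA": 0.30,
    "ETS_RUNX": 0.30,
    "RUNX_only": 0.15,
    "TEAD": 0.15,
    "promoter": 0.10,
}

# subclass -> cycle of true response codes for linked genes
DEFAULT_COUPLING = {
    "EG_reloc": ("01", "02"),  # repressed on induction; JQ1 reverses or not
    "EG_stay": ("22",),  # untouched enhancers -> unchanged genes
    "ER_target": ("10",),  # induced, JQ1-sensitive (the flagship group)
    "ER_prebound": ("12",),  # induced, JQ1-insensitive
    "ER_other": ("11",),  # induced and further up on JQ1
    "RUNX_only": ("00", "20"),
    "TEAD": ("21",),  # unchanged until JQ1
}

STRENGTH_LEVELS = (0.5, 1.0, 2.0)


class SizingError(ValueError):
    """The requested sites + genes do not fit in the genome."""


@dataclass
class ScenarioConfig:
    genome_length: int = 10_000_000
    n_chromosomes: int = 2
    n_genes: int = 300
    n_sites: int = 2000
    site_class_fractions: dict = field(
        default_factory=lambda: dict(DEFAULT_CLASS_FRACTIONS)
    )
    relocation_fraction: float = 0.6
    prebound_fraction: float = 0.25  # of ETS_RUNX sites FLI1-bound throughout
    conditions: tuple = CONDITIONS
    depth_per_site: float = 30.0
    fragment_length: int = 200
    background_rate: float = 0.1  # fragments per kb
    site_width: int = 300
    gene_length: int = 6000
    gene_spacing: int = 20_000  # genomic unit hosting a gene + its enhancer
    site_spacing: int = 2500  # genomic unit hosting a lone site
    n_background_genes: int = 2100  # stable transcriptome, own chromosome
    background_gene_length: int = 1500
    n_replicates: int = 3
    dispersion: float = 0.05  # NB dispersion of expression counts
    expression_fold: float = 4.0  # realised effect for coded comparisons
    base_mean: float = 500.0  # mean counts of an average gene
    expression_sigma: float = 0.5  # lognormal spread of base means
    expression_coupling: dict = field(
        default_factory=lambda: {k: tuple(v) for k, v in
                                 DEFAULT_COUPLING.items()}
    )
    seed: int = 0

    def validate(self) -> None:
        fr = self.site_class_fractions
        if abs(sum(fr.values()) - 1.0) > 1e-9:
            raise ValueError("site_class_fractions must sum to 1")
        if any(f < 0 for f in fr.values()):
            raise ValueError("site_class_fractions must be nonnegative")
        if not (0.0 <= self.relocation_fraction <= 1.0):
            raise ValueError("relocation_fraction must be in [0, 1]")
        if min(self.genome_length, self.n_chromosomes, self.n_genes,
               self.n_sites, self.fragment_length) <= 0:
            raise ValueError("all counts must be > 0")
        if self.genome_length < self.n_sites * 10 * self.fragment_length:
            raise SizingError(
                "genome too small: need genome_length >= "
                "n_sites * 10 * fragment_length"
            )
        counts = _class_counts(self.n_sites, fr)
        n_promoter = counts.get("promoter", 0)
        if n_promoter > self.n_genes:
            raise SizingError(
                f"{n_promoter} promoter-class sites but only "
                f"{self.n_genes} genes to host them"
            )
        n_distal = self.n_sites - n_promoter
        if self.n_genes > n_distal:
            raise SizingError("more genes than distal sites to link them to")
        needed = (self.n_genes * self.gene_spacing
                  + (n_distal - self.n_genes) * self.site_spacing)
        if needed > self.genome_length:
            raise SizingError(
                f"layout needs {needed} bp but genome is "
                f"{self.genome_length} bp"
            )
        if self.gene_length + 2 * self.site_width >= self.gene_spacing:
            raise SizingError("gene_spacing too small for gene_length")


@dataclass
class ScenarioTruth:
    """Ground truth: per-site classes/occupancy, per-gene codes and
    condition means, and the realised relocation fraction."""

    site_table: pd.DataFrame
    gene_table: pd.DataFrame
    true_relocation_fraction: float

    def to_json(self, path) -> None:
        payload = {
            "site_table": self.site_table.to_dict(orient="records"),
            "gene_table": self.gene_table.to_dict(orient="records"),
            "true_relocation_fraction": self.true_relocation_fraction,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, sort_keys=True, indent=1)

    @classmethod
    def from_json(cls, path) -> "ScenarioTruth":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            pd.DataFrame(payload["site_table"]),
            pd.DataFrame(payload["gene_table"]),
            float(payload["true_relocation_fraction"]),
        )

    def differential_genes(self) -> set[str]:
        gt = self.gene_table
        return set(gt.loc[gt["true_code"] != "22", "gene_id"])


@dataclass
class Scenario:
    config: ScenarioConfig
    sequences: dict[str, np.ndarray]  # chrom -> int8 base codes
    genes: list[GeneModel]
    truth: ScenarioTruth

    _genome_cache: dict | None = None

    def genome(self) -> dict[str, str]:
        """Sequences as strings (cached)."""
        if self._genome_cache is None:
            lut = np.frombuffer("".join(BASES).encode(), dtype=np.uint8)
            self._genome_cache = {
                c: lut[codes].tobytes().decode("ascii")
                for c, codes in self.sequences.items()
            }
        return self._genome_cache

    def chrom_sizes(self) -> dict[str, int]:
        return {c: len(s) for c, s in self.sequences.items()}


def _class_counts(n_sites: int, fractions: dict) -> dict[str, int]:
    """Largest-remainder apportionment of sites to classes."""
    names = sorted(fractions)
    exact = np.array([fractions[k] * n_sites for k in names])
    base = np.floor(exact).astype(int)
    rem = n_sites - base.sum()
    order = np.argsort(-(exact - base), kind="mergesort")
    for i in order[:rem]:
        base[i] += 1
    return {k: int(c) for k, c in zip(names, base) if c > 0}


def _apportion(n: int, weights: dict[str, int]) -> dict[str, int]:
    total = sum(weights.values())
    names = sorted(weights)
    exact = np.array([weights[k] * n / total for k in names])
    base = np.floor(exact).astype(int)
    rem = n - base.sum()
    order = np.argsort(-(exact - base), kind="mergesort")
    for i in order[:rem]:
        base[i] += 1
    return dict(zip(names, base.tolist()))


# planted motif layout per class: (pwm_name, start offset from site center)
def _plant_plan(cls: str, subclass: str, rng) -> list[tuple[str, int]]:
    plan = []
    if cls == "ETS_GATA":
        plan += [("ETS", -30), ("GATA", 15)]
        if rng.random() < 0.5:
            plan.append(("AP1", 40))
    elif cls == "ETS_RUNX":
        plan.append(("ETS_RUNX", -9))
        if rng.random() < 0.3:
            plan.append(("AP1", 25))
    elif cls == "RUNX_only":
        plan.append(("RUNX", -4))
    elif cls == "TEAD":
        plan.append(("TEAD", -4))
    elif cls == "promoter":
        plan.append(("ETS", -5))
    return plan


def build_genome(config: ScenarioConfig) -> Scenario:
    """Deterministically build genome sequence, gene models, site catalogue
    and the full ground-truth tables for a ScenarioConfig."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    pwms = load_bundled_motifs()
    consensus_codes = {
        name: np.array([BASES.index(b) for b in p.consensus], dtype=np.int8)
        for name, p in pwms.items()
    }

    # --- site classes and subclasses -------------------------------------
    counts = _class_counts(config.n_sites, config.site_class_fractions)
    classes = np.array(
        [c for c, n in sorted(counts.items()) for _ in range(n)], dtype=object
    )
    classes = classes[rng.permutation(config.n_sites)]

    eg_idx = np.flatnonzero(classes == "ETS_GATA")
    er_idx = np.flatnonzero(classes == "ETS_RUNX")
    n_reloc = int(round(config.relocation_fraction * len(eg_idx)))
    reloc_idx = rng.choice(eg_idx, size=n_reloc, replace=False) if n_reloc else \
        np.array([], dtype=int)
    n_pre = int(round(config.prebound_fraction * len(er_idx)))
    pre_idx = rng.choice(er_idx, size=n_pre, replace=False) if n_pre else \
        np.array([], dtype=int)
    free_er = np.setdiff1d(er_idx, pre_idx)
    if n_reloc > len(free_er):
        raise SizingError(
            f"{n_reloc} relocating sites but only {len(free_er)} free "
            "ETS_RUNX sites to relocate to"
        )
    target_idx = (rng.choice(free_er, size=n_reloc, replace=False)
                  if n_reloc else np.array([], dtype=int))

    subclass = np.empty(config.n_sites, dtype=object)
    for i, cls in enumerate(classes):
        subclass[i] = {"ETS_GATA": "EG_stay", "ETS_RUNX": "ER_other"}.get(
            cls, cls
        )
    subclass[reloc_idx] = "EG_reloc"
    subclass[pre_idx] = "ER_prebound"
    subclass[target_idx] = "ER_target"

    strength = rng.choice(STRENGTH_LEVELS, size=config.n_sites)

    # --- gene-to-site linkage (stratified over distal subclasses) --------
    distal_mask = classes != "promoter"
    distal_sub = {
        s: np.flatnonzero(distal_mask & (subclass == s))
        for s in sorted(set(subclass[distal_mask]))
    }
    quota = _apportion(config.n_genes,
                       {s: len(v) for s, v in distal_sub.items()})
    linked_sites: list[int] = []
    for s in sorted(quota):
        take = quota[s]
        if take:
            linked_sites.extend(
                sorted(rng.choice(distal_sub[s], size=take, replace=False))
            )
    linked_sites = list(rng.permutation(np.array(linked_sites, dtype=int)))

    # --- layout: pack units onto chromosomes ------------------------------
    chrom_len = config.genome_length // config.n_chromosomes
    chrom_names = [f"chr{i + 1}" for i in range(config.n_chromosomes)]
    distal_order = [i for i in range(config.n_sites) if distal_mask[i]]
    linked_set = set(int(i) for i in linked_sites)
    # interleave gene units among lone-site units deterministically via a
    # seeded permutation of all distal units
    distal_order = list(np.array(distal_order)[rng.permutation(len(distal_order))])

    site_center = np.full(config.n_sites, -1, dtype=np.int64)
    site_chrom = np.empty(config.n_sites, dtype=object)
    gene_rows = []  # (gene_id assigned later) per linked site
    gene_of_site: dict[int, dict] = {}

    hw = config.site_width // 2
    chrom_i, cursor = 0, 0
    for site in distal_order:
        width = config.gene_spacing if site in linked_set else \
            config.site_spacing
        while cursor + width > chrom_len:
            chrom_i += 1
            cursor = 0
            if chrom_i >= config.n_chromosomes:
                raise SizingError("units do not fit on the chromosomes")
        chrom = chrom_names[chrom_i]
        if site in linked_set:
            site_center[site] = cursor + 2000
            gstart = cursor + 8000
            gend = gstart + config.gene_length
            strand = "+" if rng.random() < 0.5 else "-"
            gene_of_site[site] = {
                "chrom": chrom, "start": gstart, "end": gend,
                "strand": strand,
                "tss": gstart if strand == "+" else gend - 1,
            }
        else:
            site_center[site] = cursor + width // 2
        site_chrom[site] = chrom
        cursor += width

    # promoter-class sites sit at gene TSSs (constitutive promoter binding)
    promoter_sites = [i for i in range(config.n_sites) if not distal_mask[i]]
    host_sites = list(rng.choice(np.array(sorted(linked_set)),
                                 size=len(promoter_sites), replace=False))
    for psite, host in zip(promoter_sites, host_sites):
        g = gene_of_site[int(host)]
        site_chrom[psite] = g["chrom"]
        site_center[psite] = g["tss"]

    # --- random sequence with planted consensus motifs --------------------
    sequences = {
        c: rng.integers(0, 4, size=chrom_len, dtype=np.int8)
        for c in chrom_names
    }
    planted: list[list] = [[] for _ in range(config.n_sites)]
    for i in range(config.n_sites):
        plan = _plant_plan(classes[i], subclass[i], rng)
        seq = sequences[site_chrom[i]]
        for name, off in plan:
            codes = consensus_codes[name]
            start = int(site_center[i]) + off
            seq[start : start + len(codes)] = codes
            planted[i].append(
                {"motif": name, "start": start,
                 "offset": start - (int(site_center[i]) - hw)}
            )

    # --- occupancy table ---------------------------------------------------
    occ = {
        (f, c): np.zeros(config.n_sites) for f in TF_FACTORS
        for c in config.conditions
    }
    s = strength
    for i in range(config.n_sites):
        sc = subclass[i]
        for cond in config.conditions:
            induced = cond.startswith("Dox")
            jq1 = cond.endswith("JQ1")
            fli1 = 0.0
            if sc in ("EG_stay", "ER_prebound", "promoter"):
                fli1 = s[i]
            elif sc == "EG_reloc":
                # leaves on induction unless relocation is blocked by JQ1
                fli1 = 0.0 if (induced and not jq1) else s[i]
            elif sc == "ER_target":
                fli1 = s[i] if (induced and not jq1) else 0.0
            runx1 = 0.0
            if induced:
                if sc in ("ER_prebound", "ER_other", "RUNX_only"):
                    runx1 = s[i]
                elif sc == "ER_target":
                    runx1 = 0.0 if jq1 else s[i]
                elif sc == "TEAD" and jq1:
                    runx1 = s[i]  # aberrant de novo gain under JQ1
            cdk9 = 0.0
            if fli1 > 0 and runx1 > 0:
                cdk9 = s[i]
            elif sc == "promoter":
                cdk9 = 0.5 * s[i]  # basal promoter presence
            occ[("FLI1", cond)][i] = fli1
            occ[("RUNX1", cond)][i] = runx1
            occ[("CDK9", cond)][i] = cdk9

    # --- genes: ids, codes, condition means --------------------------------
    coupling = {k: tuple(v) for k, v in config.expression_coupling.items()}
    counters: dict[str, int] = {}
    genes: list[GeneModel] = []
    gene_records = []
    fold = config.expression_fold
    char_fold = {"1": fold, "0": 1.0 / fold, "2": 1.0}
    for gi, site in enumerate(linked_sites):
        site = int(site)
        info = gene_of_site[site]
        gene_id = f"g{gi:04d}"
        sc = subclass[site]
        cyc = coupling.get(sc, ("22",))
        k = counters.get(sc, 0)
        code = cyc[k % len(cyc)]
        counters[sc] = k + 1
        base = float(rng.lognormal(np.log(config.base_mean),
                                   config.expression_sigma))
        m_nodox = base
        m_dox = base * char_fold[code[0]]
        m_dox_jq1 = m_dox * char_fold[code[1]]
        # BET inhibition alone perturbs JQ1-responsive genes at half
        # strength (log scale), so the four conditions are all distinct
        m_nodox_jq1 = base * np.sqrt(char_fold[code[1]])
        genes.append(
            GeneModel(gene_id,
                      GenomicInterval(info["chrom"], info["start"],
                                      info["end"], info["strand"]),
                      info["strand"])
        )
        gene_records.append(
            {
                "gene_id": gene_id, "chrom": info["chrom"],
                "start": info["start"], "end": info["end"],
                "strand": info["strand"], "tss": info["tss"],
                "linked_site": f"s{site:04d}", "true_code": code,
                **{f"mean_{c}": (m_nodox if c == "noDox" else
                                 m_dox if c == "Dox" else
                                 m_nodox_jq1 if c == "noDox_JQ1" else
                                 m_dox_jq1)
                   for c in config.conditions},
            }
        )

    # --- stable background transcriptome on its own chromosome -------------
    # Real RNA-seq libraries are dominated by genes the perturbation never
    # touches; without them per-sample library sizes would track the induced
    # fold changes and bias every FPKM ratio (composition bias).
    if config.n_background_genes > 0:
        pitch = config.background_gene_length + 200
        bg_len = config.n_background_genes * pitch + 1000
        sequences["chrBG"] = rng.integers(0, 4, size=bg_len, dtype=np.int8)
        for bi in range(config.n_background_genes):
            gene_id = f"bg{bi:04d}"
            gstart = 500 + bi * pitch
            gend = gstart + config.background_gene_length
            strand = "+" if bi % 2 == 0 else "-"
            base = float(rng.lognormal(np.log(config.base_mean),
                                       config.expression_sigma))
            genes.append(
                GeneModel(gene_id,
                          GenomicInterval("chrBG", gstart, gend, strand),
                          strand)
            )
            gene_records.append(
                {"gene_id": gene_id, "chrom": "chrBG", "start": gstart,
                 "end": gend, "strand": strand,
                 "tss": gstart if strand == "+" else gend - 1,
                 "linked_site": None, "true_code": "22",
                 **{f"mean_{c}": base for c in config.conditions}}
            )

    gene_table = pd.DataFrame(gene_records).sort_values("gene_id")
    gene_table = gene_table.reset_index(drop=True)
    genes.sort(key=lambda g: g.gene_id)

    linked_gene = {f"s{int(st):04d}": rec["gene_id"]
                   for st, rec in zip(linked_sites, gene_records)}
    site_records = []
    for i in range(config.n_sites):
        sid = f"s{i:04d}"
        center = int(site_center[i])
        site_records.append(
            {
                "site_id": sid, "chrom": site_chrom[i],
                "start": center - hw, "end": center + hw,
                "class": classes[i], "subclass": subclass[i],
                "strength": float(strength[i]),
                "relocating": subclass[i] == "EG_reloc",
                "relocated_to": subclass[i] == "ER_target",
                "prebound": subclass[i] == "ER_prebound",
                "linked_gene": linked_gene.get(sid),
                "motifs": json.dumps(planted[i]),
                **{f"occ_{f}_{c}": float(occ[(f, c)][i])
                   for f in TF_FACTORS for c in config.conditions},
            }
        )
    site_table = pd.DataFrame(site_records)

    realised = (len(reloc_idx) / len(eg_idx)) if len(eg_idx) else 0.0
    truth = ScenarioTruth(site_table, gene_table, float(realised))
    return Scenario(config, sequences, genes, truth)


# ---------------------------------------------------------------------------
# coverage simulation


def _pile(length: int, midpoints: np.ndarray,
          fragment_length: int) -> np.ndarray:
    """Pile fragments of fixed length centred on midpoints into base
    coverage, clipped at [0, length)."""
    half = fragment_length // 2
    starts = np.clip(midpoints - half, 0, length)
    ends = np.clip(midpoints - half + fragment_length, 0, length)
    delta = np.zeros(length + 1, dtype=np.int32)
    np.add.at(delta, starts, 1)
    np.add.at(delta, ends, -1)
    return np.cumsum(delta[:-1], dtype=np.int32).astype(np.float32)


def simulate_tracks(scenario: Scenario, conditions=None):
    """Per factor/condition coverage and peak sets.

    Fragment counts per occupied site are Poisson(depth_per_site x
    occupancy); fragment midpoints fall uniformly in the site (gene body for
    the elongation mark); uniform background at `background_rate` fragments
    per kb.  Peak sets are the occupied-site intervals.  Deterministic per
    seed.  Returns (tracks, peaks) keyed by (factor, condition).
    """
    cfg = scenario.config
    conditions = tuple(conditions or cfg.conditions)
    rng = np.random.default_rng([cfg.seed, 101])
    st = scenario.truth.site_table
    gt = scenario.truth.gene_table
    chrom_sizes = scenario.chrom_sizes()
    tracks: dict[tuple, CoverageTrack] = {}
    peaks: dict[tuple, list[Peak]] = {}

    site_chrom = st["chrom"].to_numpy()
    site_start = st["start"].to_numpy()
    site_end = st["end"].to_numpy()
    site_ids = st["site_id"].to_numpy()
    gene_chrom = gt["chrom"].to_numpy()
    gene_start = gt["start"].to_numpy()
    gene_end = gt["end"].to_numpy()
    gene_ids = gt["gene_id"].to_numpy()

    for factor in FACTORS:
        for cond in conditions:
            total = 0
            if factor in TF_FACTORS:
                occv = st[f"occ_{factor}_{cond}"].to_numpy()
                occupied = np.flatnonzero(occv > 0)
                lam = cfg.depth_per_site * occv[occupied]
                starts, ends = site_start[occupied], site_end[occupied]
                chroms = site_chrom[occupied]
                width = (site_end - site_start) // 2
                plist = [
                    Peak(GenomicInterval(site_chrom[i], int(site_start[i]),
                                         int(site_end[i])),
                         name=site_ids[i], score=float(occv[i]),
                         summit=int(width[i]))
                    for i in occupied
                ]
            else:  # elongation mark over gene bodies, expression-coupled
                level = gt[f"mean_{cond}"].to_numpy() / cfg.base_mean
                lam = cfg.depth_per_site * level
                starts, ends, chroms = gene_start, gene_end, gene_chrom
                plist = [
                    Peak(GenomicInterval(gene_chrom[i], int(gene_start[i]),
                                         int(gene_end[i])),
                         name=gene_ids[i], score=float(lam[i]))
                    for i in range(len(gt))
                ]
            nfr = rng.poisson(lam)
            rep = np.repeat(np.arange(len(lam)), nfr)
            mids = (rng.integers(starts[rep], ends[rep]) if rep.size
                    else np.array([], dtype=int))
            mid_chrom = chroms[rep]
            total += int(nfr.sum())
            cov = {}
            for c, n in sorted(chrom_sizes.items()):
                nbg = rng.poisson(cfg.background_rate * n / 1000.0)
                bg_mids = (rng.integers(0, n, size=nbg) if nbg
                           else np.array([], dtype=int))
                total += int(nbg)
                all_mids = np.concatenate([mids[mid_chrom == c], bg_mids])
                cov[c] = _pile(n, all_mids, cfg.fragment_length)
            tracks[(factor, cond)] = CoverageTrack(
                cov, library_size=float(max(total, 1))
            )
            peaks[(factor, cond)] = plist
    return tracks, peaks


def simulate_expression(scenario: Scenario):
    """Negative-binomial count and FPKM tables (genes x condition
    replicates).

    counts ~ NB with the configured dispersion around each gene's true
    condition mean (gamma-Poisson mixture).  Returns (counts, fpkm_table,
    sample_condition).
    """
    cfg = scenario.config
    rng = np.random.default_rng([cfg.seed, 202])
    gt = scenario.truth.gene_table
    d = cfg.dispersion
    samples, cols = [], []
    sample_condition = {}
    for cond in cfg.conditions:
        means = gt[f"mean_{cond}"].to_numpy()
        for r in range(1, cfg.n_replicates + 1):
            if d > 0:
                lam = rng.gamma(shape=1.0 / d, scale=means * d)
            else:
                lam = means
            cnt = rng.poisson(lam)
            name = f"{cond}_r{r}"
            samples.append(cnt)
            cols.append(name)
            sample_condition[name] = cond
    counts = pd.DataFrame(
        np.column_stack(samples), index=gt["gene_id"].to_numpy(), columns=cols
    )
    lengths = pd.Series(
        (gt["end"] - gt["start"]).to_numpy(), index=gt["gene_id"].to_numpy()
    )
    from .expression_response import fpkm as _fpkm

    fpkm_table = _fpkm(counts, lengths)
    return counts, fpkm_table, sample_condition
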