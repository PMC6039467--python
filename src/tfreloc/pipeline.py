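"""Pipeline orchestration: run every stage from one config with fixed
seeds, write all stage outputs under one run directory, and produce a
machine-readable run report.

Stage order follows the analysis: simulate (optional) -> pairwise binding
comparison -> anchor-centred profiles -> motif densities and enrichment ->
three-set overlap integration with gene assignment -> expression response
coding and clustering -> elongation-mark metagene.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import (
    expression_response as er,
    genomic_io as gio,
    integrate,
    motifs as mot,
    peak_compare as pc,
    profiles as prof,
    synthetic_data as synth,
)

logger = logging.getLogger(__name__)

__all__ = ["AnalysisParams", "PipelineConfig", "run_pipeline",
           "REPORT_SCHEMA", "validate_report"]


@dataclass
class AnalysisParams:
    halfwidth: int = 200  # tag-counting window around summits
    fold_threshold: float = 2.0
    cpm_pseudocount: float = 0.5
    flank: int = 1000  # anchored-matrix flank
    bin_size: int = 10
    promoter_window: int = 2000
    max_gene_distance: int = 100_000
    motif_threshold: float = 0.8
    density_row_window: int = 100
    body_bins: int = 100
    metagene_flank: int = 2000
    metagene_flank_bins: int = 20
    expr_fold_threshold: float = 2.0
    expr_min_fpkm: float = 1.0
    density_motifs: tuple = ("RUNX", "ETS", "GATA", "ETS_RUNX")


@dataclass
class PipelineConfig:
    outdir: str = "tfreloc_run"
    seed: int = 0
    simulate: bool = True
    scenario: synth.ScenarioConfig = field(
        default_factory=synth.ScenarioConfig
    )
    params: AnalysisParams = field(default_factory=AnalysisParams)
    # used when simulate is False: paths to pre-existing inputs
    inputs: dict = field(default_factory=dict)
    write_tracks: bool = True

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        known = {"outdir", "seed", "simulate", "scenario", "params",
                 "inputs", "write_tracks"}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls()
        cfg.outdir = raw.get("outdir", cfg.outdir)
        cfg.seed = int(raw.get("seed", cfg.seed))
        cfg.simulate = bool(raw.get("simulate", cfg.simulate))
        cfg.write_tracks = bool(raw.get("write_tracks", cfg.write_tracks))
        cfg.inputs = dict(raw.get("inputs", {}))
        sc = dict(raw.get("scenario", {}))
        sc.setdefault("seed", cfg.seed)
        bad = set(sc) - {f.name for f in
                         synth.ScenarioConfig.__dataclass_fields__.values()}
        if bad:
            raise ValueError(f"unknown scenario keys: {sorted(bad)}")
        cfg.scenario = synth.ScenarioConfig(**sc)
        pr = dict(raw.get("params", {}))
        badp = set(pr) - {f.name for f in
                          AnalysisParams.__dataclass_fields__.values()}
        if badp:
            raise ValueError(f"unknown params keys: {sorted(badp)}")
        cfg.params = AnalysisParams(**pr)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        self.scenario.validate()
        if not self.simulate:
            required = {"genome_fasta", "gene_table", "counts"}
            missing = required - set(self.inputs)
            if missing:
                raise ValueError(
                    f"simulate=false requires input paths: {sorted(missing)}"
                )
            for key, path in self.inputs.items():
                if not Path(str(path)).exists():
                    raise ValueError(f"input {key}={path} does not exist")


REPORT_SCHEMA = {
    "config": dict,
    "outputs": dict,
    "summary": {
        "n_union_peaks_runx1": int,
        "specificity_group_sizes": dict,
        "venn_counts": dict,
        "relocation": dict,
        "location_fractions": dict,
        "motif_fractions": dict,
        "n_differential_genes": int,
        "code_histogram": dict,
    },
}


def validate_report(report: dict, schema: dict = REPORT_SCHEMA,
                    path: str = "report") -> None:
    """Minimal structural validation of a run report against the shipped
    schema (keys present, value kinds match)."""
    for key, kind in schema.items():
        if key not in report:
            raise ValueError(f"{path}.{key} missing from report")
        if isinstance(kind, dict):
            if not isinstance(report[key], dict):
                raise ValueError(f"{path}.{key} must be an object")
            if kind:
                validate_report(report[key], kind, f"{path}.{key}")
        elif not isinstance(report[key], kind):
            raise ValueError(
                f"{path}.{key} must be {kind.__name__}, got "
                f"{type(report[key]).__name__}"
            )


def _round_floats(obj, ndigits=10):
    if isinstance(obj, float):
        return round(obj, ndigits)
    if isinstance(obj, dict):
        return {k: _round_floats(v, ndigits) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, ndigits) for v in obj]
    return obj


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage; returns the RunReport dict (also written to
    report.json in the run directory).  All stage outputs are pure
    functions of (inputs, config, seed)."""
    config.validate()
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, str] = {}
    p = config.params

    def _run(stage, fn):
        try:
            logger.info("stage %s", stage)
            return fn()
        except Exception as exc:  # noqa: BLE001 - abort naming the stage
            raise StageError(stage, exc) from exc

    # --- stage: simulate / load -------------------------------------------
    def _simulate():
        scenario = synth.build_genome(config.scenario)
        tracks, peaks = synth.simulate_tracks(scenario)
        counts, fpkm_table, sample_condition = \
            synth.simulate_expression(scenario)
        gio.write_fasta(scenario.genome(), out / "genome.fa")
        gio.write_gene_table(scenario.genes, out / "genes.tsv")
        scenario.truth.to_json(out / "truth.json")
        counts.rename_axis("gene_id").to_csv(out / "counts.tsv", sep="\t")
        outputs["genome_fasta"] = str(out / "genome.fa")
        outputs["gene_table"] = str(out / "genes.tsv")
        outputs["truth"] = str(out / "truth.json")
        outputs["counts"] = str(out / "counts.tsv")
        if config.write_tracks:
            for (factor, cond), track in tracks.items():
                path = out / f"{factor}_{cond}.bedGraph"
                gio.write_bedgraph(track, path)
                outputs[f"track_{factor}_{cond}"] = str(path)
            for (factor, cond), plist in peaks.items():
                path = out / f"{factor}_{cond}_peaks.bed"
                gio.write_bed(plist, path, narrowpeak=True)
                outputs[f"peaks_{factor}_{cond}"] = str(path)
        return scenario, tracks, peaks, counts, fpkm_table, sample_condition

    if not config.simulate:
        raise NotImplementedError(
            "externally supplied inputs are driven through the individual "
            "CLI subcommands; run-all currently requires simulate: true"
        )
    scenario, tracks, peaks, counts, fpkm_table, sample_condition = _run(
        "simulate", _simulate
    )
    genome = scenario.genome()
    genes = scenario.genes
    pwms = gio.load_bundled_motifs()

    # --- stage: compare (induced factor, +Dox vs +Dox+JQ1) -----------------
    def _compare():
        df = pc.compare_binding(
            peaks[("RUNX1", "Dox")], peaks[("RUNX1", "Dox_JQ1")],
            tracks[("RUNX1", "Dox")], tracks[("RUNX1", "Dox_JQ1")],
            halfwidth=p.halfwidth, fold_threshold=p.fold_threshold,
            pseudocount=p.cpm_pseudocount,
        )
        df.to_csv(out / "compare_RUNX1_Dox_vs_DoxJQ1.tsv", sep="\t",
                  index=False)
        outputs["comparison"] = str(out / "compare_RUNX1_Dox_vs_DoxJQ1.tsv")
        # mobile-factor view: binding before vs after induction
        df_fli1 = pc.compare_binding(
            peaks[("FLI1", "Dox")], peaks[("FLI1", "noDox")],
            tracks[("FLI1", "Dox")], tracks[("FLI1", "noDox")],
            halfwidth=p.halfwidth, fold_threshold=p.fold_threshold,
            pseudocount=p.cpm_pseudocount,
        )
        df_fli1.to_csv(out / "compare_FLI1_Dox_vs_noDox.tsv", sep="\t",
                       index=False)
        outputs["comparison_fli1"] = str(out / "compare_FLI1_Dox_vs_noDox.tsv")
        return df, df_fli1

    comparison, comparison_fli1 = _run("compare", _compare)
    anchors = pc.peaks_from_comparison(comparison)
    anchors_fli1 = pc.peaks_from_comparison(comparison_fli1)

    # --- stage: profiles ----------------------------------------------------
    def _profiles():
        group_profiles = {}
        for cond in ("noDox", "Dox", "Dox_JQ1"):
            m = prof.anchored_matrix(tracks[("CDK9", cond)], anchors,
                                     flank=p.flank, bin_size=p.bin_size)
            m.to_tsv(out / f"matrix_CDK9_{cond}.tsv.gz",
                     out / f"matrix_CDK9_{cond}.json",
                     params={"flank": p.flank, "bin_size": p.bin_size})
            for grp in (pc.GROUP_A_SPECIFIC, pc.GROUP_SHARED,
                        pc.GROUP_B_SPECIFIC):
                mask = (comparison["group"] == grp).to_numpy()
                if mask.any():
                    group_profiles[f"CDK9_{cond}_{grp}"] = \
                        prof.average_profile(m, mask)
        pd.DataFrame(group_profiles).to_csv(out / "average_profiles.tsv",
                                            sep="\t", index=False)
        outputs["average_profiles"] = str(out / "average_profiles.tsv")
        # genomic distribution of the mobile factor's specific/shared sites
        loc = prof.genomic_location(anchors_fli1, genes,
                                    promoter_window=p.promoter_window)
        loc.to_csv(out / "peak_locations.tsv", sep="\t", index=False)
        outputs["peak_locations"] = str(out / "peak_locations.tsv")
        return loc

    locations = _run("profiles", _profiles)

    # --- stage: motifs ------------------------------------------------------
    def _motifs():
        densities = {}
        for name in p.density_motifs:
            dp = mot.density_profile(anchors, genome, pwms[name],
                                     flank=p.flank, bin_size=p.bin_size,
                                     row_window=p.density_row_window,
                                     threshold_fraction=p.motif_threshold)
            densities[name] = dp
            np.savetxt(out / f"density_{name}.tsv.gz", dp.values,
                       delimiter="\t")
        outputs["motif_densities"] = str(out)
        return densities

    _run("motifs", _motifs)

    # --- stage: integrate ---------------------------------------------------
    def _integrate():
        loc_by_name = dict(zip(locations["name"],
                               locations["proximal"]))

        def distal(plist):
            ldf = prof.genomic_location(plist, genes,
                                        promoter_window=p.promoter_window)
            keep = set(ldf.loc[~ldf["proximal"], "name"])
            return [pk for pk in plist if pk.name in keep]

        a = distal(peaks[("FLI1", "noDox")])
        b = distal(peaks[("FLI1", "Dox")])
        c = distal(peaks[("RUNX1", "Dox")])
        venn = integrate.venn_groups(a, b, c,
                                     set_names=("FLI1_noDox", "FLI1_Dox",
                                                "RUNX1_Dox"))
        venn.loci.to_csv(out / "venn_loci.tsv", sep="\t", index=False)
        outputs["venn"] = str(out / "venn_loci.tsv")
        reloc = integrate.relocation_estimate(venn)

        all_loci = [
            gio.Peak(gio.GenomicInterval(r.chrom, int(r.start), int(r.end)),
                     name=r.name)
            for r in venn.loci.itertuples(index=False)
        ]
        assignment = integrate.assign_genes(all_loci, genes,
                                            max_distance=p.max_gene_distance)
        assignment.to_csv(out / "peak_gene_assignment.tsv", sep="\t",
                          index=False)
        outputs["assignment"] = str(out / "peak_gene_assignment.tsv")

        motif_fracs = {}
        for grp in integrate.GROUPS_1_TO_5:
            members = venn.member_peaks(grp)
            background = [pk for g2 in integrate.GROUPS_1_TO_5 if g2 != grp
                          for pk in venn.member_peaks(g2)]
            if not members or not background:
                continue
            for name in ("RUNX", "ETS", "GATA", "ETS_RUNX"):
                res = mot.group_enrichment(
                    members, background, genome, pwms[name],
                    threshold_fraction=p.motif_threshold)
                motif_fracs[f"{grp}_{name}"] = {
                    "fraction": res.fraction_with_hit,
                    "fold": (res.fold_vs_background
                             if np.isfinite(res.fold_vs_background)
                             else -1.0),
                    "p_value": res.p_value,
                }
        return venn, reloc, assignment, motif_fracs

    venn, reloc, assignment, motif_fracs = _run("integrate", _integrate)

    # --- stage: expression --------------------------------------------------
    def _expression():
        cond_means = er.condition_means(fpkm_table, sample_condition)
        diff = er.call_differential(cond_means,
                                    threshold=p.expr_fold_threshold,
                                    min_expr=p.expr_min_fpkm)
        codes = er.code_genes(cond_means, threshold=p.expr_fold_threshold,
                              differential=diff)
        codes.rename_axis("gene_id").to_csv(out / "response_codes.tsv",
                                            sep="\t")
        outputs["response_codes"] = str(out / "response_codes.tsv")
        grouped = codes[codes["grouped"]]
        log_fpkm = np.log2(fpkm_table.loc[diff] + 1)
        order, _ = er.cluster_genes(log_fpkm)
        pd.Series(order, name="gene_id").to_csv(out / "gene_cluster_order.tsv",
                                                sep="\t", index=False)
        corr, sample_order, _ = er.sample_correlation(log_fpkm.T)
        corr.to_csv(out / "sample_correlation.tsv", sep="\t")
        outputs["sample_correlation"] = str(out / "sample_correlation.tsv")
        return cond_means, diff, grouped

    cond_means, diff, grouped = _run("expression", _expression)

    # --- stage: metagene ----------------------------------------------------
    def _metagene():
        code_of = grouped["code"].to_dict()
        gene_groups: dict[str, list] = {}
        for g in genes:
            code = code_of.get(g.gene_id)
            if code is not None:
                gene_groups.setdefault(code, []).append(g)
        profiles_out = {}
        for cond in ("noDox", "Dox", "Dox_JQ1"):
            track = tracks[("H3K79me2", cond)]
            for code, glist in sorted(gene_groups.items()):
                mp = prof.metagene(track, glist, body_bins=p.body_bins,
                                   flank=p.metagene_flank,
                                   flank_bins=p.metagene_flank_bins)
                profiles_out[f"{cond}_group{code}"] = mp.values
        pd.DataFrame(profiles_out).to_csv(out / "metagene_profiles.tsv",
                                          sep="\t", index=False)
        outputs["metagene"] = str(out / "metagene_profiles.tsv")
        return profiles_out

    _run("metagene", _metagene)

    # --- report -------------------------------------------------------------
    spec_sizes = comparison["group"].value_counts().to_dict()
    fli1_groups = comparison_fli1["group"].to_numpy()
    loc_fracs = {
        "all": prof.location_fractions(locations),
        "A_specific": prof.location_fractions(
            locations[fli1_groups == pc.GROUP_A_SPECIFIC]),
        "shared": prof.location_fractions(
            locations[fli1_groups == pc.GROUP_SHARED]),
        "B_specific": prof.location_fractions(
            locations[fli1_groups == pc.GROUP_B_SPECIFIC]),
    }
    code_hist = grouped["code"].value_counts().sort_index().to_dict()
    summary = {
        "n_union_peaks_runx1": int(len(comparison)),
        "specificity_group_sizes": {k: int(v) for k, v in
                                    sorted(spec_sizes.items())},
        "venn_counts": {k: int(v) for k, v in sorted(venn.counts.items())},
        "relocation": reloc,
        "location_fractions": loc_fracs,
        "motif_fractions": motif_fracs,
        "n_differential_genes": int(len(diff)),
        "code_histogram": {k: int(v) for k, v in code_hist.items()},
    }
    report = {
        "config": {
            "seed": config.seed,
            "scenario": asdict(config.scenario),
            "params": asdict(config.params),
        },
        "outputs": outputs,
        "summary": _round_floats(summary),
    }
    # tuples are not JSON; normalise through a round-trip
    report = json.loads(json.dumps(report, sort_keys=True))
    validate_report(report)
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, sort_keys=True, indent=1)
    return report
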