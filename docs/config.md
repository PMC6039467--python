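# Pipeline configuration schema

`tfreloc run-all --config <file.yaml>` reads a single YAML document.
Unknown keys anywhere are rejected before any computation.

## Top level

| key           | type   | default        | meaning |
|---------------|--------|----------------|---------|
| `outdir`      | string | `tfreloc_run`  | run directory; all stage outputs and `report.json` land here |
| `seed`        | int    | `0`            | master seed; propagates to `scenario.seed` when that is not set |
| `simulate`    | bool   | `true`         | generate the synthetic scenario; `false` requires `inputs` and is served by the per-stage subcommands |
| `write_tracks`| bool   | `true`         | write per-factor/condition bedGraph and peak BED files |
| `scenario`    | map    | see below      | synthetic-scenario parameters |
| `params`      | map    | see below      | analysis parameters |
| `inputs`      | map    | `{}`           | paths (`genome_fasta`, `gene_table`, `counts`, …) when `simulate: false`; existence is checked up front |

## `scenario` (ScenarioConfig)

| key | type / unit | default | meaning |
|-----|-------------|---------|---------|
| `genome_length` | bp | 10_000_000 | total length of the site-bearing chromosomes |
| `n_chromosomes` | int | 2 | chromosomes the units are packed onto |
| `n_genes` | int | 300 | genes coupled to distal sites |
| `n_sites` | int | 2000 | regulatory sites |
| `site_class_fractions` | map class→fraction | ETS_GATA .30, ETS_RUNX .30, RUNX_only .15, TEAD .15, promoter .10 | must sum to 1 |
| `relocation_fraction` | fraction | 0.6 | ETS_GATA sites whose mobile-factor occupancy moves on induction |
| `prebound_fraction` | fraction | 0.25 | ETS_RUNX sites carrying the mobile factor in all conditions |
| `conditions` | list | noDox, Dox, noDox_JQ1, Dox_JQ1 | ordered condition names |
| `depth_per_site` | fragments | 30 | expected fragments per occupied site at strength 1 |
| `fragment_length` | bp | 200 | piled fragment length |
| `background_rate` | fragments/kb | 0.1 | uniform coverage background |
| `site_width` | bp | 300 | regulatory-site interval width |
| `gene_length` | bp | 6000 | coupled-gene body length |
| `gene_spacing` | bp | 20000 | genomic unit hosting a gene + its enhancer |
| `site_spacing` | bp | 2500 | genomic unit hosting a lone site |
| `n_background_genes` | int | 2100 | stable transcriptome on its own chromosome |
| `background_gene_length` | bp | 1500 | length of background genes |
| `n_replicates` | int | 3 | RNA replicates per condition |
| `dispersion` | — | 0.05 | negative-binomial dispersion of counts |
| `expression_fold` | fold | 4.0 | realised effect per coded comparison |
| `base_mean` | counts | 500 | mean counts of an average gene |
| `expression_sigma` | — | 0.5 | lognormal spread of base means |
| `expression_coupling` | map subclass→code cycle | see methods | true response code per site subclass |
| `seed` | int | top-level seed | generator seed |

Validation: fractions sum to 1 ± 1e-9; `relocation_fraction` ∈ [0, 1];
all counts > 0; `genome_length ≥ n_sites × 10 × fragment_length`; the unit
layout must fit the genome and promoter-class sites must not outnumber
genes (violations raise a sizing error naming the constraint).

## `params` (AnalysisParams)

| key | default | meaning |
|-----|---------|---------|
| `halfwidth` | 200 | tag-counting window ± bp around summits |
| `fold_threshold` | 2.0 | specificity threshold |
| `cpm_pseudocount` | 0.5 | CPM pseudocount in the fold |
| `flank` | 1000 | anchored-matrix flank (bp) |
| `bin_size` | 10 | anchored-matrix bin (bp) |
| `promoter_window` | 2000 | proximal/distal TSS window (bp) |
| `max_gene_distance` | 100000 | nearest-TSS assignment cap (bp) |
| `motif_threshold` | 0.8 | scan threshold as a fraction of score range |
| `density_row_window` | 100 | rolling rows in density displays |
| `body_bins` | 100 | metagene body bins |
| `metagene_flank` | 2000 | metagene flank (bp) |
| `metagene_flank_bins` | 20 | metagene flank bins |
| `expr_fold_threshold` | 2.0 | differential / coding fold threshold |
| `expr_min_fpkm` | 1.0 | minimum-expression filter |
| `density_motifs` | RUNX, ETS, GATA, ETS_RUNX | PWMs profiled along ranked anchors |

## Run report

`report.json` validates against the schema shipped as
`tfreloc.pipeline.REPORT_SCHEMA`: top-level `config` (echo), `outputs`
(stage output paths) and `summary` with `n_union_peaks_runx1`,
`specificity_group_sizes`, `venn_counts`, `relocation`
(`loss_based`/`gain_based`/`estimate`), `location_fractions`,
`motif_fractions`, `n_differential_genes` and `code_histogram`.  Rerunning
with an identical config and seed reproduces the summary bit-identically.
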