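# tfreloc

Quantitative analysis of **transcription-factor complex relocation** from
ChIP-seq and RNA-seq data.

During cell-fate transitions such as the endothelial-to-haematopoietic
transition, induction of a single factor (a RUNX-family protein under
doxycycline control) can pull pre-existing transcription-factor complexes —
an ETS factor such as FLI1 together with co-factors like CDK9/BRD4 — away
from the enhancers they occupied and onto sites carrying RUNX and ETS::RUNX
composite motifs. `tfreloc` implements the integrative analysis that
demonstrates and quantifies this relocation:

* **Pairwise binding comparison** — union peaks of a factor in two
  conditions, CPM-normalised tag counts in summit-centred windows, and the
  classification of peaks as condition-specific when one condition shows
  more than 2-fold enrichment over the other:
  `fold = (CPM_a + pc) / (CPM_b + pc)`, specific if `fold > 2` or
  `fold < 1/2`, shared otherwise (pseudocount `pc = 0.5` CPM keeps folds
  finite where a peak is absent).  Union peaks are ranked by descending
  fold; that ranked order is the shared row coordinate reused by every
  downstream heatmap.
* **Anchor-centred profiles** — peaks × positional-bin signal matrices
  (±flank around summits), per-group average profiles, and scaled gene-body
  metagene profiles for elongation marks (H3K79me2-like), plus
  promoter/intragenic/intergenic classification of peaks.
* **Motif analysis** — log-odds PWM scanning of both strands, motif-density
  matrices along the same ranked rows as the signal heatmaps, and per-group
  motif enrichment with an exact two-sided hypergeometric test.  PFMs for
  RUNX, ETS, GATA, AP1, TEAD and the ETS::RUNX composite are bundled as
  editable JASPAR-format text.
* **Three-set overlap integration** — distal-peak Venn groups
  (G1 = lost, G2 = retained, G3 = retained + co-bound, G4 = de novo at
  induced-factor sites, G5 = induced factor alone), nearest-TSS peak-to-gene
  assignment, and the relocation estimate
  `(|G1|/(|G1|+|G2|) + |G4|/(|G4|+|G2|)) / 2`.
* **Expression response coding** — FPKM, 2-fold differential calling, and
  per-gene two-character codes over {0,1,2} (up/down/unchanged) for the
  induction and inhibitor comparisons, giving the 8 response groups
  (e.g. "10" = induced genes that the BET inhibitor suppresses);
  hierarchical clustering (1 − Pearson, average linkage) of genes and
  samples.
* **A synthetic-scenario generator** — a toy genome with planted motif
  composites, four-condition coverage tracks and peak sets, and
  negative-binomial expression tables realising known response codes, with
  full ground truth, so the entire pipeline is testable end to end with no
  downloads.

## Worked example

Run the whole pipeline on a small synthetic relocation scenario (200
regulatory sites, 40 coupled genes, relocation fraction 0.6):

```bash
cat > example.yaml <<EOF
outdir: example_run
seed: 11
scenario:
  genome_length: 1500000
  n_chromosomes: 2
  n_genes: 40
  n_sites: 200
  n_background_genes: 150
EOF
tfreloc run-all --config example.yaml
```

The run directory receives the simulated FASTA/bedGraph/BED/TSV inputs and
every stage's outputs (comparison tables, anchor matrices, motif densities,
Venn loci, response codes, metagene profiles, `report.json`).  The printed
summary includes:

```json
{
 "specificity_group_sizes": {"A_specific": 37, "shared": 53, "B_specific": 30},
 "venn_counts": {"G1": 36, "G2": 24, "G3": 15, "G4": 36, "G5": 39},
 "relocation": {"loss_based": 0.6, "gain_based": 0.6, "estimate": 0.6},
 "n_differential_genes": 38,
 "code_histogram": {"00": 4, "01": 4, "02": 4, "10": 8,
                    "11": 2, "12": 3, "20": 4, "21": 7}
}
```

Reading it: the induced factor's +Dox vs +Dox+JQ1 comparison split its
union peaks into 37 Dox-specific, 53 shared and 30 JQ1-gained sites; the
distal three-set Venn found 36 enhancers the mobile factor left (G1), 24 it
kept to itself (G2) and 36 de novo sites at induced-factor loci (G4), so
both the loss-based (36/60) and gain-based (36/60) estimators recover the
planted relocation fraction 0.6; 38 genes changed ≥2-fold and each received
one of the eight 0/1/2 response codes (none code "22" by construction).

Each stage is also available separately (`tfreloc simulate / compare /
profile / motifs / integrate / expression / metagene`) on standard
BED/bedGraph/FASTA/TSV inputs, and everything is importable as a library
(`tfreloc.peak_compare.compare_binding`, `tfreloc.motifs.density_profile`,
…).  The config schema is documented in `docs/config.md` and the scientific
details in `docs/methods.md`.

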