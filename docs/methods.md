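# Methods

## The analysis model

`tfreloc` treats factor relocation as a property of *peak sets and
normalised coverage*, not of raw reads: peaks and coverage tracks are
inputs (peak calling is upstream of the package).  All coordinates are
0-based half-open; conversion to 1-based display coordinates never happens
internally.

### Pairwise binding comparison

For one factor in two conditions, overlapping or bookended peaks are merged
into union loci (sweep-line; merged summit = summit of the highest-scoring
contributor, else the midpoint).  Signal is summed in a summit-centred
window of ±200 bp — chosen to match typical TF peak width; the window is a
parameter (`halfwidth`) because no single value suits both sharp TFs and
broad marks — and scaled to counts per million of the track's library size.
Specificity uses the ratio `(CPM_a + 0.5) / (CPM_b + 0.5)`: above 2 the
locus is condition-A-specific, below 1/2 condition-B-specific, otherwise
shared.  The 0.5-CPM pseudocount implements the convention that a peak
"reduced more than 2-fold *or absent*" belongs in one class: zero counts
still yield a finite, very small or very large fold.  Loci are ranked by
descending fold, ties broken by total signal then genomic position; the
ranked order is frozen and reused as the row coordinate of every heatmap
and motif-density matrix built from the comparison, so panels line up.

No input/control track is modelled and no replicate-aware dispersion test
is performed: the classification is the deterministic 2-fold rule on
normalised counts.

### Anchor-centred matrices and metagenes

`anchored_matrix` bins mean per-bp normalised signal in ±flank around each
anchor's center (summit if present, else midpoint); bins extending past a
chromosome end read as zero.  Defaults: flank 1,000 bp for overview
heatmaps (3,000 bp is used where broader co-factor spreading matters),
bin size 10 bp.  Display smoothing (rolling mean over 50 ranked rows) is
available through `profiles.smooth_rows` but is never applied to stored
matrices or statistics.

Metagene profiles are strand-aware: fixed-resolution flanks (2,000 bp in
20 bins) around a gene body linearly rescaled onto 100 bins whatever the
gene's length; minus-strand genes are reversed so bins read 5'→3'.  Genes
shorter than the body bin count are skipped with a logged warning rather
than upsampled.

Peak location: *proximal* (= promoter) means the peak center lies within
±2,000 bp of any TSS; otherwise *intragenic* if inside a gene span, else
*intergenic*; *distal* = not proximal.  The ±2 kb promoter window is the
conventional choice and is configurable.

### Motif analysis

PFMs are read from JASPAR text with a per-cell pseudocount of 0.25 before
normalisation, `p = (c + 0.25) / (N + 1)` for column total `N`, which keeps
log-odds scores finite at zero counts.  Scores are log2 odds against a
uniform background (order-0; higher-order background models are out of
scope).  The scan threshold is range-relative —
`min + 0.8 × (max − min)` of the attainable score — because a fixed bit
threshold is not comparable across PWMs of different lengths; for these
matrices it admits roughly one mismatch.  Both strands are scanned and
reverse-strand hits are reported at their forward-strand window start.
Overlapping same-strand hits within one PWM length collapse to the best
scorer so low-complexity sequence cannot inflate densities.

Motif-density matrices count hit starts per bin per anchor along the shared
ranked rows; the stored display values are a rolling mean over 100 ranked
rows, while the raw counts remain available for statistics.  Group
enrichment reports the fraction of peaks with ≥1 hit, the fold over the
background fraction (background = all peaks not in the group; the sets must
be disjoint) and an exact two-sided hypergeometric p-value defined as the
total probability of outcomes no more likely than the observed one.

The bundled ETS::RUNX composite is one concatenated PFM: the ETS core, a
2-bp uninformative spacer (uniform columns), then the RUNX core on the same
strand.  The exact matrices a given study used are generally unknown, so
the whole motif set is plain-text and replaceable.

### Overlap integration and the relocation estimate

The three-set Venn (mobile factor before induction = A, after induction =
B, induced factor = C) is computed on *distal* peaks only, on merged union
loci so a genomic locus counts once however many raw peaks cover it.
Pattern→group mapping is configurable; the default is G1 = A only,
G2 = A∩B−C, G3 = A∩B∩C, G4 = B∩C−A, G5 = C only, with the two remaining
regions reported unlabelled.

The relocation fraction — the fraction of the mobile factor's own
enhancers it abandoned on induction — has two truth-free estimators that
coincide under the relocation model: loss-based `|G1| / (|G1| + |G2|)`
(sites it left over its own sites, i.e. sites never co-bound by the induced
factor) and gain-based `|G4| / (|G4| + |G2|)` (de novo sites at
induced-factor loci over retained own sites).  The package reports both and
their mean.  G3 is deliberately excluded from both denominators: sites
co-bound by the induced factor are not "own" sites of the mobile factor,
and including them would bias the estimate downward by the size of the
co-bound class.

Peak-to-gene assignment is nearest-TSS (peak center to TSS) with a 100 kb
cap — "nearest gene" without a cap produces absurd assignments across gene
deserts — and a documented tie rule (lexicographically smaller gene id).
Cross-tabulation counts a gene once per Venn group even when several member
peaks map to it; a gene may appear in several groups.

### Expression response coding

FPKM = counts × 10⁹ / (length × library size), replicates averaged per
condition.  A gene is differential when its maximum pairwise condition fold
(computed on FPKM + 1) reaches 2 and its maximum condition FPKM reaches 1.
Each differential gene is coded over two comparisons — induction
(+Dox vs No Dox) and inhibitor (+Dox+JQ1 vs +Dox) — with '1' for ≥2-fold
up, '0' for ≥2-fold down, '2' otherwise.  That yields the 8 response
groups; genes coding "22" are differential only with respect to
comparisons outside the coded pair (e.g. inhibitor-alone responders) and
are excluded from the groups.  No statistical DE test is applied: the
criterion is the 2-fold FPKM rule, replicate concordance being checked
separately through sample correlation.  Clustering uses 1 − Pearson with
average linkage on log2(FPKM + 1); zero-variance rows sit at distance 1
from everything (their correlation is undefined).

## The synthetic scenario

The generator emulates the study design the pipeline is built for: four
conditions (noDox, Dox, noDox_JQ1, Dox_JQ1), an induced factor present only
under Dox, a mobile factor whose occupancy relocates, a co-factor that
follows co-occupancy, and an expression-coupled elongation mark.

**Sites.**  2,000 sites (default) over a 10 Mb, 2-chromosome genome in five
classes — ETS+GATA enhancers (30%), ETS::RUNX composite sites (30%),
RUNX-only (15%), TEAD (15%), promoters (10%) — each carrying consensus
instances of the bundled PFMs at fixed offsets from the site center
(recorded in the truth tables).  A fraction `relocation_fraction` (default
0.6) of ETS+GATA sites is flagged relocating; each pairs 1:1 with a free
composite site that gains the mobile factor on induction.  A quarter of
composite sites are "prebound" (mobile factor present throughout),
creating the triple-overlap Venn group.  Per-site binding strength is
drawn from {0.5, 1, 2} to give the fold-ranking a continuum.  Under the
BET inhibitor, relocation is blocked and the induced factor aberrantly
gains TEAD sites while losing the relocated-to sites.

**Coverage.**  Fragment counts per occupied site are
Poisson(depth × strength) with depth 30 fragments per site (a desk-scale
stand-in for typical ChIP enrichment), fragment midpoints uniform in the
site, piled at 200 bp fragment length, over a uniform background of
0.1 fragments/kb.  Peak sets are the occupied-site intervals — peak
calling is out of scope, so peaks are exact; all noise enters through
coverage quantification.

**Genes.**  Each of 300 genes sits in a 20 kb unit with its linked distal
site ~6–12 kb from the TSS (so linked enhancers stay distal under the
±2 kb promoter window, and every other site is ≥5 kb from any TSS).
Promoter-class sites sit exactly at TSSs of a gene subset.  True response
codes follow the linked site's class (relocated-to → "10", prebound →
"12", relocating → "01"/"02", RUNX-only → "00"/"20", TEAD → "21",
untouched enhancers → "22"), realised as condition means with a 4-fold
effect per coded character — comfortably above the 2-fold calling
threshold at the default depth — and a half-strength (log-scale)
JQ1-alone effect so all four conditions are distinct.  A stable background
transcriptome (2,100 genes on a separate chromosome, code "22") dominates
the library so that per-sample library sizes stay nearly constant across
conditions; without it the fold changes of the coupled genes would shift
every FPKM ratio (composition bias), which real transcriptomes avoid by
being mostly unchanged.  Counts are negative binomial (gamma-Poisson) with
dispersion 0.05 — standard bulk RNA-seq noise — in 3 replicates per
condition.  The elongation-mark track covers gene bodies with depth
proportional to each gene's condition mean.

**What the generator does not emulate:** read-level artefacts
(mappability, GC bias, duplicates), peak-calling uncertainty, diploid
genomes, input/control tracks, and intragenic regulatory sites (all
synthetic distal sites are intergenic; the intragenic branch of the
location classifier is exercised by direct tests instead).  Passing
end-to-end tests therefore demonstrates correctness of the quantification,
classification, integration and coding machinery under known truth — not
robustness to alignment- or peak-calling-level noise.

## Determinism and numerics

Every stage is a pure function of (inputs, config, seed); all randomness
flows through `numpy.random.default_rng` seeded from the scenario seed
(distinct fixed stream keys for genome construction, track simulation and
expression sampling).  Rerunning with the same config reproduces the run
report bit-identically; floats in the report are rounded to 10 decimals
before serialisation.  Coverage is stored float32 and accumulated in
float64, which keeps binned means within 1e-9 of per-base brute-force
computation.  Ties are broken deterministically everywhere (ranking:
signal then position; gene assignment: lexicographic gene id; clustering:
scipy's index order).

## Problem sizes used by the test suite

Unit and property tests run on a ~10× reduced scenario (1.5 Mb, 200 sites,
40 coupled genes).  End-to-end checks use the default scenario: relocation
recovery averages the full pipeline over 10 seeds, expression-code recovery
over 3 seeds, and the interval/profile brute-force oracles use 1,000
random intervals across 20 seeds.  The hypergeometric null calibration
resamples 1,000 groups of 1,000 peaks from a 21,000-peak pool — large
enough that the discrete p-value atoms stay well below the
Kolmogorov–Smirnov resolution of the check.

## Known limitations

* The 2-fold specificity rule has no error model; with very shallow
  tracks, shared sites near the threshold flip classes (visible as small
  deviations between specificity group sizes and scenario truth at the
  default depth).
* `library_size` of a bedGraph read from disk defaults to its total
  signal; CPM values are then comparable between tracks only up to a
  constant factor (the fragment length), which cancels in every fold and
  profile comparison the pipeline makes.
* Motif fractions depend on the range-relative scan threshold; at 0.8 the
  bundled 9–10 bp PWMs admit ~one mismatch, giving a background hit
  fraction of a few percent per 300 bp — comparable to motif-fraction
  backgrounds in real peak sets, but not calibrated to any specific
  scanner.
* `run-all` currently drives only the simulated scenario; externally
  supplied data flows through the per-stage subcommands, which accept
  standard BED/bedGraph/FASTA/TSV.
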