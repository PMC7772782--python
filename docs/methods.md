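# Methods

This note documents the models and procedures implemented in `clipmap`,
the parameter choices that matter, what the synthetic-data generator does
and does not emulate, and the numerical decisions taken where the
procedure left genuine freedom.

## Binding-site definition

Input is a set of single-nucleotide significant crosslink sites, each with
a positive peak-caller score, plus per-replicate strand-specific
crosslink-event tracks. The pipeline is:

1. **Score filter** — remove sites below the 5% quantile of all scores.
   The quantile is the linear-interpolation (type-7) empirical quantile;
   sites scoring exactly the cutoff are kept, so a degenerate all-equal
   input loses nothing.
2. **Clustering** — sites on the same chromosome/strand closer than 8 nt
   (positional distance < 8, i.e. at most 6 intervening nucleotides) join
   one region spanning first to last site. Regions narrower than 3 nt are
   discarded.
3. **Equal-sized windows** — every region becomes one or more 9-nt windows
   centered on a peak summit (the position with the highest merged
   crosslink count; ties go to the 5'-most position in transcript
   orientation). Regions shorter than 9 nt are extended by 4 nt on each
   side of their summit; regions longer than 9 nt are split iteratively:
   place a window at the current global summit, mask its positions, and
   repeat. A window is placeable only when it lies inside the chromosome,
   does not overlap an already-placed window on its strand (windows from
   earlier regions included; regions are processed left to right), and
   covers at least 2 significant positions. Windows that would run off the
   chromosome are dropped, never clipped.
4. **Reproducibility** — for each replicate *r*, the support threshold
   *t_r* is the 20% (type-7) quantile of *r*'s summed events over all
   windows; *r* supports a window when its sum is ≥ *t_r* (the strict ">"
   variant is available via `inclusive=False`). Windows supported by at
   least 3 of 4 replicates are retained.

The summit of an *extended* short region is by construction the argmax of
merged counts within the region, not necessarily within the full 9-nt
window — flanking sequence outside the region may carry higher counts.
The test suite checks the summit invariant accordingly, and checks the
whole procedure against an independently coded brute-force implementation
on a thousand random toy instances (exact set equality).

## Gene and region assignment

Annotations are read in the GENCODE GTF dialect; genes with `level` > 2
and transcripts with non-numeric or > 3 `transcript_support_level` are
dropped on load. Before assignment, genes whose spans overlap another
retained gene on the same strand are removed (`overlap_removal="gene"`,
the default; `"none"` leaves resolution to the ambiguity rule). A binding
site is assigned to a gene only when it overlaps exactly one retained gene
on its own strand — iCLIP is strand-specific, so cross-strand overlap
never counts.

Within the unique gene, each transcript votes with the hierarchically
highest label (intron > CDS > 3'UTR > 5'UTR) among its region intervals
overlapping the site; the final label is the majority vote, ties broken by
the same hierarchy. Transcripts without CDS records in a coding gene vote
only on intronic overlaps; in non-coding genes exonic overlaps are
labelled `exonic`. Region densities are reported per kb of the summed
region lengths over bound transcripts.

## Motif analytics

All sequence work happens in transcript orientation (minus-strand sites
reverse-complemented), DNA alphabet internally and RNA (U for T) only at
presentation. Pentamer counts compare the 9-nt site window with its 20-nt
flanks; positional profiles record, for offsets −100..+100 around the site
center, the fraction of sites whose pentamer starts at that offset —
columns therefore sum to 1 wherever all sites have unambiguous sequence.
Profiles of the 300 pentamers with the highest in-site frequency are
clustered with k-means (k = 3, fixed seed, 10 restarts).

Triplet analytics count GAA and UUC in a 49-nt window centered on the site
(±24 nt); the 49-nt width is used rather than the alternative ±30 nt
phrasing, and the window is exposed as a parameter. Counting takes maximal
non-overlapping placements left to right (for period-3 triplets like GAA
this equals the overlapping count). Strength strata are summarized by
quartiles with counts capped at "7+". Repeat classes chain occurrences
separated by exactly 0, 1 or 2 nt; a site satisfying several classes is
classed by the smallest gap. Windows with > 20% N are excluded.

## Cassette-exon filtering

Tables use the rMATS skipped-exon dialect with sample 1 = control and
sample 2 = knockdown; ΔPSI is defined KD − control, so "decreased
inclusion upon KD" means ΔPSI < 0. An event is significant when
FDR < 0.05, |ΔPSI| > 0.05, and log2 of the junction-read support > 5.
Junction support is the mean over replicates of the per-replicate sums of
inclusion + skipping junction reads across both conditions; taking the
mean of per-replicate log2 values instead is available via
`log2_before_mean=True`. All thresholds are strict, matching their printed
form. The alternatively spliced region of an event runs from 100 nt before
the upstream exon's 5' splice site to 100 nt past the downstream exon's 3'
splice site, strand-aware.

## Splicing maps

Occupancy is the fraction of events with at least one merged crosslink
event at a given offset (−100..+100, transcript orientation) from each of
the six splice-site anchors of the exon triplet. Windows of neighboring
anchors may overlap on short exons/introns and are counted independently
per anchor.

The background pool is all measured events outside the two significant
sets. For each regulated set, the control-PSI distribution is split into
20 quantile bins (5% each) and, per iteration, the same per-bin numbers of
pool events are drawn without replacement — 50 iterations by default (100
is a supported alternative). A bin with too few pool candidates samples
with replacement; a bin with none falls back to the pool events nearest in
PSI (both with a warning). The per-position background mean and SD (ddof
= 1 across iterations) give z = (f_obs − μ)/σ; p-values are the
standard-normal upper tail (enrichment is the tested direction, matching
the display of positive z only); an empirical-rank p-value among the
background iterations is available via `p_method="empirical"`. Positions
with σ = 0 get z = 0, p = 1 and an `sd_zero` flag. Adjusted p-values are
Benjamini–Hochberg across all anchors × offsets of one set's map, and the
significance mask is z > 0 with adjusted p < 0.05.

## The synthetic-data generator

The generator emulates the statistical structure the pipeline assumes:

- **Genes** — 400 protein-coding genes by default, 3–5 exons of 80–160 nt
  with 150–400-nt introns, on two chromosomes and random strands, one
  transcript each, CDS from 30 nt inside the first exon to 30 nt before
  the end of the last. Uniform random background sequence.
- **Regulation classes** — 15% of genes down-regulated (alternative exon
  loses inclusion upon knockdown; control PSI 0.55–0.9), 8% up-regulated
  (gains inclusion; control PSI 0.1–0.45), the rest neutral (PSI 0.1–0.9).
  The down:up ratio mirrors the strong skew toward increased skipping that
  SR-protein knockdowns show.
- **Motifs** — runs of 2–5 consecutive GAA triplets (strand-aware):
  4 runs in the alternative-exon body of down genes, 3 runs in each
  flanking constitutive exon of up genes, and occasional single intronic
  runs in neutral genes. Multiple runs per exon reflect the clustered
  exonic-splicing-enhancer architecture of GAA-motif proteins.
- **Crosslink counts** — negative binomial per position and replicate
  (dispersion 2, the simplest overdispersed model for sparse iCLIP
  pile-ups), base rate 0.05 events/nt, exonic rates scaled by inclusion
  (0.4 + 1.2·PSI) so highly included exons accumulate more events — the
  coverage bias that motivates PSI matching — and multiplied by 16 over
  planted runs with a linear ramp peaking at the run's transcript 3' end.
- **Surrogate caller** — on synthetic runs only, a position is significant
  when its merged count exceeds the per-gene 99% count quantile (and ≥ 2
  events); its score is the merged count. This is a deliberately simple,
  clearly labelled stand-in that produces scored sites with the right
  qualitative structure; it is not a reimplementation of, nor equivalent
  to, an HMM-based caller.
- **PSI values** — 5 paired control/KD replicates; beta-distributed around
  the event mean with concentration 100 and a shared per-pair logit offset
  (SD 0.2) inducing the paired structure; regulated events shift the KD
  mean by at least the configured effect (default 0.2). FDR is
  Benjamini–Hochberg over paired t-tests of all events. Junction reads are
  negative binomial (mean 60 per condition and replicate) split
  binomially by PSI, so nearly all events clear the read filter.
- **Reads** — the raw-read generator emits the 9-nt barcode layout
  (3 random + 4 sample + 2 random) with configurable qualities and
  optional truncated 3' adapter, plus a ground-truth table.

All generators are deterministic in one integer seed, with sub-streams
derived per component and replicate; identical seeds give byte-identical
outputs.

What the generator does **not** emulate: alignment artifacts and mapping
bias, crosslinking sequence preferences beyond the planted motif,
transcript-abundance variation between genes beyond the PSI scaling,
multiple transcripts per gene, overlapping genes, and non-uniform genomic
base composition. Passing tests therefore demonstrate correctness of the
pipeline's rules and statistics under a faithful-but-idealized data model,
not robustness to every artifact of real libraries.

## Problem sizes and numerical choices

Test and acceptance runs use the default 400-gene dataset (~0.8 Mb of
genome, 4 replicates), 1,000 random ≤ 1-kb instances for the brute-force
equivalence check, 2,000 genes for the regulated-event recovery check and
5,000 sites for the motif–strength recovery — sizes at which every
statistical property under test is comfortably powered while the whole
suite stays fast. Quantiles are type-7 throughout; BH adjustment uses the
standard step-up procedure; beta draws are clipped to mean parameters in
[0.02, 0.98] to avoid degenerate endpoints.

## Known limitations

- The adapter trimmer matches read suffixes against adapter prefixes
  (right-tail trimming); an adapter wholly internal to a read followed by
  further sequence is not removed. Synthetic reads only ever carry the
  adapter as a (possibly truncated) suffix.
- Duplicate removal implements the stub-level contract (chromosome,
  strand, 5' position, random barcode); full BAM-level duplicate marking
  is out of scope.
- Region assignment handles GENCODE-style attributes; other GFF3 dialects
  are not parsed.
- The splicing map reports per-anchor profiles independently; it does not
  deduplicate occupancy where short introns make anchor windows overlap,
  and no statistical comparison between the up and down maps is provided.
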