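# Methods

This note documents the models and procedures `polyaflow` implements, the
parameters that matter, what the synthetic data does and does not emulate,
and the design decisions taken where more than one reasonable convention
exists.

## Coordinates and data model

All internal intervals are 0-based half-open; GFF3 I/O converts to/from
1-based inclusive, and the 6-column tag BED marks the single cleavage base
(`start = cleavage_pos`, `end = cleavage_pos + 1`, name = `tag_id|mate_status`,
score = read count). The cleavage coordinate of a tag is the genomic
position of the last transcribed nucleotide before the poly(A) tail,
strand-aware.

## Tag curation

* **Poly(T) calling.** A raw read is a poly(T) tag iff it begins with at
  least `min_t_run = 8` consecutive T. Only a "stretch of Ts" is required
  conceptually; 8 is a stringent sub-length of the 18-nt oligo-dT primer
  and is configurable.
* **Mate concordance.** Only tags whose 5' mate mapped uniquely are kept
  (`mate_status == paired_unique`). Mate status is populated upstream, by
  the aligner import or the simulator.
* **Internal priming.** A tag is discarded iff the
  `internal_priming_window = 10` nt immediately downstream of its cleavage
  position, on the tag's sense strand, contain a run of
  `internal_priming_a_run = 6` consecutive A. Strict consecutive-run
  semantics were chosen over mismatch-tolerant or A-fraction variants used
  elsewhere; both constants are parameters. The 10-nt window is the
  smallest that cannot miss a 6-run starting at the cleavage site while
  tolerating small jitter. Windows crossing a chromosome end are clipped.
* Tags sharing (chrom, strand, position) are aggregated with summed counts
  before clustering: clustering semantics depend on distinct positions,
  not read multiplicity. All three filters are order-independent.

## PAC calling

Within one (chromosome, strand), adjacent distinct cleavage positions with
separation `< cluster_gap = 24` nt chain into one PAC (single linkage).
The gap applies between adjacent positions, not to the cluster diameter —
the reading used by reference PAC-calling implementations. The PAC
representative is the summit: the position with the highest read count,
ties broken toward the 3'-most position (deterministic, and consistent
with distal-biased cleavage heterogeneity); span midpoints are not used.

## Gene models

* **Isoform merging.** Multiple transcripts of one gene are merged at
  single-nucleotide resolution: positions labelled identically by every
  covering isoform keep the label (5UTR/CDS/intron/3UTR), conflicting
  positions become `AMB`, then runs are coalesced into maximal segments.
  Exonic positions without explicit UTR features are assigned a UTR label
  by their side of the CDS span. Positions inside the merged span covered
  by no isoform are labelled intron.
* **Annotated 3'-UTR flag.** A gene "has" a 3'-UTR when its body extends
  3' of the CDS (terminal segment 3UTR or AMB); prediction-only gene
  models that stop at the stop codon therefore receive the long extension.
* **3' extension.** `ext_with_utr = 200` / `ext_without_utr = 400` nt
  (`mtr_like`), or 120/338 nt (`ath_like`), clipped at chromosome edges.
  Where an extension would enter a downstream same-strand gene body it is
  truncated there; overlap with opposite-strand genes is allowed, since
  convergent 3'-UTR overlap is exactly what produces antisense cases 1–2.
  The truncation policy is a design choice (no convention is established);
  it prevents sense misassignment while preserving convergent overlap.
* **Promoter.** `promoter_extent = 2000` nt upstream of the 5'-most
  transcribed coordinate (the 5'-UTR start when annotated, else the gene
  body start), clipped at chromosome edges.

## Assignment

Assignment is by summit position only; a single decisive coordinate avoids
double counting and keeps region tabulations additive. Sense precedence:
gene body > 3' extension (labelled 3UTR) > promoter; ties resolve to the
nearest gene 3' end, then lexicographic gene id. PACs covered by nothing
on either strand are intergenic; their distance to the nearest extended-
gene boundary feeds the intergenic distance curve, together with the
fraction within 400 nt downstream of a properly oriented extended gene.

A PAC whose summit lies inside an opposite-strand gene (body or 3'
extension — extension coverage is required so that overlapping extended
3'-UTRs of convergent pairs register as antisense) enters the antisense
tabulation. Attribution looks for a gene on the PAC's own strand that
explains it as read-through: covering 3'-UTR → case 1; covering CDS,
5'-UTR, intron or AMB → case 2 (the canonical description names CDS and
5'-UTR; introns of the covering gene are placed in case 2 as "maps to the
neighbour, not its 3'-UTR"); otherwise a same-strand gene whose body 3'
end lies within `nearby_antisense_distance = 500` nt upstream of the
summit → case 3; else case 4. The 500-nt default exceeds both extension
rules and is a parameter, not a claim. A PAC sense-covered by gene B while
antisense to gene A is tabulated in both tables; the two summaries are
independent.

## Nucleotide profiles

For each site the genomic window (`profile_upstream = 300`,
`profile_downstream = 100`; position 0 = cleavage site) is extracted on
the site's sense strand and per-position base fractions are tallied; sites
whose window crosses a chromosome edge are dropped and counted. Profiles
are stratified by region (3UTR / intron / CDS / intergenic), by antisense
group (cases 1–2 = overlap, 3 = nearby, 4 = orphan) and by single- vs
multi-PAT support. T is reported as U (transcript-space convention). The
window default is generous; published figure windows vary, so profile
checks are qualitative (feature location), not curve-exact.

## Conservation statistics

* **3'-UTR length.** Per gene, the distance from the last coding base to a
  representative poly(A) coordinate. Because "average 3'-UTR length" is
  not uniquely defined, three modes are provided — `tag_weighted_mean`
  (default), `distal_summit`, `median_summit` — and the mode is recorded in
  the report.
* **Length comparison.** Two-sided Wilcoxon rank-sum between orthologous
  and non-orthologous genes per species; Pearson correlation over complete
  ortholog pairs; Pearson over randomly assembled pairs as the null
  control (fewer than 3 complete pairs → correlation reported missing).
* **Feature conservation.** Species-B genes carrying the feature and
  having an ortholog in the species-A pool define the sample
  (deduplicated to unique B genes; with many-to-many tables a B gene
  counts as shared when *any* partner carries the feature). The observed
  shared count is compared with `n_random_trials = 1000` seeded draws of
  the same number of genes from the pool, sampled without replacement.
  The test statistic is a two-cell χ² goodness of fit of
  {shared, not shared} against the randomization-mean proportions (df 1).
  Because a single draw's shared count is hypergeometric, the
  randomization mean converges to `sample_size · K / N`; that closed form
  is reported alongside as an analytic cross-check. An empty sample is
  flagged untestable rather than scored.
* **Positional statistics.** For PAC-bearing introns and CDS exons:
  relative feature index in 5'→3' order (a single-feature gene scores
  1.0), within-feature position = 5' offset / length (> 0.5 = nearer the
  3' end), and length distributions against size-matched seeded random
  draws from the complete feature set.
* **EST validation.** An EST-derived site validates when a same-strand PAC
  summit lies within `est_match_window = 50` nt, boundary inclusive (the
  convention is stated in the report).

## Synthetic data

The generator emulates the statistical structure the pipeline targets:
uniform-composition chromosomes; single-transcript genes with Poisson
exon counts; half of the genes without an annotated 3'-UTR; a configurable
fraction of convergent gene pairs with body gaps spanning the antisense
case regimes; planted poly(A) sites per gene drawn from a Table-3-like
distribution (0.36/0.24/0.16/0.10/0.14 over 1–5 sites) with a region mix
of 70% 3'-UTR, 7% intron, 11% CDS, 12% antisense; tag counts per site
Poisson with mean 20; cleavage jitter from a discrete normal (sd 3 nt by
default) truncated at ±11 nt so one site's tags always stay within the
24-nt chaining gap and planted sites are recoverable one-to-one (sites are
placed ≥ 50 nt apart per strand); planted A-tracts (0.2/kb, length 6–9) on
both strands with internal-priming reads placed immediately upstream of
them at 5% of the read total. Downstream windows of genuine planted sites
are sanitized so the artifact filter's ground truth is exact. The
ortholog generator plants marginal and joint feature rates (joint = product
of marginals ⇒ a calibrated null; larger joint ⇒ enrichment) and the
length generator plants a bivariate-normal Pearson correlation.

Deliberately not emulated: raw FASTQ reads, sequencing error, alignment
ambiguity, multi-isoform genes (isoform merging and AMB labelling are
exercised directly in tests), expression-level variation between genes
beyond Poisson tag counts, and realistic base composition (genes have no
codon structure). Passing tests therefore demonstrate the correctness of
the clustering, filtering, assignment and statistical machinery under
known truth — not performance on real libraries, where mapping artifacts
and annotation errors dominate.

## Numerical and scale choices

Test and acceptance runs use toy problem sizes chosen for speed with
adequate statistical power: 2 × 100-kb chromosomes and 50 genes (~120
planted sites), 2000-pair ortholog tables with 20% marginal feature rates
(3× joint enrichment for the power check), 100 null + 100 enriched tables
for calibration, and 8876-pair length tables for correlation recovery.
The uniform-genome profile check compares 64 cells (window −10..+5, 800
non-overlapping sites) against a 3-standard-error binomial band: the band
has a fixed ~0.3% per-cell false-alarm rate, so the cell count is kept
small enough for an "everywhere within 3 SE" statement to be meaningful;
the broader-window property test uses a family-wise-corrected bound
instead. Degenerate inputs are defined rather than errors where a
convention exists (empty tag set → zero reports; chromosome without genes
→ intergenic distance missing; promoter clipped at chromosome edges);
empty site lists and empty EST sets are errors.

## Known limitations

* Antisense detection requires summit coverage by an opposite-strand gene
  body or extension; antisense transcription beyond the extension is
  invisible (it lands in the intergenic bin).
* The merge step labels exonic positions of non-coding isoforms `AMB`,
  which slightly over-reports AMB for genes mixing coding and non-coding
  isoforms.
* The χ² construction treats the randomization mean as fixed expected
  proportions; the Monte-Carlo uncertainty of that mean (~1/√trials) is
  ignored, which is negligible at 1000 trials.
* Ortholog tables are treated gene-symmetrically; paralog-aware weighting
  is out of scope.
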