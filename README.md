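# polyaflow

Genome-wide poly(A)-site determination and comparative alternative-
polyadenylation (APA) analysis for plant genomes.

3'-end sequencing produces *poly(A) tags* (PATs): short reads spanning the
mRNA/poly(A) junction, each defining one cleavage coordinate. `polyaflow`
turns mapped PATs into a curated map of poly(A) sites and asks how those
sites distribute over genes and how APA is conserved between two species:

1. **Tag curation** — poly(T)-prefix calling on raw reads, removal of tags
   without a uniquely mapped 5' mate, and removal of internal-priming
   artifacts: a tag is discarded iff the 10 genomic nt downstream of its
   cleavage site (sense strand) contain a run of ≥ 6 consecutive A.
2. **PAC calling** — curated cleavage positions are chained into Poly(A)
   site Clusters (PACs): adjacent positions separated by fewer than 24 nt
   join one cluster, absorbing cleavage microheterogeneity. Each PAC is
   summarised by its summit (best-supported position, ties broken 3').
3. **Gene models and assignment** — transcript isoforms are merged into
   unique gene models (positions with conflicting labels become `AMB`),
   3'-UTRs are extended (200 nt when a 3'-UTR is annotated, 400 nt when
   not; 120/338 nt under the `ath_like` profile) and each PAC summit is
   resolved to (gene, region), a 2000-nt promoter window, or intergenic.
4. **Antisense classification** — a PAC inside an opposite-strand gene is
   attributed to convergent read-through: case 1 (inside the convergent
   neighbour's 3'-UTR), case 2 (inside its CDS/5'-UTR), case 3 (near the
   neighbour's 3' end, ≤ 500 nt), case 4 (orphan).
5. **Signal profiles** — position-by-position base composition around
   summits, stratified by region and by single- vs multi-PAT support. A
   genuine plant poly(A) site shows a U-rich upstream region, an A-rich
   element near −20 and a U-rich cleavage region; a flat profile flags
   random placements.
6. **Conservation statistics** — per-gene 3'-UTR lengths and their Pearson
   correlation over ortholog pairs (with a random-pairing null control and
   Wilcoxon rank-sum ortholog/non-ortholog comparisons), and a
   randomization test of feature sharing: for genes carrying intronic /
   CDS / antisense PACs in species B, the number of orthologs carrying the
   same feature in species A is compared against 1000 random draws of the
   same number of genes from the ortholog pool (χ² two-cell goodness of
   fit; the hypergeometric closed form is reported alongside).

A first-class synthetic-data module (`polyaflow.simulate`) generates
genomes, annotations, tags, EST sites and ortholog tables with planted
ground truth, so every stage is testable without downloads.

## Worked example

```sh
python examples/01_simulate_and_call_pacs.py
```

```
curation cascade (read counts):
  input tags                                    2451
  paired tags                                   2319
  curated tags (internal priming excluded)      2196

117 PACs called from 117 planted sites
summits within 5 nt of a planted site: 117/117
```

5% of simulated reads lack a mapped mate and are dropped; the reads placed
against planted genomic A-tracts are removed by the internal-priming
filter; the surviving tags cluster into exactly one PAC per planted site,
with every summit within 5 nt of the planted cleavage coordinate despite
3-nt cleavage jitter. `examples/02_assign_regions.py` prints the region
table and antisense cases, `examples/03_signal_profiles.py` the
composition profile around a planted A-rich element, and
`examples/04_conservation.py` the randomization conservation test (planted
3× enrichment: observed 230 shared orthologs vs a randomization mean of
78.4, p ≈ 5e-82) and the recovery of a planted 3'-UTR length correlation.

The same pipeline runs from the shell:

```sh
polyaflow simulate --outdir sim --seed 3
polyaflow all --genome sim/genome.fasta --annotation sim/annotation.gff3 \
    --tags sim/tags.bed --outdir out --seed 3
```

which writes the curation report, PAC GFF3/BED, assignment tables shaped
like the per-region / per-case / PACs-per-gene summaries, profile TSVs and
a JSON run manifest.

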