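"""Synthetic genomes, annotations, poly(A) tags and ortholog tables.

Everything downstream of read mapping can be exercised on data generated
here, with fully known ground truth: gene models laid out on uniform-
composition chromosomes (half of them without an annotated 3'-UTR, to
exercise the long-extension rule), convergent gene pairs whose gaps span
the antisense case-1/3/4 regimes, poly(A) sites planted in chosen regions
with microheterogeneous tag jitter, internal-priming artifact tags placed
against planted genomic A-tracts, and ortholog tables with a controlled
joint rate of feature sharing.

Coordinates are 0-based half-open, as everywhere in the package; the
emitted GFF3/BED/FASTA use the standard on-disk dialects.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import annotation
from .annotation import GeneModel, Transcript
from .curation import MappedTag
from .params import Parameters

REGION_CHOICES = ("3UTR", "intron", "CDS", "antisense")

#: tag jitter is truncated at +/-11 nt so that one site's tags always stay
#: pairwise closer than the 24-nt clustering gap
JITTER_TRUNCATION = 11


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the synthetic data.

    Defaults emulate the statistical structure of a real poly(A)-tag
    experiment at toy scale: multi-site genes in Table-3-like proportions,
    a site-region mix dominated by 3'-UTRs, nucleotide-scale cleavage
    jitter, and a few percent internal-priming reads.
    """

    n_chromosomes: int = 2
    chrom_length: int = 100_000
    n_genes: int = 50
    fraction_convergent_pairs: float = 0.3
    mean_exons_per_gene: float = 4.0
    #: distribution of planted sites per gene over {1,2,3,4,5}
    planted_sites_per_gene: tuple = (0.36, 0.24, 0.16, 0.10, 0.14)
    #: proportions over (3UTR, intron, CDS, antisense); must sum to 1
    site_region_mix: tuple = (0.70, 0.07, 0.11, 0.12)
    microheterogeneity_sd: float = 3.0
    internal_priming_rate: float = 0.05
    a_tract_density: float = 0.2       # planted A>=6 tracts per kb
    tags_per_site: float = 20.0
    seed: int = 0

    def validate(self) -> None:
        def check_prop(name, v):
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"SimConfig.{name}={v} must be in [0, 1]")
        check_prop("fraction_convergent_pairs", self.fraction_convergent_pairs)
        check_prop("internal_priming_rate", self.internal_priming_rate)
        for name, dist in (("planted_sites_per_gene", self.planted_sites_per_gene),
                           ("site_region_mix", self.site_region_mix)):
            for v in dist:
                check_prop(name, v)
            if abs(sum(dist) - 1.0) > 1e-9:
                raise ValueError(f"SimConfig.{name} must sum to 1, got {sum(dist)}")
        if len(self.site_region_mix) != len(REGION_CHOICES):
            raise ValueError("site_region_mix must have one proportion per region "
                             f"{REGION_CHOICES}")
        if self.n_chromosomes < 1 or self.chrom_length < 1:
            raise ValueError("need at least one chromosome of positive length")
        if self.n_genes < 0:
            raise ValueError("n_genes must be non-negative")
        if self.microheterogeneity_sd < 0 or self.a_tract_density < 0:
            raise ValueError("rates must be non-negative")
        if self.tags_per_site <= 0:
            raise ValueError("tags_per_site must be positive")
        # room for ~10 mean-sized genes per chromosome worth of sequence
        mean_gene = 1500
        if self.n_genes and self.chrom_length < 10 * mean_gene:
            raise ValueError("chrom_length must be at least 10x the mean gene length")


@dataclass(frozen=True)
class PlantedSite:
    site_id: str
    chrom: str
    strand: str
    coord: int
    gene_id: str
    region: str                  # 3UTR / intron / CDS / antisense
    antisense_case: int | None = None


@dataclass
class GroundTruth:
    planted_sites: list = field(default_factory=list)
    artifact_tags: list = field(default_factory=list)
    a_tracts: list = field(default_factory=list)      # (chrom, strand, start, length)
    ortholog_truth: pd.DataFrame | None = None

    def sites_by_id(self) -> dict:
        return {s.site_id: s for s in self.planted_sites}


# ---------------------------------------------------------------------------
# genome + annotation
# ---------------------------------------------------------------------------

def _build_gene(rng, cfg: SimConfig, gene_id, chrom, strand, start):
    """One single-transcript gene; returns (Transcript, body length)."""
    n_ex = max(1, int(rng.poisson(max(cfg.mean_exons_per_gene - 1.0, 0.0))) + 1)
    utr5_len = int(rng.integers(60, 120))
    has_utr3 = bool(rng.random() < 0.5)
    utr3_len = int(rng.integers(120, 260)) if has_utr3 else 0
    exon_lens = [int(x) for x in rng.integers(120, 260, n_ex)]
    intron_lens = [int(x) for x in rng.integers(80, 220, n_ex - 1)]

    # blocks in transcription order: 5UTR, cds1, i1, cds2, ..., cdsN, [3UTR]
    blocks = [(utr5_len, "5UTR")]
    for i, el in enumerate(exon_lens):
        blocks.append((el, "CDS"))
        if i < n_ex - 1:
            blocks.append((intron_lens[i], "intron"))
    if has_utr3:
        blocks.append((utr3_len, "3UTR"))
    if strand == "-":
        blocks = blocks[::-1]

    pos = start
    segs = []
    for length, lab in blocks:
        segs.append((pos, pos + length, lab))
        pos += length
    end = pos

    exons, cds, utr5, utr3 = [], [], [], []
    cur_exon = None
    for s, e, lab in segs:
        if lab == "intron":
            if cur_exon:
                exons.append(tuple(cur_exon))
                cur_exon = None
            continue
        if cur_exon is None:
            cur_exon = [s, e]
        else:
            cur_exon[1] = e
        if lab == "CDS":
            cds.append((s, e))
        elif lab == "5UTR":
            utr5.append((s, e))
        else:
            utr3.append((s, e))
    if cur_exon:
        exons.append(tuple(cur_exon))

    t = Transcript(transcript_id=f"{gene_id}.1", gene_id=gene_id, chrom=chrom,
                   strand=strand, exons=tuple(exons), cds=tuple(cds),
                   utr5=tuple(utr5), utr3=tuple(utr3))
    return t, end - start


def simulate_genome(config: SimConfig, params: Parameters | None = None):
    """Generate (genome, transcripts, models, truth).

    * ``genome``: dict chrom -> sequence string (uniform base composition
      outside planted A/T tracts);
    * ``transcripts``: list of Transcript (for GFF3 emission);
    * ``models``: gene_id -> merged+extended GeneModel;
    * ``truth``: :class:`GroundTruth` with planted sites and A-tract loci.
    """
    config.validate()
    params = params or Parameters()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0]))
    chrom_names = [f"chr{i + 1}" for i in range(config.n_chromosomes)]
    seqs = {c: np.array(list("ACGT"))[rng.integers(0, 4, config.chrom_length)]
            for c in chrom_names}
    chrom_lengths = {c: config.chrom_length for c in chrom_names}

    transcripts, truth = [], GroundTruth()
    # --- gene placement -----------------------------------------------------
    per_chrom = [config.n_genes // config.n_chromosomes] * config.n_chromosomes
    for i in range(config.n_genes % config.n_chromosomes):
        per_chrom[i] += 1
    gene_no = 0
    for chrom, n_here in zip(chrom_names, per_chrom):
        cursor = 2500
        n_pairs = int(round(config.fraction_convergent_pairs * n_here / 2))
        remaining_pairs = n_pairs
        placed = 0
        while placed < n_here:
            if remaining_pairs > 0 and placed + 2 <= n_here:
                gid_a = f"G{gene_no + 1:04d}"
                ta, len_a = _build_gene(rng, config, gid_a, chrom, "+", cursor)
                gap = int(rng.integers(40, 900))
                gid_b = f"G{gene_no + 2:04d}"
                tb, len_b = _build_gene(rng, config, gid_b, chrom, "-",
                                        cursor + len_a + gap)
                unit_end = cursor + len_a + gap + len_b
                if unit_end > config.chrom_length - 600:
                    break
                transcripts += [ta, tb]
                gene_no += 2
                placed += 2
                remaining_pairs -= 1
                cursor = unit_end + int(rng.integers(900, 2500))
            else:
                gid = f"G{gene_no + 1:04d}"
                strand = "+" if rng.random() < 0.5 else "-"
                t, glen = _build_gene(rng, config, gid, chrom, strand, cursor)
                if cursor + glen > config.chrom_length - 600:
                    break
                transcripts.append(t)
                gene_no += 1
                placed += 1
                cursor += glen + int(rng.integers(900, 2500))
        if placed < n_here:
            raise ValueError(f"chromosome {chrom} too short to place {n_here} genes; "
                             "increase chrom_length")

    models = [annotation.merge_gene([t]) for t in transcripts]
    annotation.extend_models(models, chrom_lengths, params)
    models = {m.gene_id: m for m in models}

    # --- planted A/T tracts --------------------------------------------------
    occupied = {c: set() for c in chrom_names}
    for chrom in chrom_names:
        n_tracts = int(round(config.a_tract_density * config.chrom_length / 1000))
        tries = 0
        while n_tracts > 0 and tries < 50 * n_tracts + 100:
            tries += 1
            length = int(rng.integers(6, 10))
            start = int(rng.integers(100, config.chrom_length - 100 - length))
            span = set(range(start - 12, start + length + 12))
            if span & occupied[chrom]:
                continue
            strand = "+" if rng.random() < 0.5 else "-"
            base = "A" if strand == "+" else "T"
            seqs[chrom][start:start + length] = base
            occupied[chrom] |= span
            truth.a_tracts.append((chrom, strand, start, length))
            n_tracts -= 1

    genome_arr = seqs  # still mutable; site placement may sanitize windows

    # --- planted poly(A) sites ------------------------------------------------
    site_positions = {}  # (chrom, strand) -> sorted-ish list of planted coords
    site_no = 0
    for t in transcripts:
        m = models[t.gene_id]
        k = 1 + int(rng.choice(5, p=config.planted_sites_per_gene))
        for _ in range(k):
            region = REGION_CHOICES[int(rng.choice(4, p=config.site_region_mix))]
            planted = _plant_site(rng, config, m, region, genome_arr,
                                  occupied, site_positions, models, params,
                                  site_id=f"S{site_no + 1:05d}")
            if planted is not None:
                truth.planted_sites.append(planted)
                site_no += 1

    genome = {c: "".join(genome_arr[c]) for c in chrom_names}
    return genome, transcripts, models, truth


def _candidate_interval(m: GeneModel, region: str, rng):
    """A genomic interval eligible for a planted site of this region."""
    margin = 12
    if region == "3UTR":
        cands = [(s, e) for s, e, lab in m.segments if lab == "3UTR"]
        if not cands and m.extended_3utr is not None:
            cands = [m.extended_3utr]
    elif region == "intron":
        cands = [(s, e) for s, e, lab in m.segments if lab == "intron"]
    elif region == "CDS":
        cands = [(s, e) for s, e, lab in m.segments if lab == "CDS"]
    else:  # antisense: anywhere in the gene body
        cands = [(m.start, m.end)]
    cands = [(s + margin, e - margin) for s, e in cands if e - s > 2 * margin + 2]
    if not cands:
        return None
    return cands[int(rng.integers(0, len(cands)))]


def _plant_site(rng, cfg, m, region, genome_arr, occupied, site_positions,
                models, params, site_id):
    """Place one site; falls back 3UTR<-intron when a region is unavailable."""
    actual = region
    iv = _candidate_interval(m, region, rng)
    if iv is None and region == "intron":
        actual = "3UTR"
        iv = _candidate_interval(m, "3UTR", rng)
    if iv is None and region != "CDS":
        actual = "CDS"
        iv = _candidate_interval(m, "CDS", rng)
    if iv is None:
        return None
    strand = m.strand if actual != "antisense" else ("-" if m.strand == "+" else "+")
    key = (m.chrom, strand)
    placed_here = site_positions.setdefault(key, [])
    for _ in range(60):
        coord = int(rng.integers(iv[0], iv[1]))
        if any(abs(coord - p) < 50 for p in placed_here):
            continue
        if not _sanitize_downstream(genome_arr[m.chrom], strand, coord,
                                    occupied[m.chrom], rng, params):
            continue
        placed_here.append(coord)
        case = (_expected_antisense_case(m.chrom, strand, coord, models, params)
                if actual == "antisense" else None)
        return PlantedSite(site_id=site_id, chrom=m.chrom, strand=strand,
                           coord=coord, gene_id=m.gene_id, region=actual,
                           antisense_case=case)
    return None


def _sanitize_downstream(seq_arr, strand, coord, occupied, rng, params: Parameters):
    """Ensure the downstream priming window of a real site has no A>=run tract.

    Runs arising from the uniform background are broken by mutating one
    base; windows overlapping a planted tract reject the site instead.
    """
    w = params.internal_priming_window
    run = params.internal_priming_a_run
    if strand == "+":
        lo, hi = coord + 1, min(len(seq_arr), coord + 1 + w)
        base = "A"
        repl = "C"
    else:
        lo, hi = max(0, coord - w), coord
        base = "T"
        repl = "G"
    if any(p in occupied for p in range(lo, hi)):
        return False
    window = seq_arr[lo:hi]
    n = 0
    for i, ch in enumerate(window):
        n = n + 1 if ch == base else 0
        if n >= run:
            # break the run in the middle
            seq_arr[lo + i - run // 2] = repl
            n = 0
    return True


def _expected_antisense_case(chrom, strand, coord, models, params: Parameters):
    """Analytic antisense case from the planted geometry (cases 1-4)."""
    covering = []
    for m in models.values():
        if m.chrom != chrom or m.strand != strand:
            continue
        lab = m.label_at(coord)
        if lab is None and m.extended_3utr is not None \
                and m.extended_3utr[0] <= coord < m.extended_3utr[1]:
            lab = "3UTR"
        if lab is not None:
            covering.append((abs(coord - m.three_prime_end), m.gene_id, lab))
    if covering:
        _, _, lab = min(covering)
        return 1 if lab == "3UTR" else 2
    best = None
    for m in models.values():
        if m.chrom != chrom or m.strand != strand:
            continue
        d = coord - m.three_prime_end if strand == "+" else m.three_prime_end - coord
        if d >= 0 and (best is None or d < best):
            best = d
    return 3 if (best is not None and best <= params.nearby_antisense_distance) else 4


# ---------------------------------------------------------------------------
# tags
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SimTag:
    """A simulated mapped tag carrying its ground-truth origin."""

    tag_id: str
    chrom: str
    strand: str
    cleavage_pos: int
    count: int
    mate_status: str
    site_id: str | None          # None for artifact tags

    def as_mapped_tag(self) -> MappedTag:
        return MappedTag(tag_id=self.tag_id, chrom=self.chrom, strand=self.strand,
                         cleavage_pos=self.cleavage_pos, count=self.count,
                         mate_status=self.mate_status)


def simulate_tags(genome, models, truth: GroundTruth, config: SimConfig,
                  unpaired_rate: float = 0.0) -> list:
    """Emit tag records for every planted site plus internal-priming artifacts.

    Tags of one site are jittered by a discrete truncated normal
    (sd = ``microheterogeneity_sd``, truncation +/-11 nt) and aggregated
    per distinct cleavage position.  Artifact tags are placed immediately
    upstream of planted A-tracts at ``internal_priming_rate`` of the total
    read count.  ``unpaired_rate`` marks that fraction of real reads as
    lacking a mapped 5' mate.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    tags = []
    total_reads = 0
    for site in truth.planted_sites:
        clen = len(genome[site.chrom])
        if not (0 <= site.coord < clen):
            warnings.warn(f"site {site.site_id} outside chromosome bounds; skipped")
            continue
        n = max(1, int(rng.poisson(config.tags_per_site)))
        if config.microheterogeneity_sd == 0:
            offsets = np.zeros(n, dtype=int)
        else:
            offsets = np.rint(rng.normal(0.0, config.microheterogeneity_sd, n)).astype(int)
            offsets = np.clip(offsets, -JITTER_TRUNCATION, JITTER_TRUNCATION)
        positions, counts = np.unique(site.coord + offsets, return_counts=True)
        keep = (positions >= 0) & (positions < clen)
        positions, counts = positions[keep], counts[keep]
        for j, (pos, cnt) in enumerate(zip(positions, counts)):
            mate = "paired_unique"
            if unpaired_rate > 0 and rng.random() < unpaired_rate:
                mate = "unpaired" if rng.random() < 0.5 else "mate_multimapped"
            tags.append(SimTag(tag_id=f"{site.site_id}.{j}", chrom=site.chrom,
                               strand=site.strand, cleavage_pos=int(pos),
                               count=int(cnt), mate_status=mate,
                               site_id=site.site_id))
            total_reads += int(cnt)

    if config.internal_priming_rate > 0 and truth.a_tracts:
        n_art = int(round(config.internal_priming_rate /
                          (1.0 - config.internal_priming_rate) * total_reads))
        per_pos = {}
        for _ in range(n_art):
            chrom, strand, start, length = truth.a_tracts[
                int(rng.integers(0, len(truth.a_tracts)))]
            pos = start - 1 if strand == "+" else start + length
            per_pos[(chrom, strand, pos)] = per_pos.get((chrom, strand, pos), 0) + 1
        for k, ((chrom, strand, pos), cnt) in enumerate(sorted(per_pos.items())):
            if not (0 <= pos < len(genome[chrom])):
                continue
            tag_id = f"ART{k + 1:04d}"
            tags.append(SimTag(tag_id=tag_id, chrom=chrom, strand=strand,
                               cleavage_pos=pos, count=cnt,
                               mate_status="paired_unique", site_id=None))
            truth.artifact_tags.append(tag_id)
    elif config.internal_priming_rate > 0:
        warnings.warn("internal_priming_rate > 0 but no A-tracts were planted")
    return tags


# ---------------------------------------------------------------------------
# ortholog tables
# ---------------------------------------------------------------------------

def simulate_ortholog_table(n_pairs: int, shared_feature_rates, seed: int = 0):
    """One-to-one ortholog pairs with planted per-feature sharing.

    ``shared_feature_rates`` maps a feature name to ``(rate_a, rate_b,
    joint_rate)``: the marginal feature rates in species A and B and the
    joint rate (both orthologs carry the feature).  ``joint = rate_a *
    rate_b`` plants independence; a larger joint plants conservation
    enrichment.  Returns a dataframe with columns ``gene_a``, ``gene_b``
    and ``<feature>_a`` / ``<feature>_b`` Boolean flags.
    """
    rng = np.random.default_rng(seed)
    for feat, (ra, rb, joint) in dict(shared_feature_rates).items():
        for name, v in (("rate_a", ra), ("rate_b", rb), ("joint", joint)):
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{feat}.{name}={v} must be in [0, 1]")
        if joint > min(ra, rb) + 1e-12 or ra + rb - joint > 1.0 + 1e-12:
            raise ValueError(f"{feat}: joint rate {joint} incompatible with "
                             f"marginals ({ra}, {rb})")
    data = {"gene_a": [f"A{i + 1:05d}" for i in range(n_pairs)],
            "gene_b": [f"B{i + 1:05d}" for i in range(n_pairs)]}
    for feat, (ra, rb, joint) in dict(shared_feature_rates).items():
        u = rng.random(n_pairs)
        both = u < joint
        a_only = (u >= joint) & (u < ra)
        b_only = (u >= ra) & (u < ra + rb - joint)
        data[f"{feat}_a"] = both | a_only
        data[f"{feat}_b"] = both | b_only
    return pd.DataFrame(data)


def simulate_ortholog_utr_lengths(n_pairs: int, r: float,
                                  mean_a: float = 200.0, sd_a: float = 70.0,
                                  mean_b: float = 180.0, sd_b: float = 60.0,
                                  seed: int = 0):
    """Per-gene 3'-UTR lengths for an ortholog set with planted Pearson r.

    Returns ``(lengths_a, lengths_b, pairs)`` with lengths floored at 1 nt.
    """
    if not (-1.0 <= r <= 1.0):
        raise ValueError("correlation must lie in [-1, 1]")
    rng = np.random.default_rng(seed)
    cov = [[sd_a ** 2, r * sd_a * sd_b], [r * sd_a * sd_b, sd_b ** 2]]
    xy = rng.multivariate_normal([mean_a, mean_b], cov, size=n_pairs)
    la = np.maximum(1, np.rint(xy[:, 0])).astype(int)
    lb = np.maximum(1, np.rint(xy[:, 1])).astype(int)
    genes_a = [f"A{i + 1:05d}" for i in range(n_pairs)]
    genes_b = [f"B{i + 1:05d}" for i in range(n_pairs)]
    return (dict(zip(genes_a, la.tolist())), dict(zip(genes_b, lb.tolist())),
            list(zip(genes_a, genes_b)))


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def genome_to_fasta(genome, path_or_handle=None, width: int = 70):
    lines = []
    for chrom in sorted(genome):
        lines.append(f">{chrom}")
        seq = genome[chrom]
        lines += [seq[i:i + width] for i in range(0, len(seq), width)]
    text = "\n".join(lines) + "\n"
    if path_or_handle is None:
        return text
    if hasattr(path_or_handle, "write"):
        path_or_handle.write(text)
    else:
        with open(path_or_handle, "w") as fh:
            fh.write(text)
    return None


def read_fasta(path) -> dict:
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def transcripts_to_gff3(transcripts, path_or_handle=None):
    """Emit gene/mRNA/exon/CDS/UTR features (1-based inclusive)."""
    lines = ["##gff-version 3"]
    for t in sorted(transcripts, key=lambda t: (t.chrom, t.start, t.gene_id)):
        g0, g1 = t.start, t.end
        lines.append("\t".join([t.chrom, "polyaflow_sim", "gene", str(g0 + 1),
                                str(g1), ".", t.strand, ".", f"ID={t.gene_id}"]))
        lines.append("\t".join([t.chrom, "polyaflow_sim", "mRNA", str(g0 + 1),
                                str(g1), ".", t.strand, ".",
                                f"ID={t.transcript_id};Parent={t.gene_id}"]))
        for ftype, blocks in (("exon", t.exons), ("CDS", t.cds),
                              ("five_prime_UTR", t.utr5),
                              ("three_prime_UTR", t.utr3)):
            for s, e in blocks:
                lines.append("\t".join([t.chrom, "polyaflow_sim", ftype,
                                        str(s + 1), str(e), ".", t.strand,
                                        "0" if ftype == "CDS" else ".",
                                        f"Parent={t.transcript_id}"]))
    text = "\n".join(lines) + "\n"
    if path_or_handle is None:
        return text
    if hasattr(path_or_handle, "write"):
        path_or_handle.write(text)
    else:
        with open(path_or_handle, "w") as fh:
            fh.write(text)
    return None


def truth_to_json(truth: GroundTruth, path_or_handle=None):
    payload = {
        "planted_sites": [dataclasses.asdict(s) for s in truth.planted_sites],
        "artifact_tags": list(truth.artifact_tags),
        "a_tracts": [list(t) for t in truth.a_tracts],
    }
    text = json.dumps(payload, indent=1, sort_keys=True) + "\n"
    if path_or_handle is None:
        return text
    if hasattr(path_or_handle, "write"):
        path_or_handle.write(text)
    else:
        with open(path_or_handle, "w") as fh:
            fh.write(text)
    return None
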