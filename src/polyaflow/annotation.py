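"""Gene-model handling: GFF3 parsing, isoform merging, 3' extension, indexing.

Internally every interval is 0-based half-open; GFF3 I/O converts to and
from the on-disk 1-based inclusive convention.

A gene is represented by a single merged :class:`GeneModel` whose body is
tiled by non-overlapping labelled segments.  Positions whose label differs
between transcript isoforms (e.g. CDS in one isoform, intron in another)
are labelled ``AMB`` (ambiguous).  Models are then extended 3' of the gene
body to capture unannotated 3'-UTRs: genes with an annotated 3'-UTR get a
short extension, genes without get a long one, and an extension is
truncated where it would run into the body of a downstream gene on the
same strand (opposite-strand overlap is allowed -- convergent read-through
is exactly the phenomenon the antisense classifier looks for).
"""

from __future__ import annotations

import bisect
import warnings
from collections import defaultdict, namedtuple
from dataclasses import dataclass, field

import numpy as np
from intervaltree import IntervalTree

from .params import Parameters

GENE_BODY_LABELS = ("5UTR", "CDS", "intron", "3UTR", "AMB")
_LABEL_CODE = {lab: i + 1 for i, lab in enumerate(GENE_BODY_LABELS)}
_CODE_LABEL = {v: k for k, v in _LABEL_CODE.items()}

_GFF_TYPE = {"5UTR": "five_prime_UTR", "CDS": "CDS", "intron": "intron",
             "3UTR": "three_prime_UTR", "AMB": "AMB"}


@dataclass(frozen=True)
class Transcript:
    """One transcript isoform as read from GFF3 (0-based half-open blocks)."""

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: tuple
    cds: tuple = ()
    utr5: tuple = ()
    utr3: tuple = ()

    @property
    def start(self) -> int:
        return min(s for s, _ in self.exons)

    @property
    def end(self) -> int:
        return max(e for _, e in self.exons)


@dataclass
class GeneModel:
    """A merged, optionally 3'-extended gene model."""

    gene_id: str
    chrom: str
    strand: str
    #: non-overlapping (start, end, label) tuples tiling the gene body, sorted
    segments: list
    had_annotated_3utr: bool = False
    extended_3utr: tuple | None = None
    promoter: tuple | None = None

    @property
    def start(self) -> int:
        return self.segments[0][0]

    @property
    def end(self) -> int:
        return self.segments[-1][1]

    @property
    def three_prime_end(self) -> int:
        """Genomic coordinate of the body 3' terminus (half-open side for +)."""
        return self.end if self.strand == "+" else self.start

    @property
    def five_prime_end(self) -> int:
        return self.start if self.strand == "+" else self.end

    @property
    def extended_span(self) -> tuple:
        """Body plus 3' extension, as one (start, end) interval."""
        s, e = self.start, self.end
        if self.extended_3utr is not None:
            s = min(s, self.extended_3utr[0])
            e = max(e, self.extended_3utr[1])
        return s, e

    def label_at(self, pos: int) -> str | None:
        """Segment label covering ``pos`` in the gene body, else None."""
        for s, e, lab in self.segments:
            if s <= pos < e:
                return lab
        return None

    def cds_three_prime_end(self) -> int | None:
        """0-based coordinate of the last CDS base (stop-codon side)."""
        cds = [(s, e) for s, e, lab in self.segments if lab == "CDS"]
        if not cds:
            return None
        return max(e for _, e in cds) - 1 if self.strand == "+" else min(s for s, _ in cds)

    def introns(self) -> list:
        """(start, end) intron intervals in 5'->3' transcription order."""
        ivs = [(s, e) for s, e, lab in self.segments if lab == "intron"]
        return ivs if self.strand == "+" else ivs[::-1]

    def cds_segments(self) -> list:
        ivs = [(s, e) for s, e, lab in self.segments if lab == "CDS"]
        return ivs if self.strand == "+" else ivs[::-1]


# ---------------------------------------------------------------------------
# isoform merging
# ---------------------------------------------------------------------------

def _transcript_codes(t: Transcript, g0: int, g1: int) -> np.ndarray:
    """Per-position label codes of one transcript over [g0, g1); 0 = uncovered.

    Exonic positions without an explicit UTR/CDS feature are assigned a UTR
    label inferred from their side of the CDS span (the common case for
    prediction-based annotations that omit UTR features).
    """
    codes = np.zeros(g1 - g0, dtype=np.int8)
    exons = sorted(t.exons)
    # introns: gaps between consecutive exons
    for (s1, e1), (s2, _e2) in zip(exons, exons[1:]):
        codes[e1 - g0:s2 - g0] = _LABEL_CODE["intron"]
    for s, e in exons:
        codes[s - g0:e - g0] = _LABEL_CODE["AMB"]  # placeholder: exonic, unresolved
    for s, e in t.cds:
        codes[s - g0:e - g0] = _LABEL_CODE["CDS"]
    for s, e in t.utr5:
        codes[s - g0:e - g0] = _LABEL_CODE["5UTR"]
    for s, e in t.utr3:
        codes[s - g0:e - g0] = _LABEL_CODE["3UTR"]
    # resolve exonic positions still unlabelled relative to the CDS span
    unresolved = codes == _LABEL_CODE["AMB"]
    if unresolved.any():
        if t.cds:
            cs = min(s for s, _ in t.cds) - g0
            ce = max(e for _, e in t.cds) - g0
            idx = np.nonzero(unresolved)[0]
            before, after = idx[idx < cs], idx[idx >= ce]
            lab_before = "5UTR" if t.strand == "+" else "3UTR"
            lab_after = "3UTR" if t.strand == "+" else "5UTR"
            codes[before] = _LABEL_CODE[lab_before]
            codes[after] = _LABEL_CODE[lab_after]
            # exonic-inside-CDS-span yet not CDS: leave AMB (conflicting feature set)
        # no CDS at all: leave AMB (non-coding isoform)
    return codes


def _coalesce(codes: np.ndarray, g0: int) -> list:
    segments = []
    boundaries = np.nonzero(np.diff(codes))[0] + 1
    starts = np.concatenate(([0], boundaries))
    ends = np.concatenate((boundaries, [len(codes)]))
    for s, e in zip(starts, ends):
        c = int(codes[s])
        if c:
            segments.append((g0 + int(s), g0 + int(e), _CODE_LABEL[c]))
    return segments


def merge_gene(transcripts) -> GeneModel:
    """Merge transcript isoforms of one gene into a unique gene model.

    Positions annotated identically by every covering isoform keep that
    label; positions with conflicting labels become ``AMB``; positions
    inside the merged span covered by no isoform become ``intron``.
    """
    transcripts = list(transcripts)
    if not transcripts:
        raise ValueError("merge_gene requires at least one transcript")
    gene_id = transcripts[0].gene_id
    strands = {t.strand for t in transcripts}
    if len(strands) > 1:
        raise ValueError(f"gene {gene_id}: transcripts on mixed strands {sorted(strands)}")
    chroms = {t.chrom for t in transcripts}
    if len(chroms) > 1:
        raise ValueError(f"gene {gene_id}: transcripts on multiple chromosomes")
    g0 = min(t.start for t in transcripts)
    g1 = max(t.end for t in transcripts)
    merged = np.zeros(g1 - g0, dtype=np.int8)
    conflict = np.zeros(g1 - g0, dtype=bool)
    for t in transcripts:
        codes = _transcript_codes(t, g0, g1)
        covered = codes > 0
        fresh = covered & (merged == 0)
        merged[fresh] = codes[fresh]
        conflict |= covered & (merged > 0) & (codes != merged)
    merged[conflict] = _LABEL_CODE["AMB"]
    merged[merged == 0] = _LABEL_CODE["intron"]  # between disjoint isoforms
    segments = _coalesce(merged, g0)
    strand = transcripts[0].strand
    terminal = segments[-1][2] if strand == "+" else segments[0][2]
    # a gene "has" a 3'-UTR when its body extends 3' of the CDS
    had_utr3 = terminal in ("3UTR", "AMB")
    return GeneModel(gene_id=gene_id, chrom=transcripts[0].chrom, strand=strand,
                     segments=segments, had_annotated_3utr=had_utr3)


# ---------------------------------------------------------------------------
# 3' extension and promoter windows
# ---------------------------------------------------------------------------

def extend_model(model: GeneModel, chrom_length: int, params: Parameters,
                 downstream_limit: int | None = None) -> GeneModel:
    """Attach the 3' extension and promoter window to a gene model.

    ``downstream_limit`` is the boundary of the nearest same-strand gene
    body in the extension direction; the extension is truncated there.
    The promoter spans ``promoter_extent`` nt upstream of the 5'-most
    transcribed coordinate, clipped at the chromosome edge.
    """
    ext = params.ext_with_utr if model.had_annotated_3utr else params.ext_without_utr
    if model.strand == "+":
        e0 = model.end
        e1 = min(chrom_length, e0 + ext)
        if downstream_limit is not None:
            e1 = min(e1, max(e0, downstream_limit))
        extended = (e0, e1) if e1 > e0 else None
        p1 = model.start
        promoter = (max(0, p1 - params.promoter_extent), p1) if p1 > 0 else None
    else:
        e1 = model.start
        e0 = max(0, e1 - ext)
        if downstream_limit is not None:
            e0 = max(e0, min(e1, downstream_limit))
        extended = (e0, e1) if e1 > e0 else None
        p0 = model.end
        promoter = (p0, min(chrom_length, p0 + params.promoter_extent))
        if promoter[1] <= promoter[0]:
            promoter = None
    model.extended_3utr = extended
    model.promoter = promoter
    return model


def extend_models(models, chrom_lengths, params: Parameters):
    """Extend every model, truncating at downstream same-strand gene bodies."""
    models = list(models)
    by_cs = defaultdict(list)
    for m in models:
        by_cs[(m.chrom, m.strand)].append(m)
    for (chrom, strand), group in by_cs.items():
        clen = chrom_lengths[chrom]
        if strand == "+":
            starts = sorted(m.start for m in group)
            for m in group:
                i = bisect.bisect_left(starts, m.end)
                limit = starts[i] if i < len(starts) else None
                extend_model(m, clen, params, downstream_limit=limit)
        else:
            ends = sorted(m.end for m in group)
            for m in group:
                i = bisect.bisect_right(ends, m.start)
                limit = ends[i - 1] if i > 0 else None
                extend_model(m, clen, params, downstream_limit=limit)
    return models


# ---------------------------------------------------------------------------
# GFF3 I/O
# ---------------------------------------------------------------------------

def read_transcripts(gff3_path) -> list:
    """Parse gene/mRNA/exon/CDS/UTR features from a GFF3 file."""
    import gffutils

    db = gffutils.create_db(str(gff3_path), dbfn=":memory:", force=True,
                            keep_order=True, merge_strategy="create_unique")
    transcripts = []
    for mrna in db.features_of_type(("mRNA", "transcript")):
        parents = mrna.attributes.get("Parent", [])
        gene_id = parents[0] if parents else mrna.id

        def blocks(ftype):
            return tuple(sorted((f.start - 1, f.end)
                                for f in db.children(mrna, featuretype=ftype)))

        exons = blocks("exon")
        cds = blocks("CDS")
        if not exons:
            exons = cds or ((mrna.start - 1, mrna.end),)
        transcripts.append(Transcript(
            transcript_id=mrna.id, gene_id=gene_id, chrom=mrna.seqid,
            strand=mrna.strand, exons=exons, cds=cds,
            utr5=blocks("five_prime_UTR"), utr3=blocks("three_prime_UTR")))
    return transcripts


def read_gene_models(gff3_path, chrom_lengths, params: Parameters) -> dict:
    """GFF3 -> merged, extended gene models keyed by gene id."""
    by_gene = defaultdict(list)
    for t in read_transcripts(gff3_path):
        by_gene[t.gene_id].append(t)
    models = [merge_gene(ts) for ts in by_gene.values()]
    extend_models(models, chrom_lengths, params)
    return {m.gene_id: m for m in models}


def write_gene_models_gff3(models, path_or_handle) -> None:
    """Write merged+extended models as GFF3 (AMB as a custom feature type)."""
    lines = ["##gff-version 3"]
    for m in sorted(models, key=lambda m: (m.chrom, m.start, m.gene_id)):
        ext_len = 0 if m.extended_3utr is None else m.extended_3utr[1] - m.extended_3utr[0]
        attrs = (f"ID={m.gene_id};extension_length={ext_len};"
                 f"had_annotated_3utr={int(m.had_annotated_3utr)}")
        lines.append("\t".join([m.chrom, "polyaflow", "gene", str(m.start + 1),
                                str(m.end), ".", m.strand, ".", attrs]))
        for s, e, lab in m.segments:
            lines.append("\t".join([m.chrom, "polyaflow", _GFF_TYPE[lab],
                                    str(s + 1), str(e), ".", m.strand, ".",
                                    f"Parent={m.gene_id}"]))
        if m.extended_3utr is not None:
            s, e = m.extended_3utr
            lines.append("\t".join([m.chrom, "polyaflow", "three_prime_UTR_extension",
                                    str(s + 1), str(e), ".", m.strand, ".",
                                    f"Parent={m.gene_id};extension_length={ext_len}"]))
    text = "\n".join(lines) + "\n"
    if hasattr(path_or_handle, "write"):
        path_or_handle.write(text)
    else:
        with open(path_or_handle, "w") as fh:
            fh.write(text)


# ---------------------------------------------------------------------------
# interval index
# ---------------------------------------------------------------------------

Hit = namedtuple("Hit", "gene_id strand kind label start end")


class GenomeIndex:
    """Strand-aware point-query index over gene bodies, extensions, promoters."""

    def __init__(self, models):
        self._trees = defaultdict(IntervalTree)
        self._warned = set()
        self.models = {m.gene_id: m for m in models}
        for m in self.models.values():
            tree = self._trees[m.chrom]
            for s, e, lab in m.segments:
                tree[s:e] = Hit(m.gene_id, m.strand, "body", lab, s, e)
            if m.extended_3utr is not None:
                s, e = m.extended_3utr
                tree[s:e] = Hit(m.gene_id, m.strand, "extension", "3UTR", s, e)
            if m.promoter is not None:
                s, e = m.promoter
                tree[s:e] = Hit(m.gene_id, m.strand, "promoter", "promoter", s, e)

    def query(self, chrom: str, pos: int, strand: str | None = None) -> list:
        """All hits covering (chrom, pos); restrict to one strand if given."""
        if chrom not in self._trees:
            if chrom not in self._warned:
                warnings.warn(f"query on unknown chromosome {chrom!r}")
                self._warned.add(chrom)
            return []
        hits = [iv.data for iv in self._trees[chrom][pos]]
        if strand is not None:
            hits = [h for h in hits if h.strand == strand]
        return sorted(hits, key=lambda h: (h.kind, h.gene_id, h.start))
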