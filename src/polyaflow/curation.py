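"""Poly(A)-tag curation: poly(T) calling, mate concordance, internal priming.

The curation cascade mirrors the usual 3'-end sequencing QC ladder: raw
reads are kept only when they begin with an oligo-T stretch (evidence of a
reverse-transcribed poly(A) tail), mapped tags are kept only when their 5'
mate also mapped uniquely, and tags whose downstream genomic sequence is
an oligo-A tract are discarded as internal-priming artifacts (oligo-dT
primed inside the transcript body rather than at the tail).

The cleavage coordinate of a tag is the 0-based genomic position of the
last transcribed nucleotide before the poly(A) tail, strand-aware.  In the
6-column BED dialect used here, a tag record marks that single base
(``start = cleavage_pos``, ``end = cleavage_pos + 1``), the name field
carries ``tag_id|mate_status``, and the score field the read count.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, replace

from .params import Parameters

MATE_STATUSES = ("paired_unique", "unpaired", "mate_multimapped")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class MappedTag:
    """One curated poly(A) tag (possibly aggregating duplicate reads)."""

    tag_id: str
    chrom: str
    strand: str
    cleavage_pos: int
    count: int = 1
    mate_status: str = "paired_unique"

    def __post_init__(self):
        if self.count < 1:
            raise ValueError(f"tag {self.tag_id}: count must be >= 1")
        if self.strand not in "+-":
            raise ValueError(f"tag {self.tag_id}: bad strand {self.strand!r}")


# ---------------------------------------------------------------------------
# raw-read classification
# ---------------------------------------------------------------------------

def classify_raw_tag(sequence: str, min_t_run: int = 8):
    """Classify a raw read as a poly(T) tag.

    Returns ``(verdict, remainder)`` where verdict is ``"polyT"`` iff the
    read begins with at least ``min_t_run`` consecutive T, and remainder is
    the read with the leading T stretch trimmed (unchanged otherwise).
    """
    if not sequence:
        raise ValueError("empty read sequence")
    n = 0
    for ch in sequence:
        if ch != "T":
            break
        n += 1
    if n >= min_t_run:
        return "polyT", sequence[n:]
    return "not_polyT", sequence


# ---------------------------------------------------------------------------
# filters
# ---------------------------------------------------------------------------

def filter_pairing(tags):
    """Keep only tags whose 5' mate mapped uniquely."""
    return [t for t in tags if t.mate_status == "paired_unique"]


def aggregate_tags(tags):
    """Merge tags sharing (chrom, strand, cleavage_pos), summing counts.

    Clustering semantics depend on distinct positions, not read
    multiplicity, so duplicates collapse to one tag before clustering.
    """
    merged = {}
    for t in sorted(tags, key=lambda t: (t.chrom, t.strand, t.cleavage_pos, t.tag_id)):
        key = (t.chrom, t.strand, t.cleavage_pos)
        if key in merged:
            prev = merged[key]
            merged[key] = replace(prev, count=prev.count + t.count)
        else:
            merged[key] = t
    return [merged[k] for k in sorted(merged)]


def _has_a_run(window: str, run: int) -> bool:
    return "A" * run in window


def downstream_window(genome, tag, width: int) -> str:
    """Genomic ``width``-mer immediately downstream of the cleavage site,
    on the tag's sense strand (reverse-complemented for minus-strand tags),
    clipped at the chromosome edge."""
    seq = genome[tag.chrom]
    if tag.strand == "+":
        return seq[tag.cleavage_pos + 1:tag.cleavage_pos + 1 + width]
    lo = max(0, tag.cleavage_pos - width)
    return revcomp(seq[lo:tag.cleavage_pos])


def filter_internal_priming(tags, genome, params: Parameters):
    """Partition tags into (kept, discarded-as-internal-priming).

    A tag is discarded iff the ``internal_priming_window`` nt immediately
    downstream of its cleavage position (sense strand) contain a run of at
    least ``internal_priming_a_run`` consecutive A.
    """
    kept, discarded = [], []
    for t in tags:
        w = downstream_window(genome, t, params.internal_priming_window)
        (discarded if _has_a_run(w, params.internal_priming_a_run) else kept).append(t)
    return kept, discarded


@dataclass
class CurationReport:
    """Per-stage tag counts of the curation cascade (read counts, not positions)."""

    input_tags: int = 0
    paired_tags: int = 0
    curated_tags: int = 0          # after internal-priming removal
    internal_priming_tags: int = 0
    distinct_positions: int = 0

    def rows(self):
        return [("input tags", self.input_tags),
                ("paired tags", self.paired_tags),
                ("curated tags (internal priming excluded)", self.curated_tags)]

    def to_tsv(self) -> str:
        lines = ["stage\ttag_count"]
        lines += [f"{name}\t{n}" for name, n in self.rows()]
        return "\n".join(lines) + "\n"


def curate_tags(tags, genome, params: Parameters):
    """Run the full cascade; returns (curated tags, discarded tags, report)."""
    tags = list(tags)
    report = CurationReport(input_tags=sum(t.count for t in tags))
    paired = filter_pairing(tags)
    report.paired_tags = sum(t.count for t in paired)
    paired = aggregate_tags(paired)
    kept, discarded = filter_internal_priming(paired, genome, params)
    report.curated_tags = sum(t.count for t in kept)
    report.internal_priming_tags = sum(t.count for t in discarded)
    report.distinct_positions = len(kept)
    return kept, discarded, report


# ---------------------------------------------------------------------------
# BED I/O
# ---------------------------------------------------------------------------

def read_tags_bed(path) -> list:
    tags = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track")):
                continue
            chrom, start, end, name, score, strand = line.split("\t")[:6]
            tag_id, _, mate = name.partition("|")
            mate = mate or "paired_unique"
            start, end = int(start), int(end)
            pos = start if strand == "-" else end - 1
            tags.append(MappedTag(tag_id=tag_id, chrom=chrom, strand=strand,
                                  cleavage_pos=pos, count=int(score),
                                  mate_status=mate))
    return tags


def write_tags_bed(tags, path_or_handle) -> None:
    lines = []
    for t in sorted(tags, key=lambda t: (t.chrom, t.cleavage_pos, t.strand, t.tag_id)):
        lines.append("\t".join([t.chrom, str(t.cleavage_pos), str(t.cleavage_pos + 1),
                                f"{t.tag_id}|{t.mate_status}", str(t.count), t.strand]))
    text = "\n".join(lines) + ("\n" if lines else "")
    if hasattr(path_or_handle, "write"):
        path_or_handle.write(text)
    else:
        with open(path_or_handle, "w") as fh:
            fh.write(text)
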