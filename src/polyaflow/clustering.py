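"""PAC calling: single-linkage chaining of cleavage positions.

Cleavage of a given pre-mRNA is microheterogeneous: reads from one
biological poly(A) site scatter over a few nucleotides.  Curated tags are
therefore chained into poly(A)-site clusters (PACs): within one (chrom,
strand), adjacent distinct cleavage positions separated by fewer than
``cluster_gap`` (default 24) nt join the same PAC.  The gap applies to
adjacent positions (chaining), not to the cluster diameter.  Each PAC is
represented by its summit -- the position with the highest read support,
ties broken toward the 3'-most position.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass

from .params import Parameters


@dataclass(frozen=True)
class PAC:
    """A poly(A)-site cluster."""

    pac_id: str
    chrom: str
    strand: str
    start: int           # half-open span over member cleavage positions
    end: int
    summit: int
    tag_count: int
    n_positions: int

    @property
    def span(self) -> tuple:
        return self.start, self.end


def cluster_tags(tags, params: Parameters) -> list:
    """Chain deduplicated tags into PACs per (chromosome, strand)."""
    groups = defaultdict(list)
    for t in tags:
        groups[(t.chrom, t.strand)].append(t)
    pacs = []
    for (chrom, strand) in sorted(groups):
        members = sorted(groups[(chrom, strand)], key=lambda t: t.cleavage_pos)
        run = [members[0]]
        for t in members[1:]:
            if t.cleavage_pos - run[-1].cleavage_pos < params.cluster_gap:
                run.append(t)
            else:
                pacs.append(_make_pac(run, chrom, strand))
                run = [t]
        pacs.append(_make_pac(run, chrom, strand))
    pacs.sort(key=lambda p: (p.chrom, p.start, p.strand))
    return [PAC(pac_id=f"PAC{i + 1:06d}", chrom=p.chrom, strand=p.strand,
                start=p.start, end=p.end, summit=p.summit,
                tag_count=p.tag_count, n_positions=p.n_positions)
            for i, p in enumerate(pacs)]


def _make_pac(run, chrom, strand) -> PAC:
    # summit: max count; ties broken toward the 3'-most position (strand-aware)
    if strand == "+":
        summit_tag = max(run, key=lambda t: (t.count, t.cleavage_pos))
    else:
        summit_tag = max(run, key=lambda t: (t.count, -t.cleavage_pos))
    return PAC(pac_id="", chrom=chrom, strand=strand,
               start=run[0].cleavage_pos, end=run[-1].cleavage_pos + 1,
               summit=summit_tag.cleavage_pos,
               tag_count=sum(t.count for t in run), n_positions=len(run))


def single_tag_pac_partition(pacs):
    """Split PACs into (single-read PACs, multi-read PACs)."""
    singles = [p for p in pacs if p.tag_count == 1]
    multis = [p for p in pacs if p.tag_count > 1]
    return singles, multis


# ---------------------------------------------------------------------------
# per-gene APA summaries
# ---------------------------------------------------------------------------

GENE_REGIONS = ("3UTR", "5UTR", "CDS", "intron", "AMB")


def pacs_per_gene(assignments):
    """Per-gene PAC counts from sense assignments to gene regions.

    ``assignments`` is the dataframe from :func:`polyaflow.assignment.assign_all`;
    only sense-orientation rows with a gene-body region (3UTR/5UTR/CDS/
    intron/AMB) count, matching a per-gene tabulation over annotated regions.

    Returns ``(per_gene, marginal, frac_multi)`` where ``marginal`` maps
    the bins 1, 2, 3, 4, 5 (">=5") to gene counts.
    """
    sense = assignments[(assignments["orientation"] == "sense")
                        & assignments["region"].isin(GENE_REGIONS)]
    per_gene = sense.groupby("gene_id")["pac_id"].nunique()
    marginal = {k: 0 for k in (1, 2, 3, 4, 5)}
    for n in per_gene:
        marginal[min(int(n), 5)] += 1
    return per_gene, marginal, fraction_multi_pac(marginal)


def fraction_multi_pac(marginal) -> float:
    """Fraction of genes with more than one PAC, from a {1,2,3,4,>=5} table."""
    total = sum(marginal.values())
    if total == 0:
        return 0.0
    return 1.0 - marginal.get(1, 0) / total


def apa_table_tsv(marginal) -> str:
    total = sum(marginal.values())
    lines = ["n_pacs\tn_genes\tpct_genes"]
    for k in (1, 2, 3, 4, 5):
        name = ">=5" if k == 5 else str(k)
        n = marginal.get(k, 0)
        pct = 100.0 * n / total if total else 0.0
        lines.append(f"{name}\t{n}\t{pct:.1f}")
    lines.append(f"total\t{total}\t100.0" if total else "total\t0\t0.0")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# PAC I/O
# ---------------------------------------------------------------------------

def write_pacs_gff3(pacs, path_or_handle) -> None:
    lines = ["##gff-version 3"]
    for p in pacs:
        attrs = (f"ID={p.pac_id};tag_count={p.tag_count};summit={p.summit + 1};"
                 f"n_positions={p.n_positions}")
        lines.append("\t".join([p.chrom, "polyaflow", "PAC", str(p.start + 1),
                                str(p.end), str(p.tag_count), p.strand, ".", attrs]))
    text = "\n".join(lines) + "\n"
    if hasattr(path_or_handle, "write"):
        path_or_handle.write(text)
    else:
        with open(path_or_handle, "w") as fh:
            fh.write(text)


def write_pacs_bed(pacs, path_or_handle) -> None:
    lines = ["\t".join([p.chrom, str(p.start), str(p.end), p.pac_id,
                        str(p.tag_count), p.strand]) for p in pacs]
    text = "\n".join(lines) + ("\n" if lines else "")
    if hasattr(path_or_handle, "write"):
        path_or_handle.write(text)
    else:
        with open(path_or_handle, "w") as fh:
            fh.write(text)
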