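"""Genomic assignment of PACs: sense regions, intergenic distances, antisense.

Each PAC is resolved by its summit coordinate alone (a single decisive
base avoids double counting across segment boundaries).

Sense resolution, on the PAC's own strand: a covering gene body wins over
a covering 3' extension, which wins over a promoter window; remaining ties
go to the gene with the nearest 3' end, then to the lexicographically
smallest gene id.  A PAC covered by no same-strand feature is intergenic
-- unless it lies inside an opposite-strand gene (body or extension), in
which case it belongs to the antisense tabulation instead.

Antisense PACs (summit inside an opposite-strand gene) are attributed to
convergent read-through of a neighbour on the PAC's *own* strand:

* case 1 -- summit inside that neighbour's annotated or extended 3'-UTR;
* case 2 -- summit inside the neighbour elsewhere (CDS, 5'-UTR, intron, AMB);
* case 3 -- no covering own-strand gene, but one ends within
  ``nearby_antisense_distance`` upstream of the summit;
* case 4 -- orphan: no convergent neighbour can explain the PAC.

A PAC sense-covered by gene B while antisense to gene A (overlapping
convergent pair) appears in both tabulations; the two tables are
independent summaries.
"""

from __future__ import annotations

import bisect
from collections import defaultdict
from dataclasses import dataclass

import pandas as pd

from .params import Parameters

REGIONS = ("3UTR", "5UTR", "CDS", "intron", "AMB", "promoter", "intergenic")


@dataclass(frozen=True)
class RegionAssignment:
    pac_id: str
    gene_id: str | None
    region: str
    orientation: str                 # "sense" | "antisense"
    antisense_case: int | None = None
    distance_to_nearest_gene_end: int | None = None

    def __post_init__(self):
        if self.antisense_case is not None and self.orientation != "antisense":
            raise ValueError("antisense_case set on a sense assignment")
        if self.region == "intergenic" and self.gene_id is not None:
            raise ValueError("intergenic assignment cannot carry a gene id")


def assign_sense(pac, index, params: Parameters | None = None) -> RegionAssignment:
    """Resolve a PAC on its own strand to (gene, region), promoter or intergenic."""
    hits = index.query(pac.chrom, pac.summit, strand=pac.strand)

    def choose(kind):
        cands = [h for h in hits if h.kind == kind]
        if not cands:
            return None
        return min(cands, key=lambda h: (
            abs(pac.summit - index.models[h.gene_id].three_prime_end), h.gene_id))

    for kind in ("body", "extension"):
        h = choose(kind)
        if h is not None:
            return RegionAssignment(pac.pac_id, h.gene_id, h.label, "sense")
    h = choose("promoter")
    if h is not None:
        return RegionAssignment(pac.pac_id, h.gene_id, "promoter", "sense")
    return RegionAssignment(pac.pac_id, None, "intergenic", "sense")


def antisense_host(pac, index):
    """Opposite-strand gene whose body or 3' extension covers the summit."""
    other = "-" if pac.strand == "+" else "+"
    hits = [h for h in index.query(pac.chrom, pac.summit, strand=other)
            if h.kind in ("body", "extension")]
    if not hits:
        return None
    # prefer body coverage over extension-only coverage
    bodies = [h for h in hits if h.kind == "body"] or hits
    return min(bodies, key=lambda h: (
        abs(pac.summit - index.models[h.gene_id].three_prime_end), h.gene_id))


def classify_antisense(pac, index, params: Parameters) -> RegionAssignment:
    """Attribute an antisense PAC to convergent read-through (cases 1-4)."""
    host = antisense_host(pac, index)
    if host is None:
        raise ValueError(f"PAC {pac.pac_id} is not antisense to any gene")
    own = [h for h in index.query(pac.chrom, pac.summit, strand=pac.strand)
           if h.kind in ("body", "extension")]
    if own:
        h = min(own, key=lambda h: (
            abs(pac.summit - index.models[h.gene_id].three_prime_end), h.gene_id))
        case = 1 if h.label == "3UTR" else 2
        return RegionAssignment(pac.pac_id, host.gene_id, host.label,
                                "antisense", antisense_case=case)
    # case 3: a same-strand gene's 3' end lies within reach upstream of the summit
    near = _nearest_upstream_3p_distance(pac, index)
    case = 3 if (near is not None and near <= params.nearby_antisense_distance) else 4
    return RegionAssignment(pac.pac_id, host.gene_id, host.label,
                            "antisense", antisense_case=case)


def _nearest_upstream_3p_distance(pac, index, extended: bool = False):
    """Distance from the summit to the nearest same-strand gene 3' end that
    lies 5' of the summit (i.e. the summit could be that gene's read-through).

    With ``extended=True`` the extended 3' end is used instead of the body end.
    """
    best = None
    for m in index.models.values():
        if m.chrom != pac.chrom or m.strand != pac.strand:
            continue
        if extended:
            end3 = m.extended_span[1] if m.strand == "+" else m.extended_span[0]
        else:
            end3 = m.three_prime_end
        d = pac.summit - end3 if m.strand == "+" else end3 - pac.summit
        if d >= 0 and (best is None or d < best):
            best = d
    return best


def assign_all(pacs, index, params: Parameters) -> pd.DataFrame:
    """Assign every PAC; returns one dataframe holding both tabulations.

    Each PAC yields a sense row (when same-strand covered, or covered by
    nothing at all) and/or an antisense row (when inside an opposite-strand
    gene).  Overlapping convergent configurations yield both.
    """
    rows = []
    pac_by_id = {}
    for pac in pacs:
        pac_by_id[pac.pac_id] = pac
        sense = assign_sense(pac, index, params)
        host = antisense_host(pac, index)
        if sense.region not in ("intergenic", "promoter") or host is None:
            rows.append(_row(pac, sense))
        if host is not None:
            rows.append(_row(pac, classify_antisense(pac, index, params)))
    df = pd.DataFrame(rows, columns=["pac_id", "chrom", "strand", "summit",
                                     "tag_count", "gene_id", "region",
                                     "orientation", "antisense_case",
                                     "distance_to_nearest_gene_end"])
    # intergenic distances to the nearest extended-gene boundary (either strand)
    mask = df["region"] == "intergenic"
    if mask.any():
        dists = [nearest_extended_boundary_distance(pac_by_id[pid], index.models.values())
                 for pid in df.loc[mask, "pac_id"]]
        df.loc[mask, "distance_to_nearest_gene_end"] = dists
    return df


def _row(pac, a: RegionAssignment) -> dict:
    return dict(pac_id=pac.pac_id, chrom=pac.chrom, strand=pac.strand,
                summit=pac.summit, tag_count=pac.tag_count, gene_id=a.gene_id,
                region=a.region, orientation=a.orientation,
                antisense_case=a.antisense_case,
                distance_to_nearest_gene_end=a.distance_to_nearest_gene_end)


# ---------------------------------------------------------------------------
# intergenic distances (cumulative-curve data)
# ---------------------------------------------------------------------------

def nearest_extended_boundary_distance(pac, models):
    """Distance from the summit to the nearest extended-gene boundary on the
    PAC's chromosome (either strand); None when the chromosome has no genes."""
    best = None
    for m in models:
        if m.chrom != pac.chrom:
            continue
        s, e = m.extended_span
        if pac.summit < s:
            d = s - pac.summit
        elif pac.summit >= e:
            d = pac.summit - (e - 1)
        else:
            d = 0
        if best is None or d < best:
            best = d
    return best


def intergenic_distances(assignments: pd.DataFrame, index, params: Parameters,
                         far_threshold: int = 1000, near_threshold: int = 400):
    """Distance statistics for intergenic PACs.

    Returns a dict with the sorted distance list, the fraction of
    intergenic PACs farther than ``far_threshold`` from any extended gene,
    and the fraction lying within ``near_threshold`` downstream of an
    adjacent, properly oriented (same-strand) extended gene end.
    """
    inter = assignments[(assignments["region"] == "intergenic")
                        & (assignments["orientation"] == "sense")]
    dists, near_flags = [], []
    for _, row in inter.iterrows():
        pac = _Point(row["chrom"], row["strand"], int(row["summit"]))
        d = nearest_extended_boundary_distance(pac, index.models.values())
        if d is None:
            continue
        dists.append(d)
        up = _nearest_upstream_3p_distance(pac, index, extended=True)
        near_flags.append(up is not None and up <= near_threshold)
    n = len(dists)
    return {
        "distances": sorted(dists),
        "n_intergenic": n,
        "frac_beyond_threshold": (sum(d > far_threshold for d in dists) / n) if n else 0.0,
        "frac_near_oriented_gene": (sum(near_flags) / n) if n else 0.0,
    }


@dataclass(frozen=True)
class _Point:
    chrom: str
    strand: str
    summit: int


# ---------------------------------------------------------------------------
# paper-shaped tabulations
# ---------------------------------------------------------------------------

def tabulate_sense(assignments: pd.DataFrame) -> pd.DataFrame:
    """Region-by-region PAC/tag counts and percentages (sense tabulation)."""
    sense = assignments[assignments["orientation"] == "sense"]
    rows = []
    pac_total = len(sense)
    pat_total = int(sense["tag_count"].sum())
    for region in REGIONS:
        sub = sense[sense["region"] == region]
        rows.append({"region": region, "pac_count": len(sub),
                     "pac_pct": 100.0 * len(sub) / pac_total if pac_total else 0.0,
                     "pat_count": int(sub["tag_count"].sum()),
                     "pat_pct": 100.0 * sub["tag_count"].sum() / pat_total if pat_total else 0.0})
    rows.append({"region": "total", "pac_count": pac_total, "pac_pct": 100.0 if pac_total else 0.0,
                 "pat_count": pat_total, "pat_pct": 100.0 if pat_total else 0.0})
    return pd.DataFrame(rows)


def region_percentages(counts) -> dict:
    """Percentages from a region->count mapping (pure table arithmetic)."""
    total = sum(counts.values())
    if total == 0:
        return {k: 0.0 for k in counts}
    return {k: 100.0 * v / total for k, v in counts.items()}


def tabulate_antisense(assignments: pd.DataFrame) -> pd.DataFrame:
    """Per-case antisense PAC/tag counts and percentages."""
    anti = assignments[assignments["orientation"] == "antisense"]
    rows = []
    pac_total = len(anti)
    for case in (1, 2, 3, 4):
        sub = anti[anti["antisense_case"] == case]
        rows.append({"case": case, "pac_count": len(sub),
                     "pac_pct": 100.0 * len(sub) / pac_total if pac_total else 0.0,
                     "pat_count": int(sub["tag_count"].sum()),
                     "gene_count": sub["gene_id"].nunique()})
    rows.append({"case": "total", "pac_count": pac_total,
                 "pac_pct": 100.0 if pac_total else 0.0,
                 "pat_count": int(anti["tag_count"].sum()),
                 "gene_count": anti["gene_id"].nunique()})
    return pd.DataFrame(rows)


def antisense_case_percentages(case_counts) -> dict:
    """Case->percentage arithmetic, plus the convergent (cases 1+2) share."""
    total = sum(case_counts.values())
    pct = {k: 100.0 * v / total if total else 0.0 for k, v in case_counts.items()}
    pct["convergent_1_2"] = (100.0 * (case_counts.get(1, 0) + case_counts.get(2, 0)) / total
                             if total else 0.0)
    return pct
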