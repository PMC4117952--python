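"""Position-by-position nucleotide composition around poly(A) sites.

Authentic plant poly(A) sites carry a tri-partite signal: a U-rich far
upstream element, an A-rich element centred near -20, and a U-rich region
embedding a YA cleavage dinucleotide at position 0.  A flat profile (all
fractions near 0.25) indicates random site placement, so these profiles
double as a quality control on PAC calling.

Sequences are extracted on each site's sense strand (reverse complement
for minus-strand sites); position 0 is the cleavage site itself.  T is
reported as U, the transcript-space convention.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .curation import revcomp
from .params import Parameters

log = logging.getLogger(__name__)

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}


@dataclass
class NucleotideProfile:
    """Per-position base fractions over a site set."""

    window: tuple                 # (upstream, downstream)
    fractions: np.ndarray         # shape (upstream+downstream+1, 4), order A,C,G,T
    n_sites: int
    n_dropped: int = 0
    label: str = "all"

    @property
    def positions(self) -> np.ndarray:
        up, down = self.window
        return np.arange(-up, down + 1)

    def fraction(self, base: str) -> np.ndarray:
        return self.fractions[:, _BASE_INDEX[base]]

    def fraction_at(self, base: str, position: int) -> float:
        up, _ = self.window
        return float(self.fractions[position + up, _BASE_INDEX[base]])

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"position": self.positions})
        for base, col in zip(BASES, "ACGU"):  # report T as U
            df[f"frac{col}"] = self.fractions[:, _BASE_INDEX[base]]
        df["n_sites"] = self.n_sites
        return df


def composition_profile(sites, genome, window=(300, 100), label="all") -> NucleotideProfile:
    """Base-composition profile around ``sites`` = iterable of
    (chrom, strand, position) with position 0 at the cleavage site.

    Sites whose window would cross a chromosome edge are dropped and
    counted in ``n_dropped``.
    """
    sites = list(sites)
    if not sites:
        raise ValueError("composition_profile: empty site list")
    up, down = window
    length = up + down + 1
    counts = np.zeros((length, 4), dtype=np.int64)
    used = dropped = 0
    for chrom, strand, pos in sites:
        seq = genome[chrom]
        if strand == "+":
            lo, hi = pos - up, pos + down + 1
            if lo < 0 or hi > len(seq):
                dropped += 1
                continue
            sub = seq[lo:hi]
        else:
            lo, hi = pos - down, pos + up + 1
            if lo < 0 or hi > len(seq):
                dropped += 1
                continue
            sub = revcomp(seq[lo:hi])
        for i, ch in enumerate(sub):
            j = _BASE_INDEX.get(ch)
            if j is not None:
                counts[i, j] += 1
        used += 1
    if used == 0:
        raise ValueError("composition_profile: every site window crossed a chromosome edge")
    totals = counts.sum(axis=1, keepdims=True)
    totals[totals == 0] = 1
    return NucleotideProfile(window=(up, down), fractions=counts / totals,
                             n_sites=used, n_dropped=dropped, label=label)


# ---------------------------------------------------------------------------
# stratified profiles
# ---------------------------------------------------------------------------

SENSE_STRATA = ("3UTR", "intron", "CDS", "intergenic")
ANTISENSE_STRATA = {"antisense-overlap": (1, 2), "antisense-nearby": (3,),
                    "antisense-orphan": (4,)}


def stratified_profiles(pacs, assignments: pd.DataFrame, genome,
                        params: Parameters, window=None) -> dict:
    """Profiles keyed by (stratum, support) with support in all/single/multi.

    Sense strata follow the region assignment; antisense strata group the
    attribution cases: 1-2 = overlap, 3 = nearby, 4 = orphan.  Empty strata
    are omitted (logged).
    """
    if window is None:
        window = (params.profile_upstream, params.profile_downstream)
    pac_by_id = {p.pac_id: p for p in pacs}

    def site_list(pac_ids):
        out = []
        for pid in pac_ids:
            p = pac_by_id[pid]
            out.append((p.chrom, p.strand, p.summit))
        return out

    strata = {}
    sense = assignments[assignments["orientation"] == "sense"]
    for region in SENSE_STRATA:
        strata[region] = list(sense.loc[sense["region"] == region, "pac_id"])
    anti = assignments[assignments["orientation"] == "antisense"]
    for name, cases in ANTISENSE_STRATA.items():
        strata[name] = list(anti.loc[anti["antisense_case"].isin(cases), "pac_id"])

    profiles = {}
    for name, pac_ids in strata.items():
        subsets = {
            "all": pac_ids,
            "single-PAT": [pid for pid in pac_ids if pac_by_id[pid].tag_count == 1],
            "multi-PAT": [pid for pid in pac_ids if pac_by_id[pid].tag_count > 1],
        }
        for support, ids in subsets.items():
            if not ids:
                log.info("stratum (%s, %s) has no sites; omitted", name, support)
                continue
            try:
                profiles[(name, support)] = composition_profile(
                    site_list(ids), genome, window=window, label=f"{name}/{support}")
            except ValueError:
                log.info("stratum (%s, %s): all windows crossed an edge; omitted",
                         name, support)
    return profiles
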