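"""Cross-species conservation layer: 3'-UTR lengths, randomization tests,
intron/exon positional statistics, and EST validation.

The central statistic asks whether genes carrying a poly(A)-site feature
(intronic PAC, CDS PAC, antisense PAC) in species B are enriched for
orthologs carrying the same feature in species A.  The observed sharing is
compared against ``n_random_trials`` random draws of the same number of
genes from the species-A ortholog pool (sampling without replacement); a
two-cell chi-square goodness-of-fit against the randomization mean gives
the p-value, and the hypergeometric closed form of the expected sharing is
reported alongside (with one draw per trial, the randomization mean
converges to it).
"""

from __future__ import annotations

import bisect
from collections import defaultdict
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .params import Parameters


# ---------------------------------------------------------------------------
# 3'-UTR lengths
# ---------------------------------------------------------------------------

UTR_LENGTH_MODES = ("tag_weighted_mean", "distal_summit", "median_summit")


def utr_lengths_per_gene(pacs, assignments: pd.DataFrame, models,
                         mode: str = "tag_weighted_mean"):
    """Per-gene 3'-UTR length from 3'UTR-assigned PACs.

    The length of one PAC is the distance from the annotated CDS 3' end
    (last coding base) to the PAC summit.  Per-gene representatives:
    ``tag_weighted_mean`` (default), ``distal_summit`` (longest), or
    ``median_summit`` (unweighted median over summits).

    Returns ``(lengths, n_skipped)``; genes without an annotated CDS end
    are skipped and counted.
    """
    if mode not in UTR_LENGTH_MODES:
        raise ValueError(f"unknown mode {mode!r}; expected one of {UTR_LENGTH_MODES}")
    pac_by_id = {p.pac_id: p for p in pacs}
    utr = assignments[(assignments["orientation"] == "sense")
                      & (assignments["region"] == "3UTR")]
    lengths, skipped = {}, 0
    for gene_id, group in utr.groupby("gene_id"):
        model = models[gene_id]
        cds_3p = model.cds_three_prime_end()
        if cds_3p is None:
            skipped += 1
            continue
        ls, ws = [], []
        for pid in group["pac_id"]:
            p = pac_by_id[pid]
            ls.append(p.summit - cds_3p if model.strand == "+" else cds_3p - p.summit)
            ws.append(p.tag_count)
        ls, ws = np.asarray(ls, float), np.asarray(ws, float)
        if mode == "tag_weighted_mean":
            lengths[gene_id] = float(np.average(ls, weights=ws))
        elif mode == "distal_summit":
            lengths[gene_id] = float(ls.max())
        else:
            lengths[gene_id] = float(np.median(ls))
    return lengths, skipped


def compare_utr_lengths(lengths_a, lengths_b, ortholog_pairs,
                        n_random_pairs: int = 2000, seed: int = 0) -> dict:
    """Compare per-gene 3'-UTR lengths between two species.

    ``ortholog_pairs`` is an iterable of (gene_a, gene_b).  The report
    holds, per species, the orthologous / non-orthologous length split
    with a two-sided Wilcoxon rank-sum p-value; the Pearson correlation
    over complete ortholog pairs; and the Pearson correlation over
    ``n_random_pairs`` randomly assembled pairs as the null control.
    """
    pairs = list(ortholog_pairs)
    orth_a = {a for a, _ in pairs}
    orth_b = {b for _, b in pairs}

    def split(lengths, orth_ids):
        orth = np.array([v for k, v in lengths.items() if k in orth_ids], float)
        non = np.array([v for k, v in lengths.items() if k not in orth_ids], float)
        if len(orth) and len(non):
            stat, p = stats.ranksums(orth, non)
        else:
            stat, p = float("nan"), float("nan")
        return {"n_orth": len(orth), "n_non_orth": len(non),
                "median_orth": float(np.median(orth)) if len(orth) else float("nan"),
                "median_non_orth": float(np.median(non)) if len(non) else float("nan"),
                "wilcoxon_stat": float(stat), "wilcoxon_p": float(p)}

    xs, ys = [], []
    for a, b in pairs:
        if a in lengths_a and b in lengths_b:
            xs.append(lengths_a[a])
            ys.append(lengths_b[b])
    if len(xs) >= 3 and len(set(xs)) > 1 and len(set(ys)) > 1:
        r, p = stats.pearsonr(xs, ys)
        ortho_corr = {"n_pairs": len(xs), "pearson_r": float(r), "pearson_p": float(p)}
    else:
        ortho_corr = {"n_pairs": len(xs), "pearson_r": None, "pearson_p": None}

    rng = np.random.default_rng(seed)
    va = np.fromiter(lengths_a.values(), float)
    vb = np.fromiter(lengths_b.values(), float)
    if len(va) >= 3 and len(vb) >= 3 and n_random_pairs >= 3:
        rx = va[rng.integers(0, len(va), n_random_pairs)]
        ry = vb[rng.integers(0, len(vb), n_random_pairs)]
        r, p = stats.pearsonr(rx, ry)
        rand_corr = {"n_pairs": n_random_pairs, "pearson_r": float(r), "pearson_p": float(p)}
    else:
        rand_corr = {"n_pairs": 0, "pearson_r": None, "pearson_p": None}

    return {"species_a": split(lengths_a, orth_a),
            "species_b": split(lengths_b, orth_b),
            "ortholog_correlation": ortho_corr,
            "random_pair_correlation": rand_corr,
            "mode_note": "per-gene lengths as provided by utr_lengths_per_gene"}


# ---------------------------------------------------------------------------
# feature-conservation randomization test
# ---------------------------------------------------------------------------

@dataclass
class ConservationResult:
    feature: str
    observed_shared: int
    sample_size: int
    pool_size: int
    expected_mean: float
    expected_hypergeom: float
    chi2_stat: float
    p_value: float
    seed: int
    n_trials: int
    testable: bool = True

    def __post_init__(self):
        if self.testable:
            assert 0 <= self.observed_shared <= self.sample_size <= self.pool_size
            assert 0.0 <= self.expected_mean <= self.sample_size


def feature_conservation_test(genes_with_feature_b, ortholog_pairs,
                              genes_with_feature_a, expressed_pool_a,
                              params: Parameters, seed: int = 0,
                              feature: str = "feature") -> ConservationResult:
    """Randomization test of cross-species feature sharing.

    A species-B gene "possesses" the feature when at least one of its PACs
    carries it; many-to-many ortholog tables are deduplicated to unique
    species-B genes, and a B gene counts as shared when *any* of its
    species-A partners in the pool carries the feature.

    ``expressed_pool_a`` is the universe the random draws come from (e.g.
    all species-A orthologs, or all expressed species-A genes).
    """
    pool = sorted(set(expressed_pool_a))
    if not pool:
        raise ValueError("empty species-A pool")
    feature_a = set(genes_with_feature_a) & set(pool)
    partners = defaultdict(set)
    for a, b in ortholog_pairs:
        if a in set(pool):
            partners[b].add(a)
    b_genes = [b for b in set(genes_with_feature_b) if partners.get(b)]
    sample_size = len(b_genes)
    if sample_size == 0:
        return ConservationResult(feature, 0, 0, len(pool), 0.0, 0.0,
                                  float("nan"), float("nan"), seed,
                                  params.n_random_trials, testable=False)
    observed = sum(1 for b in b_genes if partners[b] & feature_a)

    # randomization: draws of sample_size genes from the pool, without replacement
    rng = np.random.default_rng(seed)
    flags = np.fromiter((g in feature_a for g in pool), bool, count=len(pool))
    draws = np.empty(params.n_random_trials, dtype=np.int64)
    for i in range(params.n_random_trials):
        idx = rng.choice(len(pool), size=sample_size, replace=False)
        draws[i] = int(flags[idx].sum())
    expected_mean = float(draws.mean())
    expected_hg = sample_size * len(feature_a) / len(pool)

    # two-cell goodness-of-fit of {shared, not shared} against the
    # randomization-mean proportions
    e1, e2 = expected_mean, sample_size - expected_mean
    if e1 <= 0 or e2 <= 0:
        chi2 = 0.0 if observed == round(e1) else float("inf")
        p = 1.0 if chi2 == 0.0 else 0.0
    else:
        o1, o2 = observed, sample_size - observed
        chi2 = (o1 - e1) ** 2 / e1 + (o2 - e2) ** 2 / e2
        p = float(stats.chi2.sf(chi2, df=1))
    return ConservationResult(feature=feature, observed_shared=observed,
                              sample_size=sample_size, pool_size=len(pool),
                              expected_mean=expected_mean,
                              expected_hypergeom=expected_hg,
                              chi2_stat=float(chi2), p_value=p, seed=seed,
                              n_trials=params.n_random_trials)


# ---------------------------------------------------------------------------
# intron / exon positional statistics
# ---------------------------------------------------------------------------

def intron_exon_positional_stats(pacs, assignments: pd.DataFrame, models,
                                 seed: int = 0) -> dict:
    """Positional statistics of PAC-containing introns and CDS exons.

    For each intron (exon) containing at least one PAC summit: the relative
    feature position = index / feature count in 5'->3' order (a single
    intron counts as 1.0), and the within-feature PAC position = 5' offset
    / length (values > 0.5 mean the PAC sits nearer the 3' end).  Length
    distributions of PAC-bearing features are paired with size-matched
    random draws from the complete feature set (seeded).
    """
    rng = np.random.default_rng(seed)
    pac_by_id = {p.pac_id: p for p in pacs}
    out = {}
    for region, getter in (("intron", lambda m: m.introns()),
                           ("CDS", lambda m: m.cds_segments())):
        sub = assignments[(assignments["orientation"] == "sense")
                          & (assignments["region"] == region)]
        rel_feature_pos, within_pos, hit_lengths = [], [], []
        hit_features = set()
        for _, row in sub.iterrows():
            model = models[row["gene_id"]]
            feats = getter(model)
            if not feats:
                continue
            summit = int(row["summit"])
            idx = next((i for i, (s, e) in enumerate(feats) if s <= summit < e), None)
            if idx is None:
                continue
            s, e = feats[idx]
            n = len(feats)
            rel_feature_pos.append((idx + 1) / n)
            offset = summit - s if model.strand == "+" else (e - 1) - summit
            within_pos.append(offset / (e - s))
            key = (model.gene_id, idx)
            if key not in hit_features:
                hit_features.add(key)
                hit_lengths.append(e - s)
        all_lengths = np.array([e - s for m in models.values()
                                for s, e in getter(m)], dtype=int)
        if len(all_lengths) and hit_lengths:
            control = all_lengths[rng.choice(len(all_lengths), size=len(hit_lengths),
                                             replace=False if len(hit_lengths) <= len(all_lengths) else True)]
        else:
            control = np.array([], dtype=int)
        out[region] = {
            "relative_feature_position": np.array(rel_feature_pos),
            "within_feature_position": np.array(within_pos),
            "lengths_with_pac": np.array(sorted(hit_lengths)),
            "lengths_random_control": np.array(sorted(control.tolist())),
            "median_length_with_pac": float(np.median(hit_lengths)) if hit_lengths else float("nan"),
            "median_length_control": float(np.median(control)) if len(control) else float("nan"),
            "n_features_with_pac": len(hit_lengths),
        }
    return out


# ---------------------------------------------------------------------------
# EST validation
# ---------------------------------------------------------------------------

@dataclass
class ESTValidationReport:
    n_est_sites: int
    n_validated: int
    window: int

    @property
    def pct_validated(self) -> float:
        return 100.0 * self.n_validated / self.n_est_sites


def est_validation(est_sites, pacs, params: Parameters) -> ESTValidationReport:
    """Fraction of EST-derived poly(A) sites within ``est_match_window`` nt
    (inclusive) of a same-strand PAC summit.

    ``est_sites`` is an iterable of (chrom, strand, position).
    """
    est_sites = list(est_sites)
    if not est_sites:
        raise ValueError("est_validation: empty EST site set")
    summits = defaultdict(list)
    for p in pacs:
        summits[(p.chrom, p.strand)].append(p.summit)
    for key in summits:
        summits[key].sort()
    validated = 0
    for chrom, strand, pos in est_sites:
        arr = summits.get((chrom, strand))
        if not arr:
            continue
        i = bisect.bisect_left(arr, pos)
        best = min(abs(arr[j] - pos) for j in (i - 1, i) if 0 <= j < len(arr))
        if best <= params.est_match_window:
            validated += 1
    return ESTValidationReport(n_est_sites=len(est_sites), n_validated=validated,
                               window=params.est_match_window)


def validation_percentage(n_validated: int, n_total: int) -> float:
    """Percentage arithmetic used in validation reports."""
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    return 100.0 * n_validated / n_total
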