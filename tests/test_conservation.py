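"""3'-UTR length statistics, conservation randomization test, EST validation."""

import math

import numpy as np
import pytest
from scipy import stats

import polyaflow as pf
from polyaflow.conservation import validation_percentage
from polyaflow.params import MTR_LIKE

from conftest import make_gene, pac


def _gene_with_pacs(pac_specs, utr3=300):
    """Plus-strand gene plus PACs at given (nt-past-stop, tag_count)."""
    m = make_gene("g", "chr1", "+", 10_000, utr3=utr3)
    cds_3p = m.cds_three_prime_end()
    pacs = [pac("chr1", "+", cds_3p + dist, tag_count=cnt, pac_id=f"p{i}")
            for i, (dist, cnt) in enumerate(pac_specs)]
    idx = pf.GenomeIndex([m])
    df = pf.assign_all(pacs, idx, MTR_LIKE)
    return m, pacs, df


class TestUtrLengths:
    def test_single_pac_length_is_distance_past_stop(self):
        m, pacs, df = _gene_with_pacs([(180, 1)])
        lengths, skipped = pf.utr_lengths_per_gene(pacs, df, {"g": m})
        assert lengths == {"g": 180.0} and skipped == 0

    def test_tag_weighted_mean(self):
        m, pacs, df = _gene_with_pacs([(100, 9), (200, 1)])
        lengths, _ = pf.utr_lengths_per_gene(pacs, df, {"g": m})
        assert lengths["g"] == pytest.approx(110.0)

    def test_modes_distal_and_median(self):
        m, pacs, df = _gene_with_pacs([(100, 9), (200, 1), (150, 2)])
        distal, _ = pf.utr_lengths_per_gene(pacs, df, {"g": m}, mode="distal_summit")
        med, _ = pf.utr_lengths_per_gene(pacs, df, {"g": m}, mode="median_summit")
        assert distal["g"] == 200.0 and med["g"] == 150.0
        with pytest.raises(ValueError, match="mode"):
            pf.utr_lengths_per_gene(pacs, df, {"g": m}, mode="nope")

    def test_distal_always_at_least_weighted_mean(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            n = int(rng.integers(1, 6))
            specs = [(int(rng.integers(10, 290)), int(rng.integers(1, 20)))
                     for _ in range(n)]
            specs = list({d: c for d, c in specs}.items())  # unique distances
            m, pacs, df = _gene_with_pacs(specs)
            w, _ = pf.utr_lengths_per_gene(pacs, df, {"g": m})
            d, _ = pf.utr_lengths_per_gene(pacs, df, {"g": m}, mode="distal_summit")
            assert d["g"] >= w["g"] - 1e-9


class TestCompareUtrLengths:
    def test_identity_map_gives_pearson_one(self):
        lengths = {f"g{i}": float(50 + 7 * i) for i in range(30)}
        rep = pf.compare_utr_lengths(lengths, dict(lengths),
                                     [(g, g) for g in lengths], seed=0)
        assert rep["ortholog_correlation"]["pearson_r"] == pytest.approx(1.0)

    def test_random_pairing_of_independent_lengths_is_uncorrelated(self):
        la, lb, _ = pf.simulate_ortholog_utr_lengths(3000, 0.0, seed=4)
        rep = pf.compare_utr_lengths(la, lb, [], n_random_pairs=2000, seed=4)
        assert abs(rep["random_pair_correlation"]["pearson_r"]) < 0.05

    def test_planted_correlation_recovered(self):
        la, lb, pairs = pf.simulate_ortholog_utr_lengths(8876, 0.3, seed=6)
        rep = pf.compare_utr_lengths(la, lb, pairs, seed=6)
        assert abs(rep["ortholog_correlation"]["pearson_r"] - 0.3) < 0.05

    def test_too_few_pairs_reports_missing_correlation(self):
        rep = pf.compare_utr_lengths({"a": 10.0}, {"b": 20.0}, [("a", "b")], seed=0)
        assert rep["ortholog_correlation"]["pearson_r"] is None

    def test_wilcoxon_and_pearson_match_textbook_values(self):
        # hand-computed 5-element inputs
        x = [1.0, 2.0, 3.0, 4.0, 5.0]
        y = [2.0, 1.0, 4.0, 3.0, 5.0]
        # Pearson by the definition formula, plain arithmetic
        mx, my = sum(x) / 5, sum(y) / 5
        num = sum((a - mx) * (b - my) for a, b in zip(x, y))
        den = math.sqrt(sum((a - mx) ** 2 for a in x) * sum((b - my) ** 2 for b in y))
        r_scipy, _ = stats.pearsonr(x, y)
        assert r_scipy == pytest.approx(num / den)
        lengths_a = {f"a{i}": v for i, v in enumerate(x)}
        lengths_b = {f"b{i}": v for i, v in enumerate(y)}
        pairs = [(f"a{i}", f"b{i}") for i in range(5)]
        rep = pf.compare_utr_lengths(lengths_a, lengths_b, pairs, seed=0)
        assert rep["ortholog_correlation"]["pearson_r"] == pytest.approx(num / den)
        # Wilcoxon rank-sum z for {1,3,5} (orth) vs {2,4}: rank sum 9, E=9, var=6
        za = (9 - 9) / math.sqrt(6)
        lengths = {"o1": 1.0, "o2": 3.0, "o3": 5.0, "n1": 2.0, "n2": 4.0}
        rep2 = pf.compare_utr_lengths(lengths, {"x": 1.0},
                                      [("o1", "x"), ("o2", "x"), ("o3", "x")], seed=0)
        assert rep2["species_a"]["wilcoxon_stat"] == pytest.approx(za)
        assert rep2["species_a"]["wilcoxon_p"] == pytest.approx(1.0)


class TestFeatureConservation:
    def test_feature_in_all_pool_genes_gives_chi2_zero(self, params):
        pool = [f"a{i}" for i in range(50)]
        pairs = [(a, f"b{i}") for i, a in enumerate(pool)]
        res = pf.feature_conservation_test({f"b{i}" for i in range(10)}, pairs,
                                           set(pool), pool, params, seed=1)
        assert res.observed_shared == res.sample_size == 10
        assert res.expected_mean == pytest.approx(10.0)
        assert res.chi2_stat == 0.0 and res.p_value == 1.0

    def test_randomization_mean_matches_hypergeometric_closed_form(self, params):
        rng = np.random.default_rng(0)
        pool = [f"a{i}" for i in range(400)]
        feature_a = set(rng.choice(pool, 80, replace=False))
        pairs = [(a, f"b{i}") for i, a in enumerate(pool)]
        feature_b = {f"b{i}" for i in range(60)}
        res = pf.feature_conservation_test(feature_b, pairs, feature_a, pool,
                                           params, seed=2)
        n, K, N = res.sample_size, len(feature_a), len(pool)
        hyper_mean = n * K / N
        assert res.expected_hypergeom == pytest.approx(hyper_mean)
        hyper_sd = math.sqrt(n * (K / N) * (1 - K / N) * (N - n) / (N - 1))
        mc_se = hyper_sd / math.sqrt(res.n_trials)
        assert abs(res.expected_mean - hyper_mean) < 3 * mc_se

    def test_deterministic_under_fixed_seed(self, params):
        tbl = pf.simulate_ortholog_table(500, {"f": (0.2, 0.2, 0.08)}, seed=9)
        pairs = list(zip(tbl.gene_a, tbl.gene_b))
        fa = set(tbl.loc[tbl.f_a, "gene_a"])
        fb = set(tbl.loc[tbl.f_b, "gene_b"])
        r1 = pf.feature_conservation_test(fb, pairs, fa, list(tbl.gene_a),
                                          params, seed=5)
        r2 = pf.feature_conservation_test(fb, pairs, fa, list(tbl.gene_a),
                                          params, seed=5)
        assert r1 == r2

    def test_empty_sample_flagged_untestable(self, params):
        res = pf.feature_conservation_test(set(), [("a", "b")], {"a"}, ["a"],
                                           params, seed=0)
        assert not res.testable and res.sample_size == 0

    def test_null_and_enriched_calibration_small(self, params):
        """Reduced-seed calibration; the full 100-seed version is in the
        acceptance suite."""
        fast = params.replace(n_random_trials=300)
        null_p, enr_p = [], []
        for seed in range(20):
            for joint, sink in ((0.04, null_p), (0.12, enr_p)):
                tbl = pf.simulate_ortholog_table(2000, {"f": (0.2, 0.2, joint)},
                                                 seed=seed)
                pairs = list(zip(tbl.gene_a, tbl.gene_b))
                fa = set(tbl.loc[tbl.f_a, "gene_a"])
                fb = set(tbl.loc[tbl.f_b, "gene_b"])
                res = pf.feature_conservation_test(fb, pairs, fa,
                                                   list(tbl.gene_a), fast,
                                                   seed=seed + 1000)
                sink.append(res.p_value)
        assert np.mean(np.array(null_p) > 0.05) >= 0.9
        assert np.mean(np.array(enr_p) < 0.01) >= 0.9


class TestPositionalStats:
    def test_relative_positions_match_hand_arithmetic(self):
        # 4 introns; PAC in the 3rd, at offset 150 of a 200-nt intron
        m = make_gene("g", "chr1", "+", 10_000,
                      exons=(100, 100, 100, 100, 100),
                      introns=(200, 200, 200, 200))
        introns = m.introns()
        assert len(introns) == 4
        s, e = introns[2]
        p = pac("chr1", "+", s + 150, pac_id="p0")
        idx = pf.GenomeIndex([m])
        df = pf.assign_all([p], idx, MTR_LIKE)
        out = pf.intron_exon_positional_stats([p], df, {"g": m}, seed=0)
        assert out["intron"]["relative_feature_position"].tolist() == [0.75]
        assert out["intron"]["within_feature_position"].tolist() == [0.75]
        assert out["intron"]["lengths_with_pac"].tolist() == [200]

    def test_minus_strand_within_position_measured_from_5_prime(self):
        m = make_gene("g", "chr1", "-", 10_000, exons=(100, 100), introns=(200,))
        (s, e), = m.introns()
        p = pac("chr1", "-", e - 1 - 150, pac_id="p0")  # 150 nt from intron 5' end
        idx = pf.GenomeIndex([m])
        df = pf.assign_all([p], idx, MTR_LIKE)
        out = pf.intron_exon_positional_stats([p], df, {"g": m}, seed=0)
        assert out["intron"]["within_feature_position"].tolist() == [0.75]

    def test_random_length_control_is_seed_reproducible(self, bundle_jitter):
        b = bundle_jitter
        kept, _, _ = pf.curate_tags([t.as_mapped_tag() for t in b["tags"]],
                                    b["genome"], MTR_LIKE)
        pacs = pf.cluster_tags(kept, MTR_LIKE)
        idx = pf.GenomeIndex(b["models"].values())
        df = pf.assign_all(pacs, idx, MTR_LIKE)
        o1 = pf.intron_exon_positional_stats(pacs, df, b["models"], seed=42)
        o2 = pf.intron_exon_positional_stats(pacs, df, b["models"], seed=42)
        assert o1["intron"]["lengths_random_control"].tolist() == \
            o2["intron"]["lengths_random_control"].tolist()
        assert len(o1["intron"]["lengths_random_control"]) == \
            o1["intron"]["n_features_with_pac"]


class TestESTValidation:
    def test_window_boundary_inclusive_at_50(self, params):
        p = pac("chr1", "+", 1000)
        rep50 = pf.est_validation([("chr1", "+", 1050)], [p], params)
        assert rep50.n_validated == 1
        rep51 = pf.est_validation([("chr1", "+", 1051)], [p], params)
        assert rep51.n_validated == 0
        # strand must match
        reps = pf.est_validation([("chr1", "-", 1000)], [p], params)
        assert reps.n_validated == 0

    def test_empty_est_set_rejected(self, params):
        with pytest.raises(ValueError):
            pf.est_validation([], [pac("chr1", "+", 10)], params)

    def test_published_style_percentage_arithmetic(self):
        assert round(validation_percentage(4302, 5529)) == 78

    def test_validation_counts_on_synthetic_sites(self, bundle_sd0, params):
        b = bundle_sd0
        kept, _, _ = pf.curate_tags([t.as_mapped_tag() for t in b["tags"]],
                                    b["genome"], MTR_LIKE)
        pacs = pf.cluster_tags(kept, MTR_LIKE)
        # ESTs at planted sites +/- 30 nt must all validate
        rng = np.random.default_rng(8)
        est = [(s.chrom, s.strand, s.coord + int(rng.integers(-30, 31)))
               for s in b["truth"].planted_sites]
        rep = pf.est_validation(est, pacs, params)
        assert rep.n_validated == rep.n_est_sites
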