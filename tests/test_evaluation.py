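"""Cross-validation bookkeeping, model comparison and scan statistics."""

import itertools

import numpy as np
import pytest
from scipy import stats

import gfblup as gf
from gfblup.errors import DomainError
from gfblup.mixedmodel import ModelSpec


class TestSplits:
    def test_partition_law_and_sizes(self):
        n, k, repeats = 100, 8, 3
        splits = gf.make_cv_splits(n, k, repeats, seed=5)
        assert len(splits) == k * repeats
        for r in range(repeats):
            tests = [te for _, te in splits[r * k:(r + 1) * k]]
            union = np.concatenate(tests)
            assert len(union) == n and len(np.unique(union)) == n
            sizes = [len(t) for t in tests]
            assert max(sizes) - min(sizes) <= 1
        for train, test in splits:
            assert np.intersect1d(train, test).size == 0

    def test_deterministic_given_seed(self):
        a = gf.make_cv_splits(50, 5, 2, seed=9)
        b = gf.make_cv_splits(50, 5, 2, seed=9)
        for (ta, sa), (tb, sb) in zip(a, b):
            assert np.array_equal(ta, tb) and np.array_equal(sa, sb)

    def test_k_larger_than_n_rejected(self):
        with pytest.raises(DomainError):
            gf.make_cv_splits(5, 8)


@pytest.fixture(scope="module")
def fitted_panel():
    cfg = gf.SimulationConfig(n_accessions=150, n_markers=800,
                              n_chromosomes=2, n_genes=100, n_features=4,
                              feature_size_range=(5, 15), seed=17)
    geno, genes = gf.simulate_genotypes(cfg)
    feats = gf.simulate_feature_sets(genes, cfg, geno)
    trait = gf.TraitConfig(h2_target=0.6, n_causal=400, n_replicates=1,
                           design_effect_sds={}, seed=18)
    sim = gf.simulate_trait(geno, feats, trait)
    y = sim.phenotypes.sort_values("accession")["value"].to_numpy()
    grm = gf.grm_from_genotypes(geno)
    return geno, feats, grm, y


class TestCrossValidate:
    def test_accuracies_plus_discards_account_for_every_fold(self, fitted_panel):
        _, _, grm, y = fitted_panel
        splits = gf.make_cv_splits(150, 8, 2, seed=6)
        cv = gf.cross_validate(ModelSpec([grm]), y, splits, "GBLUP", 6)
        assert len(cv.fold_accuracies) + cv.n_discarded == 16
        assert np.all((cv.fold_accuracies >= -1) & (cv.fold_accuracies <= 1))

    def test_pure_noise_mean_accuracy_near_zero(self, fitted_panel):
        _, _, grm, _ = fitted_panel
        rng = np.random.default_rng(77)
        splits = gf.make_cv_splits(150, 5, 2, seed=7)
        accs = []
        for rep in range(4):
            y = rng.standard_normal(150)
            try:
                cv = gf.cross_validate(ModelSpec([grm]), y, splits, "null", 7)
                accs.extend(cv.fold_accuracies)
            except gf.EmptyPanelError:
                continue  # all folds at the boundary: no accuracy to record
        if accs:  # any surviving folds must hover around zero accuracy
            se = np.std(accs, ddof=1) / np.sqrt(len(accs))
            assert abs(np.mean(accs)) < max(3 * se, 0.15)


class TestLikelihoodRatio:
    def test_point_mass_and_halved_tail(self):
        assert gf.likelihood_ratio_test(0.0, 0.0) == (0.0, 1.0)
        lr, p = gf.likelihood_ratio_test(1.353, 0.0)
        assert np.isclose(lr, 2.706)
        assert np.isclose(p, 0.05, atol=5e-4)
        # oracle: half the chi-square(1) survival function
        assert np.isclose(p, 0.5 * stats.chi2.sf(2.706, 1))

    def test_nesting_violation_raises(self):
        with pytest.raises(DomainError):
            gf.likelihood_ratio_test(-1.0, 0.0)


class TestCompareAccuracy:
    def test_identical_samples(self):
        a = gf.CVResult("a", [0.1, 0.2, 0.3], 0)
        b = gf.CVResult("b", [0.1, 0.2, 0.3], 0)
        med_a, med_b, gain, p = gf.compare_accuracy(a, b)
        assert gain == 0.0 and p > 0.99

    def test_median_doubling_is_100_percent_gain(self):
        a = gf.CVResult("a", [0.15, 0.2, 0.25], 0)
        b = gf.CVResult("b", [0.05, 0.1, 0.15], 0)
        assert gf.compare_accuracy(a, b)[2] == 100.0

    def test_exact_p_matches_exhaustive_permutation_enumeration(self):
        a = gf.CVResult("a", [1.0, 2.0, 3.0], 0)
        b = gf.CVResult("b", [4.0, 5.0, 6.0], 0)
        *_, p = gf.compare_accuracy(a, b)
        # oracle: all 20 assignments of 6 values into two groups of 3
        pooled = [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]
        u_obs = sum(x > y_ for x in [1, 2, 3] for y_ in [4, 5, 6])
        u_null = []
        for combo in itertools.combinations(range(6), 3):
            ga = [pooled[i] for i in combo]
            gb = [pooled[i] for i in range(6) if i not in combo]
            u_null.append(sum(x > y_ for x in ga for y_ in gb))
        n_extreme = sum(min(u, 9 - u) <= min(u_obs, 9 - u_obs) for u in u_null)
        assert np.isclose(p, n_extreme / len(u_null))

    def test_insufficient_data(self):
        with pytest.raises(DomainError):
            gf.compare_accuracy(gf.CVResult("a", [0.1], 0),
                                gf.CVResult("b", [0.1, 0.2], 0))


class TestFdr:
    def test_uniform_p_values_unchanged(self):
        q = gf.fdr_adjust([0.2, 0.2, 0.2])
        assert np.allclose(q, 0.2)

    def test_matches_brute_force_bh(self):
        p = np.array([0.01, 0.02, 0.03, 0.5])
        # oracle: sort, scale by n/rank, cumulative minimum from the right
        order = np.argsort(p)
        scaled = p[order] * len(p) / (np.arange(len(p)) + 1)
        q_sorted = np.minimum.accumulate(scaled[::-1])[::-1]
        expected = np.empty_like(p)
        expected[order] = np.minimum(q_sorted, 1.0)
        assert np.allclose(gf.fdr_adjust(p), expected)

    def test_q_never_below_p(self, rng):
        p = rng.random(50)
        assert np.all(gf.fdr_adjust(p) >= p - 1e-12)


class TestHeritabilities:
    def test_symmetric_case(self):
        fit = gf.VarianceFit(np.array([1.0]), 1.0, 0.0, True, 1,
                             np.zeros(2, bool))
        assert gf.heritabilities(fit)["h2"] == 0.5

    def test_zero_feature_variance(self):
        fit = gf.VarianceFit(np.array([0.0, 1.0]), 1.0, 0.0, True, 1,
                             np.zeros(3, bool))
        assert gf.heritabilities(fit)["hf2"] == 0.0

    def test_scale_invariance(self):
        for c in (0.1, 1.0, 42.0):
            fit = gf.VarianceFit(np.array([0.07 * c, 0.43 * c]), 0.5 * c,
                                 0.0, True, 1, np.zeros(3, bool))
            assert np.isclose(gf.heritabilities(fit)["hf2"], 0.07)

    def test_all_zero_rejected(self):
        fit = gf.VarianceFit(np.array([0.0]), 0.0, 0.0, True, 1,
                             np.zeros(2, bool))
        with pytest.raises(DomainError):
            gf.heritabilities(fit)


class TestOverlapChisq:
    def test_observed_equals_expected(self):
        universe = [f"g{i}" for i in range(100)]
        # feature = half the universe, reference = alternating half: independent
        feature = universe[:50]
        reference = universe[::2]
        stat, p = gf.overlap_chisq(feature, reference, universe)
        assert np.isclose(stat, 0.0, atol=1e-12) and np.isclose(p, 1.0)

    def test_matches_direct_arithmetic(self):
        universe = [f"g{i}" for i in range(200)]
        feature = universe[:100]
        reference = universe[:30] + universe[100:110]
        stat, p = gf.overlap_chisq(feature, reference, universe)
        table = np.array([[30.0, 70.0], [10.0, 90.0]])
        expected = table.sum(1, keepdims=True) @ table.sum(0, keepdims=True) \
            / table.sum()
        oracle = ((table - expected) ** 2 / expected).sum()
        assert np.isclose(stat, oracle)
        assert np.isclose(p, stats.chi2.sf(oracle, 1))

    def test_statistic_linear_in_total_count(self):
        u1 = [f"g{i}" for i in range(200)]
        f1, r1 = u1[:100], u1[:30] + u1[100:110]
        u2 = [f"g{i}" for i in range(400)]
        f2, r2 = u2[:200], u2[:60] + u2[200:220]
        s1, _ = gf.overlap_chisq(f1, r1, u1)
        s2, _ = gf.overlap_chisq(f2, r2, u2)
        assert np.isclose(s2, 2 * s1)


class TestFisherEnrichment:
    def test_feature_equals_universe_no_enrichment(self):
        universe = [f"g{i}" for i in range(20)]
        terms = {"t1": universe[:5], "t2": universe[5:9]}
        df = gf.fisher_enrichment(universe, terms, universe)
        assert np.allclose(df["p"], 1.0)

    def test_matches_hypergeometric_tail(self):
        universe = [f"g{i}" for i in range(100)]
        feature = universe[:10]
        term = universe[:5] + universe[10:15]  # a=5, b=5, c=5, d=85
        df = gf.fisher_enrichment(feature, {"t": term}, universe)
        oracle = sum(stats.hypergeom.pmf(k, 100, 10, 10) for k in range(5, 11))
        assert np.isclose(df["p"][0], oracle, rtol=1e-10)

    def test_q_at_least_p(self):
        universe = [f"g{i}" for i in range(50)]
        terms = {f"t{j}": universe[j:j + 7] for j in range(8)}
        df = gf.fisher_enrichment(universe[:12], terms, universe)
        assert np.all(df["q"] >= df["p"] - 1e-12)


@pytest.fixture(scope="module")
def scan_result():
    cfg = gf.SimulationConfig(n_accessions=120, n_markers=600,
                              n_chromosomes=2, n_genes=80, n_features=4,
                              feature_size_range=(4, 10), seed=19)
    geno, genes = gf.simulate_genotypes(cfg)
    feats = gf.simulate_feature_sets(genes, cfg, geno)
    trait = gf.TraitConfig(h2_target=0.6,
                           feature_id=feats[0].feature_id, hf2_share=0.7,
                           n_causal=20, n_replicates=1,
                           design_effect_sds={}, n_timepoints=2, seed=20)
    sim = gf.simulate_trait(geno, feats, trait)
    tbl = sim.phenotypes
    y_by_tp = {}
    for t in ("t1", "t2"):
        sub = tbl[tbl["timepoint"] == t].sort_values("accession")
        y_by_tp[t] = sub["value"].to_numpy()
    splits = gf.make_cv_splits(120, 5, 2, seed=8)
    scan = gf.feature_scan(feats, y_by_tp, geno, splits, 8)
    return feats, scan


class TestFeatureScan:
    def test_record_count_and_fdr_family(self, scan_result):
        feats, scan = scan_result
        usable = [f for f in feats if 0 < f.n_markers < 600]
        assert len(scan) <= len(usable) * 2
        assert scan["q_fdr"].between(0, 1).all()
        assert np.all(scan["q_fdr"] + 1e-12 >= scan["p_wilcoxon"])

    def test_filter_flags_match_their_definition(self, scan_result):
        _, scan = scan_result
        for _, r in scan.iterrows():
            expected = (0.01 < r["hf2"] < 0.99 and r["p_lrt"] < 0.05
                        and r["p_wilcoxon"] < 0.05
                        and r["median_r_gfblup"] > r["median_r_gblup"])
            assert r["passed_filters"] == expected
            if np.isfinite(r["pct_gain"]) and r["median_r_gblup"] > 0:
                oracle = 100 * (r["median_r_gfblup"] - r["median_r_gblup"]) \
                    / r["median_r_gblup"]
                assert np.isclose(r["pct_gain"], oracle)

    def test_causal_feature_has_top_hf2(self, scan_result):
        feats, scan = scan_result
        by_hf2 = scan.groupby("feature_id")["hf2"].mean().sort_values()
        assert by_hf2.index[-1] == feats[0].feature_id

    def test_extreme_hf2_fails_filters(self):
        rec = gf.FeatureScanRecord(
            feature_id="f", timepoint="t", hf2=0.995, h2_gblup=0.3, lr=10.0,
            p_lrt=0.001, median_r_gfblup=0.3, median_r_gblup=0.2,
            pct_gain=50.0, p_wilcoxon=0.001)
        assert not (0.01 < rec.hf2 < 0.99)
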