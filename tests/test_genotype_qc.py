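"""QC chain: exact HWE vs enumeration, LD pruning vs greedy oracle,
EIGENSTRAT PCA vs SVD, residualization vs normal equations, prefilter
calibration."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.special import gammaln

from paraica.datatypes import GenotypeMatrix
from paraica.genotype_qc import (
    filter_variants,
    hwe_exact_test,
    ld_prune,
    eigenstrat_pca,
    select_ancestry_axes,
    regress_out_covariates,
    logistic_prefilter,
    snp_maf,
)
from paraica.synthetic import SyntheticConfig, generate_linked_dataset


def make_geno(dosages, group=None, positions=None, chrom=None):
    dosages = np.asarray(dosages, dtype=float)
    n, m = dosages.shape
    snp = pd.DataFrame({
        "snp_id": [f"s{j}" for j in range(m)],
        "chrom": chrom if chrom is not None else ["1"] * m,
        "pos": positions if positions is not None else np.arange(1, m + 1) * 100,
        "a1": "A", "a2": "G",
    })
    samp = pd.DataFrame({"sample_id": [f"i{i}" for i in range(n)]})
    if group is not None:
        samp["group"] = group
    return GenotypeMatrix(dosages=dosages, snp_records=snp, sample_records=samp)


def hwe_enumeration_oracle(n_hom_ref, n_het, n_hom_alt):
    """Brute-force conditional distribution of the heterozygote count."""
    n = n_hom_ref + n_het + n_hom_alt
    na = 2 * n_hom_alt + n_het
    rare = min(na, 2 * n - na)
    probs = {}
    for h in range(rare % 2, rare + 1, 2):
        hr = (rare - h) // 2
        hc = n - h - hr
        logp = (gammaln(n + 1) - gammaln(hr + 1) - gammaln(h + 1) - gammaln(hc + 1)
                + h * np.log(2))
        probs[h] = np.exp(logp)
    z = sum(probs.values())
    probs = {h: v / z for h, v in probs.items()}
    obs = probs[n_het]
    return sum(v for v in probs.values() if v <= obs * (1 + 1e-12))


class TestHweExactTest:
    def test_monomorphic_degenerate_support(self):
        assert hwe_exact_test(60, 0, 0) == 1.0

    @pytest.mark.parametrize("counts", [(21, 30, 9), (25, 50, 25), (5, 10, 45), (198, 2, 0)])
    def test_matches_enumeration_oracle(self, counts):
        assert hwe_exact_test(*counts) == pytest.approx(hwe_enumeration_oracle(*counts))

    def test_hardy_weinberg_proportions_give_modal_p(self):
        # (25, 50, 25) is exactly the HWE expectation at p=0.5: observed het
        # count is modal, so the exact p is 1 (every outcome is <= modal prob)
        assert hwe_exact_test(25, 50, 25) > 0.9

    def test_agrees_with_chisquare_for_common_counts(self):
        for counts in [(40, 40, 20), (50, 45, 25), (30, 60, 30)]:
            n = sum(counts)
            p_alt = (2 * counts[2] + counts[1]) / (2 * n)
            exp = np.array([n * (1 - p_alt) ** 2, n * 2 * p_alt * (1 - p_alt), n * p_alt**2])
            chi2 = np.sum((np.array(counts) - exp) ** 2 / exp)
            p_chi = stats.chi2.sf(chi2, df=1)
            p_exact = hwe_exact_test(*counts)
            assert abs(np.log10(p_exact) - np.log10(p_chi)) < 0.2

    def test_all_zero_counts_raise(self):
        with pytest.raises(ValueError):
            hwe_exact_test(0, 0, 0)


class TestFilterVariants:
    def test_filters_apply_in_order_and_report_adds_up(self):
        rng = np.random.default_rng(0)
        base = rng.binomial(2, 0.3, size=(60, 5)).astype(float)
        base[:, 0] = 0.0  # monomorphic -> MAF filter
        base[:6, 1] = np.nan  # 10% missing -> call-rate filter
        base[:, 2] = np.repeat([0, 2], 30)  # extreme HWE violation (no hets)
        geno = make_geno(base, group=np.zeros(60, dtype=int))
        out, report = filter_variants(geno, min_call_rate=0.95, min_maf=0.01, hwe_alpha=1e-4)
        assert report.removed["call_rate"] == 1
        assert report.removed["maf"] == 1
        assert report.removed["hwe"] == 1
        assert sum(report.removed.values()) + report.n_retained == report.n_input
        assert "s0" not in out.snp_records["snp_id"].tolist()

    def test_hwe_tested_in_controls_only(self):
        # cases violate HWE wildly, controls conform -> SNP kept
        controls = np.random.default_rng(1).binomial(2, 0.5, size=(100, 1)).astype(float)
        cases = np.repeat([0.0, 2.0], 25).reshape(50, 1)
        d = np.vstack([controls, cases])
        group = np.array([0] * 100 + [1] * 50)
        geno = make_geno(d, group=group)
        _, report = filter_variants(geno, hwe_alpha=1e-3)
        assert report.removed["hwe"] == 0

    def test_empty_output_raises_naming_filter(self):
        geno = make_geno(np.zeros((20, 3)))
        with pytest.raises(ValueError, match="MAF"):
            filter_variants(geno)


def greedy_prune_oracle(dosages, maf, window, step, r2_max):
    """Direct re-implementation of the documented pruning walk."""
    m = dosages.shape[1]
    keep = np.ones(m, dtype=bool)
    start = 0
    while True:
        window_idx = [j for j in range(start, min(start + window, m))]
        changed = True
        while changed:
            changed = False
            act = [j for j in window_idx if keep[j]]
            for ai in range(len(act)):
                for bi in range(ai + 1, len(act)):
                    a, b = act[ai], act[bi]
                    if not (keep[a] and keep[b]):
                        continue
                    r = np.corrcoef(dosages[:, a], dosages[:, b])[0, 1] ** 2
                    if r > r2_max:
                        if maf[a] < maf[b]:
                            keep[a] = False
                        elif maf[b] < maf[a]:
                            keep[b] = False
                        else:
                            keep[max(a, b)] = False
                        changed = True
        if start + window >= m:
            break
        start += step
    return keep


class TestLdPrune:
    def test_duplicated_column_keeps_exactly_one(self):
        rng = np.random.default_rng(2)
        d = rng.binomial(2, 0.4, size=(80, 3)).astype(float)
        d[:, 2] = d[:, 1]
        kept = ld_prune(make_geno(d), window_snps=3, step_snps=1)
        assert ("s1" in kept) != ("s2" in kept)

    def test_independent_snps_all_retained(self):
        rng = np.random.default_rng(3)
        d = rng.binomial(2, 0.4, size=(300, 10)).astype(float)
        kept = ld_prune(make_geno(d))
        assert len(kept) == 10

    def test_matches_greedy_oracle_and_postcondition(self):
        rng = np.random.default_rng(4)
        n, m = 150, 10
        d = rng.binomial(2, 0.4, size=(n, m)).astype(float)
        # plant two highly correlated pairs
        d[:, 3] = np.clip(d[:, 2] + rng.binomial(1, 0.05, n), 0, 2)
        d[:, 7] = np.clip(d[:, 6] + rng.binomial(1, 0.05, n), 0, 2)
        geno = make_geno(d)
        kept = ld_prune(geno, window_snps=5, step_snps=2, r2_max=0.7)
        oracle_keep = greedy_prune_oracle(d, snp_maf(d), 5, 2, 0.7)
        assert kept == [f"s{j}" for j in np.flatnonzero(oracle_keep)]
        # exhaustive post-condition within every window over retained SNPs
        kept_idx = [int(s[1:]) for s in kept]
        for start in range(0, m, 2):
            win = [j for j in kept_idx if start <= j < start + 5]
            for ai in range(len(win)):
                for bi in range(ai + 1, len(win)):
                    r2 = np.corrcoef(d[:, win[ai]], d[:, win[bi]])[0, 1] ** 2
                    assert r2 <= 0.7


class TestEigenstratPca:
    def test_matches_svd_oracle_up_to_sign(self):
        rng = np.random.default_rng(5)
        d = rng.binomial(2, 0.3, size=(40, 60)).astype(float)
        evecs, evals = eigenstrat_pca(make_geno(d), n_axes=5)
        n = d.shape[0]
        p_hat = (1 + d.sum(axis=0)) / (2 + 2 * n)
        X = (d - 2 * p_hat) / np.sqrt(p_hat * (1 - p_hat))
        u, s, _ = np.linalg.svd(X, full_matrices=False)
        assert np.allclose(evals[:5], s[:5] ** 2 / d.shape[1], rtol=1e-8)
        for k in range(5):
            assert abs(abs(evecs[:, k] @ u[:, k]) - 1) < 1e-6

    def test_leading_axis_separates_subpopulations(self):
        cfg = SyntheticConfig(n_subjects=200, n_snps=1000, grid_dims=(6, 6, 6),
                              blob_radius_vox=1.2, fst=0.1, seed=13)
        geno, _, _, truth = generate_linked_dataset(cfg)
        evecs, _ = eigenstrat_pca(geno, n_axes=4)
        r = np.corrcoef(evecs[:, 0], truth.subpop_labels)[0, 1]
        assert abs(r) > 0.9

    def test_homogeneous_population_has_no_dominant_axis(self):
        rng = np.random.default_rng(6)
        d = rng.binomial(2, rng.uniform(0.1, 0.5, 1000), size=(100, 1000)).astype(float)
        _, evals = eigenstrat_pca(make_geno(d), n_axes=100)
        assert evals[0] / evals.mean() < 2

    def test_monomorphic_column_raises(self):
        d = np.ones((30, 3))
        d[:, :2] = np.random.default_rng(7).binomial(2, 0.4, size=(30, 2))
        with pytest.raises(ValueError, match="monomorphic"):
            eigenstrat_pca(make_geno(d))


class TestSelectAncestryAxes:
    def test_identical_labels_select_nothing(self):
        evecs = np.random.default_rng(8).standard_normal((50, 4))
        with pytest.warns(UserWarning):
            assert select_ancestry_axes(evecs, np.zeros(50)) == []

    def test_perfectly_separating_axis_selected_first(self):
        rng = np.random.default_rng(9)
        labels = np.repeat([0, 1], 25)
        evecs = rng.standard_normal((50, 4))
        evecs[:, 2] = labels + 0.01 * rng.standard_normal(50)
        sel = select_ancestry_axes(evecs, labels, n_keep=2)
        assert sel[0] == 2

    def test_synthetic_subpops_select_axis_matching_direct_ranking(self):
        cfg = SyntheticConfig(n_subjects=150, n_snps=600, grid_dims=(6, 6, 6),
                              blob_radius_vox=1.2, fst=0.1, seed=21)
        geno, _, covars, truth = generate_linked_dataset(cfg)
        evecs, _ = eigenstrat_pca(geno, n_axes=5)
        sel = select_ancestry_axes(evecs, covars["ethnicity"], n_keep=2)
        by_corr = int(np.argmax([abs(np.corrcoef(evecs[:, k], truth.subpop_labels)[0, 1])
                                 for k in range(5)]))
        assert by_corr in sel


class TestRegressOutCovariates:
    def test_orthogonal_covariate_leaves_column_centered(self, rng):
        x = rng.standard_normal(100)
        z = rng.standard_normal(100)
        z -= z.mean()
        xc = x - x.mean()
        z -= z @ xc / (xc @ xc) * xc  # orthogonal to [intercept, x]
        res = regress_out_covariates(x[:, None], z[:, None])
        assert np.allclose(res[:, 0], x - x.mean(), atol=1e-8)

    def test_column_equal_to_covariate_residual_zero(self, rng):
        z = rng.standard_normal(60)
        res = regress_out_covariates(z[:, None], z[:, None])
        assert np.allclose(res, 0, atol=1e-10)

    def test_matches_normal_equations_oracle(self, rng):
        M = rng.standard_normal((20, 5))
        Z = rng.standard_normal((20, 2))
        D = np.column_stack([np.ones(20), Z])
        beta = np.linalg.solve(D.T @ D, D.T @ M)
        expected = M - D @ beta
        assert np.allclose(regress_out_covariates(M, Z), expected, atol=1e-10)
        # residuals orthogonal to covariates
        assert np.max(np.abs(D.T @ regress_out_covariates(M, Z))) < 1e-8

    def test_rank_deficient_covariates_raise(self, rng):
        Z = rng.standard_normal((30, 2))
        Z2 = np.column_stack([Z, Z[:, 0]])
        with pytest.raises(ValueError, match="collinear"):
            regress_out_covariates(rng.standard_normal((30, 3)), Z2)


class TestLogisticPrefilter:
    def test_retention_is_strictly_below_alpha(self, rng):
        n = 400
        y = rng.integers(0, 2, n)
        G = rng.binomial(2, 0.3, size=(n, 30)).astype(float)
        Z = np.column_stack([rng.uniform(8, 18, n), rng.integers(0, 2, n)])
        kept, p, _ = logistic_prefilter(G, y, Z, alpha=0.1)
        assert set(kept) == set(np.flatnonzero(p < 0.1))

    def test_null_retained_fraction_and_uniformity(self):
        rng = np.random.default_rng(10)
        n, m = 500, 2000
        G = rng.binomial(2, 0.3, size=(n, m)).astype(float)
        y = rng.integers(0, 2, n)
        Z = np.column_stack([rng.uniform(8, 18, n), rng.integers(0, 2, n)])
        kept, p, flags = logistic_prefilter(G, y, Z, alpha=0.1)
        frac = len(kept) / m
        assert abs(frac - 0.10) < 0.02
        assert stats.kstest(p[~np.isnan(p)], "uniform").pvalue > 0.01

    def test_constant_column_flagged_not_fatal(self, rng):
        n = 200
        y = rng.integers(0, 2, n)
        G = rng.binomial(2, 0.3, size=(n, 3)).astype(float)
        G[:, 1] = 1.0
        with pytest.warns(UserWarning, match="constant"):
            kept, p, flags = logistic_prefilter(G, y, np.empty((n, 0)))
        assert flags[1] and np.isnan(p[1]) and 1 not in kept

    def test_perfect_separation_flagged_or_penalized(self, rng):
        n = 100
        y = np.repeat([0, 1], 50)
        G = rng.binomial(2, 0.3, size=(n, 2)).astype(float)
        G[:, 0] = y * 2.0  # perfectly separating dosage
        kept, p, flags = logistic_prefilter(G, y.astype(float), np.empty((n, 0)))
        # either excluded outright or rescued by the penalized fit with finite p
        assert flags[0] or np.isfinite(p[0])


class TestStratificationCorrection:
    def test_ancestry_regression_halves_subpop_correlation(self):
        cfg = SyntheticConfig(n_subjects=200, n_snps=800, grid_dims=(6, 6, 6),
                              blob_radius_vox=1.2, fst=0.1, seed=33)
        geno, _, covars, truth = generate_linked_dataset(cfg)
        evecs, _ = eigenstrat_pca(geno, n_axes=5)
        axes = select_ancestry_axes(evecs, covars["ethnicity"], n_keep=2)
        assert axes
        sub = truth.subpop_labels - truth.subpop_labels.mean()
        def mean_abs_corr(d):
            dc = d - d.mean(axis=0)
            sd = dc.std(axis=0)
            sd[sd == 0] = np.inf
            return np.mean(np.abs(dc.T @ sub / (len(sub) * sd * sub.std())))
        before = mean_abs_corr(geno.dosages)
        resid = regress_out_covariates(geno.dosages, evecs[:, axes])
        after = mean_abs_corr(resid)
        assert after <= 0.5 * before
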