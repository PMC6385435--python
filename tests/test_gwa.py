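import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from beefgwas.gwa import (
    VarianceComponents,
    compute_grm,
    conditional_scan,
    fit_reml,
    joint_fit,
    preprocess_trait,
    scan,
)

from conftest import make_genotypes, make_pheno


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------


class TestPreprocess:
    def test_wbsf_is_natural_log(self):
        out = preprocess_trait(np.array([math.e, 1.0, math.e**2]), "wbsf")
        np.testing.assert_allclose(out, [1.0, 0.0, 2.0])

    def test_wbsf_nonpositive_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            preprocess_trait(np.array([4.0, -1.0]), "wbsf")

    @pytest.mark.parametrize("trait", ["wbsf", "marbling", "connective_tissue", "flavor"])
    def test_transform_is_strictly_monotone(self, trait):
        rng = np.random.default_rng(3)
        x = np.exp(rng.normal(1.0, 0.4, size=200))
        out = preprocess_trait(x, trait)
        rho = stats.spearmanr(x, out).statistic
        assert rho == pytest.approx(1.0)

    def test_normalization_removes_skew(self):
        rng = np.random.default_rng(5)
        x = np.exp(rng.normal(0.0, 1.0, size=500))  # strongly right-skewed
        assert abs(stats.skew(x)) > 1.0
        out = preprocess_trait(x, "marbling")
        assert abs(stats.skew(out)) < 0.5

    def test_missing_values_preserved(self):
        x = np.array([300.0, np.nan] + list(np.linspace(200, 700, 60)))
        out = preprocess_trait(x, "marbling")
        assert np.isnan(out[1]) and np.isfinite(out[0])


# ---------------------------------------------------------------------------
# GRM
# ---------------------------------------------------------------------------


class TestGrm:
    def test_closed_form_single_variant(self):
        # dosages [0,1,2], p=0.5: W=[-1,0,1], denom=0.5
        g = make_genotypes(np.array([[0.0], [1.0], [2.0]]))
        grm = compute_grm(g)
        expected = np.array([[2.0, 0.0, -2.0], [0.0, 0.0, 0.0], [-2.0, 0.0, 2.0]])
        np.testing.assert_allclose(grm.matrix, expected)

    def test_identical_samples_have_equal_rows(self):
        rng = np.random.default_rng(0)
        dos = rng.binomial(2, 0.4, size=(5, 100)).astype(float)
        dos[1] = dos[0]
        grm = compute_grm(make_genotypes(dos))
        np.testing.assert_allclose(grm.matrix[0], grm.matrix[1])

    def test_outbred_diagonal_near_one(self):
        rng = np.random.default_rng(1)
        p = rng.uniform(0.1, 0.9, size=2000)
        dos = rng.binomial(2, p, size=(200, 2000)).astype(float)
        grm = compute_grm(make_genotypes(dos))
        assert np.diag(grm.matrix).mean() == pytest.approx(1.0, abs=0.05)

    def test_monomorphic_variant_rejected(self):
        g = make_genotypes(np.array([[0.0, 1.0], [0.0, 1.0], [0.0, 2.0]]))
        with pytest.raises(ValueError, match="qc_filter"):
            compute_grm(g)


# ---------------------------------------------------------------------------
# REML
# ---------------------------------------------------------------------------


def reml_neg2_loglik_oracle(lam, y, X, G):
    """Direct dense-matrix REML -2 log-likelihood (no spectral shortcut)."""
    n, p = X.shape
    V = lam * G + np.eye(n)
    Vi = np.linalg.inv(V)
    XtViX = X.T @ Vi @ X
    beta = np.linalg.solve(XtViX, X.T @ Vi @ y)
    r = y - X @ beta
    sigma2 = float(r @ Vi @ r) / (n - p)
    _, ldV = np.linalg.slogdet(V)
    _, ldX = np.linalg.slogdet(XtViX)
    return (n - p) * math.log(sigma2) + ldV + ldX + (n - p)


class TestReml:
    def test_matches_brute_force_grid(self):
        rng = np.random.default_rng(42)
        n = 50
        dos = rng.binomial(2, rng.uniform(0.2, 0.8, size=400), size=(n, 400))
        grm = compute_grm(make_genotypes(dos.astype(float)))
        G = grm.matrix
        L = np.linalg.cholesky(G + 1e-8 * np.eye(n))
        y = L @ rng.standard_normal(n) * 0.8 + rng.standard_normal(n)
        X = np.ones((n, 1))
        vc = fit_reml(y, X, grm)
        grid = np.logspace(-3, 3, 101)
        vals = [reml_neg2_loglik_oracle(l, y, X, G) for l in grid]
        lam_star = grid[int(np.argmin(vals))]
        # within one grid step (grid ratio ~1.148)
        step = grid[1] / grid[0]
        assert lam_star / step <= max(vc.lam, 1e-3) <= lam_star * step

    def test_null_simulation_estimates_near_zero(self):
        # a structured (admixed) GRM identifies the variance ratio well; the
        # null estimate then concentrates at the zero boundary
        from beefgwas.synthetic_data import SimConfig, simulate_genotypes

        cfg = SimConfig(n_samples=300, n_sensory=200, n_variants=1000,
                        n_genes=20, qtl_spec=[], seed=7)
        g, _ = simulate_genotypes(cfg)
        grm = compute_grm(g)
        rng = np.random.default_rng(7)
        hits = 0
        for rep in range(10):
            y = rng.standard_normal(300)  # pure noise, no genetic signal
            vc = fit_reml(y, np.ones((300, 1)), grm)
            hits += vc.h2 < 0.05
        assert hits >= 9

    def test_rank_deficient_grm_handled(self):
        rng = np.random.default_rng(2)
        dos = rng.binomial(2, 0.5, size=(20, 50)).astype(float)
        dos[1] = dos[0]  # duplicate sample -> rank-deficient G
        grm = compute_grm(make_genotypes(dos))
        y = rng.standard_normal(20)
        vc = fit_reml(y, np.ones((20, 1)), grm)
        assert vc.sigma2_e > 0


# ---------------------------------------------------------------------------
# single-marker scan
# ---------------------------------------------------------------------------


def ols_oracle(y, X, x):
    """Closed-form OLS of y on [X, x] with a 1-df Wald chi2 test."""
    D = np.column_stack([X, x])
    beta = np.linalg.solve(D.T @ D, D.T @ y)
    r = y - D @ beta
    sigma2 = float(r @ r) / (len(y) - D.shape[1])
    cov = sigma2 * np.linalg.inv(D.T @ D)
    b, se = beta[-1], math.sqrt(cov[-1, -1])
    wald = b**2 / se**2
    return b, se, stats.chi2.sf(wald, df=1)


OLS_VC = VarianceComponents(sigma2_a=0.0, sigma2_e=1.0, lam=0.0, h2=0.0, reml_loglik=0.0)


class TestScan:
    def test_gls_at_zero_lambda_equals_ols(self):
        rng = np.random.default_rng(11)
        n, m = 80, 25
        dos = rng.binomial(2, rng.uniform(0.2, 0.8, size=m), size=(n, m)).astype(float)
        g = make_genotypes(dos)
        y = rng.standard_normal(n)
        pheno = make_pheno(g.samples, y=y)
        res = scan(g, pheno, "y", covariates=("year",), vc=OLS_VC, preprocess=False)
        X = pd.get_dummies(pheno["year"].astype("category"), drop_first=True)
        X = np.column_stack([np.ones(n), X.to_numpy(float)])
        for j in rng.choice(m, size=8, replace=False):
            b, se, p = ols_oracle(y, X, dos[:, j])
            assert res[j].beta == pytest.approx(b, rel=1e-10)
            assert res[j].se == pytest.approx(se, rel=1e-10)
            assert res[j].p == pytest.approx(p, rel=1e-9)

    def test_two_group_closed_form_beta(self):
        g = make_genotypes(np.array([[0.0], [0.0], [1.0], [1.0]]))
        pheno = make_pheno(g.samples, y=[1.0, 2.0, 3.0, 4.0])
        res = scan(g, pheno, "y", covariates=(), vc=OLS_VC, preprocess=False)
        assert res[0].beta == pytest.approx(2.0)

    def test_pvalues_invariant_under_affine_rescale(self):
        rng = np.random.default_rng(13)
        n, m = 60, 30
        dos = rng.binomial(2, 0.4, size=(n, m)).astype(float)
        g = make_genotypes(dos)
        y = rng.standard_normal(n)
        p1 = [r.p for r in scan(g, make_pheno(g.samples, y=y), "y", preprocess=False)]
        p2 = [
            r.p
            for r in scan(
                g, make_pheno(g.samples, y=5.0 + 3.0 * y), "y", preprocess=False
            )
        ]
        np.testing.assert_allclose(p1, p2, rtol=1e-8)

    def test_collinear_snp_reported_missing(self):
        dos = np.column_stack([np.ones(20), np.random.default_rng(0).binomial(2, 0.5, 20)])
        g = make_genotypes(dos.astype(float))
        pheno = make_pheno(g.samples, y=np.random.default_rng(1).standard_normal(20))
        res = scan(g, pheno, "y", covariates=(), vc=OLS_VC, preprocess=False)
        assert math.isnan(res[0].p) and res[0].note != ""
        assert not math.isnan(res[1].p)


# ---------------------------------------------------------------------------
# conditional scan
# ---------------------------------------------------------------------------


def _qtl_panel(rng, n=400, r_flip=0.04):
    """Causal SNP, a tight proxy (r2 > 0.8), an unlinked SNP + 5 fillers."""
    causal = rng.binomial(2, 0.5, size=n).astype(float)
    flip = rng.random(n) < r_flip
    proxy = np.where(flip, rng.binomial(2, 0.5, size=n), causal).astype(float)
    unlinked = rng.binomial(2, 0.5, size=n).astype(float)
    fillers = rng.binomial(2, 0.4, size=(n, 5)).astype(float)
    dos = np.column_stack([causal, proxy, unlinked, fillers])
    g = make_genotypes(dos)
    y = 0.45 * (causal - causal.mean()) + rng.standard_normal(n)
    return g, make_pheno(g.samples, y=y)


class TestConditionalScan:
    def test_proxy_loses_significance_when_conditioning_on_causal(self):
        hits = 0
        for rep in range(10):
            rng = np.random.default_rng(100 + rep)
            g, pheno = _qtl_panel(rng)
            r2 = np.corrcoef(g.dosages[:, 0], g.dosages[:, 1])[0, 1] ** 2
            assert r2 > 0.8
            res = conditional_scan(g, pheno, "y", condition_on="v1", preprocess=False)
            proxy = next(r for r in res if r.variant.id == "v2")
            hits += proxy.p > 0.05
        assert hits >= 9

    def test_conditioning_on_unlinked_snp_leaves_causal_untouched(self):
        rng = np.random.default_rng(200)
        g, pheno = _qtl_panel(rng)
        base = scan(g, pheno, "y", preprocess=False)
        causal_base = next(r for r in base if r.variant.id == "v1")
        res = conditional_scan(g, pheno, "y", condition_on="v3", preprocess=False)
        causal_cond = next(r for r in res if r.variant.id == "v1")
        assert abs(math.log10(causal_cond.p) - math.log10(causal_base.p)) < 0.5

    def test_region_with_only_conditioning_snp_is_empty(self):
        rng = np.random.default_rng(300)
        g, pheno = _qtl_panel(rng)
        v = g.variants[0]
        res = conditional_scan(
            g, pheno, "y", condition_on="v1", region=(v.chrom, v.pos, v.pos),
            preprocess=False,
        )
        assert res == []

    def test_monomorphic_condition_rejected(self):
        g = make_genotypes(np.column_stack([np.zeros(10), np.arange(10) % 3]))
        pheno = make_pheno(g.samples, y=np.random.default_rng(0).standard_normal(10))
        with pytest.raises(ValueError, match="monomorphic"):
            conditional_scan(g, pheno, "y", condition_on="v1", preprocess=False)


# ---------------------------------------------------------------------------
# joint multi-SNP model
# ---------------------------------------------------------------------------


class TestJointFit:
    def _panel(self, rng, betas, n=400):
        m = len(betas)
        dos = rng.binomial(2, 0.5, size=(n, m + 10)).astype(float)
        y = rng.standard_normal(n)
        for j, b in enumerate(betas):
            y = y + b * (dos[:, j] - dos[:, j].mean())
        g = make_genotypes(dos)
        return g, make_pheno(g.samples, y=y)

    def test_two_independent_causal_snps_both_retained(self):
        rng = np.random.default_rng(17)
        g, pheno = self._panel(rng, [0.4, 0.4])
        res = joint_fit(g, pheno, "y", ["v1", "v2"], preprocess=False)
        assert set(res.retained) == {"v1", "v2"}
        assert all(p <= 0.05 for p in res.pvalues.values())

    def test_noise_snp_eliminated(self):
        kept_ok = 0
        for rep in range(5):
            rng = np.random.default_rng(500 + rep)
            g, pheno = self._panel(rng, [0.45])
            res = joint_fit(g, pheno, "y", ["v1", "v5"], preprocess=False)
            kept_ok += res.retained == ["v1"]
        assert kept_ok >= 4

    def test_single_significant_snp_unchanged(self):
        rng = np.random.default_rng(23)
        g, pheno = self._panel(rng, [0.5])
        res = joint_fit(g, pheno, "y", ["v1"], preprocess=False)
        assert res.retained == ["v1"] and res.trace == []

    def test_empty_list_rejected(self):
        rng = np.random.default_rng(29)
        g, pheno = self._panel(rng, [0.5])
        with pytest.raises(ValueError, match="non-empty"):
            joint_fit(g, pheno, "y", [], preprocess=False)

    def test_elimination_trace_deterministic(self):
        rng = np.random.default_rng(31)
        g, pheno = self._panel(rng, [0.4])
        snps = ["v1", "v4", "v5", "v6"]
        r1 = joint_fit(g, pheno, "y", snps, preprocess=False)
        r2 = joint_fit(g, pheno, "y", snps, preprocess=False)
        assert r1.trace == r2.trace and r1.retained == r2.retained
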