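"""AI-REML correctness: oracle equivalence, boundary behavior, invariances
and the separate/joint partition analysis."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize

import varpart as vp


def restricted_loglik(theta, K_list, y, X):
    """Direct dense evaluation of the restricted log-likelihood, written
    independently of the estimator (the test oracle)."""
    n = len(y)
    V = theta[-1] * np.eye(n)
    for t, K in zip(theta[:-1], K_list):
        V = V + t * K
    sign, ld = np.linalg.slogdet(V)
    if sign <= 0:
        return -np.inf
    Vi = np.linalg.inv(V)
    XtVX = X.T @ Vi @ X
    s2, ldx = np.linalg.slogdet(XtVX)
    P = Vi - Vi @ X @ np.linalg.inv(XtVX) @ X.T @ Vi
    return -0.5 * (ld + ldx + y @ P @ y)


@pytest.fixture(scope="module")
def tiny_mixed_data():
    """n=50 phenotype with a known polygenic part over a 500-SNP GRM."""
    cfg = vp.SimConfig(
        n_chromosomes=2, n_snps=500, n_sires=10, progeny_per_sire=5, seed=3
    )
    _, snps = vp.simulate_genome(cfg)
    g = vp.simulate_genotypes(cfg, snps)
    K = vp.compute_grm(g).matrix
    rng = np.random.default_rng(1)
    gv = vp.simulate_polygenic_background(vp.compute_grm(g), 0.6, rng)
    y = gv + rng.standard_normal(K.shape[0]) * np.sqrt(0.4)
    return K, y


class TestOracleEquivalence:
    def test_matches_grid_plus_polish_oracle(self, tiny_mixed_data):
        """AI-REML equals a brute-force restricted-likelihood search to
        3 decimals at n=50."""
        K, y = tiny_mixed_data
        n = len(y)
        X = np.ones((n, 1))

        def neg(theta):
            if min(theta) <= 0:
                return 1e10
            return -restricted_loglik(np.asarray(theta), [K], y, X)

        grid = np.linspace(0.01, 2.5, 40)
        best = min(((neg((a, b)), (a, b)) for a in grid for b in grid))
        res = minimize(neg, best[1], method="Nelder-Mead",
                       options=dict(xatol=1e-9, fatol=1e-12))
        est = vp.GREML().fit(K, y)
        assert est.converged_
        assert est.sigma2_[0] == pytest.approx(res.x[0], abs=1e-3)
        assert est.sigma2_e_ == pytest.approx(res.x[1], abs=1e-3)
        assert est.loglik_ == pytest.approx(-res.fun, abs=1e-6)

    @pytest.mark.parametrize("theta", [(0.3, 0.7), (1.2, 0.1), (0.05, 2.0)])
    def test_dense_and_eigen_engines_agree(self, tiny_mixed_data, theta):
        """Both likelihood engines give the same logL, score and AI matrix
        at arbitrary admissible parameter values."""
        from varpart.reml import _DenseEngine, _EigenEngine

        K, y = tiny_mixed_data
        X = np.ones((len(y), 1))
        th = np.asarray(theta)
        a = _EigenEngine(K, y, X).evaluate(th)
        b = _DenseEngine([K], y, X).evaluate(th)
        assert a.loglik == pytest.approx(b.loglik, abs=1e-8)
        np.testing.assert_allclose(a.score, b.score, atol=1e-7)
        np.testing.assert_allclose(a.ai, b.ai, atol=1e-7)
        assert a.loglik == pytest.approx(
            restricted_loglik(th, [K], y, X), abs=1e-8
        )


class TestBoundariesAndGuards:
    def test_identity_grm_flagged_non_identifiable(self):
        rng = np.random.default_rng(0)
        y = rng.standard_normal(80)
        with pytest.warns(UserWarning, match="identifiable"):
            est = vp.GREML().fit(np.eye(80), y)
        assert not est.identifiable_

    def test_null_heritability_estimated_near_zero(self):
        cfg = vp.SimConfig(
            n_chromosomes=5, n_snps=2000, n_sires=200, progeny_per_sire=5,
            seed=19,
        )
        _, snps = vp.simulate_genome(cfg)
        g = vp.simulate_genotypes(cfg, snps)
        grm = vp.compute_grm(g)
        y = np.random.default_rng(4).standard_normal(g.n_samples)
        est = vp.GREML().fit(grm, y)
        assert est.h2_[0] <= 0.02

    def test_rank_deficient_design_rejected(self, tiny_mixed_data):
        K, y = tiny_mixed_data
        X = np.ones((len(y), 2))  # duplicated intercept
        with pytest.raises(ValueError, match="rank"):
            vp.GREML().fit(K, y, X=X)

    def test_likelihood_never_decreases(self, tiny_mixed_data):
        K, y = tiny_mixed_data
        est = vp.GREML().fit(K, y)
        path = np.asarray(est.loglik_path_)
        assert (np.diff(path) >= -1e-8).all()

    def test_scale_equivariance(self, tiny_mixed_data):
        """y -> c y scales variances by c^2 and leaves h2 unchanged."""
        K, y = tiny_mixed_data
        a = vp.GREML().fit(K, y)
        b = vp.GREML().fit(K, 3.0 * y)
        assert b.sigma2_[0] == pytest.approx(9.0 * a.sigma2_[0], rel=1e-4)
        assert b.sigma2_e_ == pytest.approx(9.0 * a.sigma2_e_, rel=1e-4)
        assert b.h2_[0] == pytest.approx(a.h2_[0], abs=1e-5)


@pytest.fixture(scope="module")
def cohort_with_trait():
    cfg = vp.SimConfig(
        n_chromosomes=4, n_snps=3000, n_sires=80, progeny_per_sire=6,
        seed=23,
    )
    genes, snps = vp.simulate_genome(cfg)
    g = vp.simulate_genotypes(cfg, snps)
    ann = vp.annotate_snps(snps, genes)
    arch = vp.TraitArchitecture(h2_target=0.5, causal_per_class={"intergenic": 60})
    pheno, _ = vp.simulate_phenotypes(g, ann, arch, cfg)
    y = vp.adjust_phenotypes(pheno, "trait").to_numpy()
    return g, ann, y


class TestPartitionAnalysis:
    def test_single_label_partition_equals_plain_fit(self, cohort_with_trait):
        g, ann, y = cohort_with_trait
        parts = {"all": list(g.snp_ids)}
        sep = vp.partition_analysis(y, None, g, parts, mode="separate")
        joint = vp.partition_analysis(y, None, g, parts, mode="joint")
        direct = vp.fit_reml(y, None, [vp.compute_grm(g)])
        for tab in (sep, joint):
            assert tab.loc[0, "h2"] == pytest.approx(direct.h2[0], abs=1e-6)

    def test_joint_rejects_overlapping_subsets(self, cohort_with_trait):
        g, _, y = cohort_with_trait
        ids = list(g.snp_ids)
        parts = {"a": ids[:100], "b": ids[50:150]}
        with pytest.raises(ValueError, match="disjoint"):
            vp.partition_analysis(y, None, g, parts, mode="joint")

    def test_joint_total_consistent_with_all_snp_fit(self, cohort_with_trait):
        """Sum of joint component h2 is within 2 SE of the all-SNP h2."""
        g, ann, y = cohort_with_trait
        parts = vp.collapse_classes(ann, scheme="three")
        joint = vp.partition_analysis(y, None, g, parts, mode="joint")
        total = vp.fit_reml(y, None, [vp.compute_grm(g)])
        spread = abs(joint["h2"].sum() - total.h2[0])
        assert spread <= 2.0 * np.sqrt((joint["se"] ** 2).sum() + total.h2_se[0] ** 2)

    def test_chromosome_partition_tracks_snp_density(self):
        """Uniform polygenic architecture: per-chromosome h2 from a joint
        fit regresses on chromosome SNP count with positive slope."""
        cfg = vp.SimConfig(
            n_chromosomes=12, n_snps=6000, n_sires=80, progeny_per_sire=8,
            seed=37,
        )
        genes, snps = vp.simulate_genome(cfg)
        g = vp.simulate_genotypes(cfg, snps)
        ann = vp.annotate_snps(snps, genes)
        arch = vp.TraitArchitecture(
            h2_target=0.6, mixture_props=(0.8, 0.12, 0.06, 0.02),
        )
        pheno, _ = vp.simulate_phenotypes(g, ann, arch, cfg)
        y = vp.adjust_phenotypes(pheno, "trait").to_numpy()
        from varpart.partition import chromosome_partition

        parts = chromosome_partition(ann)
        joint = vp.partition_analysis(y, None, g, parts, mode="joint")
        counts = joint["n_snps"].to_numpy(dtype=float)
        slope, _, r2 = vp.chromosome_length_regression(
            joint["h2"].to_numpy(), counts
        )
        assert slope > 0
        assert 0.0 < r2 < 1.0


class TestLengthRegression:
    def test_exact_proportionality_gives_r2_one(self):
        lengths = np.array([1e6, 2e6, 3e6, 4e6])
        h2 = lengths * 1e-8
        slope, intercept, r2 = vp.chromosome_length_regression(h2, lengths)
        assert r2 == pytest.approx(1.0)
        assert slope == pytest.approx(1e-8)

    def test_constant_h2_gives_zero_slope_and_r2(self):
        slope, _, r2 = vp.chromosome_length_regression(
            np.full(5, 0.02), np.linspace(1e6, 3e6, 5)
        )
        assert slope == 0.0 and r2 == 0.0

    def test_dict_inputs_align_on_keys(self):
        h2 = {"chr1": 0.01, "chr2": 0.02, "chr3": 0.03}
        ln = {"chr1": 1e6, "chr2": 2e6, "chr3": 3e6}
        slope, _, r2 = vp.chromosome_length_regression(h2, ln)
        assert r2 == pytest.approx(1.0)
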