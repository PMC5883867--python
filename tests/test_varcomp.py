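"""AI-REML fitting, heritability delta-method SE and BLUP prediction."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize

from jointgp.relmat import GRM, compute_grm
from jointgp.varcomp import (
    GBLUP, GBLUPResults, HeritabilityEstimate, MixedModelSpec,
    blup_predict, fit_aireml, heritability, restricted_loglik,
)
from jointgp.simdata import SimConfig, simulate_cohort


def _grid_oracle(spec, lo=-4, hi=2, coarse=40):
    """Brute-force restricted-likelihood maximisation on a log grid + polish."""
    grid = np.exp(np.linspace(lo, hi, coarse))
    best, best_ll = None, -np.inf
    for sg in grid:
        for se in grid:
            ll = restricted_loglik(spec, sg, se)
            if ll > best_ll:
                best, best_ll = (sg, se), ll
    res = minimize(lambda p: -restricted_loglik(spec, np.exp(p[0]), np.exp(p[1])),
                   np.log(best), method="Nelder-Mead",
                   options={"xatol": 1e-12, "fatol": 1e-14, "maxiter": 5000})
    return np.exp(res.x)


class TestAIREML:
    def test_matches_brute_force_oracle_on_toy(self, reml_toy):
        G, W, y, ids = reml_toy
        spec = MixedModelSpec(y, W, G, ids)
        fit = fit_aireml(spec)
        sg, se = _grid_oracle(spec)
        assert fit.converged
        assert fit.sigma_g2 == pytest.approx(sg, abs=1e-3)
        assert fit.sigma_e2 == pytest.approx(se, abs=1e-3)

    def test_noise_free_fixed_effects_hit_floor(self, reml_toy):
        G, W, _, ids = reml_toy
        y = W @ np.array([3.0, -1.0])  # y = W alpha exactly
        fit = fit_aireml(MixedModelSpec(y, W, G, ids))
        assert fit.boundary
        assert fit.sigma_g2 < 1e-6 and fit.sigma_e2 < 1e-6

    def test_loglik_never_decreases_and_final_at_least_initial(self, reml_toy):
        G, W, y, ids = reml_toy
        fit = fit_aireml(MixedModelSpec(y, W, G, ids))
        lls = fit.theta_trace["loglik"].to_numpy()
        assert np.all(np.diff(lls) >= -1e-8)
        assert lls[-1] >= lls[0]

    def test_invariant_to_sample_reordering(self, reml_toy):
        G, W, y, ids = reml_toy
        fit1 = fit_aireml(MixedModelSpec(y, W, G, ids))
        perm = np.random.default_rng(0).permutation(len(y))
        fit2 = fit_aireml(MixedModelSpec(y[perm], W[perm], G[np.ix_(perm, perm)], ids[perm]))
        assert fit2.sigma_g2 == pytest.approx(fit1.sigma_g2, abs=1e-6)
        assert fit2.sigma_e2 == pytest.approx(fit1.sigma_e2, abs=1e-6)

    def test_parameter_recovery_simulated(self):
        """Mean heritability estimate near truth over simulated replicates."""
        h2s = []
        for seed in range(8):
            coh = simulate_cohort(SimConfig(seed=100 + seed, n_pop1=300, n_pop2=80,
                                            n_snps=1000, n_chromosomes=10))
            ph = coh.phenotypes.assign(
                angle_mean=lambda t: (t.angle_left + t.angle_right) / 2)
            grm = compute_grm(coh.genotypes, ridge=0.01)
            fit = GBLUP.from_phenotypes(ph, grm, response="angle_mean").fit()
            h2s.append(fit.heritability().h2)
        assert abs(np.mean(h2s) - 0.3) < 0.08

    def test_summary_mentions_components(self, reml_toy):
        G, W, y, ids = reml_toy
        fit = GBLUP(y, W, G, ids, fixed_names=["intercept", "covariate"]).fit()
        text = fit.summary()
        assert "sigma_g^2" in text and "h^2" in text and "converged: True" in text


class TestHeritability:
    def test_hand_example(self):
        """sg2 = se2 = 1, se_g = 0.2 only: h2 = 0.5, se = 0.25 * 0.2 = 0.05."""
        fit = GBLUPResults(
            spec=None, model=None, sigma_g2=1.0, sigma_e2=1.0,
            alpha_hat=np.array([0.0]), u_hat=np.array([]),
            ai_covariance=np.array([[0.04, 0.0], [0.0, 0.0]]),
            loglik_restricted=0.0, theta_trace=pd.DataFrame(), converged=True,
            boundary=False, n_iter=0,
        )
        h = heritability(fit)
        assert h.h2 == pytest.approx(0.5)
        assert h.se == pytest.approx(0.05)

    def test_zero_residual_gives_one(self):
        fit = GBLUPResults(None, None, 2.0, 0.0, np.array([0.0]), np.array([]),
                           np.zeros((2, 2)), 0.0, pd.DataFrame(), True, False, 0)
        assert heritability(fit).h2 == 1.0

    def test_se_matches_finite_difference_propagation(self, reml_toy):
        G, W, y, ids = reml_toy
        fit = fit_aireml(MixedModelSpec(y, W, G, ids))
        h = heritability(fit)
        # numerical gradient of h2(sg2, se2)
        eps = 1e-7
        f = lambda sg, se: sg / (sg + se)
        g0 = (f(fit.sigma_g2 + eps, fit.sigma_e2) - f(fit.sigma_g2 - eps, fit.sigma_e2)) / (2 * eps)
        g1 = (f(fit.sigma_g2, fit.sigma_e2 + eps) - f(fit.sigma_g2, fit.sigma_e2 - eps)) / (2 * eps)
        grad = np.array([g0, g1])
        var = grad @ fit.ai_covariance @ grad
        assert h.se == pytest.approx(np.sqrt(var), abs=1e-8)

    def test_zero_total_variance_errors(self):
        fit = GBLUPResults(None, None, 0.0, 0.0, np.array([0.0]), np.array([]),
                           np.zeros((2, 2)), 0.0, pd.DataFrame(), True, True, 0)
        with pytest.raises(ValueError):
            heritability(fit)


def _toy_training_system(seed=1, n=30, m=50):
    rng = np.random.default_rng(seed)
    X = rng.binomial(2, rng.uniform(0.2, 0.8, m), size=(n, m)).astype(float)
    p = X.mean(axis=0) / 2
    Z = X - 2 * p
    c = 2 * np.sum(p * (1 - p))
    G = Z @ Z.T / c
    W = np.ones((n, 1))
    y = rng.standard_normal(n) + Z[:, 0] * 0.5
    return X, Z, c, G, W, y


class TestBLUPPrediction:
    def test_duplicated_individual_interpolation_identity(self, reml_toy):
        G, W, y, ids = reml_toy
        n = len(y)
        # extend the GRM with a validation row duplicating training individual 3
        Gx = np.zeros((n + 1, n + 1))
        Gx[:n, :n] = G
        Gx[n, :n] = G[3, :]
        Gx[:n, n] = G[:, 3]
        Gx[n, n] = G[3, 3]
        all_ids = np.concatenate([ids, ["dup"]])
        grm = GRM(Gx, all_ids, np.array([]), np.array([]), 0.0)
        fit = fit_aireml(MixedModelSpec(y, W, G, ids))
        pred = blup_predict(fit, grm, ["dup"], W_val=W[[3]])
        expected = W[3] @ fit.alpha_hat + fit.u_hat[3]
        assert pred[0] == pytest.approx(expected, abs=1e-8)

    def test_snp_blup_duality(self):
        """GBLUP equals ridge regression on markers with lambda = c*se2/sg2."""
        X, Z, c, G, W, y = _toy_training_system()
        n = len(y)
        sg2, se2 = 0.8, 1.3
        Gr = G + 1e-8 * np.eye(n)
        spec = MixedModelSpec(y, W, Gr, np.arange(n))
        # GBLUP solution at fixed components
        V = sg2 * Gr + se2 * np.eye(n)
        Vi = np.linalg.inv(V)
        B = W.T @ Vi @ W
        beta = np.linalg.solve(B, W.T @ Vi @ y)
        u_gblup = sg2 * Gr @ Vi @ (y - W @ beta)
        # SNP-BLUP: marker effects from Henderson's equations at matched ridge
        lam = c * se2 / sg2
        m = Z.shape[1]
        lhs = np.block([
            [W.T @ W, W.T @ Z],
            [Z.T @ W, Z.T @ Z + lam * np.eye(m)],
        ])
        rhs = np.concatenate([W.T @ y, Z.T @ y])
        sol = np.linalg.solve(lhs, rhs)
        u_snp = Z @ sol[W.shape[1]:]
        np.testing.assert_allclose(u_gblup, u_snp, atol=1e-6)

    def test_missing_phenotype_mme_equivalence(self):
        """Conditional-expectation prediction equals Henderson's MME with the
        validation records absent, on a 30-individual toy."""
        X, Z, c, G, W, y = _toy_training_system(seed=5)
        n = len(y)
        ridge = 0.01
        Gr = G + ridge * np.eye(n)
        tr = np.arange(20)
        va = np.arange(20, n)
        sg2, se2 = 0.6, 1.1
        Gtt = Gr[np.ix_(tr, tr)]
        spec = MixedModelSpec(y[tr], W[tr], Gtt, tr)
        # build a fit object at fixed components via a single constrained run
        fit = fit_aireml(spec, start=(sg2, se2), max_iter=0)
        # conditional expectation route
        grm = GRM(Gr, np.arange(n), np.array([]), np.array([]), ridge)
        pred = blup_predict(fit, grm, va, W_val=W[va])
        # MME over all individuals with validation phenotypes missing
        Ginv = np.linalg.inv(Gr)
        lam = fit.sigma_e2 / fit.sigma_g2
        Wt, yt = W[tr], y[tr]
        Ztr = np.zeros((len(tr), n))
        Ztr[np.arange(len(tr)), tr] = 1.0
        lhs = np.block([
            [Wt.T @ Wt, Wt.T @ Ztr],
            [Ztr.T @ Wt, Ztr.T @ Ztr + lam * Ginv],
        ])
        rhs = np.concatenate([Wt.T @ yt, Ztr.T @ yt])
        sol = np.linalg.solve(lhs, rhs)
        u_all = sol[W.shape[1]:]
        expected = W[va] @ sol[: W.shape[1]] + u_all[va]
        np.testing.assert_allclose(pred, expected, atol=1e-6)

    def test_validation_overlap_rejected(self, reml_toy):
        G, W, y, ids = reml_toy
        grm = GRM(G, ids, np.array([]), np.array([]), 0.0)
        fit = fit_aireml(MixedModelSpec(y, W, G, ids))
        with pytest.raises(ValueError, match="overlap"):
            blup_predict(fit, grm, ids[:2])

    def test_unknown_validation_id_rejected(self, reml_toy):
        G, W, y, ids = reml_toy
        grm = GRM(G, ids, np.array([]), np.array([]), 0.0)
        fit = fit_aireml(MixedModelSpec(y, W, G, ids))
        with pytest.raises(KeyError, match="absent"):
            blup_predict(fit, grm, ["ghost"])

    def test_prediction_accuracy_increases_with_training_size(self):
        """Correlation with true breeding values rises on nested training sets."""
        per_size = {50: [], 150: [], 300: []}
        for seed in (55, 56, 57):
            coh = simulate_cohort(SimConfig(seed=seed, n_pop1=400, n_pop2=5,
                                            n_snps=800, n_chromosomes=10))
            geno = coh.genotypes
            pop1 = [s for s in geno.sample_ids if s.startswith("POP1")]
            grm = compute_grm(geno, ridge=0.01)
            ph = coh.phenotypes.set_index("sample_id")
            val = pop1[300:]
            tbv = ph.loc[val, "true_bv"].to_numpy()
            for ntr in per_size:
                fit = GBLUP.from_phenotypes(coh.phenotypes, grm, sample_ids=pop1[:ntr],
                                            covariates=("sex",)).fit()
                pred = blup_predict(fit, grm, val)
                per_size[ntr].append(np.corrcoef(tbv, pred)[0, 1])
        med = {k: np.median(v) for k, v in per_size.items()}
        assert med[300] > med[50]
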