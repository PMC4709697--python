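"""Genomic-prediction estimators: dualities, prior limits, oracles."""

import numpy as np
import pandas as pd
import pytest
from scipy import integrate
from sklearn.base import clone
from sklearn.linear_model import Lasso

from radgs import _samplers
from radgs.genome import ValidationError
from radgs.models import (
    BayesA,
    BayesB,
    BayesianLasso,
    GBLUP,
    MarkerLasso,
    PedigreeBLUP,
    RRBLUP,
    predict_gebv,
)


class TestGBLUPvsRRBLUP:
    """The module's central oracle: exact GEBV identity of the primal
    (ridge on markers) and dual (kinship BLUP) formulations."""

    @pytest.mark.parametrize("with_families", [False, True])
    def test_training_and_validation_identity(self, toy_gs_data,
                                              with_families):
        X, y = toy_gs_data["X"], toy_gs_data["y"]
        fam = np.arange(len(y)) % 4 if with_families else None
        gb = GBLUP().fit(X, y, families=fam)
        rr = RRBLUP().fit(X, y, families=fam)
        assert np.abs(gb.gebv_ - rr.gebv_).max() < 1e-8
        rng = np.random.default_rng(0)
        X_new = rng.integers(0, 3, (40, X.shape[1])).astype(float)
        assert np.abs(gb.predict(X_new) - rr.predict(X_new)).max() < 1e-8
        assert np.allclose(gb.backsolve_marker_effects(), rr.marker_effects_)

    def test_duplicated_individuals_get_identical_gebvs(self, toy_gs_data):
        X, y = toy_gs_data["X"].copy(), toy_gs_data["y"].copy()
        X[1], y[1] = X[0], y[0]
        gb = GBLUP().fit(X, y)
        assert np.isclose(gb.gebv_[0], gb.gebv_[1])

    def test_rrblup_matches_dense_ridge_solver(self):
        # naive closed form: g = (Xc'Xc + lam I)^-1 Xc' (y - mu)
        rng = np.random.default_rng(1)
        n, m = 30, 100
        X = rng.integers(0, 3, (n, m)).astype(float)
        y = rng.normal(0, 1, n) + X[:, 0]
        rr = RRBLUP().fit(X, y)
        Xc = X - X.mean(0)
        # same GLS intercept the mixed model uses
        V = rr.varcomp_["sigma_g2"] / rr.k_ * (Xc @ Xc.T) \
            + rr.varcomp_["sigma_e2"] * np.eye(n)
        ones = np.ones(n)
        mu = (ones @ np.linalg.solve(V, y)) / (ones @ np.linalg.solve(V, ones))
        g = np.linalg.solve(Xc.T @ Xc + rr.lambda_ * np.eye(m),
                            Xc.T @ (y - mu))
        assert np.abs(g - rr.marker_effects_).max() < 1e-6

    def test_predict_gebv_dispatch(self, toy_gs_data):
        X, y = toy_gs_data["X"], toy_gs_data["y"]
        rr = RRBLUP().fit(X, y)
        assert np.allclose(predict_gebv(rr, X), rr.predict(X))

    def test_panel_mismatch_rejected(self, toy_gs_data):
        X, y = toy_gs_data["X"], toy_gs_data["y"]
        gb = GBLUP().fit(X, y)
        with pytest.raises(ValidationError):
            gb.predict(X[:, :10])


class TestPedigreeBLUP:
    @pytest.fixture(scope="class")
    def family_data(self):
        # 4 founder pairs -> 4 full-sib families of 12, family-mean signal
        rng = np.random.default_rng(2)
        rows = [{"id": i, "sire": -1, "dam": -1} for i in range(8)]
        nid = 8
        y, ids, fams = [], [], []
        fam_bv = rng.normal(0, 1, 4)
        for f in range(4):
            for _ in range(12):
                rows.append({"id": nid, "sire": 2 * f, "dam": 2 * f + 1})
                y.append(fam_bv[f] + rng.normal(0, 1))
                ids.append(nid)
                fams.append(f)
                nid += 1
        ped = pd.DataFrame(rows)
        return ped, np.array(y), np.array(ids), np.array(fams)

    def test_dense_mixed_model_oracle(self, family_data):
        # independent route: u = lam A_xo (lam A_oo + I)^-1 (y - mu) by a
        # dense solve, vs the eigen-decomposition solver inside the fit
        from radgs.kinship import numerator_relationship_matrix

        ped, y, ids, fams = family_data
        fit = PedigreeBLUP(pedigree=ped).fit(None, y, ids=ids)
        A = numerator_relationship_matrix(ped)
        obs = np.array([list(ped["id"]).index(i) for i in ids])
        lam = fit.sol_.reml.lam
        Aoo = A[np.ix_(obs, obs)]
        V = lam * Aoo + np.eye(len(y))
        ones = np.ones(len(y))
        mu = (ones @ np.linalg.solve(V, y)) / (ones @ np.linalg.solve(V, ones))
        resid = np.linalg.solve(V, y - mu)
        assert np.abs(fit.gebv_ - lam * Aoo @ resid).max() < 1e-8
        founders = np.arange(8)
        expect = lam * A[np.ix_(founders, obs)] @ resid
        assert np.abs(fit.predict(ids=founders) - expect).max() < 1e-8
        # parental GEBVs order families consistently with family means
        par = 0.5 * (fit.predict(ids=founders)[::2]
                     + fit.predict(ids=founders)[1::2])
        fam_means = np.array([y[fams == f].mean() for f in range(4)])
        assert np.corrcoef(par, fam_means)[0, 1] > 0.95

    def test_matches_gblup_solver_when_A_is_used_as_K(self, family_data):
        # shared mixed-model machinery: feeding A through the generic
        # solver must reproduce the pedigree-BLUP GEBVs
        from radgs.kinship import numerator_relationship_matrix
        from radgs.reml import solve_blup

        ped, y, ids, fams = family_data
        fit = PedigreeBLUP(pedigree=ped).fit(None, y, ids=ids)
        A = numerator_relationship_matrix(ped)
        rows = np.array([list(ped["id"]).index(i) for i in ids])
        sol = solve_blup(y, A[np.ix_(rows, rows)])
        assert np.allclose(fit.gebv_, sol.u)

    def test_requires_pedigree_and_ids(self, family_data):
        ped, y, ids, fams = family_data
        with pytest.raises(ValidationError):
            PedigreeBLUP().fit(None, y, ids=ids)
        with pytest.raises(ValidationError):
            PedigreeBLUP(pedigree=ped).fit(None, y)


class TestBayesA:
    def test_null_data_shrinks_effects(self):
        # pure-noise phenotype: typical posterior-mean effects near zero,
        # no marker escaping shrinkage
        rng = np.random.default_rng(3)
        n, m = 500, 800
        X = rng.integers(0, 3, (n, m)).astype(float)
        y = rng.normal(0, 1, n)
        fit = BayesA(niter=800, burnin=200, random_state=5).fit(X, y)
        assert np.abs(fit.marker_effects_).mean() < 0.05 * y.std()
        assert np.abs(fit.marker_effects_).max() < 0.1 * y.std()

    def test_single_marker_conjugate_posterior(self):
        # fixed variances (huge prior df): posterior mean of g is the
        # ridge value x'y~ / (x'x + se2/sg2); independent closed form
        rng = np.random.default_rng(6)
        n = 80
        x = rng.integers(0, 3, (n, 1)).astype(float)
        g_true = 0.8
        se2, sg2 = 1.0, 0.25
        y = x[:, 0] * g_true + rng.normal(0, np.sqrt(se2), n)
        fit = BayesA(niter=6000, burnin=1000, nu=1e8, scale=sg2,
                     random_state=7).fit(x, y)
        # analytic conditional posterior given converged mu ~= GLS mean
        mu = fit.mu_
        resid = y - mu
        expect = (x[:, 0] @ resid) / (x[:, 0] @ x[:, 0] + se2 / sg2)
        assert abs(fit.marker_effects_[0] - expect) < 0.05

    def test_large_nu_limit_matches_rrblup(self, toy_gs_data):
        X, y = toy_gs_data["X"], toy_gs_data["y"]
        rr = RRBLUP().fit(X, y)
        # prior pinned at the RR-BLUP per-marker variance sg2/k
        s = rr.varcomp_["sigma_g2"] / rr.k_
        ba = BayesA(niter=1500, burnin=300, nu=1e8, scale=s,
                    random_state=8).fit(X, y)
        r = np.corrcoef(ba.gebv_, rr.gebv_)[0, 1]
        assert r > 0.99

    def test_chains_bit_identical_for_fixed_seed(self, toy_gs_data):
        X, y = toy_gs_data["X"], toy_gs_data["y"]
        a = BayesA(niter=300, burnin=100, random_state=9).fit(X, y)
        b = BayesA(niter=300, burnin=100, random_state=9).fit(X, y)
        assert np.array_equal(a.marker_effects_, b.marker_effects_)
        assert a.diagnostics_["split_rhat_se2"] == b.diagnostics_["split_rhat_se2"]

    def test_niter_must_exceed_burnin(self, toy_gs_data):
        with pytest.raises(ValidationError):
            BayesA(niter=100, burnin=100).fit(toy_gs_data["X"],
                                              toy_gs_data["y"])


class TestBayesB:
    def test_pi_zero_reproduces_bayesa(self, toy_gs_data):
        X, y = toy_gs_data["X"], toy_gs_data["y"]
        ba = BayesA(niter=1000, burnin=250, random_state=10).fit(X, y)
        bb = BayesB(niter=1000, burnin=250, pi=0.0, random_state=10).fit(X, y)
        r = np.corrcoef(ba.gebv_, bb.gebv_)[0, 1]
        assert r > 0.99

    def test_near_one_pi_on_null_data_excludes_almost_all(self):
        rng = np.random.default_rng(11)
        n, m = 150, 300
        X = rng.integers(0, 3, (n, m)).astype(float)
        y = rng.normal(0, 1, n)
        fit = BayesB(niter=600, burnin=150, pi=0.99,
                     random_state=12).fit(X, y)
        assert fit.posterior_inclusion_.mean() < 0.05

    def test_two_marker_posterior_inclusion_matches_enumeration(self):
        # tiny spike-slab model with FIXED variances: integrate the
        # marginal likelihood over the 4 indicator configurations
        rng = np.random.default_rng(13)
        n = 60
        X = rng.integers(0, 3, (n, 2)).astype(float)
        Xc = X - X.mean(0)
        se2, sg2, pi = 1.0, 0.5, 0.5
        y = Xc[:, 0] * 0.9 + rng.normal(0, 1.0, n)

        def log_ml(active):
            C = se2 * np.eye(n)
            for j in active:
                C = C + sg2 * np.outer(Xc[:, j], Xc[:, j])
            sign, logdet = np.linalg.slogdet(C)
            return -0.5 * (logdet + y @ np.linalg.solve(C, y))

        configs = [(), (0,), (1,), (0, 1)]
        logp = np.array([
            log_ml(a) + len(a) * np.log(1 - pi)
            + (2 - len(a)) * np.log(pi) for a in configs])
        w = np.exp(logp - logp.max())
        w /= w.sum()
        pip_expect = np.array([w[1] + w[3], w[2] + w[3]])

        fit = BayesB(niter=20_000, burnin=2_000, pi=pi, nu=1e8, scale=sg2,
                     random_state=14)
        fit.fit(Xc + 1.0, y + 0.0)  # shift back to dosage-like values
        assert np.abs(fit.posterior_inclusion_ - pip_expect).max() < 0.06


class TestBayesianLasso:
    def test_null_data_shrinks_effects(self):
        rng = np.random.default_rng(15)
        n, m = 120, 200
        X = rng.integers(0, 3, (n, m)).astype(float)
        y = rng.normal(0, 1, n)
        fit = BayesianLasso(niter=800, burnin=200, random_state=16).fit(X, y)
        assert np.abs(fit.marker_effects_).max() < 0.05 * y.std()

    def test_shrinkage_monotone_in_lambda(self, toy_gs_data):
        X, y = toy_gs_data["X"], toy_gs_data["y"]
        norms = []
        for lam2 in (1e-2, 1e2, 1e4, 1e6):
            fit = BayesianLasso(niter=800, burnin=200, lambda2=lam2,
                                random_state=17).fit(X, y)
            norms.append(np.linalg.norm(fit.marker_effects_))
        assert all(a > b for a, b in zip(norms, norms[1:]))

    def test_single_marker_matches_quadrature(self):
        # 1-marker BL with fixed lam2 and se2-conditional prior: compare
        # E[g | y] against direct numerical integration of the DE-prior
        # posterior with se2 fixed at its posterior mean
        rng = np.random.default_rng(18)
        n = 50
        x = rng.integers(0, 3, (n, 1)).astype(float)
        y = x[:, 0] * 0.6 + rng.normal(0, 1.0, n)
        lam2 = 4.0
        fit = BayesianLasso(niter=30_000, burnin=3_000, lambda2=lam2,
                            random_state=19).fit(x, y)
        se2 = fit.sigma_e2_
        mu = fit.mu_
        resid = y - mu
        lam = np.sqrt(lam2)
        xs = x[:, 0]

        def unnorm(g):
            ll = -0.5 * np.sum((resid - xs * g) ** 2) / se2
            prior = -lam * abs(g) / np.sqrt(se2)
            return np.exp(ll + prior)

        grid = np.linspace(-2, 2, 4001)
        vals = np.array([unnorm(g) for g in grid])
        expect = integrate.trapezoid(grid * vals, grid) / \
            integrate.trapezoid(vals, grid)
        assert abs(fit.marker_effects_[0] - expect) < 0.05


class TestMarkerLasso:
    def test_lambda_above_max_gives_null_model(self):
        rng = np.random.default_rng(20)
        n, m = 50, 30
        X = rng.integers(0, 3, (n, m)).astype(float)
        y = rng.normal(0, 1, n)
        Xc = np.ascontiguousarray((X - X.mean(0)).T)
        yc = y - y.mean()
        lam_max = np.abs(Xc @ yc).max() / n
        coefs = _samplers.cd_lasso_path(Xc, yc,
                                        np.array([lam_max * 1.001]), 100,
                                        1e-8)
        assert not coefs.any()

    def test_orthonormal_design_soft_threshold(self):
        # columns orthonormal after scaling: g_j = S(x_j'y/n, lam)
        rng = np.random.default_rng(21)
        n, m = 64, 8
        Q, _ = np.linalg.qr(rng.normal(size=(n, n)))
        X = Q[:, :m] * np.sqrt(n)  # X'X = n I
        y = rng.normal(0, 1, n)
        lam = 0.05
        coefs = _samplers.cd_lasso_path(np.ascontiguousarray(X.T),
                                        y - 0.0, np.array([lam]), 200,
                                        1e-10)[0]
        rho = X.T @ y / n
        expect = np.sign(rho) * np.maximum(np.abs(rho) - lam, 0)
        assert np.abs(coefs - expect).max() < 1e-8

    def test_objective_never_increases_over_sweeps(self, toy_gs_data):
        X, y = toy_gs_data["X"], toy_gs_data["y"]
        Xc = X - X.mean(0)
        yc = y - y.mean()
        lam = 0.1 * np.abs(Xc.T @ yc).max() / len(y)
        objs = []
        for sweeps in (1, 2, 4, 8, 16):
            g = _samplers.cd_lasso_path(np.ascontiguousarray(Xc.T), yc,
                                        np.array([lam]), sweeps, 0.0)[0]
            objs.append(_samplers.lasso_objective(Xc, yc, g, lam))
        assert all(a >= b - 1e-12 for a, b in zip(objs, objs[1:]))

    def test_matches_sklearn_at_fixed_penalty(self, toy_gs_data):
        X, y = toy_gs_data["X"], toy_gs_data["y"]
        fit = MarkerLasso(random_state=22).fit(X, y)
        Xc = X - X.mean(0)
        yc = y - y.mean()
        sk = Lasso(alpha=fit.lambda_, fit_intercept=False,
                   max_iter=50_000, tol=1e-10).fit(Xc, yc)
        denom = max(1.0, np.abs(sk.coef_).max())
        assert np.abs(sk.coef_ - fit.marker_effects_).max() / denom < 1e-3

    def test_constant_y_rejected(self, toy_gs_data):
        with pytest.raises(ValidationError):
            MarkerLasso().fit(toy_gs_data["X"], np.ones(len(toy_gs_data["y"])))


class TestSklearnProtocol:
    @pytest.mark.parametrize("est", [
        GBLUP(), RRBLUP(), BayesA(niter=60, burnin=20),
        BayesB(niter=60, burnin=20), BayesianLasso(niter=60, burnin=20),
        MarkerLasso(n_lambdas=10),
    ])
    def test_clone_get_set_params(self, est, toy_gs_data):
        params = est.get_params()
        c = clone(est)
        assert c.get_params() == params
        c.fit(toy_gs_data["X"][:80], toy_gs_data["y"][:80])
        assert hasattr(c, "gebv_")
        assert c.predict(toy_gs_data["X"][:5]).shape == (5,)
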