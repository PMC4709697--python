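"""Genomic-prediction estimators under the shared linear model

    y = mu + Z w + X g + e

with X the 0/1/2 alt-allele dosage matrix (AA/AB/BB) and w optional family
fixed effects.  All estimators follow the scikit-learn protocol: ``fit(X,
y, families=..., ids=...)``, ``predict(X)`` returning GEBVs, get_params /
set_params, and trailing-underscore fitted attributes.  ``predict``
returns the genomic value X_new g_hat (or its kinship-projected analogue);
family effects are added only on request via ``predict_phenotype``.

Marker-effect methods expose ``marker_effects_``; kinship methods
(G-BLUP, pedigree BLUP) expose ``gebv_`` and project to new individuals
through the train/new relationship block.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin

from . import _samplers
from .genome import ValidationError
from .kinship import (
    allele_frequencies,
    cross_relationship,
    genomic_relationship_matrix,
    numerator_relationship_matrix,
)
from .reml import solve_blup


def _check_Xy(X, y):
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if X.ndim != 2:
        raise ValidationError("X must be 2-D (individuals x markers)")
    if X.shape[0] != y.size:
        raise ValidationError("X and y have incompatible shapes")
    if np.isnan(X).any():
        raise ValidationError("X contains missing values; impute before fitting")
    if not np.isfinite(y).all():
        raise ValidationError("y contains non-finite values")
    return X, y


def _family_codes(families, n):
    """Return (codes, levels). Single-family data drops the family effect."""
    if families is None:
        return np.zeros(n, dtype=np.int64), None
    families = np.asarray(families)
    if families.size != n:
        raise ValidationError("families length must match sample size")
    codes, levels = pd.factorize(families)
    if len(levels) < 2:
        return np.zeros(n, dtype=np.int64), None
    return codes.astype(np.int64), levels


def _family_dummies(codes, levels):
    if levels is None:
        return None
    n_fam = len(levels)
    Z = np.zeros((codes.size, n_fam - 1))
    for f in range(1, n_fam):  # first level absorbed in the intercept
        Z[codes == f, f - 1] = 1.0
    return Z


class _MarkerModel(BaseEstimator, RegressorMixin):
    """Shared predict logic for methods that estimate per-marker effects."""

    def predict(self, X, ids=None):
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self.n_features_in_:
            raise ValidationError("marker panel mismatch between fit and predict")
        return (X - 2.0 * self.p_) @ self.marker_effects_

    def predict_phenotype(self, X, families=None):
        out = self.mu_ + self.predict(X) + 2.0 * (self.p_ @ self.marker_effects_)
        if families is not None and self.family_levels_ is not None:
            eff = dict(zip(self.family_levels_, self.family_effects_))
            out = out + np.array([eff.get(f, 0.0) for f in np.asarray(families)])
        return out


def _center_fixed(y, X, codes, levels):
    """Return y and X with intercept+family means absorbed, plus the means."""
    if levels is None:
        ybar = y.mean()
        Xbar = X.mean(axis=0)
        return y - ybar, X - Xbar, np.array([ybar]), Xbar
    yc = y.astype(float).copy()
    Xc = X.astype(float).copy()
    fam_means_y = np.zeros(len(levels))
    Xbar = X.mean(axis=0)
    Xc -= Xbar
    for f in range(len(levels)):
        rows = codes == f
        fam_means_y[f] = y[rows].mean()
        yc[rows] -= fam_means_y[f]
        Xc[rows] -= Xc[rows].mean(axis=0)
    return yc, Xc, fam_means_y, Xbar


class GBLUP(BaseEstimator, RegressorMixin):
    """G-BLUP: mixed-model BLUP with the marker-derived relationship matrix.

    Variance components are estimated by REML on the training data; GEBVs
    for new individuals are projected through the train/new relationship
    block computed from stored training allele frequencies.
    """

    def __init__(self, blend: float = 0.0):
        self.blend = blend  # optional ridge added to G (breaks exact RR-BLUP duality)

    def fit(self, X, y, families=None, ids=None):
        X, y = _check_Xy(X, y)
        codes, levels = _family_codes(families, y.size)
        self.family_levels_ = levels
        self.p_ = allele_frequencies(X)
        G, k = genomic_relationship_matrix(X, self.p_, return_scale=True)
        if self.blend:
            G = G + self.blend * np.eye(G.shape[0])
        W = _family_dummies(codes, levels)
        sol = solve_blup(y, G, W)
        self.k_ = k
        self.X_train_ = X
        self.sol_ = sol
        self.mu_ = float(sol.beta[0])
        self.family_effects_ = (
            np.concatenate([[0.0], sol.beta[1:]]) if levels is not None else None
        )
        self.gebv_ = sol.u
        self.varcomp_ = {
            "sigma_g2": sol.reml.sigma_a2,
            "sigma_e2": sol.reml.sigma_e2,
            "h2": sol.reml.h2,
        }
        self.marker_effects_ = None  # not estimated per marker; see backsolve
        self.n_features_in_ = X.shape[1]
        return self

    def backsolve_marker_effects(self) -> np.ndarray:
        """Equivalent ridge-regression marker effects (RR-BLUP duality)."""
        Xc = self.X_train_ - 2.0 * self.p_
        return (self.sol_.reml.lam / self.k_) * (
            Xc.T @ (self.sol_._U @ self.sol_._w)
        )

    def predict(self, X, ids=None):
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self.n_features_in_:
            raise ValidationError("marker panel mismatch between fit and predict")
        Gc = cross_relationship(X, self.X_train_, self.p_, self.k_)
        return self.sol_.predict_new(Gc)


class RRBLUP(BaseEstimator, RegressorMixin):
    """Ridge-regression BLUP: one common shrinkage for all marker effects.

    lambda = sigma_e^2 / (sigma_g^2 / k), k = sum_j 2 p_j (1 - p_j), with
    variance components from REML on the genomic relationship matrix, which
    makes the training GEBVs exactly equal to G-BLUP's.
    """

    def fit(self, X, y, families=None, ids=None):
        X, y = _check_Xy(X, y)
        codes, levels = _family_codes(families, y.size)
        self.family_levels_ = levels
        self.p_ = allele_frequencies(X)
        G, k = genomic_relationship_matrix(X, self.p_, return_scale=True)
        W = _family_dummies(codes, levels)
        sol = solve_blup(y, G, W)
        Xc = X - 2.0 * self.p_
        self.marker_effects_ = (sol.reml.lam / k) * (Xc.T @ (sol._U @ sol._w))
        self.mu_ = float(sol.beta[0])
        self.family_effects_ = (
            np.concatenate([[0.0], sol.beta[1:]]) if levels is not None else None
        )
        self.gebv_ = Xc @ self.marker_effects_
        self.k_ = k
        self.lambda_ = sol.reml.sigma_e2 / (sol.reml.sigma_a2 / k)
        self.varcomp_ = {
            "sigma_g2": sol.reml.sigma_a2,
            "sigma_e2": sol.reml.sigma_e2,
            "h2": sol.reml.h2,
        }
        self.n_features_in_ = X.shape[1]
        return self

    predict = _MarkerModel.predict
    predict_phenotype = _MarkerModel.predict_phenotype


class PedigreeBLUP(BaseEstimator, RegressorMixin):
    """Traditional BLUP with the pedigree numerator relationship matrix.

    The pedigree (id, sire, dam; parents before offspring; unknown parent
    -1) must cover every training and prediction individual.  ``ids`` maps
    data rows to pedigree entries.  Marker data are ignored.
    """

    def __init__(self, pedigree: pd.DataFrame | None = None):
        self.pedigree = pedigree

    def fit(self, X, y, families=None, ids=None):
        if self.pedigree is None:
            raise ValidationError("PedigreeBLUP requires a pedigree")
        if ids is None:
            raise ValidationError("PedigreeBLUP requires row ids into the pedigree")
        y = np.asarray(y, dtype=float).ravel()
        codes, levels = _family_codes(families, y.size)
        self.family_levels_ = levels
        self.A_ = numerator_relationship_matrix(self.pedigree)
        self.index_ = {int(v): i for i, v in enumerate(self.pedigree["id"])}
        rows = np.array([self.index_[int(i)] for i in np.asarray(ids)])
        K = self.A_[np.ix_(rows, rows)]
        W = _family_dummies(codes, levels)
        sol = solve_blup(y, K, W)
        self.rows_ = rows
        self.sol_ = sol
        self.mu_ = float(sol.beta[0])
        self.family_effects_ = (
            np.concatenate([[0.0], sol.beta[1:]]) if levels is not None else None
        )
        self.gebv_ = sol.u
        self.varcomp_ = {
            "sigma_g2": sol.reml.sigma_a2,
            "sigma_e2": sol.reml.sigma_e2,
            "h2": sol.reml.h2,
        }
        self.marker_effects_ = None
        self.n_features_in_ = 0 if X is None else np.asarray(X).shape[1]
        return self

    def predict(self, X=None, ids=None):
        if ids is None:
            raise ValidationError("PedigreeBLUP prediction requires ids")
        rows = np.array([self.index_[int(i)] for i in np.asarray(ids)])
        A_cross = self.A_[np.ix_(rows, self.rows_)]
        return self.sol_.predict_new(A_cross)


class _GibbsBase(_MarkerModel):
    """Common fit wrapper around the numba Gibbs kernels."""

    def _prepare(self, X, y, families):
        X, y = _check_Xy(X, y)
        codes, levels = _family_codes(families, y.size)
        n_fam = 0 if levels is None else len(levels)
        self.family_levels_ = levels
        self.p_ = allele_frequencies(X)
        k = float(np.sum(2.0 * self.p_ * (1.0 - self.p_)))
        if k <= 0:
            raise ValidationError("all markers monomorphic")
        return X, y, codes, n_fam, k

    def _finalize(self, X, mu, w, g, se2_chain, burnin):
        tail = se2_chain[burnin:]
        if not np.isfinite(tail).all():
            raise RuntimeError(
                "residual variance diverged; chain tail: "
                f"{se2_chain[-5:]}"
            )
        self.mu_ = float(mu)
        self.family_effects_ = w[: len(self.family_levels_)] if self.family_levels_ is not None else None
        self.marker_effects_ = g
        Xc = X - 2.0 * self.p_
        self.gebv_ = Xc @ g
        self.sigma_e2_ = float(tail.mean())
        self.diagnostics_ = {
            "niter": int(self.niter),
            "burnin": int(self.burnin),
            "thin": int(self.thin),
            "n_kept": int(self.niter - self.burnin),
            "split_rhat_se2": _samplers.split_rhat(tail),
        }
        self.n_features_in_ = X.shape[1]
        return self


class BayesA(_GibbsBase):
    """BayesA: marker effects with locus-specific variances.

    g_j | sg2_j ~ N(0, sg2_j), sg2_j ~ scaled-inv-chi2(nu, S).  With the
    default ``scale=None`` the prior scale S is set so that the prior
    expectation of the total marker variance matches ``h2_prior`` of
    var(y): S = (nu - 2)/nu * h2_prior * var(y) / sum_j 2 p_j q_j.
    """

    def __init__(self, niter=1500, burnin=300, thin=5, nu=4.2, scale=None,
                 h2_prior=0.5, random_state=0):
        self.niter = niter
        self.burnin = burnin
        self.thin = thin
        self.nu = nu
        self.scale = scale
        self.h2_prior = h2_prior
        self.random_state = random_state

    _pi = 0.0

    def _scale_from_data(self, y, k):
        vy = float(np.var(y))
        return (self.nu - 2.0) / self.nu * self.h2_prior * vy / k

    def fit(self, X, y, families=None, ids=None):
        if self.niter <= self.burnin:
            raise ValidationError("niter must exceed burnin")
        X, y, codes, n_fam, k = self._prepare(X, y, families)
        S = self.scale if self.scale is not None else self._scale_from_data(y, k)
        if self._pi > 0:
            S = S / (1.0 - self._pi)
        nu_e, Se = 4.0, 0.5 * float(np.var(y))
        mu, w, g, sg2, pip, se2_chain = _samplers.gibbs_bayes_ab(
            np.ascontiguousarray(X.T), y, codes, n_fam,
            int(self.niter), int(self.burnin),
            float(self.nu), float(S), float(self._pi), nu_e, Se,
            int(self.random_state) & 0x7FFFFFFF,
        )
        self.locus_variances_ = sg2
        self.posterior_inclusion_ = pip
        self.scale_used_ = float(S)
        return self._finalize(X, mu, w, g, se2_chain, int(self.burnin))


class BayesB(BayesA):
    """BayesB: g_j = 0 with probability pi, else as BayesA.

    pi = 0 reproduces BayesA (same kernel, same seed path)."""

    def __init__(self, niter=1500, burnin=300, thin=5, nu=4.2, scale=None,
                 h2_prior=0.5, pi=0.95, random_state=0):
        super().__init__(niter, burnin, thin, nu, scale, h2_prior, random_state)
        self.pi = pi

    @property
    def _pi(self):
        if not 0 <= self.pi < 1:
            raise ValidationError("pi must lie in [0, 1)")
        return self.pi


class BayesianLasso(_GibbsBase):
    """Bayesian LASSO: double-exponential marker-effect prior via the
    normal scale mixture, fitted by Gibbs sampling.

    ``lambda2`` fixes the squared regularization parameter; with the
    default None it receives a diffuse Gamma(r, delta) hyperprior and is
    sampled.
    """

    def __init__(self, niter=1500, burnin=300, thin=5, lambda2=None,
                 r_gamma=1.1, delta_gamma=1e-3, random_state=0):
        self.niter = niter
        self.burnin = burnin
        self.thin = thin
        self.lambda2 = lambda2
        self.r_gamma = r_gamma
        self.delta_gamma = delta_gamma
        self.random_state = random_state

    def fit(self, X, y, families=None, ids=None):
        if self.niter <= self.burnin:
            raise ValidationError("niter must exceed burnin")
        X, y, codes, n_fam, k = self._prepare(X, y, families)
        m = X.shape[1]
        if self.lambda2 is None:
            lam2_init, update = float(2 * m), True
        else:
            lam2_init, update = float(self.lambda2), False
        nu_e, Se = 4.0, 0.5 * float(np.var(y))
        mu, w, g, lam2, se2_chain = _samplers.gibbs_bl(
            np.ascontiguousarray(X.T), y, codes, n_fam,
            int(self.niter), int(self.burnin),
            lam2_init, update, float(self.r_gamma), float(self.delta_gamma),
            nu_e, Se, int(self.random_state) & 0x7FFFFFFF,
        )
        self.lambda2_ = float(lam2)
        return self._finalize(X, mu, w, g, se2_chain, int(self.burnin))


class MarkerLasso(_MarkerModel):
    """l1-penalized regression of phenotypes on markers (coordinate
    descent); the penalty is chosen by cross-validation inside the
    training data only.  Family effects are absorbed by within-family
    centering before the penalized fit."""

    def __init__(self, n_lambdas=50, lambda_min_ratio=1e-3, cv=5,
                 max_sweeps=200, tol=1e-6, random_state=0):
        self.n_lambdas = n_lambdas
        self.lambda_min_ratio = lambda_min_ratio
        self.cv = cv
        self.max_sweeps = max_sweeps
        self.tol = tol
        self.random_state = random_state

    def _path(self, X, y):
        n = X.shape[0]
        lam_max = np.abs(X.T @ y).max() / n
        if lam_max <= 0:
            return None
        return np.geomspace(lam_max, lam_max * self.lambda_min_ratio,
                            self.n_lambdas)

    def fit(self, X, y, families=None, ids=None):
        X, y = _check_Xy(X, y)
        if np.var(y) == 0:
            raise ValidationError("y is constant")
        codes, levels = _family_codes(families, y.size)
        self.family_levels_ = levels
        self.p_ = allele_frequencies(X)
        yc, Xc, fam_means, _ = _center_fixed(y, X, codes, levels)
        Xct = np.ascontiguousarray(Xc.T)
        lambdas = self._path(Xc, yc)
        if lambdas is None:
            warnings.warn("degenerate design; returning the null model")
            self.marker_effects_ = np.zeros(X.shape[1])
            self.lambda_ = np.inf
        else:
            rng = np.random.default_rng(self.random_state)
            folds = rng.integers(0, self.cv, size=y.size)
            cv_err = np.zeros(lambdas.size)
            for f in range(self.cv):
                tr = folds != f
                if tr.all() or (~tr).all():
                    continue
                coefs = _samplers.cd_lasso_path(
                    np.ascontiguousarray(Xct[:, tr]),
                    yc[tr] - yc[tr].mean(), lambdas,
                    int(self.max_sweeps), float(self.tol))
                resid = yc[~tr][None, :] - coefs @ Xc[~tr].T
                cv_err += (resid**2).mean(axis=1)
            best = int(np.argmin(cv_err))
            coefs = _samplers.cd_lasso_path(
                Xct, yc, lambdas, int(self.max_sweeps), float(self.tol))
            self.marker_effects_ = coefs[best]
            self.lambda_ = float(lambdas[best])
            if not np.any(self.marker_effects_):
                warnings.warn("all marker effects shrunk to zero (null model)")
        if levels is None:
            self.mu_ = float(fam_means[0])
            self.family_effects_ = None
        else:
            self.mu_ = float(fam_means[0])
            self.family_effects_ = fam_means - fam_means[0]
        self.gebv_ = (X - 2.0 * self.p_) @ self.marker_effects_
        self.varcomp_ = {}
        self.n_features_in_ = X.shape[1]
        return self


def predict_gebv(fit, X_new=None, ids=None):
    """GEBVs for new individuals: X_new g_hat for marker-effect methods,
    relationship-block projection for kinship methods."""
    if getattr(fit, "marker_effects_", None) is not None:
        return fit.predict(X_new)
    return fit.predict(X_new, ids=ids)


MODEL_REGISTRY = {
    "BLUP": PedigreeBLUP,
    "G-BLUP": GBLUP,
    "RR-BLUP": RRBLUP,
    "BayesA": BayesA,
    "BayesB": BayesB,
    "BL": BayesianLasso,
    "LASSO": MarkerLasso,
}
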