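"""REML variance components for a single random effect.

Model: y = W b + u + e with u ~ N(0, sa2 K), e ~ N(0, se2 I).  K is a
relationship matrix (pedigree A or genomic G).  The restricted likelihood
is profiled over the variance ratio lam = sa2/se2 after one eigen-
decomposition of K, which makes each likelihood evaluation O(n f^2).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize_scalar

from .genome import ValidationError


@dataclass
class REMLResult:
    sigma_a2: float
    sigma_e2: float
    h2: float
    se_h2: float
    loglik: float
    boundary: bool  # variance ratio pinned at the search boundary
    lam: float


def _prepare_fixed(y, W):
    n = y.size
    if W is None:
        W = np.ones((n, 1))
    else:
        W = np.atleast_2d(np.asarray(W, dtype=float))
        if W.shape[0] != n:
            W = W.T
        if not np.any(np.ptp(W, axis=0) == 0):
            W = np.column_stack([np.ones(n), W])
    # drop linearly dependent columns
    _, r = np.linalg.qr(W)
    diag = np.abs(np.diag(r))
    keep = diag > 1e-8 * diag.max()
    return W[:, keep]


def _profile(eigvals, Wt, yt, log_lam):
    lam = np.exp(log_lam)
    d = lam * eigvals + 1.0
    WtD = Wt / d[:, None]
    M = Wt.T @ WtD  # W' V^-1 W (on the error-variance scale)
    cho = np.linalg.cholesky(M)
    beta = np.linalg.solve(M, WtD.T @ yt)
    resid = yt - Wt @ beta
    rss = float(resid @ (resid / d))
    n, f = Wt.shape
    se2 = rss / (n - f)
    logdet_M = 2.0 * float(np.sum(np.log(np.diag(cho))))
    # restricted log-likelihood up to an additive constant
    ll = -0.5 * ((n - f) * np.log(se2) + np.sum(np.log(d)) + logdet_M + (n - f))
    return ll, se2, beta, d, resid


@dataclass
class _REMLFit:
    reml: REMLResult
    beta: np.ndarray
    U: np.ndarray
    eigvals: np.ndarray
    w: np.ndarray  # resid / d in the eigenbasis
    eigmin_raw: float


def _reml_core(y, K, W=None, bounds=(-12.0, 12.0)) -> _REMLFit:
    y = np.asarray(y, dtype=float).ravel()
    n = y.size
    K = np.asarray(K, dtype=float)
    if K.shape != (n, n):
        raise ValidationError("K must be n x n")
    W = _prepare_fixed(y, W)
    eigvals, U = np.linalg.eigh(K)
    eigmin_raw = float(eigvals[0])
    eigvals = np.clip(eigvals, 0.0, None)
    yt = U.T @ y
    Wt = U.T @ W

    def neg(log_lam):
        return -_profile(eigvals, Wt, yt, log_lam)[0]

    res = minimize_scalar(neg, bounds=bounds, method="bounded",
                          options={"xatol": 1e-6})
    log_lam = float(res.x)
    ll, se2, beta, d, resid = _profile(eigvals, Wt, yt, log_lam)
    lam = float(np.exp(log_lam))
    sa2 = lam * se2
    h2 = sa2 / (sa2 + se2)
    boundary = abs(log_lam - bounds[0]) < 1e-3 or abs(log_lam - bounds[1]) < 1e-3

    # observed information on log lam -> SE of h2 by the delta method
    eps = 1e-3
    ll_p = _profile(eigvals, Wt, yt, log_lam + eps)[0]
    ll_m = _profile(eigvals, Wt, yt, log_lam - eps)[0]
    curv = -(ll_p - 2 * ll + ll_m) / eps**2
    if curv > 0:
        se_h2 = float(np.sqrt(1.0 / curv) * h2 * (1.0 - h2))
    else:
        se_h2 = np.nan
    reml = REMLResult(float(sa2), float(se2), float(h2), se_h2, float(ll),
                      boundary, lam)
    return _REMLFit(reml, beta, U, eigvals, resid / d, eigmin_raw)


def estimate_h2_reml(
    y: np.ndarray,
    K: np.ndarray,
    W: np.ndarray | None = None,
    bounds: tuple[float, float] = (-12.0, 12.0),
) -> REMLResult:
    """REML estimate of (sigma_a^2, sigma_e^2) and h2 = sa2/(sa2+se2).

    ``W`` holds fixed-effect covariates (an intercept is added when no
    constant column is present).  Boundary estimates (h2 near 0 or 1) are
    flagged via ``boundary``, not raised.
    """
    return _reml_core(y, K, W, bounds).reml


@dataclass
class BLUPSolution:
    """Mixed-model solution shared by pedigree BLUP and G-BLUP."""

    beta: np.ndarray
    u: np.ndarray  # BLUP of the random genetic values, training rows
    reml: REMLResult
    _U: np.ndarray = field(repr=False, default=None)
    _w: np.ndarray = field(repr=False, default=None)

    def predict_new(self, K_cross: np.ndarray) -> np.ndarray:
        """BLUP of genetic values for individuals with relationship rows
        ``K_cross`` (n_new x n_train) to the training set:
        u_new = lam K_cross U (resid/d)."""
        return self.reml.lam * (K_cross @ (self._U @ self._w))


def solve_blup(
    y: np.ndarray,
    K: np.ndarray,
    W: np.ndarray | None = None,
    psd_tol: float = 1e-6,
) -> BLUPSolution:
    """REML variance components followed by BLUP of u (one eigh of K).

    u_hat = lam K (lam K + I)^-1 (y - W beta) computed in the eigenbasis.
    Raises if K has eigenvalues below -psd_tol * max|K|.
    """
    fit = _reml_core(y, K, W)
    scale = max(1.0, float(np.abs(K).max()))
    if fit.eigmin_raw < -psd_tol * scale:
        raise ValidationError(
            f"relationship matrix is not PSD (min eigenvalue {fit.eigmin_raw:.3g}); "
            "consider blending with the identity"
        )
    u = fit.reml.lam * (np.asarray(K, dtype=float) @ (fit.U @ fit.w))
    return BLUPSolution(beta=fit.beta, u=u, reml=fit.reml, _U=fit.U, _w=fit.w)
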