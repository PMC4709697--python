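"""Numba kernels: Gibbs samplers for the Bayesian whole-genome regressions
and coordinate descent for the l1-penalized regression.

All kernels operate on the shared linear model

    y = mu + Z w + X g + e

with X the 0/1/2 marker dosage matrix and w optional family fixed effects
(flat priors).  Residuals are maintained incrementally; each kernel seeds
numpy's legacy global RNG inside the jitted scope, so a fixed seed gives a
bit-identical chain.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def _update_mu_and_families(e, mu, w, fam, n_fam, se2):
    n = e.shape[0]
    # intercept
    s = 0.0
    for i in range(n):
        s += e[i]
    mu_new = np.random.normal(mu + s / n, np.sqrt(se2 / n))
    delta = mu_new - mu
    for i in range(n):
        e[i] -= delta
    # family effects (flat prior); leave-one-out mean update
    if n_fam > 0:
        sums = np.zeros(n_fam)
        counts = np.zeros(n_fam)
        for i in range(n):
            sums[fam[i]] += e[i]
            counts[fam[i]] += 1.0
        w_new = np.empty(n_fam)
        for f in range(n_fam):
            mean = w[f] + sums[f] / counts[f]
            w_new[f] = np.random.normal(mean, np.sqrt(se2 / counts[f]))
        for i in range(n):
            e[i] -= w_new[fam[i]] - w[fam[i]]
        for f in range(n_fam):
            w[f] = w_new[f]
    return mu_new


@njit(cache=True)
def gibbs_bayes_ab(Xt, y, fam, n_fam, niter, burnin, nu, S, pi, nu_e, Se, seed):
    """BayesA (pi = 0) / BayesB (pi > 0) spike-and-slab Gibbs sampler.

    ``Xt`` is the marker matrix transposed (markers x individuals,
    C-contiguous) so each marker's genotypes are a contiguous row.
    Marker effect g_j ~ 0 w.p. pi, else N(0, sg2_j) with
    sg2_j ~ scaled-inv-chi2(nu, S).  Returns posterior means (post burn-in)
    of mu, w, g, sg2, the inclusion probabilities and the se2 chain.
    """
    np.random.seed(seed)
    m, n = Xt.shape
    xtx = np.empty(m)
    for j in range(m):
        s = 0.0
        for i in range(n):
            s += Xt[j, i] * Xt[j, i]
        xtx[j] = s
    mu = 0.0
    for i in range(n):
        mu += y[i]
    mu /= n
    w = np.zeros(max(n_fam, 1))
    g = np.zeros(m)
    sg2 = np.full(m, S * nu / max(nu - 2.0, 0.1))
    vy = 0.0
    for i in range(n):
        vy += (y[i] - mu) ** 2
    vy /= n
    se2 = 0.5 * vy if vy > 0 else 1.0
    e = np.empty(n)
    for i in range(n):
        e[i] = y[i] - mu

    keep = niter - burnin
    mu_sum = 0.0
    w_sum = np.zeros(max(n_fam, 1))
    g_sum = np.zeros(m)
    sg2_sum = np.zeros(m)
    incl_sum = np.zeros(m)
    se2_chain = np.empty(niter)

    for it in range(niter):
        mu = _update_mu_and_families(e, mu, w, fam, n_fam, se2)
        for j in range(m):
            gj = g[j]
            if xtx[j] <= 0.0:
                g[j] = 0.0
                sg2[j] = nu * S / np.random.chisquare(nu)
                continue
            rhs = xtx[j] * gj
            for i in range(n):
                rhs += Xt[j, i] * e[i]
            include = True
            if pi > 0.0:
                v0 = xtx[j] * se2
                v1 = v0 + xtx[j] * xtx[j] * sg2[j]
                logodds = (
                    np.log((1.0 - pi) / pi)
                    + 0.5 * np.log(v0 / v1)
                    + 0.5 * rhs * rhs * (1.0 / v0 - 1.0 / v1)
                )
                if logodds > 35.0:
                    p1 = 1.0
                elif logodds < -35.0:
                    p1 = 0.0
                else:
                    p1 = 1.0 / (1.0 + np.exp(-logodds))
                include = np.random.random() < p1
            if include:
                C = xtx[j] + se2 / sg2[j]
                mean = rhs / C
                sd = np.sqrt(se2 / C)
                gnew = np.random.normal(mean, sd)
                sg2[j] = (nu * S + gnew * gnew) / np.random.chisquare(nu + 1.0)
            else:
                gnew = 0.0
                sg2[j] = nu * S / np.random.chisquare(nu)
            if gnew != gj:
                diff = gnew - gj
                for i in range(n):
                    e[i] -= Xt[j, i] * diff
                g[j] = gnew
            if it >= burnin and include:
                incl_sum[j] += 1.0
        sse = 0.0
        for i in range(n):
            sse += e[i] * e[i]
        se2 = (sse + nu_e * Se) / np.random.chisquare(n + nu_e)
        se2_chain[it] = se2
        if it >= burnin:
            mu_sum += mu
            for f in range(n_fam):
                w_sum[f] += w[f]
            for j in range(m):
                g_sum[j] += g[j]
                sg2_sum[j] += sg2[j]

    return (
        mu_sum / keep,
        w_sum / keep,
        g_sum / keep,
        sg2_sum / keep,
        incl_sum / keep,
        se2_chain,
    )


@njit(cache=True)
def _rand_invgauss(mean, shape):
    """Inverse-Gaussian draw (Michael-Schucany-Haas)."""
    z = np.random.normal(0.0, 1.0)
    v = z * z
    x = mean + mean * mean * v / (2.0 * shape) - (mean / (2.0 * shape)) * np.sqrt(
        4.0 * mean * shape * v + mean * mean * v * v
    )
    if x <= 0.0:
        x = 1e-12
    if np.random.random() <= mean / (mean + x):
        return x
    return mean * mean / x


@njit(cache=True)
def gibbs_bl(Xt, y, fam, n_fam, niter, burnin, lam2_init, update_lambda,
             r_gamma, delta_gamma, nu_e, Se, seed):
    """Bayesian LASSO Gibbs sampler (double-exponential prior on g via the
    normal scale mixture g_j | tau2_j ~ N(0, tau2_j se2),
    tau2_j ~ Exp(lam2/2); lam2 optionally given a Gamma hyperprior).
    ``Xt`` is markers x individuals, C-contiguous."""
    np.random.seed(seed)
    m, n = Xt.shape
    xtx = np.empty(m)
    for j in range(m):
        s = 0.0
        for i in range(n):
            s += Xt[j, i] * Xt[j, i]
        xtx[j] = s
    mu = 0.0
    for i in range(n):
        mu += y[i]
    mu /= n
    w = np.zeros(max(n_fam, 1))
    g = np.zeros(m)
    tau2 = np.ones(m)
    lam2 = lam2_init
    vy = 0.0
    for i in range(n):
        vy += (y[i] - mu) ** 2
    vy /= n
    se2 = 0.5 * vy if vy > 0 else 1.0
    e = np.empty(n)
    for i in range(n):
        e[i] = y[i] - mu

    keep = niter - burnin
    mu_sum = 0.0
    w_sum = np.zeros(max(n_fam, 1))
    g_sum = np.zeros(m)
    lam2_sum = 0.0
    se2_chain = np.empty(niter)

    for it in range(niter):
        mu = _update_mu_and_families(e, mu, w, fam, n_fam, se2)
        for j in range(m):
            gj = g[j]
            rhs = xtx[j] * gj
            for i in range(n):
                rhs += Xt[j, i] * e[i]
            C = xtx[j] + 1.0 / tau2[j]
            mean = rhs / C
            sd = np.sqrt(se2 / C)
            gnew = np.random.normal(mean, sd)
            diff = gnew - gj
            if diff != 0.0:
                for i in range(n):
                    e[i] -= Xt[j, i] * diff
            g[j] = gnew
            g2 = gnew * gnew
            if g2 < 1e-12:
                g2 = 1e-12
            inv_tau2 = _rand_invgauss(np.sqrt(lam2 * se2 / g2), lam2)
            tau2[j] = 1.0 / inv_tau2
        if update_lambda:
            rate = delta_gamma
            for j in range(m):
                rate += tau2[j] / 2.0
            lam2 = np.random.gamma(r_gamma + m, 1.0 / rate)
        sse = 0.0
        for i in range(n):
            sse += e[i] * e[i]
        quad = 0.0
        for j in range(m):
            quad += g[j] * g[j] / tau2[j]
        se2 = (sse + quad + nu_e * Se) / np.random.chisquare(n + m + nu_e)
        se2_chain[it] = se2
        if it >= burnin:
            mu_sum += mu
            for f in range(n_fam):
                w_sum[f] += w[f]
            for j in range(m):
                g_sum[j] += g[j]
            lam2_sum += lam2

    return (
        mu_sum / keep,
        w_sum / keep,
        g_sum / keep,
        lam2_sum / keep,
        se2_chain,
    )


@njit(cache=True)
def cd_lasso_path(Xt, y, lambdas, max_sweeps, tol):
    """Cyclic coordinate descent over a decreasing lambda path.

    Objective (glmnet convention): (1/2n)||y - X g||^2 + lam * ||g||_1.
    ``Xt`` (markers x individuals, C-contiguous) and ``y`` are expected
    centered.  Warm starts along the path.  Returns the (n_lambda, m)
    coefficient array.
    """
    m, n = Xt.shape
    nl = lambdas.shape[0]
    out = np.zeros((nl, m))
    g = np.zeros(m)
    e = y.copy()
    xtx_n = np.empty(m)
    for j in range(m):
        s = 0.0
        for i in range(n):
            s += Xt[j, i] * Xt[j, i]
        xtx_n[j] = s / n
    for li in range(nl):
        lam = lambdas[li]
        for _ in range(max_sweeps):
            max_delta = 0.0
            for j in range(m):
                if xtx_n[j] <= 0.0:
                    continue
                gj = g[j]
                rho = gj * xtx_n[j]
                for i in range(n):
                    rho += Xt[j, i] * e[i] / n
                if rho > lam:
                    gnew = (rho - lam) / xtx_n[j]
                elif rho < -lam:
                    gnew = (rho + lam) / xtx_n[j]
                else:
                    gnew = 0.0
                diff = gnew - gj
                if diff != 0.0:
                    for i in range(n):
                        e[i] -= Xt[j, i] * diff
                    g[j] = gnew
                    ad = abs(diff)
                    if ad > max_delta:
                        max_delta = ad
            if max_delta < tol:
                break
        for j in range(m):
            out[li, j] = g[j]
    return out


def lasso_objective(X, y, g, lam):
    """(1/2n)||y - X g||^2 + lam ||g||_1 on centered data."""
    n = X.shape[0]
    r = y - X @ g
    return float(r @ r) / (2 * n) + lam * float(np.abs(g).sum())


def split_rhat(chain: np.ndarray) -> float:
    """Gelman-style split-chain potential scale reduction on one chain."""
    x = np.asarray(chain, dtype=float)
    half = x.size // 2
    if half < 4:
        return np.nan
    a, b = x[:half], x[half : 2 * half]
    means = np.array([a.mean(), b.mean()])
    vars_ = np.array([a.var(ddof=1), b.var(ddof=1)])
    W = vars_.mean()
    B = half * means.var(ddof=1)
    if W <= 0:
        return np.nan
    var_hat = (half - 1) / half * W + B / half
    return float(np.sqrt(var_hat / W))
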