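"""Negative-binomial log-linear GLM machinery.

Fits many genes at once by vectorized iteratively reweighted least squares
(IRLS) with a shared design matrix and per-observation log offsets.  The
NB2 parameterization is used throughout: for mean ``mu`` and dispersion
``phi >= 0``, ``Var(Y) = mu + phi * mu**2``; ``phi = 0`` is Poisson.
"""

from __future__ import annotations

import numpy as np
from scipy.special import gammaln

_POISSON_EPS = 1e-8
MAX_ITER = 100
REL_TOL = 1e-8


def nb_loglik(y: np.ndarray, mu: np.ndarray, phi) -> np.ndarray:
    """Row-wise NB2 log-likelihood.

    Parameters
    ----------
    y, mu : arrays broadcastable to (genes, samples)
    phi : scalar or (genes,) dispersion

    Returns
    -------
    (genes,) array of log-likelihood sums over samples.
    """
    y = np.atleast_2d(np.asarray(y, dtype=float))
    mu = np.broadcast_to(np.atleast_2d(mu), y.shape)
    phi = np.asarray(phi, dtype=float)
    phi_col = phi.reshape(-1, 1) if phi.ndim == 1 else phi
    mu = np.clip(mu, 1e-300, None)
    if np.all(phi < _POISSON_EPS):
        ll = y * np.log(mu) - mu - gammaln(y + 1.0)
        return ll.sum(axis=1)
    r = 1.0 / np.clip(phi_col, _POISSON_EPS, None)
    ll = (
        gammaln(y + r)
        - gammaln(r)
        - gammaln(y + 1.0)
        + r * np.log(r / (r + mu))
        + y * np.log(mu / (r + mu))
    )
    if np.any(phi < _POISSON_EPS):
        pois = (y * np.log(mu) - mu - gammaln(y + 1.0)).sum(axis=1)
        mask = np.broadcast_to(phi < _POISSON_EPS, pois.shape)
        out = ll.sum(axis=1)
        out[mask] = pois[mask]
        return out
    return ll.sum(axis=1)


def nb_deviance(y: np.ndarray, mu: np.ndarray, phi) -> np.ndarray:
    """Row-wise NB2 deviance (2 * [loglik(saturated) - loglik(mu)])."""
    y = np.atleast_2d(np.asarray(y, dtype=float))
    mu = np.clip(np.broadcast_to(np.atleast_2d(mu), y.shape), 1e-300, None)
    phi = np.asarray(phi, dtype=float)
    phi_col = phi.reshape(-1, 1) if phi.ndim == 1 else phi
    with np.errstate(divide="ignore", invalid="ignore"):
        ylogy = np.where(y > 0, y * np.log(np.clip(y, 1e-300, None) / mu), 0.0)
    if np.all(phi < _POISSON_EPS):
        dev = 2.0 * (ylogy - (y - mu))
        return dev.sum(axis=1)
    r = 1.0 / np.clip(phi_col, _POISSON_EPS, None)
    dev = 2.0 * (ylogy - (y + r) * np.log((y + r) / (mu + r)))
    if np.any(phi < _POISSON_EPS):
        pois = (2.0 * (ylogy - (y - mu))).sum(axis=1)
        out = dev.sum(axis=1)
        mask = np.broadcast_to(phi < _POISSON_EPS, pois.shape)
        out[mask] = pois[mask]
        return out
    return dev.sum(axis=1)


def fit_nb_glm(
    y: np.ndarray,
    design: np.ndarray,
    dispersion,
    offset=0.0,
    max_iter: int = MAX_ITER,
    tol: float = REL_TOL,
):
    """Fit ``log mu = offset + X beta`` per gene by IRLS.

    Parameters
    ----------
    y : (genes, samples) counts
    design : (samples, p) full-rank design matrix, shared across genes
    dispersion : scalar or (genes,) NB dispersion phi
    offset : scalar, (samples,) or (genes, samples) natural-log offset

    Returns
    -------
    dict with keys
        ``beta`` (genes, p), ``mu`` (genes, samples), ``deviance`` (genes,),
        ``loglik`` (genes,), ``converged`` (genes,) bool,
        ``cr_logdet`` (genes,) 0.5*logdet of the Fisher information
        X'WX at the optimum (Cox–Reid adjustment term).
    """
    y = np.atleast_2d(np.asarray(y, dtype=float))
    X = np.asarray(design, dtype=float)
    G, n = y.shape
    p = X.shape[1]
    if X.shape[0] != n:
        raise ValueError("design rows must match sample count")
    phi = np.broadcast_to(np.asarray(dispersion, dtype=float), (G,)).copy()
    if np.any(phi < 0):
        raise ValueError("dispersion must be >= 0")
    off = np.broadcast_to(np.asarray(offset, dtype=float), (G, n))

    # moment-based start: shrink observations toward the gene mean
    mu = y + np.maximum(y.mean(axis=1, keepdims=True), 0.5) / 2.0
    mu = np.clip(mu, 1e-4, None)
    eta = np.log(mu)

    beta = np.zeros((G, p))
    dev = np.full(G, np.inf)
    converged = np.zeros(G, dtype=bool)
    active = np.ones(G, dtype=bool)
    phi_col = phi[:, None]

    for _ in range(max_iter):
        idx = np.flatnonzero(active)
        if idx.size == 0:
            break
        mu_a = mu[idx]
        w = mu_a / (1.0 + phi_col[idx] * mu_a)  # IRLS weights for log link
        z = (eta[idx] - off[idx]) + (y[idx] - mu_a) / mu_a
        xtwx = np.einsum("ki,gk,kj->gij", X, w, X)
        xtwz = np.einsum("ki,gk->gi", X, w * z)
        try:
            beta_new = np.linalg.solve(xtwx, xtwz[..., None])[..., 0]
        except np.linalg.LinAlgError:
            beta_new = np.einsum(
                "gij,gj->gi", np.linalg.pinv(xtwx), xtwz
            )
        beta[idx] = beta_new
        eta_new = off[idx] + beta_new @ X.T
        eta_new = np.clip(eta_new, -700, 700)
        mu_new = np.clip(np.exp(eta_new), 1e-300, 1e300)
        dev_new = nb_deviance(y[idx], mu_new, phi[idx])
        rel = np.abs(dev_new - dev[idx]) / (np.abs(dev_new) + 0.1)
        eta[idx] = eta_new
        mu[idx] = mu_new
        done = rel < tol
        converged[idx[done]] = True
        dev[idx] = dev_new
        active[idx[done]] = False

    ll = nb_loglik(y, mu, phi)
    w = mu / (1.0 + phi_col * mu)
    xtwx = np.einsum("ki,gk,kj->gij", X, w, X)
    sign, logdet = np.linalg.slogdet(xtwx)
    cr = 0.5 * np.where(sign > 0, logdet, -np.inf)
    return {
        "beta": beta,
        "mu": mu,
        "deviance": dev,
        "loglik": ll,
        "converged": converged,
        "cr_logdet": cr,
    }


def adjusted_profile_loglik(
    y: np.ndarray, design: np.ndarray, dispersion, offset=0.0
) -> np.ndarray:
    """Cox–Reid adjusted profile log-likelihood per gene at one dispersion."""
    fit = fit_nb_glm(y, design, dispersion, offset=offset)
    return fit["loglik"] - fit["cr_logdet"]
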