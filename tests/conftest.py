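"""Shared fixtures and independent brute-force oracles.

The oracles here deliberately re-derive every quantity with plain numpy double
loops (or closed forms), independent of the package's compiled kernels.
"""

from __future__ import annotations

import numpy as np
import pytest
from scipy.special import digamma


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)


# ---------------------------------------------------------------------------
# brute-force KSG estimator (max norm, strict range counts, digamma form)
# ---------------------------------------------------------------------------

def _cheby(block: np.ndarray) -> np.ndarray:
    n = block.shape[0]
    if block.shape[1] == 0:
        return np.zeros((n, n))
    return np.max(np.abs(block[:, None, :] - block[None, :, :]), axis=2)


def bf_ksg_cmi(xb, yb, zb, T: int, theiler: int = 0) -> float:
    """O(N^2) reference KSG conditional mutual information in nats."""
    xb = np.atleast_2d(np.asarray(xb, float).T).T
    yb = np.atleast_2d(np.asarray(yb, float).T).T
    n = xb.shape[0]
    zb = np.empty((n, 0)) if zb is None else np.atleast_2d(np.asarray(zb, float).T).T
    dx, dy, dz = _cheby(xb), _cheby(yb), _cheby(zb)
    joint = np.maximum(np.maximum(dx, dy), dz)
    idx = np.arange(n)
    banned = np.abs(idx[:, None] - idx[None, :]) <= theiler
    joint = joint.copy()
    joint[banned] = np.inf
    eps = np.sort(joint, axis=1)[:, T - 1]
    total = 0.0
    for i in range(n):
        ok = ~banned[i]
        nz = int(np.sum(ok & (dz[i] < eps[i])))
        nxz = int(np.sum(ok & (dz[i] < eps[i]) & (dx[i] < eps[i])))
        nyz = int(np.sum(ok & (dz[i] < eps[i]) & (dy[i] < eps[i])))
        total += digamma(nz + 1) - digamma(nxz + 1) - digamma(nyz + 1)
    return float(digamma(T) + total / n)


def bf_nn_predict(u, y, T: int, exclude_self: bool = True, theiler: int = 0):
    """O(N^2) nearest-neighbor regression with (distance, index) tie order."""
    u = np.atleast_2d(np.asarray(u, float).T).T
    y = np.asarray(y, float).ravel()
    n = u.shape[0]
    preds = np.empty(n)
    for i in range(n):
        d = np.sqrt(np.sum((u - u[i]) ** 2, axis=1))
        allowed = np.ones(n, bool)
        if exclude_self:
            allowed[i] = False
        if theiler > 0:
            lo, hi = max(0, i - theiler), min(n, i + theiler + 1)
            allowed[lo:hi] = False
        cand = np.flatnonzero(allowed)
        order = cand[np.lexsort((cand, d[cand]))]
        preds[i] = y[order[:T]].mean()
    residuals = y - preds
    return preds, residuals, float(np.mean(residuals**2))


def bf_kde_predict(u, y):
    """Double-loop Gaussian-kernel regression oracle (leave-one-out), with
    Mahalanobis whitening and the Gaussian reference bandwidth."""
    u = np.atleast_2d(np.asarray(u, float).T).T
    y = np.asarray(y, float).ravel()
    n, k = u.shape
    c = u - u.mean(axis=0)
    cov = np.atleast_2d(np.cov(c, rowvar=False, ddof=1))
    inv = np.linalg.inv(cov)
    h = (4.0 / (k + 2.0)) ** (1.0 / (k + 4.0)) * n ** (-1.0 / (k + 4.0))
    kern = np.empty((n, n))
    for i in range(n):
        for j in range(n):
            d = c[i] - c[j]
            kern[i, j] = np.exp(-float(d @ inv @ d) / (2.0 * h * h))
    p = sum(kern[i, i] / kern[i].sum() for i in range(n))
    preds = np.empty(n)
    for i in range(n):
        w = kern[i].copy()
        w[i] = 0.0
        preds[i] = (w @ y) / w.sum() if w.sum() > 0 else 0.0
    return preds, float(p)


# ---------------------------------------------------------------------------
# Gaussian closed forms
# ---------------------------------------------------------------------------

def gaussian_mi(rho: float) -> float:
    return -0.5 * np.log(1.0 - rho * rho)


def gaussian_cmi(cov: np.ndarray, ix, iy, iz) -> float:
    """I(X;Y|Z) for a joint Gaussian via log-determinants."""
    cov = np.asarray(cov, float)

    def logdet(ids):
        ids = list(ids)
        if not ids:
            return 0.0
        return float(np.linalg.slogdet(cov[np.ix_(ids, ids)])[1])

    ix, iy, iz = list(ix), list(iy), list(iz)
    return 0.5 * (
        logdet(ix + iz) + logdet(iy + iz) - logdet(ix + iy + iz) - logdet(iz)
    )


def random_correlation(rng, dim: int) -> np.ndarray:
    """A well-conditioned random correlation matrix."""
    a = rng.standard_normal((dim, dim + 3))
    cov = a @ a.T / (dim + 3) + 0.5 * np.eye(dim)
    d = np.sqrt(np.diag(cov))
    return cov / np.outer(d, d)
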