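"""Information-theoretic and regression estimators.

Kraskov-Stogbauer-Grassberger (KSG) k-nearest-neighbor estimators of mutual
information, conditional mutual information and conditional transfer entropy,
nearest-neighbor regression with its mean squared residual (MSR), and
Gaussian-kernel (KDE) regression with the AIC model-selection score.

All information values are reported in nats.  KSG estimates carry a small
negative bias floor and may dip slightly below zero for (conditionally)
independent data; callers must not assume non-negativity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
import scipy.linalg
from scipy.special import digamma

from ._kernels import ksg_cmi_kernel, nn_predict_kernel
from .config import NeighborConfig
from .embedding import lagged_design, present_column

__all__ = [
    "InformationEstimate",
    "PredictionResult",
    "ksg_mutual_information",
    "ksg_conditional_mutual_information",
    "nn_predict",
    "kde_predict",
    "aic_score",
    "estimate_cte",
]


@dataclass(frozen=True)
class InformationEstimate:
    """A scalar information estimate in nats with its provenance."""

    value: float
    estimator: str
    T: int
    note: Optional[str] = None


@dataclass(frozen=True)
class PredictionResult:
    """Nearest-neighbor regression output.

    ``residuals[i] = y[i] - predictions[i]`` exactly, and ``msr`` is the mean
    of the squared residuals (squared units of ``y``).
    """

    predictions: np.ndarray
    residuals: np.ndarray
    msr: float


def _as_block(a, name: str, allow_empty: bool = False) -> np.ndarray:
    """Coerce to an (N, k) float matrix of realizations."""
    if a is None:
        if allow_empty:
            return np.empty((0, 0))
        raise ValueError(f"{name} must be provided")
    a = np.asarray(a, dtype=np.float64)
    if a.ndim == 1:
        a = a[:, None]
    if a.ndim != 2:
        raise ValueError(f"{name} must be 1- or 2-dimensional")
    if a.shape[1] == 0 and not allow_empty:
        raise ValueError(f"{name} must have at least one column")
    if a.size and not np.isfinite(a).all():
        raise ValueError(f"{name} contains non-finite values")
    return a


def _check_same_n(*blocks: np.ndarray) -> int:
    ns = {b.shape[0] for b in blocks if b.shape[1] > 0}
    if len(ns) != 1:
        raise ValueError(f"blocks disagree on sample count: {sorted(ns)}")
    return ns.pop()


def psi_table(n: int) -> np.ndarray:
    """digamma lookup table, ``table[i] = digamma(i)`` for ``i >= 1``."""
    table = np.empty(n + 1)
    table[0] = np.nan
    table[1:] = digamma(np.arange(1, n + 1, dtype=np.float64))
    return table


def jitter_columns(
    blocks: Sequence[np.ndarray], cfg: NeighborConfig
) -> list[np.ndarray]:
    """Add the deterministic tie-breaking jitter to every column.

    Draws are consumed column by column in block order, so the perturbation of
    a given block does not depend on how many blocks follow it — this is what
    makes conditional-MI-with-empty-condition bit-identical to plain MI.
    """
    if cfg.jitter_seed is None:
        return [b.copy() for b in blocks]
    rng = np.random.default_rng(cfg.jitter_seed)
    out = []
    for b in blocks:
        b = b.copy()
        for c in range(b.shape[1]):
            sd = float(b[:, c].std())
            scale = cfg.jitter_scale * (sd if sd > 0.0 else 1.0)
            b[:, c] += (rng.random(b.shape[0]) * 2.0 - 1.0) * scale
        out.append(b)
    return out


def ksg_mutual_information(
    x, y, cfg: Optional[NeighborConfig] = None
) -> InformationEstimate:
    """KSG (algorithm 1) estimate of the mutual information I(X;Y).

    Joint-space neighbors are ranked under the max norm; marginal neighbor
    counts use strict inequality against the distance to the T-th joint
    neighbor, with the digamma correction of KSG algorithm 1.
    """
    cfg = cfg or NeighborConfig()
    xb = _as_block(x, "x")
    yb = _as_block(y, "y")
    n = _check_same_n(xb, yb)
    cfg.validate_for(n)
    xb, yb = jitter_columns([xb, yb], cfg)
    value = ksg_cmi_kernel(
        xb, yb, np.empty((n, 0)), cfg.T, cfg.theiler_window, psi_table(n)
    )
    return InformationEstimate(float(value), "ksg_mi", cfg.T)


def ksg_conditional_mutual_information(
    x, y, z, cfg: Optional[NeighborConfig] = None
) -> InformationEstimate:
    """KSG estimate of the conditional mutual information I(X;Y|Z).

    ``z`` may be ``None`` or have zero columns; the estimate then equals
    :func:`ksg_mutual_information` on the same inputs, bit for bit.
    """
    cfg = cfg or NeighborConfig()
    xb = _as_block(x, "x")
    yb = _as_block(y, "y")
    zb = _as_block(z, "z", allow_empty=True)
    if zb.shape[1] == 0:
        zb = np.empty((xb.shape[0], 0))
    n = _check_same_n(xb, yb, zb)
    cfg.validate_for(n)
    xb, yb, zb = jitter_columns([xb, yb, zb], cfg)
    value = ksg_cmi_kernel(xb, yb, zb, cfg.T, cfg.theiler_window, psi_table(n))
    return InformationEstimate(float(value), "ksg_cmi", cfg.T)


def nn_predict(u, y, cfg: Optional[NeighborConfig] = None) -> PredictionResult:
    """Nearest-neighbor regression of ``y`` on the rows of ``u``.

    Each prediction is the mean of ``y`` over the ``T`` nearest rows of ``u``
    (Euclidean metric by default); with ``exclude_self`` the query row never
    participates in its own average, the leave-one-out convention that keeps
    the residuals honest.
    """
    cfg = cfg or NeighborConfig()
    ub = _as_block(u, "u")
    yv = np.asarray(y, dtype=np.float64).ravel()
    if ub.shape[0] != yv.shape[0]:
        raise ValueError("u and y disagree on sample count")
    n = ub.shape[0]
    if cfg.exclude_self:
        cfg.validate_for(n)
    elif cfg.T > n:
        raise ValueError(f"T={cfg.T} infeasible for N={n}")
    (ub,) = jitter_columns([ub], cfg)
    preds = nn_predict_kernel(
        ub,
        yv,
        cfg.T,
        cfg.theiler_window,
        cfg.exclude_self,
        cfg.metric == "max_norm",
    )
    residuals = yv - preds
    return PredictionResult(preds, residuals, float(np.mean(residuals**2)))


# Gaussian reference (Silverman) bandwidth on whitened coordinates.
def _reference_bandwidth(n: int, k: int) -> float:
    return (4.0 / (k + 2.0)) ** (1.0 / (k + 4.0)) * n ** (-1.0 / (k + 4.0))


def kde_predict(u, y) -> Tuple[np.ndarray, float]:
    """Gaussian-kernel (Nadaraya-Watson) regression of ``y`` on ``u``.

    The kernel uses the Mahalanobis distance (coordinates whitened by the
    sample covariance, diagonal-regularized when near-singular) with the
    Gaussian reference bandwidth ``h = (4/(k+2))^{1/(k+4)} N^{-1/(k+4)}``.
    Predictions are leave-one-out — the query point's own kernel mass is
    removed from its average, the same convention as :func:`nn_predict` —
    which keeps the residuals an out-of-sample quantity.  (A self-inclusive
    average degenerates as the dimension grows: every point predicts itself,
    the residuals collapse, and an AIC stop built on them never fires.)  A
    point with no leave-one-out kernel mass predicts 0, the mean of a
    standardized target.

    Returns the predictions and the model complexity ``p``: the trace of the
    (self-inclusive) smoother matrix, ``p = sum_i K(u_i,u_i) / sum_j
    K(u_i,u_j)``, which runs from 1 (all points identical) to N (all points
    isolated).
    """
    ub = _as_block(u, "u")
    yv = np.asarray(y, dtype=np.float64).ravel()
    n, k = ub.shape
    if n != yv.shape[0]:
        raise ValueError("u and y disagree on sample count")
    centered = ub - ub.mean(axis=0)
    if n == 1:
        return np.zeros(1), 1.0
    if not centered.any():
        # all rows identical: every kernel weight is equal, p attains its
        # lower bound of 1 and each point is predicted by the others' mean
        preds = (yv.sum() - yv) / (n - 1)
        return preds, 1.0
    cov = np.atleast_2d(np.cov(centered, rowvar=False, ddof=1))
    try:
        chol = np.linalg.cholesky(cov)
    except np.linalg.LinAlgError:
        cov = cov + (1e-8 * max(np.trace(cov), 1e-300) / k) * np.eye(k)
        try:
            chol = np.linalg.cholesky(cov)
        except np.linalg.LinAlgError as err:
            raise np.linalg.LinAlgError(
                "sample covariance of u is singular even after diagonal "
                "regularization; KDE regression is undefined"
            ) from err
    white = scipy.linalg.solve_triangular(chol, centered.T, lower=True).T
    h = _reference_bandwidth(n, k)
    sq = np.sum(white**2, axis=1)
    d2 = sq[:, None] + sq[None, :] - 2.0 * (white @ white.T)
    np.maximum(d2, 0.0, out=d2)
    kern = np.exp(-d2 / (2.0 * h * h))
    p = float(np.sum(1.0 / kern.sum(axis=1)))  # K(u_i, u_i) = 1
    np.fill_diagonal(kern, 0.0)
    rowsum = kern.sum(axis=1)
    preds = (kern @ yv) / np.where(rowsum == 0.0, 1.0, rowsum)
    return preds, p


def aic_score(u, y) -> float:
    """AIC of the KDE regression: ``N log(MSE) + 2 p`` (natural log).

    Returns ``-inf`` when the fit is exact (MSE = 0), the degenerate
    perfect-fit sentinel.
    """
    yv = np.asarray(y, dtype=np.float64).ravel()
    preds, p = kde_predict(u, yv)
    n = yv.shape[0]
    mse = float(np.mean((yv - preds) ** 2))
    if mse == 0.0:
        return float("-inf")
    return n * math.log(mse) + 2.0 * p


def estimate_cte(
    data,
    selection,
    source: int,
    target: int,
    cfg: Optional[NeighborConfig] = None,
) -> InformationEstimate:
    """Conditional transfer entropy from ``source`` to ``target`` in nats.

    Given a non-uniform embedding ``selection`` for ``target``, computes
    ``I(Y_n ; {selected source lags} | {selected non-source lags})`` with the
    KSG conditional-MI estimator.  If the selection holds no lag of the source
    process the transfer entropy is exactly zero by the termination rule and
    the result is flagged accordingly.
    """
    if source == target:
        raise ValueError("source and target must differ")
    cfg = cfg or NeighborConfig()
    data = np.asarray(data, dtype=np.float64)
    src = [c for c in selection.selected if c.process == source]
    if not src:
        return InformationEstimate(0.0, "ksg_cte", cfg.T, note="no source lag selected")
    rest = [c for c in selection.selected if c.process != source]
    max_lag = selection.max_lag
    yv = present_column(data, target, max_lag)
    xb = lagged_design(data, src, max_lag)
    zb = lagged_design(data, rest, max_lag)
    n = yv.shape[0]
    cfg.validate_for(n)
    xb, yb, zb = jitter_columns([xb, yv[:, None], zb], cfg)
    value = ksg_cmi_kernel(xb, yb, zb, cfg.T, cfg.theiler_window, psi_table(n))
    return InformationEstimate(float(value), "ksg_cte", cfg.T)
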