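"""Ground-truth generators for benchmarking directed-dependency detection.

Two 5-node systems with known coupling structure:

* a ring of coupled Henon maps where the interior nodes are driven by both
  neighbors through a coupling strength ``Q`` (nodes 1 and 5 run free), and
* a nonlinear autoregressive (AR) system driven by independent unit-variance
  Gaussian noise, with a mix of linear and quadratic cross-couplings.

An instantaneous mixing operator emulates zero-lag information sharing such
as volume conduction in scalp/intracranial EEG: each observed channel is a
convex-ish combination of all sources, ``(1 - alpha)`` of itself plus
``alpha`` of every other.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Union

import numpy as np

__all__ = [
    "HenonConfig",
    "ARConfig",
    "MixingConfig",
    "GroundTruth",
    "SimulationError",
    "simulate_henon",
    "simulate_ar",
    "mix_instantaneous",
    "ground_truth",
]

N_NODES = 5


class SimulationError(RuntimeError):
    """Raised when a simulated trajectory cannot be produced."""


@dataclass(frozen=True)
class HenonConfig:
    Q: float = 0.6
    N: int = 512
    transient: int = 1000
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.Q <= 1.0:
            raise ValueError("Q must lie in [0, 1]")
        if self.N < 32:
            raise ValueError("N must be at least 32")
        if self.transient < 0:
            raise ValueError("transient must be non-negative")


@dataclass(frozen=True)
class ARConfig:
    N: int = 512
    transient: int = 1000
    seed: int = 0

    def __post_init__(self):
        if self.N < 32:
            raise ValueError("N must be at least 32")
        if self.transient < 0:
            raise ValueError("transient must be non-negative")


@dataclass(frozen=True)
class MixingConfig:
    alpha: float = 0.1

    def __post_init__(self):
        if not 0.0 <= self.alpha <= 0.3:
            raise ValueError("alpha must lie in [0, 0.3]")


@dataclass(frozen=True)
class GroundTruth:
    """Binary directed-dependency matrix; ``adjacency[i, j] = 1`` iff i -> j.

    The diagonal (self-dependence) is excluded from scoring by convention.
    """

    adjacency: np.ndarray

    @property
    def n_positives(self) -> int:
        return int(self.adjacency.sum())


_DIVERGENCE_BOUND = 1e4
_MAX_RETRIES = 100


def henon_step(prev1: np.ndarray, prev2: np.ndarray, Q: float) -> np.ndarray:
    """One update of the 5-node coupled Henon ring.

    Free nodes (1 and 5): ``y = 1.4 - y_{n-1}^2 + 0.3 y_{n-2}``.  Driven
    nodes square the coupling-weighted mixture of their own and both
    neighbors' previous values:
    ``y = 1.4 - (0.5 Q (left + right) + (1 - Q) own)^2 + 0.3 y_{n-2}``, which
    collapses to the free map at Q = 0.
    """
    arg = prev1.copy()
    arg[1:4] = 0.5 * Q * (prev1[0:3] + prev1[2:5]) + (1.0 - Q) * prev1[1:4]
    return 1.4 - arg**2 + 0.3 * prev2


def simulate_henon(
    cfg: HenonConfig, initial: Optional[np.ndarray] = None, return_info: bool = False
):
    """Simulate the coupled Henon ring, discarding the transient.

    Initial conditions (the two required past values per node) are drawn
    i.i.d. uniform on [0, 0.5]; trajectories that escape (|y| > 1e4) are
    redrawn from the same seeded stream, up to a bounded retry budget, and the
    retry count is reported via ``return_info``.  ``initial`` (a (2, 5) array
    of [y_{n-2}; y_{n-1}] rows) bypasses the random draw.

    Returns an ``N x 5`` matrix (and an info dict when ``return_info``).
    """
    rng = np.random.default_rng(cfg.seed)
    total = cfg.transient + cfg.N
    retries = 0
    for attempt in range(_MAX_RETRIES + 1):
        if initial is not None:
            prev2 = np.asarray(initial, dtype=np.float64)[0].copy()
            prev1 = np.asarray(initial, dtype=np.float64)[1].copy()
        else:
            draw = rng.uniform(0.0, 0.5, size=(2, N_NODES))
            prev2, prev1 = draw[0].copy(), draw[1].copy()
        out = np.empty((total, N_NODES))
        ok = True
        for n in range(total):
            cur = henon_step(prev1, prev2, cfg.Q)
            if np.any(np.abs(cur) > _DIVERGENCE_BOUND):
                ok = False
                break
            out[n] = cur
            prev2, prev1 = prev1, cur
        if ok:
            data = out[cfg.transient :]
            if return_info:
                return data, {"retries": retries}
            return data
        if initial is not None:
            raise SimulationError("trajectory diverged from the given initial state")
        retries += 1
    raise SimulationError(
        f"Henon trajectory diverged in all {_MAX_RETRIES} retries (Q={cfg.Q})"
    )


def simulate_ar(cfg: ARConfig, noise: Optional[np.ndarray] = None) -> np.ndarray:
    """Simulate the 5-node nonlinear AR system, discarding the transient.

    The system (unit-variance white Gaussian innovations, zeros before t=0),
    a variant of the classic five-variate linear/quadratic benchmark with the
    5-to-4 feedback removed:

    ``y1 = 0.95*sqrt(2) y1[-1] - 0.9025 y1[-2] + e1``
    ``y2 = 0.5 y1[-2]^2 + e2``
    ``y3 = -0.4 y1[-3] + 0.4 y2[-1] + e3``
    ``y4 = -0.5 y1[-1]^2 + 0.25*sqrt(2) y4[-1] + e4``
    ``y5 = -0.25*sqrt(2) y4[-1] + 0.25*sqrt(2) y5[-2] + e5``

    Node 1 is a stochastic oscillator (poles at radius 0.95, period 8) that
    drives nodes 2-4; nodes 2 and 4 receive it through a square, node 3
    linearly and through node 2.

    ``noise`` (shape ``(transient + N, 5)``) substitutes the innovations; it
    exists so tests can drive the recursion with recorded or zero noise.
    """
    total = cfg.transient + cfg.N
    if noise is None:
        rng = np.random.default_rng(cfg.seed)
        eps = rng.standard_normal((total, N_NODES))
    else:
        eps = np.asarray(noise, dtype=np.float64)
        if eps.shape != (total, N_NODES):
            raise ValueError(f"noise must have shape {(total, N_NODES)}")
    a1 = 0.95 * np.sqrt(2.0)
    a2 = 0.9025
    c = 0.25 * np.sqrt(2.0)
    p = 3  # deepest lag in the system
    y = np.zeros((total + p, N_NODES))
    for t in range(p, total + p):
        e = eps[t - p]
        y[t, 0] = a1 * y[t - 1, 0] - a2 * y[t - 2, 0] + e[0]
        y[t, 1] = 0.5 * y[t - 2, 0] ** 2 + e[1]
        y[t, 2] = -0.4 * y[t - 3, 0] + 0.4 * y[t - 1, 1] + e[2]
        y[t, 3] = -0.5 * y[t - 1, 0] ** 2 + c * y[t - 1, 3] + e[3]
        y[t, 4] = -c * y[t - 1, 3] + c * y[t - 2, 4] + e[4]
    return y[p + cfg.transient :]


def mixing_matrix(alpha: float) -> np.ndarray:
    """The instantaneous-coupling matrix: ``1 - alpha`` diagonal, ``alpha`` off."""
    A = np.full((N_NODES, N_NODES), alpha)
    np.fill_diagonal(A, 1.0 - alpha)
    return A


def mix_instantaneous(
    data: np.ndarray, cfg: Union[MixingConfig, float]
) -> np.ndarray:
    """Mix channels instantaneously: ``Y_mixed = Y A``.

    Each output channel keeps ``1 - alpha`` of itself and receives ``alpha``
    of every other source — the zero-lag confound that produces spurious
    directed dependencies if the detector is too permissive.
    """
    if not isinstance(cfg, MixingConfig):
        cfg = MixingConfig(alpha=float(cfg))
    data = np.asarray(data, dtype=np.float64)
    if data.ndim != 2 or data.shape[1] != N_NODES:
        raise ValueError(f"expected an N x {N_NODES} matrix")
    return data @ mixing_matrix(cfg.alpha)


_HENON_EDGES = [(0, 1), (2, 1), (1, 2), (3, 2), (2, 3), (4, 3)]
_AR_EDGES = [(0, 1), (0, 2), (0, 3), (1, 2), (3, 4)]


def ground_truth(model: str) -> GroundTruth:
    """True directed-dependency matrix of a simulated model (0-based nodes)."""
    if model == "henon":
        edges = _HENON_EDGES
    elif model == "ar":
        edges = _AR_EDGES
    else:
        raise ValueError(f"unknown model {model!r}; expected 'henon' or 'ar'")
    adj = np.zeros((N_NODES, N_NODES), dtype=np.int64)
    for i, j in edges:
        adj[i, j] = 1
    return GroundTruth(adjacency=adj)
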