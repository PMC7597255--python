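"""Greedy non-uniform embedding (NUE) of multivariate time series.

Starting from the pool of lagged variables of every channel, the search
repeatedly picks the candidate that ranks highest under the configured
criterion and stops when the candidate no longer earns its place:

* ``msr``   — rank by ``(1 - lambda) * CMI - lambda * MSR`` (conditional
  mutual information with the already-selected block versus the mean squared
  residual of nearest-neighbor prediction); the first winner is always kept
  and, from the second iteration on, a candidate is kept only when it improves
  the MSR by more than ``gamma``.
* ``bootstrap`` — rank by CMI; keep a winner whose CMI exceeds the 95th
  percentile of estimates under independent row shuffles of the winner and the
  target (conditioning block unshuffled).
* ``la``    — rank by the low-dimensional approximation of the CMI
  (relevance minus average redundancy plus average conditional redundancy);
  shuffle-percentile stop computed with the same approximation.
* ``aic``   — rank by CMI; keep a winner while the AIC of the KDE regression
  of the target on the selected block keeps improving.

All ranking ties break toward the earlier candidate in process-major,
lag-minor pool order, which makes every run deterministic given the data and
the configuration.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from ._kernels import (
    cmi_perm_batch,
    cmi_select_batch,
    ksg_cmi_kernel,
    msr_batch_kernel,
    nn_predict_kernel,
)
from .config import NUEConfig
from .embedding import CandidateVariable, build_candidate_set, lagged_design, present_column
from .estimators import aic_score, psi_table

__all__ = [
    "IterationRecord",
    "EmbeddingSelection",
    "standardize",
    "run_nue",
    "select_candidate_cmi",
    "select_candidate_la",
    "select_candidate_msr",
    "bootstrap_threshold",
    "selection_for_gamma",
]

_JITTER_STREAM = 1
_BOOTSTRAP_STREAM = 2


@dataclass(frozen=True)
class IterationRecord:
    """One tested iteration of the greedy search (accepted or not).

    ``criterion`` is the winning candidate's ranking value; ``msr`` the mean
    squared residual of predicting the target from the selected block plus the
    winner; ``threshold`` the value the acceptance rule compared against
    (previous MSR, shuffle percentile, or previous AIC — NaN when the rule did
    not apply); ``aic`` the winner's AIC for the aic variant.
    """

    iteration: int
    candidate: CandidateVariable
    criterion: float
    msr: float
    threshold: float
    accepted: bool
    aic: float = float("nan")


@dataclass(frozen=True)
class EmbeddingSelection:
    """Result of a non-uniform embedding run for one target channel."""

    target: int
    selected: List[CandidateVariable]
    trace: List[IterationRecord]
    termination_reason: str
    max_lag: int

    @property
    def n_iterations(self) -> int:
        """Iterations performed, counting a final rejected test."""
        return len(self.trace)

    @property
    def msr_trace(self) -> np.ndarray:
        return np.array([e.msr for e in self.trace])


def standardize(data) -> np.ndarray:
    """Scale every channel to zero mean and unit (population) variance."""
    data = np.asarray(data, dtype=np.float64)
    if data.ndim != 2:
        raise ValueError("expected an N x L matrix")
    mean = data.mean(axis=0)
    std = data.std(axis=0)
    dead = np.flatnonzero(std == 0.0)
    if dead.size:
        raise ValueError(f"constant channel(s) cannot be standardized: {dead.tolist()}")
    return (data - mean) / std


class _Workspace:
    """Jittered, lag-aligned view of one target's candidate pool."""

    def __init__(self, data, target: int, cfg: NUEConfig):
        data = np.asarray(data, dtype=np.float64)
        if data.ndim != 2:
            raise ValueError("expected an N x L matrix")
        n, L = data.shape
        if not 0 <= target < L:
            raise ValueError(f"target {target} out of range for L={L}")
        max_lag = cfg.max_lag
        if n - max_lag <= cfg.T + 1:
            raise ValueError(
                f"record too short: N={n} with max lag {max_lag} leaves "
                f"{n - max_lag} aligned samples for T={cfg.T} neighbors"
            )
        self.cfg = cfg
        self.ncfg = cfg.effective_neighbor()
        self.target = target
        self.cands = build_candidate_set(L, cfg.m, cfg.d)
        self.n_eff = n - max_lag
        self.ncfg.validate_for(self.n_eff)

        X = lagged_design(data, self.cands, max_lag)
        y = present_column(data, target, max_lag)
        # Tie-breaking jitter, one stream for the whole pool: target column
        # first, then candidates in pool order, so public per-step calls see
        # exactly what run_nue sees.
        if self.ncfg.jitter_seed is not None:
            rng = np.random.default_rng([cfg.seed, _JITTER_STREAM])
            y = y + self._draw(rng, y)
            X = X.copy()
            for c in range(X.shape[1]):
                X[:, c] += self._draw(rng, X[:, c])
        self.y = y
        self.y2d = np.ascontiguousarray(y[:, None])
        self.Xt = np.ascontiguousarray(X.T)
        self.psi = psi_table(self.n_eff)

    def _draw(self, rng, col: np.ndarray) -> np.ndarray:
        sd = float(col.std())
        scale = self.ncfg.jitter_scale * (sd if sd > 0.0 else 1.0)
        return (rng.random(col.shape[0]) * 2.0 - 1.0) * scale

    # -- block assembly -------------------------------------------------
    def col2d(self, ci: int) -> np.ndarray:
        return self.Xt[ci][:, None]

    def block(self, idx: Sequence[int]) -> np.ndarray:
        if not idx:
            return np.empty((self.n_eff, 0))
        return np.column_stack([self.Xt[i] for i in idx])

    # -- primitive estimates --------------------------------------------
    def cmi(self, w: np.ndarray, cond: np.ndarray, y: Optional[np.ndarray] = None) -> float:
        yb = self.y2d if y is None else y
        return float(
            ksg_cmi_kernel(w, yb, cond, self.ncfg.T, self.ncfg.theiler_window, self.psi)
        )

    def msr(self, idx: Sequence[int]) -> float:
        u = self.block(idx)
        preds = nn_predict_kernel(
            u,
            self.y,
            self.ncfg.T,
            self.ncfg.theiler_window,
            self.ncfg.exclude_self,
            self.ncfg.metric == "max_norm",
        )
        r = self.y - preds
        return float(np.mean(r * r))

    # -- selection criteria ---------------------------------------------
    def _rows(self, remaining: Sequence[int]) -> np.ndarray:
        return self.Xt[np.asarray(remaining, dtype=np.intp)]

    def select_cmi(self, remaining: Sequence[int], cond: np.ndarray) -> Tuple[int, float]:
        vals = cmi_select_batch(
            self._rows(remaining), self.y, cond,
            self.ncfg.T, self.ncfg.theiler_window, self.psi,
        )
        pos = int(np.argmax(vals))  # argmax keeps the first of tied maxima
        return pos, float(vals[pos])

    def select_msr(
        self, remaining: Sequence[int], selected: Sequence[int], cond: np.ndarray
    ) -> Tuple[int, float, float]:
        """Returns (position, criterion, winner's MSR — NaN when lambda=0)."""
        lam = self.cfg.lambda_weight
        if lam > 0.0:
            msr_vals = msr_batch_kernel(
                self._rows(remaining), self.y, cond,
                self.ncfg.T, self.ncfg.theiler_window, self.ncfg.exclude_self,
            )
        if lam < 1.0:
            cmi_vals = cmi_select_batch(
                self._rows(remaining), self.y, cond,
                self.ncfg.T, self.ncfg.theiler_window, self.psi,
            )
        if lam == 0.0:
            vals, msr_vals = cmi_vals, None
        elif lam == 1.0:
            vals = -msr_vals
        else:
            vals = (1.0 - lam) * cmi_vals - lam * msr_vals
        pos = int(np.argmax(vals))
        win_msr = float(msr_vals[pos]) if msr_vals is not None else np.nan
        return pos, float(vals[pos]), win_msr

    def la_criterion(
        self, ci: int, selected: Sequence[int], cache: Dict[tuple, float]
    ) -> float:
        key = ("mi_y", ci)
        if key not in cache:
            cache[key] = self.cmi(self.col2d(ci), self._EMPTY)
        value = cache[key]
        if selected:
            red = 0.0
            syn = 0.0
            for sj in selected:
                kp = ("pair", ci, sj)
                if kp not in cache:
                    wj = self.col2d(sj)
                    cache[kp] = (
                        float(
                            ksg_cmi_kernel(
                                self.col2d(ci), wj, self._EMPTY,
                                self.ncfg.T, self.ncfg.theiler_window, self.psi,
                            )
                        ),
                        float(
                            ksg_cmi_kernel(
                                self.col2d(ci), wj, self.y2d,
                                self.ncfg.T, self.ncfg.theiler_window, self.psi,
                            )
                        ),
                    )
                mi_ww, cmi_wwy = cache[kp]
                red += mi_ww
                syn += cmi_wwy
            value += (2.0 / len(selected)) * (syn - red)
        return value

    def select_la(
        self, remaining: Sequence[int], selected: Sequence[int], cache: Dict[tuple, float]
    ) -> Tuple[int, float]:
        best_pos, best = 0, -np.inf
        for pos, ci in enumerate(remaining):
            v = self.la_criterion(ci, selected, cache)
            if v > best:
                best_pos, best = pos, v
        return best_pos, best

    # -- shuffle threshold -----------------------------------------------
    def bootstrap_i95(self, wi: int, selected: Sequence[int], iteration: int) -> float:
        """Percentile of the criterion under independent row shuffles of the
        winner column and the target (conditioning columns untouched)."""
        cfg = self.cfg
        ncfg = self.ncfg
        rng = np.random.default_rng([cfg.seed, _BOOTSTRAP_STREAM, self.target, iteration])
        n = self.n_eff
        B = cfg.bootstrap_size
        w = self.Xt[wi]
        Wp = np.empty((B, n))
        Yp = np.empty((B, n))
        for b in range(B):
            Wp[b] = w[rng.permutation(n)]
            Yp[b] = self.y[rng.permutation(n)]
        no_zx = np.empty((0, n))
        if cfg.variant == "la":
            vals = cmi_perm_batch(Wp, Yp, no_zx, self._EMPTY,
                                  ncfg.T, ncfg.theiler_window, self.psi)
            if selected:
                red = np.zeros(B)
                syn = np.zeros(B)
                for sj in selected:
                    wj = self.Xt[sj]
                    red += cmi_select_batch(Wp, wj, self._EMPTY,
                                            ncfg.T, ncfg.theiler_window, self.psi)
                    syn += cmi_perm_batch(Wp, wj[None, :], Yp, self._EMPTY,
                                          ncfg.T, ncfg.theiler_window, self.psi)
                vals = vals + (2.0 / len(selected)) * (syn - red)
        else:
            vals = cmi_perm_batch(Wp, Yp, no_zx, self.block(selected),
                                  ncfg.T, ncfg.theiler_window, self.psi)
        return float(np.percentile(vals, cfg.bootstrap_level))

    @property
    def _EMPTY(self) -> np.ndarray:
        return np.empty((self.n_eff, 0))

    def to_indices(self, cands: Sequence[CandidateVariable]) -> List[int]:
        lookup = {c: i for i, c in enumerate(self.cands)}
        try:
            return [lookup[CandidateVariable(*c)] for c in cands]
        except KeyError as err:
            raise ValueError(f"candidate {err.args[0]} not in the pool") from None


def run_nue(data, target: int, cfg: Optional[NUEConfig] = None) -> EmbeddingSelection:
    """Run the greedy non-uniform embedding search for one target channel.

    ``data`` is an N x L matrix, standardized per channel (see
    :func:`standardize`); standardization is what makes the ``msr`` variant's
    information and prediction terms commensurable and gives ``gamma`` its
    units.  Returns the ordered selection with a full per-iteration trace,
    including the final rejected test when a rule fired.
    """
    cfg = cfg or NUEConfig()
    ws = _Workspace(data, target, cfg)
    selected: List[int] = []
    remaining = list(range(len(ws.cands)))
    trace: List[IterationRecord] = []
    termination = "candidates_exhausted"
    msr_prev = np.nan
    aic_prev = np.nan
    la_cache: Dict[tuple, float] = {}
    k = 0
    while remaining:
        k += 1
        cond = ws.block(selected)
        aic_k = np.nan
        if cfg.variant == "msr":
            pos, crit, msr_w = ws.select_msr(remaining, selected, cond)
            wi = remaining[pos]
            if np.isnan(msr_w):  # lambda = 0: criterion never touched the MSR
                msr_w = ws.msr(selected + [wi])
            if k == 1:
                accepted, threshold = True, np.nan
            else:
                threshold = msr_prev
                accepted = (msr_prev - msr_w) > cfg.gamma
            reason = "msr_no_improvement"
        elif cfg.variant in ("bootstrap", "la"):
            if cfg.variant == "bootstrap":
                pos, crit = ws.select_cmi(remaining, cond)
            else:
                pos, crit = ws.select_la(remaining, selected, la_cache)
            wi = remaining[pos]
            threshold = ws.bootstrap_i95(wi, selected, k)
            accepted = crit > threshold
            msr_w = ws.msr(selected + [wi])
            reason = "bootstrap_nonsignificant"
        else:  # aic
            pos, crit = ws.select_cmi(remaining, cond)
            wi = remaining[pos]
            u = ws.block(selected + [wi])
            aic_k = aic_score(u, ws.y)
            if k == 1:
                accepted, threshold = True, np.nan
            else:
                threshold = aic_prev
                if cfg.aic_literal_direction:
                    accepted = aic_k > aic_prev
                else:
                    accepted = aic_k < aic_prev
            msr_w = ws.msr(selected + [wi])
            reason = "aic_no_improvement"

        trace.append(
            IterationRecord(k, ws.cands[wi], float(crit), float(msr_w),
                            float(threshold), bool(accepted), float(aic_k))
        )
        if not accepted:
            termination = reason
            break
        selected.append(wi)
        remaining.remove(wi)
        msr_prev = msr_w
        aic_prev = aic_k
    return EmbeddingSelection(
        target=target,
        selected=[ws.cands[i] for i in selected],
        trace=trace,
        termination_reason=termination,
        max_lag=cfg.max_lag,
    )


# ---------------------------------------------------------------------------
# single-step public entry points (mirror run_nue's internals exactly)
# ---------------------------------------------------------------------------

def _step_workspace(data, target, S, C_remaining, cfg):
    ws = _Workspace(data, target, cfg)
    sel = ws.to_indices(S)
    if C_remaining is None:
        rem = [i for i in range(len(ws.cands)) if i not in set(sel)]
    else:
        rem = ws.to_indices(C_remaining)
        if not rem:
            raise ValueError("C_remaining must not be empty")
    return ws, sel, rem


def select_candidate_cmi(data, target, S, C_remaining, cfg) -> Tuple[CandidateVariable, float]:
    """Best remaining candidate by I(candidate; target | selected block)."""
    ws, sel, rem = _step_workspace(data, target, S, C_remaining, cfg)
    pos, crit = ws.select_cmi(rem, ws.block(sel))
    return ws.cands[rem[pos]], crit


def select_candidate_la(data, target, S, C_remaining, cfg) -> Tuple[CandidateVariable, float]:
    """Best remaining candidate by the low-dimensional CMI approximation."""
    ws, sel, rem = _step_workspace(data, target, S, C_remaining, cfg)
    pos, crit = ws.select_la(rem, sel, {})
    return ws.cands[rem[pos]], crit


def select_candidate_msr(data, target, S, C_remaining, cfg) -> Tuple[CandidateVariable, float]:
    """Best remaining candidate by the weighted CMI/MSR criterion."""
    ws, sel, rem = _step_workspace(data, target, S, C_remaining, cfg)
    pos, crit, _ = ws.select_msr(rem, sel, ws.block(sel))
    return ws.cands[rem[pos]], crit


def bootstrap_threshold(winner, data, target, S, cfg) -> float:
    """Shuffle-percentile acceptance threshold for a tested winner.

    Draws ``cfg.bootstrap_size`` independent row permutations of the winner
    column and of the target, re-estimates the selection criterion on each,
    and returns the ``cfg.bootstrap_level`` percentile (linear interpolation).
    Deterministic given ``cfg.seed``, the target and the iteration index
    (``len(S) + 1``).
    """
    ws = _Workspace(data, target, cfg)
    sel = ws.to_indices(S)
    (wi,) = ws.to_indices([winner])
    return ws.bootstrap_i95(wi, sel, len(sel) + 1)


def selection_for_gamma(selection: EmbeddingSelection, gamma: float) -> Tuple[List[CandidateVariable], int]:
    """Re-derive an ``msr``-variant selection for a stricter ``gamma``.

    The greedy path does not depend on ``gamma`` — the threshold only decides
    where it stops — so a run recorded at ``gamma = 0`` determines the
    selection for every larger ``gamma`` exactly: keep the forced first
    winner, then accept while the recorded MSR improvement exceeds ``gamma``.
    Returns the selected candidates and the number of iterations performed
    (counting the rejected final test).
    """
    trace = selection.trace
    if not trace:
        return [], 0
    chosen = [trace[0].candidate]
    prev = trace[0].msr
    iters = 1
    for entry in trace[1:]:
        iters += 1
        if prev - entry.msr > gamma:
            chosen.append(entry.candidate)
            prev = entry.msr
        else:
            return chosen, iters
    return chosen, iters
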