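"""Candidate variables and lag-aligned design matrices.

A candidate is a (process, lag) pair: "channel ``process`` observed ``lag``
samples before the target's present".  The candidate pool for an L-channel
record with embedding delay ``m`` and dimension ``d`` holds the lags
``m, 2m, ..., d*m`` of every channel, the target's own past included.
"""

from __future__ import annotations

from typing import List, NamedTuple, Sequence

import numpy as np


class CandidateVariable(NamedTuple):
    process: int
    lag: int


def build_candidate_set(L: int, m: int, d: int) -> List[CandidateVariable]:
    """All L*d candidates in deterministic process-major, lag-minor order."""
    if L < 2:
        raise ValueError("need at least two channels")
    if m < 1 or d < 1:
        raise ValueError("m and d must be positive integers")
    return [
        CandidateVariable(p, lag * m)
        for p in range(L)
        for lag in range(1, d + 1)
    ]


def lagged_design(
    data: np.ndarray,
    candidates: Sequence[CandidateVariable],
    max_lag: int,
) -> np.ndarray:
    """Aligned realization matrix of the given candidates.

    The first ``max_lag`` rows of the record are dropped so that every lagged
    column shares the same time support as the target's present; the result
    has ``N - max_lag`` rows and one column per candidate.
    """
    data = np.asarray(data, dtype=np.float64)
    n, L = data.shape
    if max_lag >= n:
        raise ValueError("max_lag must be smaller than the record length")
    for c in candidates:
        if not 1 <= c.lag <= max_lag:
            raise ValueError(f"candidate lag {c.lag} outside [1, {max_lag}]")
        if not 0 <= c.process < L:
            raise ValueError(f"candidate process {c.process} outside [0, {L})")
    cols = [data[max_lag - c.lag : n - c.lag, c.process] for c in candidates]
    if not cols:
        return np.empty((n - max_lag, 0))
    return np.column_stack(cols)


def present_column(data: np.ndarray, target: int, max_lag: int) -> np.ndarray:
    """The target channel's present, aligned with :func:`lagged_design`."""
    data = np.asarray(data, dtype=np.float64)
    return np.ascontiguousarray(data[max_lag:, target])
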