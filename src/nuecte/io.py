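"""Delimited-text I/O and run manifests.

CSV dialect: comma-separated, UTF-8, one header row of channel names, one
column per channel, '.' decimal, no index column.  Floats are written with 17
significant digits so a written matrix re-reads bit-identically.
"""

from __future__ import annotations

import json
import platform
from datetime import datetime, timezone
from pathlib import Path
from typing import List, Optional, Tuple

import numpy as np
import pandas as pd


def default_channel_names(L: int) -> List[str]:
    return [f"ch{i + 1}" for i in range(L)]


def save_timeseries(path, data: np.ndarray, channels: Optional[List[str]] = None) -> None:
    data = np.asarray(data, dtype=np.float64)
    if data.ndim != 2:
        raise ValueError("expected an N x L matrix")
    channels = channels or default_channel_names(data.shape[1])
    if len(channels) != data.shape[1]:
        raise ValueError("channel name count does not match column count")
    frame = pd.DataFrame(data, columns=channels)
    frame.to_csv(path, index=False, float_format="%.17g")


def load_timeseries(path) -> Tuple[np.ndarray, List[str]]:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"input file not found: {path}")
    frame = pd.read_csv(path, float_precision="round_trip")
    data = frame.to_numpy(dtype=np.float64)
    if data.ndim != 2 or data.shape[1] < 2:
        raise ValueError(f"{path}: expected at least two numeric channel columns")
    return data, list(frame.columns)


def save_adjacency(path, adjacency: np.ndarray, channels: List[str]) -> None:
    frame = pd.DataFrame(np.asarray(adjacency), index=channels, columns=channels)
    frame.to_csv(path, index=True, index_label="driver")


def save_matrix(path, matrix: np.ndarray, channels: List[str]) -> None:
    frame = pd.DataFrame(np.asarray(matrix, dtype=np.float64), index=channels, columns=channels)
    frame.to_csv(path, index=True, index_label="driver", float_format="%.17g")


def write_manifest(path, *, command: str, config: dict, seeds: dict,
                   inputs: Optional[dict] = None, outputs: Optional[dict] = None) -> None:
    """Record everything needed to re-run a result bit-identically."""
    from . import __version__

    manifest = {
        "tool": "nuecte",
        "version": __version__,
        "command": command,
        "timestamp": datetime.now(timezone.utc).isoformat(),
        "python": platform.python_version(),
        "config": config,
        "seeds": seeds,
        "inputs": inputs or {},
        "outputs": outputs or {},
    }
    Path(path).write_text(json.dumps(manifest, indent=2, default=str) + "\n")


def selection_to_dict(selection) -> dict:
    return {
        "target": selection.target,
        "selected": [[c.process, c.lag] for c in selection.selected],
        "termination_reason": selection.termination_reason,
        "max_lag": selection.max_lag,
        "trace": [
            {
                "iteration": e.iteration,
                "candidate": [e.candidate.process, e.candidate.lag],
                "criterion": e.criterion,
                "msr": e.msr,
                "threshold": e.threshold,
                "accepted": e.accepted,
                "aic": e.aic,
            }
            for e in selection.trace
        ],
    }
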