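"""Configuration objects shared across estimators, embedding search and evaluation."""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

#: NUE variants: weighted CMI/MSR ranking with the prediction-improvement stop
#: ("msr"), CMI ranking with a shuffle-percentile stop ("bootstrap"), the
#: low-dimensional approximation of the CMI with the same stop ("la"), and CMI
#: ranking with a KDE-regression AIC stop ("aic").
VARIANTS = ("msr", "bootstrap", "la", "aic")

METRICS = ("euclidean", "max_norm")


@dataclass(frozen=True)
class NeighborConfig:
    """Settings for k-nearest-neighbor searches.

    Parameters
    ----------
    T : int
        Number of neighbors.
    metric : str
        ``"euclidean"`` or ``"max_norm"``; applies to nearest-neighbor
        prediction.  KSG information estimates always use the max norm in the
        joint space, per the standard construction.
    theiler_window : int
        Samples ``|i - j| <= theiler_window`` are excluded from the neighbor
        candidates of query ``i`` (autocorrelation guard; 0 disables).
    exclude_self : bool
        Whether a point may be its own neighbor in prediction searches.  KSG
        searches always exclude the query point.
    ksg_algorithm : int
        KSG estimator flavor.  Only algorithm 1 (max-norm joint space,
        strict-inequality range counts) is implemented; the field exists so a
        second flavor can be added without breaking configs.
    jitter_seed : int or None
        Seed for the deterministic tie-breaking jitter added to every column
        before any neighbor search (``None`` disables jitter).  Degenerate
        (exactly repeated) distances break the KSG neighbor counts, so a
        vanishing seeded perturbation is applied by default.
    jitter_scale : float
        Jitter amplitude as a fraction of each column's standard deviation.
    """

    T: int = 10
    metric: str = "euclidean"
    theiler_window: int = 0
    exclude_self: bool = True
    ksg_algorithm: int = 1
    jitter_seed: Optional[int] = 0
    jitter_scale: float = 1e-10

    def __post_init__(self) -> None:
        if self.T < 1:
            raise ValueError("T must be a positive integer")
        if self.ksg_algorithm != 1:
            raise ValueError("only KSG algorithm 1 is implemented")
        if self.metric not in METRICS:
            raise ValueError(f"metric must be one of {METRICS}")
        if self.theiler_window < 0:
            raise ValueError("theiler_window must be non-negative")

    def validate_for(self, n: int) -> None:
        """Check that ``T`` neighbors exist for ``n`` aligned samples."""
        excluded = 1 + 2 * self.theiler_window
        if self.T >= n - excluded + 1:
            raise ValueError(
                f"T={self.T} infeasible for N={n} with "
                f"theiler_window={self.theiler_window}"
            )


@dataclass(frozen=True)
class NUEConfig:
    """Knobs of the non-uniform embedding search.

    ``m`` and ``d`` are the embedding delay and dimension: the candidate pool
    holds lags ``m, 2m, ..., d*m`` of every channel.  ``lambda_weight``
    interpolates between pure conditional-mutual-information ranking (0) and
    pure prediction-error ranking (1); ``gamma`` is the minimum mean-squared
    -residual improvement (in units of the standardized target's variance)
    required to accept a candidate.  ``bootstrap_size``/``bootstrap_level``
    parameterize the shuffle test used by the bootstrap and LA variants.
    """

    variant: str = "msr"
    m: int = 1
    d: int = 5
    T: int = 10
    lambda_weight: float = 1.0
    gamma: float = 0.0
    bootstrap_size: int = 100
    bootstrap_level: float = 95.0
    seed: int = 0
    neighbor: NeighborConfig = field(default_factory=NeighborConfig)
    # The printed AIC rule ("include if AIC_k > AIC_{k-1}") rewards worse
    # trade-offs; the default accepts when AIC decreases.  Set True to apply
    # the literal rule.
    aic_literal_direction: bool = False

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise ValueError(f"variant must be one of {VARIANTS}")
        if self.m < 1 or self.d < 1:
            raise ValueError("m and d must be positive integers")
        if not 0.0 <= self.lambda_weight <= 1.0:
            raise ValueError("lambda_weight must lie in [0, 1]")
        if self.gamma < 0.0:
            raise ValueError("gamma must be non-negative")
        if self.bootstrap_size < 1:
            raise ValueError("bootstrap_size must be >= 1")
        if not 0.0 < self.bootstrap_level <= 100.0:
            raise ValueError("bootstrap_level must lie in (0, 100]")

    @property
    def max_lag(self) -> int:
        return self.d * self.m

    def effective_neighbor(self) -> NeighborConfig:
        """Neighbor settings with this config's ``T`` substituted in."""
        return replace(self.neighbor, T=self.T)
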