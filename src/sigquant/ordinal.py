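"""Bandt-Pompe ordinal symbolization of real-valued time series.

A window of ``D`` samples spaced ``tau`` apart is mapped to the permutation
that sorts it ascending (its *ordinal pattern*); sliding the window over the
whole series and histogramming the ``D!`` possible patterns yields a
probability distribution that is invariant under monotone rescaling of the
amplitudes and sensitive only to the time ordering of the data.

Conventions frozen here (and relied upon downstream):

* ties are broken by ascending temporal index (stable sort), so the map is
  deterministic on any input;
* patterns are indexed by the lexicographic rank of the sorting permutation
  (identity pattern has rank 0).  The Fisher information measure depends on
  this bin ordering, which is why it is fixed once, here.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

logger = logging.getLogger(__name__)

DEFAULT_DIMENSION = 5
DEFAULT_LAG = 1

__all__ = [
    "DEFAULT_DIMENSION",
    "DEFAULT_LAG",
    "OrdinalConfig",
    "OrdinalDistribution",
    "ordinal_pattern",
    "pattern_rank",
    "bandt_pompe_distribution",
    "uniform_distribution",
]


@dataclass(frozen=True)
class OrdinalConfig:
    """Embedding dimension ``D`` and time lag ``tau`` of the symbolization.

    The defaults, D = 5 and tau = 1, give 120 pattern bins -- coarse enough
    that a 5000-sample trajectory populates them well, fine enough to
    discriminate writing dynamics.
    """

    dimension: int = DEFAULT_DIMENSION
    lag: int = DEFAULT_LAG

    def __post_init__(self) -> None:
        if int(self.dimension) != self.dimension or self.dimension < 2:
            raise ValueError(f"embedding dimension must be an integer >= 2, got {self.dimension}")
        if int(self.lag) != self.lag or self.lag < 1:
            raise ValueError(f"time lag must be an integer >= 1, got {self.lag}")

    @property
    def n_patterns(self) -> int:
        """Number of histogram bins, D!."""
        return math.factorial(self.dimension)


@dataclass(frozen=True)
class OrdinalDistribution:
    """Probability vector over the ``D!`` ordinal patterns of one series.

    ``probabilities[r]`` is the relative frequency of the pattern whose
    sorting permutation has lexicographic rank ``r``.
    """

    dimension: int
    lag: int
    probabilities: np.ndarray
    window_count: int

    def __post_init__(self) -> None:
        p = np.asarray(self.probabilities, dtype=float)
        object.__setattr__(self, "probabilities", p)
        if p.ndim != 1 or len(p) != math.factorial(self.dimension):
            raise ValueError(
                f"expected {math.factorial(self.dimension)} probabilities for D={self.dimension}, got {p.shape}"
            )
        if np.any(p < 0) or not math.isclose(p.sum(), 1.0, abs_tol=1e-12):
            raise ValueError("probabilities must be non-negative and sum to 1")

    @property
    def n_patterns(self) -> int:
        return len(self.probabilities)


def _as_series(values) -> np.ndarray:
    x = np.asarray(values, dtype=float)
    if x.ndim != 1:
        raise ValueError(f"expected a one-dimensional series, got shape {x.shape}")
    if not np.all(np.isfinite(x)):
        raise ValueError("series contains non-finite values")
    return x


def ordinal_pattern(window) -> np.ndarray:
    """Permutation ``pi`` such that ``window[pi[0]] <= ... <= window[pi[D-1]]``.

    Ties are broken by ascending temporal index (stable sort), so equal
    values keep their original order.
    """
    w = _as_series(window)
    if len(w) < 2:
        raise ValueError("a window needs at least 2 samples")
    return np.argsort(w, kind="stable")


def pattern_rank(pi) -> int:
    """Lexicographic rank of a permutation of ``0..D-1`` (identity -> 0)."""
    perm = np.asarray(pi)
    d = len(perm)
    if sorted(perm.tolist()) != list(range(d)):
        raise ValueError(f"{perm.tolist()} is not a permutation of 0..{d - 1}")
    rank = 0
    for j in range(d - 1):
        smaller_later = int(np.sum(perm[j + 1 :] < perm[j]))
        rank += smaller_later * math.factorial(d - 1 - j)
    return rank


def _lexicographic_ranks(perms: np.ndarray) -> np.ndarray:
    """Vectorized lexicographic rank of each row of an array of permutations."""
    n, d = perms.shape
    ranks = np.zeros(n, dtype=np.int64)
    for j in range(d - 1):
        smaller_later = (perms[:, j + 1 :] < perms[:, j : j + 1]).sum(axis=1)
        ranks += smaller_later * math.factorial(d - 1 - j)
    return ranks


def bandt_pompe_distribution(series, config: OrdinalConfig | None = None) -> OrdinalDistribution:
    """Ordinal-pattern probability distribution of ``series``.

    All ``len(series) - (D-1)*tau`` overlapping windows (stride 1) are
    symbolized and histogrammed; counts are normalized by the window count.
    """
    cfg = config or OrdinalConfig()
    x = _as_series(series)
    d, tau = cfg.dimension, cfg.lag
    span = (d - 1) * tau + 1
    if len(x) < span:
        raise ValueError(
            f"series of length {len(x)} too short for D={d}, tau={tau} (needs >= {span})"
        )
    n_bins = cfg.n_patterns
    windows = sliding_window_view(x, span)[:, ::tau]
    window_count = len(windows)
    if window_count < 10 * n_bins:
        logger.warning(
            "only %d windows for %d pattern bins (D=%d); histogram may be undersampled",
            window_count,
            n_bins,
            d,
        )
    perms = np.argsort(windows, axis=1, kind="stable")
    ranks = _lexicographic_ranks(perms)
    counts = np.bincount(ranks, minlength=n_bins)
    return OrdinalDistribution(
        dimension=d,
        lag=tau,
        probabilities=counts / window_count,
        window_count=window_count,
    )


def uniform_distribution(dimension: int, lag: int = 1) -> OrdinalDistribution:
    """Equilibrium reference distribution: all ``D!`` patterns equiprobable."""
    cfg = OrdinalConfig(dimension=dimension, lag=lag)
    n = cfg.n_patterns
    return OrdinalDistribution(
        dimension=dimension, lag=lag, probabilities=np.full(n, 1.0 / n), window_count=0
    )
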