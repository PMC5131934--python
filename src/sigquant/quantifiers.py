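"""Information-theory quantifiers of ordinal distributions.

Three quantifiers summarize an ordinal-pattern distribution P over N = D!
bins (natural logarithms throughout):

* normalized permutation Shannon entropy ``H[P] = S[P] / ln N``, a global
  measure of randomness of the writing dynamics;
* MPR statistical complexity ``C[P] = Q_J[P, P_e] * H[P]``, where
  ``Q_J = J[P, P_e] / J_max`` is the Jensen-Shannon disequilibrium from the
  uniform distribution ``P_e``; C vanishes at both entropy extremes and
  peaks for structured-but-not-trivial dynamics;
* discrete Fisher information measure
  ``F[P] = F0 * sum_i (sqrt(p_{i+1}) - sqrt(p_i))^2``, a local quantifier
  sensitive to the (frozen, lexicographic) bin ordering; ``F0 = 1`` when P
  is a delta on the first or last bin, else ``F0 = 1/2``, which normalizes
  F into [0, 1].

A signature contributes one quantifier triple per pen coordinate, giving
the 6-D feature vector (H_X, H_Y, C_X, C_Y, F_X, F_Y).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .ordinal import OrdinalConfig, OrdinalDistribution, bandt_pompe_distribution

GENUINE = "G"
FORGERY = "F"

#: column order of the feature table / CSV export
FEATURE_COLUMNS = ("h_x", "h_y", "c_x", "c_y", "f_x", "f_y")
ID_COLUMNS = ("subject_id", "signature_id", "authenticity")

__all__ = [
    "GENUINE",
    "FORGERY",
    "FEATURE_COLUMNS",
    "ID_COLUMNS",
    "QuantifierVector",
    "shannon_entropy",
    "jensen_shannon_divergence",
    "max_disequilibrium",
    "statistical_complexity",
    "fisher_information",
    "quantifier_vector",
    "extract_features",
    "write_features",
    "read_features",
]


def _probs(dist) -> np.ndarray:
    """Accept an OrdinalDistribution or a bare probability vector."""
    if isinstance(dist, OrdinalDistribution):
        return dist.probabilities
    p = np.asarray(dist, dtype=float)
    if p.ndim != 1:
        raise ValueError("probability vector must be one-dimensional")
    if np.any(p < 0) or not math.isclose(p.sum(), 1.0, abs_tol=1e-9):
        raise ValueError("probabilities must be non-negative and sum to 1")
    return p


def _raw_entropy(p: np.ndarray) -> float:
    # 0 * ln 0 := 0
    nz = p[p > 0]
    return float(-np.sum(nz * np.log(nz)))


def shannon_entropy(dist, normalized: bool = True) -> float:
    """Shannon entropy ``S[P] = -sum p ln p``; normalized by ``ln N`` if asked."""
    p = _probs(dist)
    s = _raw_entropy(p)
    if not normalized:
        return s
    return s / math.log(len(p))


def jensen_shannon_divergence(p_dist, q_dist) -> float:
    """Jensen-Shannon divergence ``J[P,Q] = S[(P+Q)/2] - S[P]/2 - S[Q]/2``.

    Raw (unnormalized) entropy form; symmetric, bounded, zero iff P = Q.
    """
    p = _probs(p_dist)
    q = _probs(q_dist)
    if len(p) != len(q):
        raise ValueError(f"distributions have different sizes: {len(p)} vs {len(q)}")
    return _raw_entropy((p + q) / 2.0) - 0.5 * _raw_entropy(p) - 0.5 * _raw_entropy(q)


def max_disequilibrium(n: int) -> float:
    """Largest possible J[P, P_e] over N bins (P a delta, P_e uniform).

    ``J_max = -1/2 [ ((N+1)/N) ln(N+1) - 2 ln(2N) + ln N ]``
    """
    if n < 2:
        raise ValueError("need at least 2 bins")
    return -0.5 * (((n + 1) / n) * math.log(n + 1) - 2 * math.log(2 * n) + math.log(n))


def statistical_complexity(dist) -> float:
    """MPR statistical complexity ``C[P] = (J[P, P_e]/J_max) * H[P]``."""
    p = _probs(dist)
    n = len(p)
    p_e = np.full(n, 1.0 / n)
    q_j = jensen_shannon_divergence(p, p_e) / max_disequilibrium(n)
    return q_j * shannon_entropy(p, normalized=True)


def fisher_information(dist) -> float:
    """Discrete normalized Fisher information measure of ``P``.

    ``F[P] = F0 * sum_{i=1}^{N-1} (sqrt(p_{i+1}) - sqrt(p_i))^2`` with the
    endpoint convention ``F0 = 1`` if P is a delta on the first or last bin,
    else ``F0 = 1/2``.  Bin order is the lexicographic pattern rank frozen
    in :mod:`sigquant.ordinal`; unlike H and C, F depends on it.
    """
    p = _probs(dist)
    amp = np.sqrt(p)
    total = float(np.sum(np.diff(amp) ** 2))
    f0 = 1.0 if (p[0] >= 1.0 - 1e-12 or p[-1] >= 1.0 - 1e-12) else 0.5
    return f0 * total


@dataclass(frozen=True)
class QuantifierVector:
    """The six per-signature features (entropy, complexity, Fisher; X and Y)."""

    h_x: float
    h_y: float
    c_x: float
    c_y: float
    f_x: float
    f_y: float

    def as_array(self) -> np.ndarray:
        return np.array([self.h_x, self.h_y, self.c_x, self.c_y, self.f_x, self.f_y])


def quantifier_vector(trajectory, config: OrdinalConfig | None = None) -> QuantifierVector:
    """Compute (H_X, H_Y, C_X, C_Y, F_X, F_Y) of a preprocessed trajectory.

    ``trajectory`` is anything with ``x`` and ``y`` series attributes
    (normally a :class:`sigquant.preprocess.Trajectory`).
    """
    cfg = config or OrdinalConfig()
    p_x = bandt_pompe_distribution(trajectory.x, cfg)
    p_y = bandt_pompe_distribution(trajectory.y, cfg)
    return QuantifierVector(
        h_x=shannon_entropy(p_x),
        h_y=shannon_entropy(p_y),
        c_x=statistical_complexity(p_x),
        c_y=statistical_complexity(p_y),
        f_x=fisher_information(p_x),
        f_y=fisher_information(p_y),
    )


def extract_features(
    signatures: Iterable,
    config: OrdinalConfig | None = None,
    m: int = 5000,
) -> pd.DataFrame:
    """Feature table for an iterable of raw signatures.

    Each signature is rescaled to the unit square, resampled to ``m``
    points and symbolized; the result has one row per signature with the
    identity columns and the six quantifiers.
    """
    from .preprocess import preprocess  # deferred: avoids import cycle

    cfg = config or OrdinalConfig()
    rows = []
    for sig in signatures:
        traj = preprocess(sig, m=m)
        qv = quantifier_vector(traj, cfg)
        rows.append(
            {
                "subject_id": sig.subject_id,
                "signature_id": sig.signature_id,
                "authenticity": GENUINE if sig.authenticity.startswith(("g", "G")) else FORGERY,
                **{name: getattr(qv, name) for name in FEATURE_COLUMNS},
            }
        )
    return pd.DataFrame(rows, columns=list(ID_COLUMNS) + list(FEATURE_COLUMNS))


def write_features(
    df: pd.DataFrame, path, config: OrdinalConfig | None = None, m: int | None = None
) -> None:
    """Write the feature table as CSV with a commented metadata header."""
    cfg = config or OrdinalConfig()
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# dimension={cfg.dimension} lag={cfg.lag}")
        if m is not None:
            fh.write(f" m={m}")
        fh.write("\n")
        df.to_csv(fh, index=False)


def read_features(path) -> pd.DataFrame:
    """Round-trip reader for :func:`write_features` output.

    Metadata from the comment header is attached as ``df.attrs``.
    """
    path = Path(path)
    meta: dict[str, int] = {}
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("#"):
            for tok in first[1:].split():
                key, _, val = tok.partition("=")
                if val:
                    meta[key] = int(val)
        else:
            fh.seek(0)
        df = pd.read_csv(fh, dtype={"subject_id": str, "signature_id": str})
    missing = [c for c in list(ID_COLUMNS) + list(FEATURE_COLUMNS) if c not in df.columns]
    if missing:
        raise ValueError(f"feature table {path} is missing columns: {', '.join(missing)}")
    df.attrs.update(meta)
    return df
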