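"""Per-subject signature stability (instability) indices.

Given the ordinal distributions of a subject's genuine signatures, two
indices quantify how consistently the subject signs:

* a *global* index eta based on the Jensen-Shannon divergence of the
  ensemble: ``Delta = S[mean of P_j] - mean of S[P_j]`` (raw Shannon
  entropies, equal weights).  By concavity of the entropy Delta >= 0; the
  square root of Delta is reported by default (the sqrt of the
  Jensen-Shannon divergence is a metric), with the raw divergence
  available via ``apply_sqrt=False``.
* a *local* index xi, the Jensen-Fisher divergence:
  ``mean of F[P_j] - F[mean of P_j]`` with F the discrete Fisher
  information measure.  xi is normally >= 0 but the endpoint F0
  convention can in principle produce negative values, which are logged
  and returned as-is rather than clamped.

Low indices mean a stable, characterizable writer.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .ordinal import OrdinalDistribution
from .quantifiers import fisher_information, _probs, _raw_entropy

logger = logging.getLogger(__name__)

__all__ = [
    "SubjectEnsemble",
    "InstabilityIndices",
    "js_instability",
    "jf_instability",
    "subject_instability",
    "instability_frame",
]


def _stack(dists: Sequence) -> np.ndarray:
    if len(dists) < 2:
        raise ValueError("need at least 2 distributions")
    rows = [_probs(d) for d in dists]
    sizes = {len(r) for r in rows}
    if len(sizes) != 1:
        raise ValueError(f"distributions have mismatched sizes: {sorted(sizes)}")
    return np.stack(rows)


def js_instability(dists: Sequence, apply_sqrt: bool = True, normalized: bool = False) -> float:
    """Global instability: generalized Jensen-Shannon divergence of an ensemble.

    ``Delta = S[mean P] - mean S[P]`` with equal weights; returns
    ``sqrt(Delta)`` by default.  ``normalized=True`` divides Delta by
    ``ln N`` before the optional square root.
    """
    p = _stack(dists)
    if np.all(p == p[0]):  # identical replicates: exactly zero by definition
        return 0.0
    delta = _raw_entropy(p.mean(axis=0)) - float(np.mean([_raw_entropy(row) for row in p]))
    # concavity guarantees delta >= 0; guard float round-off near zero
    if delta < 0:
        if delta < -1e-10:
            raise AssertionError(f"Jensen-Shannon instability came out negative: {delta}")
        delta = 0.0
    if normalized:
        delta /= math.log(p.shape[1])
    return math.sqrt(delta) if apply_sqrt else delta


def jf_instability(dists: Sequence) -> float:
    """Local instability: Jensen-Fisher divergence ``mean F[P] - F[mean P]``."""
    p = _stack(dists)
    if np.all(p == p[0]):
        return 0.0
    value = float(np.mean([fisher_information(row) for row in p])) - fisher_information(
        p.mean(axis=0)
    )
    if value < -1e-12:
        logger.warning(
            "Jensen-Fisher instability is negative (%.3e); possible endpoint-delta F0 effect",
            value,
        )
    return value


@dataclass
class SubjectEnsemble:
    """Ordinal distributions of one subject's genuine signatures, per coordinate."""

    subject_id: str
    distributions_x: Sequence[OrdinalDistribution]
    distributions_y: Sequence[OrdinalDistribution]

    def __post_init__(self) -> None:
        if len(self.distributions_x) != len(self.distributions_y):
            raise ValueError("X and Y ensembles must have equal counts")
        if len(self.distributions_x) < 2:
            raise ValueError("an ensemble needs at least 2 signatures")

    @property
    def count(self) -> int:
        return len(self.distributions_x)


@dataclass(frozen=True)
class InstabilityIndices:
    eta_x: float
    eta_y: float
    xi_x: float
    xi_y: float


def subject_instability(
    ensemble: SubjectEnsemble, apply_sqrt: bool = True, normalized: bool = False
) -> InstabilityIndices:
    """Global (eta) and local (xi) instability of one subject, per coordinate."""
    return InstabilityIndices(
        eta_x=js_instability(ensemble.distributions_x, apply_sqrt, normalized),
        eta_y=js_instability(ensemble.distributions_y, apply_sqrt, normalized),
        xi_x=jf_instability(ensemble.distributions_x),
        xi_y=jf_instability(ensemble.distributions_y),
    )


def instability_frame(
    ensembles: Sequence[SubjectEnsemble],
    class_labels: dict[str, str] | None = None,
    apply_sqrt: bool = True,
) -> pd.DataFrame:
    """Per-subject instability table: subject_id, class_label, eta_X/Y, xi_X/Y."""
    rows = []
    for ens in ensembles:
        idx = subject_instability(ens, apply_sqrt=apply_sqrt)
        rows.append(
            {
                "subject_id": ens.subject_id,
                "class_label": (class_labels or {}).get(ens.subject_id, ""),
                "eta_x": idx.eta_x,
                "eta_y": idx.eta_y,
                "xi_x": idx.xi_x,
                "xi_y": idx.xi_y,
            }
        )
    return pd.DataFrame(rows)
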