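"""Signature typology: clustering subjects and the parallelepiped classifier.

Subjects are summarized by the sample mean and standard deviation of their
genuine-signature quantifiers; a distance matrix over those summaries is
clustered two ways (agglomerative hierarchical clustering and
neighbor-joining), and a simple per-feature min-max box ("parallelepiped")
classifier assigns points to the resulting signature types.

Dendrogram "levels" are merge heights expressed as a percentage of the
total tree height, so a cut at, say, 25% groups the subjects whose
summaries merge within the lowest quarter of the dendrogram.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix
from skbio.tree import nj

from .quantifiers import FEATURE_COLUMNS, GENUINE, QuantifierVector

#: feature subsets selectable for clustering: one quantifier over both
#: coordinates (mean and SD of each), or all six features
QUANTIFIER_GROUPS: dict[str, tuple[str, ...]] = {
    "entropy": ("h_x", "h_y"),
    "complexity": ("c_x", "c_y"),
    "fisher": ("f_x", "f_y"),
    "all": FEATURE_COLUMNS,
}

_METRICS = {"euclidean": "euclidean", "manhattan": "cityblock", "chebyshev": "chebyshev"}

__all__ = [
    "QUANTIFIER_GROUPS",
    "FeatureSummary",
    "feature_summary",
    "summarize_subjects",
    "distance_matrix",
    "SubjectTree",
    "hierarchical_tree",
    "neighbor_joining_tree",
    "ParallelepipedModel",
    "parallelepiped_fit",
    "parallelepiped_predict",
]


@dataclass(frozen=True)
class FeatureSummary:
    """Mean and sample SD of each of the six quantifiers for one subject."""

    subject_id: str
    mean: np.ndarray  # length 6, FEATURE_COLUMNS order
    sd: np.ndarray

    def as_array(self) -> np.ndarray:
        return np.concatenate([self.mean, self.sd])


def feature_summary(subject_id: str, vectors: Sequence[QuantifierVector]) -> FeatureSummary:
    """Sample mean and SD (n-1 denominator) of a subject's quantifier vectors."""
    if len(vectors) < 2:
        raise ValueError("need at least 2 signatures to summarize a subject")
    arr = np.stack([v.as_array() for v in vectors])
    return FeatureSummary(subject_id=subject_id, mean=arr.mean(axis=0), sd=arr.std(axis=0, ddof=1))


def summarize_subjects(features: pd.DataFrame, authenticity: str = GENUINE) -> pd.DataFrame:
    """Per-subject mean/SD table from a feature table.

    Returns a frame indexed by subject_id with columns ``mean_<q>`` and
    ``sd_<q>`` for each quantifier, computed over signatures of the given
    authenticity class (genuine by default, as for the typology).
    """
    sel = features[features["authenticity"] == authenticity]
    if sel.empty:
        raise ValueError(f"no signatures with authenticity {authenticity!r}")
    counts = sel.groupby("subject_id").size()
    if (counts < 2).any():
        bad = counts[counts < 2].index.tolist()
        raise ValueError(f"subjects with fewer than 2 signatures: {bad}")
    grouped = sel.groupby("subject_id")[list(FEATURE_COLUMNS)]
    mean = grouped.mean().add_prefix("mean_")
    sd = grouped.std(ddof=1).add_prefix("sd_")
    return mean.join(sd)


def _summary_matrix(summaries: pd.DataFrame, quantifier: str) -> np.ndarray:
    try:
        cols = QUANTIFIER_GROUPS[quantifier]
    except KeyError:
        raise ValueError(
            f"unknown quantifier subset {quantifier!r}; choose from {sorted(QUANTIFIER_GROUPS)}"
        ) from None
    names = [f"{stat}_{c}" for c in cols for stat in ("mean", "sd")]
    return summaries[names].to_numpy()


def distance_matrix(
    summaries: pd.DataFrame, quantifier: str = "entropy", metric: str = "euclidean"
) -> tuple[np.ndarray, list[str]]:
    """Symmetric subject-by-subject distance matrix over summary features."""
    if len(summaries) < 2:
        raise ValueError("need at least 2 subjects")
    if metric not in _METRICS:
        raise ValueError(f"unknown metric {metric!r}; choose from {sorted(_METRICS)}")
    pts = _summary_matrix(summaries, quantifier)
    dist = squareform(pdist(pts, metric=_METRICS[metric]))
    return dist, [str(s) for s in summaries.index]


@dataclass
class SubjectTree:
    """Agglomerative tree over subjects (scipy linkage + leaf labels)."""

    linkage: np.ndarray
    labels: list[str]

    @property
    def n_leaves(self) -> int:
        return len(self.labels)

    @property
    def total_height(self) -> float:
        return float(self.linkage[:, 2].max())

    def cut(self, height_pct: float | None = None, n_clusters: int | None = None) -> dict[str, int]:
        """Partition subjects at a relative height (%) or into n clusters."""
        if (height_pct is None) == (n_clusters is None):
            raise ValueError("give exactly one of height_pct or n_clusters")
        if height_pct is not None:
            flat = hierarchy.fcluster(
                self.linkage, t=self.total_height * height_pct / 100.0, criterion="distance"
            )
        else:
            flat = hierarchy.fcluster(self.linkage, t=n_clusters, criterion="maxclust")
        return dict(zip(self.labels, (int(c) for c in flat)))

    def to_newick(self) -> str:
        """Newick export; branch lengths are merge-height differences."""
        root = hierarchy.to_tree(self.linkage)

        def render(node, parent_height: float) -> str:
            length = parent_height - (0.0 if node.is_leaf() else node.dist)
            if node.is_leaf():
                length = parent_height
                return f"{self.labels[node.id]}:{length:.10g}"
            left = render(node.left, node.dist)
            right = render(node.right, node.dist)
            return f"({left},{right}):{length:.10g}"

        left = render(root.left, root.dist)
        right = render(root.right, root.dist)
        return f"({left},{right});"


def hierarchical_tree(
    dist: np.ndarray, labels: Sequence[str], method: str = "average"
) -> SubjectTree:
    """Agglomerative clustering of a symmetric distance matrix."""
    dist = np.asarray(dist, dtype=float)
    if dist.ndim != 2 or dist.shape[0] != dist.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(dist, dist.T):
        raise ValueError("distance matrix must be symmetric")
    if len(labels) != dist.shape[0]:
        raise ValueError("labels must match the matrix size")
    z = hierarchy.linkage(squareform(dist, checks=False), method=method)
    return SubjectTree(linkage=z, labels=[str(l) for l in labels])


def neighbor_joining_tree(dist: np.ndarray, labels: Sequence[str], rooted: bool = True):
    """Classical neighbor-joining tree; midpoint-rooted for display by default.

    Returns a ``skbio.TreeNode``; use ``str(tree)`` or ``tree.write`` for
    Newick export.
    """
    dist = np.asarray(dist, dtype=float)
    if dist.shape[0] < 3:
        raise ValueError("neighbor joining needs at least 3 subjects")
    dm = DistanceMatrix(dist, ids=[str(l) for l in labels])
    tree = nj(dm)
    if rooted:
        tree = tree.root_at_midpoint()
    return tree


@dataclass
class ParallelepipedModel:
    """Per-class per-feature min-max boxes.

    Prediction returns the class whose box contains the point; overlaps are
    resolved by smallest box volume, then by class declaration order.
    """

    classes: list[str]
    lower: dict[str, np.ndarray]
    upper: dict[str, np.ndarray]

    def volume(self, cls: str) -> float:
        return float(np.prod(self.upper[cls] - self.lower[cls]))


def parallelepiped_fit(points_by_class: Mapping[str, np.ndarray]) -> ParallelepipedModel:
    """Fit one min-max box per class from its training points."""
    if not points_by_class:
        raise ValueError("need at least one class")
    dims = set()
    lower, upper = {}, {}
    for cls, pts in points_by_class.items():
        arr = np.atleast_2d(np.asarray(pts, dtype=float))
        if len(arr) < 1:
            raise ValueError(f"class {cls!r} has no training points")
        dims.add(arr.shape[1])
        lower[cls] = arr.min(axis=0)
        upper[cls] = arr.max(axis=0)
    if len(dims) != 1:
        raise ValueError(f"classes have mismatched feature dimensions: {sorted(dims)}")
    return ParallelepipedModel(classes=list(points_by_class), lower=lower, upper=upper)


def parallelepiped_predict(model: ParallelepipedModel, point) -> str | None:
    """Class of the containing box, or None ("unclassified") if outside all."""
    p = np.asarray(point, dtype=float)
    dim = len(next(iter(model.lower.values())))
    if p.shape != (dim,):
        raise ValueError(f"point has dimension {p.shape}, model expects ({dim},)")
    hits = [
        cls
        for cls in model.classes
        if np.all(p >= model.lower[cls]) and np.all(p <= model.upper[cls])
    ]
    if not hits:
        return None
    hits.sort(key=lambda cls: (model.volume(cls), model.classes.index(cls)))
    return hits[0]
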