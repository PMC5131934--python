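"""One-class verification protocol and its performance metrics.

For each subject, a one-class SVM with Gaussian kernel is trained on a
random sample of ``n`` genuine feature vectors; the remaining genuine
signatures (positives) and all forgeries (negatives) are scored with the
signed decision function.  Performance is summarized by

* ACC: accuracy at the default threshold 0 (predict genuine iff score >= 0),
* AUC: probability that a random genuine outscores a random forgery
  (rank statistic, ties counted 1/2),
* EER: the operating point where the false-acceptance and false-rejection
  rates cross, linearly interpolated between adjacent thresholds.

The kernel width parameter follows the ``sigma2`` convention
``k(u, v) = exp(-||u - v||^2 / (2 sigma^2))`` by default; the alternative
``gamma = 1/sigma^2`` reading is selectable because conventions differ
across SVM tool chains.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.svm import OneClassSVM

from .quantifiers import FEATURE_COLUMNS, FORGERY, GENUINE

#: training-sample sweep of the verification protocol
DEFAULT_N_TRAIN = (5, 10, 14, 18, 22)

__all__ = [
    "DEFAULT_N_TRAIN",
    "VerificationConfig",
    "SubjectVerificationResult",
    "VerificationReport",
    "split_train_test",
    "one_class_train",
    "accuracy",
    "roc_auc",
    "equal_error_rate",
    "run_protocol",
]


@dataclass(frozen=True)
class VerificationConfig:
    """Protocol parameters.

    sigma2 is the Gaussian kernel width (sigma^2 = 10 by default); nu the
    one-class margin parameter; repetitions the number of random
    train/test splits averaged per (subject, n_train).
    """

    n_train_values: tuple[int, ...] = DEFAULT_N_TRAIN
    sigma2: float = 10.0
    nu: float = 0.1
    repetitions: int = 10
    seed: int = 0
    kernel_convention: str = "half"  # "half": gamma = 1/(2 sigma2); "inverse": 1/sigma2
    standardize: bool = False
    threshold: float = 0.0

    def __post_init__(self) -> None:
        if self.sigma2 <= 0:
            raise ValueError("sigma2 must be positive")
        if not 0 < self.nu <= 1:
            raise ValueError("nu must be in (0, 1]")
        if self.repetitions < 1:
            raise ValueError("repetitions must be >= 1")
        if self.kernel_convention not in ("half", "inverse"):
            raise ValueError("kernel_convention must be 'half' or 'inverse'")
        if any(n < 1 for n in self.n_train_values):
            raise ValueError("n_train values must be >= 1")


def split_train_test(
    genuine: np.ndarray, forgery: np.ndarray, n_train: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Sample ``n_train`` genuine rows for training, without replacement.

    The held-out genuine rows are the positive test set; all forgeries are
    the negatives.
    """
    genuine = np.atleast_2d(genuine)
    forgery = np.atleast_2d(forgery)
    if n_train >= len(genuine):
        raise ValueError(f"n_train={n_train} must be < genuine count {len(genuine)}")
    idx = rng.choice(len(genuine), size=n_train, replace=False)
    mask = np.zeros(len(genuine), dtype=bool)
    mask[idx] = True
    return genuine[mask], genuine[~mask], forgery


def one_class_train(
    train: np.ndarray,
    sigma2: float = 10.0,
    nu: float = 0.1,
    kernel_convention: str = "half",
) -> OneClassSVM:
    """Fit a Gaussian-kernel one-class SVM; score with ``.decision_function``."""
    train = np.atleast_2d(np.asarray(train, dtype=float))
    gamma = 1.0 / (2.0 * sigma2) if kernel_convention == "half" else 1.0 / sigma2
    # tight solver tolerance so the fit is reproducible and order-invariant
    model = OneClassSVM(kernel="rbf", gamma=gamma, nu=nu, tol=1e-6)
    model.fit(train)
    return model


def accuracy(scores_pos, scores_neg, threshold: float = 0.0) -> float:
    """(TP + TN) / (P + N) with predict-genuine iff score >= threshold."""
    pos = np.asarray(scores_pos, dtype=float)
    neg = np.asarray(scores_neg, dtype=float)
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("both score sets must be non-empty")
    tp = int(np.sum(pos >= threshold))
    tn = int(np.sum(neg < threshold))
    return (tp + tn) / (len(pos) + len(neg))


def roc_auc(scores_pos, scores_neg) -> float:
    """P(random positive > random negative), ties 1/2 (Mann-Whitney form)."""
    pos = np.asarray(scores_pos, dtype=float)
    neg = np.asarray(scores_neg, dtype=float)
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("both score sets must be non-empty")
    ranks = rankdata(np.concatenate([pos, neg]))
    r_pos = ranks[: len(pos)].sum()
    return (r_pos - len(pos) * (len(pos) + 1) / 2.0) / (len(pos) * len(neg))


def _far_frr(pos: np.ndarray, neg: np.ndarray, thresholds: np.ndarray):
    """FAR(t) = share of negatives accepted, FRR(t) = share of positives rejected,
    under predict-genuine iff score >= t, vectorized over thresholds."""
    pos_sorted = np.sort(pos)
    neg_sorted = np.sort(neg)
    far = 1.0 - np.searchsorted(neg_sorted, thresholds, side="left") / len(neg)
    frr = np.searchsorted(pos_sorted, thresholds, side="left") / len(pos)
    return far, frr


def equal_error_rate(scores_pos, scores_neg) -> float:
    """EER: error rate where FAR and FRR cross, interpolated between thresholds.

    Thresholds sweep the pooled scores; when no threshold gives an exact
    crossing the two step functions are linearly interpolated between the
    adjacent thresholds bracketing the sign change of FAR - FRR.
    """
    pos = np.asarray(scores_pos, dtype=float)
    neg = np.asarray(scores_neg, dtype=float)
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("both score sets must be non-empty")
    pooled = np.unique(np.concatenate([pos, neg]))
    # bracket the sweep so FAR starts at 1 (accept all) and ends at 0
    thresholds = np.concatenate([[pooled[0] - 1.0], pooled, [pooled[-1] + 1.0]])
    far, frr = _far_frr(pos, neg, thresholds)
    diff = far - frr  # decreasing from +1-ish to -1-ish
    cross = int(np.argmax(diff <= 0))
    if diff[cross] == 0:
        return float(far[cross])
    i, j = cross - 1, cross
    lam = diff[i] / (diff[i] - diff[j])
    eer_far = far[i] + lam * (far[j] - far[i])
    eer_frr = frr[i] + lam * (frr[j] - frr[i])
    return float((eer_far + eer_frr) / 2.0)


@dataclass
class SubjectVerificationResult:
    """Per-repetition and mean metrics for one subject at one n_train."""

    subject_id: str
    n_train: int
    acc: list[float]
    auc: list[float]
    eer: list[float]

    @property
    def mean_acc(self) -> float:
        return float(np.mean(self.acc))

    @property
    def mean_auc(self) -> float:
        return float(np.mean(self.auc))

    @property
    def mean_eer(self) -> float:
        return float(np.mean(self.eer))


@dataclass
class VerificationReport:
    """Full protocol output: config echo, per-subject results, aggregates."""

    config: VerificationConfig
    results: list[SubjectVerificationResult]
    groups: dict[str, str] = field(default_factory=dict)

    def per_subject_frame(self) -> pd.DataFrame:
        rows = [
            {
                "subject_id": r.subject_id,
                "group": self.groups.get(r.subject_id, ""),
                "n_train": r.n_train,
                "acc": r.mean_acc,
                "auc": r.mean_auc,
                "eer": r.mean_eer,
                "eer_pct": 100.0 * r.mean_eer,
            }
            for r in self.results
        ]
        return pd.DataFrame(rows)

    def summary_frame(self, by_group: bool = False) -> pd.DataFrame:
        """Grand means over subjects per n_train (optionally per group)."""
        df = self.per_subject_frame()
        keys = ["group", "n_train"] if by_group else ["n_train"]
        return df.groupby(keys, as_index=False)[["acc", "auc", "eer", "eer_pct"]].mean()

    def to_json(self, path=None) -> str:
        payload = {
            "config": asdict(self.config),
            "groups": self.groups,
            "subjects": [
                {
                    "subject_id": r.subject_id,
                    "n_train": r.n_train,
                    "acc": r.acc,
                    "auc": r.auc,
                    "eer": r.eer,
                    "mean_acc": r.mean_acc,
                    "mean_auc": r.mean_auc,
                    "mean_eer": r.mean_eer,
                }
                for r in self.results
            ],
            "summary": self.summary_frame().to_dict(orient="records"),
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    def to_csv(self, path) -> None:
        self.per_subject_frame().to_csv(path, index=False)


def _feature_matrix(df: pd.DataFrame) -> np.ndarray:
    return df[list(FEATURE_COLUMNS)].to_numpy(dtype=float)


def run_protocol(
    features: pd.DataFrame,
    config: VerificationConfig,
    groups: Mapping[str, str] | None = None,
) -> VerificationReport:
    """Run the full verification sweep over all subjects in a feature table.

    ``features`` must carry the identity columns and the six quantifiers;
    every subject needs more genuine signatures than the largest n_train
    and at least one forgery.  Each (subject, n_train, repetition) cell
    draws its own substream from the config seed, so the report is fully
    reproducible and stable under changes of the subject count.
    """
    results: list[SubjectVerificationResult] = []
    subject_ids = sorted(features["subject_id"].unique())
    mu = sd = None
    if config.standardize:
        genuine_all = features[features["authenticity"] == GENUINE]
        mat = _feature_matrix(genuine_all)
        mu, sd = mat.mean(axis=0), mat.std(axis=0)
        sd[sd == 0] = 1.0

    for si, subject in enumerate(subject_ids):
        sub = features[features["subject_id"] == subject]
        genuine = _feature_matrix(sub[sub["authenticity"] == GENUINE])
        forgery = _feature_matrix(sub[sub["authenticity"] == FORGERY])
        if len(forgery) == 0:
            raise ValueError(f"subject {subject} has no forgeries to test against")
        if config.standardize:
            genuine = (genuine - mu) / sd
            forgery = (forgery - mu) / sd
        for ni, n_train in enumerate(config.n_train_values):
            if n_train >= len(genuine):
                raise ValueError(
                    f"subject {subject}: n_train={n_train} >= genuine count {len(genuine)}"
                )
            accs, aucs, eers = [], [], []
            for rep in range(config.repetitions):
                rng = np.random.default_rng(
                    np.random.SeedSequence(config.seed, spawn_key=(si, ni, rep))
                )
                train, test_pos, test_neg = split_train_test(genuine, forgery, n_train, rng)
                model = one_class_train(
                    train, config.sigma2, config.nu, config.kernel_convention
                )
                s_pos = model.decision_function(test_pos)
                s_neg = model.decision_function(test_neg)
                accs.append(accuracy(s_pos, s_neg, config.threshold))
                aucs.append(roc_auc(s_pos, s_neg))
                eers.append(equal_error_rate(s_pos, s_neg))
            results.append(
                SubjectVerificationResult(
                    subject_id=str(subject), n_train=n_train, acc=accs, auc=aucs, eer=eers
                )
            )
    return VerificationReport(
        config=config, results=results, groups=dict(groups or {})
    )
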