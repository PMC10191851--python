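"""Leave-one-participant-out decoding of word-frequency condition.

Trials are represented as rows of time-binned high-gamma envelope
features; an L2-regularized logistic regression (C = 1) is trained on
all participants but one and scored on the held-out participant.  The
pooled held-out accuracy is tested against chance with an exact
binomial upper-tail test (primary) and its normal approximation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import LeaveOneGroupOut
from sklearn.preprocessing import StandardScaler

__all__ = ["FeatureMatrix", "DecodeResult", "decode_lopo", "accuracy_significance"]


@dataclass
class FeatureMatrix:
    """Trial-by-feature matrix with condition labels and participant ids."""

    X: np.ndarray
    y: np.ndarray
    groups: np.ndarray

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y)
        self.groups = np.asarray(self.groups)
        if self.X.ndim != 2:
            raise ValueError("X must be 2-D (trials x features)")
        if not np.isfinite(self.X).all():
            raise ValueError("feature matrix contains missing/non-finite values")
        if len(self.y) != len(self.X) or len(self.groups) != len(self.X):
            raise ValueError("labels/groups do not match the number of trials")
        if len(np.unique(self.y)) < 2:
            raise ValueError("need at least 2 classes")

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "FeatureMatrix":
        feat_cols = [c for c in df.columns if c not in ("label", "group")]
        return cls(df[feat_cols].to_numpy(float), df["label"].to_numpy(), df["group"].to_numpy())

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.X, columns=[f"f{i}" for i in range(self.X.shape[1])])
        df["label"] = self.y
        df["group"] = self.groups
        return df


@dataclass
class DecodeResult:
    per_fold_accuracy: dict
    mean_accuracy: float
    n_correct: int
    n_test_trials: int
    p_value: float  # exact binomial upper tail (primary)
    p_value_z: float  # one-sided normal approximation
    single_class_folds: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "mean_accuracy": self.mean_accuracy,
            "n_correct": self.n_correct,
            "n_test_trials": self.n_test_trials,
            "p_value_exact_binomial": self.p_value,
            "p_value_z": self.p_value_z,
            "per_fold_accuracy": {str(k): v for k, v in self.per_fold_accuracy.items()},
        }


def decode_lopo(features: FeatureMatrix, cost: float = 1.0) -> DecodeResult:
    """Leave-one-participant-out cross-validated decoding accuracy.

    Features are standardized per fold using training-fold statistics
    only (no leakage).  ``cost`` is the inverse regularization strength
    C of the l2 penalty.  Deterministic given the solver tolerance 1e-8.
    """
    uniq = np.unique(features.groups)
    if len(uniq) < 2:
        raise ValueError("leave-one-participant-out requires >= 2 participants")
    splitter = LeaveOneGroupOut()
    per_fold: dict = {}
    single_class_folds = []
    n_correct = 0
    n_total = 0
    for train, test in splitter.split(features.X, features.y, features.groups):
        held_out = features.groups[test][0]
        y_train = features.y[train]
        if len(np.unique(y_train)) < 2:
            raise ValueError(
                f"training folds contain a single class when holding out {held_out!r}"
            )
        scaler = StandardScaler().fit(features.X[train])
        # l2 penalty (the estimator default) with inverse strength C
        clf = LogisticRegression(C=cost, solver="lbfgs", tol=1e-8, max_iter=5000)
        clf.fit(scaler.transform(features.X[train]), y_train)
        pred = clf.predict(scaler.transform(features.X[test]))
        correct = int((pred == features.y[test]).sum())
        per_fold[held_out] = correct / len(test)
        if len(np.unique(features.y[test])) < 2:
            single_class_folds.append(held_out)
        n_correct += correct
        n_total += len(test)
    mean_acc = float(np.mean(list(per_fold.values())))
    p_exact, p_z, _ = accuracy_significance(n_correct, n_total)
    return DecodeResult(
        per_fold_accuracy=per_fold,
        mean_accuracy=mean_acc,
        n_correct=n_correct,
        n_test_trials=n_total,
        p_value=p_exact,
        p_value_z=p_z,
        single_class_folds=single_class_folds,
    )


def accuracy_significance(
    n_correct: int, n_total: int, chance: float = 0.5
) -> tuple[float, float, str]:
    """One-sided significance of a classification accuracy against chance.

    Returns ``(p_exact, p_z, primary)`` where ``p_exact`` is the exact
    binomial upper tail P(X >= n_correct), ``p_z`` the one-sided normal
    (Z-test) approximation, and ``primary`` names the exact test.
    """
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    if not 0 <= n_correct <= n_total:
        raise ValueError("n_correct must lie in [0, n_total]")
    # P(X >= k) = sf(k - 1)
    p_exact = float(stats.binom.sf(n_correct - 1, n_total, chance))
    z = (n_correct - n_total * chance) / np.sqrt(n_total * chance * (1 - chance))
    p_z = float(stats.norm.sf(z))
    return p_exact, p_z, "exact_binomial"
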