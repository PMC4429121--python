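"""Supervised co-expression prediction.

The classifier is a feed-forward network with one hidden layer whose hidden
weights are random and fixed (a random-projection / extreme-learning-machine
realization): features are z-scored with training-fold statistics, projected
through a seeded random layer with sigmoid activation, and the output layer
is solved in closed form by ridge-regularized least squares against +/-1
targets. Training is deterministic given the seed and takes seconds even
with 800 hidden units.

Evaluation is rank-based AUC under stratified k-fold cross-validation, plus
greedy forward feature selection and leave-one-chromosome-out transfer.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.model_selection import StratifiedKFold

__all__ = [
    "ClassifierSpec",
    "RandomProjectionNet",
    "CVResult",
    "auc",
    "cross_validate",
    "forward_select",
    "leave_one_chromosome_out",
]


@dataclass
class ClassifierSpec:
    """Hyperparameters: 800 hidden nodes by default, 100 for feature
    selection; ridge regularization for the output-layer solve."""

    hidden_nodes: int = 800
    ridge: float = 1e-3
    seed: int = 0

    def __post_init__(self):
        if self.hidden_nodes < 1:
            raise ValueError("hidden_nodes must be >= 1")


class RandomProjectionNet:
    """One-hidden-layer network trained only at the output layer."""

    def __init__(self, spec: ClassifierSpec):
        self.spec = spec

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.ndim != 2:
            raise ValueError("X must be 2-D")
        if not np.all(np.isfinite(X)):
            raise ValueError("features must be finite")
        classes = np.unique(y)
        if classes.size != 2:
            raise ValueError("y must contain exactly two classes")
        self.classes_ = classes
        t = np.where(y == classes[1], 1.0, -1.0)
        self.mean_ = X.mean(axis=0)
        sd = X.std(axis=0)
        self.sd_ = np.where(sd > 0, sd, 1.0)
        rng = np.random.default_rng(self.spec.seed)
        d, h = X.shape[1], self.spec.hidden_nodes
        # standard-normal draws scaled by 1/sqrt(d) so pre-activations on
        # z-scored inputs stay O(1) and the sigmoid does not saturate
        self.W_ = rng.standard_normal((h, d)) / np.sqrt(d)
        self.b_ = rng.standard_normal(h)
        H = self._hidden(X)
        # ridge scaled by n so the solve is invariant to duplicating the
        # training set
        A = H.T @ H + self.spec.ridge * len(t) * np.eye(h)
        self.w_out_ = np.linalg.solve(A, H.T @ t)
        return self

    def _hidden(self, X):
        Z = (np.asarray(X, dtype=float) - self.mean_) / self.sd_
        return expit(Z @ self.W_.T + self.b_)

    def predict_scores(self, X):
        """Continuous decision scores; higher means more likely positive."""
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self.mean_.shape[0]:
            raise ValueError("feature-column mismatch with training data")
        return self._hidden(X) @ self.w_out_


def auc(scores, labels) -> float:
    """Rank-based (Mann-Whitney) AUC with tie correction."""
    labels = np.asarray(labels)
    if np.unique(labels).size != 2:
        raise ValueError("both classes must be present")
    return float(roc_auc_score(labels, scores))


@dataclass
class CVResult:
    fold_aucs: list[float]
    seed: int
    folds: int
    roc_points: list = field(default_factory=list, repr=False)

    @property
    def mean_auc(self) -> float:
        return float(np.mean(self.fold_aucs))

    @property
    def median_auc(self) -> float:
        return float(np.median(self.fold_aucs))


def _as_binary(y) -> np.ndarray:
    y = np.asarray(y)
    if y.dtype.kind in "OUS":  # label strings: 'strong' is the positive class
        return (y == "strong").astype(int)
    return y.astype(int)


def cross_validate(
    spec: ClassifierSpec, X, y, folds: int = 10, seed: int = 0, keep_roc: bool = False
) -> CVResult:
    """Stratified seeded k-fold CV; z-scoring is fit on training folds only."""
    X = np.asarray(X, dtype=float)
    yb = _as_binary(y)
    if min(np.bincount(yb)) < folds:
        raise ValueError("too few rows in the minority class for the fold count")
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    aucs, rocs = [], []
    for train, test in skf.split(X, yb):
        model = RandomProjectionNet(spec).fit(X[train], yb[train])
        scores = model.predict_scores(X[test])
        aucs.append(auc(scores, yb[test]))
        if keep_roc:
            fpr, tpr, _ = roc_curve(yb[test], scores)
            rocs.append((fpr, tpr))
    return CVResult(aucs, seed, folds, rocs)


@dataclass
class SelectionResult:
    per_fold_selected: list[list]
    per_fold_auc: list[float]
    seed: int

    @property
    def union(self) -> list:
        seen: dict = {}
        for sel in self.per_fold_selected:
            for f in sel:
                seen.setdefault(f, None)
        return list(seen)

    @property
    def top5_per_fold(self) -> list[list]:
        return [sel[:5] for sel in self.per_fold_selected]

    @property
    def mean_auc(self) -> float:
        return float(np.mean(self.per_fold_auc))


def forward_select(
    spec: ClassifierSpec,
    X: pd.DataFrame,
    y,
    folds: int = 5,
    seed: int = 0,
    inner_folds: int = 3,
    max_features: int | None = None,
    min_gain: float = 0.01,
) -> SelectionResult:
    """Greedy forward feature selection wrapped around the classifier.

    Within each outer training fold, features are added one at a time,
    each step keeping the candidate that maximizes mean validation AUC over
    an inner stratified CV; selection stops when the best addition improves
    the AUC by less than ``min_gain`` (guarding against pure CV jitter).
    Held-out performance is then measured on the outer test fold with the
    selected set.
    """
    X = pd.DataFrame(X)
    if X.shape[1] < 2:
        raise ValueError("need at least 2 features to select from")
    yb = _as_binary(y)
    cols = list(X.columns)
    Xa = X.to_numpy(dtype=float)
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    selected_all, test_aucs = [], []
    cap = max_features or len(cols)
    for train, test in skf.split(Xa, yb):
        Xtr, ytr = Xa[train], yb[train]
        selected: list[int] = []
        best_auc = -np.inf
        while len(selected) < cap:
            gains = []
            for ci in range(len(cols)):
                if ci in selected:
                    continue
                trial = selected + [ci]
                cv = cross_validate(spec, Xtr[:, trial], ytr, inner_folds, seed)
                gains.append((cv.mean_auc, ci))
            if not gains:
                break
            gain, ci = max(gains)
            if len(selected) > 0 and gain < best_auc + min_gain:
                break
            best_auc = gain
            selected.append(ci)
        model = RandomProjectionNet(spec).fit(Xtr[:, selected], ytr)
        test_aucs.append(auc(model.predict_scores(Xa[test][:, selected]), yb[test]))
        selected_all.append([cols[i] for i in selected])
    return SelectionResult(selected_all, test_aucs, seed)


def leave_one_chromosome_out(
    spec: ClassifierSpec,
    X_by_chrom: dict[str, pd.DataFrame],
    y_by_chrom: dict[str, np.ndarray],
) -> dict[str, float]:
    """Train on all chromosomes but one; report test AUC on the held-out one.

    All chromosomes must share an identical feature-column set.
    """
    chroms = list(X_by_chrom)
    ref_cols = list(pd.DataFrame(X_by_chrom[chroms[0]]).columns)
    frames = {}
    for c in chroms:
        df = pd.DataFrame(X_by_chrom[c])
        if list(df.columns) != ref_cols:
            raise ValueError(f"feature columns of {c} do not match")
        frames[c] = df
    out = {}
    for held in chroms:
        Xtr = np.vstack([frames[c].to_numpy(dtype=float) for c in chroms if c != held])
        ytr = np.concatenate([_as_binary(y_by_chrom[c]) for c in chroms if c != held])
        model = RandomProjectionNet(spec).fit(Xtr, ytr)
        scores = model.predict_scores(frames[held].to_numpy(dtype=float))
        out[held] = auc(scores, _as_binary(y_by_chrom[held]))
    return out
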