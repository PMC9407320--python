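"""Kennard–Stone splitting, LS-SVM grading and confusion-matrix evaluation.

The least-squares SVM replaces the SVM's inequality constraints with
equalities and a squared-error loss, so training one binary model reduces to
a single dense linear system

    [ 0   1ᵀ ] [ b ]   [ 0 ]
    [ 1  K + I/γ ] [ α ] = [ y ],      f(x) = Σ_i α_i K(x_i, x) + b,

whose first row enforces Σ α_i = 0.  Multiclass grading uses one-vs-one
majority voting over all class pairs; features are standardized with
training-set statistics stored in the model.  The Kennard–Stone algorithm
picks a representative training subset by iteratively adding the candidate
with the largest minimum distance to the already-selected set.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from sklearn.model_selection import StratifiedKFold

RBF = "RBF"
LIN = "LIN"

#: Canonical severity order used for vote tie-breaking (ties -> lowest grade).
GRADE_ORDER = ("SOUND", "I", "II", "III", "IV")


# ---------------------------------------------------------------- splitting

@dataclass
class SplitResult:
    train_indices: np.ndarray
    test_indices: np.ndarray


def kennard_stone(X: np.ndarray, n_train: int) -> SplitResult:
    """Classic max–min Kennard–Stone selection on Euclidean distances.

    Seeds with the two points at maximum mutual distance, then repeatedly
    adds the candidate maximizing its minimum distance to the selected set.
    All ties resolve to the lowest index, so the split is deterministic.
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if n_train < 2:
        raise ValueError("n_train must be >= 2")
    if n < n_train:
        raise ValueError(f"cannot select {n_train} of {n} samples")
    D = cdist(X, X)
    # lowest-index pair among those at maximum distance
    flat = int(np.argmax(D))
    i, j = sorted(divmod(flat, n))
    selected = [i, j]
    min_dist = np.minimum(D[i], D[j])
    min_dist[selected] = -1.0
    while len(selected) < n_train:
        nxt = int(np.argmax(min_dist))  # argmax is lowest index on ties
        selected.append(nxt)
        min_dist = np.minimum(min_dist, D[nxt])
        min_dist[nxt] = -1.0
    train = np.array(sorted(selected))
    test = np.setdiff1d(np.arange(n), train)
    return SplitResult(train, test)


def kennard_stone_stratified(
    X: np.ndarray, y: Sequence, train_fraction: float = 0.75
) -> SplitResult:
    """Per-class Kennard–Stone split on standardized features.

    Each class contributes round(train_fraction · n_class) training samples
    (at least 1, at most n_class − 1 so every class is tested), selected by
    max–min distance within the class.  Standardizing first keeps Euclidean
    distances meaningful across heterogeneously scaled features.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    Z = (X - mu) / sd
    train_parts = []
    for cls in _ordered_classes(y):
        idx = np.flatnonzero(y == cls)
        k = int(round(train_fraction * len(idx)))
        k = max(1, min(k, len(idx) - 1)) if len(idx) > 1 else 1
        if k >= 2:
            sub = kennard_stone(Z[idx], k)
            train_parts.append(idx[sub.train_indices])
        else:
            train_parts.append(idx[:1])
    train = np.sort(np.concatenate(train_parts))
    test = np.setdiff1d(np.arange(len(y)), train)
    return SplitResult(train, test)


def _ordered_classes(y: np.ndarray) -> list:
    classes = list(pd.unique(y))
    known = [g for g in GRADE_ORDER if g in classes]
    return known + sorted(c for c in classes if c not in GRADE_ORDER)


# ------------------------------------------------------------------ kernels

def _kernel(A: np.ndarray, B: np.ndarray, kernel: str, sigma: float) -> np.ndarray:
    if kernel == LIN:
        return A @ B.T
    if kernel == RBF:
        if sigma <= 0:
            raise ValueError("sigma must be > 0 for the RBF kernel")
        return np.exp(-cdist(A, B, "sqeuclidean") / (2.0 * sigma**2))
    raise ValueError(f"unknown kernel {kernel!r}")


# ------------------------------------------------------------------- models

@dataclass
class PairModel:
    neg: object  # class encoded as -1
    pos: object  # class encoded as +1
    alpha: np.ndarray
    b: float
    X: np.ndarray  # training features (standardized space)


@dataclass
class LSSVMModel:
    kernel: str
    sigma: float
    gamma: float
    classes: list
    mean: np.ndarray
    scale: np.ndarray
    pairs: list[PairModel] = field(default_factory=list)

    def save(self, path: str) -> None:
        payload = {
            "format": "hsibruise-lssvm",
            "version": 1,
            "kernel": self.kernel,
            "sigma": self.sigma,
            "gamma": self.gamma,
            "classes": [str(c) for c in self.classes],
            "mean": self.mean.tolist(),
            "scale": self.scale.tolist(),
            "pairs": [
                {
                    "neg": str(p.neg),
                    "pos": str(p.pos),
                    "alpha": p.alpha.tolist(),
                    "b": p.b,
                    "X": p.X.tolist(),
                }
                for p in self.pairs
            ],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def load(cls, path: str) -> "LSSVMModel":
        with open(path) as fh:
            d = json.load(fh)
        if d.get("format") != "hsibruise-lssvm":
            raise ValueError("not an hsibruise LS-SVM model file")
        model = cls(
            kernel=d["kernel"],
            sigma=d["sigma"],
            gamma=d["gamma"],
            classes=d["classes"],
            mean=np.asarray(d["mean"]),
            scale=np.asarray(d["scale"]),
        )
        model.pairs = [
            PairModel(
                p["neg"], p["pos"], np.asarray(p["alpha"]), p["b"], np.asarray(p["X"])
            )
            for p in d["pairs"]
        ]
        return model


def lssvm_train(
    X: np.ndarray,
    y: np.ndarray,
    kernel: str = RBF,
    sigma: float = 1.0,
    gamma: float = 10.0,
) -> tuple[np.ndarray, float]:
    """Solve the LS-SVM linear system for ±1 labels; returns (α, b)."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if set(np.unique(y)) != {-1.0, 1.0}:
        raise ValueError("labels must contain both classes, encoded ±1")
    if gamma <= 0:
        raise ValueError("gamma must be > 0")
    n = len(y)
    K = _kernel(X, X, kernel, sigma)
    A = np.zeros((n + 1, n + 1))
    A[0, 1:] = 1.0
    A[1:, 0] = 1.0
    A[1:, 1:] = K + np.eye(n) / gamma
    rhs = np.concatenate(([0.0], y))
    try:
        sol = np.linalg.solve(A, rhs)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            "singular LS-SVM system; try a smaller gamma (larger ridge 1/gamma)"
        ) from exc
    residual = float(np.max(np.abs(A @ sol - rhs)))
    if residual > 1e-8 * max(1.0, float(np.max(np.abs(rhs)))):
        raise np.linalg.LinAlgError(
            f"ill-conditioned LS-SVM system (residual {residual:.2e}); "
            "try a smaller gamma"
        )
    return sol[1:], float(sol[0])


def lssvm_decision(
    X_train: np.ndarray,
    alpha: np.ndarray,
    b: float,
    X: np.ndarray,
    kernel: str = RBF,
    sigma: float = 1.0,
) -> np.ndarray:
    """Decision values f(x) = Σ α_i K(x_i, x) + b."""
    return _kernel(np.atleast_2d(X), X_train, kernel, sigma) @ alpha + b


def lssvm_train_multiclass(
    X: np.ndarray,
    y: Sequence,
    kernel: str = RBF,
    sigma: float = 1.0,
    gamma: float = 10.0,
) -> LSSVMModel:
    """One-vs-one LS-SVM over all class pairs, on standardized features."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes = _ordered_classes(y)
    if len(classes) < 2:
        raise ValueError("need at least 2 classes")
    for cls in classes:
        if not np.any(y == cls):
            raise ValueError(f"class {cls!r} has no samples")
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    Z = (X - mu) / sd
    model = LSSVMModel(kernel, sigma, gamma, classes, mu, sd)
    for neg, pos in combinations(classes, 2):
        sel = (y == neg) | (y == pos)
        ypm = np.where(y[sel] == pos, 1.0, -1.0)
        alpha, b = lssvm_train(Z[sel], ypm, kernel, sigma, gamma)
        model.pairs.append(PairModel(neg, pos, alpha, b, Z[sel]))
    return model


def predict(model: LSSVMModel, X: np.ndarray) -> np.ndarray:
    """One-vs-one majority vote; ties resolve to the lowest grade index."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] == 0:
        return np.array([], dtype=object)
    if X.shape[1] != len(model.mean):
        raise ValueError(
            f"feature length {X.shape[1]} does not match training ({len(model.mean)})"
        )
    Z = (X - model.mean) / model.scale
    votes = np.zeros((X.shape[0], len(model.classes)), dtype=int)
    col = {c: k for k, c in enumerate(model.classes)}
    for p in model.pairs:
        f = lssvm_decision(p.X, p.alpha, p.b, Z, model.kernel, model.sigma)
        winner = np.where(f >= 0, col[p.pos], col[p.neg])
        votes[np.arange(len(Z)), winner] += 1
    best = np.argmax(votes, axis=1)  # argmax -> lowest class index on ties
    return np.array([model.classes[k] for k in best], dtype=object)


# --------------------------------------------------------------- evaluation

@dataclass
class ConfusionMatrix:
    counts: pd.DataFrame  # rows = truth, cols = predicted
    recall: pd.Series
    accuracy: float


def evaluate(pred: Sequence, truth: Sequence) -> ConfusionMatrix:
    """Confusion counts, per-class recall and overall accuracy."""
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if len(pred) != len(truth):
        raise ValueError("prediction and truth lengths differ")
    classes = _ordered_classes(np.concatenate([truth, pred]))
    counts = pd.DataFrame(0, index=classes, columns=classes, dtype=int)
    for t, p in zip(truth, pred):
        counts.loc[t, p] += 1
    row_sums = counts.sum(axis=1)
    recall = pd.Series(
        np.where(row_sums > 0, np.diag(counts) / row_sums.replace(0, 1), np.nan),
        index=classes,
    )
    accuracy = float(np.trace(counts)) / len(truth)
    return ConfusionMatrix(counts, recall, accuracy)


# ------------------------------------------------------ hyperparameter search

DEFAULT_GAMMA_GRID = tuple(10.0**k for k in range(-1, 5))
DEFAULT_SIGMA_GRID = tuple(np.round(np.logspace(-1, 2, 7), 6))


def cv_select_hyperparams(
    X: np.ndarray,
    y: Sequence,
    kernel: str = RBF,
    gamma_grid: Sequence[float] = DEFAULT_GAMMA_GRID,
    sigma_grid: Sequence[float] = DEFAULT_SIGMA_GRID,
    n_folds: int = 5,
    seed: int = 0,
) -> tuple[float, float]:
    """Pick (gamma, sigma) by stratified k-fold CV accuracy on the training set.

    The fold assignment is seeded; grid ties resolve to the earliest grid
    entry, so selection is deterministic.  Linear kernels search gamma only.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    sigmas = list(sigma_grid) if kernel == RBF else [1.0]
    smallest = int(min(np.sum(y == c) for c in np.unique(y)))
    n_folds = max(2, min(n_folds, smallest))
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    folds = list(skf.split(X, y))
    best = (-1.0, None, None)
    for gamma in gamma_grid:
        for sigma in sigmas:
            correct = total = 0
            try:
                for tr, te in folds:
                    m = lssvm_train_multiclass(X[tr], y[tr], kernel, sigma, gamma)
                    correct += int(np.sum(predict(m, X[te]) == y[te]))
                    total += len(te)
            except np.linalg.LinAlgError:
                continue
            acc = correct / total
            if acc > best[0]:
                best = (acc, gamma, sigma)
    if best[1] is None:
        raise RuntimeError("no hyperparameter combination produced a solvable model")
    return float(best[1]), float(best[2])
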