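"""Linear probing of the embedding for a labeled folding pattern.

A max-margin linear classifier (linear kernel, balanced class weights,
C = 0.01) is trained on labeled embeddings; its decision values are mapped
to probabilities by a Platt-style logistic calibration fit on out-of-fold
decision values.  The probe generalizes labels to unlabeled cohorts, whose
probability ranking drives moving-average occupancy maps.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .encoder import EmbeddingMatrix


@dataclass
class ProbeModel:
    weights: np.ndarray
    bias: float
    C: float
    balanced: bool
    platt_a: float  # probability = sigmoid(platt_a * decision + platt_b)
    platt_b: float
    # embedding standardization fitted with the probe (dimensions of a PCA
    # embedding have wildly different scales; C is meaningful on unit scale)
    center: np.ndarray = None
    scale: np.ndarray = None

    def decision(self, E: EmbeddingMatrix | np.ndarray) -> np.ndarray:
        X = E.values if isinstance(E, EmbeddingMatrix) else np.asarray(E)
        if X.shape[1] != self.weights.size:
            raise ValueError("embedding dimensionality does not match the probe")
        if self.center is not None:
            X = (X - self.center) / self.scale
        return X @ self.weights + self.bias


@dataclass
class FrequencyMap:
    """Voxelwise occupancy fraction over a batch of binary volumes."""

    values: np.ndarray
    batch_indices: np.ndarray
    batch_size: int
    display_low: float = 0.05
    display_high: float = 0.35

    def __post_init__(self) -> None:
        v = self.values
        if (v < -1e-12).any() or (v > 1 + 1e-12).any():
            raise ValueError("frequency map values must lie in [0,1]")


def train_linear_probe(E: EmbeddingMatrix, labels, C: float = 0.01,
                       balanced: bool = True, calib_folds: int = 5,
                       seed: int = 0) -> ProbeModel:
    """Fit the linear SVM and its logistic probability calibration.

    Calibration decision values come from ``calib_folds`` internal
    training-fold splits so the logistic map is not fit on resubstitution
    scores.
    """
    X = E.values if isinstance(E, EmbeddingMatrix) else np.asarray(E)
    y = np.asarray(labels).astype(int)
    if np.unique(y).size != 2:
        raise ValueError("exactly two classes required")
    center = X.mean(axis=0)
    scale = X.std(axis=0)
    scale[scale == 0] = 1.0
    X = (X - center) / scale
    cw = "balanced" if balanced else None
    svm = SVC(kernel="linear", C=C, class_weight=cw)
    svm.fit(X, y)

    # out-of-fold decision values for Platt calibration
    dec_oof = np.empty(len(y))
    skf = StratifiedKFold(n_splits=calib_folds, shuffle=True, random_state=seed)
    for tr, te in skf.split(X, y):
        m = SVC(kernel="linear", C=C, class_weight=cw)
        m.fit(X[tr], y[tr])
        dec_oof[te] = m.decision_function(X[te])
    lr = LogisticRegression(C=1e6, solver="lbfgs")
    lr.fit(dec_oof[:, None], y)
    return ProbeModel(weights=svm.coef_.ravel(), bias=float(svm.intercept_[0]),
                      C=C, balanced=balanced,
                      platt_a=float(lr.coef_[0, 0]), platt_b=float(lr.intercept_[0]),
                      center=center, scale=scale)


def predict_pattern_prob(probe: ProbeModel, E) -> np.ndarray:
    """Probability of pattern presence; monotone in the decision value."""
    d = probe.decision(E)
    return 1.0 / (1.0 + np.exp(-(probe.platt_a * d + probe.platt_b)))


def make_strata(labels, site=None, sex=None, min_count: int = 10) -> np.ndarray:
    """Joint label x site x sex strata; strata rarer than ``min_count`` are
    merged into one pooled stratum so stratified folds stay constructible."""
    n = len(labels)
    parts = [np.asarray(labels).astype(str)]
    if site is not None:
        parts.append(np.asarray(site).astype(str))
    if sex is not None:
        parts.append(np.asarray(sex).astype(str))
    joint = np.array(["|".join(t) for t in zip(*parts)])
    vals, counts = np.unique(joint, return_counts=True)
    rare = set(vals[counts < min_count])
    if rare:
        joint = np.array([s if s not in rare else "pooled" for s in joint])
    return joint


def cv_auc(E, labels, strata=None, n_folds: int = 10, C: float = 0.01,
           balanced: bool = True, seed: int = 0) -> float:
    """Mean out-of-fold ROC AUC over stratified folds.

    Folds are stratified on the provided joint strata (label x site x sex
    built with :func:`make_strata`) or on the labels alone.
    """
    X = E.values if isinstance(E, EmbeddingMatrix) else np.asarray(E)
    y = np.asarray(labels).astype(int)
    if len(y) < n_folds:
        raise ValueError("fewer samples than folds")
    strat = np.asarray(strata) if strata is not None else y
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    aucs = []
    cw = "balanced" if balanced else None
    for tr, te in skf.split(X, strat):
        if np.unique(y[tr]).size < 2 or np.unique(y[te]).size < 2:
            continue
        mu, sd = X[tr].mean(axis=0), X[tr].std(axis=0)
        sd[sd == 0] = 1.0
        m = SVC(kernel="linear", C=C, class_weight=cw)
        m.fit((X[tr] - mu) / sd, y[tr])
        aucs.append(roc_auc_score(y[te], m.decision_function((X[te] - mu) / sd)))
    if not aucs:
        raise ValueError("no fold contained both classes")
    return float(np.mean(aucs))


def moving_average_maps(volumes, ranking_scores, batch_size: int = 200,
                        n_batches: int = 10) -> list[FrequencyMap]:
    """Rank subjects by score and average batches at regular rank intervals.

    Subjects are sorted by (score, subject index) — a stable, reproducible
    ranking — and ``n_batches`` windows of ``batch_size`` consecutive
    subjects are taken with starts evenly spaced from rank 0 to
    n - batch_size.  Each map is the voxelwise mean of the binary volumes in
    its window.
    """
    n = len(volumes)
    scores = np.asarray(ranking_scores, dtype=float)
    if n < batch_size:
        raise ValueError("need at least batch_size subjects")
    if scores.size != n:
        raise ValueError("one score per volume required")
    order = np.lexsort((np.arange(n), scores))
    grids = np.stack([v.grid if hasattr(v, "grid") else v for v in volumes]).astype(float)
    if n == batch_size:
        starts = [0]
    else:
        starts = np.unique(np.round(np.linspace(0, n - batch_size, n_batches)).astype(int))
    maps = []
    for s in starts:
        idx = order[s:s + batch_size]
        maps.append(FrequencyMap(values=grids[idx].mean(axis=0),
                                 batch_indices=idx, batch_size=batch_size))
    return maps
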