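"""ReliefF marker selection and per-feature diagnostic statistics.

ReliefF weights a feature by how well it separates each instance from its
nearest neighbours of the other class (misses) relative to its nearest
neighbours of the same class (hits): weights fall with the mean absolute
feature difference to hits and rise with the class-prior-weighted mean
difference to misses.  It is sensitive to feature interactions, which is
why it is preferred here over univariate screens for pre-filtering a
high-dimensional feature matrix ahead of latent-variable classification.

Selected markers carry single-feature diagnostics — sensitivity,
specificity, positive and negative predictive values — computed at the
Youden-optimal point of the feature's own empirical ROC curve.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import roc_curve

__all__ = ["MarkerSet", "relieff_weights", "select_top",
           "univariate_diagnostics", "log2_halfmin"]


def log2_halfmin(intensities: np.ndarray) -> np.ndarray:
    """Log2-transform a samples x features intensity matrix, imputing zeros.

    Zero intensities are detection dropouts, not true zeros; left at
    log2(0+1)=0 they dominate distance-based methods.  The standard
    metabolomics remedy is half-minimum imputation: each zero is replaced
    by half of the feature's smallest observed intensity (one log2 unit
    below the observed minimum).  Features observed nowhere stay zero.
    """
    X = np.log2(np.asarray(intensities, dtype=float) + 1.0)
    for j in range(X.shape[1]):
        col = X[:, j]
        nz = col[col > 0]
        if len(nz):
            col[col == 0] = nz.min() - 1.0
    return X


@dataclass
class MarkerSet:
    """Ranked selected features with per-feature diagnostics."""

    table: pd.DataFrame   # index = feature ids, sorted by weight descending

    @property
    def feature_ids(self) -> list:
        return list(self.table.index)

    def __len__(self) -> int:
        return len(self.table)


def _scale_unit_range(X: np.ndarray) -> np.ndarray:
    lo = X.min(axis=0)
    span = X.max(axis=0) - lo
    span[span == 0] = 1.0
    return (X - lo) / span


def relieff_weights(X: np.ndarray, y: np.ndarray, k_neighbors: int = 10,
                    n_iterations: int | None = None,
                    seed: int = 0) -> np.ndarray:
    """Standard ReliefF feature weights for a labelled matrix.

    Parameters
    ----------
    X : (n_samples, n_features) array; internally scaled to [0, 1] per
        feature by range so that units cancel.
    y : class labels (any hashable values; >= 2 classes, each with more
        than ``k_neighbors`` members).
    n_iterations : number of sampled reference instances; ``None`` (the
        default) iterates over every instance exhaustively.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    n, p = X.shape
    classes, y_idx = np.unique(y, return_inverse=True)
    priors = np.bincount(y_idx) / n
    if len(classes) < 2:
        raise ValueError("need at least two classes")
    for c, cnt in zip(classes, np.bincount(y_idx)):
        if cnt <= k_neighbors:
            raise ValueError(
                f"class {c!r} has {cnt} members; needs > k_neighbors="
                f"{k_neighbors} — use a smaller k")

    Xs = _scale_unit_range(X)
    rng = np.random.default_rng(seed)
    if n_iterations is None or n_iterations >= n:
        ref = np.arange(n)
    else:
        ref = rng.choice(n, size=n_iterations, replace=False)

    # full pairwise Euclidean on scaled features (n is small in this domain)
    d2 = np.sum((Xs[:, None, :] - Xs[None, :, :]) ** 2, axis=2)
    np.fill_diagonal(d2, np.inf)

    W = np.zeros(p)
    m = len(ref)
    for i in ref:
        own = y_idx[i]
        order = np.argsort(d2[i], kind="stable")
        hits = [j for j in order if y_idx[j] == own][:k_neighbors]
        W -= np.abs(Xs[i] - Xs[hits]).sum(axis=0) / (m * k_neighbors)
        for c in range(len(classes)):
            if c == own:
                continue
            misses = [j for j in order if y_idx[j] == c][:k_neighbors]
            w_c = priors[c] / (1.0 - priors[own])
            W += w_c * np.abs(Xs[i] - Xs[misses]).sum(axis=0) / (m * k_neighbors)
    return W


def select_top(weights: np.ndarray, n_select: int,
               feature_ids=None, mz: np.ndarray | None = None) -> pd.DataFrame:
    """Top ``n_select`` features by weight; ties go to the smaller m/z."""
    weights = np.asarray(weights, dtype=float)
    if n_select <= 0:
        raise ValueError("n_select must be positive")
    if n_select > len(weights):
        raise ValueError(f"n_select={n_select} exceeds {len(weights)} features")
    tiebreak = np.asarray(mz, dtype=float) if mz is not None else np.arange(len(weights))
    order = np.lexsort((tiebreak, -weights))
    chosen = order[:n_select]
    ids = (np.asarray(feature_ids)[chosen] if feature_ids is not None else chosen)
    return pd.DataFrame({"feature_id": ids,
                         "weight": weights[chosen],
                         "rank": np.arange(1, n_select + 1)}).set_index("feature_id")


def univariate_diagnostics(x: np.ndarray, y: np.ndarray,
                           positive_label="case") -> dict:
    """Sens/spec/PPV/NPV of one feature at its Youden-optimal threshold.

    The direction of change (markers can rise or fall in cases) is
    auto-detected from the sign of the case-vs-control median difference;
    the ROC is computed on the signed intensities so that "score above
    threshold predicts case" always holds.  Degenerate (constant) features
    return chance-level diagnostics with ``degenerate=True``.
    """
    x = np.asarray(x, dtype=float)
    pos = np.asarray(y) == positive_label
    if pos.all() or (~pos).all():
        raise ValueError("both classes must be present")
    med_diff = np.median(x[pos]) - np.median(x[~pos])
    direction = "up" if med_diff >= 0 else "down"
    if np.all(x == x[0]):
        n_pos, n_neg = pos.sum(), (~pos).sum()
        return {"sens": 1.0, "spec": 0.0, "ppv": n_pos / len(x),
                "npv": 0.0, "threshold": float(x[0]), "auc": 0.5,
                "direction": direction, "degenerate": True}
    score = x if direction == "up" else -x
    fpr, tpr, thr = roc_curve(pos.astype(int), score)
    j = tpr - fpr
    best = int(np.argmax(j))
    pred = score >= thr[best]
    tp = int((pred & pos).sum())
    fp = int((pred & ~pos).sum())
    fn = int((~pred & pos).sum())
    tn = int((~pred & ~pos).sum())
    auc = float(np.trapezoid(tpr, fpr))
    return {"sens": tp / (tp + fn) if tp + fn else 0.0,
            "spec": tn / (tn + fp) if tn + fp else 0.0,
            "ppv": tp / (tp + fp) if tp + fp else 0.0,
            "npv": tn / (tn + fn) if tn + fn else 0.0,
            "threshold": float(thr[best]) * (1 if direction == "up" else -1),
            "auc": auc, "direction": direction, "degenerate": False}


def build_marker_set(X: np.ndarray, y: np.ndarray, feature_ids,
                     mz: np.ndarray, n_select: int, k_neighbors: int = 10,
                     seed: int = 0, formulas: dict | None = None) -> MarkerSet:
    """Rank by ReliefF, select the top subset, attach diagnostics."""
    W = relieff_weights(X, y, k_neighbors=k_neighbors, seed=seed)
    sel = select_top(W, n_select, feature_ids=feature_ids, mz=mz)
    mz_map = dict(zip(feature_ids, mz))
    col_of = {fid: i for i, fid in enumerate(feature_ids)}
    rows = []
    for fid in sel.index:
        d = univariate_diagnostics(X[:, col_of[fid]], y)
        d["mz"] = mz_map[fid]
        if formulas:
            d["formula"] = formulas.get(fid, "")
        rows.append(d)
    diag = pd.DataFrame(rows, index=sel.index)
    return MarkerSet(pd.concat([sel, diag], axis=1))
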