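"""Sparse PLS-DA and OPLS-DA classifiers with 7-fold cross-validation.

Both models project the autoscaled feature matrix onto a few latent
components.  Sparse PLS-DA (NIPALS with soft-thresholded X-loading
weights) performs variable selection inside each component; OPLS-DA first
strips variation orthogonal to the class vector, concentrating the
between-class difference into a single predictive component whose scores
and loadings are directly interpretable.

Performance reporting follows metabolomics practice: R2Y (fitted explained
class variance), Q2 (cross-validated predictive ability, 1 - PRESS/SS),
the balanced error rate (BER, mean per-class misclassification — the
appropriate error for unbalanced cohorts), and the ROC/AUC of held-out
first-component scores.  Model significance is assessed by a permutation
test on Q2 (the rank of the true Q2 among label-permuted refits), a
distribution-free stand-in for parametric cross-validation ANOVA.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

__all__ = ["LatentModel", "CVReport", "fit_splsda", "fit_oplsda", "cross_validate"]


@dataclass
class LatentModel:
    kind: str                       # "splsda" | "oplsda"
    scores: np.ndarray              # n x k predictive scores
    loadings: np.ndarray            # p x k X-loadings
    weights: np.ndarray             # p x k projection weights w* = W(P'W)^-1
    y_loadings: np.ndarray          # k x q
    x_mean: np.ndarray
    x_scale: np.ndarray
    y_mean: np.ndarray
    classes: np.ndarray
    keepX: tuple[int, ...] = ()
    raw_weights: np.ndarray | None = None   # p x k NIPALS weight vectors (sparse)
    r2y: float = float("nan")
    explained_x_variance: np.ndarray = field(default_factory=lambda: np.array([]))
    ortho_scores: np.ndarray | None = None     # OPLS only
    ortho_loadings: np.ndarray | None = None
    ortho_weights: np.ndarray | None = None
    x_residual: np.ndarray | None = None

    def _prepare(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, dtype=float) - self.x_mean) / self.x_scale

    def transform(self, X: np.ndarray) -> np.ndarray:
        """Predictive scores for new samples (orthogonal variation removed
        first for OPLS)."""
        Xs = self._prepare(X)
        if self.kind == "oplsda" and self.ortho_weights is not None:
            for a in range(self.ortho_weights.shape[1]):
                t_o = Xs @ self.ortho_weights[:, a]
                Xs = Xs - np.outer(t_o, self.ortho_loadings[:, a])
        # w* = W (P'W)^-1 maps X to scores directly for NIPALS models
        return Xs @ self.weights

    def predict_dummy(self, X: np.ndarray) -> np.ndarray:
        return self.transform(X) @ self.y_loadings + self.y_mean

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Max-distance class rule: the largest predicted dummy column wins."""
        return self.classes[np.argmax(self.predict_dummy(X), axis=1)]


def _dummy(y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    classes = np.unique(y)
    return (y[:, None] == classes[None, :]).astype(float), classes


def _autoscale(X: np.ndarray):
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    sd[sd == 0] = 1.0
    return (X - mu) / sd, mu, sd


def _soft_threshold_keep(w: np.ndarray, keep: int) -> np.ndarray:
    """Soft-threshold w so exactly ``keep`` coordinates stay nonzero."""
    if keep >= len(w):
        return w
    a = np.abs(w)
    lam = np.sort(a)[::-1][keep]      # (keep+1)-th largest
    out = np.sign(w) * np.maximum(a - lam, 0.0)
    return out


def fit_splsda(X: np.ndarray, y: np.ndarray, n_components: int = 2,
               keepX=None, max_iter: int = 500, tol: float = 1e-9,
               seed: int = 0) -> LatentModel:
    """NIPALS sparse PLS-DA on the dummy-coded class matrix.

    ``keepX`` is the number of variables retained per component (int or
    sequence); ``None`` keeps all, which coincides with dense PLS-DA.  The
    algorithm is deterministic; ``seed`` is accepted for interface
    uniformity.
    """
    X = np.asarray(X, dtype=float)
    Y, classes = _dummy(np.asarray(y))
    n, p = X.shape
    if keepX is None:
        keepX = [p] * n_components
    elif np.isscalar(keepX):
        keepX = [int(keepX)] * n_components
    keepX = [int(k) for k in keepX]
    if any(k > p or k < 1 for k in keepX):
        raise ValueError(f"keepX entries must be in [1, {p}]")

    Xs, mu, sd = _autoscale(X)
    Ym = Y.mean(axis=0)
    Yc = Y - Ym
    ss_y = (Yc ** 2).sum()
    Xd, Yd = Xs.copy(), Yc.copy()
    T = np.zeros((n, n_components))
    P = np.zeros((p, n_components))
    Wmat = np.zeros((p, n_components))
    Q = np.zeros((n_components, Y.shape[1]))
    ssx_total = (Xs ** 2).sum()
    expl = np.zeros(n_components)

    for a in range(n_components):
        u = Yd[:, int(np.argmax((Yd ** 2).sum(axis=0)))].copy()
        w = np.zeros(p)
        for _ in range(max_iter):
            w_new = Xd.T @ u
            w_new = _soft_threshold_keep(w_new, keepX[a])
            nrm = np.linalg.norm(w_new)
            if nrm == 0:
                break
            w_new /= nrm
            t = Xd @ w_new
            q = Yd.T @ t / (t @ t)
            u_new = Yd @ q / (q @ q) if q @ q > 0 else u
            if np.linalg.norm(w_new - w) < tol:
                w = w_new
                break
            w, u = w_new, u_new
        t = Xd @ w
        tt = t @ t
        if tt == 0:
            T, P, Wmat, Q = T[:, :a], P[:, :a], Wmat[:, :a], Q[:a]
            expl = expl[:a]
            break
        pvec = Xd.T @ t / tt
        q = Yd.T @ t / tt
        Xd = Xd - np.outer(t, pvec)
        Yd = Yd - np.outer(t, q)
        T[:, a], P[:, a], Wmat[:, a], Q[a] = t, pvec, w, q
        expl[a] = tt * (pvec @ pvec) / ssx_total

    # w* = W (P'W)^-1: direct projection weights
    k = Wmat.shape[1]
    wstar = Wmat @ np.linalg.pinv(P.T @ Wmat) if k else Wmat
    r2y = 1.0 - (Yd ** 2).sum() / ss_y if ss_y > 0 else float("nan")
    return LatentModel("splsda", T, P, wstar, Q, mu, sd, Ym, classes,
                       tuple(keepX[:k]), raw_weights=Wmat, r2y=r2y,
                       explained_x_variance=expl, x_residual=Xd)


def fit_oplsda(X: np.ndarray, y: np.ndarray, n_orthogonal: int = 1) -> LatentModel:
    """Orthogonal-signal-corrected PLS-DA with one predictive component.

    Each orthogonal round removes from X the strongest component of the
    X-loading that is orthogonal to the class-covariance weight vector, so
    the orthogonal scores are exactly uncorrelated with y in training.
    """
    X = np.asarray(X, dtype=float)
    Y, classes = _dummy(np.asarray(y))
    yv = Y[:, 1] - Y[:, 1].mean() if Y.shape[1] == 2 else Y[:, 0] - Y[:, 0].mean()
    n, p = X.shape
    if n_orthogonal >= min(n, p):
        raise ValueError("n_orthogonal must be below rank(X)")
    Xs, mu, sd = _autoscale(X)
    Xd = Xs.copy()
    T_o = np.zeros((n, n_orthogonal))
    P_o = np.zeros((p, n_orthogonal))
    W_o = np.zeros((p, n_orthogonal))
    for a in range(n_orthogonal):
        w = Xd.T @ yv
        w /= np.linalg.norm(w)
        t = Xd @ w
        pvec = Xd.T @ t / (t @ t)
        w_o = pvec - (w @ pvec) * w
        nrm = np.linalg.norm(w_o)
        if nrm < 1e-12:
            T_o, P_o, W_o = T_o[:, :a], P_o[:, :a], W_o[:, :a]
            break
        w_o /= nrm
        t_o = Xd @ w_o
        p_o = Xd.T @ t_o / (t_o @ t_o)
        Xd = Xd - np.outer(t_o, p_o)
        T_o[:, a], P_o[:, a], W_o[:, a] = t_o, p_o, w_o

    w = Xd.T @ yv
    w /= np.linalg.norm(w)
    t = Xd @ w
    pvec = Xd.T @ t / (t @ t)
    Ym = Y.mean(axis=0)
    Yc = Y - Ym
    q = Yc.T @ t / (t @ t)
    r2y = 1.0 - ((Yc - np.outer(t, q)) ** 2).sum() / (Yc ** 2).sum()
    ssx = (Xs ** 2).sum()
    expl = np.array([(t @ t) * (pvec @ pvec) / ssx])
    model = LatentModel("oplsda", t[:, None], pvec[:, None], w[:, None],
                        q[None, :], mu, sd, Ym, classes,
                        raw_weights=w[:, None], r2y=float(r2y),
                        explained_x_variance=expl,
                        ortho_scores=T_o, ortho_loadings=P_o, ortho_weights=W_o,
                        x_residual=Xd - np.outer(t, pvec))
    return model


@dataclass
class CVReport:
    folds: list[np.ndarray]
    ber: dict[int, float]           # per component count (sPLS-DA) or {1: ber}
    auc: float
    roc: tuple[np.ndarray, np.ndarray]
    r2y: float
    q2: float
    permutation_p: float | None = None
    permutation_q2: np.ndarray | None = None


def _fit_for_spec(spec: dict, X, y):
    if spec["kind"] == "splsda":
        return fit_splsda(X, y, n_components=spec.get("n_components", 2),
                          keepX=spec.get("keepX"))
    if spec["kind"] == "oplsda":
        return fit_oplsda(X, y, n_orthogonal=spec.get("n_orthogonal", 1))
    raise ValueError(f"unknown model kind {spec['kind']!r}")


def cross_validate(spec: dict, X: np.ndarray, y: np.ndarray,
                   n_folds: int = 7, seed: int = 0,
                   n_permutations: int = 0) -> CVReport:
    """Stratified k-fold CV of a latent model specification.

    Fold assignment depends only on (seed, y).  Q2 = 1 - PRESS/SS over
    held-out dummy classes; BER uses the max-distance prediction rule, per
    component count for sPLS-DA.  The ROC is built from held-out
    first-component scores (oriented per training fold).  When
    ``n_permutations`` > 0, the permutation p-value is the rank of the true
    Q2 among Q2 values from label-permuted reruns.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes = np.unique(y)
    counts = np.array([(y == c).sum() for c in classes])
    if n_folds > counts.min():
        raise ValueError(f"n_folds={n_folds} exceeds the smallest class "
                         f"({counts.min()} samples); stratification impossible")
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    folds = [test for _, test in skf.split(np.zeros(len(y)), y)]

    def _one_cv(y_run):
        press = 0.0
        ss = 0.0
        held_scores = np.zeros(len(y_run))
        held_pred: dict[int, np.ndarray] = {}
        max_comp = (spec.get("n_components", 2) if spec["kind"] == "splsda" else 1)
        for nc in range(1, max_comp + 1):
            held_pred[nc] = np.empty(len(y_run), dtype=object)
        for train, test in ((np.setdiff1d(np.arange(len(y_run)), f), f) for f in folds):
            run_spec = dict(spec)
            model = _fit_for_spec(run_spec, X[train], y_run[train])
            Yd_test, _ = _dummy_for(classes, y_run[test])
            pred_dummy = model.predict_dummy(X[test])
            press += ((Yd_test - pred_dummy) ** 2).sum()
            Ym_train, _ = _dummy_for(classes, y_run[train])
            ss += ((Yd_test - Ym_train.mean(axis=0)) ** 2).sum()
            sc = model.transform(X[test])[:, 0]
            # orient scores so larger = second class, using training loadings
            orient = np.sign(model.y_loadings[0, -1]) or 1.0
            held_scores[test] = sc * orient
            if spec["kind"] == "splsda":
                for nc in range(1, max_comp + 1):
                    sub = _truncate(model, nc)
                    held_pred[nc][test] = sub.predict(X[test])
            else:
                held_pred[1][test] = model.predict(X[test])
        q2 = 1.0 - press / ss
        return q2, held_scores, held_pred

    q2, held_scores, held_pred = _one_cv(y)
    ber = {nc: _balanced_error(y, held_pred[nc]) for nc in held_pred}
    y_bin = (y == classes[-1]).astype(int)
    auc = float(roc_auc_score(y_bin, held_scores))
    from sklearn.metrics import roc_curve
    fpr, tpr, _ = roc_curve(y_bin, held_scores)
    full_model = _fit_for_spec(spec, X, y)

    perm_p = None
    perm_q2 = None
    if n_permutations > 0:
        rng = np.random.default_rng(seed + 1)
        perm_q2 = np.empty(n_permutations)
        for b in range(n_permutations):
            y_perm = rng.permutation(y)
            perm_q2[b], _, _ = _one_cv(y_perm)
        perm_p = (1 + int(np.sum(perm_q2 >= q2))) / (n_permutations + 1)

    return CVReport(folds, ber, auc, (fpr, tpr), full_model.r2y, q2,
                    perm_p, perm_q2)


def _dummy_for(classes: np.ndarray, y: np.ndarray):
    return (y[:, None] == classes[None, :]).astype(float), classes


def _truncate(model: LatentModel, n_comp: int) -> LatentModel:
    """View of a fitted sPLS-DA restricted to its first ``n_comp`` components."""
    if model.weights.shape[1] <= n_comp:
        return model
    from dataclasses import replace
    # P'W is upper triangular for NIPALS, so the first columns of
    # w* = W(P'W)^-1 are exactly the truncated model's projection weights.
    return replace(model, scores=model.scores[:, :n_comp],
                   y_loadings=model.y_loadings[:n_comp],
                   weights=model.weights[:, :n_comp],
                   loadings=model.loadings[:, :n_comp])


def _balanced_error(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    classes = np.unique(y_true)
    errs = [np.mean(np.asarray(y_pred)[y_true == c] != c) for c in classes]
    return float(np.mean(errs))
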