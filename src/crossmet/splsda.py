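"""Sparse partial least squares discriminant analysis (sPLS-DA).

The model regresses a one-hot class indicator on the feature matrix by
NIPALS-style iterations, hard-thresholding each X-weight vector to its
``keepx`` largest-magnitude entries (the mixOmics-style ``keepX``
cardinality constraint), and deflating X by regression on the component
scores.  Fitted models expose scores ("X-variates"), loadings, VIP
scores, class prediction and cross-validated tuning/performance.

Usage follows the statsmodels convention::

    model = SPLSDA(X, labels, n_components=2, keepx=[50, 50])
    res = model.fit()
    res.predict(X_new)
    res.vip()
    print(res.summary())
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.model_selection import StratifiedKFold


class SplsdaError(ValueError):
    pass


def _one_hot(labels, classes):
    idx = {c: k for k, c in enumerate(classes)}
    Y = np.zeros((len(labels), len(classes)))
    for i, lab in enumerate(labels):
        Y[i, idx[lab]] = 1.0
    return Y


def _threshold(w: np.ndarray, keep: int) -> np.ndarray:
    """Zero all but the ``keep`` largest |entries|; index-order tie-break."""
    if keep >= len(w):
        return w.copy()
    order = np.argsort(-np.abs(w), kind="stable")
    out = np.zeros_like(w)
    sel = order[:keep]
    out[sel] = w[sel]
    return out


class SPLSDA:
    """Sparse PLS-DA model specification.

    Parameters
    ----------
    X : array-like, shape (n_samples, n_features)
        Feature matrix (typically preprocessed: drift-corrected, imputed,
        normalized, log-transformed).
    labels : sequence
        Class label per sample; at least two classes.
    n_components : int
        Number of latent components.
    keepx : sequence of int, optional
        Number of nonzero X-weights per component; defaults to all
        features (dense PLS-DA).  Values above the feature count are
        clipped with a warning.
    scale : bool
        Autoscale features to unit variance before fitting (centering is
        always applied).
    """

    def __init__(self, X, labels, n_components: int = 2, keepx=None,
                 scale: bool = False, max_iter: int = 500, tol: float = 1e-6):
        self.X = np.asarray(X, dtype=float)
        if self.X.ndim != 2:
            raise SplsdaError("X must be 2-dimensional")
        self.labels = np.asarray(labels)
        if len(self.labels) != self.X.shape[0]:
            raise SplsdaError("labels length must match number of samples")
        self.classes = sorted(pd.unique(self.labels).tolist())
        if len(self.classes) < 2:
            raise SplsdaError("need at least 2 classes")
        self.n_components = int(n_components)
        p = self.X.shape[1]
        if keepx is None:
            keepx = [p] * self.n_components
        keepx = list(keepx)
        if len(keepx) != self.n_components:
            raise SplsdaError("keepx length must equal n_components")
        if any(k < 1 for k in keepx):
            raise SplsdaError("keepx entries must be >= 1")
        if any(k > p for k in keepx):
            import warnings

            warnings.warn("keepx exceeds feature count; clipped")
            keepx = [min(k, p) for k in keepx]
        self.keepx = keepx
        self.scale = scale
        self.max_iter = max_iter
        self.tol = tol

    def fit(self) -> "SPLSDAResults":
        X = self.X
        n, p = X.shape
        Y = _one_hot(self.labels, self.classes)
        x_mean = X.mean(axis=0)
        x_std = X.std(axis=0, ddof=1) if self.scale else np.ones(p)
        x_std = np.where(x_std == 0, 1.0, x_std)
        Xc = (X - x_mean) / x_std
        y_mean = Y.mean(axis=0)
        Yc = Y - y_mean

        H = self.n_components
        Wm = np.zeros((p, H))
        Pm = np.zeros((p, H))
        Cm = np.zeros((Y.shape[1], H))
        Tm = np.zeros((n, H))
        Xh = Xc.copy()
        for h in range(H):
            M = Xh.T @ Yc
            k0 = int(np.argmax(np.linalg.norm(M, axis=0)))
            u = Yc[:, k0].copy()
            w_old = np.zeros(p)
            for _ in range(self.max_iter):
                w = Xh.T @ u
                w = _threshold(w, self.keepx[h])
                nw = np.linalg.norm(w)
                if nw == 0:
                    raise SplsdaError(f"zero weight vector on component {h + 1}")
                w /= nw
                t = Xh @ w
                tt = t @ t
                if tt == 0:
                    raise SplsdaError(f"degenerate scores on component {h + 1}")
                c = Yc.T @ t / tt
                u = Yc @ c
                if np.linalg.norm(w - w_old) < self.tol:
                    break
                w_old = w
            t = Xh @ w
            tt = t @ t
            p_load = Xh.T @ t / tt
            c = Yc.T @ t / tt
            Wm[:, h], Pm[:, h], Cm[:, h], Tm[:, h] = w, p_load, c, t
            Xh = Xh - np.outer(t, p_load)

        return SPLSDAResults(
            model=self,
            x_weights=Wm,
            x_loadings=Pm,
            x_scores=Tm,
            y_loadings=Cm,
            x_mean=x_mean,
            x_std=x_std,
            y_mean=y_mean,
        )


def fit(X, labels, n_components=2, keepx=None, **kw) -> "SPLSDAResults":
    """Functional shorthand for ``SPLSDA(...).fit()``."""
    return SPLSDA(X, labels, n_components=n_components, keepx=keepx, **kw).fit()


@dataclass
class SPLSDAResults:
    """Fitted sPLS-DA model: weights, loadings, scores and predictions."""

    model: SPLSDA
    x_weights: np.ndarray   # p x H, unit-norm sparse weight vectors
    x_loadings: np.ndarray  # p x H
    x_scores: np.ndarray    # n x H ("X-variate" columns)
    y_loadings: np.ndarray  # K x H
    x_mean: np.ndarray
    x_std: np.ndarray
    y_mean: np.ndarray

    @property
    def classes(self):
        return self.model.classes

    @property
    def class_map(self):
        return {c: k for k, c in enumerate(self.classes)}

    @property
    def n_components(self) -> int:
        return self.model.n_components

    @property
    def keepx(self):
        return self.model.keepx

    def rotation(self, n_components: int | None = None) -> np.ndarray:
        """Projection matrix R with scores = Xc @ R (R = W (P'W)^-1)."""
        h = n_components or self.n_components
        W, P = self.x_weights[:, :h], self.x_loadings[:, :h]
        return W @ np.linalg.inv(P.T @ W)

    def coefficients(self, n_components: int | None = None) -> np.ndarray:
        """Regression coefficients B with Yhat = Xc @ B + y_mean."""
        h = n_components or self.n_components
        return self.rotation(h) @ self.y_loadings[:, :h].T

    @property
    def regression_coefficients(self) -> np.ndarray:
        return self.coefficients()

    def transform(self, Xnew, n_components: int | None = None) -> np.ndarray:
        Xnew = np.asarray(Xnew, dtype=float)
        if Xnew.shape[1] != len(self.x_mean):
            raise SplsdaError(
                f"feature dimension mismatch: {Xnew.shape[1]} vs {len(self.x_mean)}"
            )
        Xc = (Xnew - self.x_mean) / self.x_std
        return Xc @ self.rotation(n_components)

    def decision_values(self, Xnew, n_components: int | None = None) -> np.ndarray:
        Xnew = np.asarray(Xnew, dtype=float)
        if Xnew.shape[1] != len(self.x_mean):
            raise SplsdaError(
                f"feature dimension mismatch: {Xnew.shape[1]} vs {len(self.x_mean)}"
            )
        Xc = (Xnew - self.x_mean) / self.x_std
        return Xc @ self.coefficients(n_components) + self.y_mean

    def predict(self, Xnew, distance: str = "max_dist",
                n_components: int | None = None) -> np.ndarray:
        """Predict class labels for new samples.

        ``max_dist`` assigns the class with the largest predicted one-hot
        score; ``centroids_dist`` the nearest training-class centroid in
        component-score space.
        """
        classes = np.asarray(self.classes, dtype=object)
        if distance == "max_dist":
            scores = self.decision_values(Xnew, n_components)
            return classes[np.argmax(scores, axis=1)]
        if distance == "centroids_dist":
            h = n_components or self.n_components
            Tnew = self.transform(Xnew, h)
            cents = np.vstack([
                self.x_scores[self.model.labels == c, :h].mean(axis=0)
                for c in self.classes
            ])
            d = np.linalg.norm(Tnew[:, None, :] - cents[None, :, :], axis=2)
            return classes[np.argmin(d, axis=1)]
        raise SplsdaError(f"unknown distance {distance!r}")

    def explained_y_variance(self) -> np.ndarray:
        """Per-component response sum of squares explained (q_h^2 * t_h't_h)."""
        tt = np.einsum("ij,ij->j", self.x_scores, self.x_scores)
        return (self.y_loadings**2).sum(axis=0) * tt

    def vip(self) -> np.ndarray:
        """Variable importance in projection, scaled so mean(VIP^2) = 1."""
        ss = self.explained_y_variance()
        if ss.sum() <= 0:
            raise SplsdaError("zero explained response variance")
        p = self.x_weights.shape[0]
        w2 = self.x_weights**2  # columns are unit-norm
        return np.sqrt(p * (w2 @ ss) / ss.sum())

    def support(self, component: int = 0) -> np.ndarray:
        """Indices of nonzero weights on one component (0-based)."""
        return np.flatnonzero(self.x_weights[:, component])

    def to_json(self, path=None) -> str:
        payload = {
            "classes": [str(c) for c in self.classes],
            "n_components": self.n_components,
            "keepx": list(map(int, self.keepx)),
            "x_mean": self.x_mean.tolist(),
            "x_std": self.x_std.tolist(),
            "y_mean": self.y_mean.tolist(),
            "y_loadings": self.y_loadings.tolist(),
            "x_weights_sparse": [
                {"index": np.flatnonzero(col).tolist(),
                 "value": col[np.flatnonzero(col)].tolist()}
                for col in self.x_weights.T
            ],
            "x_loadings": self.x_loadings.tolist(),
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    def summary(self) -> str:
        lines = [
            "Sparse PLS-DA results",
            "=" * 46,
            f"samples: {self.x_scores.shape[0]}    features: {self.x_weights.shape[0]}",
            f"classes: {', '.join(map(str, self.classes))}",
            f"components: {self.n_components}    keepX: {list(self.keepx)}",
        ]
        ss = self.explained_y_variance()
        frac = ss / ss.sum() if ss.sum() else ss
        for h in range(self.n_components):
            nz = int((self.x_weights[:, h] != 0).sum())
            lines.append(
                f"  comp {h + 1}: nonzero weights {nz:4d}, "
                f"share of explained Y-SS {frac[h]:.3f}"
            )
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# cross-validated tuning and performance
# ---------------------------------------------------------------------------

@dataclass
class TuneResult:
    """Grid of per-component CV errors and score correlations."""

    keepx_grid: list
    errors: np.ndarray          # H x G mean misclassification
    correlations: np.ndarray    # H x G mean CV-vs-full score correlation
    chosen_keepx: list
    criterion: str
    n_folds: int
    n_repeats: int
    seed: int


def _stratified_folds(labels, n_folds, rng_seed):
    counts = pd.Series(labels).value_counts()
    if counts.min() < n_folds:
        raise SplsdaError(
            f"cannot build {n_folds} stratified folds: "
            f"smallest class has {counts.min()} samples"
        )
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=rng_seed)
    return list(skf.split(np.zeros(len(labels)), labels))


def tune(
    X,
    labels,
    keepx_grid=(50, 60, 70),
    n_components: int = 3,
    n_folds: int = 7,
    n_repeats: int = 10,
    criterion: str = "error",
    seed: int = 0,
    scale: bool = False,
) -> TuneResult:
    """Choose keepX by repeated stratified cross-validation.

    For each grid value ``g`` the model is fitted with ``keepx = [g] *
    n_components``; the error criterion is the mean held-out
    misclassification using the first h components, the correlation
    criterion the mean Pearson correlation between held-out component
    scores (projected through the fold model, sign-aligned) and the
    full-data model's scores on the same samples.
    """
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    grid = list(keepx_grid)
    if not grid:
        raise SplsdaError("empty keepx grid")
    if criterion not in ("error", "correlation"):
        raise SplsdaError(f"unknown criterion {criterion!r}")
    H, G = n_components, len(grid)
    errors = np.zeros((H, G))
    correlations = np.zeros((H, G))
    rng = np.random.default_rng(seed)

    for gi, g in enumerate(grid):
        keepx = [min(g, X.shape[1])] * H
        full = SPLSDA(X, labels, H, keepx, scale=scale).fit()
        err_sum = np.zeros(H)
        corr_sum = np.zeros(H)
        n_eval = 0
        corr_counts = np.zeros(H)
        for _ in range(n_repeats):
            folds = _stratified_folds(labels, n_folds, int(rng.integers(2**31)))
            for train, test in folds:
                res = SPLSDA(X[train], labels[train], H, keepx, scale=scale).fit()
                for h in range(1, H + 1):
                    pred = res.predict(X[test], n_components=h)
                    err_sum[h - 1] += np.mean(pred != labels[test])
                t_cv = res.transform(X[test])
                t_full = full.transform(X[test])
                sign = np.sign(
                    np.einsum("ph,ph->h", res.x_weights, full.x_weights)
                )
                sign[sign == 0] = 1.0
                for h in range(H):
                    a, b = t_cv[:, h] * sign[h], t_full[:, h]
                    if np.std(a) > 0 and np.std(b) > 0:
                        corr_sum[h] += stats.pearsonr(a, b)[0]
                        corr_counts[h] += 1
                n_eval += 1
        errors[:, gi] = err_sum / n_eval
        with np.errstate(invalid="ignore"):
            correlations[:, gi] = np.where(
                corr_counts > 0, corr_sum / np.maximum(corr_counts, 1), np.nan
            )

    if criterion == "error":
        chosen = [grid[int(np.argmin(errors[h]))] for h in range(H)]
    else:
        chosen = [grid[int(np.nanargmax(correlations[h]))] for h in range(H)]
    return TuneResult(grid, errors, correlations, chosen, criterion,
                      n_folds, n_repeats, seed)


@dataclass
class PerformanceResult:
    """Cross-validated fit quality: R2/Q2 per component and error rates."""

    r2: np.ndarray            # cumulative in-fit explained Y variance
    q2: np.ndarray            # cumulative CV predictive ability
    error_rate: float
    balanced_error_rate: float
    n_folds: int
    seed: int


def performance(
    X,
    labels,
    n_components: int = 2,
    keepx=None,
    n_folds: int = 7,
    seed: int = 0,
    scale: bool = False,
    distance: str = "max_dist",
) -> PerformanceResult:
    """R2, Q2 and error rates by stratified M-fold cross-validation.

    R2_h is the in-fit fraction of one-hot response variance explained by
    the first h components; Q2_h = 1 - PRESS_h / TSS over held-out folds.
    """
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    full = SPLSDA(X, labels, n_components, keepx, scale=scale).fit()
    classes = full.classes
    Y = _one_hot(labels, classes)
    tss = np.sum((Y - Y.mean(axis=0)) ** 2)

    r2 = np.empty(n_components)
    for h in range(1, n_components + 1):
        resid = Y - full.decision_values(X, n_components=h)
        r2[h - 1] = 1.0 - np.sum(resid**2) / tss

    press = np.zeros(n_components)
    preds = np.empty(len(labels), dtype=object)
    folds = _stratified_folds(labels, n_folds, seed)
    for train, test in folds:
        res = SPLSDA(X[train], labels[train], n_components, keepx, scale=scale).fit()
        for h in range(1, n_components + 1):
            press[h - 1] += np.sum((Y[test] - res.decision_values(
                X[test], n_components=h)) ** 2)
        preds[test] = res.predict(X[test], distance=distance)
    q2 = 1.0 - press / tss

    err = float(np.mean(preds != labels))
    per_class = [np.mean(preds[labels == c] != c) for c in classes]
    return PerformanceResult(r2, q2, err, float(np.mean(per_class)),
                             n_folds, seed)
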