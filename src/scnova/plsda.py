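"""Partial least squares discriminant analysis (PLS-DA) on gene-body NO features.

Cells are observations, normalized gene-body nucleosome occupancy values are
features, and class membership (cell type or subclone) is dummy-coded into a
response matrix. The model is a NIPALS PLS2 fit: latent components maximize
covariance between the standardized feature block and the centered response
block. Feature relevance is summarized by the variable importance in
projection,

    VIP_g = sqrt( G * sum_a w_ga^2 SS_a / sum_a SS_a ),

where G is the number of features, w_ga the normalized X-weights and SS_a the
response variance explained by component a; sum_g VIP_g^2 = G by construction.

Usage follows the Model -> fit() -> Results convention::

    res = PLSDA(X, labels, n_components=3).fit()
    res.vip()
    res.predict(X_new)
    res.auc(X_test, labels_test)
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

from .stats import bh_adjust


def _as_matrix(X):
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=float), list(X.columns), list(X.index)
    X = np.asarray(X, dtype=float)
    return X, [f"f{i}" for i in range(X.shape[1])], list(range(X.shape[0]))


def dummy_code(labels, classes=None):
    labels = np.asarray(labels)
    if classes is None:
        classes = sorted(pd.unique(labels))
    Y = np.zeros((len(labels), len(classes)))
    for j, c in enumerate(classes):
        Y[:, j] = labels == c
    return Y, list(classes)


class PLSDA:
    """PLS-DA model: cells x features matrix plus a class label per cell."""

    def __init__(self, X, labels, n_components: int = 2, min_class_size: int = 2):
        self.X, self.feature_ids, self.obs_ids = _as_matrix(X)
        self.labels = np.asarray(labels)
        if len(self.labels) != self.X.shape[0]:
            raise ValueError("labels length must match number of observations")
        classes, counts = np.unique(self.labels, return_counts=True)
        if len(classes) < 2:
            raise ValueError("need >= 2 classes")
        if counts.min() < min_class_size:
            raise ValueError(f"every class needs >= {min_class_size} cells")
        self.n_components = int(n_components)

    def fit(self, max_iter: int = 500, tol: float = 1e-12) -> "PLSDAResults":
        X = self.X.copy()
        x_mean = X.mean(axis=0)
        x_sd = X.std(axis=0, ddof=1)
        x_sd = np.where(x_sd < 1e-12, 1.0, x_sd)
        Xr = (X - x_mean) / x_sd
        Y, classes = dummy_code(self.labels)
        y_mean = Y.mean(axis=0)
        Yr = Y - y_mean

        n, G = Xr.shape
        A = min(self.n_components, n - 1, G)
        W, P, Q, T = [], [], [], []
        ss = []
        a = 0
        while a < A:
            u = Yr[:, int(np.argmax(Yr.var(axis=0)))].copy()
            t_old = None
            for _ in range(max_iter):
                w = Xr.T @ u
                nw = np.linalg.norm(w)
                if nw < 1e-14:
                    break
                w /= nw
                t = Xr @ w
                tt = t @ t
                if tt < 1e-14:
                    break
                q = Yr.T @ t / tt
                qq = q @ q
                if qq < 1e-14:
                    break
                u = Yr @ q / qq
                if t_old is not None and np.linalg.norm(t - t_old) < tol * max(1.0, np.linalg.norm(t)):
                    break
                t_old = t
            t = Xr @ w
            tt = t @ t
            if tt < 1e-12:
                warnings.warn(f"rank exhausted after {a} components (requested {self.n_components})")
                break
            q = Yr.T @ t / tt
            p = Xr.T @ t / tt
            Xr = Xr - np.outer(t, p)
            Yr = Yr - np.outer(t, q)
            W.append(w)
            P.append(p)
            Q.append(q)
            T.append(t)
            ss.append(tt * (q @ q))  # response variance captured by component a
            a += 1
        if not W:
            raise ValueError("PLS-DA fit failed: no informative component")
        return PLSDAResults(
            model=self,
            weights=np.column_stack(W),
            loadings=np.column_stack(P),
            y_loadings=np.column_stack(Q),
            scores=np.column_stack(T),
            ss=np.array(ss),
            x_mean=x_mean,
            x_sd=x_sd,
            y_mean=y_mean,
            classes=classes,
            feature_ids=list(self.feature_ids),
        )


@dataclass
class PLSDAResults:
    """Fitted PLS-DA model: weights, loadings, explained response variance."""

    model: PLSDA
    weights: np.ndarray  # G x A normalized X-weights
    loadings: np.ndarray  # G x A
    y_loadings: np.ndarray  # K x A
    scores: np.ndarray  # n x A
    ss: np.ndarray  # per-component explained response variance
    x_mean: np.ndarray
    x_sd: np.ndarray
    y_mean: np.ndarray
    classes: list
    feature_ids: list
    _coef: np.ndarray = field(default=None, repr=False)

    @property
    def n_components(self) -> int:
        return self.weights.shape[1]

    def coefficients(self) -> np.ndarray:
        if self._coef is None:
            W, P, Q = self.weights, self.loadings, self.y_loadings
            self._coef = W @ np.linalg.solve(P.T @ W, Q.T)
        return self._coef

    def vip(self) -> pd.Series:
        w2 = self.weights**2
        v = np.sqrt(len(self.feature_ids) * (w2 @ self.ss) / self.ss.sum())
        return pd.Series(v, index=self.feature_ids, name="vip")

    def select_features(self, threshold: float = 1.0) -> list:
        v = self.vip()
        return list(v.index[v > threshold])

    def _standardize(self, X) -> tuple:
        if isinstance(X, pd.DataFrame):
            missing = [f for f in self.feature_ids if f not in X.columns]
            if missing:
                raise ValueError(f"missing features: {missing[:10]}{'...' if len(missing) > 10 else ''}")
            Xm = X[self.feature_ids].to_numpy(dtype=float)
            idx = list(X.index)
        else:
            Xm = np.atleast_2d(np.asarray(X, dtype=float))
            if Xm.shape[1] != len(self.feature_ids):
                raise ValueError(f"expected {len(self.feature_ids)} features, got {Xm.shape[1]}")
            idx = list(range(Xm.shape[0]))
        return (Xm - self.x_mean) / self.x_sd, idx

    def predict(self, X) -> pd.DataFrame:
        """Per-cell class scores (projected dummy predictions) and hard labels."""
        Xs, idx = self._standardize(X)
        scores = Xs @ self.coefficients() + self.y_mean
        out = pd.DataFrame(scores, columns=self.classes, index=idx)
        out["label"] = [self.classes[k] for k in np.argmax(scores, axis=1)]
        return out

    def auc(self, X, labels) -> float:
        """One-vs-rest AUC, macro-averaged over classes."""
        pred = self.predict(X)
        Y, _ = dummy_code(labels, self.classes)
        aucs = []
        for j, c in enumerate(self.classes):
            if Y[:, j].min() == Y[:, j].max():
                continue
            aucs.append(roc_auc_score(Y[:, j], pred[c].to_numpy()))
        if not aucs:
            raise ValueError("AUC undefined: single-class labels")
        return float(np.mean(aucs))

    def refit_selected(self, threshold: float = 1.0) -> "PLSDAResults":
        """Refit on the VIP-selected feature subset."""
        keep = self.select_features(threshold)
        if not keep:
            raise ValueError("no feature passes the VIP threshold")
        pos = [self.feature_ids.index(f) for f in keep]
        sub = PLSDA(
            pd.DataFrame(self.model.X[:, pos], columns=keep, index=self.model.obs_ids),
            self.model.labels,
            self.n_components,
        )
        return sub.fit()

    def summary(self) -> str:
        lines = [
            "PLS-DA results",
            f"  observations: {self.model.X.shape[0]}  features: {len(self.feature_ids)}",
            f"  classes: {', '.join(map(str, self.classes))}",
            f"  components: {self.n_components}",
            "  explained response variance per component: "
            + ", ".join(f"{s / self.ss.sum():.3f}" for s in self.ss),
        ]
        top = self.vip().sort_values(ascending=False).head(5)
        lines.append("  top VIP features: " + ", ".join(f"{g} ({v:.2f})" for g, v in top.items()))
        return "\n".join(lines)


def cross_val_auc(X, labels, n_components: int = 2, n_splits: int = 5, seed: int = 0) -> float:
    """Stratified cross-validated macro AUC of a PLS-DA classifier."""
    from sklearn.model_selection import StratifiedKFold

    Xm, feat, _ = _as_matrix(X)
    labels = np.asarray(labels)
    skf = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
    aucs = []
    for tr, te in skf.split(Xm, labels):
        res = PLSDA(pd.DataFrame(Xm[tr], columns=feat), labels[tr], n_components).fit()
        try:
            aucs.append(res.auc(pd.DataFrame(Xm[te], columns=feat), labels[te]))
        except ValueError:
            continue
    return float(np.mean(aucs))


def plsda_permutation_test(X, labels, n_components: int = 2, n_perm: int = 199, seed: int = 0, min_class_size: int = 2):
    """Per-feature VIP with permutation p-values under label shuffling.

    p_g = (1 + #{perm VIP_g >= observed VIP_g}) / (n_perm + 1). When fewer
    distinct label arrangements than ``n_perm`` exist they are enumerated
    exhaustively instead.
    """
    from itertools import combinations
    from math import comb

    labels = np.asarray(labels)
    res = PLSDA(X, labels, n_components, min_class_size=min_class_size).fit()
    vip_obs = res.vip().to_numpy()
    n = len(labels)
    classes, counts = np.unique(labels, return_counts=True)
    exceed = np.zeros(len(vip_obs))
    if len(classes) == 2 and comb(n, int(counts[0])) <= n_perm:
        arrangements = []
        base = np.array([classes[1]] * n, dtype=labels.dtype)
        for pos in combinations(range(n), int(counts[0])):
            lab = base.copy()
            lab[list(pos)] = classes[0]
            arrangements.append(lab)
        n_done = len(arrangements)
        for lab in arrangements:
            vip_p = PLSDA(X, lab, n_components, min_class_size=min_class_size).fit().vip().to_numpy()
            exceed += vip_p >= vip_obs
    else:
        rng = np.random.default_rng(seed)
        n_done = n_perm
        lab = labels.copy()
        for _ in range(n_perm):
            rng.shuffle(lab)
            vip_p = PLSDA(X, lab, n_components, min_class_size=min_class_size).fit().vip().to_numpy()
            exceed += vip_p >= vip_obs
    p = (1.0 + exceed) / (n_done + 1.0)
    return pd.DataFrame({"vip": vip_obs, "p": p, "q": bh_adjust(p)}, index=res.feature_ids)
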