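"""Supervised projection models for metabolomic fingerprints.

PLS-DA regresses autoscaled intensities against one-hot class indicators
with the NIPALS algorithm; OPLS-DA additionally strips class-orthogonal
structured variation from a two-class model so the single predictive
component carries all between-class separation. Model quality follows the
conventions of chemometric practice: cumulative R²Y (explained indicator
variance), Q² from stratified 7-fold cross-validation (1 − PRESS/TSS on the
centered indicator matrix), a cross-validated classification table with its
CC% (correctly classified), and label-permutation p-values for both R²Y
and Q².

Both models are sklearn estimators: ``fit``/``predict``/``transform``,
``get_params``/``set_params``, trailing-underscore fitted attributes. They
therefore compose with :mod:`sklearn.model_selection` and pipelines.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.model_selection import StratifiedKFold

from .core import ValidationError

__all__ = [
    "PLSDAClassifier",
    "OPLSDAClassifier",
    "ModelQuality",
    "fit_plsda",
    "fit_oplsda",
    "cross_validate",
    "permutation_validate",
    "project_samples",
]


def _as_matrix(X):
    cols = list(X.columns) if isinstance(X, pd.DataFrame) else None
    A = np.asarray(X, dtype=float)
    if A.ndim != 2:
        raise ValidationError("X must be a 2-D samples x features matrix")
    if np.isnan(A).any():
        raise ValidationError("X contains missing values; impute upstream")
    return A, cols


def _check_classes(y, min_members: int = 2):
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValidationError("need at least 2 classes")
    small = classes[counts < min_members]
    if small.size:
        raise ValidationError(f"class {small[0]!r} has fewer than {min_members} members")
    return y, classes


def _autoscale_fit(A):
    mean = A.mean(axis=0)
    std = A.std(axis=0, ddof=1)
    return mean, std


class _DABase(ClassifierMixin, BaseEstimator):
    """Shared autoscaling, validation and projection machinery."""

    def _prepare(self, X, y):
        A, cols = _as_matrix(X)
        y, classes = _check_classes(y)
        if A.shape[0] != len(y):
            raise ValidationError("X and y length mismatch")
        mean, std = _autoscale_fit(A)
        zero = np.where(std == 0)[0]
        if zero.size:
            name = cols[zero[0]] if cols else f"column {zero[0]}"
            raise ValidationError(f"constant (zero variance) feature: {name}")
        self.feature_names_in_ = cols
        self.n_features_in_ = A.shape[1]
        self.classes_ = classes
        self.x_mean_, self.x_std_ = mean, std
        Y = np.array([[1.0 if yi == c else 0.0 for c in classes] for yi in y])
        self.y_mean_ = Y.mean(axis=0)
        return (A - mean) / std, Y - self.y_mean_, Y

    def _scale_new(self, X):
        A, cols = _as_matrix(X)
        if A.shape[1] != self.n_features_in_:
            raise ValidationError(
                f"feature mismatch: model fitted with {self.n_features_in_}, got {A.shape[1]}"
            )
        if cols is not None and self.feature_names_in_ is not None and cols != self.feature_names_in_:
            raise ValidationError("feature names/order differ from training matrix")
        return (A - self.x_mean_) / self.x_std_

    def predict(self, X):
        """Class with the largest predicted indicator; ties break toward the
        smaller class index."""
        Yhat = self.decision_function(X)
        return self.classes_[np.argmax(Yhat, axis=1)]


def _sign_fix(w):
    """Deterministic sign convention: the largest-magnitude weight is positive."""
    s = np.sign(w[np.argmax(np.abs(w))])
    return 1.0 if s == 0 else s


def _nipals(E, F, n_components, tol=1e-12, max_iter=1000):
    """NIPALS PLS2 on preprocessed E (X) and F (Y); returns W, T, P, Q."""
    n, p = E.shape
    g = F.shape[1]
    W = np.zeros((p, n_components))
    T = np.zeros((n, n_components))
    P = np.zeros((p, n_components))
    Q = np.zeros((g, n_components))
    actual = 0
    for k in range(n_components):
        if np.linalg.norm(F) < 1e-12 or np.linalg.norm(E) < 1e-12:
            break  # residual exhausted: rank bound reached
        u = F[:, np.argmax(F.var(axis=0))].copy()
        t_old = None
        for _ in range(max_iter):
            w = E.T @ u / (u @ u)
            w /= np.linalg.norm(w)
            t = E @ w
            q = F.T @ t / (t @ t)
            if np.linalg.norm(q) < 1e-14:
                break
            u = F @ q / (q @ q)
            if t_old is not None and np.linalg.norm(t - t_old) <= tol * np.linalg.norm(t):
                break
            t_old = t
        s = _sign_fix(w)
        w, t, q = s * w, s * t, s * q
        pk = E.T @ t / (t @ t)
        E = E - np.outer(t, pk)
        F = F - np.outer(t, q)
        W[:, k], T[:, k], P[:, k], Q[:, k] = w, t, pk, q
        actual = k + 1
    return W[:, :actual], T[:, :actual], P[:, :actual], Q[:, :actual]


class PLSDAClassifier(_DABase):
    """Partial least squares discriminant analysis (NIPALS PLS2).

    X is mean-centered and unit-variance scaled (autoscaling, sample sd);
    the class-indicator matrix Y is one-hot and mean-centered. Successive
    score vectors are mutually orthogonal. Deterministic given input order.

    Attributes (after ``fit``)
    --------------------------
    x_weights_ (p, k), x_scores_ (n, k), x_loadings_ (p, k),
    y_loadings_ (g, k), x_rotations_ (p, k) : NIPALS matrices.
    coef_ : regression coefficients mapping scaled X to centered Y.
    r2y_cum_ : cumulative fraction of centered-Y variance explained, per
        component; non-decreasing and bounded by 1.
    """

    kind = "plsda"

    def __init__(self, n_components: int = 2):
        self.n_components = n_components

    def fit(self, X, y):
        if self.n_components < 1:
            raise ValidationError("n_components must be >= 1")
        E, F, _ = self._prepare(X, y)
        tss = float((F**2).sum())
        W, T, P, Q = _nipals(E.copy(), F.copy(), self.n_components)
        if W.shape[1] < self.n_components:
            warnings.warn(
                f"Y residual exhausted after {W.shape[1]} components "
                f"(requested {self.n_components})"
            )
        self.x_weights_, self.x_scores_, self.x_loadings_, self.y_loadings_ = W, T, P, Q
        self.n_components_ = W.shape[1]
        self.x_rotations_ = W @ np.linalg.pinv(P.T @ W)
        self.coef_ = self.x_rotations_ @ Q.T
        r2 = []
        for k in range(1, self.n_components_ + 1):
            resid = F - T[:, :k] @ Q[:, :k].T
            r2.append(1.0 - float((resid**2).sum()) / tss)
        self.r2y_cum_ = np.array(r2)
        return self

    def transform(self, X):
        return self._scale_new(X) @ self.x_rotations_

    def decision_function(self, X, n_components: int | None = None):
        """Predicted class-indicator values (one column per class)."""
        k = self.n_components_ if n_components is None else min(n_components, self.n_components_)
        Z = self._scale_new(X)
        B = self.x_rotations_[:, :k] @ self.y_loadings_[:, :k].T
        return Z @ B + self.y_mean_


class OPLSDAClassifier(_DABase):
    """Two-class orthogonal PLS-DA (orthogonal signal correction).

    ``n_orthogonal`` components of Y-orthogonal structured variation are
    removed before a single predictive component is extracted, so with
    ``n_orthogonal=0`` the predictive scores coincide with one-component
    PLS-DA. Predictive and orthogonal score vectors are mutually orthogonal.
    """

    kind = "oplsda"

    def __init__(self, n_orthogonal: int = 1):
        self.n_orthogonal = n_orthogonal

    # fitted: x_weights_ (p,1) predictive weight; x_scores_ predictive scores;
    # ortho_weights_/ortho_scores_/ortho_loadings_ for the removed part.
    def fit(self, X, y):
        if self.n_orthogonal < 0:
            raise ValidationError("n_orthogonal must be >= 0")
        E, F, _ = self._prepare(X, y)
        if len(self.classes_) != 2:
            raise ValidationError("OPLS-DA requires exactly 2 classes")
        yc = F[:, 1]  # centered indicator of the second class
        tss = float(F[:, 1] @ F[:, 1]) * 2  # both indicator columns, symmetric
        w = E.T @ yc / (yc @ yc)
        w /= np.linalg.norm(w)
        w *= _sign_fix(w)
        n, p = E.shape
        Wo = np.zeros((p, self.n_orthogonal))
        To = np.zeros((n, self.n_orthogonal))
        Po = np.zeros((p, self.n_orthogonal))
        n_o = 0
        for k in range(self.n_orthogonal):
            t = E @ w
            pk = E.T @ t / (t @ t)
            wo = pk - (w @ pk) * w
            norm = np.linalg.norm(wo)
            if norm < 1e-12:
                warnings.warn(f"no orthogonal variation left after {k} components")
                break
            wo /= norm
            to = E @ wo
            po = E.T @ to / (to @ to)
            E = E - np.outer(to, po)
            Wo[:, k], To[:, k], Po[:, k] = wo, to, po
            n_o = k + 1
        self.ortho_weights_, self.ortho_scores_, self.ortho_loadings_ = (
            Wo[:, :n_o], To[:, :n_o], Po[:, :n_o],
        )
        self.n_orthogonal_ = n_o
        t = E @ w
        self.x_weights_ = w[:, None]
        self.x_scores_ = t[:, None]
        self.x_loadings_ = (E.T @ t / (t @ t))[:, None]
        q = F.T @ t / (t @ t)  # (2,) loadings for both indicator columns
        self.y_loadings_ = q[:, None]
        self.n_components_ = 1
        resid = F - np.outer(t, q)
        self.r2y_cum_ = np.array([1.0 - float((resid**2).sum()) / tss])
        return self

    def _filter(self, Z):
        for k in range(self.n_orthogonal_):
            to = Z @ self.ortho_weights_[:, k]
            Z = Z - np.outer(to, self.ortho_loadings_[:, k])
        return Z

    def transform(self, X):
        """Predictive score (column 0) then orthogonal scores of new samples."""
        Z = self._scale_new(X)
        t_ortho = np.zeros((Z.shape[0], self.n_orthogonal_))
        for k in range(self.n_orthogonal_):
            t_ortho[:, k] = Z @ self.ortho_weights_[:, k]
            Z = Z - np.outer(t_ortho[:, k], self.ortho_loadings_[:, k])
        t_pred = Z @ self.x_weights_[:, 0]
        return np.column_stack([t_pred, t_ortho])

    def decision_function(self, X, n_components: int | None = None):
        Z = self._filter(self._scale_new(X))
        t = Z @ self.x_weights_[:, 0]
        return np.outer(t, self.y_loadings_[:, 0]) + self.y_mean_


# ---------------------------------------------------------------------------
# quality assessment


@dataclass
class ModelQuality:
    """Cross-validated quality of a discriminant model."""

    kind: str
    r2y_cum: list[float]
    q2_cum: list[float]
    classification_table: pd.DataFrame
    cc_percent: float
    folds: int
    n_permutations: int = 0
    p_r2y: float | None = None
    p_q2: float | None = None
    seed: int | None = None

    @property
    def q2(self) -> float:
        return self.q2_cum[-1]

    @property
    def r2y(self) -> float:
        return self.r2y_cum[-1]

    def to_dict(self) -> dict:
        return {
            "kind": self.kind,
            "r2y_cum": [float(v) for v in self.r2y_cum],
            "q2_cum": [float(v) for v in self.q2_cum],
            "classification_table": {
                str(k): {str(c): int(v) for c, v in row.items()}
                for k, row in self.classification_table.to_dict(orient="index").items()
            },
            "cc_percent": float(self.cc_percent),
            "folds": self.folds,
            "n_permutations": self.n_permutations,
            "p_r2y": self.p_r2y,
            "p_q2": self.p_q2,
            "seed": self.seed,
        }


def _make_model(kind: str, n_components: int) -> _DABase:
    if kind == "plsda":
        return PLSDAClassifier(n_components=n_components)
    if kind == "oplsda":
        return OPLSDAClassifier(n_orthogonal=n_components)
    raise ValidationError(f"unknown model kind {kind!r}")


def cross_validate(
    X, y, kind: str = "plsda", n_components: int = 2, folds: int = 7, seed: int = 0
) -> ModelQuality:
    """Stratified k-fold cross-validation of a discriminant model.

    The sample set is partitioned into ``folds`` random stratified subsets;
    each subset is predicted by a model fitted on the others, so every sample
    is predicted exactly once. Q² = 1 − PRESS/TSS on the centered one-hot
    indicator matrix, pooled over folds; the classification table counts
    argmax-indicator class assignments of held-out samples.
    """
    A, _ = _as_matrix(X)
    y = np.asarray(y)
    if A.shape[0] < folds:
        raise ValidationError(f"fewer samples ({A.shape[0]}) than folds ({folds})")
    classes, counts = np.unique(y, return_counts=True)
    if counts.min() < folds:
        warnings.warn(
            f"smallest class has {counts.min()} members; reducing folds from {folds}"
        )
        folds = int(counts.min())
        if folds < 2:
            raise ValidationError("smallest class too small to cross-validate")
    Y = np.array([[1.0 if yi == c else 0.0 for c in classes] for yi in y])
    tss_vec = ((Y - Y.mean(axis=0)) ** 2).sum()
    kmax = n_components if kind == "plsda" else 1
    press = np.zeros(kmax)
    pred_class = np.empty(len(y), dtype=object)
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    for train, test in skf.split(A, y):
        model = _make_model(kind, n_components).fit(A[train], y[train])
        for k in range(1, kmax + 1):
            Yhat = model.decision_function(A[test], n_components=k)
            # map the fold model's class order onto the global one
            col = {c: j for j, c in enumerate(model.classes_)}
            Yhat = Yhat[:, [col[c] for c in classes]]
            press[k - 1] += ((Y[test] - Yhat) ** 2).sum()
            if k == kmax:
                pred_class[test] = classes[np.argmax(Yhat, axis=1)]
    q2_cum = [1.0 - float(p) / tss_vec for p in press]
    ct = pd.crosstab(
        pd.Series(y, name="true"), pd.Series(pred_class, name="predicted")
    ).reindex(index=classes, columns=classes, fill_value=0)
    cc = 100.0 * np.trace(ct.to_numpy()) / len(y)
    full = _make_model(kind, n_components).fit(A, y)
    return ModelQuality(
        kind=kind,
        r2y_cum=list(full.r2y_cum_),
        q2_cum=q2_cum,
        classification_table=ct,
        cc_percent=cc,
        folds=folds,
        seed=seed,
    )


def permutation_validate(
    X,
    y,
    kind: str = "plsda",
    n_components: int = 2,
    n_permutations: int = 200,
    folds: int = 7,
    seed: int = 0,
) -> tuple[float, float]:
    """Label-permutation p-values for R²Y and Q².

    p = (1 + #{permuted statistic >= observed}) / (1 + n_permutations); the
    observed model counts itself in the denominator, so p >= 1/(n+1).
    """
    if n_permutations < 20:
        raise ValidationError("n_permutations must be >= 20")
    obs = cross_validate(X, y, kind, n_components, folds, seed)
    rng = np.random.default_rng(seed)
    y = np.asarray(y)
    ge_r2, ge_q2 = 0, 0
    for _ in range(n_permutations):
        yp = rng.permutation(y)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            perm = cross_validate(X, yp, kind, n_components, obs.folds, seed)
        ge_r2 += perm.r2y >= obs.r2y
        ge_q2 += perm.q2 >= obs.q2
    p_r2y = (1 + ge_r2) / (1 + n_permutations)
    p_q2 = (1 + ge_q2) / (1 + n_permutations)
    return p_r2y, p_q2


# ---------------------------------------------------------------------------
# thin wrappers


def fit_plsda(X, y, n_components: int = 2) -> PLSDAClassifier:
    return PLSDAClassifier(n_components=n_components).fit(X, y)


def fit_oplsda(X, y, n_orthogonal: int = 1) -> OPLSDAClassifier:
    return OPLSDAClassifier(n_orthogonal=n_orthogonal).fit(X, y)


def project_samples(model: _DABase, X_new) -> np.ndarray:
    """Component scores of new samples under a fitted model's preprocessing."""
    return model.transform(X_new)
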