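"""Biomarker validation: ROC/Youden/DeLong per feature, group-median
imputation, and SVM-RBF leave-one-out classification over significant
feature panels.

The AUC is computed by Mann-Whitney pair counting (ties count half) with
automatic orientation so the reported value is >= 0.5; the operating
threshold maximizes the Youden index J = sensitivity + specificity - 1 over
midpoints of adjacent distinct pooled scores; the DeLong structural-
components variance yields a Wald 95% CI and a one-sided p-value against
AUC = 0.5. The panel-level check trains a soft-margin RBF support vector
machine and reports leave-one-out accuracy, standardizing features with
training-fold statistics inside every iteration to avoid leakage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.model_selection import LeaveOneOut
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .core import FeatureTable, ValidationError

logger = logging.getLogger(__name__)

DEGENERATE_P = 1e-16  # reported when DeLong variance collapses to zero


@dataclass
class RocResult:
    feature_id: str
    comparison: tuple[str, str]
    auc: float
    ci95_low: float
    ci95_high: float
    p_greater: float
    youden_threshold: float
    sensitivity: float
    specificity: float
    orientation: str  # group treated as "positive" (higher scores)
    degenerate: bool = False

    def to_dict(self) -> dict:
        d = dict(self.__dict__)
        d["comparison"] = list(self.comparison)
        return d


@dataclass
class SvmReport:
    comparison: tuple[str, str]
    feature_ids: list[str]
    kernel: str
    accuracy_percent: float
    per_class_accuracy: dict[str, float]
    c: float
    gamma: str | float
    standardized: bool
    seed: int
    dropped_features: list[str]

    def to_dict(self) -> dict:
        d = dict(self.__dict__)
        d["comparison"] = list(self.comparison)
        return d


# ---------------------------------------------------------------------------
# ROC primitives


def auc_mann_whitney(scores_pos, scores_neg) -> float:
    """AUC by pair counting: P(pos > neg) + 0.5 P(pos = neg)."""
    pos = np.asarray(scores_pos, float)
    neg = np.asarray(scores_neg, float)
    if len(pos) == 0 or len(neg) == 0:
        raise ValidationError("both groups must be non-empty")
    pooled = np.concatenate([pos, neg])
    ranks = stats.rankdata(pooled)
    r_pos = ranks[: len(pos)].sum()
    u = r_pos - len(pos) * (len(pos) + 1) / 2.0
    return float(u / (len(pos) * len(neg)))


def youden_threshold(scores_pos, scores_neg) -> tuple[float, float, float]:
    """Maximize J = sensitivity + specificity - 1 over candidate thresholds.

    Candidates are midpoints between adjacent distinct pooled scores plus
    +/- infinity; a sample is called positive when its score >= threshold.
    Ties in J break toward higher sensitivity, then lower threshold.
    """
    pos = np.asarray(scores_pos, float)
    neg = np.asarray(scores_neg, float)
    if len(pos) == 0 or len(neg) == 0:
        raise ValidationError("both groups must be non-empty")
    distinct = np.unique(np.concatenate([pos, neg]))
    mids = (distinct[:-1] + distinct[1:]) / 2.0 if len(distinct) > 1 else np.array([])
    candidates = np.concatenate([[-np.inf], mids, [np.inf]])
    best = None
    for thr in candidates:
        sens = float((pos >= thr).mean())
        spec = float((neg < thr).mean())
        j = sens + spec - 1.0
        key = (j, sens, -thr)
        if best is None or key > best[0]:
            best = (key, thr, sens, spec)
    _, thr, sens, spec = best
    return float(thr), sens, spec


def _delong_components(pos: np.ndarray, neg: np.ndarray):
    """Structural components V10 (per positive) and V01 (per negative)."""
    cmp = (pos[:, None] > neg[None, :]).astype(float) + 0.5 * (
        pos[:, None] == neg[None, :]
    )
    return cmp.mean(axis=1), cmp.mean(axis=0)


def delong_variance(scores_pos, scores_neg) -> float:
    pos = np.asarray(scores_pos, float)
    neg = np.asarray(scores_neg, float)
    v10, v01 = _delong_components(pos, neg)
    return float(np.var(v10, ddof=1) / len(pos) + np.var(v01, ddof=1) / len(neg))


def delong_inference(scores_pos, scores_neg) -> tuple[float, float, float]:
    """Wald 95% CI (truncated to [0, 1]) and one-sided p for AUC > 0.5."""
    pos = np.asarray(scores_pos, float)
    neg = np.asarray(scores_neg, float)
    if len(pos) < 2 or len(neg) < 2:
        raise ValidationError("DeLong inference needs >= 2 scores per group")
    auc = auc_mann_whitney(pos, neg)
    var = delong_variance(pos, neg)
    if var <= 0:
        # perfect separation (or total degeneracy): variance collapses
        p = DEGENERATE_P if auc > 0.5 else 0.5
        return max(0.0, auc), min(1.0, auc), p
    se = np.sqrt(var)
    z = (auc - 0.5) / se
    lo = max(0.0, auc - 1.959963984540054 * se)
    hi = min(1.0, auc + 1.959963984540054 * se)
    return lo, hi, float(stats.norm.sf(z))


def roc_analysis(
    table: FeatureTable,
    feature_ids: list[str],
    group_a: str | list[str],
    group_b: str | list[str],
    names: tuple[str, str] | None = None,
) -> list[RocResult]:
    """Per-feature ROC with auto-orientation so the reported AUC >= 0.5."""
    out = []
    A = table.group_intensities(group_a)
    B = table.group_intensities(group_b)
    if names is None:
        names = (
            group_a if isinstance(group_a, str) else "+".join(group_a),
            group_b if isinstance(group_b, str) else "+".join(group_b),
        )
    group_a, group_b = names
    for fid in feature_ids:
        a = A[fid].dropna().to_numpy(float)
        b = B[fid].dropna().to_numpy(float)
        if len(a) < 2 or len(b) < 2:
            logger.info("feature %s: too few values for ROC in (%s, %s)", fid, group_a, group_b)
            continue
        auc_ab = auc_mann_whitney(a, b)
        if auc_ab >= 0.5:
            pos, neg, orientation = a, b, group_a
        else:
            pos, neg, orientation = b, a, group_b
        auc = auc_mann_whitney(pos, neg)
        lo, hi, p = delong_inference(pos, neg)
        thr, sens, spec = youden_threshold(pos, neg)
        var = delong_variance(pos, neg)
        out.append(RocResult(
            feature_id=fid, comparison=(group_a, group_b), auc=auc,
            ci95_low=lo, ci95_high=hi, p_greater=p,
            youden_threshold=thr, sensitivity=sens, specificity=spec,
            orientation=orientation, degenerate=var <= 0,
        ))
    return out


# ---------------------------------------------------------------------------
# imputation + SVM


def impute_median_by_group(
    table: FeatureTable, groups: list[str] | None = None
) -> tuple[FeatureTable, list[str]]:
    """Replace missing values by the within-group median of the feature.

    Features with a (group, feature) cell that has no present value at all
    are dropped from the returned table and listed second in the result.
    QC samples, if any remain, are imputed with the QC median.
    """
    groups = groups if groups is not None else table.group_labels()
    X = table.intensities.copy()
    S = table.samples
    dropped: list[str] = []
    strata = [("__qc__", S["is_qc"].astype(bool).to_numpy())] + [
        (g, (S["group"] == g).to_numpy()) for g in groups
    ]
    for fid in X.columns:
        col = X[fid]
        if not col.isna().any():
            continue
        new = col.copy()
        ok = True
        for g, mask in strata:
            if not mask.any():
                continue
            vals = col[mask]
            if not vals.isna().any():
                continue
            if not vals.notna().any():
                ok = False
                break
            med = vals.median()
            new[mask] = vals.fillna(med)
        if ok:
            X[fid] = new
        else:
            dropped.append(fid)
    if dropped:
        logger.info("dropping %d features fully missing within a group", len(dropped))
        X = X.drop(columns=dropped)
    feats = table.features.drop(index=dropped)
    return FeatureTable(X, table.samples.copy(), feats, scale=table.scale), dropped


def svm_loocv_accuracy(
    X,
    y,
    c: float = 1.0,
    gamma: str | float = "scale",
    seed: int = 0,
    comparison: tuple[str, str] | None = None,
    feature_ids: list[str] | None = None,
    dropped_features: list[str] | None = None,
) -> SvmReport:
    """Leave-one-out accuracy of an RBF support vector machine.

    Each sample is predicted by an SVM trained on the remaining n-1;
    features are z-scored with training-fold statistics inside every
    iteration. Deterministic given the hyperparameters.
    """
    A = np.asarray(X, float)
    y = np.asarray(y)
    if np.isnan(A).any():
        raise ValidationError("X contains missing values; impute first")
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) != 2:
        raise ValidationError("SVM check is defined for exactly 2 classes")
    if counts.min() < 2:
        raise ValidationError(f"class {classes[np.argmin(counts)]!r} has a single member")
    pred = np.empty(len(y), dtype=object)
    for train, test in LeaveOneOut().split(A):
        clf = make_pipeline(
            StandardScaler(), SVC(C=c, gamma=gamma, kernel="rbf", random_state=seed)
        )
        clf.fit(A[train], y[train])
        pred[test[0]] = clf.predict(A[test])[0]
    correct = pred == y
    per_class = {
        str(cl): float(100.0 * correct[y == cl].mean()) for cl in classes
    }
    if feature_ids is None:
        feature_ids = list(X.columns) if isinstance(X, pd.DataFrame) else [
            f"f{i}" for i in range(A.shape[1])
        ]
    return SvmReport(
        comparison=comparison or (str(classes[0]), str(classes[1])),
        feature_ids=list(feature_ids),
        kernel="rbf",
        accuracy_percent=float(100.0 * correct.mean()),
        per_class_accuracy=per_class,
        c=c,
        gamma=gamma,
        standardized=True,
        seed=seed,
        dropped_features=list(dropped_features or []),
    )
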