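"""End-to-end orchestration of the analysis on one single-polarity table.

Order of operations mirrors the published workflow: filter cascade and
drift correction, log10 transform; per-pair univariate screening with FDR;
ROC/Youden/DeLong on the FDR-significant features; group-median imputation
and SVM-RBF leave-one-out accuracy over the significant panel; PLS-DA on
the three top-level groups with QC samples projected into the score space;
OPLS-DA per disjoint two-group comparison.

Nested subgroups (a label such as ``Ia`` inside group ``I``) are resolved
by prefix: a comparison member named ``I`` means the union of ``I`` and its
subgroup labels. Comparisons whose two sides share samples (I vs Ia) run
the univariate screen only — a classifier cannot hold the same sample in
both classes, which is why the published accuracy table has no such row.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .core import FeatureTable, StudyConfig, ValidationError
from .multivariate import (
    ModelQuality,
    PLSDAClassifier,
    cross_validate,
    permutation_validate,
    project_samples,
)
from .preprocess import FilterReport, run_preprocess
from .univariate import UnivariateResult, adjust_fdr, compare_groups, results_to_frame
from .validate import SvmReport, impute_median_by_group, roc_analysis, svm_loocv_accuracy

logger = logging.getLogger(__name__)

STUDY_COMPARISONS = [("I", "Ia"), ("I", "II"), ("Ia", "II"), ("I", "III"), ("II", "III")]


def subgroup_parents(labels: list[str]) -> dict[str, str]:
    """Infer nesting from label shape: ``Ia`` is a subgroup of ``I``.

    A label is nested in another when it extends it by a lowercase suffix,
    so ``Ia`` ⊂ ``I`` but ``II`` is not nested in ``I``.
    """
    parents = {}
    for lab in labels:
        cands = [
            p for p in labels
            if p != lab and lab.startswith(p) and lab[len(p):].islower()
        ]
        if cands:
            parents[lab] = max(cands, key=len)
    return parents


def resolve_group(name: str, labels: list[str], parents: dict[str, str]) -> list[str]:
    if name in labels:
        return [name] + [l for l, p in parents.items() if p == name]
    raise ValidationError(f"unknown group {name!r} in comparison (labels: {labels})")


@dataclass
class ComparisonResult:
    comparison: tuple[str, str]
    univariate: list[UnivariateResult]
    significant: list[str]
    roc: list
    svm: SvmReport | None
    svm_skipped_reason: str | None
    oplsda_quality: ModelQuality | None

    def table2_frame(self) -> pd.DataFrame:
        uni = results_to_frame(self.univariate)
        uni["comparison"] = "{} vs {}".format(*self.comparison)
        roc_cols = ["auc", "ci95_low", "ci95_high", "p_greater",
                    "youden_threshold", "sensitivity", "specificity"]
        if self.roc:
            roc = pd.DataFrame([r.to_dict() for r in self.roc])
            roc = roc.drop(columns=["comparison", "degenerate"], errors="ignore")
            merged = uni.merge(roc, on="feature_id", how="left")
        else:
            merged = uni.copy()
            for c in roc_cols:
                merged[c] = np.nan
            merged["orientation"] = pd.Series([None] * len(merged), dtype=object)
        merged["significant"] = merged["feature_id"].isin(self.significant)
        return merged


@dataclass
class AnalysisResult:
    """Everything one run of the workflow produces."""

    config: StudyConfig
    preprocessed: FeatureTable
    filter_report: FilterReport
    comparisons: list[ComparisonResult]
    plsda_quality: ModelQuality | None
    plsda_model: PLSDAClassifier | None
    qc_scores: np.ndarray | None
    group_scores: dict[str, np.ndarray] = field(default_factory=dict)

    def table2(self) -> pd.DataFrame:
        frames = [c.table2_frame() for c in self.comparisons]
        return pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()

    def table3(self) -> dict:
        out = {}
        for c in self.comparisons:
            key = "{} vs {}".format(*c.comparison)
            entry: dict = {"n_significant": len(c.significant)}
            if c.svm is not None:
                entry["svm_accuracy_percent"] = c.svm.accuracy_percent
                entry["svm_per_class"] = c.svm.per_class_accuracy
                entry["n_features_used"] = len(c.svm.feature_ids)
            else:
                entry["svm_skipped"] = True
                entry["svm_skipped_reason"] = c.svm_skipped_reason
            if c.oplsda_quality is not None:
                entry["oplsda"] = {
                    "r2y": c.oplsda_quality.r2y,
                    "q2": c.oplsda_quality.q2,
                    "cc_percent": c.oplsda_quality.cc_percent,
                    "p_r2y": c.oplsda_quality.p_r2y,
                    "p_q2": c.oplsda_quality.p_q2,
                }
            out[key] = entry
        return out

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        paths = {}
        paths["filter_report"] = out_dir / "filter_report.json"
        self.filter_report.to_json(paths["filter_report"])
        paths["table2"] = out_dir / "table2.tsv"
        self.table2().to_csv(paths["table2"], sep="\t", index=False, na_rep="NA")
        paths["table3"] = out_dir / "table3.json"
        paths["table3"].write_text(json.dumps(self.table3(), indent=1))
        if self.plsda_quality is not None:
            paths["plsda_quality"] = out_dir / "plsda_quality.json"
            paths["plsda_quality"].write_text(json.dumps(self.plsda_quality.to_dict(), indent=1))
        if self.plsda_model is not None:
            scores = pd.DataFrame(
                self.plsda_model.x_scores_,
                columns=[f"t{k+1}" for k in range(self.plsda_model.n_components_)],
            )
            paths["plsda_scores"] = out_dir / "plsda_scores.tsv"
            scores.to_csv(paths["plsda_scores"], sep="\t", index=False)
        if self.qc_scores is not None and len(self.qc_scores):
            paths["qc_scores"] = out_dir / "plsda_qc_scores.tsv"
            pd.DataFrame(
                self.qc_scores,
                columns=[f"t{k+1}" for k in range(self.qc_scores.shape[1])],
            ).to_csv(paths["qc_scores"], sep="\t", index=False)
        return paths


def run_analysis(
    table: FeatureTable,
    config: StudyConfig | None = None,
    comparisons: list[tuple[str, str]] | None = None,
    n_permutations: int | None = None,
) -> AnalysisResult:
    """Run the whole statistical workflow on a raw-scale feature table.

    ``n_permutations`` overrides the config permutation count; 0 disables
    permutation validation (R²Y/Q²/CC are still reported from cross-
    validation).
    """
    config = config or StudyConfig()
    n_perm = config.n_permutations if n_permutations is None else n_permutations

    processed, report = run_preprocess(table, config)
    labels = processed.group_labels()
    parents = subgroup_parents(labels)
    top_level = [l for l in labels if l not in parents]
    if comparisons is None:
        if set(labels) == {"I", "Ia", "II", "III"}:
            comparisons = STUDY_COMPARISONS
        else:
            comparisons = [
                (a, b) for i, a in enumerate(top_level) for b in top_level[i + 1:]
            ]

    comp_results: list[ComparisonResult] = []
    for name_a, name_b in comparisons:
        ga = resolve_group(name_a, labels, parents)
        gb = resolve_group(name_b, labels, parents)
        overlap = bool(set(ga) & set(gb))
        uni = compare_groups(processed, ga, gb, config.alpha, names=(name_a, name_b))
        uni = adjust_fdr(uni)
        significant = [
            r.feature_id for r in uni
            if r.p_fdr is not None and r.p_fdr < config.fdr_alpha
        ]
        roc = roc_analysis(processed, significant, ga, gb, names=(name_a, name_b))
        svm = None
        skip_reason = None
        opls_q = None
        if overlap:
            skip_reason = "groups share samples (nested subgroup); classification undefined"
        elif not significant:
            skip_reason = "no FDR-significant features"
        else:
            panel = processed.subset_features(significant)
            imputed, dropped = impute_median_by_group(panel, ga + gb)
            mask = imputed.samples["group"].isin(ga + gb).to_numpy()
            X = imputed.intensities.loc[mask]
            y = np.where(
                imputed.samples.loc[mask, "group"].isin(ga), name_a, name_b
            )
            svm = svm_loocv_accuracy(
                X, y, c=config.svm_c, gamma=config.svm_gamma, seed=config.seed,
                comparison=(name_a, name_b), feature_ids=list(X.columns),
                dropped_features=dropped,
            )
        if not overlap:
            opls_q = _fit_pairwise_oplsda(
                processed, ga, gb, name_a, name_b, config, n_perm
            )
        comp_results.append(ComparisonResult(
            comparison=(name_a, name_b), univariate=uni, significant=significant,
            roc=roc, svm=svm, svm_skipped_reason=skip_reason, oplsda_quality=opls_q,
        ))

    plsda_q, plsda_model, qc_scores, group_scores = _fit_global_plsda(
        processed, parents, config, n_perm
    )
    return AnalysisResult(
        config=config, preprocessed=processed, filter_report=report,
        comparisons=comp_results, plsda_quality=plsda_q, plsda_model=plsda_model,
        qc_scores=qc_scores, group_scores=group_scores,
    )


def _imputed_matrix(table: FeatureTable, groups: list[str]):
    imputed, _ = impute_median_by_group(table, groups)
    return imputed


def _fit_pairwise_oplsda(
    processed, ga, gb, name_a, name_b, config, n_perm
) -> ModelQuality | None:
    if processed.n_features < 2:
        return None
    imputed = _imputed_matrix(processed, ga + gb)
    mask = imputed.samples["group"].isin(ga + gb).to_numpy()
    X = imputed.intensities.loc[mask].to_numpy(float)
    y = np.where(imputed.samples.loc[mask, "group"].isin(ga), name_a, name_b)
    X, keep = _drop_constant(X)
    try:
        q = cross_validate(
            X, y, kind="oplsda", n_components=config.oplsda_orthogonal,
            folds=config.cv_folds, seed=config.seed,
        )
        if n_perm:
            q.p_r2y, q.p_q2 = permutation_validate(
                X, y, kind="oplsda", n_components=config.oplsda_orthogonal,
                n_permutations=n_perm, folds=config.cv_folds, seed=config.seed,
            )
            q.n_permutations = n_perm
        return q
    except ValidationError as exc:
        logger.warning("OPLS-DA skipped for %s vs %s: %s", name_a, name_b, exc)
        return None


def _fit_global_plsda(processed, parents, config, n_perm):
    if processed.n_features < 2:
        return None, None, None, {}
    labels = processed.group_labels()
    imputed = _imputed_matrix(processed, labels)
    S = imputed.samples
    study = ~S["is_qc"].astype(bool).to_numpy()
    # subgroup labels fold back into their parent for the global model
    y = S.loc[study, "group"].map(lambda l: parents.get(l, l)).to_numpy()
    X = imputed.intensities.loc[study].to_numpy(float)
    X, keep = _drop_constant(X)
    try:
        quality = cross_validate(
            X, y, kind="plsda", n_components=config.plsda_components,
            folds=config.cv_folds, seed=config.seed,
        )
        if n_perm:
            quality.p_r2y, quality.p_q2 = permutation_validate(
                X, y, kind="plsda", n_components=config.plsda_components,
                n_permutations=n_perm, folds=config.cv_folds, seed=config.seed,
            )
            quality.n_permutations = n_perm
        model = PLSDAClassifier(n_components=config.plsda_components).fit(X, y)
    except ValidationError as exc:
        logger.warning("global PLS-DA skipped: %s", exc)
        return None, None, None, {}
    qc_rows = S["is_qc"].astype(bool).to_numpy()
    qc_scores = None
    if qc_rows.any():
        Xqc = imputed.intensities.loc[qc_rows].to_numpy(float)[:, keep]
        if not np.isnan(Xqc).any():
            qc_scores = project_samples(model, Xqc)
    group_scores = {
        g: model.x_scores_[y == g] for g in np.unique(y)
    }
    return quality, model, qc_scores, group_scores


def _drop_constant(X: np.ndarray):
    keep = X.std(axis=0, ddof=1) > 0
    return X[:, keep], keep
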