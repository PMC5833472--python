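"""Post-alignment cleaning chain for batched LC-MS feature tables.

The chain mirrors the standard pooled-QC protocol for untargeted plasma
fingerprints: discard features seen in fewer than half of the QC injections,
discard features whose QC coefficient of variation exceeds 30%, keep only
features present in at least 90% of some study group, then rescale every
value by the drift interpolated between "bracketing" QC injections within
its analytical batch, and finally take the common logarithm so intensities
are approximately normal.

Each stage is a transformer operating on :class:`~plasmet.core.FeatureTable`
objects (fit/transform with sklearn parameter semantics, composable in an
sklearn :class:`~sklearn.pipeline.Pipeline`); module-level functions wrap
them with the one-shot signatures used throughout the package. Filters only
remove features — never samples and never individual values — and every
removal is attributed to exactly one stage in the :class:`FilterReport`.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .core import FeatureTable, StudyConfig, ValidationError

logger = logging.getLogger(__name__)


@dataclass
class FilterStage:
    name: str
    features_in: int
    features_out: int
    removed: dict[str, str] = field(default_factory=dict)  # feature_id -> reason


@dataclass
class FilterReport:
    """Ordered per-stage accounting of the filter cascade.

    ``features_out`` of stage k equals ``features_in`` of stage k+1 and the
    removed sets are disjoint across stages. ``feature_metrics`` holds, for
    every feature surviving the cascade, its QC presence fraction, QC CV
    (computed pre-correction on the raw scale) and maximum within-group
    presence fraction.
    """

    stages: list[FilterStage] = field(default_factory=list)
    feature_metrics: pd.DataFrame | None = None
    uncorrected: list[tuple[str, int]] = field(default_factory=list)  # (feature, batch)

    def add(self, stage: FilterStage) -> None:
        if self.stages and self.stages[-1].features_out != stage.features_in:
            raise ValidationError(
                f"stage chain broken: {self.stages[-1].name} out "
                f"{self.stages[-1].features_out} != {stage.name} in {stage.features_in}"
            )
        self.stages.append(stage)

    def removed_ids(self, stage_name: str | None = None) -> set[str]:
        return {
            fid
            for st in self.stages
            if stage_name is None or st.name == stage_name
            for fid in st.removed
        }

    def stage_for(self, feature_id: str) -> str | None:
        for st in self.stages:
            if feature_id in st.removed:
                return st.name
        return None

    def to_dict(self) -> dict:
        d = {
            "stages": [
                {
                    "name": s.name,
                    "features_in": s.features_in,
                    "features_out": s.features_out,
                    "removed": s.removed,
                }
                for s in self.stages
            ],
            "uncorrected_feature_batches": [list(t) for t in self.uncorrected],
        }
        if self.feature_metrics is not None:
            d["feature_metrics"] = {
                fid: {k: (None if pd.isna(v) else float(v)) for k, v in row.items()}
                for fid, row in self.feature_metrics.to_dict(orient="index").items()
            }
        return d

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))


# ---------------------------------------------------------------------------
# per-feature metrics

def qc_presence_fraction(table: FeatureTable) -> pd.Series:
    qc = table.qc_intensities()
    if qc.shape[0] == 0:
        raise ValidationError("table contains no QC samples")
    return qc.notna().sum(axis=0) / qc.shape[0]


def qc_cv(table: FeatureTable) -> pd.Series:
    """Per-feature sd/mean over present QC intensities (sample sd, ddof=1).

    NaN where fewer than two present QC values exist.
    """
    qc = table.qc_intensities()
    n = qc.notna().sum(axis=0)
    mean = qc.mean(axis=0)
    sd = qc.std(axis=0, ddof=1)
    cv = sd / mean
    cv[n < 2] = np.nan
    return cv


def group_presence_fractions(table: FeatureTable, groups: list[str]) -> pd.DataFrame:
    out = {}
    for g in groups:
        sub = table.group_intensities(g)
        out[g] = sub.notna().sum(axis=0) / sub.shape[0]
    return pd.DataFrame(out)


# ---------------------------------------------------------------------------
# transformers


class _FeatureFilter(TransformerMixin, BaseEstimator):
    """Base for filters that drop feature columns and record why."""

    def fit(self, table: FeatureTable, y=None):
        keep, removed = self._decide(table)
        self.kept_ids_ = keep
        self.removed_ = removed
        self.stage_ = FilterStage(
            name=self.stage_name,
            features_in=table.n_features,
            features_out=len(keep),
            removed=removed,
        )
        return self

    def transform(self, table: FeatureTable) -> FeatureTable:
        return table.subset_features(self.kept_ids_)

    def fit_transform(self, table: FeatureTable, y=None, **kw) -> FeatureTable:
        return self.fit(table, y).transform(table)


class QCPresenceFilter(_FeatureFilter):
    """Keep features present in at least ``min_frac`` of QC injections."""

    stage_name = "qc_presence"

    def __init__(self, min_frac: float = 0.50):
        self.min_frac = min_frac

    def _decide(self, table: FeatureTable):
        frac = qc_presence_fraction(table)
        keep = [f for f in table.intensities.columns if frac[f] >= self.min_frac]
        removed = {
            f: f"QC presence {frac[f]:.3f} < {self.min_frac}"
            for f in table.intensities.columns
            if frac[f] < self.min_frac
        }
        return keep, removed


class QCCVFilter(_FeatureFilter):
    """Keep features whose QC coefficient of variation is at most ``max_cv``.

    Features with fewer than two present QC values cannot be assessed and are
    removed with reason ``insufficient QC values``.
    """

    stage_name = "qc_cv"

    def __init__(self, max_cv: float = 0.30):
        self.max_cv = max_cv

    def _decide(self, table: FeatureTable):
        cv = qc_cv(table)
        keep, removed = [], {}
        for f in table.intensities.columns:
            if np.isnan(cv[f]):
                removed[f] = "insufficient QC values"
            elif cv[f] > self.max_cv:
                removed[f] = f"QC CV {cv[f]:.3f} > {self.max_cv}"
            else:
                keep.append(f)
        return keep, removed


class GroupPresenceFilter(_FeatureFilter):
    """Keep features present in at least ``min_frac`` of some study group.

    QC samples never count; the criterion is a max over listed groups ("any
    of studied groups").
    """

    stage_name = "group_presence"

    def __init__(self, min_frac: float = 0.90, groups: list[str] | None = None):
        self.min_frac = min_frac
        self.groups = groups

    def _decide(self, table: FeatureTable):
        groups = self.groups if self.groups is not None else table.group_labels()
        known = set(table.group_labels())
        for g in groups:
            if g not in known:
                raise ValidationError(f"unknown group label {g!r}")
        frac = group_presence_fractions(table, list(groups)).max(axis=1)
        keep = [f for f in table.intensities.columns if frac[f] >= self.min_frac]
        removed = {
            f: f"max group presence {frac[f]:.3f} < {self.min_frac}"
            for f in table.intensities.columns
            if frac[f] < self.min_frac
        }
        return keep, removed


class BracketingQCCorrector(TransformerMixin, BaseEstimator):
    """Remove within-batch signal drift using bracketing QC injections.

    For each feature *f* and batch, the expected QC level at a sample's
    injection index is the linear interpolation (in injection index) between
    the nearest preceding and following QC injections with a present value of
    *f*; samples before the first / after the last such QC use it directly
    (constant extrapolation). The corrected value is
    ``raw * ref_f / expected`` where ``ref_f`` is the study-wide median of
    *f*'s present QC intensities, so corrected values are comparable across
    batches. Batches with fewer than two present QC values for *f* are left
    uncorrected and logged.
    """

    def fit(self, table: FeatureTable, y=None):
        if table.scale != "raw":
            raise ValidationError(f"drift correction expects raw scale, got {table.scale!r}")
        S = table.samples
        for b, sub in S.groupby("batch"):
            if not sub["is_qc"].any():
                raise ValidationError(f"batch {b} contains no QC injections")
        self.ref_ = table.qc_intensities().median(axis=0)
        return self

    def transform(self, table: FeatureTable) -> FeatureTable:
        X = table.intensities
        vals = X.to_numpy(dtype=float, copy=True)
        S = table.samples
        uncorrected: list[tuple[str, int]] = []
        for b, sub in S.groupby("batch"):
            qc_sub = sub[sub["is_qc"]]
            idx_all = sub["injection_index"].to_numpy(float)
            rows = X.index.get_indexer(sub.index)
            qc_rows = X.index.get_indexer(qc_sub.index)
            qc_idx = qc_sub["injection_index"].to_numpy(float)
            order = np.argsort(qc_idx)
            qc_idx, qc_rows = qc_idx[order], qc_rows[order]
            for j, fid in enumerate(X.columns):
                qv = vals[qc_rows, j]
                present = ~np.isnan(qv)
                if present.sum() < 2:
                    uncorrected.append((fid, int(b)))
                    continue
                expected = np.interp(idx_all, qc_idx[present], qv[present])
                vals[rows, j] = vals[rows, j] * self.ref_[fid] / expected
        self.uncorrected_ = uncorrected
        for fid, b in uncorrected:
            logger.info("feature %s left uncorrected in batch %d (<2 present QC values)", fid, b)
        corrected = pd.DataFrame(vals, index=X.index, columns=X.columns)
        return table.with_intensities(corrected, scale="corrected")


class Log10Transformer(TransformerMixin, BaseEstimator):
    """Common-logarithm transform to approximate normality.

    Present values become ``log10(value)``; missing stays missing. Applying
    it to an already log10 table, or to non-positive values, is an error.
    """

    def fit(self, table: FeatureTable, y=None):
        return self

    def transform(self, table: FeatureTable) -> FeatureTable:
        if table.scale not in ("raw", "corrected"):
            raise ValidationError(f"cannot log10-transform a table on scale {table.scale!r}")
        vals = table.intensities.to_numpy(float)
        if np.any(vals[~np.isnan(vals)] <= 0):
            r, c = np.argwhere(~np.isnan(vals) & (vals <= 0))[0]
            raise ValidationError(
                f"non-positive value at sample {table.intensities.index[r]!r}, "
                f"feature {table.intensities.columns[c]!r}"
            )
        X = pd.DataFrame(
            np.log10(vals), index=table.intensities.index, columns=table.intensities.columns
        )
        return table.with_intensities(X, scale="log10")


# ---------------------------------------------------------------------------
# one-shot functional wrappers


def filter_qc_presence(table: FeatureTable, min_frac: float = 0.50):
    f = QCPresenceFilter(min_frac).fit(table)
    return f.transform(table), f.stage_

def filter_qc_cv(table: FeatureTable, max_cv: float = 0.30):
    f = QCCVFilter(max_cv).fit(table)
    return f.transform(table), f.stage_

def filter_group_presence(table: FeatureTable, min_frac: float = 0.90, groups=None):
    f = GroupPresenceFilter(min_frac, groups).fit(table)
    return f.transform(table), f.stage_

def correct_qc_bracketing(table: FeatureTable) -> FeatureTable:
    return BracketingQCCorrector().fit(table).transform(table)

def log10_transform(table: FeatureTable) -> FeatureTable:
    return Log10Transformer().transform(table)


def run_preprocess(
    table: FeatureTable, config: StudyConfig | None = None, groups: list[str] | None = None
) -> tuple[FeatureTable, FilterReport]:
    """Full cleaning chain: QC presence -> QC CV -> group presence ->
    bracketing-QC correction -> log10, with a complete :class:`FilterReport`.

    CVs recorded in the report are pre-correction, on the raw scale, because
    filtering precedes the drift correction.
    """
    config = config or StudyConfig()
    report = FilterReport()

    presence = qc_presence_fraction(table)
    cv = qc_cv(table)

    t, stage = filter_qc_presence(table, config.qc_presence_min_frac)
    report.add(stage)
    t, stage = filter_qc_cv(t, config.qc_cv_max)
    report.add(stage)
    t, stage = filter_group_presence(t, config.group_presence_min_frac, groups)
    report.add(stage)

    surviving = list(t.intensities.columns)
    gp = group_presence_fractions(t, groups or t.group_labels()).max(axis=1)
    report.feature_metrics = pd.DataFrame(
        {
            "qc_presence_frac": presence[surviving],
            "qc_cv": cv[surviving],
            "max_group_presence_frac": gp[surviving],
        }
    )
    if t.n_features:
        corrector = BracketingQCCorrector().fit(t)
        t = corrector.transform(t)
        report.uncorrected = corrector.uncorrected_
        t = log10_transform(t)
    else:
        t = t.with_intensities(t.intensities.copy(), scale="log10")
    for st in report.stages:
        logger.info("%s: %d -> %d features", st.name, st.features_in, st.features_out)
    return t, report
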