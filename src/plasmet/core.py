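"""Data model and I/O for aligned LC-MS feature tables.

A :class:`FeatureTable` bundles the intensity matrix (samples x features,
``NaN`` marking below-detection / unaligned entries) with per-sample and
per-feature metadata. It is the object every pipeline stage consumes and
returns. Tables are single-polarity: positive- and negative-mode data are
analysed independently.

On-disk representation is plain delimited text (TSV by default):

* intensity matrix — first column ``sample_id``, remaining columns feature ids;
* sample metadata — columns ``sample_id, group, batch, injection_index,
  is_qc, polarity``;
* feature metadata — columns ``feature_id, neutral_mass, rt_min, polarity,
  annotation``.

Missing intensities are written as the ``NA`` token and held internally as
``NaN`` — never zero, which would corrupt CVs and log10.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

NA_TOKEN = "NA"
POLARITIES = ("positive", "negative")
SCALES = ("raw", "corrected", "log10")

SAMPLE_COLUMNS = ["sample_id", "group", "batch", "injection_index", "is_qc", "polarity"]
FEATURE_COLUMNS = ["feature_id", "neutral_mass", "rt_min", "polarity", "annotation"]


class ValidationError(ValueError):
    """A table or metadata file violates a structural invariant."""


@dataclass
class FeatureTable:
    """Samples x features intensity matrix with aligned metadata.

    Parameters
    ----------
    intensities : pandas.DataFrame
        Index = sample ids, columns = feature ids, float values, ``NaN`` for
        missing. All present values must be > 0 on the ``raw`` and
        ``corrected`` scales.
    samples : pandas.DataFrame
        Indexed by sample id; columns ``group`` (nullable string — null iff
        QC), ``batch`` (positive int), ``injection_index`` (positive int,
        batch-local run order), ``is_qc`` (bool), ``polarity``.
    features : pandas.DataFrame
        Indexed by feature id; columns ``neutral_mass`` (Da), ``rt_min``
        (minutes), ``polarity``, ``annotation`` (free text, may be null).
    scale : str
        One of ``raw``, ``corrected``, ``log10``.
    """

    intensities: pd.DataFrame
    samples: pd.DataFrame
    features: pd.DataFrame
    scale: str = "raw"

    def __post_init__(self) -> None:
        self.validate()

    # -- structural checks -------------------------------------------------
    def validate(self) -> None:
        if self.scale not in SCALES:
            raise ValidationError(f"unknown scale {self.scale!r}")
        X, S, F = self.intensities, self.samples, self.features
        if list(X.index) != list(S.index):
            raise ValidationError("sample ids of matrix and sample metadata differ")
        if list(X.columns) != list(F.index):
            raise ValidationError("feature ids of matrix and feature metadata differ")
        if S.index.has_duplicates:
            dup = S.index[S.index.duplicated()][0]
            raise ValidationError(f"duplicate sample_id {dup!r}")
        if F.index.has_duplicates:
            dup = F.index[F.index.duplicated()][0]
            raise ValidationError(f"duplicate feature_id {dup!r}")
        vals = X.to_numpy(dtype=float)
        if self.scale in ("raw", "corrected") and np.any(vals[~np.isnan(vals)] <= 0):
            r, c = np.argwhere(~np.isnan(vals) & (vals <= 0))[0]
            raise ValidationError(
                f"non-positive intensity at sample {X.index[r]!r}, feature {X.columns[c]!r}"
            )
        # QC flag <-> absent group label
        is_qc = S["is_qc"].astype(bool)
        group_absent = S["group"].isna()
        bad = is_qc != group_absent
        if bad.any():
            raise ValidationError(
                f"sample {S.index[bad][0]!r}: is_qc must hold exactly when group is absent"
            )
        if (S["batch"] <= 0).any() or (S["injection_index"] <= 0).any():
            raise ValidationError("batch and injection_index must be positive")
        for df, col, allowed in ((S, "polarity", POLARITIES), (F, "polarity", POLARITIES)):
            bad_pol = ~df[col].isin(allowed)
            if bad_pol.any():
                raise ValidationError(f"unknown polarity {df[col][bad_pol].iloc[0]!r}")
        pols = set(S["polarity"]) | set(F["polarity"])
        if len(pols) > 1:
            raise ValidationError(f"table mixes polarities {sorted(pols)}")
        dup_inj = S.duplicated(subset=["batch", "injection_index"])
        if dup_inj.any():
            raise ValidationError(
                f"duplicate injection_index within batch for sample {S.index[dup_inj][0]!r}"
            )
        if (F["neutral_mass"] <= 0).any():
            fid = F.index[F["neutral_mass"] <= 0][0]
            raise ValidationError(f"feature {fid!r}: neutral_mass must be > 0")
        if (F["rt_min"] < 0).any():
            fid = F.index[F["rt_min"] < 0][0]
            raise ValidationError(f"feature {fid!r}: retention time must be >= 0")

    # -- convenience accessors --------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.intensities.shape[0]

    @property
    def n_features(self) -> int:
        return self.intensities.shape[1]

    @property
    def qc_mask(self) -> pd.Series:
        return self.samples["is_qc"].astype(bool)

    @property
    def polarity(self) -> str:
        return str(self.samples["polarity"].iloc[0]) if len(self.samples) else "positive"

    def qc_intensities(self) -> pd.DataFrame:
        return self.intensities.loc[self.qc_mask.to_numpy()]

    def group_intensities(self, group: str | list[str]) -> pd.DataFrame:
        """Rows of the given study group; a list means the union of labels
        (used for nested subgroups, e.g. group I = labels {I, Ia})."""
        labels = [group] if isinstance(group, str) else list(group)
        mask = self.samples["group"].isin(labels).to_numpy()
        if not mask.any():
            raise ValidationError(f"unknown or empty group {group!r}")
        return self.intensities.loc[mask]

    def group_labels(self) -> list[str]:
        g = self.samples.loc[~self.qc_mask, "group"]
        return sorted(g.unique().tolist())

    def subset_features(self, feature_ids: Iterable[str], scale: str | None = None) -> "FeatureTable":
        ids = list(feature_ids)
        return FeatureTable(
            intensities=self.intensities[ids].copy(),
            samples=self.samples.copy(),
            features=self.features.loc[ids].copy(),
            scale=scale or self.scale,
        )

    def with_intensities(self, X: pd.DataFrame, scale: str | None = None) -> "FeatureTable":
        return FeatureTable(
            intensities=X, samples=self.samples.copy(),
            features=self.features.copy(), scale=scale or self.scale,
        )

    def equals(self, other: "FeatureTable") -> bool:
        return (
            self.scale == other.scale
            and self.intensities.equals(other.intensities)
            and self.samples.equals(other.samples)
            and self.features.equals(other.features)
        )


# ---------------------------------------------------------------------------
# configuration


@dataclass
class StudyConfig:
    """Thresholds and analysis settings for the whole workflow.

    Defaults mirror the published protocol: features present in fewer than
    50% of QC injections or with QC coefficient of variation above 30% are
    discarded, then features must be present in at least 90% of any study
    group; all hypothesis tests use alpha = 0.05 with Benjamini–Hochberg
    control at the same level.
    """

    qc_presence_min_frac: float = 0.50
    qc_cv_max: float = 0.30
    group_presence_min_frac: float = 0.90
    alpha: float = 0.05
    fdr_alpha: float = 0.05
    plsda_components: int = 2
    oplsda_orthogonal: int = 1
    cv_folds: int = 7
    n_permutations: int = 200
    svm_c: float = 1.0
    svm_gamma: str | float = "scale"
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("qc_presence_min_frac", "qc_cv_max", "group_presence_min_frac"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValidationError(f"{name} must be in (0, 1], got {v}")
        for name in ("alpha", "fdr_alpha"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValidationError(f"{name} must be in (0, 1), got {v}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StudyConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def default_config() -> StudyConfig:
    """Return the study's default thresholds and settings."""
    return StudyConfig()


# ---------------------------------------------------------------------------
# readers / writers


def _read_delimited(path: str | Path) -> pd.DataFrame:
    sep = "," if str(path).endswith(".csv") else "\t"
    return pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)


def read_feature_table(
    table_path: str | Path,
    sample_meta_path: str | Path,
    feature_meta_path: str | Path,
    scale: str = "raw",
) -> FeatureTable:
    """Read and cross-validate a feature matrix plus its two metadata files.

    Blank cells and the ``NA`` token become missing values. Zeros in raw
    input are treated as below-detection missing values and logged, since
    aligned exports encode absence either way.
    """
    raw = _read_delimited(table_path)
    if raw.columns[0] != "sample_id":
        raise ValidationError(
            f"matrix file {table_path}: first column must be 'sample_id', got {raw.columns[0]!r}"
        )
    X = raw.set_index("sample_id")
    X = X.replace({"": np.nan, NA_TOKEN: np.nan}).astype(float)

    smeta = _read_delimited(sample_meta_path)
    missing_cols = set(SAMPLE_COLUMNS) - set(smeta.columns)
    if missing_cols:
        raise ValidationError(f"sample metadata missing columns {sorted(missing_cols)}")
    smeta = smeta.set_index("sample_id")
    samples = pd.DataFrame(index=smeta.index)
    samples["group"] = smeta["group"].replace({"": None, NA_TOKEN: None})
    samples["batch"] = smeta["batch"].astype(int)
    samples["injection_index"] = smeta["injection_index"].astype(int)
    samples["is_qc"] = smeta["is_qc"].str.lower().map(
        {"true": True, "false": False, "1": True, "0": False}
    )
    if samples["is_qc"].isna().any():
        sid = samples.index[samples["is_qc"].isna()][0]
        raise ValidationError(f"sample {sid!r}: unparseable is_qc flag")
    samples["polarity"] = smeta["polarity"]

    fmeta = _read_delimited(feature_meta_path)
    missing_cols = set(FEATURE_COLUMNS) - set(fmeta.columns)
    if missing_cols:
        raise ValidationError(f"feature metadata missing columns {sorted(missing_cols)}")
    fmeta = fmeta.set_index("feature_id")
    features = pd.DataFrame(index=fmeta.index)
    features["neutral_mass"] = fmeta["neutral_mass"].astype(float)
    features["rt_min"] = fmeta["rt_min"].astype(float)
    features["polarity"] = fmeta["polarity"]
    features["annotation"] = fmeta["annotation"].replace({"": None, NA_TOKEN: None})

    extra = set(samples.index) - set(X.index)
    if extra:
        raise ValidationError(f"sample metadata lists id absent from matrix: {sorted(extra)[0]!r}")
    extra = set(X.index) - set(samples.index)
    if extra:
        raise ValidationError(f"matrix row without sample metadata: {sorted(extra)[0]!r}")
    extra = set(features.index) ^ set(X.columns)
    if extra:
        raise ValidationError(f"feature id mismatch between matrix and metadata: {sorted(extra)[0]!r}")

    # align metadata to matrix order
    samples = samples.loc[X.index]
    features = features.loc[X.columns]

    if scale == "raw":
        zeros = (X == 0)
        n_zero = int(zeros.to_numpy().sum())
        if n_zero:
            logger.info("treating %d zero entries in raw input as missing (below detection)", n_zero)
            X = X.mask(zeros)
    vals = X.to_numpy()
    if scale in ("raw", "corrected") and np.any(vals[~np.isnan(vals)] < 0):
        r, c = np.argwhere(~np.isnan(vals) & (vals < 0))[0]
        raise ValidationError(
            f"negative intensity at sample {X.index[r]!r}, feature {X.columns[c]!r}"
        )
    return FeatureTable(intensities=X, samples=samples, features=features, scale=scale)


def write_feature_table(table: FeatureTable, prefix: str | Path, sep: str = "\t") -> dict[str, Path]:
    """Write matrix + metadata as ``<prefix>_{matrix,samples,features}.tsv``.

    Values are printed at full ``repr`` precision so that a read-back is
    bit-identical; missing cells carry the ``NA`` token.
    """
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    ext = "csv" if sep == "," else "tsv"
    paths = {
        "matrix": prefix.parent / f"{prefix.name}_matrix.{ext}",
        "samples": prefix.parent / f"{prefix.name}_samples.{ext}",
        "features": prefix.parent / f"{prefix.name}_features.{ext}",
    }
    X = table.intensities.copy()
    X.index.name = "sample_id"
    X.to_csv(paths["matrix"], sep=sep, na_rep=NA_TOKEN, float_format="%.17g")

    S = table.samples.copy()
    S.index.name = "sample_id"
    S = S.assign(is_qc=S["is_qc"].map({True: "true", False: "false"}))
    S.to_csv(paths["samples"], sep=sep, na_rep=NA_TOKEN)

    F = table.features.copy()
    F.index.name = "feature_id"
    F.to_csv(paths["features"], sep=sep, na_rep=NA_TOKEN, float_format="%.17g")
    return paths


def read_feature_table_prefix(prefix: str | Path, scale: str = "raw", sep: str = "\t") -> FeatureTable:
    """Inverse of :func:`write_feature_table` for a path prefix."""
    prefix = Path(prefix)
    ext = "csv" if sep == "," else "tsv"
    return read_feature_table(
        prefix.parent / f"{prefix.name}_matrix.{ext}",
        prefix.parent / f"{prefix.name}_samples.{ext}",
        prefix.parent / f"{prefix.name}_features.{ext}",
        scale=scale,
    )
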