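"""Synthetic batched LC-MS study generator with known ground truth.

The generator emulates the run design of a case-control plasma
fingerprinting study: three clinical groups (with one nested subgroup),
four analytical batches each holding close to a quarter of every group,
pooled-QC injections at the start of each batch run, after every 8 study
samples and at the end of the run, log-normal feature intensities,
within-batch multiplicative signal drift, per-feature batch offsets,
group effects on a designated feature subset (multiplicative on the raw
scale, i.e. additive on log10), and below-detection censoring to missing.

QC samples are the pooled mean profile of the first batch's study samples,
subjected to the same drift and noise — so QC projections sit near the
centroid of the groups that dominate that batch rather than at the global
center.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .core import FeatureTable, ValidationError

LOG2 = np.log10(2.0)


@dataclass
class SimulationConfig:
    """Stated world of the default scenario.

    Group sizes 57/49/25 with a 37-sample subgroup Ia nested in group I
    (131 study samples), 4 batches, QC every 8 injections, baseline log10
    intensities uniform in [4.5, 6.5], log10 noise sd 0.06 (raw-scale QC CV
    around 14%, the mid-range of what surviving features show under a 30%
    CV filter), linear multiplicative drift decaying 0-20% across each
    batch, small per-feature batch offsets, and a detection limit censoring
    low intensities to missing.
    """

    group_sizes: dict[str, int] = field(
        default_factory=lambda: {"I": 57, "II": 49, "III": 25}
    )
    subgroup: tuple[str, str, int] | None = ("I", "Ia", 37)  # (parent, name, size)
    n_features: int = 500
    n_batches: int = 4
    qc_every: int = 8
    baseline_log10_range: tuple[float, float] = (4.5, 6.5)
    noise_sd_log10: float = 0.06
    drift_max_loss: float = 0.20
    drift_curvature: float = 0.0
    batch_offset_sd_log10: float = 0.02
    n_differential: int = 30
    effect_log2: float = np.log2(1.5)
    effect_groups: tuple[str, ...] = ("I",)  # groups carrying the effect
    lod_log10: float = 4.0
    polarity: str = "positive"
    qc_pool_batch: int = 1

    def __post_init__(self) -> None:
        for g, n in self.group_sizes.items():
            if n < 2:
                raise ValidationError(f"group_sizes[{g!r}] must be >= 2, got {n}")
        if self.n_batches < 1:
            raise ValidationError("n_batches must be >= 1")
        if self.subgroup is not None:
            parent, name, size = self.subgroup
            if parent not in self.group_sizes:
                raise ValidationError(f"subgroup parent {parent!r} not a group")
            if not 0 < size <= self.group_sizes[parent]:
                raise ValidationError("subgroup size must be within its parent group")


@dataclass
class SimulationTruth:
    """Ground truth for parameter-recovery tests."""

    differential: dict[str, dict[str, float]]  # feature -> {group: log2 effect}
    baseline_log10: dict[str, float]
    drift: dict[int, dict[str, float]]  # batch -> {slope, curvature}
    batch_offset_log10: dict[str, dict[int, float]]  # feature -> batch -> offset
    lod_log10: float
    noise_sd_log10: float
    group_sizes: dict[str, int]
    subgroup_members: list[str]
    seed: int

    def to_dict(self) -> dict:
        return {
            "differential": self.differential,
            "baseline_log10": self.baseline_log10,
            "drift": {str(k): v for k, v in self.drift.items()},
            "batch_offset_log10": {
                f: {str(b): v for b, v in d.items()}
                for f, d in self.batch_offset_log10.items()
            },
            "lod_log10": self.lod_log10,
            "noise_sd_log10": self.noise_sd_log10,
            "group_sizes": self.group_sizes,
            "subgroup_members": self.subgroup_members,
            "seed": self.seed,
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "SimulationTruth":
        d = json.loads(Path(path).read_text())
        return cls(
            differential=d["differential"],
            baseline_log10=d["baseline_log10"],
            drift={int(k): v for k, v in d["drift"].items()},
            batch_offset_log10={
                f: {int(b): v for b, v in bd.items()}
                for f, bd in d["batch_offset_log10"].items()
            },
            lod_log10=d["lod_log10"],
            noise_sd_log10=d["noise_sd_log10"],
            group_sizes=d["group_sizes"],
            subgroup_members=d["subgroup_members"],
            seed=d["seed"],
        )


def qc_schedule(n_samples_in_batch: int, qc_every: int = 8) -> list[str]:
    """Injection layout of one batch as a list of "qc"/"sample" slots.

    A QC opens the run, another follows every ``qc_every`` study samples,
    and one closes the run (deduplicated when the last every-N QC already
    falls at the end).
    """
    if n_samples_in_batch < 1:
        raise ValidationError("need at least one sample in a batch")
    layout = ["qc"]
    since = 0
    for _ in range(n_samples_in_batch):
        layout.append("sample")
        since += 1
        if since == qc_every:
            layout.append("qc")
            since = 0
    if layout[-1] != "qc":
        layout.append("qc")
    return layout


def qc_positions(n_samples_in_batch: int, qc_every: int = 8) -> list[int]:
    """1-based injection indices of the QCs in :func:`qc_schedule`."""
    layout = qc_schedule(n_samples_in_batch, qc_every)
    return [i + 1 for i, kind in enumerate(layout) if kind == "qc"]


def _drift_factor(position: float, run_length: int, loss: float, curvature: float) -> float:
    """Multiplicative drift at a 1-based injection position; 1.0 at start,
    1 - loss at the end, optional quadratic curvature."""
    if run_length <= 1:
        return 1.0
    x = (position - 1) / (run_length - 1)
    return 1.0 - loss * x + curvature * x * (1.0 - x)


def simulate_study(
    config: SimulationConfig | None = None, seed: int = 0
) -> tuple[FeatureTable, SimulationTruth]:
    """Generate one single-polarity feature table plus its ground truth.

    Sample-to-batch assignment is stratified: each group is split into
    near-equal random quarters (one per batch). Per-sample raw intensity is
    ``10 ** (baseline + group_effect + batch_offset + noise)`` scaled by the
    batch drift at the sample's injection position; values whose raw
    intensity falls below ``10**lod_log10`` become missing.
    """
    cfg = config or SimulationConfig()
    rng = np.random.default_rng(seed)

    feature_ids = [f"F{i:04d}" for i in range(cfg.n_features)]
    baseline = rng.uniform(*cfg.baseline_log10_range, size=cfg.n_features)

    # differential features: planted multiplicative effects for chosen groups
    diff_ids = list(rng.choice(cfg.n_features, size=cfg.n_differential, replace=False))
    signs = rng.choice([-1.0, 1.0], size=cfg.n_differential)
    differential: dict[str, dict[str, float]] = {}
    for j, s in zip(diff_ids, signs):
        differential[feature_ids[j]] = {g: float(s * cfg.effect_log2) for g in cfg.effect_groups}

    # batch assignment: stratified near-equal random quarters
    sample_rows = []
    for g, n in cfg.group_sizes.items():
        ids = [f"{g}_{i:03d}" for i in range(n)]
        perm = rng.permutation(n)
        for rank, i in enumerate(perm):
            sample_rows.append((ids[i], g, rank % cfg.n_batches + 1))
    subgroup_members: list[str] = []
    if cfg.subgroup is not None:
        parent, name, size = cfg.subgroup
        parent_ids = [sid for sid, g, _ in sample_rows if g == parent]
        subgroup_members = sorted(
            rng.choice(parent_ids, size=size, replace=False).tolist()
        )
        members = set(subgroup_members)
        sample_rows = [
            (sid, name if sid in members else g, b) for sid, g, b in sample_rows
        ]

    drift = {
        b: {"slope": -cfg.drift_max_loss, "curvature": cfg.drift_curvature}
        for b in range(1, cfg.n_batches + 1)
    }
    offsets = rng.normal(0.0, cfg.batch_offset_sd_log10, size=(cfg.n_features, cfg.n_batches))
    batch_offset = {
        feature_ids[j]: {b + 1: float(offsets[j, b]) for b in range(cfg.n_batches)}
        for j in range(cfg.n_features)
    }

    # noiseless per-sample expected log10 intensity (before drift/offset).
    # A subgroup label inherits its parent group's planted effects.
    def _in_scope(label: str, effect_group: str) -> bool:
        if label == effect_group:
            return True
        return (
            cfg.subgroup is not None
            and cfg.subgroup[0] == effect_group
            and label == cfg.subgroup[1]
        )

    def expected_log10(label: str) -> np.ndarray:
        e = baseline.copy()
        index = {fid: j for j, fid in enumerate(feature_ids)}
        for fid, effects in differential.items():
            for g, eff in effects.items():
                if _in_scope(label, g):
                    e[index[fid]] += eff * LOG2
        return e

    labels = sorted({g for _, g, _ in sample_rows})
    group_expected = {g: expected_log10(g) for g in labels}

    # QC pool: mean raw profile over the designated batch's study samples
    pool_members = [(sid, g) for sid, g, b in sample_rows if b == cfg.qc_pool_batch]
    qc_profile_raw = np.mean(
        [10.0 ** group_expected[g] for _, g in pool_members], axis=0
    )
    qc_log10 = np.log10(qc_profile_raw)

    all_ids: list[str] = []
    meta_rows: list[dict] = []
    values: list[np.ndarray] = []
    for b in range(1, cfg.n_batches + 1):
        members = [(sid, g) for sid, g, bb in sample_rows if bb == b]
        order = rng.permutation(len(members))
        members = [members[i] for i in order]
        layout = qc_schedule(len(members), cfg.qc_every)
        run_len = len(layout)
        sample_iter = iter(members)
        qc_count = 0
        for pos, kind in enumerate(layout, start=1):
            d = _drift_factor(pos, run_len, cfg.drift_max_loss, cfg.drift_curvature)
            noise = rng.normal(0.0, cfg.noise_sd_log10, size=cfg.n_features)
            off = offsets[:, b - 1]
            if kind == "qc":
                qc_count += 1
                sid = f"QC_b{b}_{qc_count:02d}"
                log_val = qc_log10 + off + noise
                group = None
                is_qc = True
            else:
                sid, group = next(sample_iter)
                log_val = group_expected[group] + off + noise
                is_qc = False
            raw = (10.0**log_val) * d
            raw[raw < 10.0**cfg.lod_log10] = np.nan
            all_ids.append(sid)
            values.append(raw)
            meta_rows.append(
                dict(sample_id=sid, group=group, batch=b, injection_index=pos,
                     is_qc=is_qc, polarity=cfg.polarity)
            )

    X = pd.DataFrame(np.vstack(values), index=all_ids, columns=feature_ids)
    samples = pd.DataFrame(meta_rows).set_index("sample_id")
    features = pd.DataFrame(
        {
            "neutral_mass": rng.uniform(80.0, 1000.0, size=cfg.n_features),
            "rt_min": rng.uniform(0.5, 35.0, size=cfg.n_features),
            "polarity": cfg.polarity,
            "annotation": None,
        },
        index=pd.Index(feature_ids, name="feature_id"),
    )
    table = FeatureTable(X, samples, features, scale="raw")
    truth = SimulationTruth(
        differential=differential,
        baseline_log10={feature_ids[j]: float(baseline[j]) for j in range(cfg.n_features)},
        drift=drift,
        batch_offset_log10=batch_offset,
        lod_log10=cfg.lod_log10,
        noise_sd_log10=cfg.noise_sd_log10,
        group_sizes=dict(cfg.group_sizes),
        subgroup_members=subgroup_members,
        seed=seed,
    )
    return table, truth


def planted_truth_report(truth: SimulationTruth) -> pd.DataFrame:
    """Machine-readable table of planted differential features."""
    rows = [
        {"feature_id": fid, "group": g, "log2_effect": eff}
        for fid, effects in truth.differential.items()
        for g, eff in effects.items()
    ]
    return pd.DataFrame(rows, columns=["feature_id", "group", "log2_effect"])


# ---------------------------------------------------------------------------
# designed filter-cascade scenario


def simulate_filter_cascade(
    n_features: int = 500,
    n_fail_qc_presence: int = 40,
    n_fail_qc_cv: int = 40,
    n_fail_group_presence: int = 40,
    seed: int = 0,
) -> tuple[FeatureTable, dict[str, str]]:
    """Table where a designed subset violates exactly one filter each.

    Returns the table and ``{feature_id: expected_stage}`` for the designed
    failures; every other feature passes all three filters by a wide margin
    (tiny noise, detection limit far below all baselines).
    """
    cfg = SimulationConfig(
        group_sizes={"I": 20, "II": 20, "III": 20},
        subgroup=None,
        n_features=n_features,
        noise_sd_log10=0.03,
        drift_max_loss=0.05,
        batch_offset_sd_log10=0.0,
        n_differential=0,
        lod_log10=0.0,
    )
    table, _ = simulate_study(cfg, seed=seed)
    rng = np.random.default_rng(seed + 1)
    chosen = rng.choice(
        n_features, size=n_fail_qc_presence + n_fail_qc_cv + n_fail_group_presence,
        replace=False,
    )
    fids = list(table.intensities.columns)
    X = table.intensities.copy()
    qc_rows = table.samples.index[table.qc_mask]
    expected: dict[str, str] = {}
    i = 0
    for _ in range(n_fail_qc_presence):
        fid = fids[chosen[i]]; i += 1
        # missing in 60% of QC injections -> presence 0.4 < 0.5
        n_mask = int(np.ceil(0.6 * len(qc_rows)))
        X.loc[qc_rows[:n_mask], fid] = np.nan
        expected[fid] = "qc_presence"
    for _ in range(n_fail_qc_cv):
        fid = fids[chosen[i]]; i += 1
        # triple every other QC value -> CV far above 0.30
        X.loc[qc_rows[::2], fid] = X.loc[qc_rows[::2], fid] * 3.0
        expected[fid] = "qc_cv"
    study_by_group = {
        g: table.samples.index[(table.samples["group"] == g).to_numpy()]
        for g in table.group_labels()
    }
    for _ in range(n_fail_group_presence):
        fid = fids[chosen[i]]; i += 1
        # missing in 20% of every group -> max presence 0.8 < 0.9
        for g, rows in study_by_group.items():
            n_mask = int(np.ceil(0.2 * len(rows)))
            X.loc[rows[:n_mask], fid] = np.nan
        expected[fid] = "group_presence"
    return table.with_intensities(X), expected
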