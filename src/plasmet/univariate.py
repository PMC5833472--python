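"""Per-feature two-group screening with assumption-gated test choice.

For every feature, the Shapiro-Wilk test (each group) and Levene's test
(mean-centered, across both groups) gate the choice between a one-way ANOVA
F-test — equivalent to a pooled-variance t for two groups — and the
two-sided Wilcoxon rank-sum test: a single significant gate at alpha sends
the feature down the nonparametric path. Raw p-values within one comparison
(and one polarity) form the Benjamini–Hochberg family. Percent change is
reported on the corrected raw scale (arithmetic means) even though testing
runs on log10 intensities.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core import FeatureTable, ValidationError

logger = logging.getLogger(__name__)


@dataclass
class GateDiagnostics:
    shapiro_p_a: float | None
    shapiro_p_b: float | None
    levene_p: float | None
    evaluable: bool = True


@dataclass
class UnivariateResult:
    """One feature, one two-group comparison."""

    feature_id: str
    comparison: tuple[str, str]
    test_used: str  # "anova" | "wilcoxon"
    p_raw: float
    p_fdr: float | None
    percent_change: float
    mean_a: float
    mean_b: float
    sem_a: float
    sem_b: float
    n_a: int
    n_b: int
    gates: GateDiagnostics
    testable: bool = True
    zero_variance: bool = False

    def to_dict(self) -> dict:
        return {
            "feature_id": self.feature_id,
            "comparison": list(self.comparison),
            "test_used": self.test_used,
            "p_raw": self.p_raw,
            "p_fdr": self.p_fdr,
            "percent_change": self.percent_change,
            "mean_a": self.mean_a,
            "mean_b": self.mean_b,
            "sem_a": self.sem_a,
            "sem_b": self.sem_b,
            "n_a": self.n_a,
            "n_b": self.n_b,
            "shapiro_p_a": self.gates.shapiro_p_a,
            "shapiro_p_b": self.gates.shapiro_p_b,
            "levene_p": self.gates.levene_p,
            "gates_evaluable": self.gates.evaluable,
            "testable": self.testable,
            "zero_variance": self.zero_variance,
        }


def choose_test(values_a, values_b, alpha: float = 0.05) -> tuple[str, GateDiagnostics]:
    """Gate between ANOVA and Wilcoxon on normality/variance-homogeneity.

    Requires >= 3 present values per group (the Shapiro-Wilk minimum);
    smaller groups fall back to the rank-sum test with gates marked
    not-evaluable. Constant values within a group make Shapiro-Wilk
    undefined — also a nonparametric fallback.
    """
    a = np.asarray(values_a, float)
    b = np.asarray(values_b, float)
    a, b = a[~np.isnan(a)], b[~np.isnan(b)]
    if len(a) < 3 or len(b) < 3:
        logger.info("group below Shapiro-Wilk minimum; defaulting to wilcoxon")
        return "wilcoxon", GateDiagnostics(None, None, None, evaluable=False)
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        return "wilcoxon", GateDiagnostics(None, None, None, evaluable=False)
    sw_a = stats.shapiro(a).pvalue
    sw_b = stats.shapiro(b).pvalue
    lev = stats.levene(a, b, center="mean").pvalue
    gates = GateDiagnostics(float(sw_a), float(sw_b), float(lev))
    if min(sw_a, sw_b, lev) < alpha:
        return "wilcoxon", gates
    return "anova", gates


def _wilcoxon_p(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sided Wilcoxon rank-sum p: exact for n <= 25 per group without
    ties, normal approximation with continuity correction otherwise."""
    if max(len(a), len(b)) <= 25:
        method = "exact" if len(np.unique(np.concatenate([a, b]))) == len(a) + len(b) else "asymptotic"
    else:
        method = "asymptotic"
    return float(stats.mannwhitneyu(a, b, alternative="two-sided", method=method).pvalue)


def percent_change(mean_a: float, mean_b: float) -> float:
    """Signed percent difference of raw-scale group means, relative to b."""
    if mean_b <= 0:
        raise ValidationError(f"reference group mean must be > 0, got {mean_b}")
    return 100.0 * (mean_a - mean_b) / mean_b


def compare_groups(
    table: FeatureTable,
    group_a: str | list[str],
    group_b: str | list[str],
    alpha: float = 0.05,
    names: tuple[str, str] | None = None,
) -> list[UnivariateResult]:
    """Screen every feature for a difference between two study groups.

    ``table`` must be on the log10 scale; testing uses the log10 values,
    descriptives and percent change use the back-transformed (corrected raw
    scale) values. Missing values are excluded listwise within each feature;
    features with fewer than two present values in a group are flagged
    untestable and excluded from the FDR family. Either group may be a list
    of labels (their union), which supports nested subgroups.
    """
    if table.scale != "log10":
        raise ValidationError(f"compare_groups expects log10 scale, got {table.scale!r}")
    A = table.group_intensities(group_a)
    B = table.group_intensities(group_b)
    if names is None:
        names = (
            group_a if isinstance(group_a, str) else "+".join(group_a),
            group_b if isinstance(group_b, str) else "+".join(group_b),
        )
    group_a, group_b = names
    if A.shape[0] < 2 or B.shape[0] < 2:
        raise ValidationError("both groups need >= 2 samples")
    results: list[UnivariateResult] = []
    for fid in table.intensities.columns:
        a = A[fid].to_numpy(float)
        b = B[fid].to_numpy(float)
        a, b = a[~np.isnan(a)], b[~np.isnan(b)]
        raw_a, raw_b = 10.0**a, 10.0**b
        mean_a = float(raw_a.mean()) if len(a) else np.nan
        mean_b = float(raw_b.mean()) if len(b) else np.nan
        sem_a = float(raw_a.std(ddof=1) / np.sqrt(len(a))) if len(a) > 1 else np.nan
        sem_b = float(raw_b.std(ddof=1) / np.sqrt(len(b))) if len(b) > 1 else np.nan
        base = dict(
            feature_id=fid, comparison=(group_a, group_b),
            mean_a=mean_a, mean_b=mean_b, sem_a=sem_a, sem_b=sem_b,
            n_a=len(a), n_b=len(b),
        )
        if len(a) < 2 or len(b) < 2:
            logger.info("feature %s untestable for (%s, %s)", fid, group_a, group_b)
            results.append(UnivariateResult(
                test_used="wilcoxon", p_raw=np.nan, p_fdr=None, percent_change=np.nan,
                gates=GateDiagnostics(None, None, None, evaluable=False),
                testable=False, **base,
            ))
            continue
        pc = percent_change(mean_a, mean_b)
        pooled = np.concatenate([a, b])
        if np.ptp(pooled) == 0:
            # no evidence whatsoever; rank-sum convention p = 1
            results.append(UnivariateResult(
                test_used="wilcoxon", p_raw=1.0, p_fdr=None, percent_change=pc,
                gates=GateDiagnostics(None, None, None, evaluable=False),
                zero_variance=True, **base,
            ))
            continue
        test, gates = choose_test(a, b, alpha)
        if test == "anova":
            p = float(stats.f_oneway(a, b).pvalue)
        else:
            p = _wilcoxon_p(a, b)
        results.append(UnivariateResult(
            test_used=test, p_raw=p, p_fdr=None, percent_change=pc, gates=gates, **base,
        ))
    return results


def adjust_fdr(results: list[UnivariateResult]) -> list[UnivariateResult]:
    """Benjamini–Hochberg step-up adjustment over the testable features of
    one comparison (one polarity). Untestable features keep ``p_fdr=None``."""
    testable = [r for r in results if r.testable and not np.isnan(r.p_raw)]
    if testable:
        p = np.array([r.p_raw for r in testable])
        adj = multipletests(p, method="fdr_bh")[1]
        for r, q in zip(testable, adj):
            r.p_fdr = float(q)
    return results


def results_to_frame(results: list[UnivariateResult]) -> pd.DataFrame:
    return pd.DataFrame([r.to_dict() for r in results])
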