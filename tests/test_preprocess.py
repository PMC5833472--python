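"""Filter cascade, bracketing-QC drift correction and log transform."""

import numpy as np
import pytest

from plasmet.core import StudyConfig, ValidationError
from plasmet.preprocess import (
    correct_qc_bracketing,
    filter_group_presence,
    filter_qc_cv,
    filter_qc_presence,
    log10_transform,
    qc_cv,
    run_preprocess,
)
from plasmet.simulate import SimulationConfig, simulate_study

from conftest import make_table


def qc_table(qc_values_per_feature, study_value=100.0):
    """n QC rows from per-feature value lists, plus two study samples."""
    qc = np.asarray(qc_values_per_feature, float).T  # rows = QC injections
    n_qc, p = qc.shape
    study = np.full((2, p), study_value)
    vals = np.vstack([qc, study])
    return make_table(
        vals,
        is_qc=[True] * n_qc + [False] * 2,
        groups=[None] * n_qc + ["A", "A"],
    )


class TestQCPresence:
    @pytest.mark.parametrize(
        "n_present, kept",
        [(5, True), (4, False), (0, False), (10, True)],
        ids=["boundary-50pct", "below", "never-present", "always"],
    )
    def test_threshold_semantics(self, n_present, kept):
        # 10 QCs; the published rule removes "< 50%", so exactly 50% survives
        col = [100.0] * n_present + [np.nan] * (10 - n_present)
        t = qc_table([col])
        out, stage = filter_qc_presence(t, 0.5)
        assert (out.n_features == 1) is kept
        assert (stage.removed == {}) is kept

    def test_no_qc_samples_is_error(self):
        t = make_table([[1.0], [2.0]])
        with pytest.raises(ValidationError, match="QC"):
            filter_qc_presence(t, 0.5)


class TestQCCV:
    def test_cv_formula_sample_sd(self):
        # sd = 10 (ddof=1), mean = 100 -> CV 0.10, retained at 0.30
        t = qc_table([[100.0, 110.0, 90.0]])
        assert qc_cv(t).iloc[0] == pytest.approx(0.10)
        out, stage = filter_qc_cv(t, 0.30)
        assert out.n_features == 1

    def test_two_point_cv_removed(self):
        # sd = |100-10|/sqrt(2) = 63.64, mean 55 -> CV ~ 1.157
        t = qc_table([[10.0, 100.0]])
        assert qc_cv(t).iloc[0] == pytest.approx(np.std([10, 100], ddof=1) / 55)
        out, stage = filter_qc_cv(t, 0.30)
        assert out.n_features == 0
        assert "CV" in next(iter(stage.removed.values()))

    def test_identical_qcs_zero_cv_retained(self):
        t = qc_table([[100.0, 100.0, 100.0]])
        out, _ = filter_qc_cv(t, 0.30)
        assert out.n_features == 1

    def test_single_present_qc_removed_with_reason(self):
        t = qc_table([[100.0, np.nan, np.nan]])
        out, stage = filter_qc_cv(t, 0.30)
        assert out.n_features == 0
        assert "insufficient" in next(iter(stage.removed.values()))


class TestGroupPresence:
    def make_groups(self, cols_by_group):
        """cols_by_group: {group: per-sample presence lists per feature}."""
        rows, groups = [], []
        for g, mat in cols_by_group.items():
            for r in np.asarray(mat, float).T:
                rows.append(r)
                groups.append(g)
        vals = np.vstack(rows)
        return make_table(vals, groups=groups)

    def test_any_group_semantics(self):
        # present in 100% of A, absent everywhere in B -> retained
        t = self.make_groups({"A": [[1.0] * 5], "B": [[np.nan] * 5]})
        out, _ = filter_group_presence(t, 0.9)
        assert out.n_features == 1

    def test_max_fraction_below_threshold_removed(self):
        # 80% in both groups -> max 0.8 < 0.9 -> removed
        col = [1.0] * 8 + [np.nan] * 2
        t = self.make_groups({"A": [col], "B": [col]})
        out, stage = filter_group_presence(t, 0.9)
        assert out.n_features == 0

    def test_boundary_9_of_10(self):
        col = [1.0] * 9 + [np.nan]
        t = self.make_groups({"A": [col]})
        out, _ = filter_group_presence(t, 0.9)
        assert out.n_features == 1

    def test_unknown_group_label(self):
        t = make_table([[1.0], [1.0]])
        with pytest.raises(ValidationError, match="ZZZ"):
            filter_group_presence(t, 0.9, groups=["ZZZ"])


class TestBracketingCorrection:
    def test_flat_qcs_identity(self):
        vals = np.array([[100.0], [50.0], [100.0], [70.0], [100.0]])
        t = make_table(vals, is_qc=[True, False, True, False, True],
                       groups=[None, "A", None, "A", None])
        out = correct_qc_bracketing(t)
        assert out.scale == "corrected"
        np.testing.assert_allclose(out.intensities.to_numpy(), vals)

    def test_hand_interpolation(self):
        # QCs at injections 1 and 10 with 100 and 200; sample at 5.
        # expected(5) = 100 + 100*(5-1)/(10-1); ref = median(100, 200) = 150
        t = make_table(
            [[100.0], [80.0], [200.0]],
            is_qc=[True, False, True],
            groups=[None, "A", None],
            injections=[1, 5, 10],
        )
        out = correct_qc_bracketing(t)
        expected_qc = 100 + 100 * (5 - 1) / (10 - 1)
        assert out.intensities.iloc[1, 0] == pytest.approx(80.0 * 150.0 / expected_qc)
        # QC injections land exactly on ref
        assert out.intensities.iloc[0, 0] == pytest.approx(150.0)
        assert out.intensities.iloc[2, 0] == pytest.approx(150.0)

    def test_constant_extrapolation_outside_qcs(self):
        t = make_table(
            [[60.0], [100.0], [200.0], [90.0]],
            is_qc=[False, True, True, False],
            groups=["A", None, None, "A"],
            injections=[1, 2, 3, 4],
        )
        out = correct_qc_bracketing(t)
        ref = 150.0
        assert out.intensities.iloc[0, 0] == pytest.approx(60.0 * ref / 100.0)
        assert out.intensities.iloc[3, 0] == pytest.approx(90.0 * ref / 200.0)

    def test_missing_qc_anchor_falls_back_to_nearest_present(self):
        t = make_table(
            [[100.0], [80.0], [np.nan], [200.0]],
            is_qc=[True, False, True, True],
            groups=[None, "A", None, None],
            injections=[1, 2, 3, 4],
        )
        out = correct_qc_bracketing(t)
        # anchors for the feature are injections 1 and 4 only
        expected = 100 + 100 * (2 - 1) / (4 - 1)
        assert out.intensities.iloc[1, 0] == pytest.approx(80.0 * 150.0 / expected)

    def test_batch_without_qc_errors(self):
        t = make_table([[1.0], [2.0]], batches=[1, 2],
                       is_qc=[True, False], groups=[None, "A"], injections=[1, 1])
        with pytest.raises(ValidationError, match="batch 2"):
            correct_qc_bracketing(t)

    def test_under_two_present_qcs_leaves_feature_uncorrected(self):
        t = make_table(
            [[100.0, 100.0], [80.0, 80.0], [np.nan, 120.0]],
            is_qc=[True, False, True],
            groups=[None, "A", None],
        )
        from plasmet.preprocess import BracketingQCCorrector

        corr = BracketingQCCorrector().fit(t)
        out = corr.transform(t)
        assert ("F00", 1) in corr.uncorrected_
        assert out.intensities.iloc[1, 0] == 80.0  # untouched

    def test_injected_drift_inverted_exactly(self):
        """Constructed inverse: with zero noise and a linear multiplicative
        drift, every corrected study value equals the drift-free truth times
        the study-wide QC reference ratio, to 1e-6 relative — i.e. the drift
        is removed exactly at all QC-bracketed injection indices."""
        from plasmet.simulate import qc_positions

        loss = 0.2
        cfg = SimulationConfig(
            group_sizes={"A": 10, "B": 10}, subgroup=None, n_features=20,
            noise_sd_log10=0.0, batch_offset_sd_log10=0.0, n_differential=0,
            n_batches=2, drift_max_loss=loss, lod_log10=0.0,
        )
        table, truth = simulate_study(cfg, seed=5)
        out = correct_qc_bracketing(table)
        baseline = np.array([truth.baseline_log10[f] for f in table.intensities.columns])
        truth_raw = 10.0 ** baseline  # drift-free noiseless study-sample level
        # closed-form reference: all groups share the same expected profile,
        # so the QC pool equals the study level and ref_f is the drift-free
        # truth scaled by the median drift factor over all QC injections
        drifts = []
        for _, sub in table.samples.groupby("batch"):
            run_len = int(sub["injection_index"].max())
            n_study = int((~sub["is_qc"]).sum())
            for pos in qc_positions(n_study):
                drifts.append(1.0 - loss * (pos - 1) / (run_len - 1))
        expected = truth_raw * np.median(drifts)
        study = ~table.qc_mask.to_numpy()
        got = out.intensities.to_numpy()[study]
        np.testing.assert_allclose(got, np.tile(expected, (study.sum(), 1)), rtol=1e-6)


class TestLog10:
    def test_powers_of_ten_and_missingness(self):
        t = make_table([[100.0, np.nan], [1000.0, 10.0]])
        out = log10_transform(t)
        assert out.scale == "log10"
        assert out.intensities.iloc[0, 0] == 2.0
        assert np.isnan(out.intensities.iloc[0, 1])

    def test_double_transform_guard(self):
        t = log10_transform(make_table([[100.0]]))
        with pytest.raises(ValidationError):
            log10_transform(t)


class TestRunPreprocess:
    def test_stage_chain_and_monotone_shrinkage(self, small_study):
        table, _ = small_study
        out, report = run_preprocess(table, StudyConfig())
        for a, b in zip(report.stages, report.stages[1:]):
            assert a.features_out == b.features_in
        removed_sets = [set(s.removed) for s in report.stages]
        for i, a in enumerate(removed_sets):
            for b in removed_sets[i + 1:]:
                assert not (a & b)
        assert out.n_samples == table.n_samples
        assert out.scale == "log10"

    def test_all_features_fail_first_stage(self):
        # feature absent from every QC -> everything removed at stage 1
        t = qc_table([[np.nan, np.nan, np.nan]])
        out, report = run_preprocess(t, StudyConfig())
        assert out.n_features == 0
        assert report.stages[0].features_out == 0
        assert len(report.stages[0].removed) == 1

    def test_row_order_invariance_within_batch(self, small_study):
        table, _ = small_study
        out1, _ = run_preprocess(table, StudyConfig())
        perm = np.random.default_rng(0).permutation(table.n_samples)
        shuffled = type(table)(
            table.intensities.iloc[perm],
            table.samples.iloc[perm],
            table.features,
            scale="raw",
        )
        out2, _ = run_preprocess(shuffled, StudyConfig())
        a = out1.intensities.sort_index()
        b = out2.intensities.sort_index()
        np.testing.assert_allclose(a.to_numpy(), b.to_numpy(), rtol=1e-12)
        assert list(a.columns) == list(b.columns)

    def test_drift_correction_reduces_qc_cv(self):
        """Post-correction QC CV <= pre-correction for >= 95% of features
        under smooth multiplicative drift."""
        cfg = SimulationConfig(
            group_sizes={"A": 16, "B": 16}, subgroup=None, n_features=150,
            n_differential=0, drift_max_loss=0.25, lod_log10=0.0,
        )
        table, _ = simulate_study(cfg, seed=7)
        pre = qc_cv(table)
        post = qc_cv(correct_qc_bracketing(table))
        frac = (post <= pre + 1e-12).mean()
        assert frac >= 0.95
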