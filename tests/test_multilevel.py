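"""Variance decomposition and multilevel model construction."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from crossmet.design_io import DesignError
from crossmet.multilevel import (
    Grouping,
    MultilevelSPLSDA,
    encode_classes,
    fit_mlsplsda,
    remove_variation,
)
from crossmet.preprocess import transform_scale
from crossmet.splsda import performance
from crossmet.synthetic import SyntheticSpec, generate_crossover


def loop_oracle(X, labels):
    """Per-group centering by explicit loops (independent of the vectorized path)."""
    X = np.asarray(X, dtype=float)
    grand = X.mean(axis=0)
    residual = X.copy()
    for level in set(labels):
        idx = [i for i, l in enumerate(labels) if l == level]
        gmean = X[idx].mean(axis=0)
        for i in idx:
            residual[i] = X[i] - gmean + grand
    return residual


class TestRemoveVariation:
    def test_two_singleton_groups_collapse_to_grand_mean(self):
        X = np.array([[0.0, 0.0], [2.0, 2.0]])
        res = remove_variation(X, Grouping("g", ["a", "b"]))
        np.testing.assert_allclose(res.residual, [[1.0, 1.0], [1.0, 1.0]])
        np.testing.assert_allclose(res.removed, [[-1.0, -1.0], [1.0, 1.0]])

    def test_single_group_is_identity(self, rng):
        X = rng.normal(size=(8, 4))
        res = remove_variation(X, Grouping("g", ["a"] * 8))
        np.testing.assert_allclose(res.residual, X, atol=1e-12)
        assert res.ss_between_groups == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_loop_oracle_with_ss_additivity(self, seed):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(20, 5))
        labels = rng.choice(list("wxyz"), size=20)
        res = remove_variation(X, Grouping("g", labels))
        np.testing.assert_allclose(res.residual, loop_oracle(X, labels), atol=1e-10)
        assert res.ss_between_groups + res.ss_residual == pytest.approx(
            res.ss_total, rel=1e-10)
        # input = residual + removed, with grand mean assigned to the residual
        np.testing.assert_allclose(res.residual + res.removed, X, atol=1e-12)

    def test_idempotent_for_fixed_grouping(self, rng):
        X = rng.normal(size=(15, 6))
        labels = rng.choice(["a", "b", "c"], 15)
        g = Grouping("g", labels)
        once = remove_variation(X, g).residual
        twice = remove_variation(once, g).residual
        np.testing.assert_allclose(twice, once, atol=1e-12)

    def test_sequential_subject_then_week_equals_two_way_oracle(self):
        # balanced design: every (subject, week) cell equally filled
        rng = np.random.default_rng(3)
        subjects = np.repeat(["s1", "s2", "s3"], 4)
        weeks = np.tile(["w1", "w1", "w2", "w2"], 3)
        X = rng.normal(size=(12, 5))
        step1 = remove_variation(X, Grouping("subject", subjects)).residual
        step2 = remove_variation(step1, Grouping("week", weeks)).residual

        grand = X.mean(axis=0)
        oracle = X.copy()
        for s in set(subjects):
            idx = subjects == s
            oracle[idx] -= X[idx].mean(axis=0) - grand
        tmp = oracle.copy()
        for w in set(weeks):
            idx = weeks == w
            oracle[idx] -= tmp[idx].mean(axis=0) - grand
        np.testing.assert_allclose(step2, oracle, atol=1e-10)

    def test_size_mismatch_rejected(self, rng):
        with pytest.raises(DesignError):
            remove_variation(rng.normal(size=(5, 3)), Grouping("g", ["a"] * 4))

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(
        X=arrays(np.float64, (12, 4),
                 elements=st.floats(-100, 100, allow_nan=False)),
        labels=st.lists(st.sampled_from("abc"), min_size=12, max_size=12),
    )
    def test_split_exact_and_ss_additive_for_any_input(self, X, labels):
        res = remove_variation(X, Grouping("g", labels))
        np.testing.assert_allclose(res.residual + res.removed, X, atol=1e-9)
        assert res.ss_between_groups + res.ss_residual == pytest.approx(
            res.ss_total, abs=1e-6 * max(res.ss_total, 1.0))
        # residual group means all collapse onto the grand mean
        grand = X.mean(axis=0)
        for lev in set(labels):
            idx = np.asarray(labels) == lev
            np.testing.assert_allclose(res.residual[idx].mean(axis=0), grand,
                                       atol=1e-8)


class TestEncodeClasses:
    def test_phase_on_administration_samples_two_classes(self, default_study):
        _, design, _, _ = default_study
        labels = encode_classes(design, ["phase"])
        assert set(labels) == {"placebo", "oleuropein"}
        assert len(labels) == 90  # 9 subjects x 2 weeks x 5 administration days

    def test_phase_week_interaction_four_classes(self, default_study):
        _, design, _, _ = default_study
        labels = encode_classes(design, ["phase", "week"])
        assert len(set(labels)) == 4

    def test_subject_factor_gives_nine_classes(self, default_study):
        _, design, _, _ = default_study
        labels = encode_classes(design, ["subject"])
        assert len(set(labels)) == 9
        assert len(labels) == 126  # baseline retained for subject clustering

    def test_phase_on_baseline_only_design_rejected(self, default_study):
        _, design, _, _ = default_study
        from crossmet.design_io import StudyDesign

        base = StudyDesign(
            design.samples.loc[design.samples["phase"] == "baseline"].copy())
        with pytest.raises(DesignError):
            encode_classes(base, ["phase"])

    def test_three_factors_rejected(self, default_study):
        _, design, _, _ = default_study
        with pytest.raises(DesignError):
            encode_classes(design, ["phase", "week", "day"])


class TestMultilevelSPLSDA:
    def test_overlapping_subtract_and_discriminant_rejected(self, default_study):
        table, design, _, _ = default_study
        scaled = transform_scale(table, "log10", "none")
        with pytest.raises(DesignError, match="overlap"):
            MultilevelSPLSDA(scaled, design, ("phase",), "phase")

    def test_model_equals_manual_decompose_then_fit(self, default_study):
        table, design, _, _ = default_study
        scaled = transform_scale(table, "log10", "none")
        res = fit_mlsplsda(scaled, design, ("phase",), "subject",
                           n_components=2, keepx=[30, 30])
        labels = encode_classes(design, ["phase"])
        X = scaled.intensities.loc[labels.index].to_numpy()
        manual = remove_variation(
            X, Grouping.from_design(design, "subject", sample_ids=labels.index))
        from crossmet.splsda import SPLSDA

        inner = SPLSDA(manual.residual, labels.to_numpy(), 2, [30, 30]).fit()
        np.testing.assert_allclose(res.splsda.x_scores, inner.x_scores, atol=1e-10)

    def test_two_level_model_stores_interaction_labels(self, default_study):
        table, design, _, _ = default_study
        scaled = transform_scale(table, "log10", "none")
        res = fit_mlsplsda(scaled, design, ("phase", "day"), "subject",
                           n_components=2, keepx=[20, 20])
        assert len(res.classes) == 10  # 2 phases x 5 days
        assert set(res.model.class_series) == set(res.splsda.class_map)

    def test_subtraction_improves_cv_error_under_subject_dominance(self):
        # paired comparison on generator output: subject-subtracted model
        # must beat the plain model when between-subject variance dominates
        wins = 0
        n_seeds = 8
        for seed in range(n_seeds):
            spec = SyntheticSpec(n_features=200, seed=200 + seed)
            table, design, _ = generate_crossover(spec)
            scaled = transform_scale(table, "log10", "none")
            labels = encode_classes(design, ["phase"])
            X = scaled.intensities.loc[labels.index].to_numpy()
            resid = remove_variation(
                X, Grouping.from_design(design, "subject",
                                        sample_ids=labels.index)).residual
            plain = performance(X, labels.to_numpy(), 1, [50], 7, seed=seed)
            multi = performance(resid, labels.to_numpy(), 1, [50], 7, seed=seed)
            wins += multi.error_rate < plain.error_rate
        assert wins >= n_seeds - 1

    def test_subtracting_the_only_real_effect_leaves_chance(self):
        # only week effects exist; subtract week -> phase model is at chance
        errs = []
        for seed in range(5):
            spec = SyntheticSpec(n_features=150, n_affected=0, effect_size=0.0,
                                 sigma_between=0.0, sigma_week=1.0,
                                 sigma_day=0.0, sigma_error=0.3, seed=seed)
            table, design, _ = generate_crossover(spec)
            scaled = transform_scale(table, "log10", "none")
            labels = encode_classes(design, ["phase"])
            X = scaled.intensities.loc[labels.index].to_numpy()
            resid = remove_variation(
                X, Grouping.from_design(design, "week",
                                        sample_ids=labels.index)).residual
            perf = performance(resid, labels.to_numpy(), 1, [50], 7, seed=seed)
            errs.append(perf.error_rate)
        assert np.mean(errs) == pytest.approx(0.5, abs=0.1)

    def test_nested_grouping_builds_subject_week_cells(self, default_study):
        _, design, _, _ = default_study
        g = Grouping.from_design(design, "week", nested_in_subject=True)
        assert g.name == "subject:week"
        assert len(set(g.labels)) == 18  # 9 subjects x 2 weeks

    def test_summary_reports_subtracted_share(self, default_study):
        table, design, _, _ = default_study
        scaled = transform_scale(table, "log10", "none")
        res = fit_mlsplsda(scaled, design, ("phase",), "subject",
                           n_components=2, keepx=[20, 20])
        text = res.summary()
        assert "subtracted component: subject" in text
        assert "phase" in text
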