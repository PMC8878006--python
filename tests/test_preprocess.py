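"""Preprocessing: consensus matching, PPCA imputation, quotient
normalization, QC-RLSC and scaling."""

import numpy as np
import pytest

from crossmet.preprocess import (
    PeakList,
    PreprocessError,
    consensus_features,
    consensus_percentages,
    impute_ppca,
    normalize_reference,
    qc_rlsc,
    summarize_consensus,
    transform_scale,
)
from crossmet.synthetic import (
    SyntheticSpec,
    apply_drift,
    generate_crossover,
    make_qc_series,
)

from conftest import make_table


# ---------------------------------------------------------------------------
# consensus matching
# ---------------------------------------------------------------------------

def brute_force_match(a, b, ppm_tol, rt_tol):
    """Independent greedy matcher over the all-pairs candidate table."""
    cand = []
    for i in range(len(a)):
        for j in range(len(b)):
            ppm = abs(b.mz[j] - a.mz[i]) / a.mz[i] * 1e6
            drt = abs(b.rt[j] - a.rt[i])
            if ppm <= ppm_tol and drt <= rt_tol:
                dist = np.hypot(ppm / ppm_tol, drt / rt_tol)
                cand.append((dist, ppm, i, j))
    pairs, ua, ub = [], set(range(len(a))), set(range(len(b)))
    for dist, ppm, i, j in sorted(cand):
        if i in ua and j in ub:
            pairs.append((i, j))
            ua.discard(i)
            ub.discard(j)
    return sorted(pairs), sorted(ua), sorted(ub)


class TestConsensus:
    def test_identical_lists_all_common(self, rng):
        mz = rng.uniform(100, 900, 20)
        rt = rng.uniform(1, 20, 20)
        res = consensus_features(PeakList(mz, rt), PeakList(mz, rt), 10, 0.1)
        assert (res.n_common, res.n_unique_a, res.n_unique_b) == (20, 0, 0)

    def test_five_ppm_pair_matches_at_10_not_1_ppm(self):
        a = PeakList([100.0000], [1.0])
        b = PeakList([100.0005], [1.0])
        res10 = consensus_features(a, b, ppm_tol=10, rt_tol=0.1)
        assert res10.n_common == 1
        res1 = consensus_features(a, b, ppm_tol=1, rt_tol=0.1)
        assert (res1.n_common, res1.n_unique_a, res1.n_unique_b) == (0, 1, 1)

    def test_empty_lists_give_empty_result(self):
        res = consensus_features(PeakList([], []), PeakList([], []), 10, 0.1)
        assert res.total == 0

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_agrees_with_brute_force_and_counts_sum(self, seed):
        rng = np.random.default_rng(seed)
        a = PeakList(rng.uniform(100, 110, 50), rng.uniform(1, 3, 50))
        b = PeakList(rng.uniform(100, 110, 50), rng.uniform(1, 3, 50))
        res = consensus_features(a, b, ppm_tol=50, rt_tol=0.2)
        pairs, ua, ub = brute_force_match(a, b, 50, 0.2)
        assert sorted(res.pairs) == pairs
        assert (res.n_unique_a, res.n_unique_b) == (len(ua), len(ub))
        assert res.total == len(res.merged)
        # swapping the lists swaps the unique counts
        swapped = consensus_features(b, a, ppm_tol=50, rt_tol=0.2)
        assert swapped.n_unique_a == res.n_unique_b
        assert swapped.n_unique_b == res.n_unique_a

    def test_percent_summary_rounds_to_integers(self):
        assert consensus_percentages(887, 203, 402) == (59, 14, 27)
        assert 887 + 203 + 402 == 1492
        assert consensus_percentages(1, 0, 0) == (100, 0, 0)
        with pytest.raises(PreprocessError):
            consensus_percentages(0, 0, 0)

    def test_summarize_uses_result_counts(self):
        a = PeakList([100.0], [1.0])
        res = consensus_features(a, a, 10, 0.1)
        assert summarize_consensus(res) == (100, 0, 0)


# ---------------------------------------------------------------------------
# PPCA imputation
# ---------------------------------------------------------------------------

class TestImputePPCA:
    def test_complete_table_returned_unchanged(self, rng):
        table = make_table(rng.lognormal(3, 1, (15, 8)))
        out = impute_ppca(table, 2)
        np.testing.assert_array_equal(out.values, table.values)

    def test_noiseless_rank2_recovered(self, rng):
        A = rng.normal(size=(30, 2))
        B = rng.normal(size=(2, 20))
        X = A @ B + 5.0
        mask = rng.random(X.shape) < 0.10
        Xm = X.copy()
        Xm[mask] = np.nan
        table = make_table(Xm, raw=False)
        out = impute_ppca(table, 2, max_iter=5000, tol=1e-12)
        rel = np.abs(out.values[mask] - X[mask]) / np.abs(X[mask])
        assert rel.max() < 1e-6

    def test_observed_cells_never_altered(self, rng):
        X = rng.lognormal(3, 1, (20, 10))
        mask = rng.random(X.shape) < 0.15
        Xm = X.copy()
        Xm[mask] = np.nan
        table = make_table(Xm)
        out = impute_ppca(table, 3)
        np.testing.assert_array_equal(out.values[~mask], X[~mask])

    def test_beats_mean_imputation_on_noisy_low_rank(self, rng):
        A = rng.normal(size=(40, 2))
        B = rng.normal(size=(2, 25))
        X = A @ B + rng.normal(0, 0.1, (40, 25)) + 10
        mask = rng.random(X.shape) < 0.1
        Xm = X.copy()
        Xm[mask] = np.nan
        out = impute_ppca(make_table(Xm, raw=False), 2)
        rmse_ppca = np.sqrt(np.mean((out.values[mask] - X[mask]) ** 2))
        col_means = np.nanmean(Xm, axis=0)
        mean_fill = np.take(col_means, np.where(mask)[1])
        rmse_mean = np.sqrt(np.mean((mean_fill - X[mask]) ** 2))
        assert rmse_ppca < rmse_mean

    def test_all_missing_feature_named_in_error(self, rng):
        X = rng.lognormal(3, 1, (10, 4))
        X[:, 2] = np.nan
        with pytest.raises(PreprocessError, match="F003"):
            impute_ppca(make_table(X), 2)

    def test_deterministic_under_seed(self, rng):
        X = rng.lognormal(3, 1, (20, 10))
        X[rng.random(X.shape) < 0.1] = np.nan
        a = impute_ppca(make_table(X), 2, seed=5)
        b = impute_ppca(make_table(X), 2, seed=5)
        np.testing.assert_array_equal(a.values, b.values)


# ---------------------------------------------------------------------------
# probabilistic quotient normalization
# ---------------------------------------------------------------------------

class TestNormalizeReference:
    def base_table(self, rng, n=6, p=40):
        return make_table(rng.lognormal(3, 0.5, (n, p)))

    def test_sample_equal_to_reference_unchanged(self, rng):
        table = self.base_table(rng)
        ref_ids = table.sample_ids[:3]
        reference = table.intensities.loc[ref_ids].mean(axis=0)
        vals = table.values.copy()
        vals[5] = reference.to_numpy()
        table = table.with_values(vals)
        out = normalize_reference(table, ref_ids)
        np.testing.assert_allclose(out.values[5], reference, rtol=1e-12)

    def test_double_of_reference_is_halved(self, rng):
        table = self.base_table(rng)
        ref_ids = table.sample_ids[:3]
        reference = table.intensities.loc[ref_ids].mean(axis=0).to_numpy()
        vals = table.values.copy()
        vals[5] = 2.0 * reference
        out = normalize_reference(table.with_values(vals), ref_ids)
        np.testing.assert_allclose(out.values[5], reference, rtol=1e-12)

    def test_median_quotient_is_robust_to_10pct_outliers(self, rng):
        table = self.base_table(rng, p=50)
        ref_ids = table.sample_ids[:3]
        reference = table.intensities.loc[ref_ids].mean(axis=0).to_numpy()
        vals = table.values.copy()
        sample = 3.0 * reference
        sample[:5] = rng.lognormal(8, 1, 5)  # 10% corrupted features
        vals[5] = sample
        out = normalize_reference(table.with_values(vals), ref_ids)
        # quotient must be exactly 3 -> uncorrupted features return to reference
        np.testing.assert_allclose(out.values[5][5:], reference[5:], rtol=1e-12)

    def test_idempotent_on_proportional_samples(self, rng):
        reference = rng.lognormal(3, 0.5, 30)
        scales = rng.uniform(0.5, 2.0, 6)
        table = make_table(np.outer(scales, reference))
        ref_ids = table.sample_ids[:3]
        once = normalize_reference(table, ref_ids)
        twice = normalize_reference(once, ref_ids)
        np.testing.assert_allclose(twice.values, once.values, rtol=1e-12)

    def test_all_zero_reference_rejected(self, rng):
        table = self.base_table(rng)
        vals = table.values.copy()
        vals[:3] = 0.0
        with pytest.raises(PreprocessError):
            normalize_reference(table.with_values(vals), table.sample_ids[:3])


# ---------------------------------------------------------------------------
# QC-RLSC
# ---------------------------------------------------------------------------

def qc_study_tables(seed=5, slope=0.01):
    spec = SyntheticSpec(n_features=30, n_affected=5, seed=seed)
    table, design, _ = generate_crossover(spec)
    t_qc, d_qc = make_qc_series(table, design)
    return t_qc, d_qc, apply_drift(t_qc, d_qc, slope)


class TestQcRlsc:
    def test_constant_signal_unchanged(self):
        t_qc, d_qc, _ = qc_study_tables()
        const = t_qc.with_values(np.full_like(t_qc.values, 100.0))
        out = qc_rlsc(const, d_qc)
        np.testing.assert_allclose(out.values, 100.0, rtol=1e-10)

    def test_linear_drift_reduces_qc_rsd_below_1pct(self):
        t_qc, d_qc, drifted = qc_study_tables()
        out = qc_rlsc(drifted, d_qc)
        qc_mask = d_qc.samples.loc[out.sample_ids, "is_qc"].to_numpy(bool)
        qc_vals = out.values[qc_mask]
        rsd = qc_vals.std(axis=0, ddof=1) / qc_vals.mean(axis=0)
        assert (rsd < 0.01).all()
        # and the correction never worsens the QC RSD
        pre = drifted.values[qc_mask]
        pre_rsd = pre.std(axis=0, ddof=1) / pre.mean(axis=0)
        assert (rsd <= pre_rsd + 1e-12).all()

    def test_linear_drift_inverted_up_to_feature_constant(self):
        t_qc, d_qc, drifted = qc_study_tables()
        out = qc_rlsc(drifted, d_qc)
        qc_mask = d_qc.samples.loc[out.sample_ids, "is_qc"].to_numpy(bool)
        ratio = out.values[~qc_mask] / t_qc.values[~qc_mask]
        spread = ratio.max(axis=0) / ratio.min(axis=0) - 1
        assert spread.max() < 1e-6

    def test_injection_order_permutation_invariant(self):
        t_qc, d_qc, drifted = qc_study_tables()
        perm = np.random.default_rng(0).permutation(drifted.n_samples)
        ids = [drifted.sample_ids[i] for i in perm]
        shuffled = drifted.subset_samples(ids)
        out_ref = qc_rlsc(drifted, d_qc)
        out_shuf = qc_rlsc(shuffled, d_qc)
        np.testing.assert_allclose(
            out_shuf.intensities.loc[out_ref.sample_ids].to_numpy(),
            out_ref.values, rtol=1e-10)

    def test_fewer_than_4_qcs_rejected(self):
        spec = SyntheticSpec(n_features=5, n_affected=1, seed=0)
        table, design, _ = generate_crossover(spec)
        t_qc, d_qc = make_qc_series(table, design, qc_every=1000, n_lead=2, n_tail=1)
        with pytest.raises(PreprocessError):
            qc_rlsc(t_qc, d_qc)


# ---------------------------------------------------------------------------
# transform and scale
# ---------------------------------------------------------------------------

class TestTransformScale:
    def test_centering_only(self, rng):
        table = make_table(rng.lognormal(3, 1, (20, 10)))
        out = transform_scale(table, "none", "none")
        assert np.abs(out.values.mean(axis=0)).max() < 1e-12

    def test_unit_variance(self, rng):
        table = make_table(rng.lognormal(3, 1, (20, 10)))
        out = transform_scale(table, "log10", "unit_variance")
        np.testing.assert_allclose(out.values.std(axis=0, ddof=1), 1.0, atol=1e-9)

    def test_pareto_sd_is_sqrt_of_original(self, rng):
        table = make_table(rng.lognormal(3, 1, (20, 10)))
        orig_sd = np.log10(table.values).std(axis=0, ddof=1)
        out = transform_scale(table, "log10", "pareto")
        np.testing.assert_allclose(
            out.values.std(axis=0, ddof=1), np.sqrt(orig_sd), atol=1e-9)

    def test_log_of_nonpositive_lists_cells(self):
        table = make_table([[1.0, 0.0], [2.0, 3.0]])
        with pytest.raises(PreprocessError, match="F002"):
            transform_scale(table, "log10", "none")
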