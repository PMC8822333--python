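"""Cleaning-cascade tests: replicate QC, ComBat, missingness, normalization."""

import numpy as np
import pandas as pd
import pytest

from neurometab.errors import (
    ConfigurationError,
    DegenerateInputError,
    NumericDomainError,
)
from neurometab.preprocess import (
    MetabolomicsPreprocessor,
    combat_correct,
    filter_and_impute_missing,
    filter_replicate_cv,
    filter_sample_replicate_corr,
    log2_quantile_normalize,
    preprocess,
    quantile_normalize,
    summarize_replicates,
)

from conftest import make_meta, make_raw


def triplicate_table(*rows_per_feature):
    """Each arg is a 3-tuple replicated across 4 samples."""
    reps = np.array([[list(r)] * 4 for r in rows_per_feature], dtype=float)
    return make_raw(reps)


class TestReplicateCVFilter:
    @pytest.mark.parametrize(
        "triple, kept",
        [
            ((100, 100, 100), True),   # CV 0
            ((1, 10, 100), False),     # CV ~ 1.48 (sd 54.74 / mean 37)
            ((10, 20, 30), True),      # CV 0.5
        ],
    )
    def test_cv_rule(self, triple, kept):
        raw = triplicate_table(triple)
        out, log = filter_replicate_cv(raw)
        assert (out.n_features == 1) is kept
        assert bool(log["dropped_cv"].iloc[0]) is (not kept)

    def test_cv_value_recorded(self):
        raw = triplicate_table((1, 10, 100))
        _, log = filter_replicate_cv(raw)
        assert log["median_cv"].iloc[0] == pytest.approx(54.74179 / 37.0, abs=1e-4)

    def test_invalid_threshold(self):
        with pytest.raises(ConfigurationError):
            filter_replicate_cv(triplicate_table((1, 2, 3)), cv_max=0.0)


class TestSampleReplicateCorrFilter:
    def test_identical_replicates_kept(self):
        reps = np.stack([np.tile(np.arange(1, 6, dtype=float)[:, None], 3)] , axis=0)
        reps = np.repeat(reps, 2, axis=0).transpose(2, 0, 1)  # shaped wrong; rebuild
        vals = np.arange(1.0, 6.0)
        reps = np.stack([np.stack([vals, vals, vals], axis=1)] * 2, axis=1)
        raw = make_raw(reps)
        out, dropped = filter_sample_replicate_corr(raw)
        assert dropped == []
        assert out.n_samples == 2

    def test_anticorrelated_replicate_dropped(self):
        # replicate 3 is the negation pattern of replicates 1-2 across features
        a = np.array([1.0, 2.0, 3.0])
        reps = np.stack([a, a, a[::-1]], axis=1)[:, None, :]
        raw = make_raw(reps)
        out, dropped = filter_sample_replicate_corr(raw)
        assert dropped == ["S001"]
        assert out.n_samples == 0

    def test_rmin_one_with_noise_drops_all(self):
        rng = np.random.default_rng(0)
        reps = rng.lognormal(10, 1, (20, 3, 3))
        raw = make_raw(reps)
        out, dropped = filter_sample_replicate_corr(raw, r_min=1.0)
        assert out.n_samples == 0 and len(dropped) == 3

    def test_too_few_features(self):
        raw = make_raw(np.ones((2, 2, 3)))
        with pytest.raises(DegenerateInputError):
            filter_sample_replicate_corr(raw)


class TestSummarize:
    def test_median_rules(self):
        reps = np.array(
            [[[10.0, 12.0, np.nan]], [[10.0, np.nan, np.nan]], [[3.0, 5.0, 7.0]]]
        )
        table = summarize_replicates(make_raw(reps))
        assert table.iloc[0, 0] == 11.0
        assert np.isnan(table.iloc[1, 0])
        assert table.iloc[2, 0] == 5.0


class TestComBat:
    def test_single_batch_identity(self):
        rng = np.random.default_rng(0)
        t = pd.DataFrame(rng.normal(16, 2, (30, 10)))
        out = combat_correct(t, np.zeros(10, dtype=int))
        pd.testing.assert_frame_equal(out, t)

    def test_single_sample_batch_rejected(self):
        t = pd.DataFrame(np.ones((5, 3)))
        with pytest.raises(DegenerateInputError):
            combat_correct(t, np.array([0, 0, 1]))

    def test_mean_shift_removed(self):
        rng = np.random.default_rng(1)
        n_feat, n_per = 300, 50
        base = rng.normal(16, 1.5, n_feat)
        x = base[:, None] + rng.normal(0, 1, (n_feat, 2 * n_per))
        x[:, n_per:] += 2.0  # pure delta = 2 batch shift on the log scale
        batches = np.repeat([0, 1], n_per)
        raw_diff = np.abs(x[:, :n_per].mean(1) - x[:, n_per:].mean(1))
        out = combat_correct(pd.DataFrame(x), batches).to_numpy()
        diff = np.abs(out[:, :n_per].mean(1) - out[:, n_per:].mean(1))
        # the planted shift (about 2.0 per feature) collapses to the sampling
        # noise floor of two n=50 batch means
        assert raw_diff.mean() > 1.8
        assert diff.mean() < 0.15
        assert np.mean(diff < 0.3) >= 0.95

    def test_variance_ratio_corrected(self):
        rng = np.random.default_rng(2)
        n_feat, n_per = 300, 50
        x = rng.normal(0, 1, (n_feat, 2 * n_per))
        x[:, n_per:] *= 2.0  # variance ratio 4:1
        batches = np.repeat([0, 1], n_per)
        out = combat_correct(pd.DataFrame(x), batches).to_numpy()
        ratio = out[:, n_per:].var(1, ddof=1) / out[:, :n_per].var(1, ddof=1)
        # 4:1 planted ratio collapses to ~1 up to residual F-noise
        assert 0.8 < np.median(ratio) < 1.25
        assert np.mean((ratio > 0.7) & (ratio < 1 / 0.7)) >= 0.90

    def test_grand_means_approximately_preserved(self):
        rng = np.random.default_rng(3)
        x = rng.normal(16, 1, (100, 40)) + np.repeat([0.0, 1.0], 20)[None, :]
        out = combat_correct(pd.DataFrame(x), np.repeat([0, 1], 20)).to_numpy()
        np.testing.assert_allclose(out.mean(1), x.mean(1), atol=0.15)


class TestMissingness:
    def _table(self, miss_mci, miss_cn, n_per=10):
        x = np.full((1, 2 * n_per), 100.0)
        x[0, : int(miss_mci * n_per)] = np.nan
        x[0, n_per : n_per + int(miss_cn * n_per)] = np.nan
        samples = [f"S{i:03d}" for i in range(2 * n_per)]
        meta = make_meta(samples, ["MCI"] * n_per + ["CN"] * n_per)
        return pd.DataFrame(x, columns=samples, index=["F1"]), meta

    def test_complete_feature_unchanged(self):
        t, meta = self._table(0.0, 0.0)
        out, log = filter_and_impute_missing(t, meta)
        pd.testing.assert_frame_equal(out, t)
        assert log["n_imputed"].iloc[0] == 0

    def test_retained_if_low_missing_in_one_group(self):
        t, meta = self._table(0.1, 0.3)
        out, log = filter_and_impute_missing(t, meta)
        assert len(out) == 1
        assert log["n_imputed"].iloc[0] == 4
        # imputed cells hold half the feature's minimum observed value
        assert (out.to_numpy() == 50.0).sum() == 4

    def test_excluded_if_high_missing_in_both(self):
        t, meta = self._table(0.5, 0.5)
        out, log = filter_and_impute_missing(t, meta)
        assert len(out) == 0
        assert bool(log["dropped_missing"].iloc[0])

    def test_both_groups_mode(self):
        t, meta = self._table(0.1, 0.3)
        out, _ = filter_and_impute_missing(t, meta, require_both_groups=True)
        assert len(out) == 0

    def test_missing_group_rejected(self):
        t, meta = self._table(0.0, 0.0)
        meta["diagnosis"] = "MCI"
        with pytest.raises(DegenerateInputError):
            filter_and_impute_missing(t, meta)


class TestQuantileNormalization:
    def test_rank_mean_hand_oracle(self):
        t = pd.DataFrame([[1.0, 4.0], [3.0, 2.0]])
        out = quantile_normalize(t)
        np.testing.assert_allclose(out.to_numpy(), [[1.5, 3.5], [3.5, 1.5]])

    def test_idempotent(self):
        rng = np.random.default_rng(0)
        t = pd.DataFrame(rng.normal(0, 1, (50, 8)))
        once = quantile_normalize(t)
        twice = quantile_normalize(once)
        np.testing.assert_allclose(once.to_numpy(), twice.to_numpy(), atol=1e-12)

    def test_columns_share_sorted_values(self):
        rng = np.random.default_rng(1)
        t = pd.DataFrame(rng.lognormal(10, 1, (40, 6)))
        out = log2_quantile_normalize(t).to_numpy()
        ref = np.sort(out[:, 0])
        for j in range(1, out.shape[1]):
            np.testing.assert_allclose(np.sort(out[:, j]), ref, atol=1e-12)

    def test_ties_get_mean_of_tied_reference(self):
        t = pd.DataFrame({"a": [1.0, 1.0, 5.0], "b": [2.0, 4.0, 6.0]})
        out = quantile_normalize(t)
        # ranks 1-2 of column a are tied; both get mean of reference[0:2]
        assert out["a"].iloc[0] == out["a"].iloc[1]

    def test_identical_columns_unchanged_up_to_log2(self):
        col = np.array([2.0, 8.0, 32.0])
        t = pd.DataFrame({"a": col, "b": col})
        out = log2_quantile_normalize(t)
        np.testing.assert_allclose(out["a"].to_numpy(), np.log2(col))

    def test_nonpositive_rejected(self):
        with pytest.raises(NumericDomainError):
            log2_quantile_normalize(pd.DataFrame([[0.0, 1.0]]))


class TestCascade:
    def test_full_cascade_bookkeeping(self, tiny_dataset):
        clean = preprocess(tiny_dataset.raw, tiny_dataset.cohort)
        qc = clean.qc_log
        n_in = tiny_dataset.raw.n_features
        n_out = clean.intensities.shape[0]
        assert n_out <= n_in
        assert n_out == n_in - int(qc["dropped_cv"].sum()) - int(qc["dropped_missing"].sum())
        assert not clean.intensities.isna().any().any()
        # post quantile normalization all columns share sorted values
        x = clean.matrix
        np.testing.assert_allclose(
            np.sort(x[:, 0]), np.sort(x[:, -1]), atol=1e-10
        )

    def test_estimator_wrapper_params(self, tiny_dataset):
        prep = MetabolomicsPreprocessor(cv_max=0.5)
        assert prep.get_params()["cv_max"] == 0.5
        prep.set_params(miss_max=0.3)
        clean = prep.fit_transform(tiny_dataset.raw, tiny_dataset.cohort)
        assert prep.qc_log_ is clean.qc_log
        with pytest.raises(ConfigurationError):
            prep.set_params(nope=1)
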