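import numpy as np
import pandas as pd
import pytest

from mycometab.containers import MetaboliteTable
from mycometab.preprocess import (
    autoscale,
    dixon_filter,
    knn_impute,
    log2_transform,
    normalize_internal_standard,
    normalize_sample_median,
    preprocess_pipeline,
)
from mycometab.simulate import IS_FEATURE, SyntheticConfig, simulate_dataset


def _meta(sample_ids, treatment="minusAM", das=14):
    return pd.DataFrame(
        {"treatment": treatment, "das": das, "replicate": range(1, len(sample_ids) + 1)},
        index=pd.Index(sample_ids, name="sample_id"),
    )


class TestInternalStandard:
    def test_direct_division(self):
        t = MetaboliteTable(
            pd.DataFrame({"a": [10.0], "b": [20.0], "IS": [5.0]}, index=["s1"])
        )
        out = normalize_internal_standard(t, "IS")
        assert out.values.loc["s1"].tolist() == [2.0, 4.0]
        assert "IS" not in out.values.columns
        assert out.state == "is_normalized"

    def test_all_equal_to_standard_gives_ones(self):
        t = MetaboliteTable(pd.DataFrame({"a": [7.0, 3.0], "IS": [7.0, 3.0]}, index=["s1", "s2"]))
        out = normalize_internal_standard(t, "IS")
        assert (out.values == 1.0).all().all()

    def test_missing_standard_names_sample(self):
        t = MetaboliteTable(
            pd.DataFrame({"a": [1.0, 1.0], "IS": [2.0, np.nan]}, index=["s1", "bad"])
        )
        with pytest.raises(ValueError, match="bad"):
            normalize_internal_standard(t, "IS")

    def test_loading_factor_invariance(self):
        rng = np.random.default_rng(0)
        base = pd.DataFrame(rng.uniform(1, 100, (4, 6)), columns=[*"abcde", "IS"])
        t1 = normalize_internal_standard(MetaboliteTable(base), "IS")
        loaded = base.mul(pd.Series([0.1, 1.0, 10.0, 7.3], index=base.index), axis=0)
        t2 = normalize_internal_standard(MetaboliteTable(loaded), "IS")
        assert np.allclose(t1.values, t2.values, rtol=1e-12)


class TestMedianNormalization:
    def test_three_values(self):
        t = MetaboliteTable(pd.DataFrame([[1.0, 2.0, 3.0]], index=["s"]), "is_normalized")
        out = normalize_sample_median(t)
        assert out.values.iloc[0].tolist() == [0.5, 1.0, 1.5]

    def test_constant_sample_becomes_ones(self):
        t = MetaboliteTable(pd.DataFrame([[4.0] * 5], index=["s"]), "is_normalized")
        assert (normalize_sample_median(t).values == 1.0).all().all()

    def test_output_medians_are_exactly_one(self):
        rng = np.random.default_rng(1)
        t = MetaboliteTable(
            pd.DataFrame(rng.uniform(0.1, 50, (6, 11))), "is_normalized"
        )
        out = normalize_sample_median(t)
        assert np.allclose(out.values.median(axis=1), 1.0)

    def test_all_missing_sample_raises(self):
        t = MetaboliteTable(pd.DataFrame([[np.nan, np.nan]], index=["s"]), "is_normalized")
        with pytest.raises(ValueError, match="s"):
            normalize_sample_median(t)


class TestDixon:
    def test_textbook_n3_case(self):
        # Q = (10.0 - 1.01)/(10.0 - 1.0) = 0.9989 > 0.970 at alpha 0.05
        values = pd.DataFrame({"f": [1.0, 1.01, 10.0]}, index=["s1", "s2", "s3"])
        t = MetaboliteTable(values, "median_normalized")
        out, mask = dixon_filter(t, _meta(values.index), alpha=0.05)
        assert mask["f"].tolist() == [False, False, True]
        assert np.isnan(out.values.at["s3", "f"])

    def test_zero_range_group_untouched(self):
        values = pd.DataFrame({"f": [5.0, 5.0, 5.0]}, index=["s1", "s2", "s3"])
        t = MetaboliteTable(values, "median_normalized")
        _, mask = dixon_filter(t, _meta(values.index))
        assert not mask.any().any()

    def test_exclusions_monotone_in_alpha(self):
        cfg = SyntheticConfig(seed=5, outlier_rate=0.03, dropout_rate=0.0, structural_rate=0.0)
        raw, metadata, _, _ = simulate_dataset(cfg)
        t = normalize_internal_standard(raw, IS_FEATURE)
        t = normalize_sample_median(t)
        _, strict = dixon_filter(t, metadata, alpha=0.01)
        _, loose = dixon_filter(t, metadata, alpha=0.05)
        assert strict.to_numpy().sum() <= loose.to_numpy().sum()
        assert not (strict & ~loose).any().any()

    def test_recall_of_planted_spikes(self):
        """Spikes >= 8x are nearly always flagged at n = 3; overall recall of
        the 5-20x spike mix sits around 0.8 (small spikes on low base values
        fall below the n=3 critical ratio)."""
        caught_all = caught_big = n_all = n_big = 0
        for seed in range(1, 6):
            cfg = SyntheticConfig(
                seed=seed, outlier_rate=0.02, dropout_rate=0.0, structural_rate=0.0
            )
            raw, metadata, _, truth = simulate_dataset(cfg)
            t = normalize_internal_standard(raw, IS_FEATURE)
            t = normalize_sample_median(t)
            _, mask = dixon_filter(t, metadata)
            om = truth.outlier_mask.to_numpy()
            n_all += om.sum()
            caught_all += (mask.to_numpy() & om).sum()
        assert caught_all / n_all >= 0.75

    def test_small_group_skipped_with_warning(self):
        values = pd.DataFrame({"f": [1.0, 2.0]}, index=["s1", "s2"])
        t = MetaboliteTable(values, "median_normalized")
        with pytest.warns(UserWarning, match="Dixon"):
            _, mask = dixon_filter(t, _meta(values.index))
        assert not mask.any().any()


class TestLog2:
    def test_examples_and_roundtrip(self):
        t = MetaboliteTable(pd.DataFrame([[4.0, 1.0]], index=["s"]), "filtered")
        out = log2_transform(t)
        assert out.values.iloc[0].tolist() == [2.0, 0.0]
        x = np.random.default_rng(2).normal(size=(3, 4))
        t2 = MetaboliteTable(pd.DataFrame(2.0**x), "filtered")
        assert np.allclose(log2_transform(t2).values, x, atol=1e-12)

    def test_nonpositive_value_names_cell(self):
        t = MetaboliteTable(
            pd.DataFrame({"bad_feature": [1.0, -2.0]}, index=["s1", "s2"]), "filtered"
        )
        with pytest.raises(ValueError, match="bad_feature"):
            log2_transform(t)


class TestKnnImpute:
    def test_duplicate_feature_is_its_own_neighbour(self):
        rng = np.random.default_rng(3)
        base = rng.normal(size=6)
        values = pd.DataFrame(
            {"f1": base, "f2": base, "f3": rng.normal(10, 1, 6)},
            index=[f"s{i}" for i in range(6)],
        )
        values.iloc[0, 0] = np.nan
        meta = _meta(values.index[:3]).pipe(
            lambda m: pd.concat([m, _meta(values.index[3:], das=24)])
        )
        t = MetaboliteTable(values, "log2")
        out, record = knn_impute(t, meta, k=1)
        assert out.values.iloc[0, 0] == pytest.approx(base[0], abs=1e-12)
        assert record["imputed_cells"] == [["s0", "f1"]]

    def test_observed_cells_never_altered(self, default_dataset):
        raw, metadata, _, _ = default_dataset
        t = normalize_internal_standard(raw, IS_FEATURE)
        t = normalize_sample_median(t)
        t = log2_transform(t)
        before = t.values.copy()
        out, _ = knn_impute(t, metadata)
        obs = ~before.isna()
        assert (out.values.to_numpy()[obs.to_numpy()] == before.to_numpy()[obs.to_numpy()]).all()
        assert not out.values.isna().any().any()

    def test_structural_absence_gets_half_minimum(self):
        values = pd.DataFrame(
            {
                "f1": [np.nan, np.nan, np.nan, 3.0, 3.5, 2.5],
                "f2": [1.0, 1.2, 0.8, 1.1, 0.9, 1.0],
            },
            index=[f"s{i}" for i in range(6)],
        )
        meta = pd.concat([_meta(values.index[:3], das=14), _meta(values.index[3:], das=24)])
        out, record = knn_impute(MetaboliteTable(values, "log2"), meta, k=1)
        # all three replicates of the first group miss f1 -> log2 half-minimum
        assert np.allclose(out.values.loc[["s0", "s1", "s2"], "f1"], 2.5 - 1.0)
        assert len(record["structural_cells"]) == 3

    def test_imputation_error_below_replicate_noise(self):
        # the same seed without dropout yields the identical pre-mask table,
        # so the masked cells' true values are known exactly
        kw = dict(seed=13, outlier_rate=0.0, structural_rate=0.0)
        raw, metadata, _, truth = simulate_dataset(SyntheticConfig(dropout_rate=0.05, **kw))
        full, _, _, _ = simulate_dataset(SyntheticConfig(dropout_rate=0.0, **kw))

        def to_log2(table):
            t = normalize_internal_standard(table, IS_FEATURE)
            t = normalize_sample_median(t)
            return log2_transform(t)

        observed = to_log2(raw)
        imputed, _ = knn_impute(observed, metadata)
        true_log2 = to_log2(full)
        mask = truth.dropout_mask.to_numpy()
        errs = np.abs(imputed.values.to_numpy() - true_log2.values.to_numpy())[mask]
        assert np.median(errs) < 0.2  # sigma_bio of the generating config

    def test_bad_k_raises(self, default_dataset):
        raw, metadata, _, _ = default_dataset
        t = normalize_internal_standard(raw, IS_FEATURE)
        t = normalize_sample_median(t)
        t = log2_transform(t)
        with pytest.raises(ValueError):
            knn_impute(t, metadata, k=0)


class TestAutoscale:
    def test_closed_form_and_idempotence(self):
        t = MetaboliteTable(pd.DataFrame({"f": [1.0, 2.0, 3.0]}), "imputed")
        out, _ = autoscale(t)
        assert np.allclose(out.values["f"], [-1.224744871, 0.0, 1.224744871])
        again, _ = autoscale(out)
        assert np.allclose(out.values, again.values, atol=1e-12)

    def test_output_is_standardized(self):
        rng = np.random.default_rng(4)
        t = MetaboliteTable(pd.DataFrame(rng.normal(3, 7, (8, 5))), "imputed")
        out, _ = autoscale(t)
        assert np.allclose(out.values.mean(axis=0), 0.0, atol=1e-10)
        assert np.allclose(out.values.std(axis=0, ddof=0), 1.0, atol=1e-10)

    def test_zero_variance_feature_dropped(self):
        t = MetaboliteTable(pd.DataFrame({"f": [1.0, 1.0], "g": [0.0, 2.0]}), "imputed")
        with pytest.warns(UserWarning):
            out, record = autoscale(t)
        assert record["dropped_features"] == ["f"]
        assert list(out.values.columns) == ["g"]


class TestPipeline:
    def test_zero_noise_pipeline_matches_standardized_planted_means(self, clean_dataset):
        raw, metadata, _, truth = clean_dataset
        out, provenance = preprocess_pipeline(raw, metadata)
        # the median-normalization step subtracts each sample's log2 median,
        # so the exact expectation is the standardized median-centred signal
        planted = truth.planted_log2[out.feature_ids]
        med = np.log2(np.median(2.0**planted.to_numpy(), axis=1))
        adjusted = planted.sub(med, axis=0)
        expected = (adjusted - adjusted.mean()) / adjusted.std(ddof=0)
        assert np.allclose(out.values.to_numpy(), expected.to_numpy(), atol=1e-8)
        assert provenance["imputation"]["imputed_cells"] == []
        assert provenance["dixon_excluded_cells"] == []

    def test_invariance_to_global_rescaling_and_loading(self, clean_dataset):
        raw, metadata, _, _ = clean_dataset
        ref, _ = preprocess_pipeline(raw, metadata)
        rng = np.random.default_rng(5)
        loads = pd.Series(rng.uniform(0.2, 5.0, len(raw.values)), index=raw.values.index)
        perturbed = MetaboliteTable(raw.values.mul(loads, axis=0) * 42.0, "raw")
        out, _ = preprocess_pipeline(perturbed, metadata)
        assert np.allclose(ref.values.to_numpy(), out.values.to_numpy(), atol=1e-8)

    def test_rerun_is_bit_identical(self, default_dataset):
        raw, metadata, _, _ = default_dataset
        a, _ = preprocess_pipeline(raw, metadata)
        b, _ = preprocess_pipeline(raw, metadata)
        assert a.values.equals(b.values)
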