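"""Tests of the virtual-cohort generator."""

import numpy as np
import pandas as pd
import pytest

from icgsim.population import (
    CohortConfig, PhysiologyTrends, apply_exclusions, attach_physiology,
    build_cohort, load_cohort_csv, oversample, sample_anthropometry,
    sample_oatp1b3, sample_physiology, age_group, weight_class,
)


@pytest.fixture(scope="module")
def small_config():
    return CohortConfig(n_base=3000, n_target=5000, seed=123)


@pytest.fixture(scope="module")
def small_cohort(small_config):
    return build_cohort(small_config)


class TestAnthropometry:
    def test_fixed_seed_reproduces_table(self, small_config):
        a = sample_anthropometry(small_config)
        b = sample_anthropometry(small_config)
        pd.testing.assert_frame_equal(a, b)

    def test_ages_within_configured_range(self, small_config):
        df = sample_anthropometry(small_config)
        assert df["age"].between(18.0, 85.0, inclusive="left").all()

    def test_men_heavier_than_women_on_average(self):
        df = sample_anthropometry(CohortConfig(n_base=10_000, seed=5))
        means = df.groupby("sex")["body_weight_kg"].mean()
        assert means["M"] > means["F"]

    def test_body_weight_rises_to_midlife_then_declines(self):
        df = sample_anthropometry(CohortConfig(n_base=40_000, seed=9))
        df, _ = apply_exclusions(df, CohortConfig(n_base=1))
        young = df.loc[df["age"].between(18, 30), "body_weight_kg"].mean()
        mid = df.loc[df["age"].between(45, 55), "body_weight_kg"].mean()
        old = df.loc[df["age"].between(75, 85), "body_weight_kg"].mean()
        assert mid > young
        assert mid > old

    def test_height_moments_recovered(self, small_config):
        df = sample_anthropometry(CohortConfig(n_base=100_000, seed=11))
        for sex, params in (("M", small_config.male), ("F", small_config.female)):
            h = df.loc[df["sex"] == sex, "height_cm"]
            se = params.height_sd / np.sqrt(len(h))
            assert abs(h.mean() - params.height_mean) < 3 * se


class TestExclusions:
    def test_rules(self):
        records = pd.DataFrame({
            "age": [17.0, 50.0, 50.0, 90.0],
            "bmi": [25.0, 31.0, 25.0, 25.0],
        })
        kept, removed = apply_exclusions(records, CohortConfig(n_base=1))
        assert len(kept) == 1
        assert kept.iloc[0]["age"] == 50.0 and kept.iloc[0]["bmi"] == 25.0
        assert removed == {"age_below_minimum": 1, "bmi_above_maximum": 1,
                           "age_top_coded": 1}

    def test_all_excluded_raises(self):
        records = pd.DataFrame({"age": [10.0], "bmi": [40.0]})
        with pytest.raises(ValueError):
            apply_exclusions(records, CohortConfig(n_base=1))


class TestOversample:
    def test_resampling_contract(self):
        base = pd.DataFrame({"base_id": range(5), "age": np.linspace(20, 60, 5)})
        rng = np.random.default_rng(0)
        out = oversample(base, 15, rng)
        assert len(out) == 15
        assert set(out["base_id"]) <= set(range(5))
        assert out.attrs["oversampled"] is True

    def test_subsample_flagged_when_target_below_base(self):
        base = pd.DataFrame({"base_id": range(10), "age": np.full(10, 30.0)})
        out = oversample(base, 4, np.random.default_rng(0))
        assert len(out) == 4
        assert out["base_id"].is_unique
        assert out.attrs["oversampled"] is False

    def test_replicates_share_anthropometry_but_not_physiology(self, small_cohort):
        dup = small_cohort[small_cohort.duplicated("base_id", keep=False)]
        assert len(dup) > 0
        g = dup.groupby("base_id")
        assert (g["body_weight_kg"].nunique() == 1).all()
        # physiology re-drawn per replicate
        assert (g["fv_liver"].nunique() == g.size()).all()
        assert (g["f_oatp1b3"].nunique() == g.size()).all()


class TestPhysiology:
    def test_zero_correlation_config(self):
        trends = PhysiologyTrends(correlation=0.0)
        rng = np.random.default_rng(3)
        fv, fb = sample_physiology(np.full(10_000, 40.0), trends, rng)
        assert abs(np.corrcoef(fv, fb)[0, 1]) < 0.05

    def test_configured_correlation_recovered_at_fixed_age(self):
        trends = PhysiologyTrends()
        rng = np.random.default_rng(4)
        fv, fb = sample_physiology(np.full(10_000, 40.0), trends, rng)
        assert np.corrcoef(fv, fb)[0, 1] == pytest.approx(0.5, abs=0.05)

    def test_liver_volume_declines_with_age(self):
        trends = PhysiologyTrends()
        rng = np.random.default_rng(5)
        fv_young, fb_young = sample_physiology(np.full(10_000, 25.0), trends, rng)
        fv_old, fb_old = sample_physiology(np.full(10_000, 70.0), trends, rng)
        assert fv_old.mean() < fv_young.mean()
        assert fb_old.mean() < fb_young.mean()

    def test_zero_variance_returns_configured_mean(self):
        trends = PhysiologyTrends(cv=0.0)
        fv, fb = sample_physiology(np.array([20.0]), trends, np.random.default_rng(0))
        assert fv[0] == pytest.approx(0.026)
        assert fb[0] == pytest.approx(19.0 / 14.0)


class TestOatp1b3:
    def test_degenerate_distribution(self):
        x = sample_oatp1b3(10, 1.3, 0.0, np.random.default_rng(0))
        assert np.all(x == 1.3)

    def test_median_recovered(self):
        x = sample_oatp1b3(100_000, 1.0, 0.35, np.random.default_rng(1))
        assert np.median(x) == pytest.approx(1.0, rel=0.02)

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            sample_oatp1b3(5, -1.0, 0.3, np.random.default_rng(0))
        with pytest.raises(ValueError):
            sample_oatp1b3(5, 1.0, -0.1, np.random.default_rng(0))


class TestBuildCohort:
    def test_target_size_and_invariants(self, small_cohort, small_config):
        coh = small_cohort
        assert len(coh) == small_config.n_target
        assert (coh["age"] >= 18.0).all()
        assert (coh["bmi"] <= 30.0).all()
        assert (coh["age"] < 85.0).all()
        assert (coh[["fv_liver", "f_bloodflow", "f_oatp1b3"]] > 0).all().all()

    def test_byte_identical_under_fixed_seed(self, small_config, small_cohort):
        again = build_cohort(small_config)
        assert again.to_csv(index=False) == small_cohort.to_csv(index=False)

    def test_transporter_independent_of_age(self):
        coh = build_cohort(CohortConfig(n_base=35_427, n_target=100_000, seed=2))
        r = np.corrcoef(coh["age"], coh["f_oatp1b3"])[0, 1]
        assert abs(r) < 0.02

    def test_no_women_above_configured_weight_cap(self, small_cohort):
        women = small_cohort[small_cohort["sex"] == "F"]
        assert (women["body_weight_kg"] <= 100.0).all()

    def test_stratification_labels_partition(self, small_cohort):
        coh = small_cohort
        in_range = coh["body_weight_kg"].between(40, 140)
        assert coh.loc[in_range, "weight_class"].notna().all()
        assert coh["age_group"].notna().all()
        assert age_group([18, 40.9, 41, 66])[0] == "18-40"
        assert list(age_group([39.0, 41.0, 70.0])) == ["18-40", "41-65", "66-84"]
        assert list(weight_class([45, 65, 85, 120])) == ["40-60", "60-80", "80-100", "100-140"]


class TestCsvAdapter:
    def test_roundtrip_with_physiology_attachment(self, tmp_path):
        df = pd.DataFrame({
            "age": [30.0, 60.0], "sex": ["M", "F"],
            "weight": [80.0, 60.0], "height": [180.0, 160.0]})
        path = tmp_path / "cohort.csv"
        df.to_csv(path, index=False)
        loaded = load_cohort_csv(path)
        assert {"body_weight_kg", "height_cm", "bmi"} <= set(loaded.columns)
        full = attach_physiology(loaded, CohortConfig(n_base=1, seed=0))
        assert {"fv_liver", "f_bloodflow", "f_oatp1b3"} <= set(full.columns)

    def test_missing_columns_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        pd.DataFrame({"age": [30]}).to_csv(path, index=False)
        with pytest.raises(ValueError, match="missing"):
            load_cohort_csv(path)
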