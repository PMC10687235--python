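"""EMR cohort rules and feature engineering."""

from datetime import date, timedelta

import numpy as np
import pandas as pd
import pytest

from ihdrisk.emr import (
    Code,
    FeatureConfig,
    Observation,
    OntologyMap,
    PatientRecord,
    apply_inclusion_filters,
    build_feature_vector,
    charlson_index,
    exp_weighted_value,
    impute_targeted_median,
    label_outcome,
    load_charlson_map,
    measurement_count,
    prune_correlated,
    rollup_codes,
    stratified_split,
)

SCAN = date(2016, 6, 1)


def make_record(pid="P1", codes=(), encounters=None, observations=(), age_years=50,
                scan=SCAN):
    if encounters is None:
        encounters = [scan - timedelta(days=100), scan + timedelta(days=400)]
    return PatientRecord(
        patient_id=pid,
        scan_date=scan,
        birthdate=scan - timedelta(days=round(age_years * 365.25)),
        sex="F",
        encounters=list(encounters),
        observations=list(observations),
        codes=list(codes),
    )


class TestOutcomeLabel:
    def test_ihd_code_within_horizon_is_positive(self):
        rec = make_record(codes=[Code(SCAN + timedelta(days=100), "ICD10", "I21.4")])
        assert label_outcome(rec, 1)

    def test_code_outside_i20_i25_is_negative(self):
        rec = make_record(codes=[Code(SCAN + timedelta(days=100), "ICD10", "I26.0")])
        assert not label_outcome(rec, 1)

    def test_code_beyond_horizon_is_negative_at_1y_positive_at_5y(self):
        rec = make_record(codes=[Code(SCAN + timedelta(days=800), "ICD10", "I25.1")])
        assert not label_outcome(rec, 1)
        assert label_outcome(rec, 5)

    def test_code_at_or_before_scan_never_labels(self):
        rec = make_record(codes=[Code(SCAN, "ICD10", "I21.0")])
        assert not label_outcome(rec, 1)


class TestInclusionFilters:
    def build_audit_fixture(self):
        ok = make_record("ok")
        minor = make_record("minor", age_years=15)
        no_enc = make_record("no_enc", encounters=[SCAN + timedelta(days=400)])
        prior = make_record(
            "prior", codes=[Code(SCAN - timedelta(days=30), "ICD10", "I25.9")]
        )
        short_fu = make_record(
            "short_fu",
            encounters=[SCAN - timedelta(days=50), SCAN + timedelta(days=330)],
        )
        dup_a = make_record("dup", scan=SCAN)
        dup_b = make_record("dup", scan=SCAN + timedelta(days=90))
        return [ok, minor, no_enc, prior, short_fu, dup_a, dup_b]

    def test_each_rule_attributed_and_counts_conserved(self):
        records = self.build_audit_fixture()
        included, audit = apply_inclusion_filters(records, horizon_years=1)
        assert {r.patient_id for r in included} == {"ok", "dup"}
        assert audit.dropped == {
            "age_under_18": 1,
            "no_prior_year_encounter": 1,
            "prior_ihd": 1,
            "insufficient_follow_up": 1,
            "within_6_months_of_included_scan": 1,
        }
        assert audit.conserved()

    def test_scans_three_months_apart_second_dropped(self):
        a = make_record("p", scan=SCAN)
        b = make_record("p", scan=SCAN + timedelta(days=92))
        included, audit = apply_inclusion_filters([a, b])
        assert len(included) == 1 and included[0].scan_date == SCAN
        assert audit.dropped["within_6_months_of_included_scan"] == 1

    def test_positive_outcome_with_short_followup_kept(self):
        rec = make_record(
            "pos",
            codes=[Code(SCAN + timedelta(days=60), "ICD10", "I21.0")],
            encounters=[SCAN - timedelta(days=10), SCAN + timedelta(days=70)],
        )
        included, _ = apply_inclusion_filters([rec], horizon_years=1)
        assert len(included) == 1


class TestStratifiedSplit:
    def test_exact_counts_at_round_numbers(self):
        labels = np.array([1] * 25 + [0] * 75)
        train, test = stratified_split(labels, 0.2, seed=0)
        assert labels[test].sum() == 5 and len(test) == 20
        assert labels[train].sum() == 20 and len(train) == 80

    def test_deterministic_and_partition(self):
        labels = (np.random.default_rng(1).uniform(size=57) < 0.3).astype(int)
        t1 = stratified_split(labels, 0.2, seed=42)
        t2 = stratified_split(labels, 0.2, seed=42)
        assert np.array_equal(t1[0], t2[0]) and np.array_equal(t1[1], t2[1])
        assert len(set(t1[0]) | set(t1[1])) == 57

    def test_all_negative_cohort_splits_with_warning(self):
        with pytest.warns(UserWarning):
            train, test = stratified_split(np.zeros(10, int), 0.2, seed=0)
        assert len(train) == 8 and len(test) == 2

    def test_prevalence_equal_up_to_rounding_across_cohorts(self):
        rng = np.random.default_rng(9)
        for _ in range(100):
            n = int(rng.integers(40, 400))
            labels = (rng.uniform(size=n) < rng.uniform(0.1, 0.5)).astype(int)
            if labels.sum() < 2 or labels.sum() > n - 2:
                continue
            train, test = stratified_split(labels, 0.2, seed=int(rng.integers(1000)))
            expected_test_pos = round(labels.sum() * 0.2)
            assert labels[test].sum() == expected_test_pos


class TestTemporalAggregation:
    def test_single_value_and_zero_decay(self):
        t = [SCAN - timedelta(days=10)]
        assert exp_weighted_value([120.0], t, SCAN) == 120.0
        times = [SCAN - timedelta(days=d) for d in (0, 10, 40)]
        assert exp_weighted_value([1.0, 2.0, 6.0], times, SCAN, decay_per_day=0.0) == 3.0

    def test_half_life_30_days_worked_example(self):
        times = [SCAN, SCAN - timedelta(days=30)]
        got = exp_weighted_value([100.0, 200.0], times, SCAN, decay_per_day=np.log(2) / 30)
        assert got == pytest.approx((100 + 200 * 0.5) / 1.5)

    def test_bounds_and_large_decay_limit(self):
        times = [SCAN - timedelta(days=d) for d in (3, 17, 200)]
        vals = [80.0, 120.0, 300.0]
        got = exp_weighted_value(vals, times, SCAN, decay_per_day=0.05)
        assert min(vals) <= got <= max(vals)
        recent = exp_weighted_value(vals, times, SCAN, decay_per_day=1e3)
        assert recent == pytest.approx(80.0)

    def test_empty_series_is_missing_marker(self):
        assert np.isnan(exp_weighted_value([], [], SCAN))

    def test_inverse_time_scheme(self):
        times = [SCAN, SCAN - timedelta(days=1)]
        got = exp_weighted_value([10.0, 20.0], times, SCAN, scheme="inverse_time")
        assert got == pytest.approx((10 + 20 * 0.5) / 1.5)

    def test_measurement_count_windowing(self):
        times = [SCAN - timedelta(days=d) for d in (1, 100, 364, 366, 400)]
        assert measurement_count(times, SCAN) == 3
        assert measurement_count([], SCAN) == 0


TOY_ICD = OntologyMap("ICD10", {"I1": "hypertensive diseases", "E11": "diabetes"})


class TestCodeRollups:
    def test_toy_map_counts(self):
        codes = [
            Code(SCAN - timedelta(days=10), "ICD10", "I10"),
            Code(SCAN - timedelta(days=20), "ICD10", "I10"),
            Code(SCAN - timedelta(days=30), "ICD10", "E11.9"),
            Code(SCAN - timedelta(days=40), "ICD10", "Z99"),
            Code(SCAN - timedelta(days=500), "ICD10", "I10"),  # outside window
        ]
        counts, unmapped = rollup_codes(codes, [TOY_ICD], SCAN)
        assert counts == {"hypertensive diseases": 2, "diabetes": 1}
        assert unmapped == ["Z99"]

    def test_no_codes_gives_zero_counts(self):
        counts, unmapped = rollup_codes([], [TOY_ICD], SCAN)
        assert set(counts.values()) == {0} and unmapped == []

    def test_longest_prefix_wins(self):
        m = OntologyMap("ICD10", {"I2": "broad", "I21": "specific"})
        assert m.lookup("I21.4") == "specific"
        assert m.lookup("I25") == "broad"


class TestCharlson:
    def setup_method(self):
        self.cmap = load_charlson_map()

    def test_no_qualifying_codes(self):
        assert charlson_index([Code(SCAN, "ICD10", "Z00")], self.cmap) == 0

    def test_mi_plus_diabetes_is_two(self):
        codes = [
            Code(SCAN - timedelta(days=9), "ICD10", "I21.4"),
            Code(SCAN - timedelta(days=5), "ICD10", "E11.9"),
        ]
        assert charlson_index(codes, self.cmap) == 2

    def test_condition_counted_once(self):
        codes = [
            Code(SCAN - timedelta(days=9), "ICD10", "I21.4"),
            Code(SCAN - timedelta(days=3), "ICD10", "I22.0"),
        ]
        assert charlson_index(codes, self.cmap) == 1

    def test_weights_above_one(self):
        codes = [Code(SCAN, "ICD10", "N18.5"), Code(SCAN, "ICD10", "C78.0")]
        assert charlson_index(codes, self.cmap) == 2 + 6

    def test_post_scan_codes_ignored_when_anchored(self):
        codes = [Code(SCAN + timedelta(days=10), "ICD10", "I21.4")]
        assert charlson_index(codes, self.cmap, scan_time=SCAN) == 0


class TestPruneCorrelated:
    def test_duplicate_column_dropped_once(self, rng):
        x = rng.normal(size=100)
        df = pd.DataFrame({"a": x, "b": x, "c": rng.normal(size=100)})
        kept, dropped = prune_correlated(df)
        assert dropped == ["b"] and list(kept.columns) == ["a", "c"]

    def test_boundary_exactly_r_max_retained(self):
        # binary 2x2 design with phi coefficient exactly (3*3-1*1)/16 = 0.5
        a = np.array([1, 1, 1, 1, 0, 0, 0, 0], dtype=float)
        b = np.array([1, 1, 1, 0, 1, 0, 0, 0], dtype=float)
        df = pd.DataFrame({"a": a, "b": b})
        r = float(df.corr().iloc[0, 1])
        assert r == pytest.approx(0.5)
        # comparison is strictly greater-than: a pair at exactly r_max survives,
        # while any threshold below it triggers the drop
        kept, dropped = prune_correlated(df, r_max=r)
        assert dropped == [] and kept.shape[1] == 2
        kept, dropped = prune_correlated(df, r_max=r - 1e-9)
        assert dropped == ["b"]

    def test_mutually_correlated_trio_leaves_one(self, rng):
        base = rng.normal(size=200)
        df = pd.DataFrame(
            {
                "a": base + 0.1 * rng.normal(size=200),
                "b": base + 0.1 * rng.normal(size=200),
                "c": base + 0.1 * rng.normal(size=200),
            }
        )
        kept, dropped = prune_correlated(df)
        assert kept.shape[1] == 1 and len(dropped) == 2
        corr = kept.corr().abs().to_numpy()
        np.fill_diagonal(corr, 0)
        assert corr.max() <= 0.5

    def test_postcondition_recomputed_on_messy_table(self, rng):
        df = pd.DataFrame(rng.normal(size=(150, 8)), columns=list("abcdefgh"))
        df["dup1"] = df["a"] * 2 + 0.01 * rng.normal(size=150)
        df.loc[rng.uniform(size=150) < 0.1, "b"] = np.nan
        kept, _ = prune_correlated(df)
        corr = kept.corr().abs().to_numpy()
        np.fill_diagonal(corr, 0)
        assert np.nanmax(corr) <= 0.5


class TestTargetedImputation:
    def test_only_named_targets_imputed(self):
        df = pd.DataFrame({"ldl": [np.nan, 100.0], "crp": [np.nan, 1.0]})
        out = impute_targeted_median(df, ["ldl"], pd.Series({"ldl": 110.0}))
        assert out["ldl"].iloc[0] == 110.0
        assert np.isnan(out["crp"].iloc[0])

    def test_training_only_medians(self):
        df = pd.DataFrame({"ldl": [np.nan, 100.0, 200.0, 300.0]})
        train_mask = np.array([False, True, True, False])
        out = impute_targeted_median(df, ["ldl"], train_mask=train_mask)
        assert out["ldl"].iloc[0] == 150.0  # median of rows 1-2 only

    def test_all_missing_target_requires_explicit_default(self):
        df = pd.DataFrame({"ldl": [np.nan, np.nan]})
        with pytest.raises(ValueError):
            impute_targeted_median(df, ["ldl"])


class TestFeatureVector:
    def make_config(self):
        return FeatureConfig(
            vitals=("sbp",),
            labs=("glucose",),
            ontology_maps=[TOY_ICD],
            charlson_map=load_charlson_map(),
        )

    def test_demographics_only_record(self):
        rec = make_record(age_years=40)
        vec = build_feature_vector(rec, self.make_config())
        assert vec["age"] == pytest.approx(40, abs=0.01)
        assert vec["sex_male"] == 0.0
        assert np.isnan(vec["sbp"]) and vec["sbp_n_measurements"] == 0
        assert vec["diabetes"] == 0 and vec["charlson_index"] == 0

    def test_hand_computed_fixture(self):
        obs = [
            Observation(SCAN, "sbp", 130.0),
            Observation(SCAN - timedelta(days=30), "sbp", 150.0),
            Observation(SCAN - timedelta(days=5), "glucose", 99.0),
        ]
        codes = [
            Code(SCAN - timedelta(days=10), "ICD10", "I10"),
            Code(SCAN - timedelta(days=40), "ICD10", "E11.9"),
        ]
        rec = make_record(codes=codes, observations=obs, age_years=60)
        vec = build_feature_vector(rec, self.make_config())
        assert vec["sbp"] == pytest.approx((130 + 150 * 0.5) / 1.5)
        assert vec["sbp_n_measurements"] == 2
        assert vec["glucose"] == 99.0
        assert vec["hypertensive diseases"] == 1
        assert vec["diabetes"] == 1
        assert vec["charlson_index"] == 1  # uncomplicated diabetes

    def test_same_day_reordering_is_invariant(self):
        obs = [
            Observation(SCAN, "glucose", 90.0),
            Observation(SCAN, "glucose", 110.0),
        ]
        r1 = make_record(observations=obs)
        r2 = make_record(observations=obs[::-1])
        cfg = self.make_config()
        pd.testing.assert_series_equal(
            build_feature_vector(r1, cfg), build_feature_vector(r2, cfg)
        )

    def test_pure_function_repeated_calls_identical(self):
        rec = make_record(observations=[Observation(SCAN, "sbp", 120.0)])
        cfg = self.make_config()
        pd.testing.assert_series_equal(
            build_feature_vector(rec, cfg), build_feature_vector(rec, cfg)
        )
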