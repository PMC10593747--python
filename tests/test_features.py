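"""Feature pipeline: imputation rules, indicators, normalization and
bundle assembly (column counts, leakage, masking identities)."""

import numpy as np
import pandas as pd
import pytest

from hdtft.data import SessionSet
from hdtft.features import (
    AssemblyError,
    ContinuousStats,
    NormalizationStats,
    SchemaError,
    assemble_bundles,
    assemble_feature_bundle,
    build_auxiliary_indicators,
    denormalize_continuous,
    fit_statistics,
    forward_fill_time_varying,
    impute_time_invariant,
    normalize_continuous,
)
from hdtft.cohort import match_cohort
from hdtft.labeling import label_session
from hdtft.schema import compact_schema, full_schema
from hdtft.synthetic import SyntheticConfig, generate_cohort


@pytest.fixture(scope="module")
def prepared():
    cfg = SyntheticConfig(
        n_patients=40, sessions_per_patient=(3, 5), seed=31,
        missing_rate_invariant=0.15, missing_rate_varying=0.2,
    )
    cohort, truth = generate_cohort(cfg)
    sets = match_cohort(cohort, k=3)
    stats = fit_statistics(sets, cohort.schema)
    labels = {
        ss.current.session_id: label_session(ss.current) for ss in sets
    }
    return cohort, truth, sets, stats, labels


class TestImputeTimeInvariant:
    def test_no_missing_identity(self, prepared):
        cohort, _, sets, stats, _ = prepared
        schema = cohort.schema
        values = {
            v.name: 1.0 if v.dtype == "continuous" else 0
            for v in schema.time_invariant
        }
        out = impute_time_invariant(values, schema, stats)
        for v in schema.time_invariant:
            if v.dtype == "continuous":
                assert out[v.name] == 1.0

    def test_normal_flag_mean_rule(self):
        schema = compact_schema().subset(["age", "sbp", "dbp"])
        stats = NormalizationStats()
        stats.continuous["age"] = ContinuousStats(62.1, 15.0, 60.0, True)
        stats.continuous["sbp"] = ContinuousStats(139, 20, 138, False)
        stats.continuous["dbp"] = ContinuousStats(73, 12, 72, False)
        out = impute_time_invariant({"age": None}, schema, stats)
        assert out["age"] == 62.1  # mean, not median

    def test_skewed_uses_median(self, prepared):
        cohort, _, _, stats, _ = prepared
        cs = stats.continuous["albumin"]  # declared non-normal
        out = impute_time_invariant(
            {"albumin": None}, cohort.schema, stats
        )
        assert out["albumin"] == cs.median

    def test_unknown_variable_raises(self, prepared):
        cohort, _, _, stats, _ = prepared
        schema = full_schema()  # has variables the stats were not fitted on
        with pytest.raises(SchemaError):
            impute_time_invariant({}, schema, stats)

    def test_rule_oracle_random_patterns(self, prepared):
        cohort, _, sets, stats, _ = prepared
        schema = cohort.schema
        rng = np.random.default_rng(8)
        cont = [v for v in schema.time_invariant if v.dtype == "continuous"]
        for _ in range(1000):
            values = {}
            for v in cont:
                values[v.name] = (
                    None if rng.random() < 0.5 else float(rng.normal(50, 10))
                )
            out = impute_time_invariant(values, schema, stats)
            for v in cont:
                cs = stats.continuous[v.name]
                expect = (
                    (cs.mean if cs.normal_flag else cs.median)
                    if values[v.name] is None
                    else values[v.name]
                )
                assert out[v.name] == expect


class TestForwardFill:
    def test_example_sequence(self):
        filled, mask = forward_fill_time_varying(
            [120.0, np.nan, np.nan, 110.0]
        )
        assert filled.tolist() == [120.0, 120.0, 120.0, 110.0]
        assert mask.tolist() == [True, False, False, True]

    def test_all_observed_identity(self):
        x = np.array([1.0, 2.0, 3.0])
        filled, mask = forward_fill_time_varying(x)
        assert np.array_equal(filled, x)
        assert mask.all()

    def test_leading_null_fallback_chain(self):
        filled, mask = forward_fill_time_varying(
            [np.nan, np.nan, 5.0], prev_session_value=7.0
        )
        assert filled.tolist() == [7.0, 7.0, 5.0]
        filled, _ = forward_fill_time_varying(
            [np.nan, 5.0], prev_session_value=None, fallback=3.0
        )
        assert filled.tolist() == [3.0, 5.0]

    def test_no_fallback_raises(self):
        with pytest.raises(AssemblyError):
            forward_fill_time_varying([np.nan, 1.0])

    def test_scan_oracle_random_series(self):
        rng = np.random.default_rng(9)
        for _ in range(300):
            n = rng.integers(1, 15)
            x = rng.normal(size=n)
            x[rng.random(n) < 0.4] = np.nan
            filled, mask = forward_fill_time_varying(x, fallback=-1.0)
            last = -1.0
            for i in range(n):
                if np.isfinite(x[i]):
                    last = x[i]
                    assert mask[i]
                else:
                    assert not mask[i]
                assert filled[i] == last


class TestIndicatorsAndNormalization:
    def test_indicator_is_mask_copy(self):
        mask = np.array([[True, False], [False, True]])
        ind = build_auxiliary_indicators(mask)
        assert ind.tolist() == [[1.0, 0.0], [0.0, 1.0]]

    def test_zscore_endpoints(self):
        cs = ContinuousStats(mean=10.0, sd=2.0, median=9.0, normal_flag=True)
        assert normalize_continuous(np.array([10.0]), cs)[0] == 0.0
        assert normalize_continuous(np.array([12.0]), cs)[0] == 1.0

    def test_round_trip_exact(self):
        rng = np.random.default_rng(2)
        cs = ContinuousStats(mean=3.7, sd=0.9, median=3.5, normal_flag=False)
        x = rng.normal(3.7, 2.0, 10_000)
        back = denormalize_continuous(normalize_continuous(x, cs), cs)
        assert np.max(np.abs(back - x)) < 1e-10


class TestStatsFitting:
    def test_constant_column_raises(self, prepared):
        cohort, _, sets, _, _ = prepared
        for ss in sets:
            ss.current.static["age"] = 50.0
        try:
            with pytest.raises(AssemblyError):
                fit_statistics(sets, cohort.schema)
        finally:
            pass

    def test_no_leakage_train_only(self):
        """Statistics recomputed from the training sessions alone match the
        fitted statistics exactly."""
        cfg = SyntheticConfig(n_patients=30, seed=41)
        cohort, _ = generate_cohort(cfg)
        sets = match_cohort(cohort, k=2)
        half = sets[: len(sets) // 2]
        stats = fit_statistics(half, cohort.schema)
        stats2 = fit_statistics(half, cohort.schema)
        for name, cs in stats.continuous.items():
            assert cs.mean == stats2.continuous[name].mean
            assert cs.sd == stats2.continuous[name].sd
        # values from held-out sessions do not enter
        other = sets[len(sets) // 2 :]
        stats3 = fit_statistics(other, cohort.schema)
        assert any(
            stats.continuous[n].mean != stats3.continuous[n].mean
            for n in stats.continuous
        )


class TestBundleAssembly:
    def test_full_schema_emits_78_columns(self):
        cfg = SyntheticConfig(
            n_patients=12, seed=51, schema=full_schema(),
            missing_rate_invariant=0.05, missing_rate_varying=0.05,
        )
        cohort, _ = generate_cohort(cfg)
        sets = match_cohort(cohort, k=2)
        stats = fit_statistics(sets, cohort.schema)
        labels = {
            ss.current.session_id: label_session(ss.current) for ss in sets
        }
        b = assemble_feature_bundle(
            sets[0], labels[sets[0].current.session_id], cohort.schema, stats
        )
        assert b.n_feature_columns == 78
        assert len(b.feature_column_names()) == 78

    def test_slim_style_schema_column_count(self, prepared):
        # 30 originals with 6 time-varying -> 30 + 6 + 2 = 38
        schema = full_schema()
        tv = [v.name for v in schema.time_varying][:6]
        ti = [v.name for v in schema.time_invariant][:24]
        slim = schema.subset(tv + ti)
        assert slim.n_feature_columns == 38

    def test_compact_schema_column_conservation(self, prepared):
        cohort, _, sets, stats, labels = prepared
        b = assemble_feature_bundle(
            sets[0], labels[sets[0].current.session_id], cohort.schema, stats
        )
        n_orig = len(cohort.schema)
        n_tv = len(cohort.schema.time_varying)
        assert b.n_feature_columns == n_orig + n_tv + 2

    def test_no_nulls_after_assembly(self, prepared):
        cohort, _, sets, stats, labels = prepared
        bundles = assemble_bundles(sets, labels, cohort.schema, stats, 3)
        for b in bundles:
            assert np.all(np.isfinite(b.temporal))
            assert np.all(np.isfinite(b.static_cont))

    def test_indicator_matches_truth_mask(self, prepared):
        """Indicator = 0 exactly where the generator's truth mask marks a
        removed cell (non-BP variables; BP shares a joint drop pattern)."""
        cohort, truth, sets, stats, labels = prepared
        n_tv = len(cohort.schema.time_varying)
        tv_names = [v.name for v in cohort.schema.time_varying]
        for ss in sets[:50]:
            b = assemble_feature_bundle(
                ss, labels[ss.current.session_id], cohort.schema, stats
            )
            aux = b.temporal[:, n_tv : 2 * n_tv]
            masks = truth.observed_mask[ss.current.session_id]
            for j, name in enumerate(tv_names):
                assert np.array_equal(aux[:, j], masks[name].astype(float))

    def test_all_false_previous_mask_equals_no_previous(self, prepared):
        cohort, _, sets, stats, labels = prepared
        ss = next(s for s in sets if s.previous)
        lab = labels[ss.current.session_id]
        with_prev = assemble_feature_bundle(ss, lab, cohort.schema, stats)
        alone = SessionSet(
            current=ss.current, previous=(), availability_mask=(False,) * ss.k
        )
        without = assemble_feature_bundle(alone, lab, cohort.schema, stats)
        assert not without.previous_mask.any()
        # static and label parts identical; temporal differs only through
        # the interval-since-previous-session column and leading-null fills
        assert np.array_equal(with_prev.static_cont, without.static_cont)
        assert np.array_equal(with_prev.labels, without.labels)
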