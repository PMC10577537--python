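"""Intersection, restriction, training and prediction of the clock ensemble."""

import numpy as np
import pandas as pd
import pytest

import isectclock as ic
from isectclock import ClockConfig, ClockConfigError, CpGCoordinate, DegenerateTrainingError
from isectclock.clock_core import predict_sample


def _table(sites, values, ages, ids=None):
    idx = pd.MultiIndex.from_tuples(sites, names=["chrom", "pos"])
    ids = ids or [f"s{i:02d}" for i in range(len(ages))]
    return ic.FeatureTable(sample_ids=ids, ages=np.asarray(ages, float),
                           sites=idx, values=np.asarray(values, float))


def _cs(sites, sample_id="t"):
    return ic.MethylationCallSet.from_arrays(
        sample_id, [c for c, _ in sites], [p for _, p in sites],
        [5] * len(sites), [5] * len(sites),
    )


class TestIntersectSites:
    def test_simple_overlap(self):
        table = _table([("chr1", 1 + 2 * i) for i in range(3)],
                       [[50.0] * 3] * 2, [10, 20])
        test = _cs([("chr1", 3), ("chr1", 5), ("chr1", 7)])
        res = ic.intersect_sites(table, test)
        assert res.n_sites == 2
        assert res.site_list() == [CpGCoordinate("chr1", 3), CpGCoordinate("chr1", 5)]

    def test_disjoint_is_empty(self):
        table = _table([("chr1", 1)], [[50.0]] * 2, [10, 20])
        res = ic.intersect_sites(table, _cs([("chr2", 1)]))
        assert res.n_sites == 0

    def test_assembly_mismatch(self):
        table = _table([("chr1", 1)], [[50.0]] * 2, [10, 20])
        test = _cs([("chr1", 1)])
        test.assembly = "hg19"
        with pytest.raises(ClockConfigError, match="assembly"):
            ic.intersect_sites(table, test)

    def test_matches_brute_force_on_random_subsets(self, small_spec, small_table):
        rng = np.random.default_rng(42)
        training_set = set(small_table.site_list())
        for rep in range(20):
            k = int(0.6 * small_spec.n_sites)
            chosen = rng.choice(small_spec.n_sites, k, replace=False)
            positions = small_spec.start_pos + small_spec.spacing * np.sort(chosen)
            test = _cs([("chr1", int(p)) for p in positions], sample_id=f"f{rep}")
            res = ic.intersect_sites(small_table, test)
            brute = {s for s in test.coordinate_set() if s in training_set}
            assert res.n_sites == len(brute)
            assert set(res.site_list()) == brute


class TestRestrict:
    def test_all_sites_is_identity(self, small_table):
        out = ic.restrict(small_table, small_table.sites)
        np.testing.assert_array_equal(out.values, small_table.values)
        assert list(out.sites) == list(small_table.sites)

    def test_single_site(self, small_table):
        out = ic.restrict(small_table, small_table.sites[:1])
        assert out.n_sites == 1
        np.testing.assert_array_equal(out.ages, small_table.ages)

    def test_elementwise_against_original(self, small_table):
        rng = np.random.default_rng(1)
        cols = np.sort(rng.choice(small_table.n_sites, 40, replace=False))
        out = ic.restrict(small_table, small_table.sites[cols])
        np.testing.assert_array_equal(out.values, small_table.values[:, cols])

    def test_absent_site_raises(self, small_table):
        with pytest.raises(ClockConfigError, match="not present"):
            ic.restrict(small_table, [("chrZ", 1)])


class TestTrainOneClock:
    def test_noiseless_single_site_recovery(self):
        # age is an exact affine function of one site: held-out predictions
        # should match true ages up to the small elastic-net shrinkage
        ages = np.linspace(5, 44, 40)
        rng = np.random.default_rng(0)
        values = np.column_stack([10 + 2.0 * ages, rng.uniform(30, 70, (40, 4))])
        table = _table([("chr1", 100 + 10 * i) for i in range(5)], values, ages)
        fold = np.tile(np.arange(1, 6), 8)
        cfg = ClockConfig(rng_seed=1, min_intersection=1)
        model, hold_pred, hold_idx = ic.train_one_clock(table, cfg, fold, 1)
        assert np.abs(hold_pred - ages[hold_idx]).max() < 0.5
        assert model.fold_id == 1
        assert model.lambda_ > 0

    def test_constant_ages_degenerate(self, small_table):
        table = ic.FeatureTable(
            sample_ids=small_table.sample_ids,
            ages=np.full(small_table.n_samples, 33.0),
            sites=small_table.sites,
            values=small_table.values,
        )
        fold = np.tile(np.arange(1, 6), small_table.n_samples // 5)
        with pytest.raises(DegenerateTrainingError, match="identical"):
            ic.train_one_clock(table, ClockConfig(min_intersection=1), fold, 1)

    def test_too_few_samples_for_inner_cv(self):
        ages = np.arange(6, dtype=float)
        table = _table([("chr1", 100)], ages.reshape(-1, 1) * 10, ages)
        fold = np.array([1, 1, 1, 2, 2, 2])
        with pytest.raises(DegenerateTrainingError, match="inner CV"):
            ic.train_one_clock(table, ClockConfig(min_intersection=1), fold, 2)

    def test_weights_on_original_percent_scale(self):
        # model.predict_vector on raw percentages must equal the holdout path
        ages = np.linspace(5, 44, 40)
        rng = np.random.default_rng(2)
        values = np.clip(np.column_stack(
            [20 + 1.5 * ages + rng.normal(0, 1, 40) for _ in range(6)]
        ), 0, 100)
        table = _table([("chr1", 100 + 10 * i) for i in range(6)], values, ages)
        fold = np.tile(np.arange(1, 6), 8)
        model, hold_pred, hold_idx = ic.train_one_clock(
            table, ClockConfig(rng_seed=3, min_intersection=1), fold, 2
        )
        for k, i in enumerate(hold_idx):
            assert model.predict_vector(values[i]) == pytest.approx(hold_pred[k], abs=1e-9)


class TestPredictSample:
    def test_below_threshold_not_admitted(self, small_table, small_spec):
        test = ic.generate_test_sample(small_spec, 20.0, 0.1, "tiny", seed=1, min_depth=5)
        res = predict_sample(small_table, test, ClockConfig(min_intersection=50, rng_seed=0))
        assert not res.admitted
        assert res.fold_predictions is None
        assert np.isnan(res.predicted_age)

    def test_empty_intersection_not_an_exception(self, small_table):
        test = _cs([("chr9", 1)])
        res = predict_sample(small_table, test, ClockConfig(rng_seed=0))
        assert not res.admitted and res.n_intersected_sites == 0

    def test_predicted_age_is_mean_of_folds(self, small_table, small_spec, small_config):
        test = ic.generate_test_sample(small_spec, 18.0, 1.0, "m", seed=2, min_depth=5)
        res = predict_sample(small_table, test, small_config)
        assert res.admitted
        assert len(res.fold_predictions) == small_config.outer_folds
        assert res.predicted_age == float(np.mean(res.fold_predictions))

    def test_monotone_admission(self, small_table, small_spec):
        test = ic.generate_test_sample(small_spec, 18.0, 0.5, "adm", seed=3, min_depth=5)
        n = ic.intersect_sites(small_table, test).n_sites
        admitted_at = predict_sample(
            small_table, test, ClockConfig(min_intersection=n, rng_seed=1)
        ).admitted
        lower = predict_sample(
            small_table, test, ClockConfig(min_intersection=max(1, n - 30), rng_seed=1)
        ).admitted
        assert admitted_at and lower  # lowering the threshold keeps admission

    def test_models_only_use_intersected_sites(self, small_table, small_spec, small_config):
        # no imputation: every clock is defined exactly on the intersection
        test = ic.generate_test_sample(small_spec, 25.0, 0.6, "sub", seed=4, min_depth=5)
        inter = ic.intersect_sites(small_table, test)
        res = predict_sample(small_table, test, small_config, keep_models=True)
        for model in res.models:
            assert list(model.sites) == list(inter.sites)
            assert set(model.weights) <= set(inter.site_list())

    def test_missingness_robustness(self, small_spec, small_table, small_config):
        # dropping coverage from 100% to 30% of sites changes the prediction
        # only boundedly; the clock retrains rather than imputing
        full = ic.generate_test_sample(small_spec, 22.0, 1.0, "cov100", seed=5, min_depth=5)
        part = ic.generate_test_sample(small_spec, 22.0, 0.3, "cov30", seed=5, min_depth=5)
        r_full = predict_sample(small_table, full, small_config)
        r_part = predict_sample(small_table, part, small_config)
        assert r_full.admitted and r_part.admitted
        assert abs(r_full.predicted_age - r_part.predicted_age) < 8.0

    def test_cv_metrics_pooled_over_all_training_samples(
        self, small_table, small_spec, small_config
    ):
        test = ic.generate_test_sample(small_spec, 18.0, 1.0, "cv", seed=6, min_depth=5)
        res = predict_sample(small_table, test, small_config)
        assert -1.0 <= res.cv_r <= 1.0
        assert res.cv_medae >= 0.0


class TestPredictCohort:
    def test_identical_callsets_identical_results(self, small_table, small_spec, small_config):
        t1 = ic.generate_test_sample(small_spec, 30.0, 0.9, "twin", seed=7, min_depth=5)
        t2 = ic.MethylationCallSet(sample_id="twin", data=t1.data.copy(),
                                   assembly=t1.assembly)
        r1, r2 = ic.predict_cohort(small_table, [t1, t2], small_config)
        assert r1.fold_predictions == r2.fold_predictions
        assert r1.predicted_age == r2.predicted_age

    def test_admission_flagging_in_cohort(self, small_table, small_spec, small_config):
        tests = [
            ic.generate_test_sample(small_spec, 20.0, 1.0, "a", seed=8, min_depth=5),
            ic.generate_test_sample(small_spec, 20.0, 1.0, "b", seed=9, min_depth=5),
            ic.generate_test_sample(small_spec, 20.0, 0.05, "c", seed=10, min_depth=5),
        ]
        results = ic.predict_cohort(small_table, tests, small_config)
        assert [r.admitted for r in results] == [True, True, False]
        assert [r.test_sample_id for r in results] == ["a", "b", "c"]

    def test_cohort_order_invariance(self, small_table, small_spec, small_config):
        tests = [
            ic.generate_test_sample(small_spec, age, 0.9, f"s{k}", seed=20 + k, min_depth=5)
            for k, age in enumerate([10.0, 25.0, 38.0])
        ]
        fwd = {r.test_sample_id: r for r in ic.predict_cohort(small_table, tests, small_config)}
        rev = {r.test_sample_id: r for r in
               ic.predict_cohort(small_table, tests[::-1], small_config)}
        for sid in fwd:
            assert fwd[sid].fold_predictions == rev[sid].fold_predictions
            assert fwd[sid].predicted_age == rev[sid].predicted_age

    def test_error_carries_sample_id(self, small_table):
        bad = _cs([("chr1", 1000)], sample_id="broken")
        bad.assembly = "hg19"
        with pytest.raises(ClockConfigError, match="broken"):
            ic.predict_cohort(small_table, [bad], ClockConfig(rng_seed=0))


def test_noise_degrades_cv_performance_monotonically():
    """Pooled out-of-fold r should fall as biological noise grows (10 seeds)."""
    r_low, r_high = [], []
    for seed in range(10):
        results = {}
        for noise in (1.0, 15.0):
            spec = ic.GeneratorSpec(
                n_samples=40, n_sites=250, n_informative=60, noise_sd=noise,
                rng_seed=100 + seed,
            )
            table = ic.training_feature_table(spec)
            test = ic.generate_test_sample(spec, 20.0, 1.0, "probe", seed=seed, min_depth=5)
            res = predict_sample(table, test, ClockConfig(min_intersection=50, rng_seed=seed))
            results[noise] = res.cv_r
        r_low.append(results[1.0])
        r_high.append(results[15.0])
    wins = sum(lo > hi for lo, hi in zip(r_low, r_high))
    assert wins >= 9
    assert np.mean(r_low) > np.mean(r_high)


def test_config_validation():
    with pytest.raises(ClockConfigError):
        ClockConfig(alpha=1.5)
    with pytest.raises(ClockConfigError):
        ClockConfig(outer_folds=1)
    with pytest.raises(ClockConfigError):
        ClockConfig(min_intersection=0)


def test_write_predictions_tsv(small_table, small_spec, small_config, tmp_path):
    tests = [
        ic.generate_test_sample(small_spec, 20.0, 1.0, "w1", seed=30, min_depth=5),
        ic.generate_test_sample(small_spec, 20.0, 0.05, "w2", seed=31, min_depth=5),
    ]
    results = ic.predict_cohort(small_table, tests, small_config)
    out = tmp_path / "pred.tsv"
    ic.write_predictions_tsv(results, out, labels={"w1": "g1", "w2": "g2"})
    df = pd.read_csv(out, sep="\t")
    assert list(df["sample_id"]) == ["w1", "w2"]
    assert list(df["admitted"]) == [True, False]
    assert df.loc[0, "predicted_age"] == results[0].predicted_age
    assert {"fold_pred_1", "fold_pred_5", "cv_r", "cv_medae"} <= set(df.columns)
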