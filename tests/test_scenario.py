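import numpy as np
import pytest

import fireglm as fg
from fireglm.predictors import (
    CLIMATE_PREDICTORS,
    CONSTANT_PREDICTORS,
    HUMAN_PREDICTORS,
    VEGETATION_PREDICTORS,
)
from fireglm.scenario import (
    EXPERIMENT_LABELS,
    ExperimentSpec,
    apply_anomaly,
    build_experiment_matrix,
    compute_anomaly,
    fit_road_model,
    project_road_density,
    summarise_climatology,
)
from fireglm.synthetic import generate_scenario, monthly_climatology


@pytest.fixture(scope="module")
def bundle(dataset):
    return generate_scenario(
        dataset.predictors,
        {"DD": 2.0, "VPD": 0.5, "tas": 2.5, "popd": 3.0, "crop": 0.04,
         "roads": 0.05},
        seed=11)


class TestAnomalies:
    def test_identical_climatologies_give_zero_delta(self, bundle):
        gcm = bundle.gcms[0]
        delta = compute_anomaly(bundle.picontrol[gcm], bundle.picontrol[gcm])
        for arr in delta.values():
            np.testing.assert_array_equal(arr, 0.0)

    def test_round_trip_is_bit_exact(self, bundle):
        base = bundle.baseline_monthly
        delta = compute_anomaly(base, base)
        out = apply_anomaly(base, delta)
        for var in base:
            np.testing.assert_array_equal(out[var], base[var])

    def test_constant_shift_recovered(self, bundle):
        base = bundle.baseline_monthly
        shifted = {var: arr + 2.0 for var, arr in base.items()}
        delta = compute_anomaly(base, shifted)
        for arr in delta.values():
            np.testing.assert_allclose(arr, 2.0)

    def test_month_mismatch_rejected(self, bundle):
        base = bundle.baseline_monthly
        broken = {var: arr[:6] for var, arr in base.items()}
        with pytest.raises(ValueError, match="mismatch"):
            compute_anomaly(base, broken)

    def test_clip_rules_bound_dry_days_and_vpd(self, bundle):
        base = bundle.baseline_monthly
        delta = {"DD": np.full_like(base["DD"], 40.0),
                 "VPD": np.full_like(base["VPD"], -50.0)}
        out = apply_anomaly(base, delta)
        assert out["DD"][0].max() <= 31.0   # January cap
        assert out["DD"][1].max() <= 28.0   # February cap
        assert out["VPD"].min() == 0.0

    def test_missing_clip_rule_is_an_error(self):
        with pytest.raises(ValueError, match="clip rule"):
            apply_anomaly({"unknown_var": np.zeros((12, 2, 2))},
                          {"unknown_var": np.ones((12, 2, 2))})

    def test_clipping_never_moves_in_bounds_values(self, bundle):
        base = bundle.baseline_monthly
        tiny = {var: np.full_like(arr, 1e-6) for var, arr in base.items()}
        out = apply_anomaly(base, tiny)
        for var in base:
            np.testing.assert_allclose(out[var], base[var] + 1e-6, rtol=1e-12)


class TestSummariseClimatology:
    def test_constant_fields_return_constant_and_zero_seasonality(self):
        monthly = {var: np.full((12, 3, 4), 5.0)
                   for var in ("DD", "VPD", "DTR", "wind", "tas", "light")}
        out = summarise_climatology(monthly)
        np.testing.assert_allclose(out["DD"], 5.0)
        np.testing.assert_allclose(out["DD_s"], 0.0)
        np.testing.assert_allclose(out["VPD"], 5.0)
        np.testing.assert_allclose(out["light"], 5.0)

    def test_single_peak_vpd_selects_peak_month(self):
        monthly = {var: np.full((12, 1, 1), 1.0)
                   for var in ("DD", "VPD", "DTR", "wind", "tas")}
        vpd = np.full((12, 1, 1), 1.0)
        vpd[6] = 3.7  # July spike
        monthly["VPD"] = vpd
        out = summarise_climatology(monthly)
        assert out["VPD"][0, 0] == 3.7

    def test_wind_taken_from_hottest_month(self):
        monthly = {var: np.full((12, 1, 1), 1.0)
                   for var in ("DD", "VPD", "DTR", "wind", "tas")}
        monthly["tas"] = np.arange(12, dtype=float).reshape(12, 1, 1)
        monthly["wind"] = np.arange(12, dtype=float).reshape(12, 1, 1) * 0.5
        out = summarise_climatology(monthly)
        assert out["wind"][0, 0] == 11 * 0.5

    def test_dry_day_seasonality_hand_computed(self):
        dd_months = np.array([10.0, 20, 30, 10, 20, 30, 10, 20, 30, 10, 20, 30])
        monthly = {var: np.full((12, 1, 1), 1.0)
                   for var in ("DD", "VPD", "DTR", "wind", "tas")}
        monthly["DD"] = dd_months.reshape(12, 1, 1)
        out = summarise_climatology(monthly)
        assert out["DD"][0, 0] == pytest.approx(20.0)
        assert out["DD_s"][0, 0] == pytest.approx((30 - 10) / 20.0)

    def test_fewer_than_twelve_months_rejected(self):
        monthly = {var: np.full((6, 1, 1), 1.0)
                   for var in ("DD", "VPD", "DTR", "wind", "tas")}
        with pytest.raises(ValueError, match="12 months|fewer"):
            summarise_climatology(monthly)

    def test_baseline_monthly_reproduces_predictor_layers(self, dataset):
        # the synthetic seasonal cycles are built to summarise back exactly
        monthly = monthly_climatology(dataset.predictors)
        out = summarise_climatology(monthly)
        for name in ("DD", "DD_s", "VPD", "DTR", "wind"):
            np.testing.assert_allclose(out[name], dataset.predictors[name],
                                       rtol=1e-10, err_msg=name)


class TestExperimentMatrix:
    def test_emits_exactly_forty_unique_experiments(self, bundle):
        experiments = build_experiment_matrix(bundle)
        assert len(experiments) == 40
        keys = {spec.key for spec, _ in experiments}
        assert len(keys) == 40

    def test_held_constant_groups_bit_identical_to_baseline(self, bundle):
        base = bundle.baseline
        groups = {"climate": CLIMATE_PREDICTORS + VEGETATION_PREDICTORS,
                  "co2": VEGETATION_PREDICTORS,
                  "human": HUMAN_PREDICTORS}
        for spec, fld in build_experiment_matrix(bundle):
            frozen = set(CONSTANT_PREDICTORS)
            for factor, names in groups.items():
                if factor not in spec.vary:
                    frozen.update(names)
            # vegetation varies with either climate or co2
            if {"climate", "co2"} & spec.vary:
                frozen -= set(VEGETATION_PREDICTORS)
            for name in frozen:
                np.testing.assert_array_equal(fld[name], base[name], err_msg=name)

    def test_climate_co2_differs_from_climate_only_in_vegetation_only(self, bundle):
        experiments = dict((spec.key, fld)
                           for spec, fld in build_experiment_matrix(bundle))
        a = experiments[("climate_only", "rcp60", bundle.gcms[0])]
        b = experiments[("climate_co2", "rcp60", bundle.gcms[0])]
        differing = [name for name in a.data
                     if not np.array_equal(a[name], b[name])]
        assert set(differing) <= set(VEGETATION_PREDICTORS)
        assert differing  # CO2 fertilisation does change vegetation

    def test_incomplete_bundle_names_missing_members(self, bundle):
        import copy
        broken = copy.copy(bundle)
        broken.picontrol = {g: v for g, v in bundle.picontrol.items()
                            if g != bundle.gcms[0]}
        with pytest.raises(ValueError, match=bundle.gcms[0]):
            build_experiment_matrix(broken)

    def test_label_vary_consistency_enforced(self):
        with pytest.raises(ValueError, match="requires vary"):
            ExperimentSpec("realistic", "rcp26", "GFDL-ESM2M",
                           vary=frozenset({"climate"}))

    def test_all_labels_cover_design(self):
        assert set(EXPERIMENT_LABELS) == {
            "realistic", "climate_only", "co2_only", "climate_co2", "human_only"}


class TestRoadDensity:
    def test_noiseless_linear_data_recovered_to_machine_precision(self):
        rng = np.random.default_rng(4)
        n = 300
        popd = rng.gamma(2, 20, n)
        area = rng.uniform(2000.0, 3000.0, n)
        oecd = (rng.random(n) > 0.5).astype(float)
        gpc = rng.gamma(3, 5, n)
        gdp_total = gpc * popd * area
        truth = np.array([0.3, 0.002, 0.01, 0.4, 1e-5])
        roads = truth[0] + truth[1] * popd + truth[2] * gpc + truth[3] * oecd \
            + truth[4] * area
        model = fit_road_model(popd, gdp_total, oecd, area, roads)
        np.testing.assert_allclose(model.coefficients, truth, rtol=1e-6)
        pred = project_road_density(popd, gdp_total, oecd, area, model.coefficients)
        np.testing.assert_allclose(pred, roads, rtol=1e-6)

    def test_area_linearity_probe(self):
        coefs = np.array([0.0, 0.0, 0.0, 0.0, 2.0])
        popd = np.array([10.0])
        gdp = np.array([1000.0])
        oecd = np.array([0.0])
        p1 = project_road_density(popd, gdp, oecd, np.array([100.0]), coefs)
        p2 = project_road_density(popd, gdp, oecd, np.array([200.0]), coefs)
        # doubling area changes the prediction by beta_area * area
        assert p2[0] - p1[0] == pytest.approx(2.0 * 100.0)

    def test_zero_population_cells_get_median_gdp_per_capita(self, caplog):
        popd = np.array([0.0, 10.0, 20.0])
        gdp = np.array([500.0, 1000.0, 4000.0])
        area = np.full(3, 100.0)
        with caplog.at_level("WARNING"):
            pred = project_road_density(popd, gdp, np.zeros(3), area,
                                        np.array([0.0, 0.0, 1.0, 0.0, 0.0]))
        assert "zero-population" in caplog.text
        gpc_valid = np.array([1000.0 / 1000.0, 4000.0 / 2000.0])
        assert pred[0] == pytest.approx(np.median(gpc_valid))

    def test_predictions_clamped_nonnegative(self):
        coefs = np.array([-10.0, 0.0, 0.0, 0.0, 0.0])
        pred = project_road_density(np.array([1.0]), np.array([1.0]),
                                    np.array([0.0]), np.array([1.0]), coefs)
        assert pred[0] == 0.0


class TestApplyHumanAnomaly:
    def test_identity_when_simulations_agree(self, dataset):
        base = {n: dataset.predictors[n] for n in HUMAN_PREDICTORS}
        out = fg.apply_human_anomaly(base, base, base)
        for name in HUMAN_PREDICTORS:
            np.testing.assert_array_equal(out[name], base[name])

    def test_cropland_clipped_at_one(self):
        base = {"crop": np.array([[0.95]])}
        modern = {"crop": np.array([[0.5]])}
        future = {"crop": np.array([[0.6]])}
        out = fg.apply_human_anomaly(base, modern, future)
        assert out["crop"][0, 0] == 1.0

    def test_anomaly_additivity(self):
        base = {"popd": np.array([[10.0]])}
        modern = {"popd": np.array([[8.0]])}
        mid = {"popd": np.array([[9.0]])}
        future = {"popd": np.array([[12.0]])}
        step1 = fg.apply_human_anomaly(base, modern, mid)
        step2 = fg.apply_human_anomaly(step1, mid, future)
        joint = fg.apply_human_anomaly(base, modern, future)
        np.testing.assert_allclose(step2["popd"], joint["popd"])
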