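"""End-to-end habitat pipeline, occurrence surfaces and co-occurrence models."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from felidniche.glm import fit_logistic
from felidniche.habitat import (MultiScaleHabitatModel, OccurrenceSurface,
                                compare_surfaces, prey_cooccurrence_model,
                                run_habitat_pipeline, univariate_association)
from felidniche.rasters import Raster
from felidniche.synthetic import (CovariateSpec, SyntheticConfig,
                                  generate_covariate_stack, place_stations,
                                  simulate_detections)

SCALES = (240.0, 960.0, 3840.0)


def _pipeline_setup(seed, n_stations=300, betas=None, extra_noise=0):
    specs = [CovariateSpec("v1", autocorrelation_range=480.0),
             CovariateSpec("v2", autocorrelation_range=960.0)]
    specs += [CovariateSpec(f"n{i}", autocorrelation_range=480.0)
              for i in range(extra_noise)]
    cfg = SyntheticConfig(
        extent_cells=64, cell_size=120.0, covariate_specs=specs,
        n_stations=n_stations, n_clusters=6,
        true_scales={"v1": 960.0, "v2": 960.0},
        true_beta=betas or {"intercept": -0.4, "effort": 0.004,
                            "v1": 1.0, "v2": -0.8},
    )
    stack = generate_covariate_stack(cfg, seed)
    stations = place_stations(cfg, seed + 1)
    det = simulate_detections(stack, stations, cfg, seed + 2)
    matrix = pd.DataFrame({"felid": det["count"].to_numpy()},
                          index=pd.Index(stations["station_id"], name="station_id"))
    return cfg, stack, stations, matrix


class TestHabitatPipeline:
    def test_recovers_generating_covariates(self):
        hits_v1 = hits_v2 = 0
        reps = 20
        for r in range(reps):
            cfg, stack, stations, matrix = _pipeline_setup(3000 + 10 * r,
                                                           extra_noise=2)
            res = run_habitat_pipeline("felid", stack, stations, matrix,
                                       scales=SCALES)
            avg = res.ensemble.averaged
            hits_v1 += "v1" in avg and avg["v1"].importance > 0.5
            hits_v2 += "v2" in avg and avg["v2"].importance > 0.5
        assert hits_v1 >= int(0.8 * reps)
        assert hits_v2 >= int(0.8 * reps)

    def test_deterministic_given_inputs(self):
        cfg, stack, stations, matrix = _pipeline_setup(77)
        r1 = run_habitat_pipeline("felid", stack, stations, matrix, scales=SCALES)
        r2 = run_habitat_pipeline("felid", stack, stations, matrix, scales=SCALES)
        pd.testing.assert_frame_equal(r1.summary(), r2.summary())

    def test_null_covariates_rarely_significant(self):
        false_pos = 0
        reps = 30
        for r in range(reps):
            cfg, stack, stations, matrix = _pipeline_setup(
                6000 + 10 * r,
                betas={"intercept": -0.3, "effort": 0.0, "v1": 0.0, "v2": 0.0})
            res = run_habitat_pipeline("felid", stack, stations, matrix,
                                       scales=SCALES)
            sig = [t for t, a in res.ensemble.averaged.items()
                   if t not in ("(Intercept)", "effort") and a.pvalue <= 0.05]
            false_pos += bool(sig)
        assert false_pos <= 0.15 * reps + 1e-9

    def test_unknown_species_raises(self):
        cfg, stack, stations, matrix = _pipeline_setup(1)
        with pytest.raises(KeyError):
            run_habitat_pipeline("ghost", stack, stations, matrix, scales=SCALES)

    def test_all_screened_out_returns_forced_only_model(self):
        cfg, stack, stations, matrix = _pipeline_setup(5)
        with pytest.warns(UserWarning, match="screened"):
            res = run_habitat_pipeline("felid", stack, stations, matrix,
                                       scales=SCALES, p_screen=1e-12)
        assert res.retained == []
        assert set(res.ensemble.averaged) == {"(Intercept)", "effort"}


class TestPredictSurface:
    def test_surface_probabilities_in_unit_interval(self):
        cfg, stack, stations, matrix = _pipeline_setup(21)
        model = MultiScaleHabitatModel(SCALES).fit(
            stack, stations,
            (matrix["felid"].to_numpy() > 0).astype(float))
        if not model.retained_:
            pytest.skip("no variable retained in this realization")
        surf = model.predict_surface(stack, species="felid")
        finite = surf.raster.values[np.isfinite(surf.raster.values)]
        assert np.all((finite >= 0) & (finite <= 1))

    def test_station_probabilities_match_surface_at_station_effort(self):
        cfg, stack, stations, matrix = _pipeline_setup(22)
        y = (matrix["felid"].to_numpy() > 0).astype(float)
        model = MultiScaleHabitatModel(SCALES).fit(stack, stations, y)
        p_station = model.station_probabilities()
        # rebuild the linear predictor per station from the surface equation
        avg = model.ensemble_.averaged
        z = np.full(len(stations), avg["(Intercept)"].coef)
        z += avg["effort"].coef * stations["effort"].to_numpy()
        for name in model.retained_:
            z += avg[name].coef * model.result_.covariates[name].station_values
        np.testing.assert_allclose(p_station, expit(z), atol=1e-10)

    def test_intercept_only_logistic_mapping(self):
        # averaged model with only an intercept of -2.2348 -> p = 0.0967
        from felidniche.glm import all_subsets
        rng = np.random.default_rng(0)
        y = (rng.random(300) < 0.1).astype(float)
        ens = all_subsets(y, {}, {"(Intercept)": np.ones(300)})
        ens.averaged["(Intercept)"].coef = -2.2348
        p = expit(ens.averaged["(Intercept)"].coef)
        assert p == pytest.approx(0.0967, abs=1e-4)

    def test_monotone_in_positive_covariate(self):
        cfg, stack, stations, matrix = _pipeline_setup(23)
        y = (matrix["felid"].to_numpy() > 0).astype(float)
        model = MultiScaleHabitatModel(SCALES).fit(stack, stations, y)
        if "v1" not in model.retained_:
            pytest.skip("v1 not retained in this realization")
        surf = model.predict_surface(stack, species="felid")
        beta = model.ensemble_.averaged["v1"].coef
        bumped = {n: r for n, r in stack.items()}
        bumped["v1"] = Raster(stack["v1"].values + 0.5, stack["v1"].cell_size,
                              name="v1")
        surf2 = model.predict_surface(bumped, species="felid")
        diff = surf2.raster.values - surf.raster.values
        if beta > 0:
            assert np.nanmin(diff) > 0
        else:
            assert np.nanmax(diff) < 0


class TestCompareSurfaces:
    @staticmethod
    def _surface(vals, name):
        return OccurrenceSurface(Raster(np.asarray(vals, float), 100.0), name,
                                 [], {}, {})

    def test_identical_surfaces(self):
        rng = np.random.default_rng(0)
        a = self._surface(rng.uniform(0, 1, (5, 5)), "a")
        cmp_ = compare_surfaces(a, a)
        assert cmp_.pearson_r == pytest.approx(1.0)
        assert cmp_.mean_abs_diff == 0.0

    def test_complement_surface_perfect_negative(self):
        rng = np.random.default_rng(1)
        vals = rng.uniform(0, 1, (4, 4))
        cmp_ = compare_surfaces(self._surface(vals, "a"),
                                self._surface(1 - vals, "b"))
        assert cmp_.pearson_r == pytest.approx(-1.0)

    def test_hand_built_three_by_three(self):
        a = np.array([[0.1, 0.2, 0.3], [0.4, 0.5, 0.6], [0.7, 0.8, 0.9]])
        b = np.array([[0.2, 0.1, 0.4], [0.3, 0.6, 0.5], [0.8, 0.7, 1.0]])
        cmp_ = compare_surfaces(self._surface(a, "a"), self._surface(b, "b"))
        assert cmp_.mean_abs_diff == pytest.approx(np.mean(np.abs(a - b)))
        assert cmp_.pearson_r == pytest.approx(np.corrcoef(a.ravel(), b.ravel())[0, 1])

    def test_constant_surface_r_undefined(self):
        a = self._surface(np.full((3, 3), 0.5), "a")
        b = self._surface(np.linspace(0, 1, 9).reshape(3, 3), "b")
        cmp_ = compare_surfaces(a, b)
        assert np.isnan(cmp_.pearson_r)
        assert cmp_.mean_abs_diff >= 0


class TestUnivariateAssociation:
    def test_delegates_to_logistic_fit(self, rng):
        flag = (rng.random(200) < 0.4).astype(float)
        y = (rng.random(200) < 0.3).astype(float)
        fit = univariate_association(y, flag)
        ref = fit_logistic(y, np.column_stack([np.ones(200), flag]))
        np.testing.assert_allclose(fit.coef, ref.coef)

    def test_null_flag_coefficient_centred_on_zero(self):
        # Wald SE of the log-odds difference at n=1000 is ~0.13, so the null
        # coefficient should be near zero on average and almost always
        # within ~2.5 SE.
        rng = np.random.default_rng(31)
        coefs = []
        reps = 30
        for _ in range(reps):
            flag = (rng.random(1000) < 0.5).astype(float)
            y = (rng.random(1000) < 0.4).astype(float)
            coefs.append(univariate_association(y, flag).coef[1])
        assert abs(np.mean(coefs)) < 0.05
        assert np.mean(np.abs(coefs) < 0.33) >= 0.9

    def test_detections_only_at_flagged_stations_separated(self):
        flag = np.array([0.0] * 50 + [1.0] * 50)
        y = flag.copy()
        fit = univariate_association(y, flag)
        assert not fit.converged

    def test_single_level_flag_rejected(self):
        with pytest.raises(ValueError):
            univariate_association(np.array([0.0, 1.0]), np.array([1.0, 1.0]))


class TestPreyCooccurrence:
    @staticmethod
    def _matrix(rng, n=500, effect=0.3, n_prey=3):
        prey = {f"prey{i}": rng.poisson(3.0, n) for i in range(n_prey)}
        z = -0.5 + effect * prey["prey0"]
        felid = (rng.random(n) < expit(z)).astype(int) * (1 + rng.poisson(1.0, n))
        mat = pd.DataFrame({"felid": felid, **prey})
        effort = rng.uniform(80, 160, n)
        return mat, effort

    def test_positive_effect_recovered_with_importance(self):
        wins = 0
        reps = 20
        for r in range(reps):
            rng = np.random.default_rng(4000 + r)
            mat, effort = self._matrix(rng)
            ens = prey_cooccurrence_model("felid", mat, effort)
            avg = ens.averaged["prey0"]
            wins += avg.coef > 0 and avg.importance > 0.5
        assert wins >= int(0.8 * reps)

    def test_null_effects_low_mean_importance(self):
        imps = []
        for r in range(20):
            rng = np.random.default_rng(5000 + r)
            mat, effort = self._matrix(rng, effect=0.0)
            ens = prey_cooccurrence_model("felid", mat, effort)
            imps += [ens.averaged[f"prey{i}"].importance for i in range(3)]
        assert np.mean(imps) < 0.5

    def test_candidate_cap_via_univariate_prescreen(self):
        rng = np.random.default_rng(2)
        n = 200
        mat = pd.DataFrame({f"p{i}": rng.poisson(2.0, n) for i in range(20)})
        mat["felid"] = (rng.random(n) < 0.3).astype(int)
        ens = prey_cooccurrence_model("felid", mat, rng.uniform(50, 150, n))
        assert len(ens.free_terms) == 15
        assert ens.prescreened_from == 20

    def test_min_detection_filter_applied(self):
        rng = np.random.default_rng(3)
        n = 100
        mat = pd.DataFrame({"rare": np.zeros(n, dtype=int),
                            "common": rng.poisson(2.0, n),
                            "felid": (rng.random(n) < 0.4).astype(int)})
        mat.loc[0, "rare"] = 19
        ens = prey_cooccurrence_model("felid", mat, rng.uniform(50, 150, n))
        assert "rare" not in ens.free_terms
        assert "common" in ens.free_terms

    def test_missing_felid_rejected(self):
        with pytest.raises(KeyError):
            prey_cooccurrence_model("ghost", pd.DataFrame({"a": [1, 2]}),
                                    np.array([1.0, 1.0]))
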