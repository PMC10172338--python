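import numpy as np
import pytest

from nicheshift.range_projection import (CHANGE_CLASSES, PresenceSurface,
                                         binarize_presence, project_abundance,
                                         recruitment_change, run_scenarios,
                                         summarize_areas)
from nicheshift.rasters import Raster


def presence_from(data, px=1000.0, threshold=1.0):
    data = np.asarray(data, dtype=float)
    r = Raster(data=data, origin=(0.0, data.shape[0] * px), pixel_size=px)
    return PresenceSurface(raster=r, threshold=threshold)


class TestProjection:
    def test_constant_climate_gives_constant_surface(self, marula_adult_fit, scene):
        from nicheshift.abundance_model import predict_expected
        from nicheshift.rasters import ClimateStack

        const = scene.stack.grid.like(np.full(scene.stack.grid.shape, 20.0))
        stack = ClimateStack(layers={"annual_mean_temp": const})
        surf = project_abundance(marula_adult_fit, stack)
        want = predict_expected(marula_adult_fit, 20.0)
        np.testing.assert_allclose(surf.raster.data, want)

    def test_pixelwise_brute_force_equality(self, marula_adult_fit, scene):
        from nicheshift.abundance_model import predict_expected

        surf = project_abundance(marula_adult_fit, scene.stack)
        layer = scene.stack["annual_mean_temp"]
        for i in range(0, 20):
            for j in range(0, 20):
                want = predict_expected(marula_adult_fit, layer.data[i, j],
                                        extrapolation_guard=np.inf)
                assert surf.raster.data[i, j] == want

    def test_missing_climate_propagates(self, marula_adult_fit, scene):
        stack = scene.stack.copy()
        stack.layers["annual_mean_temp"].data[3, 5] = np.nan
        surf = project_abundance(marula_adult_fit, stack)
        assert np.isnan(surf.raster.data[3, 5])

    def test_absent_covariate_layer(self, marula_adult_fit, scene):
        from nicheshift.rasters import ClimateStack

        stack = ClimateStack(layers={"pet": scene.stack["pet"]})
        with pytest.raises(KeyError, match="annual_mean_temp"):
            project_abundance(marula_adult_fit, stack)


class TestBinarize:
    def test_threshold_above_max_all_absent(self, marula_adult_fit, scene):
        surf = project_abundance(marula_adult_fit, scene.stack)
        pres = binarize_presence(surf, threshold=np.nanmax(surf.raster.data) + 1)
        assert np.nansum(pres.raster.data) == 0

    def test_zero_threshold_all_present(self, marula_adult_fit, scene):
        surf = project_abundance(marula_adult_fit, scene.stack)
        pres = binarize_presence(surf, threshold=0.0)
        ok = np.isfinite(surf.raster.data)
        assert np.all(pres.raster.data[ok] == 1)

    def test_idempotent_on_own_output(self, marula_adult_fit, scene):
        surf = project_abundance(marula_adult_fit, scene.stack)
        p1 = binarize_presence(surf, threshold=1.0)
        surf2 = type(surf)(raster=p1.raster, fit_label=surf.fit_label,
                           scenario=surf.scenario, level=surf.level)
        p2 = binarize_presence(surf2, threshold=0.5)
        np.testing.assert_array_equal(p1.raster.data, p2.raster.data)

    def test_negative_threshold_rejected(self, marula_adult_fit, scene):
        surf = project_abundance(marula_adult_fit, scene.stack)
        with pytest.raises(ValueError):
            binarize_presence(surf, threshold=-0.5)


class TestChangeMap:
    def test_identical_surfaces_all_cooccur(self):
        s = presence_from([[1, 0], [1, 1]])
        cm = recruitment_change(s, s)
        assert cm.class_mask("gained").sum() == 0
        assert cm.class_mask("lost").sum() == 0
        assert cm.class_mask("co_occur").sum() == 3

    def test_disjoint_surfaces(self):
        seed = presence_from([[1, 1], [0, 0]])
        adult = presence_from([[0, 0], [1, 1]])
        cm = recruitment_change(seed, adult)
        assert cm.class_mask("gained").sum() == 2
        assert cm.class_mask("lost").sum() == 2
        assert cm.class_mask("co_occur").sum() == 0

    def test_set_algebra_on_random_fixtures(self):
        rng = np.random.default_rng(0)
        for _ in range(25):
            s = presence_from(rng.integers(0, 2, size=(12, 9)))
            a = presence_from(rng.integers(0, 2, size=(12, 9)))
            cm = recruitment_change(s, a)
            # classes partition the domain
            total = sum(cm.class_mask(c).sum() for c in CHANGE_CLASSES)
            assert total == 12 * 9
            # gained + co-occur = seedling presence, exactly
            assert (cm.class_mask("gained").sum() + cm.class_mask("co_occur").sum()
                    == s.raster.data.sum())
            # co-occur bounded by both areas
            assert cm.class_mask("co_occur").sum() <= min(s.raster.data.sum(),
                                                          a.raster.data.sum())

    def test_geometry_mismatch_rejected(self):
        with pytest.raises(ValueError, match="co-registered"):
            recruitment_change(presence_from(np.ones((3, 3))),
                               presence_from(np.ones((4, 4))))

    def test_missing_propagates(self):
        s = presence_from([[1.0, np.nan]])
        a = presence_from([[1.0, 1.0]])
        cm = recruitment_change(s, a)
        assert np.isnan(cm.raster.data[0, 1])


class TestAreas:
    def test_pixel_count_times_area(self):
        s = presence_from(np.ones((5, 2)))
        a = presence_from(np.zeros((5, 2)))
        cm = recruitment_change(s, a)
        out = summarize_areas(cm, pixel_area_km2=1.0, initial_area_km2=100.0)
        assert out.areas_km2["gained"] == 10.0
        assert out.ratios_pct["gained"] == pytest.approx(10.0)

    def test_knobthorn_loss_ratio_arithmetic(self):
        # 648.5 km2 lost of a 2854.9 km2 initial range is 22.7% (~ 23%)
        cm = recruitment_change(presence_from(np.zeros((1, 1297))),
                                presence_from(np.ones((1, 1297))))
        out = summarize_areas(cm, pixel_area_km2=0.5, initial_area_km2=2854.9)
        assert out.areas_km2["lost"] == pytest.approx(648.5)
        assert out.ratios_pct["lost"] == pytest.approx(22.71, abs=0.01)
        assert out.printed("lost") == "648.5 km2 (~ 23%)"

    def test_knobthorn_gain_ratio_under_one_percent(self):
        # 21.5 km2 gained of 2854.9 km2 initial: 0.75% (< 1%)
        cm = recruitment_change(presence_from(np.ones((1, 43))),
                                presence_from(np.zeros((1, 43))))
        out = summarize_areas(cm, pixel_area_km2=0.5, initial_area_km2=2854.9)
        assert out.areas_km2["gained"] == pytest.approx(21.5)
        assert out.ratios_pct["gained"] == pytest.approx(0.753, abs=0.005)
        assert out.ratios_pct["gained"] < 1.0


@pytest.fixture(scope="module")
def best_fits(count_table):
    from nicheshift.abundance_model import ModelSpec, fit_zinb_glmm

    return {
        (sp, cls): fit_zinb_glmm(ModelSpec(sp, cls), count_table,
                                 n_starts=2, compute_vcov=False)
        for sp in ("marula", "knobthorn") for cls in ("adult", "young")
    }


class TestScenarios:
    def test_table_shape_matches_field_configuration(self, best_fits, scene):
        from nicheshift.synthetic_scene import DEFAULT_SCENARIOS, shift_future_climate

        stacks = {"baseline": scene.stack}
        for label, (dt, pf) in DEFAULT_SCENARIOS.items():
            stacks[label] = shift_future_climate(scene.stack, dt, pf, label=label)
        table = run_scenarios(best_fits, stacks)
        # 2 species x 5 scenarios x {gained, lost}
        assert len(table) == 2 * 5 * 2
        assert set(table.category) == {"gained", "lost"}
        assert (table.area_km2 >= 0).all()

    def test_identity_scenario_equals_baseline(self, best_fits, scene):
        from nicheshift.synthetic_scene import shift_future_climate

        stacks = {"baseline": scene.stack,
                  "same": shift_future_climate(scene.stack, 0.0, 1.0, label="same")}
        table = run_scenarios(best_fits, stacks)
        for sp in ("marula", "knobthorn"):
            for cat in ("gained", "lost"):
                sel = (table.species == sp) & (table.category == cat)
                vals = table[sel].set_index("scenario")["area_km2"]
                assert vals["same"] == vals["baseline"]

    def test_missing_baseline_rejected(self, best_fits, scene):
        with pytest.raises(ValueError, match="baseline"):
            run_scenarios(best_fits, {"other": scene.stack})

    def test_decoupling_signature_cool_side_gain(self, best_fits, scene):
        """Seedling optimum 2 degC cooler than adults: gains accrue on the cool
        side of the adult range and losses on the hot side."""
        pres_t = scene.stack["annual_mean_temp"].data
        from nicheshift.range_projection import (binarize_presence, project_abundance,
                                                 recruitment_change)

        seed = binarize_presence(project_abundance(best_fits[("marula", "young")],
                                                   scene.stack), 1.0)
        adult = binarize_presence(project_abundance(best_fits[("marula", "adult")],
                                                    scene.stack), 1.0)
        cm = recruitment_change(seed, adult)
        t_gained = pres_t[cm.class_mask("gained")]
        t_lost = pres_t[cm.class_mask("lost")]
        t_adult = pres_t[adult.raster.data == 1]
        assert t_gained.mean() < t_adult.mean() < t_lost.mean()
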