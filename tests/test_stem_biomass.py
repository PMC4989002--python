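import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import quad

from savagb.stem_biomass import (
    BefModel,
    StemSection,
    bef,
    compare_bef_models,
    compare_methods,
    destructive_total,
    fit_bef_model,
    predict_agb_from_stem,
    section_volume,
    stem_biomass,
    stem_biomass_table,
)
from savagb.study import BEF_LNB_COEF


class TestSectionVolume:
    def test_cylinder_identity(self):
        # girth of a radius-10 circle; volume must be pi r^2 H
        c = 2 * math.pi * 10.0
        v = section_volume(StemSection(100.0, c, c))
        assert v == pytest.approx(math.pi * 100.0 * 100.0, rel=1e-9)

    def test_frustum_closed_form(self):
        v = section_volume(StemSection(200.0, 40.0, 30.0))
        assert v == pytest.approx(200.0 * 3700.0 / (12 * math.pi), rel=1e-12)

    def test_cone_limit(self):
        v = section_volume(StemSection(90.0, 50.0, 0.0))
        assert v == pytest.approx(90.0 * 2500.0 / (12 * math.pi), rel=1e-12)

    def test_invalid_sections_rejected(self):
        with pytest.raises(ValueError):
            StemSection(-1.0, 40.0, 30.0)
        with pytest.raises(ValueError):
            StemSection(100.0, 30.0, 40.0)  # C1 < C2

    @settings(max_examples=30, deadline=None)
    @given(
        h=st.floats(10.0, 500.0),
        c1=st.floats(10.0, 200.0),
        frac=st.floats(0.0, 1.0),
    )
    def test_matches_taper_integration(self, h, c1, frac):
        """The frustum formula equals the integral of the cross-section of a
        linearly tapering girth to better than 0.1 %."""
        c2 = c1 * frac
        v = section_volume(StemSection(h, c1, c2))
        area = lambda x: (c1 + (c2 - c1) * x / h) ** 2 / (4 * math.pi)
        v_num, _ = quad(area, 0.0, h)
        assert v == pytest.approx(v_num, rel=1e-3)


class TestStemBiomass:
    def test_single_section(self):
        # one section of 10,000 cm^3 at rho = 0.8 -> 8 kg
        s = StemSection(10_000.0 * 12 * math.pi / 3.0, 1.0, 1.0)
        assert stem_biomass([s], 0.8) == pytest.approx(8.0, rel=1e-9)

    def test_additive_in_sections(self):
        s = StemSection(120.0, 80.0, 60.0)
        one = stem_biomass([s], 0.7)
        assert stem_biomass([s, s], 0.7) == pytest.approx(2 * one)

    def test_cylinder_with_density(self):
        c = 2 * math.pi * 10.0
        b = stem_biomass([StemSection(100.0, c, c)], 0.821)
        assert b == pytest.approx(31415.93 * 0.821 / 1000.0, rel=1e-5)

    def test_missing_density_is_error(self):
        with pytest.raises(ValueError, match="density"):
            stem_biomass([StemSection(100.0, 50.0, 40.0)], 0.0)

    def test_table_matches_sections(self, rng):
        rows = []
        for _ in range(5):
            g1 = rng.uniform(40, 120)
            t = rng.uniform(0.6, 0.95)
            rows.append(
                {
                    "girth_bh_cm": g1, "girth_23_cm": g1 * t,
                    "girth_crown_cm": g1 * t**2, "sec1_h_cm": 130.0,
                    "sec2_h_cm": 100.0, "sec3_h_cm": rng.uniform(80, 250),
                    "density": rng.uniform(0.5, 0.9),
                }
            )
        df = pd.DataFrame(rows)
        expected = [
            stem_biomass(
                [
                    StemSection(r["sec1_h_cm"], r["girth_bh_cm"], r["girth_bh_cm"]),
                    StemSection(r["sec2_h_cm"], r["girth_bh_cm"], r["girth_23_cm"]),
                    StemSection(r["sec3_h_cm"], r["girth_23_cm"], r["girth_crown_cm"]),
                ],
                r["density"],
            )
            for r in rows
        ]
        np.testing.assert_allclose(stem_biomass_table(df).to_numpy(), expected)


class TestDestructiveTotal:
    def test_three_equal_components(self):
        comp = [(100.0, 1.0, 0.5)] * 3
        assert destructive_total(comp) == pytest.approx(150.0)

    def test_dry_ratio_one(self):
        comp = [(40.0, 1.0, 1.0), (25.0, 1.0, 1.0), (5.0, 1.0, 1.0)]
        assert destructive_total(comp) == pytest.approx(70.0)

    def test_zero_fresh_component_contributes_nothing(self):
        comp = [(100.0, 1.0, 0.5), (50.0, 1.0, 0.5), (0.0, 1.0, 0.0)]
        assert destructive_total(comp) == pytest.approx(75.0)

    def test_zero_subsample_is_error(self):
        with pytest.raises(ValueError):
            destructive_total([(100.0, 0.0, 0.0)])


class TestBef:
    def test_ratios(self):
        assert bef(100.0, 100.0) == pytest.approx(1.0)
        assert bef(167.0, 100.0) == pytest.approx(1.67)
        assert bef(188.0, 100.0) == pytest.approx(1.88)

    def test_below_one_warns(self):
        with pytest.warns(UserWarning, match="BEF < 1"):
            assert bef(90.0, 100.0) == pytest.approx(0.9)

    def test_zero_stem_is_error(self):
        with pytest.raises(ValueError):
            bef(100.0, 0.0)


class TestFitBefModel:
    def test_noise_free_recovery(self):
        b = np.geomspace(5, 500, 20)
        y = 1.2 + 0.15 * np.log(b)
        m = fit_bef_model(b, y)
        assert m.beta0 == pytest.approx(1.2, abs=1e-10)
        assert m.beta1 == pytest.approx(0.15, abs=1e-10)
        assert m.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_published_truth_recovery(self, rng):
        b = np.exp(rng.uniform(np.log(5), np.log(500), 500))
        truth0, truth1 = BEF_LNB_COEF["intercept"], BEF_LNB_COEF["slope"]
        y = truth0 + truth1 * np.log(b) + rng.normal(0, 0.05, 500)
        m = fit_bef_model(b, y)
        assert abs(m.beta0 - truth0) <= 2 * m.se_beta0
        assert abs(m.beta1 - truth1) <= 2 * m.se_beta1

    def test_constant_bef_gives_zero_slope(self):
        b = np.geomspace(5, 500, 10)
        m = fit_bef_model(b, np.full(10, 1.7))
        assert m.beta1 == pytest.approx(0.0, abs=1e-10)

    def test_zero_variance_predictor_is_error(self):
        with pytest.raises(ValueError):
            fit_bef_model([10.0, 10.0, 10.0], [1.5, 1.6, 1.7])

    def test_dbh_predictor(self):
        d = np.linspace(5, 25, 13)
        y = 1.25801 + 0.0314 * d
        m = fit_bef_model(d, y, predictor="dbh")
        assert m.beta1 == pytest.approx(0.0314, abs=1e-10)


class TestPredictAgb:
    def test_published_model_at_100kg(self):
        m = BefModel("ln_stem_biomass", 1.24155, 0.14701, 0.0, 0.0, 0.0, 13, 1.0)
        expected_bef = 1.24155 + 0.14701 * math.log(100.0)
        assert m.bef(100.0) == pytest.approx(expected_bef, rel=1e-12)
        assert predict_agb_from_stem(100.0, m) == pytest.approx(100 * expected_bef)
        # agrees with the printed worked value to its precision
        assert predict_agb_from_stem(100.0, m) == pytest.approx(191.86, abs=0.01)

    def test_constant_bef(self):
        m = BefModel("ln_stem_biomass", 2.0, 0.0, 0.0, 0.0, 0.0, 13, 1.0)
        for b in (1.0, 10.0, 250.0):
            assert predict_agb_from_stem(b, m) == pytest.approx(2.0 * b)

    def test_unit_stem_returns_intercept(self):
        m = BefModel("ln_stem_biomass", 1.3, 0.2, 0.0, 0.0, 0.0, 13, 1.0)
        assert m.bef(1.0) == pytest.approx(1.3)

    def test_consistency_with_bef(self):
        m = BefModel("ln_stem_biomass", 1.24155, 0.14701, 0.0, 0.0, 0.0, 13, 1.0)
        b = np.geomspace(2, 400, 9)
        np.testing.assert_allclose(predict_agb_from_stem(b, m) / b, m.bef(b))

    def test_monotone_increasing(self):
        m = BefModel("ln_stem_biomass", 1.24155, 0.14701, 0.0, 0.0, 0.0, 13, 1.0)
        b = np.geomspace(1, 600, 50)
        assert np.all(np.diff(predict_agb_from_stem(b, m)) > 0)


class TestCompareMethods:
    def test_identical(self):
        sd, ad, r = compare_methods([10.0, 20.0, 30.0], [10.0, 20.0, 30.0])
        assert sd == pytest.approx(0.0)
        assert ad == pytest.approx(0.0)
        assert r == pytest.approx(1.0)

    def test_uniform_overestimate(self):
        obs = np.array([10.0, 20.0, 30.0])
        sd, ad, r = compare_methods(obs, obs * 1.1)
        assert sd == pytest.approx(10.0)
        assert ad == pytest.approx(10.0)
        assert r == pytest.approx(1.0)

    def test_anti_ordered_pairs(self):
        sd, ad, r = compare_methods([1.0, 2.0], [2.0, 1.0])
        assert r == pytest.approx(-1.0)

    def test_nonpositive_observation_is_error(self):
        with pytest.raises(ValueError):
            compare_methods([0.0, 2.0], [1.0, 2.0])


def test_compare_bef_models_reports_preference(rng):
    b = np.exp(rng.uniform(np.log(4), np.log(80), 13))
    d = 5 + (b - 4) / 4
    y = 1.24 + 0.147 * np.log(b) + rng.normal(0, 0.04, 13)
    m_ln = fit_bef_model(b, y)
    m_dbh = fit_bef_model(d, y, predictor="dbh")
    out = compare_bef_models(m_ln, m_dbh)
    assert out["preferred"] in ("ln_stem_biomass", "dbh")
    assert out["delta_aicc"] >= 0.0
    assert set(out["aicc"]) == {"ln_stem_biomass", "dbh"}
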