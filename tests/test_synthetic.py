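import dataclasses

import numpy as np
import pytest

from savagb.stem_biomass import destructive_total, fit_bef_model, stem_biomass_table
from savagb.study import MAIN_SPECIES, MODEL_LUCAS, LucaProfile
from savagb.synthetic import (
    SimulationConfig,
    generate_cores,
    generate_destructive_set,
    generate_inventory,
    generate_landscape,
)

FOREST = [p for p in MODEL_LUCAS if p.luca_name == "forest land"]


class TestInventory:
    def test_forest_counts_and_dbh_domain(self, config):
        inv = generate_inventory(FOREST, MAIN_SPECIES, config)
        assert len(inv) == 181
        assert inv["dbh_cm"].between(5.6, 44.7).all()

    def test_all_categories_hold_their_ranges(self, config):
        inv = generate_inventory(MODEL_LUCAS, MAIN_SPECIES, config)
        for prof in MODEL_LUCAS:
            sub = inv[inv["luca"] == prof.luca_name]
            assert len(sub) == prof.n_trees
            assert sub["dbh_cm"].between(*prof.dbh_range).all()
        assert (inv["height_m"] > 0).all()
        assert (inv["density"] > 0).all()

    def test_determinism_byte_identical(self, config):
        a = generate_inventory(MODEL_LUCAS, MAIN_SPECIES, config)
        b = generate_inventory(MODEL_LUCAS, MAIN_SPECIES, config)
        assert a.to_csv(index=False) == b.to_csv(index=False)

    def test_girths_follow_taper_powers(self, config):
        inv = generate_inventory(FOREST, MAIN_SPECIES, config)
        t = config.taper_ratio
        np.testing.assert_allclose(inv["girth_bh_cm"], np.pi * inv["dbh_cm"])
        np.testing.assert_allclose(inv["girth_23_cm"], inv["girth_bh_cm"] * t)
        np.testing.assert_allclose(inv["girth_crown_cm"], inv["girth_bh_cm"] * t**2)

    def test_degenerate_taper_gives_equal_girths(self):
        cfg = SimulationConfig(seed=1, taper_ratio=1.0)
        inv = generate_inventory(FOREST, MAIN_SPECIES, cfg)
        np.testing.assert_allclose(inv["girth_23_cm"], inv["girth_bh_cm"])
        np.testing.assert_allclose(inv["girth_crown_cm"], inv["girth_bh_cm"])

    def test_empty_species_pool_is_error(self, config):
        with pytest.raises(ValueError, match="species"):
            generate_inventory(FOREST, [], config)

    def test_total_trees_rescaling(self):
        cfg = SimulationConfig(seed=0, total_trees=270)
        inv = generate_inventory(MODEL_LUCAS, MAIN_SPECIES, cfg)
        assert abs(len(inv) - 270) <= len(MODEL_LUCAS)  # rounding slack


class TestCores:
    def test_species_mean_recovered(self, config):
        tmac = [p for p in MAIN_SPECIES if "macroptera" in p.species_name]
        cores = generate_cores(tmac, config)
        assert len(cores) == 19
        from savagb.densitometry import species_summary

        out = species_summary(cores).iloc[0]
        assert abs(out["mean_density"] - 0.821) <= 2 * 0.010

    def test_zero_se_gives_exact_density(self):
        prof = dataclasses.replace(MAIN_SPECIES[0], density_se=0.0)
        cores = generate_cores([prof], SimulationConfig(seed=9))
        from savagb.densitometry import core_density

        rho = core_density(
            cores["dry_mass_g"].to_numpy(),
            cores["bit_diameter_cm"].to_numpy(),
            cores["core_length_cm"].to_numpy(),
        )
        np.testing.assert_allclose(rho, prof.density_mean, rtol=1e-12)

    def test_labels_and_counts_per_species(self, config):
        two = list(MAIN_SPECIES[:2])
        cores = generate_cores(two, config)
        counts = cores.groupby("species").size()
        for prof in two:
            assert counts[prof.species_name] == prof.n_cores
        assert (cores["bit_diameter_cm"] == 0.5).all()


class TestDestructiveSet:
    def test_refit_recovers_generating_line(self):
        cfg = SimulationConfig(seed=12, bef_noise_sd=0.05)
        trees, _ = generate_destructive_set(13, cfg)
        m = fit_bef_model(trees["bstem_kg"].to_numpy(), trees["bef"].to_numpy())
        assert abs(m.beta0 - cfg.bef_intercept) <= 2 * m.se_beta0
        assert abs(m.beta1 - cfg.bef_slope) <= 2 * m.se_beta1

    def test_noise_free_round_trip_exact(self):
        cfg = SimulationConfig(seed=4, bef_noise_sd=0.0)
        trees, comp = generate_destructive_set(20, cfg)
        m = fit_bef_model(trees["bstem_kg"].to_numpy(), trees["bef"].to_numpy())
        assert m.beta0 == pytest.approx(cfg.bef_intercept, rel=1e-7)
        assert m.beta1 == pytest.approx(cfg.bef_slope, rel=1e-7)

    def test_sections_reproduce_stem_biomass(self):
        cfg = SimulationConfig(seed=4, bef_noise_sd=0.0)
        trees, _ = generate_destructive_set(10, cfg)
        np.testing.assert_allclose(
            stem_biomass_table(trees).to_numpy(), trees["bstem_kg"].to_numpy(),
            rtol=1e-10,
        )

    def test_components_reproduce_total(self):
        trees, comp = generate_destructive_set(10, SimulationConfig(seed=6))
        for tid, expected in zip(trees["tree_id"], trees["btot_kg"]):
            got = destructive_total(comp[comp["tree_id"] == tid])
            assert got == pytest.approx(expected, rel=1e-10)

    def test_wide_range_bef_bounded_by_line_endpoints(self):
        cfg = SimulationConfig(seed=5, bef_noise_sd=0.0, bstem_range_kg=(5.0, 600.0))
        trees, _ = generate_destructive_set(200, cfg)
        lo = cfg.bef_intercept + cfg.bef_slope * np.log(5.0)
        hi = cfg.bef_intercept + cfg.bef_slope * np.log(600.0)
        assert 1.4 < lo and hi < 2.2
        assert trees["bef"].between(lo - 1e-9, hi + 1e-9).all()

    def test_sub_unity_bef_model_rejected(self):
        cfg = SimulationConfig(seed=1, bef_intercept=0.9, bef_slope=0.01)
        with pytest.raises(ValueError, match="BEF"):
            generate_destructive_set(13, cfg)

    def test_minimum_sample_size(self, config):
        with pytest.raises(ValueError):
            generate_destructive_set(2, config)


class TestLandscape:
    TWO = (
        LucaProfile("a", (5.0, 40.0), 10, 2, (30.0, 30.0), 75.0),
        LucaProfile("b", (5.0, 40.0), 10, 2, (30.0, 30.0), 25.0),
    )

    def test_cell_counts_proportional_to_area(self, config):
        grid, _ = generate_landscape(self.TWO, (10, 10), config)
        values, counts = np.unique(grid.data, return_counts=True)
        assert dict(zip(values, counts)) == {1.0: 75, 2.0: 25}

    def test_ndvi_values_in_range(self, config):
        _, stack = generate_landscape(self.TWO, (10, 10), config)
        assert stack.shape[0] == config.n_dates
        assert (stack >= -1.0).all() and (stack <= 1.0).all()

    def test_kmeans_recovers_classes_when_separated(self):
        from savagb.ndvi import mean_ndvi, stratify

        cfg = SimulationConfig(seed=2, ndvi_noise_sd=0.01)
        grid, stack = generate_landscape(self.TWO, (12, 12), cfg)
        labels = stratify(mean_ndvi(stack), k=2, seed=0)
        # class means are ~0.6/noise_sd apart: partition must match exactly
        assert (labels[grid.data == 1.0] == 0).all()
        assert (labels[grid.data == 2.0] == 1).all()
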