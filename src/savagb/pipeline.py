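"""End-to-end orchestration on synthetic or user-supplied tables.

Stage order mirrors the field workflow: stratify a vegetation-index map,
build the inventory, rank species by IVI, summarise wood density from
cores, calibrate the BEF on destructive trees, fit the land-use allometric
models, upscale plot densities to class stocks and paint the density map.
Every run writes a manifest (seed, package version, per-stage row counts)
and is byte-reproducible under a fixed seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
import numpy as np
import pandas as pd

from . import __version__
from .allometry import AllometricModel, fit_allometric, model_to_dict, predict_agb
from .densitometry import species_summary
from .io import write_table
from .ivi import ivi_table, occurrences_from_inventory
from .ndvi import mean_ndvi, stratify_and_sample
from .rasters import Grid, write_ascii_grid
from .stem_biomass import (
    compare_methods,
    destructive_total,
    fit_bef_model,
    predict_agb_from_stem,
    stem_biomass_table,
)
from .study import IVI_EXCLUSIONS, MAIN_SPECIES, MODEL_LUCAS, LucaProfile
from .synthetic import SimulationConfig, generate_cores, generate_destructive_set, \
    generate_inventory, generate_landscape
from .upscaling import density_map, summarize_lulc

log = logging.getLogger("savagb.pipeline")


@dataclass(frozen=True)
class PipelineConfig:
    seed: int = 0
    outdir: str | Path = "savagb_run"
    z_value: float = 1.96
    top_k_species: int = 15
    aicc_threshold: float = 2.0
    model_types: tuple[str, ...] = ("I", "II", "III")
    n_destructive: int = 13
    grid_shape: tuple[int, int] = (40, 40)
    n_strata_samples: int = 10
    luca_profiles: tuple[LucaProfile, ...] = MODEL_LUCAS
    simulation: SimulationConfig | None = None

    def sim(self) -> SimulationConfig:
        if self.simulation is not None:
            return self.simulation
        return SimulationConfig(seed=self.seed)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full chain on synthetic data; returns the manifest dict."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sim = config.sim()
    lucas = config.luca_profiles
    manifest: dict = {
        "package": "savagb",
        "version": __version__,
        "seed": config.seed,
        "stages": {},
        "skipped": [],
    }

    # -- stratification -------------------------------------------------
    log.info("[stratify] landscape %sx%s", *config.grid_shape)
    lulc_grid, stack = generate_landscape(lucas, config.grid_shape, sim)
    composite = mean_ndvi(stack)
    sample = stratify_and_sample(
        composite, k=len(lucas), n_per_stratum=config.n_strata_samples,
        seed=config.seed, cell_size=lulc_grid.cellsize,
        validation_fraction=0.3,
    )
    write_ascii_grid(outdir / "lulc_map.asc", lulc_grid)
    write_ascii_grid(outdir / "mean_ndvi.asc", Grid(composite, cellsize=lulc_grid.cellsize))
    sample.to_csv(outdir / "strata_sample.csv", index=False)
    manifest["stages"]["stratify"] = {"samples": len(sample), "k": len(lucas)}

    # -- inventory ------------------------------------------------------
    log.info("[inventory] generating synthetic inventory")
    inventory = generate_inventory(lucas, MAIN_SPECIES, sim)
    manifest["stages"]["inventory"] = {"trees": len(inventory)}

    # -- IVI ------------------------------------------------------------
    occ = occurrences_from_inventory(inventory)
    ivi = ivi_table(occ, exclusions=IVI_EXCLUSIONS, top_k=config.top_k_species)
    write_table(ivi, outdir / "ivi.csv", "ivi")
    manifest["stages"]["ivi"] = {"species": len(ivi)}

    # -- wood density ---------------------------------------------------
    cores = generate_cores(MAIN_SPECIES, sim)
    write_table(cores, outdir / "cores.csv", "cores")
    dens = species_summary(cores)
    write_table(dens, outdir / "density_summary.csv", "density_summary")
    manifest["stages"]["density"] = {"cores": len(cores), "species": len(dens)}

    # -- BEF calibration ------------------------------------------------
    log.info("[bef] calibrating on %d destructive trees", config.n_destructive)
    dest_trees, dest_comp = generate_destructive_set(config.n_destructive, sim)
    write_table(dest_comp, outdir / "destructive_components.csv", "destructive_components")
    dest_trees.to_csv(outdir / "destructive_trees.csv", index=False)
    bstem_nd = stem_biomass_table(dest_trees)
    btot_obs = np.array(
        [
            destructive_total(dest_comp[dest_comp["tree_id"] == tid])
            for tid in dest_trees["tree_id"]
        ]
    )
    bef_model = fit_bef_model(bstem_nd.to_numpy(), btot_obs / bstem_nd.to_numpy())
    agb_pred = predict_agb_from_stem(bstem_nd.to_numpy(), bef_model)
    signed_dev, abs_dev, r = compare_methods(btot_obs, agb_pred)
    (outdir / "bef_model.json").write_text(
        json.dumps(
            {
                "predictor": bef_model.predictor,
                "beta0": bef_model.beta0,
                "beta1": bef_model.beta1,
                "se_beta0": bef_model.se_beta0,
                "se_beta1": bef_model.se_beta1,
                "residual_sd": bef_model.residual_sd,
                "n": bef_model.n,
                "r_squared": bef_model.r_squared,
                "method_comparison": {
                    "mean_signed_pct": signed_dev,
                    "mean_abs_pct": abs_dev,
                    "pearson_r": r,
                },
            },
            indent=2,
        )
    )
    manifest["stages"]["bef"] = {"trees": config.n_destructive, "pearson_r": r}

    # -- allometric models ----------------------------------------------
    inventory = inventory.assign(bstem_kg=stem_biomass_table(inventory))
    inventory = inventory.assign(
        agb_kg=predict_agb_from_stem(inventory["bstem_kg"].to_numpy(), bef_model)
    )
    write_table(inventory, outdir / "inventory.csv", "inventory")
    models: dict[str, dict[str, AllometricModel]] = {}
    for prof in lucas:
        sub = inventory[inventory["luca"] == prof.luca_name]
        models[prof.luca_name] = {}
        for mtype in config.model_types:
            models[prof.luca_name][mtype] = fit_allometric(
                sub, mtype, luca=prof.luca_name, dbh_domain=prof.dbh_range,
                aicc_threshold=config.aicc_threshold,
            )
    for mtype in ("I", "II", "III"):
        if mtype not in config.model_types:
            manifest["skipped"].append(f"model type {mtype}")
    (outdir / "allometric_models.json").write_text(
        json.dumps(
            {
                luca: {mtype: model_to_dict(m) for mtype, m in per.items()}
                for luca, per in models.items()
            },
            indent=2,
        )
    )
    manifest["stages"]["allometry"] = {
        "lucas": len(models), "types": list(config.model_types),
    }

    # -- upscaling ------------------------------------------------------
    # the best (most complex requested) type per land-use category
    best_type = config.model_types[-1]
    plot_area = {p.luca_name: p.plot_area_ha for p in lucas}
    dens_rows = []
    for (plot_id, luca), grp in inventory.groupby(["plot_id", "luca"]):
        model = models[luca][best_type]
        agb_model, _flags = predict_agb(
            model,
            grp["dbh_cm"].to_numpy(),
            grp["height_m"].to_numpy(),
            grp["density"].to_numpy(),
        )
        dens_rows.append(
            {
                "plot_id": plot_id,
                "lulc": luca,
                "plot_area_ha": plot_area[luca],
                "agb_density": float(np.sum(agb_model)) / 1000.0 / plot_area[luca],
            }
        )
    plot_dens = pd.DataFrame(dens_rows)
    write_table(plot_dens, outdir / "plot_densities.csv", "plot_densities")
    areas = {p.luca_name: p.area_ha for p in lucas}
    summary = summarize_lulc(plot_dens, areas, z=config.z_value)
    write_table(summary, outdir / "lulc_summary.csv", "lulc_summary")
    manifest["stages"]["upscale"] = {
        "plots": len(plot_dens), "classes": len(summary),
    }

    # -- density map ----------------------------------------------------
    code_to_density = {
        float(i + 1): float(
            summary.set_index("lulc").loc[p.luca_name, "mean_density"]
        )
        for i, p in enumerate(lucas)
    }
    dmap = density_map(lulc_grid.data, code_to_density, nodata=lulc_grid.nodata)
    write_ascii_grid(
        outdir / "density_map.asc",
        Grid(dmap, cellsize=lulc_grid.cellsize, nodata=lulc_grid.nodata),
        fmt="%.4f",
    )
    manifest["stages"]["map"] = {"cells": int(dmap.size)}

    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
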