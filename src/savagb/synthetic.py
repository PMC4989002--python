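"""Seeded synthetic field data with the statistical structure of the study.

Every downstream stage (densitometry, BEF calibration, IVI ranking,
allometric fitting, upscaling, stratification) is testable without field
data: the generators emulate the study conditions — per-species wood
densities, per-category DBH validity ranges and sample sizes, the
BEF-ln(stem biomass) line with noise, plot counts/sizes and land-use
areas — under a single global seed with per-operation substreams, so a
fixed seed reproduces every table bit for bit.

The DBH distribution within a category is a truncated log-normal on the
category's validity range (inventories are right-skewed); tree height
follows H = a * DBH^b with log-normal noise; stem girth tapers
geometrically between breast height, 2.3 m and the crown base.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .densitometry import DEFAULT_BIT_DIAMETER_CM
from .rasters import DEFAULT_NODATA, Grid
from .study import BEF_LNB_COEF, LucaProfile, SpeciesProfile

# substream tags so the per-operation streams are independent
_OP_INVENTORY, _OP_CORES, _OP_DESTRUCTIVE, _OP_LANDSCAPE = 11, 13, 17, 19

#: Species used for the destructive calibration set.
DESTRUCTIVE_SPECIES = (
    "Terminalia macroptera",
    "Ficus sp.",
    "Acacia seyal",
    "Entada africana",
    "Combretum glutinosum",
    "Crosopteryx febrifuga",
    "Anogeisus leiocarpus",
)


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the synthetic generators; defaults are the study conditions."""

    seed: int = 0
    # BEF = intercept + slope * ln(Bstem) + N(0, noise_sd)
    bef_intercept: float = BEF_LNB_COEF["intercept"]
    bef_slope: float = BEF_LNB_COEF["slope"]
    bef_noise_sd: float = 0.05
    # stem dry biomass of destructive trees, log-uniform over this range (kg);
    # the default inverts the observed BEF range 1.46-1.88 through the line
    bstem_range_kg: tuple[float, float] = (4.4, 77.4)
    # height model H = a * DBH^b * exp(N(0, sd)), H in m, DBH in cm
    height_a: float = 1.5
    height_b: float = 0.6
    height_sd: float = 0.1
    # geometric girth taper between breast height, 2.3 m and crown base
    taper_ratio: float = 0.8
    bit_diameter_cm: float = DEFAULT_BIT_DIAMETER_CM
    # NDVI landscape
    n_dates: int = 6
    ndvi_noise_sd: float = 0.02
    # optional rescaling of per-category tree counts to a fixed total
    total_trees: int | None = None

    def __post_init__(self) -> None:
        if self.bef_noise_sd < 0:
            raise ValueError("bef_noise_sd must be >= 0")
        if not 0 < self.taper_ratio <= 1:
            raise ValueError("taper_ratio must lie in (0, 1]")
        if not 0 < self.bstem_range_kg[0] < self.bstem_range_kg[1]:
            raise ValueError("bstem_range_kg must be an increasing positive pair")

    def rng(self, op_tag: int) -> np.random.Generator:
        return np.random.default_rng([int(self.seed), op_tag])


def _truncated_lognormal(
    rng: np.random.Generator, lo: float, hi: float, size: int
) -> np.ndarray:
    """Right-skewed DBH draw on [lo, hi]: log-normal truncated to the range.

    The log-scale mean sits in the lower third of the range and the spread
    covers it, so small stems dominate as in real inventories.
    """
    llo, lhi = math.log(lo), math.log(hi)
    mu = llo + 0.35 * (lhi - llo)
    sigma = (lhi - llo) / 3.0
    a, b = (llo - mu) / sigma, (lhi - mu) / sigma
    z = stats.truncnorm.rvs(a, b, loc=mu, scale=sigma, size=size, random_state=rng)
    return np.exp(z)


def generate_inventory(
    luca_profiles: Sequence[LucaProfile],
    species_profiles: Sequence[SpeciesProfile],
    config: SimulationConfig,
) -> pd.DataFrame:
    """Per-tree inventory grouped into plots, one row per measured tree.

    Columns: ``tree_id, plot_id, luca, species, dbh_cm, height_m, density,
    girth_bh_cm, girth_23_cm, girth_crown_cm, sec1_h_cm, sec2_h_cm,
    sec3_h_cm, crown_base_m``.  Per-category tree counts equal the
    profile's ``n_trees`` (optionally rescaled to ``config.total_trees``);
    every DBH lies inside the category's validity range.
    """
    if not species_profiles:
        raise ValueError("species pool is empty")
    if not luca_profiles:
        raise ValueError("no land-use profiles given")
    rng = config.rng(_OP_INVENTORY)
    species_arr = list(species_profiles)
    weights = np.array([p.n_cores for p in species_arr], dtype=float)
    weights /= weights.sum()

    counts = {p.luca_name: p.n_trees for p in luca_profiles}
    if config.total_trees is not None:
        raw_total = sum(counts.values())
        counts = {
            k: max(1, round(v * config.total_trees / raw_total))
            for k, v in counts.items()
        }

    frames = []
    for prof in luca_profiles:
        n = counts[prof.luca_name]
        lo, hi = prof.dbh_range
        dbh = _truncated_lognormal(rng, lo, hi, n)
        sp_idx = rng.choice(len(species_arr), size=n, p=weights)
        density = np.array(
            [
                max(
                    0.05,
                    species_arr[i].density_mean
                    + rng.normal(0.0, species_arr[i].density_se * math.sqrt(species_arr[i].n_cores)),
                )
                for i in sp_idx
            ]
        )
        height = config.height_a * dbh**config.height_b * np.exp(
            rng.normal(0.0, config.height_sd, size=n)
        )
        g1 = math.pi * dbh
        g2 = g1 * config.taper_ratio
        gcrown = g1 * config.taper_ratio**2
        crown_base = np.maximum(2.4, 0.6 * height)
        n_plots = max(1, prof.n_plots)
        plot_idx = rng.integers(0, n_plots, size=n)
        frames.append(
            pd.DataFrame(
                {
                    "plot_id": [f"{prof.luca_name}-P{j + 1:03d}" for j in plot_idx],
                    "luca": prof.luca_name,
                    "species": [species_arr[i].species_name for i in sp_idx],
                    "dbh_cm": dbh,
                    "height_m": height,
                    "density": density,
                    "girth_bh_cm": g1,
                    "girth_23_cm": g2,
                    "girth_crown_cm": gcrown,
                    "sec1_h_cm": 130.0,
                    "sec2_h_cm": 100.0,
                    "sec3_h_cm": (crown_base - 2.3) * 100.0,
                    "crown_base_m": crown_base,
                }
            )
        )
    out = pd.concat(frames, ignore_index=True)
    out.insert(0, "tree_id", [f"T{i + 1:04d}" for i in range(len(out))])
    return out


def generate_cores(
    species_profiles: Sequence[SpeciesProfile], config: SimulationConfig
) -> pd.DataFrame:
    """Increment-borer cores whose implied densities match the species table.

    Per-core density is drawn as ``N(mean, se * sqrt(n))`` — so the species
    sample mean has standard error ``se`` — and converted to a dry mass via
    the cylinder volume of the core.  Columns: ``core_id, species,
    dry_mass_g, bit_diameter_cm, core_length_cm``.
    """
    if not species_profiles:
        raise ValueError("species pool is empty")
    rng = config.rng(_OP_CORES)
    rows = []
    for prof in species_profiles:
        sd = prof.density_se * math.sqrt(prof.n_cores)
        rho = prof.density_mean + rng.normal(0.0, sd, size=prof.n_cores) if sd > 0 \
            else np.full(prof.n_cores, prof.density_mean)
        rho = np.maximum(rho, 0.05)
        length = rng.uniform(2.0, 6.0, size=prof.n_cores)
        volume = math.pi * config.bit_diameter_cm**2 * length / 4.0
        for j in range(prof.n_cores):
            rows.append(
                {
                    "core_id": f"{prof.species_name[:3].upper()}-{j + 1:02d}",
                    "species": prof.species_name,
                    "dry_mass_g": rho[j] * volume[j],
                    "bit_diameter_cm": config.bit_diameter_cm,
                    "core_length_cm": length[j],
                }
            )
    return pd.DataFrame(rows)


def generate_destructive_set(
    n_trees: int, config: SimulationConfig
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Paired destructive / non-destructive measurements for BEF calibration.

    Returns ``(trees, components)``.  ``trees`` has one row per harvested
    tree with its stem geometry (three girth-measured sections consistent
    with the stem dry biomass and wood density), true stem biomass
    ``bstem_kg``, total biomass ``btot_kg`` and realized ``bef``; BEF
    follows the generating line ``intercept + slope * ln(Bstem)`` plus
    Gaussian noise.  ``components`` holds stem/branches/foliage fresh and
    subsample masses whose dry totals reproduce ``btot_kg`` exactly.
    """
    if n_trees < 3:
        raise ValueError("need at least 3 destructive trees")
    lo, hi = config.bstem_range_kg
    for endpoint in (lo, hi):
        line = config.bef_intercept + config.bef_slope * math.log(endpoint)
        if line < 1.0:
            raise ValueError(
                f"BEF model predicts {line:.3f} < 1 at Bstem={endpoint} kg; "
                "total biomass cannot be below stem biomass"
            )
    rng = config.rng(_OP_DESTRUCTIVE)
    bstem = np.exp(rng.uniform(math.log(lo), math.log(hi), size=n_trees))
    noise = rng.normal(0.0, config.bef_noise_sd, size=n_trees) if config.bef_noise_sd else 0.0
    bef = config.bef_intercept + config.bef_slope * np.log(bstem) + noise
    btot = bstem * bef
    rho = rng.uniform(0.5, 0.9, size=n_trees)
    sec3_h = rng.uniform(100.0, 300.0, size=n_trees)
    t = config.taper_ratio

    tree_rows, comp_rows = [], []
    dry_fraction = {"stem": 0.60, "branches": 0.55, "foliage": 0.35}
    for i in range(n_trees):
        tree_id = f"D{i + 1:03d}"
        volume_cm3 = 1000.0 * bstem[i] / rho[i]
        # unit volumes of the three frustum sections at girth G1 = 1
        u = (
            130.0 * 3.0
            + 100.0 * (1.0 + t**2 + t)
            + sec3_h[i] * (t**2 + t**4 + t**3)
        ) / (12.0 * math.pi)
        g1 = math.sqrt(volume_cm3 / u)
        dry = {
            "stem": bstem[i],
            "branches": 0.8 * (btot[i] - bstem[i]),
            "foliage": 0.2 * (btot[i] - bstem[i]),
        }
        for comp, dmass in dry.items():
            fresh = dmass / dry_fraction[comp] if dmass > 0 else 0.0
            fms = min(1.0, fresh) if fresh > 0 else 1.0
            dms = fms * (dmass / fresh) if fresh > 0 else 0.0
            comp_rows.append(
                {
                    "tree_id": tree_id,
                    "component": comp,
                    "fresh_mass_kg": fresh,
                    "sample_fresh_kg": fms,
                    "sample_dry_kg": dms,
                }
            )
        tree_rows.append(
            {
                "tree_id": tree_id,
                "species": DESTRUCTIVE_SPECIES[i % len(DESTRUCTIVE_SPECIES)],
                "density": rho[i],
                "girth_bh_cm": g1,
                "girth_23_cm": g1 * t,
                "girth_crown_cm": g1 * t**2,
                "sec1_h_cm": 130.0,
                "sec2_h_cm": 100.0,
                "sec3_h_cm": sec3_h[i],
                "bstem_kg": bstem[i],
                "btot_kg": btot[i],
                "bef": bef[i] if np.ndim(bef) else float(bef),
            }
        )
    return pd.DataFrame(tree_rows), pd.DataFrame(comp_rows)


def generate_landscape(
    luca_profiles: Sequence[LucaProfile],
    grid_shape: tuple[int, int],
    config: SimulationConfig,
) -> tuple[Grid, np.ndarray]:
    """A land-use raster plus a multi-date NDVI-like stack over it.

    Cell counts per class are proportional to class areas (largest-
    remainder apportionment, so they sum to the grid size exactly); class
    codes are 1-based in profile order.  The NDVI stack has
    ``config.n_dates`` dates with class-specific means equally spaced in
    [0.15, 0.75] plus Gaussian noise, clipped to [-1, 1].
    """
    nrows, ncols = grid_shape
    if nrows <= 0 or ncols <= 0:
        raise ValueError("grid_shape must be positive")
    rng = config.rng(_OP_LANDSCAPE)
    areas = np.array([p.area_ha for p in luca_profiles], dtype=float)
    n_cells = nrows * ncols
    quota = areas / areas.sum() * n_cells
    counts = np.floor(quota).astype(int)
    remainder = quota - counts
    for idx in np.argsort(-remainder)[: n_cells - counts.sum()]:
        counts[idx] += 1

    codes = np.repeat(np.arange(1, len(luca_profiles) + 1), counts)
    rng.shuffle(codes)
    lulc = codes.reshape(nrows, ncols).astype(float)

    class_means = np.linspace(0.15, 0.75, len(luca_profiles))
    mean_map = class_means[lulc.astype(int) - 1]
    stack = np.clip(
        mean_map[None, :, :]
        + rng.normal(0.0, config.ndvi_noise_sd, size=(config.n_dates, nrows, ncols)),
        -1.0,
        1.0,
    )
    return Grid(data=lulc, cellsize=30.0, nodata=DEFAULT_NODATA), stack


def with_seed(config: SimulationConfig, seed: int) -> SimulationConfig:
    """A copy of ``config`` with a different master seed."""
    return replace(config, seed=seed)
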