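"""From plot inventories to watershed-level biomass stocks.

Each plot's aboveground biomass (sum of per-tree predictions from the
land-use model, plus a pluggable equation for palm species the models do
not cover) is converted to a density in Mg ha^-1.  Land-use classes are
summarised by the plot mean, its standard error, the half-width of the
~95 % confidence interval as a percentage of the mean
(100 * z * SE / mean, z = 1.96), and the total stock = mean density x
class area.  Class stocks combine into group totals with standard errors
added in quadrature (plots are sampled independently per class), and class
means paint a wall-to-wall density raster from a land-use map.
"""

from __future__ import annotations

import math
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .allometry import AllometricModel, predict_agb
from .study import SPECIAL_SPECIES

KG_PER_MG = 1000.0


def pct_error(mean: float, se: float, z: float = 1.96) -> float:
    """Half-width of the z-level confidence interval as % of the mean."""
    if mean == 0:
        raise ValueError("percent error undefined for zero mean")
    return 100.0 * z * se / mean


def plot_density(
    plot_trees: pd.DataFrame,
    models_by_luca: Mapping[str, AllometricModel],
    plot_area_ha: float,
    special_species_hook: Callable[[pd.DataFrame], float] | None = None,
    special_species: Sequence[str] = SPECIAL_SPECIES,
) -> float:
    """AGB density of one plot, Mg ha^-1.

    ``plot_trees`` holds the trees of a single plot (columns ``luca``,
    ``species``, ``dbh_cm`` and, as required by the models, ``height_m``
    and ``density``).  Trees of ``special_species`` are routed to
    ``special_species_hook`` (a callable returning their summed AGB in kg);
    all others go through their land-use category's fitted model.
    """
    if plot_area_ha <= 0:
        raise ValueError("plot area must be positive")
    if plot_trees.empty:
        return 0.0
    special_mask = plot_trees["species"].isin(special_species)
    special = plot_trees[special_mask]
    regular = plot_trees[~special_mask]

    total_kg = 0.0
    if not special.empty:
        if special_species_hook is None:
            raise ValueError(
                "no model covers species "
                f"{sorted(special['species'].unique())} and no hook was supplied"
            )
        total_kg += float(special_species_hook(special))

    for luca, grp in regular.groupby("luca"):
        model = models_by_luca.get(luca) or models_by_luca.get("generic")
        if model is None:
            raise ValueError(f"no allometric model for land-use category {luca!r}")
        agb, _ = predict_agb(
            model,
            grp["dbh_cm"].to_numpy(),
            grp["height_m"].to_numpy() if "height_m" in grp.columns else None,
            grp["density"].to_numpy() if "density" in grp.columns else None,
        )
        total_kg += float(np.sum(agb))
    return total_kg / KG_PER_MG / plot_area_ha


def summarize_lulc(
    plot_densities: pd.DataFrame,
    areas_ha: Mapping[str, float],
    z: float = 1.96,
) -> pd.DataFrame:
    """Per-class density and stock summary.

    ``plot_densities`` needs columns ``plot_id``, ``lulc``,
    ``agb_density`` (Mg ha^-1).  Returns one row per class with
    ``n_plots, mean_density, se_density, pct_error, area_ha, total_stock,
    se_stock, min_density, max_density``; the SE columns are NaN for
    single-plot classes.
    """
    rows = []
    for lulc, grp in plot_densities.groupby("lulc", sort=True):
        dens = grp["agb_density"].to_numpy(dtype=float)
        n = len(dens)
        if lulc not in areas_ha:
            raise ValueError(f"no area for class {lulc!r}")
        area = float(areas_ha[lulc])
        mean = float(dens.mean())
        if n >= 2:
            se = float(dens.std(ddof=1) / math.sqrt(n))
            perr = pct_error(mean, se, z) if mean != 0 else 0.0
        else:
            se = float("nan")
            perr = float("nan")
        rows.append(
            {
                "lulc": lulc,
                "n_plots": n,
                "mean_density": mean,
                "se_density": se,
                "pct_error": perr,
                "area_ha": area,
                "total_stock": mean * area,
                "se_stock": se * area if not math.isnan(se) else float("nan"),
                "min_density": float(dens.min()),
                "max_density": float(dens.max()),
            }
        )
    return pd.DataFrame(rows)


def aggregate_stocks(
    summaries: pd.DataFrame, grouping: Mapping[str, Sequence[str]]
) -> pd.DataFrame:
    """Combine class stocks into group totals.

    ``grouping`` maps group name -> member class names (a partition of the
    summary rows that appear in any group).  Group SE combines member stock
    SEs in quadrature.
    """
    by_class = summaries.set_index("lulc")
    rows = []
    for group, members in grouping.items():
        members = [m for m in members if m in by_class.index]
        if not members:
            continue
        sub = by_class.loc[members]
        se_sq = sub["se_stock"].to_numpy(dtype=float) ** 2
        row = {
            "group": group,
            "n_classes": len(members),
            "total_stock": float(sub["total_stock"].sum()),
            "se_stock": float(np.sqrt(np.nansum(se_sq))),
        }
        if "area_ha" in sub.columns:
            row["area_ha"] = float(sub["area_ha"].sum())
        rows.append(row)
    return pd.DataFrame(rows)


def density_map(
    lulc_grid: np.ndarray,
    class_density: Mapping[int | str, float],
    nodata: float = -9999.0,
) -> np.ndarray:
    """Paint each land-use cell with its class mean density, Mg ha^-1.

    ``lulc_grid`` holds class codes; cells equal to ``nodata`` stay nodata.
    Unknown class codes raise.
    """
    grid = np.asarray(lulc_grid)
    out = np.full(grid.shape, nodata, dtype=float)
    valid = grid != nodata
    codes = np.unique(grid[valid])
    unknown = [c for c in codes if c not in class_density]
    if unknown:
        raise ValueError(f"no density for land-use class codes {unknown}")
    for code in codes:
        out[grid == code] = class_density[code]
    return out


def map_total_stock(
    density_raster: np.ndarray, cell_area_ha: float, nodata: float = -9999.0
) -> float:
    """Integrate a density raster into a total stock, Mg."""
    valid = density_raster != nodata
    return float(density_raster[valid].sum() * cell_area_ha)
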