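"""Built-in description of the Dassari-watershed study conditions.

The package ships the published field-design tables as plain data so the
synthetic generators and the worked examples can reproduce the study setup
without any external files: per-species basic wood densities from increment
cores, the land-use sampling design (plot counts, plot dimensions, class
areas) and the published per-class biomass-density summaries used for
cross-checking the upscaling arithmetic.

Units: densities g cm^-3, areas ha, DBH cm, biomass density Mg ha^-1,
stocks Mg.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

#: Total watershed area, ha (192.57 km^2).
WATERSHED_AREA_HA = 19257.0


@dataclass(frozen=True)
class SpeciesProfile:
    """Species-level wood-density summary from increment-borer cores."""

    species_name: str
    density_mean: float  # g cm^-3
    density_se: float  # g cm^-3, standard error of the mean
    n_cores: int
    dbh_min: float  # cm, range of the sampled trees
    dbh_max: float  # cm

    def __post_init__(self) -> None:
        if self.density_mean <= 0:
            raise ValueError(f"{self.species_name}: density_mean must be > 0")
        if not self.dbh_min < self.dbh_max:
            raise ValueError(f"{self.species_name}: dbh_min must be < dbh_max")
        if self.n_cores < 1:
            raise ValueError(f"{self.species_name}: n_cores must be >= 1")


@dataclass(frozen=True)
class LucaProfile:
    """Sampling design of one land-use category (LUCa)."""

    luca_name: str
    dbh_range: tuple[float, float]  # cm, validity domain of the fitted models
    n_trees: int  # trees measured in the category
    n_plots: int
    plot_dims: tuple[float, float]  # m x m
    area_ha: float

    def __post_init__(self) -> None:
        lo, hi = self.dbh_range
        if not (0 < lo < hi < 200):
            raise ValueError(f"{self.luca_name}: dbh_range must lie within (0, 200)")
        if self.n_plots < 0:
            raise ValueError(f"{self.luca_name}: n_plots must be >= 0")
        if self.area_ha <= 0:
            raise ValueError(f"{self.luca_name}: area_ha must be > 0")

    @property
    def plot_area_ha(self) -> float:
        return self.plot_dims[0] * self.plot_dims[1] / 10_000.0


# Basic wood density of the 15 main species (mean, SE, n, DBH range of the
# cored trees).  n sums to 270, the full non-destructive sample.
MAIN_SPECIES: tuple[SpeciesProfile, ...] = (
    SpeciesProfile("Terminalia macroptera", 0.821, 0.010, 19, 9.3, 40.7),
    SpeciesProfile("Acacia seyal", 0.751, 0.015, 16, 7.6, 34.4),
    SpeciesProfile("Combretum glutinosum", 0.877, 0.013, 11, 7.9, 31.9),
    SpeciesProfile("Pterocarpus erinaceus", 0.826, 0.015, 21, 6.9, 44.7),
    SpeciesProfile("Anogeisus leiocarpus", 0.889, 0.012, 16, 6.9, 32.4),
    SpeciesProfile("Mitragyna inermis", 0.631, 0.008, 18, 7.0, 34.5),
    SpeciesProfile("Lannea microcrapa", 0.546, 0.011, 22, 7.0, 50.6),
    SpeciesProfile("Lannea acida", 0.573, 0.027, 6, 10.8, 35.9),
    SpeciesProfile("Ficus sp.", 0.528, 0.010, 21, 8.6, 52.7),
    SpeciesProfile("Crosopteryx febrifuga", 0.704, 0.016, 18, 5.6, 30.5),
    SpeciesProfile("Entada africana", 0.631, 0.010, 15, 8.4, 27.6),
    SpeciesProfile("Parkia biglobosa", 0.630, 0.006, 23, 8.6, 62.4),
    SpeciesProfile("Vitelaria paradoxa", 0.838, 0.016, 23, 8.0, 53.8),
    SpeciesProfile("Azadirachta indica", 0.763, 0.018, 16, 8.8, 50.5),
    SpeciesProfile("Anacardium occidentale", 0.569, 0.006, 25, 9.2, 57.9),
)

# Modelling categories: DBH validity domain and per-category sample size of
# the allometric fits.  n_plots/plot_dims/area aggregate the member LULC
# classes of the sampling design below.
MODEL_LUCAS: tuple[LucaProfile, ...] = (
    LucaProfile("forest land", (5.6, 44.7), 181, 92, (30.0, 30.0), 10100.29),
    LucaProfile("grassland", (7.6, 40.7), 90, 34, (30.0, 30.0), 96.57),
    LucaProfile("cropland", (6.9, 62.4), 178, 80, (30.0, 30.0), 8044.47),
    LucaProfile("settlement", (7.0, 52.7), 63, 8, (100.0, 100.0), 488.34),
    LucaProfile("agroforestry", (9.2, 57.9), 25, 13, (10.0, 20.0), 20.7),
)

# The finer land-use/land-cover sampling design (plot counts and class areas).
LULC_DESIGN: tuple[LucaProfile, ...] = (
    LucaProfile("riparian forest and woodland", (5.6, 44.7), 18, 9, (30.0, 30.0), 341.19),
    LucaProfile("Savanna Woodland", (5.6, 44.7), 54, 27, (30.0, 30.0), 5476.54),
    LucaProfile("shrub Savanna", (5.6, 44.7), 109, 56, (30.0, 30.0), 4282.56),
    LucaProfile("grassland", (7.6, 40.7), 90, 34, (30.0, 30.0), 96.57),
    LucaProfile("cropland and fallow", (6.9, 62.4), 178, 80, (30.0, 30.0), 8044.47),
    LucaProfile("settlement", (7.0, 52.7), 63, 8, (100.0, 100.0), 488.34),
    LucaProfile("agroforestry", (9.2, 57.9), 25, 13, (10.0, 20.0), 20.7),
    LucaProfile("plantation", (7.0, 60.0), 46, 23, (10.0, 20.0), 17.1),
)

#: Grouping of LULC classes into IPCC-style land-use categories.
LULC_GROUPS: dict[str, tuple[str, ...]] = {
    "Forest land": ("riparian forest and woodland", "Savanna Woodland", "shrub Savanna"),
    "Grassland": ("grassland",),
    "Cropland": ("cropland and fallow",),
    "Settlements": ("settlement",),
    "Agroforestry": ("agroforestry",),
    "Plantation": ("E. grandis", "T. grandis", "A. indica", "G. arborea"),
}

# Published per-class biomass summaries: mean density (SE) Mg ha^-1,
# percent error and total stock Mg.  Used as reference inputs for the
# uncertainty-convention and stock-aggregation cross-checks.
PUBLISHED_LULC_SUMMARY = pd.DataFrame(
    [
        ("riparian forest and woodland", 94.58, 4.98, 10.33, 32271.87),
        ("Savanna Woodland", 45.29, 2.51, 10.89, 248050.22),
        ("shrub Savanna", 14.05, 0.72, 10.11, 60212.61),
        ("grassland", 3.62, 0.36, 19.68, 349.66),
        ("cropland and fallow", 3.28, 0.31, 19.02, 26409.82),
        ("settlement", 4.86, 1.03, 41.59, 2375.84),
        ("agroforestry", 46.06, 14.40, 61.28, 1132.73),
        ("E. grandis", 204.92, 57.69, 55.17, 2819.78),
        ("T. grandis", 162.00, 64.88, 78.50, 145.80),
        ("A. indica", 179.62, 57.61, 62.86, 129.33),
        ("G. arborea", 25.17, 7.46, 58.09, 43.29),
    ],
    columns=["lulc", "mean_density", "se_density", "pct_error", "total_stock"],
)

#: Published biomass-expansion-factor regression on ln(stem dry biomass),
#: fitted on 13 destructively sampled trees.
BEF_LNB_COEF = {"intercept": 1.24155, "slope": 0.14701,
                "se_intercept": 0.09253, "se_slope": 0.02968, "n": 13}
#: Alternative published regression of BEF on DBH (cm).
BEF_DBH_COEF = {"intercept": 1.25801, "slope": 0.0314,
                "se_intercept": 0.07697, "se_slope": 0.00543, "n": 13}

#: Species handled by a dedicated palm/coconut equation instead of the
#: fitted land-use models.
SPECIAL_SPECIES: tuple[str, ...] = ("Phoenix reclinata", "Borassus flabellifer")

#: Species excluded from the importance-value ranking (baobab plus the two
#: palm species above).
IVI_EXCLUSIONS: tuple[str, ...] = (
    "Adansonia digitata",
    "Phoenix reclinata",
    "Borassus flabellifer",
)


def total_sampled_area_ha(profiles: tuple[LucaProfile, ...] = LULC_DESIGN) -> float:
    """Total inventoried area: sum of plot counts times plot area, ha."""
    return float(sum(p.n_plots * p.plot_area_ha for p in profiles))


def area_percentages(
    profiles: tuple[LucaProfile, ...] = LULC_DESIGN,
    watershed_area_ha: float = WATERSHED_AREA_HA,
) -> pd.Series:
    """Class area as a percentage of the watershed area."""
    return pd.Series(
        {p.luca_name: 100.0 * p.area_ha / watershed_area_ha for p in profiles}
    )
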