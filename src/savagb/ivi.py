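"""Importance value index (IVI) of tree species in a plot network.

Following the Curtis convention, the importance of species i is

    IVI_i = RD_i + RF_i + RDom_i

where RD is relative density (share of stems per unit sampled area), RF is
relative frequency (plot-presence share, normalized over species) and RDom
is relative dominance (share of basal area).  Each component sums to 100
over species, so IVI sums to 300.  The ranked table drives the selection of
the main species used for allometric model development.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

_REQUIRED = {"plot_id", "species", "stem_count", "basal_area_cm2"}


def _check(occurrences: pd.DataFrame) -> pd.DataFrame:
    missing = _REQUIRED - set(occurrences.columns)
    if missing:
        raise ValueError(f"occurrence table missing columns: {sorted(missing)}")
    occ = occurrences.copy()
    if (occ["stem_count"] < 0).any() or (occ["basal_area_cm2"] < 0).any():
        raise ValueError("stem counts and basal areas must be non-negative")
    return occ


def _plot_areas(occ: pd.DataFrame, plot_areas_ha: pd.Series | None) -> pd.Series:
    plots = occ["plot_id"].unique()
    if plot_areas_ha is None:
        return pd.Series(1.0, index=plots)
    missing = set(plots) - set(plot_areas_ha.index)
    if missing:
        raise ValueError(f"no area for plots: {sorted(missing)}")
    return plot_areas_ha


def relative_density(
    occurrences: pd.DataFrame,
    species: str,
    plot_areas_ha: pd.Series | None = None,
) -> float:
    """Stem density of one species as a percentage of total stem density."""
    occ = _check(occurrences)
    total = occ["stem_count"].sum()
    if total <= 0:
        raise ValueError("no stems in the occurrence table")
    # density = stems / total sampled area; the common denominator cancels
    # in the ratio, so relative density is the stem share.
    return 100.0 * occ.loc[occ["species"] == species, "stem_count"].sum() / total


def relative_frequency(occurrences: pd.DataFrame, species: str) -> float:
    """Plot-presence frequency of a species, normalized over all species."""
    occ = _check(occurrences)
    n_plots = occ["plot_id"].nunique()
    present = occ[occ["stem_count"] > 0]
    freq = present.groupby("species")["plot_id"].nunique() / n_plots
    total = freq.sum()
    if total <= 0:
        raise ValueError("no species present in any plot")
    return 100.0 * freq.get(species, 0.0) / total


def relative_dominance(occurrences: pd.DataFrame, species: str) -> float:
    """Basal-area share of a species, percent."""
    occ = _check(occurrences)
    total = occ["basal_area_cm2"].sum()
    if total <= 0:
        raise ValueError("total basal area is zero")
    return 100.0 * occ.loc[occ["species"] == species, "basal_area_cm2"].sum() / total


def ivi_table(
    occurrences: pd.DataFrame,
    exclusions: tuple[str, ...] = (),
    top_k: int = 15,
    plot_areas_ha: pd.Series | None = None,
) -> pd.DataFrame:
    """Ranked IVI table over all non-excluded species.

    Returns a DataFrame with columns ``species, rd, rf, rdom, ivi, rank,
    selected_main_species``; IVI sums to 300 over the table.  Ranking is
    descending by IVI with alphabetical tie-break; the first ``top_k``
    species are marked as main species.
    """
    occ = _check(occurrences)
    occ = occ[~occ["species"].isin(exclusions)]
    if occ.empty:
        raise ValueError("no species remain after exclusions")
    _plot_areas(occ, plot_areas_ha)  # validates coverage when areas given

    stems = occ.groupby("species")["stem_count"].sum()
    basal = occ.groupby("species")["basal_area_cm2"].sum()
    n_plots = occ["plot_id"].nunique()
    freq = (
        occ[occ["stem_count"] > 0].groupby("species")["plot_id"].nunique() / n_plots
    ).reindex(stems.index, fill_value=0.0)

    rd = 100.0 * stems / stems.sum()
    rdom = 100.0 * basal / basal.sum() if basal.sum() > 0 else basal * 0.0
    rf = 100.0 * freq / freq.sum()

    table = pd.DataFrame({"species": stems.index, "rd": rd.values,
                          "rf": rf.values, "rdom": rdom.values})
    table["ivi"] = table["rd"] + table["rf"] + table["rdom"]
    table = table.sort_values(["ivi", "species"], ascending=[False, True],
                              kind="mergesort").reset_index(drop=True)
    table["rank"] = np.arange(1, len(table) + 1)
    if top_k > len(table):
        warnings.warn(
            f"top_k={top_k} exceeds the {len(table)} available species; "
            "selecting all", stacklevel=2,
        )
    table["selected_main_species"] = table["rank"] <= top_k
    return table


def basal_area_cm2(dbh_cm: float | np.ndarray) -> float | np.ndarray:
    """Cross-sectional stem area at breast height, pi * DBH^2 / 4, cm^2."""
    d = np.asarray(dbh_cm, dtype=float)
    out = np.pi * d**2 / 4.0
    return float(out) if np.ndim(out) == 0 else out


def occurrences_from_inventory(inventory: pd.DataFrame) -> pd.DataFrame:
    """Collapse a per-tree inventory into per-plot per-species occurrences.

    ``inventory`` needs columns ``plot_id``, ``species``, ``dbh_cm`` (and
    optionally ``luca``, carried through).
    """
    inv = inventory.copy()
    inv["basal_area_cm2"] = basal_area_cm2(inv["dbh_cm"].to_numpy())
    keys = ["plot_id", "species"] + (["luca"] if "luca" in inv.columns else [])
    out = (
        inv.groupby(keys, sort=True)
        .agg(stem_count=("species", "size"), basal_area_cm2=("basal_area_cm2", "sum"))
        .reset_index()
    )
    return out
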