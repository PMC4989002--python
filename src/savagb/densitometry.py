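"""Basic wood density from increment-borer cores.

A core extracted with an increment borer is a cylinder of known diameter
(the borer bit, 0.5 cm in the field protocol) and measured length; after
oven-drying, basic density is dry mass over fresh cylinder volume:

    rho = 4 * dMS / (pi * d^2 * L)      [g cm^-3]

Species are then summarised by the mean, its standard error, and the
observed min/max, one core per tree.
"""

from __future__ import annotations

import math
import warnings

import numpy as np
import pandas as pd

#: Densities above this are physically implausible for wood and flagged.
SUSPECT_DENSITY = 1.5

#: Inner diameter of the increment-borer bit, cm.
DEFAULT_BIT_DIAMETER_CM = 0.5


def core_density(
    dry_mass_g: float | np.ndarray,
    bit_diameter_cm: float | np.ndarray = DEFAULT_BIT_DIAMETER_CM,
    core_length_cm: float | np.ndarray = 3.0,
) -> float | np.ndarray:
    """Basic wood density of a core, g cm^-3.

    Parameters are scalar or array-like; arrays broadcast.  Raises
    ``ValueError`` on non-positive bit diameter or core length, or negative
    dry mass.  A zero dry mass yields zero density (an empty core).
    """
    m = np.asarray(dry_mass_g, dtype=float)
    d = np.asarray(bit_diameter_cm, dtype=float)
    length = np.asarray(core_length_cm, dtype=float)
    if np.any(d <= 0) or np.any(length <= 0):
        raise ValueError("bit diameter and core length must be positive")
    if np.any(m < 0):
        raise ValueError("dry mass must be non-negative")
    rho = 4.0 * m / (math.pi * d**2 * length)
    if np.any(rho > SUSPECT_DENSITY):
        warnings.warn(
            f"core density above {SUSPECT_DENSITY} g cm^-3 is physically "
            "suspect for wood; value kept",
            stacklevel=2,
        )
    if np.ndim(rho) == 0:
        return float(rho)
    return rho


def species_summary(cores: pd.DataFrame) -> pd.DataFrame:
    """Per-species density summary from a table of cores.

    ``cores`` needs columns ``species``, ``dry_mass_g``, ``bit_diameter_cm``,
    ``core_length_cm`` (a precomputed ``density`` column is used as-is when
    present).  Returns one row per species with columns ``species``, ``n``,
    ``mean_density``, ``se``, ``min_density``, ``max_density``, sorted by
    species name.  The SE is the sample (n-1) standard deviation over
    sqrt(n); a single core yields SE 0.
    """
    df = cores.copy()
    if "density" not in df.columns:
        df["density"] = core_density(
            df["dry_mass_g"].to_numpy(),
            df["bit_diameter_cm"].to_numpy(),
            df["core_length_cm"].to_numpy(),
        )

    def _summ(g: pd.Series) -> pd.Series:
        n = len(g)
        sd = g.std(ddof=1) if n > 1 else 0.0
        return pd.Series(
            {
                "n": n,
                "mean_density": g.mean(),
                "se": sd / math.sqrt(n),
                "min_density": g.min(),
                "max_density": g.max(),
            }
        )

    out = (
        df.groupby("species", sort=True)["density"]
        .apply(_summ)
        .unstack()
        .reset_index()
    )
    out["n"] = out["n"].astype(int)
    return out
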