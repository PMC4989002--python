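"""Non-destructive stem biomass and the biomass expansion factor (BEF).

The stem is measured in sections (girth at the lower and upper end, section
length); each section is treated as the frustum of a cone, giving

    V = H * (C1^2 + C2^2 + C1*C2) / (12*pi)     [cm^3, lengths in cm]

since for a circle the cross-sectional area is C^2 / (4*pi).  Dry stem
biomass follows from basic wood density, B = rho * V / 1000 [kg].  For
destructively sampled trees the total dry biomass is the sum over stem,
branches and foliage of fresh mass scaled by the dry:fresh ratio of an
oven-dried subsample, and the biomass expansion factor is

    BEF = Btot / Bstem,

modelled as a linear function of ln(Bstem) (or of DBH) by ordinary least
squares.  Applying the fitted BEF to a non-destructively measured stem
yields total aboveground biomass, AGB = Bstem * BEF(Bstem).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .allometry import aicc

CM_PER_M = 100.0

Predictor = Literal["ln_stem_biomass", "dbh"]


@dataclass(frozen=True)
class StemSection:
    """One stem section: length and end girths, all in cm.

    ``girth_lower`` is the greater girth (toward the stem base) and
    ``girth_upper`` the smaller one.
    """

    height_cm: float
    girth_lower_cm: float
    girth_upper_cm: float

    def __post_init__(self) -> None:
        if self.height_cm <= 0:
            raise ValueError("section height must be positive")
        if self.girth_upper_cm < 0 or self.girth_lower_cm < self.girth_upper_cm:
            raise ValueError("girths must satisfy C1 >= C2 >= 0")


@dataclass(frozen=True)
class BefModel:
    """Fitted BEF regression: BEF = beta0 + beta1 * x, x = ln(Bstem) or DBH."""

    predictor: Predictor
    beta0: float
    beta1: float
    se_beta0: float
    se_beta1: float
    residual_sd: float
    n: int
    r_squared: float
    loglik: float = float("nan")

    def bef(self, x_raw: float | np.ndarray) -> float | np.ndarray:
        """BEF at a raw predictor value (stem biomass in kg, or DBH in cm)."""
        x = np.asarray(x_raw, dtype=float)
        if self.predictor == "ln_stem_biomass":
            if np.any(x <= 0):
                raise ValueError("stem biomass must be positive")
            x = np.log(x)
        out = self.beta0 + self.beta1 * x
        return float(out) if np.ndim(out) == 0 else out

    @property
    def aicc(self) -> float:
        # 2 slopes-and-intercept coefficients + residual variance
        return aicc(self.loglik, 3, self.n)


def section_volume(section: StemSection) -> float:
    """Frustum volume of one stem section, cm^3 (all lengths in cm)."""
    c1, c2 = section.girth_lower_cm, section.girth_upper_cm
    return section.height_cm * (c1**2 + c2**2 + c1 * c2) / (12.0 * math.pi)


def stem_biomass(sections: Iterable[StemSection], density: float) -> float:
    """Dry stem biomass, kg: sum over sections of rho * V / 1000.

    ``density`` is basic wood density in g cm^-3.
    """
    if density is None or not density > 0:
        raise ValueError("wood density must be positive")
    sections = list(sections)
    if not sections:
        raise ValueError("at least one stem section is required")
    return sum(density * section_volume(s) / 1000.0 for s in sections)


def stem_biomass_table(trees: pd.DataFrame) -> pd.Series:
    """Vectorized stem biomass (kg) for trees measured in three sections.

    Expects girth columns ``girth_bh_cm, girth_23_cm, girth_crown_cm``,
    section lengths ``sec1_h_cm, sec2_h_cm, sec3_h_cm`` and basic wood
    ``density`` (g cm^-3).  Sections run base->breast height (cylindric at
    girth G1), breast height->2.3 m (G1->G2) and 2.3 m->crown base
    (G2->Gcrown), each a cone frustum.
    """
    g1 = trees["girth_bh_cm"].to_numpy(dtype=float)
    g2 = trees["girth_23_cm"].to_numpy(dtype=float)
    g3 = trees["girth_crown_cm"].to_numpy(dtype=float)
    h1 = trees["sec1_h_cm"].to_numpy(dtype=float)
    h2 = trees["sec2_h_cm"].to_numpy(dtype=float)
    h3 = trees["sec3_h_cm"].to_numpy(dtype=float)
    rho = trees["density"].to_numpy(dtype=float)
    if np.any(rho <= 0):
        raise ValueError("wood density must be positive for every tree")
    volume = (
        h1 * 3.0 * g1**2
        + h2 * (g1**2 + g2**2 + g1 * g2)
        + h3 * (g2**2 + g3**2 + g2 * g3)
    ) / (12.0 * math.pi)
    return pd.Series(rho * volume / 1000.0, index=trees.index, name="bstem_kg")


def destructive_total(components: pd.DataFrame | Sequence[tuple[float, float, float]]) -> float:
    """Total dry biomass of a harvested tree, kg.

    ``components`` holds (fresh_mass_kg, sample_fresh_kg, sample_dry_kg) for
    stem, branches and foliage, either as a sequence of triples or as a
    DataFrame with those columns.  Each component contributes
    fresh mass * (sample dry / sample fresh); a zero fresh mass contributes
    nothing, a zero subsample fresh mass is an error.
    """
    if isinstance(components, pd.DataFrame):
        rows = components[["fresh_mass_kg", "sample_fresh_kg", "sample_dry_kg"]].to_numpy()
    else:
        rows = np.asarray(list(components), dtype=float)
    total = 0.0
    for fm, fms, dms in rows:
        if fm == 0:
            continue
        if fms <= 0:
            raise ValueError("subsample fresh mass must be positive")
        if dms > fms:
            raise ValueError("subsample dry mass cannot exceed its fresh mass")
        total += fm * dms / fms
    return float(total)


def bef(btot_kg: float, bstem_kg: float) -> float:
    """Biomass expansion factor Btot/Bstem; warns when < 1."""
    if bstem_kg <= 0:
        raise ValueError("stem biomass must be positive")
    ratio = btot_kg / bstem_kg
    if ratio < 1.0:
        warnings.warn(
            "BEF < 1 (total biomass below stem biomass) is physically "
            "suspect; value kept",
            stacklevel=2,
        )
    return ratio


def fit_bef_model(
    x: np.ndarray | Sequence[float],
    bef_values: np.ndarray | Sequence[float],
    predictor: Predictor = "ln_stem_biomass",
) -> BefModel:
    """Ordinary least squares of BEF on ln(stem biomass) or on DBH.

    ``x`` is raw stem dry biomass (kg) for the ``ln_stem_biomass`` predictor
    (log taken internally) or DBH (cm) for the ``dbh`` predictor.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(bef_values, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need at least 3 paired observations")
    if predictor == "ln_stem_biomass":
        if np.any(x <= 0):
            raise ValueError("stem biomass must be positive for the log predictor")
        x = np.log(x)
    elif predictor != "dbh":
        raise ValueError(f"unknown predictor {predictor!r}")
    if np.ptp(x) == 0:
        raise ValueError("predictor has zero variance")
    res = sm.OLS(y, sm.add_constant(x)).fit()
    resid_sd = float(np.sqrt(res.ssr / res.df_resid)) if res.df_resid > 0 else 0.0
    return BefModel(
        predictor=predictor,
        beta0=float(res.params[0]),
        beta1=float(res.params[1]),
        se_beta0=float(res.bse[0]),
        se_beta1=float(res.bse[1]),
        residual_sd=resid_sd,
        n=int(res.nobs),
        r_squared=float(res.rsquared),
        loglik=float(res.llf),
    )


def predict_agb_from_stem(bstem_kg: float | np.ndarray, model: BefModel) -> float | np.ndarray:
    """Total aboveground biomass from stem biomass via the fitted BEF, kg."""
    if model.predictor != "ln_stem_biomass":
        raise ValueError("AGB prediction from stem biomass needs the ln-Bstem model")
    b = np.asarray(bstem_kg, dtype=float)
    if np.any(b <= 0):
        raise ValueError("stem biomass must be positive")
    factor = model.bef(b)
    if np.any(np.asarray(factor) <= 0):
        raise ValueError("predicted BEF is non-positive; outside model domain")
    out = b * factor
    return float(out) if np.ndim(out) == 0 else out


def compare_methods(
    observed_btot: Sequence[float], predicted_agb: Sequence[float]
) -> tuple[float, float, float]:
    """Destructive vs non-destructive totals.

    Returns (mean signed percent deviation, mean absolute percent deviation,
    Pearson correlation).  Positive signed deviation means the
    non-destructive prediction overestimates.
    """
    obs = np.asarray(observed_btot, dtype=float)
    pred = np.asarray(predicted_agb, dtype=float)
    if len(obs) != len(pred) or len(obs) < 2:
        raise ValueError("need at least 2 paired observations")
    if np.any(obs <= 0):
        raise ValueError("observed totals must be positive")
    pct = 100.0 * (pred - obs) / obs
    r = float(stats.pearsonr(obs, pred).statistic)
    return float(pct.mean()), float(np.abs(pct).mean()), r


def compare_bef_models(model_a: BefModel, model_b: BefModel) -> dict:
    """AICc / likelihood comparison of two BEF regressions on the same trees.

    Both models have the same parameter count, so the AICc difference equals
    twice the log-likelihood difference.
    """
    if model_a.n != model_b.n:
        raise ValueError("models were not fitted on the same sample")
    delta = model_a.aicc - model_b.aicc
    preferred = model_a if delta <= 0 else model_b
    return {
        "aicc": {model_a.predictor: model_a.aicc, model_b.predictor: model_b.aicc},
        "delta_aicc": abs(delta),
        "loglik_ratio": 2.0 * abs(model_a.loglik - model_b.loglik),
        "preferred": preferred.predictor,
        "clearly_different": abs(delta) > 2.0,
    }
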