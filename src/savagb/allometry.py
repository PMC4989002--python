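"""Land-use-stratified allometric models for tree aboveground biomass.

AGB (kg, dry) is modelled by a gamma GLM with a log link on untransformed
predictors: DBH (cm), total height H (m) and basic wood density rho
(g cm^-3).  Three nested model types are supported:

    type I    AGB ~ DBH
    type II   AGB ~ DBH + H + DBH:H
    type III  AGB ~ DBH + H + rho + DBH:H + DBH:rho + H:rho

Starting from the full structure of a type, two-way interactions (and, for
type III, the rho main effect once none of its interactions remain) are
removed backward whenever removal lowers the small-sample-corrected AIC
(AICc) by at least 2, respecting marginality; DBH and H main effects and
the intercept are never removed.  Goodness of fit is reported as explained
deviance and Nagelkerke's pseudo-R^2; coefficient standard errors use the
Pearson-estimated dispersion while the log-likelihood entering AICc is the
full gamma likelihood maximized over the shape parameter.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize, special

ModelType = str  # "I", "II" or "III"

#: Canonical term order for the linear predictor.
TERM_ORDER = ("intercept", "DBH", "H", "rho", "DBH:H", "DBH:rho", "H:rho")

FULL_TERMS: dict[ModelType, tuple[str, ...]] = {
    "I": ("intercept", "DBH"),
    "II": ("intercept", "DBH", "H", "DBH:H"),
    "III": ("intercept", "DBH", "H", "rho", "DBH:H", "DBH:rho", "H:rho"),
}

#: Terms that backward elimination may never remove.
FORCED_TERMS = {"intercept", "DBH", "H"}

_COLUMNS = {"DBH": "dbh_cm", "H": "height_m", "rho": "density"}


def aicc(loglik: float, k_params: int, n: int) -> float:
    """Small-sample-corrected AIC: AIC + 2k(k+1)/(n-k-1).

    ``k_params`` counts estimated parameters including the dispersion (or
    residual-variance) parameter, so it is always >= 1.
    """
    if k_params < 1:
        raise ValueError("k_params must count at least the intercept")
    if n <= k_params + 1:
        raise ValueError(
            f"AICc undefined for n={n} <= k+1={k_params + 1} (correction blows up)"
        )
    aic = 2.0 * k_params - 2.0 * loglik
    return aic + 2.0 * k_params * (k_params + 1) / (n - k_params - 1)


def explained_deviance(model_deviance: float, null_deviance: float) -> float:
    """Fraction of the null deviance explained: 1 - D_model/D_null."""
    if null_deviance == 0:
        raise ValueError("null deviance is zero; response is constant")
    return 1.0 - model_deviance / null_deviance


def nagelkerke_r2(ll_null: float, ll_model: float, n: int) -> float:
    """Nagelkerke's pseudo-R^2 (Cox-Snell rescaled to a [0, 1] maximum)."""
    cox_snell = 1.0 - math.exp(2.0 * (ll_null - ll_model) / n)
    max_cs = 1.0 - math.exp(2.0 * ll_null / n)
    if max_cs == 0:
        raise ValueError("degenerate null likelihood")
    return cox_snell / max_cs


def fit_quality(
    model_deviance: float,
    null_deviance: float,
    ll_model: float,
    ll_null: float,
    n: int,
) -> tuple[float, float]:
    """(explained deviance, Nagelkerke pseudo-R^2) for a fitted model."""
    return (
        explained_deviance(model_deviance, null_deviance),
        nagelkerke_r2(ll_null, ll_model, n),
    )


def gamma_loglik_ml(y: np.ndarray, mu: np.ndarray) -> tuple[float, float]:
    """Gamma log-likelihood maximized over the shape parameter.

    Returns ``(loglik, shape)`` for observations ``y`` with fitted means
    ``mu`` under a gamma density with common shape alpha (variance
    mu^2/alpha).
    """
    y = np.asarray(y, dtype=float)
    mu = np.asarray(mu, dtype=float)

    def negll(log_alpha: float) -> float:
        return -_gamma_ll(math.exp(log_alpha), y, mu)

    res = optimize.minimize_scalar(negll, bounds=(-10.0, 15.0), method="bounded")
    alpha = math.exp(res.x)
    return -float(res.fun), alpha


def _gamma_ll(alpha: float, y: np.ndarray, mu: np.ndarray) -> float:
    return float(
        np.sum(
            alpha * (math.log(alpha) - np.log(mu))
            + (alpha - 1.0) * np.log(y)
            - alpha * y / mu
            - special.gammaln(alpha)
        )
    )


@dataclass(frozen=True)
class AllometricModel:
    """A fitted (and possibly reduced) gamma-GLM allometric model."""

    luca: str
    model_type: ModelType
    terms: tuple[str, ...]
    coefficients: dict[str, float]  # link (log) scale
    std_errors: dict[str, float]
    dispersion: float  # Pearson dispersion estimate
    shape: float  # ML gamma shape used for the likelihood
    n: int
    loglik: float
    deviance: float
    null_deviance: float
    ll_null: float
    aicc: float
    explained_deviance: float
    nagelkerke_r2: float
    dbh_domain: tuple[float, float] | None = None

    def linear_predictor(
        self,
        dbh: float | np.ndarray,
        height: float | np.ndarray | None = None,
        rho: float | np.ndarray | None = None,
    ) -> np.ndarray:
        vals = {"DBH": np.asarray(dbh, dtype=float)}
        if any(t for t in self.terms if "H" in t.split(":") or t == "H"):
            if height is None:
                raise ValueError("model requires height (H)")
            vals["H"] = np.asarray(height, dtype=float)
        if any(t for t in self.terms if "rho" in t.split(":") or t == "rho"):
            if rho is None:
                raise ValueError("model requires wood density (rho)")
            vals["rho"] = np.asarray(rho, dtype=float)
        eta = np.zeros(np.broadcast(*(np.atleast_1d(v) for v in vals.values())).shape)
        for term in self.terms:
            beta = self.coefficients[term]
            if term == "intercept":
                eta = eta + beta
            elif ":" in term:
                a, b = term.split(":")
                eta = eta + beta * vals[a] * vals[b]
            else:
                eta = eta + beta * vals[term]
        return eta


def _design_matrix(df: pd.DataFrame, terms: Sequence[str]) -> np.ndarray:
    cols = []
    for term in terms:
        if term == "intercept":
            cols.append(np.ones(len(df)))
        elif ":" in term:
            a, b = term.split(":")
            cols.append(df[_COLUMNS[a]].to_numpy() * df[_COLUMNS[b]].to_numpy())
        else:
            cols.append(df[_COLUMNS[term]].to_numpy())
    return np.column_stack(cols)


def _fit_glm(df: pd.DataFrame, terms: Sequence[str]):
    y = df["agb_kg"].to_numpy(dtype=float)
    X = _design_matrix(df, terms)
    model = sm.GLM(y, X, family=sm.families.Gamma(link=sm.families.links.Log()))
    res = model.fit()
    ll, shape = gamma_loglik_ml(y, res.mu)
    k = len(terms) + 1  # coefficients + dispersion
    return res, ll, shape, aicc(ll, k, len(y))


def _removable(terms: Sequence[str]) -> list[str]:
    """Terms eligible for elimination, respecting marginality."""
    out = [t for t in terms if ":" in t]
    if "rho" in terms and not any(":" in t and "rho" in t.split(":") for t in terms):
        out.append("rho")
    return out


def fit_allometric(
    trees: pd.DataFrame,
    model_type: ModelType,
    luca: str = "generic",
    dbh_domain: tuple[float, float] | None = None,
    aicc_threshold: float = 2.0,
) -> AllometricModel:
    """Fit one allometric model type to a tree table, with AICc reduction.

    ``trees`` needs columns ``agb_kg`` and ``dbh_cm``, plus ``height_m``
    (types II/III) and ``density`` (type III).  Backward elimination removes
    at each step the candidate term whose removal lowers AICc the most,
    as long as the drop is at least ``aicc_threshold``.
    """
    if model_type not in FULL_TERMS:
        raise ValueError(f"unknown model type {model_type!r}; expected I, II or III")
    required = {"agb_kg", "dbh_cm"}
    if model_type in ("II", "III"):
        required.add("height_m")
    if model_type == "III":
        required.add("density")
    missing = required - set(trees.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    df = trees.dropna(subset=sorted(required))
    n = len(df)
    if n < 10:
        raise ValueError(f"need at least 10 trees, got {n}")
    if np.any(df["agb_kg"].to_numpy() <= 0) or np.any(df["dbh_cm"].to_numpy() <= 0):
        raise ValueError("AGB and DBH must be strictly positive")

    terms = list(FULL_TERMS[model_type])
    res, ll, shape, current_aicc = _fit_glm(df, terms)

    while True:
        candidates = _removable(terms)
        best = None
        for term in candidates:
            reduced = [t for t in terms if t != term]
            r_res, r_ll, r_shape, r_aicc = _fit_glm(df, reduced)
            if best is None or r_aicc < best[-1]:
                best = (term, reduced, r_res, r_ll, r_shape, r_aicc)
        if best is None or current_aicc - best[-1] < aicc_threshold:
            break
        _, terms, res, ll, shape, current_aicc = best

    # null (intercept-only) model for fit-quality metrics
    null_res, ll_null, _, _ = _fit_glm(df, ["intercept"])
    exp_dev, nag = fit_quality(res.deviance, null_res.deviance, ll, ll_null, n)
    pearson_dispersion = float(res.pearson_chi2 / res.df_resid) if res.df_resid > 0 else float("nan")

    return AllometricModel(
        luca=luca,
        model_type=model_type,
        terms=tuple(terms),
        coefficients={t: float(b) for t, b in zip(terms, res.params)},
        std_errors={t: float(s) for t, s in zip(terms, res.bse)},
        dispersion=pearson_dispersion,
        shape=shape,
        n=n,
        loglik=ll,
        deviance=float(res.deviance),
        null_deviance=float(null_res.deviance),
        ll_null=ll_null,
        aicc=current_aicc,
        explained_deviance=exp_dev,
        nagelkerke_r2=nag,
        dbh_domain=dbh_domain,
    )


def predict_agb(
    model: AllometricModel,
    dbh: float | np.ndarray,
    height: float | np.ndarray | None = None,
    rho: float | np.ndarray | None = None,
) -> tuple[float | np.ndarray, bool | np.ndarray]:
    """Predict AGB (kg) and flag DBH values outside the validity domain.

    Returns ``(agb, out_of_domain)``; the flag is False when the model has
    no recorded DBH domain.
    """
    eta = model.linear_predictor(dbh, height, rho)
    agb = np.exp(eta)
    d = np.asarray(dbh, dtype=float)
    if model.dbh_domain is None:
        flag = np.zeros_like(np.atleast_1d(d), dtype=bool)
    else:
        lo, hi = model.dbh_domain
        flag = (np.atleast_1d(d) < lo) | (np.atleast_1d(d) > hi)
    if np.ndim(dbh) == 0:
        return float(agb.reshape(-1)[0]), bool(flag.reshape(-1)[0])
    return agb, flag


def mean_deviation(
    reference_agb: Sequence[float], candidate_predictions: Sequence[float]
) -> float:
    """Mean absolute percent deviation of predictions from a reference."""
    obs = np.asarray(reference_agb, dtype=float)
    pred = np.asarray(candidate_predictions, dtype=float)
    if len(obs) != len(pred) or len(obs) == 0:
        raise ValueError("need paired, non-empty reference and predictions")
    if np.any(obs <= 0):
        raise ValueError("reference AGB must be strictly positive")
    return float(np.mean(100.0 * np.abs(pred - obs) / obs))


def model_to_dict(model: AllometricModel) -> dict:
    """JSON-serializable representation of a fitted model."""
    return {
        "luca": model.luca,
        "model_type": model.model_type,
        "terms": list(model.terms),
        "coefficients": model.coefficients,
        "std_errors": model.std_errors,
        "dispersion": model.dispersion,
        "shape": model.shape,
        "n": model.n,
        "aicc": model.aicc,
        "explained_deviance": model.explained_deviance,
        "nagelkerke_r2": model.nagelkerke_r2,
        "dbh_domain": list(model.dbh_domain) if model.dbh_domain else None,
    }
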