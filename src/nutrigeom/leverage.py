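"""Regression models for protein leverage of food and energy intake.

Three model families, all fit on per-unit mean daily intakes joined to
diet composition:

* linear: ``intake = alpha + beta * x`` with x the protein energy
  fraction (0-1) or the protein mass fraction — ordinary least squares
  with a two-sided t-test on the slope;
* power-law leverage: ``intake = P * p**L`` with p the protein
  proportion of the diet — nonlinear least squares. L = -1 corresponds
  to complete leverage (absolute protein intake held constant), L = 0 to
  no compensation; the null hypothesis L = 0 is tested with the
  asymptotic t statistic;
* between-study comparison: a pooled model with a study indicator for
  the elevation difference and a predictor-by-study interaction for the
  slope difference, each Wald-tested;
* log-ratio dilution: OLS of intake on ln(protein : diluent) mass
  ratio, contrasting caloric (fat) with noncaloric (cellulose) diluents.

Estimates are unweighted; cage-level means count as single
observations; p-values are reported raw, with no multiple-testing
correction.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.optimize
import scipy.stats
import statsmodels.api as sm

from .diets import DEFAULT_FACTORS, DietSpec, EnergyFactors, diets_to_frame

__all__ = [
    "LinearFit",
    "LeverageFit",
    "StudyComparison",
    "fit_linear",
    "fit_power_leverage",
    "compare_studies",
    "fit_log_ratio",
]

logger = logging.getLogger(__name__)

_RESPONSE_COLUMNS = {"food": "food_intake_g", "energy": "energy_intake_kj"}


class ModelInputError(ValueError):
    pass


def _merged(obs: pd.DataFrame, diets: Sequence[DietSpec], factors: EnergyFactors) -> pd.DataFrame:
    dt = diets_to_frame(diets, factors)
    merged = obs.merge(dt, on="diet_id", how="left", suffixes=("", "_diet"))
    if merged["frac_protein"].isna().any():
        missing = sorted(obs.loc[merged["frac_protein"].isna(), "diet_id"].unique())
        raise ModelInputError(f"observations reference unknown diets: {missing}")
    return merged


def _response(df: pd.DataFrame, response: str) -> np.ndarray:
    try:
        return df[_RESPONSE_COLUMNS[response]].to_numpy(float)
    except KeyError:
        raise ModelInputError(
            f"response must be one of {sorted(_RESPONSE_COLUMNS)}, got {response!r}"
        ) from None


@dataclass
class LinearFit:
    alpha: float
    beta: float
    se_alpha: float
    se_beta: float
    t_beta: float
    p_beta: float
    n: int
    predictor_name: str
    response: str
    n_excluded: int = 0

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def fit_linear(
    obs: pd.DataFrame,
    diets: Sequence[DietSpec],
    response: str = "food",
    predictor: str = "pct_energy_protein",
    factors: EnergyFactors = DEFAULT_FACTORS,
) -> LinearFit:
    """OLS of intake on dietary protein content.

    ``predictor`` is either "pct_energy_protein" (energy fraction, 0-1)
    or "frac_protein" (mass fraction). The two are distinct quantities
    and are never interchanged implicitly.
    """
    if predictor not in ("pct_energy_protein", "frac_protein"):
        raise ModelInputError(f"unknown linear predictor {predictor!r}")
    df = _merged(obs, diets, factors)
    y = _response(df, response)
    x = df[predictor].to_numpy(float)
    if len(y) < 3:
        raise ModelInputError(f"need at least 3 observations, got {len(y)}")
    if np.ptp(x) == 0:
        raise ModelInputError(f"predictor {predictor!r} is constant; model is rank-deficient")
    res = sm.OLS(y, sm.add_constant(x)).fit()
    return LinearFit(
        alpha=float(res.params[0]),
        beta=float(res.params[1]),
        se_alpha=float(res.bse[0]),
        se_beta=float(res.bse[1]),
        t_beta=float(res.tvalues[1]),
        p_beta=float(res.pvalues[1]),
        n=int(res.nobs),
        predictor_name=predictor,
        response=response,
    )


@dataclass
class LeverageFit:
    """Power-law leverage estimates with asymptotic uncertainty."""

    P_hat: float
    L_hat: float
    se_P: float
    se_L: float
    t_L: float
    p_L: float
    n: int
    converged: bool
    predictor: str
    response: str
    start: tuple[float, float] = (np.nan, np.nan)
    n_iter: int = 0

    def ci_L(self, level: float = 0.95) -> tuple[float, float]:
        """Asymptotic t confidence interval for the leverage exponent."""
        tcrit = scipy.stats.t.ppf(0.5 + level / 2.0, max(self.n - 2, 1))
        return (self.L_hat - tcrit * self.se_L, self.L_hat + tcrit * self.se_L)

    def to_dict(self) -> dict:
        d = dict(self.__dict__)
        d["start"] = list(self.start)
        return d


def fit_power_leverage(
    obs: pd.DataFrame,
    diets: Sequence[DietSpec],
    response: str = "food",
    predictor: str = "mass",
    factors: EnergyFactors = DEFAULT_FACTORS,
    xtol: float = 1e-8,
    max_iter: int = 200,
) -> LeverageFit:
    """Nonlinear least squares fit of ``intake = P * p**L``.

    ``predictor="mass"`` uses the protein proportion of the diet by mass
    (the Figure-4/5 convention); ``predictor="energy"`` uses the protein
    fraction of dietary energy. Both live in (0, 1] and share the code
    path. Starting values are (median intake, log-log OLS slope); a fit
    that fails to converge is returned flagged, never raised.
    """
    if predictor == "mass":
        col = "frac_protein"
    elif predictor == "energy":
        col = "pct_energy_protein"
    else:
        raise ModelInputError(f"predictor must be 'mass' or 'energy', got {predictor!r}")
    df = _merged(obs, diets, factors)
    y = _response(df, response)
    p = df[col].to_numpy(float)
    n = len(y)
    if n < 4:
        raise ModelInputError(f"need at least 4 observations, got {n}")
    if np.any(p <= 0) or np.any(p > 1):
        raise ModelInputError("protein proportions must lie in (0, 1] for the power model")

    # log-log OLS as a cheap consistent initializer (exact when noiseless)
    pos = y > 0
    if pos.sum() >= 3 and np.ptp(np.log(p[pos])) > 0:
        coef = np.polyfit(np.log(p[pos]), np.log(y[pos]), 1)
        L0 = float(np.clip(coef[0], -5.0, 5.0))
    else:
        L0 = 0.0
    P0 = float(np.median(y))
    if P0 <= 0:
        P0 = max(float(np.mean(np.abs(y))), 1e-6)

    def residuals(theta: np.ndarray) -> np.ndarray:
        P, L = theta
        return P * p**L - y

    sol = scipy.optimize.least_squares(
        residuals,
        x0=np.array([P0, L0]),
        xtol=xtol,
        ftol=xtol,
        gtol=1e-12,
        max_nfev=max_iter * 3,
        method="lm",
    )
    P_hat, L_hat = (float(v) for v in sol.x)
    converged = bool(sol.success)
    dof = n - 2
    rss = float(np.sum(sol.fun**2))
    sigma2 = rss / dof if dof > 0 else np.nan
    JtJ = sol.jac.T @ sol.jac
    try:
        cov = sigma2 * np.linalg.inv(JtJ)
        se_P = float(np.sqrt(max(cov[0, 0], 0.0)))
        se_L = float(np.sqrt(max(cov[1, 1], 0.0)))
    except np.linalg.LinAlgError:
        se_P = se_L = np.nan
        converged = False
    if se_L > 0:
        t_L = L_hat / se_L
        p_L = float(2 * scipy.stats.t.sf(abs(t_L), dof))
    else:
        # zero residual variance: the exponent is determined exactly
        t_L = np.inf if L_hat != 0 else 0.0
        p_L = 0.0 if L_hat != 0 else 1.0
    if not converged:
        warnings.warn(
            f"power-leverage fit did not converge (status {sol.status}); result flagged",
            RuntimeWarning,
            stacklevel=2,
        )
    return LeverageFit(
        P_hat=P_hat,
        L_hat=L_hat,
        se_P=se_P,
        se_L=se_L,
        t_L=float(t_L),
        p_L=p_L,
        n=n,
        converged=converged,
        predictor=predictor,
        response=response,
        start=(P0, L0),
        n_iter=int(sol.nfev),
    )


@dataclass
class StudyComparison:
    """Between-study elevation and slope-difference tests.

    ``elevation_diff`` is comparison-study intake minus reference-study
    intake from the pooled intake ~ study model; ``slope_diff`` is the
    predictor-by-study interaction coefficient from the pooled
    intake ~ predictor * study model.
    """

    reference_study: str
    comparison_study: str
    elevation_diff: float
    se_elevation: float
    t_elevation: float
    p_elevation: float
    slope_diff: float
    se_slope_diff: float
    t_slope: float
    p_slope: float
    n_reference: int
    n_comparison: int
    predictor_name: str
    response: str
    warnings: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def compare_studies(
    obs_a: pd.DataFrame,
    obs_b: pd.DataFrame,
    diets: Sequence[DietSpec],
    response: str = "energy",
    predictor: str = "pct_energy_protein",
    factors: EnergyFactors = DEFAULT_FACTORS,
) -> StudyComparison:
    """Pooled two-study models: elevation (intake ~ study) and
    interaction (intake ~ predictor * study)."""
    if obs_a.empty or obs_b.empty:
        raise ModelInputError("both study datasets must be nonempty")
    df_a = _merged(obs_a, diets, factors)
    df_b = _merged(obs_b, diets, factors)
    ref = str(df_a["study_id"].iloc[0])
    cmp_ = str(df_b["study_id"].iloc[0])
    if ref == cmp_:
        cmp_ = cmp_ + "_b"

    notes: list[str] = []
    xa, xb = df_a[predictor], df_b[predictor]
    if xa.min() > xb.max() or xb.min() > xa.max():
        notes.append(
            f"predictor ranges are disjoint ({xa.min():.3g}-{xa.max():.3g} vs "
            f"{xb.min():.3g}-{xb.max():.3g}); elevation contrast extrapolates"
        )

    y = np.concatenate([_response(df_a, response), _response(df_b, response)])
    x = np.concatenate([xa.to_numpy(float), xb.to_numpy(float)])
    ind = np.concatenate([np.zeros(len(df_a)), np.ones(len(df_b))])

    elev = sm.OLS(y, sm.add_constant(ind)).fit()
    inter = sm.OLS(y, np.column_stack([np.ones_like(x), x, ind, x * ind])).fit()
    return StudyComparison(
        reference_study=ref,
        comparison_study=cmp_,
        elevation_diff=float(elev.params[1]),
        se_elevation=float(elev.bse[1]),
        t_elevation=float(elev.tvalues[1]),
        p_elevation=float(elev.pvalues[1]),
        slope_diff=float(inter.params[3]),
        se_slope_diff=float(inter.bse[3]),
        t_slope=float(inter.tvalues[3]),
        p_slope=float(inter.pvalues[3]),
        n_reference=len(df_a),
        n_comparison=len(df_b),
        predictor_name=predictor,
        response=response,
        warnings=notes,
    )


def fit_log_ratio(
    obs: pd.DataFrame,
    diets: Sequence[DietSpec],
    diluent: str = "cellulose",
    response: str = "food",
    factors: EnergyFactors = DEFAULT_FACTORS,
) -> LinearFit:
    """OLS of intake on ln(protein : diluent) by mass.

    Contrasting a noncaloric (cellulose) with a caloric (fat) diluent
    separates palatability-free protein dilution from energy-dense
    dilution: under pure protein leverage, food intake responds to both
    the same way, while only the caloric diluent raises energy intake.
    Diets with a zero diluent fraction are excluded (counted in
    ``n_excluded``).
    """
    if diluent not in ("cellulose", "fat"):
        raise ModelInputError(f"diluent must be 'cellulose' or 'fat', got {diluent!r}")
    col = {"cellulose": "frac_cellulose", "fat": "frac_fat"}[diluent]
    df = _merged(obs, diets, factors)
    usable = (df[col] > 0) & (df["frac_protein"] > 0)
    n_excluded = int((~usable).sum())
    if n_excluded:
        logger.info(
            "fit_log_ratio: excluded %d observations on diets with zero %s or protein",
            n_excluded,
            diluent,
        )
    df = df[usable]
    if len(df) < 3:
        raise ModelInputError("fewer than 3 usable observations after diluent filtering")
    y = _response(df, response)
    x = np.log(df["frac_protein"].to_numpy(float) / df[col].to_numpy(float))
    if np.ptp(x) == 0:
        raise ModelInputError("log ratio is constant across usable diets")
    res = sm.OLS(y, sm.add_constant(x)).fit()
    return LinearFit(
        alpha=float(res.params[0]),
        beta=float(res.params[1]),
        se_alpha=float(res.bse[0]),
        se_beta=float(res.bse[1]),
        t_beta=float(res.tvalues[1]),
        p_beta=float(res.pvalues[1]),
        n=int(res.nobs),
        predictor_name=f"log_protein_to_{diluent}",
        response=response,
        n_excluded=n_excluded,
    )
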