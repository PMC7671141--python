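"""Linear mixed-effects stage/sex/weather models.

The analysis models either an activity-level response (mean daily ODBA, g)
or a timing response (onset relative to dusk, offset relative to dawn, in
minutes; bout duration, h) with random intercepts for individual animal
and day of year (crossed), REML estimation, and Treatment coding with the
study's baselines: winter stage, female sex, snow < 8 cm.

Seasonal stage and weather covariates are collinear by construction (each
stage is one block of calendar time with its own weather), so a model
specification may contain stage *or* weather terms, never both; that
constraint is enforced at specification time.  Stage-wise least-squares
means with Tukey-adjusted pairwise comparisons and a quantile-quantile
residual diagnostic complete the reporting surface.

Numerical fitting is delegated to :class:`statsmodels` ``MixedLM``.
Fixed-effect inference is large-sample Wald (normal) based; the Tukey step
uses the studentized-range distribution with residual degrees of freedom
approximated as ``n - rank(X)``.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.formula.api as smf
from statsmodels.tools.sm_exceptions import ConvergenceWarning

from .core import STAGES, ValidationError

RESPONSES = (
    "mean_daily_odba",
    "onset_rel_dusk_min",
    "offset_rel_dawn_min",
    "duration_h",
)
WEATHER_TERMS = ("temp_c", "wind_ms", "precip_sqrt", "snow_cat", "temp_x_wind")
FIXED_TERMS = ("stage", "sex") + WEATHER_TERMS
RANDOM_TERMS = ("individual", "day_of_year")

_TERM_FORMULA = {
    "stage": "C(stage, Treatment('winter'))",
    "sex": "C(sex, Treatment('female'))",
    "snow_cat": "C(snow_cat, Treatment('lt8cm'))",
    "temp_c": "temp_c",
    "wind_ms": "wind_ms",
    "precip_sqrt": "precip_sqrt",
    "temp_x_wind": "temp_c:wind_ms",
}


class SpecificationError(ValidationError):
    """The model specification violates a design constraint."""


@dataclasses.dataclass(frozen=True)
class ModelSpec:
    """Declarative model specification.

    ``fixed`` is a subset of stage, sex and the weather terms;
    ``random_intercepts`` a subset of {"individual", "day_of_year"}.  Stage
    and weather terms cannot co-occur.
    """

    response: str
    fixed: tuple[str, ...]
    random_intercepts: tuple[str, ...] = ("individual", "day_of_year")

    def __post_init__(self) -> None:
        if self.response not in RESPONSES:
            raise SpecificationError(
                f"response must be one of {RESPONSES}, got {self.response!r}"
            )
        object.__setattr__(self, "fixed", tuple(self.fixed))
        object.__setattr__(self, "random_intercepts", tuple(self.random_intercepts))
        for term in self.fixed:
            if term not in FIXED_TERMS:
                raise SpecificationError(f"unknown fixed term {term!r}")
        for term in self.random_intercepts:
            if term not in RANDOM_TERMS:
                raise SpecificationError(f"unknown random intercept {term!r}")
        if not self.random_intercepts:
            raise SpecificationError("at least one random intercept is required")
        if "stage" in self.fixed and any(t in WEATHER_TERMS for t in self.fixed):
            raise SpecificationError(
                "seasonal stage and weather covariates are collinear by design "
                "and cannot co-occur in one model"
            )

    def formula(self) -> str:
        terms = [_TERM_FORMULA[t] for t in self.fixed] or ["1"]
        return f"{self.response} ~ " + " + ".join(terms)


@dataclasses.dataclass
class ModelFit:
    """Fit report: fixed estimates with 95% CI and p, variance components."""

    spec: ModelSpec
    params: pd.DataFrame
    sigma2: float
    tau00: dict
    converged: bool
    singular: bool
    n_obs: int
    result: object
    data: pd.DataFrame


def _prepare(records: pd.DataFrame, spec: ModelSpec) -> pd.DataFrame:
    df = records.copy()
    if "day_of_year" not in df.columns:
        if "date" not in df.columns:
            raise ValidationError("records need a 'date' or 'day_of_year' column")
        df["day_of_year"] = pd.DatetimeIndex(df["date"]).dayofyear
    needed = [spec.response, "animal_id", "day_of_year"]
    for term in spec.fixed:
        needed.extend(["temp_c", "wind_ms"] if term == "temp_x_wind" else [term])
    df = df.dropna(subset=[c for c in dict.fromkeys(needed)])
    if df["animal_id"].nunique() < 2:
        raise ValidationError("mixed model requires at least 2 individuals")
    return df


def fit_lmm(records: pd.DataFrame, spec: ModelSpec) -> ModelFit:
    """REML fit of ``spec`` on complete-case rows of ``records``.

    Random intercepts for individual and day of year are crossed (a single
    grouping with two variance components).  A singular fit — a variance
    component estimated at (numerically) zero — is reported via the
    ``singular`` flag, not raised.
    """
    df = _prepare(records, spec)
    formula = spec.formula()
    kwargs = {}
    if set(spec.random_intercepts) == {"individual", "day_of_year"}:
        df = df.assign(_all=1)
        kwargs = dict(
            groups="_all",
            re_formula="0",
            vc_formula={
                "individual": "0 + C(animal_id)",
                "day_of_year": "0 + C(day_of_year)",
            },
        )
    elif spec.random_intercepts == ("individual",):
        kwargs = dict(groups="animal_id")
    else:
        kwargs = dict(groups="day_of_year")

    model = smf.mixedlm(formula, df, **kwargs)
    # Boundary-proximity ConvergenceWarnings are advisory (they can fire on
    # fits with strictly positive variance components); suppress them and
    # trust the optimizer's own convergence status.  If the first optimizer
    # stalls, fall back through alternatives before reporting failure.
    result = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        for method in ("lbfgs", "cg", "powell"):
            candidate = model.fit(reml=True, method=method, maxiter=2000)
            if result is None or candidate.converged:
                result = candidate
            if candidate.converged:
                break
    converged = bool(getattr(result, "converged", True))

    k_fe = len(result.fe_params)
    ci = result.conf_int().iloc[:k_fe]
    params = pd.DataFrame(
        {
            "estimate": result.fe_params,
            "ci_low": ci[0],
            "ci_high": ci[1],
            "p_value": result.pvalues.iloc[:k_fe],
        }
    )
    sigma2 = float(result.scale)
    tau00: dict[str, float] = {}
    if "vc_formula" in kwargs:
        names = model.exog_vc.names
        tau00 = {name: float(v) for name, v in zip(names, result.vcomp)}
    elif result.cov_re.size:
        key = "individual" if kwargs.get("groups") == "animal_id" else "day_of_year"
        tau00[key] = float(result.cov_re.iloc[0, 0])
    singular = any(v < 1e-8 for v in tau00.values())
    return ModelFit(
        spec=spec,
        params=params,
        sigma2=sigma2,
        tau00=tau00,
        converged=converged,
        singular=singular,
        n_obs=len(df),
        result=result,
        data=df,
    )


def _factor_column(factor: str) -> str:
    if factor not in ("stage", "sex", "snow_cat"):
        raise ValidationError(f"{factor!r} is not a categorical fixed factor")
    return factor


def _reference_grid(fit: ModelFit, factor: str, level) -> pd.DataFrame:
    """Prediction rows for one factor level: numeric covariates at their
    sample mean, other categorical factors averaged with equal weight."""
    df = fit.data
    other_cats = [
        t for t in fit.spec.fixed if t in ("stage", "sex", "snow_cat") and t != factor
    ]
    grids = [{factor: level}]
    for cat in other_cats:
        levels = sorted(df[cat].unique())
        grids = [dict(g, **{cat: lv}) for g in grids for lv in levels]
    rows = pd.DataFrame(grids)
    for term in fit.spec.fixed:
        cols = ("temp_c", "wind_ms") if term == "temp_x_wind" else (term,)
        for col in cols:
            if col not in rows.columns and col in df.columns:
                rows[col] = df[col].mean()
    return rows


def lsmeans_tukey(
    fit: ModelFit, factor: str = "stage", alpha: float = 0.05
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Least-squares means per factor level and Tukey-adjusted pairs.

    Returns ``(lsmeans, pairs)``: per-level model-adjusted means with SE,
    and all k(k-1)/2 pairwise differences with family-wise adjusted
    p-values (studentized range).  Significance at ``alpha`` = 0.05.
    """
    factor = _factor_column(factor)
    if factor not in fit.spec.fixed:
        raise ValidationError(f"factor {factor!r} is not in the fitted fixed effects")
    df = fit.data
    levels = [s for s in STAGES if s in set(df[factor])] if factor == "stage" else sorted(
        df[factor].unique()
    )
    design_info = fit.result.model.data.design_info
    from patsy import build_design_matrices

    beta = fit.result.fe_params.to_numpy()
    cov = np.asarray(fit.result.cov_params())[: len(beta), : len(beta)]
    L = []
    for level in levels:
        grid = _reference_grid(fit, factor, level)
        X = np.asarray(build_design_matrices([design_info], grid)[0])
        L.append(X.mean(axis=0))
    L = np.vstack(L)
    means = L @ beta
    ses = np.sqrt(np.einsum("ij,jk,ik->i", L, cov, L))
    lsmeans = pd.DataFrame({"level": levels, "lsmean": means, "se": ses}).set_index(
        "level"
    )

    k = len(levels)
    n = fit.n_obs
    df_resid = max(n - len(beta), 2)
    rows = []
    for i in range(k):
        for j in range(i + 1, k):
            diff = means[i] - means[j]
            ell = L[i] - L[j]
            se = float(np.sqrt(ell @ cov @ ell))
            q = abs(diff) / se * np.sqrt(2.0)
            p = float(stats.studentized_range.sf(q, k, df_resid))
            rows.append(
                {
                    "pair": f"{levels[i]} - {levels[j]}",
                    "diff": float(diff),
                    "se": se,
                    "p_tukey": p,
                    "significant": p <= alpha,
                }
            )
    return lsmeans, pd.DataFrame(rows)


def residual_diagnostics(fit: ModelFit) -> dict:
    """Quantile-quantile normality summary for the fit residuals.

    Returns ordered residuals, matching normal quantiles, a
    correlation-based straightness statistic (the probability-plot
    correlation), and an advisory ``flag`` when the statistic drops below
    0.99.  With fewer than 3 residuals the diagnostic is not applicable.
    """
    resid = np.sort(np.asarray(fit.result.resid, dtype=float))
    n = resid.size
    if n < 3:
        return {
            "applicable": False,
            "straightness": np.nan,
            "flag": False,
            "sample_quantiles": resid,
            "theoretical_quantiles": np.full(n, np.nan),
        }
    theo = stats.norm.ppf((np.arange(1, n + 1) - 0.375) / (n + 0.25))
    r = float(np.corrcoef(theo, resid)[0, 1])
    return {
        "applicable": True,
        "straightness": r,
        "flag": r < 0.99,
        "sample_quantiles": resid,
        "theoretical_quantiles": theo,
    }
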