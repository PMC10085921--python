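"""Weighted-regression model search over sex structures and variance laws.

The response is an ln-transformed tooth outcome; age (decimal years) is
always a predictor.  Sex enters in one of five ways:

    i    sex not considered:               y = b0 + b1*age
    ii   sex-specific intercepts:          y = b0 + b_M*isMale + b1*age
    iii  sex-specific slopes, one intercept: y = b0 + bF*age*isF + bM*age*isM
    iv   sex-specific slopes + intercepts
    v    fully separate per-sex models (iv plus separate residual variance)

crossed with three variance weightings: constant (w = 1), age (w = age,
i.e. Var shrinks with age) and 1/age (w = 1/age, i.e. Var grows with age —
biologically plausible as tooth maturation asymptotes).  The weight w_i is
the regression weight, so Var(eps_i) = sigma^2 / w_i.

The 15 candidates are compared by AIC with k = (#coefficients + 1 variance
parameter), using the maximum-likelihood variance estimate in the
likelihood; significance tests use the unbiased variance estimate and the
t distribution (n - p df).  Candidate (outcome, tooth set) pairs are then
ranked by the p-value of the age effect — for separate-slope models the
*larger* of the two per-sex p-values, requiring signal in both sexes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .errors import (
    DegenerateDesignError,
    DegenerateFitError,
    SelectionError,
    SingularDesignError,
)
from .outcomes import TOOTH_PAIRS, OutcomeSpec, outcome_series
from .segmentation import FDI_TEETH

__all__ = [
    "SEX_MODELS",
    "WEIGHTINGS",
    "DAYS_PER_YEAR",
    "ModelSpec",
    "FitResult",
    "SexSplitFit",
    "enumerate_toothsets",
    "design_matrix",
    "design_row",
    "regression_weights",
    "variance_scale",
    "fit_wls",
    "aic",
    "fit_sex_model",
    "select_model",
    "ranking_pvalue",
    "explore",
]

logger = logging.getLogger(__name__)

SEX_MODELS = ("i", "ii", "iii", "iv", "v")
WEIGHTINGS = ("constant", "age", "inv_age")

#: Conversion between recorded age in days and decimal years.
DAYS_PER_YEAR = 365.25

_EPS_SIGMA2 = 1e-12

#: Candidates within this many AIC units of the minimum are treated as
#: statistically indistinguishable and resolved by parsimony (the
#: conventional delta-AIC <= 2 equivalence band).
AIC_EQUIVALENCE = 2.0


@dataclass(frozen=True)
class ModelSpec:
    """Identifies one candidate in the exploration grid."""

    sex_model: str
    weighting: str
    outcome_label: str | None = None
    teeth: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        if self.sex_model not in SEX_MODELS:
            raise ValueError(f"sex_model must be in {SEX_MODELS}")
        if self.weighting not in WEIGHTINGS:
            raise ValueError(f"weighting must be in {WEIGHTINGS}")


def enumerate_toothsets() -> list[tuple[int, ...]]:
    """The 11 analysed tooth sets: 4 single third molars followed by the
    7 averaged combinations (both uppers, both lowers, the four diagonal /
    same-side pairs, and all four)."""
    return [(t,) for t in FDI_TEETH] + [tuple(p) for p in TOOTH_PAIRS]


def regression_weights(weighting: str, age_years: np.ndarray) -> np.ndarray:
    """Regression weight w_i per observation (Var(eps_i) = sigma^2 / w_i)."""
    age_years = np.asarray(age_years, dtype=float)
    if weighting == "constant":
        return np.ones_like(age_years)
    if weighting == "age":
        return age_years.copy()
    if weighting == "inv_age":
        return 1.0 / age_years
    raise ValueError(f"unknown weighting {weighting!r}")


def variance_scale(weighting: str, age_years):
    """v(age) = 1/w(age): multiplier of sigma^2 in the residual variance."""
    return 1.0 / regression_weights(weighting, np.asarray(age_years, dtype=float))


def design_matrix(series: pd.DataFrame, sex_model: str) -> tuple[np.ndarray, list[str]]:
    """Predictor matrix and coefficient names for sex models i-iv.

    Model v is fitted as two per-sex model-i problems (see
    :func:`fit_sex_model`) and is rejected here.
    """
    if sex_model == "v":
        raise ValueError("model v is fitted per sex; build per-sex model-i designs")
    if sex_model not in SEX_MODELS:
        raise ValueError(f"sex_model must be in {SEX_MODELS}")
    if series.empty:
        raise DegenerateDesignError("empty series")
    age = series["age_years"].to_numpy(dtype=float)
    ones = np.ones_like(age)
    if sex_model == "i":
        return np.column_stack([ones, age]), ["intercept", "age"]
    sexes = set(series["sex"])
    if sexes != {"F", "M"}:
        raise DegenerateDesignError(
            f"sex model {sex_model} requires both sexes, found {sorted(sexes)}"
        )
    is_m = (series["sex"] == "M").to_numpy(dtype=float)
    is_f = 1.0 - is_m
    if sex_model == "ii":
        return np.column_stack([ones, is_m, age]), ["intercept", "male", "age"]
    if sex_model == "iii":
        return (
            np.column_stack([ones, age * is_f, age * is_m]),
            ["intercept", "age_f", "age_m"],
        )
    return (
        np.column_stack([ones, is_m, age * is_f, age * is_m]),
        ["intercept", "male", "age_f", "age_m"],
    )


def design_row(age_years: float, sex: str, sex_model: str) -> np.ndarray:
    """Single predictor row, for evaluating a fitted mean at (age, sex)."""
    if sex_model == "i":
        return np.array([1.0, age_years])
    is_m = 1.0 if sex == "M" else 0.0
    if sex_model == "ii":
        return np.array([1.0, is_m, age_years])
    if sex_model == "iii":
        return np.array([1.0, age_years * (1 - is_m), age_years * is_m])
    if sex_model == "iv":
        return np.array([1.0, is_m, age_years * (1 - is_m), age_years * is_m])
    raise ValueError(f"no single design row for sex model {sex_model!r}")


@dataclass
class FitResult:
    """A fitted weighted regression for sex models i-iv.

    ``sigma2_ml`` = sum(w e^2)/n drives the AIC; ``sigma2`` (unbiased,
    denominator n - p) drives the coefficient covariance, p-values and
    prediction variance.  ``k`` counts the variance parameter.
    """

    coef: dict[str, float]
    cov: np.ndarray
    names: list[str]
    sigma2: float
    sigma2_ml: float
    sum_log_w: float
    n: int
    k: int
    aic: float
    pvalues: dict[str, float]
    spec: ModelSpec
    n_by_sex: dict[str, int] = field(default_factory=dict)
    degenerate: bool = False

    @property
    def params(self) -> np.ndarray:
        return np.array([self.coef[name] for name in self.names])

    def mean(self, age_years, sex: str) -> np.ndarray:
        """Fitted mean ln-outcome at (age, sex)."""
        age_arr = np.atleast_1d(np.asarray(age_years, dtype=float))
        rows = np.vstack([design_row(a, sex, self.spec.sex_model) for a in age_arr])
        mu = rows @ self.params
        return mu if np.ndim(age_years) else float(mu[0])

    def resid_variance(self, sex: str) -> float:
        """Base residual variance sigma^2 (unbiased) for the given sex."""
        if self.spec.sex_model != "i" and sex not in ("F", "M"):
            raise ValueError(f"sex must be 'F' or 'M', got {sex!r}")
        return self.sigma2

    def variance_scale(self, age_years):
        return variance_scale(self.spec.weighting, age_years)

    def age_pvalues(self) -> dict[str, float]:
        """p-value(s) of the age effect: common or per sex."""
        if self.spec.sex_model in ("i", "ii"):
            return {"common": self.pvalues["age"]}
        return {"F": self.pvalues["age_f"], "M": self.pvalues["age_m"]}


@dataclass
class SexSplitFit:
    """Sex model v: two independent per-sex fits with separate variances.

    AIC is the sum of the per-sex AICs (k summed), equivalent to the joint
    likelihood of the stratified model.
    """

    fits: dict[str, FitResult]
    spec: ModelSpec

    @property
    def aic(self) -> float:
        return sum(f.aic for f in self.fits.values())

    @property
    def k(self) -> int:
        return sum(f.k for f in self.fits.values())

    @property
    def n(self) -> int:
        return sum(f.n for f in self.fits.values())

    @property
    def degenerate(self) -> bool:
        return any(f.degenerate for f in self.fits.values())

    def mean(self, age_years, sex: str):
        return self.fits[sex].mean(age_years, "F")  # per-sex fit is model i

    def resid_variance(self, sex: str) -> float:
        return self.fits[sex].sigma2

    def variance_scale(self, age_years):
        return variance_scale(self.spec.weighting, age_years)

    def age_pvalues(self) -> dict[str, float]:
        return {sex: f.pvalues["age"] for sex, f in self.fits.items()}


def fit_wls(
    X: np.ndarray,
    y: np.ndarray,
    w: np.ndarray,
    names: list[str] | None = None,
    spec: ModelSpec | None = None,
) -> FitResult:
    """Weighted least squares via statsmodels, packaged with the AIC
    conventions used throughout the model search.

    Coefficients minimise sum w_i (y_i - x_i b)^2.  Raises
    ``SingularDesignError`` on rank deficiency.  A numerically perfect fit
    (zero residual variance) still returns its coefficients but is marked
    ``degenerate`` with AIC guarded at -inf: its likelihood is unbounded,
    so model selection excludes it.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    w = np.asarray(w, dtype=float)
    if np.any(w <= 0):
        raise ValueError("weights must be strictly positive")
    n, p = X.shape
    if n <= p:
        raise DegenerateDesignError(f"n={n} observations cannot identify p={p} coefficients plus a variance")
    if np.linalg.matrix_rank(X) < p:
        raise SingularDesignError("design matrix is rank deficient")
    names = names or [f"b{j}" for j in range(p)]
    spec = spec or ModelSpec("i", "constant")

    res = sm.WLS(y, X, weights=w).fit()
    resid = y - X @ res.params
    sigma2_ml = float(np.sum(w * resid**2) / n)
    sum_log_w = float(np.sum(np.log(w)))
    k = p + 1
    degenerate = sigma2_ml < _EPS_SIGMA2
    if degenerate:
        llf = np.inf
        logger.warning("degenerate fit: zero residual variance; AIC guarded at -inf")
    else:
        llf = -0.5 * n * np.log(2 * np.pi * sigma2_ml) + 0.5 * sum_log_w - 0.5 * n
    fit = FitResult(
        coef=dict(zip(names, map(float, res.params))),
        cov=np.asarray(res.cov_params()),
        names=list(names),
        sigma2=float(res.scale),
        sigma2_ml=sigma2_ml,
        sum_log_w=sum_log_w,
        n=n,
        k=k,
        aic=float(-2.0 * llf + 2.0 * k),
        pvalues=dict(zip(names, map(float, res.pvalues))),
        spec=spec,
        degenerate=degenerate,
    )
    return fit


def aic(fit: FitResult | SexSplitFit) -> float:
    """AIC = -2 max-log-likelihood + 2k, with k counting every coefficient
    plus each residual-variance parameter."""
    return fit.aic


def fit_sex_model(
    series: pd.DataFrame, sex_model: str, weighting: str,
    outcome_label: str | None = None, teeth: tuple[int, ...] | None = None,
) -> FitResult | SexSplitFit:
    """Fit one (sex model, weighting) candidate on an outcome series."""
    spec = ModelSpec(sex_model, weighting, outcome_label, teeth)
    if sex_model == "v":
        sexes = set(series["sex"])
        if sexes != {"F", "M"}:
            raise DegenerateDesignError(
                f"sex model v requires both sexes, found {sorted(sexes)}"
            )
        fits: dict[str, FitResult] = {}
        for sex in ("F", "M"):
            sub = series[series["sex"] == sex]
            X, names = design_matrix(sub, "i")
            w = regression_weights(weighting, sub["age_years"].to_numpy())
            fits[sex] = fit_wls(X, sub["y"].to_numpy(), w, names, ModelSpec("i", weighting))
        return SexSplitFit(fits=fits, spec=spec)
    X, names = design_matrix(series, sex_model)
    w = regression_weights(weighting, series["age_years"].to_numpy())
    fit = fit_wls(X, series["y"].to_numpy(), w, names, spec)
    fit.n_by_sex = series["sex"].value_counts().to_dict()
    return fit


def select_model(
    series: pd.DataFrame,
    outcome_label: str | None = None,
    teeth: tuple[int, ...] | None = None,
) -> FitResult | SexSplitFit:
    """AIC selection over the 5 x 3 grid of sex models and weightings.

    Candidates within 2 AIC units of the minimum are conventionally
    indistinguishable; among them the most parsimonious fit is returned
    (fewest parameters, then the weighting order constant/age/1-per-age,
    then the simplest sex structure).  Without this parsimony band a
    strict arg-min AIC overselects the larger nested models at the usual
    ~16% chi-square rate.  Candidates that cannot be fitted (single-sex
    data, rank deficiency, perfect fits) are skipped; if none survives a
    ``SelectionError`` is raised.
    """
    candidates: list[tuple[float, int, int, int, FitResult | SexSplitFit]] = []
    for mi, sex_model in enumerate(SEX_MODELS):
        for wi, weighting in enumerate(WEIGHTINGS):
            try:
                fit = fit_sex_model(series, sex_model, weighting, outcome_label, teeth)
            except (DegenerateDesignError, SingularDesignError, DegenerateFitError) as exc:
                logger.debug("candidate (%s, %s) skipped: %s", sex_model, weighting, exc)
                continue
            if fit.degenerate:
                logger.debug("candidate (%s, %s) degenerate, skipped", sex_model, weighting)
                continue
            candidates.append((fit.aic, fit.k, wi, mi, fit))
    if not candidates:
        raise SelectionError("all 15 candidate fits were degenerate")
    aic_min = min(c[0] for c in candidates)
    band = [c for c in candidates if c[0] <= aic_min + AIC_EQUIVALENCE]
    k_min = min(c[1] for c in band)
    # parsimony only trades AIC for fewer parameters; among equally
    # complex candidates the lower AIC wins (exact ties by weighting
    # order, then sex-model order)
    band.sort(key=lambda t: (t[1] != k_min, t[0], t[2], t[3]))
    return band[0][4]


def ranking_pvalue(fit: FitResult | SexSplitFit) -> float:
    """p-value used to rank (outcome, tooth set) candidates: the common
    age p for pooled-slope models, else the larger per-sex age p."""
    pvals = fit.age_pvalues()
    return max(pvals.values())


def explore(
    cohort: pd.DataFrame,
    specs: list[OutcomeSpec],
    toothsets: list[tuple[int, ...]] | None = None,
    averaging: str = "ratio_mean",
) -> pd.DataFrame:
    """Run model selection for every (outcome, tooth set) candidate.

    Returns one row per candidate sorted ascending by the ranking p-value
    with the best row first; candidates with insufficient data are kept
    with status 'skipped' (and NaN statistics) rather than dropped
    silently.  AIC selection is performed independently per candidate.
    """
    toothsets = toothsets if toothsets is not None else enumerate_toothsets()
    rows = []
    for spec in specs:
        for teeth in toothsets:
            row: dict[str, object] = {
                "outcome": spec.label,
                "teeth": "+".join(str(t) for t in teeth),
                "status": "ok",
            }
            try:
                series = outcome_series(cohort, spec, teeth, averaging=averaging)
                fit = select_model(series, spec.label, tuple(teeth))
            except Exception as exc:  # recorded, not silently dropped
                logger.warning("candidate (%s, %s) skipped: %s", spec.label, teeth, exc)
                row.update(
                    status="skipped", reason=str(exc), sex_model=None, weighting=None,
                    aic=np.nan, p_common=np.nan, p_F=np.nan, p_M=np.nan,
                    ranking_p=np.nan, n=np.nan,
                )
                rows.append(row)
                continue
            pvals = fit.age_pvalues()
            row.update(
                reason="",
                sex_model=fit.spec.sex_model,
                weighting=fit.spec.weighting,
                aic=fit.aic,
                p_common=pvals.get("common", np.nan),
                p_F=pvals.get("F", np.nan),
                p_M=pvals.get("M", np.nan),
                ranking_p=ranking_pvalue(fit),
                n=fit.n,
            )
            rows.append(row)
    report = pd.DataFrame(rows)
    report = report.sort_values(
        ["ranking_p", "outcome", "teeth"], na_position="last", kind="stable"
    ).reset_index(drop=True)
    report["best"] = False
    if report["ranking_p"].notna().any():
        report.loc[0, "best"] = True
    return report
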