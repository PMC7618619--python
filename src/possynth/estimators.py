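"""Point estimators for the population mean SBP under nonpositivity.

Estimand: ``mu = E[Y]`` for children aged 2-17, where Y (SBP) is observed
only in the positive region (ages 8-17) and there only for complete cases.
The decomposition

    mu = E[Y | X*=1] Pr(X*=1) + E[Y | X*=0] Pr(X*=0) = e1*p1 + e0*p0

drives the synthesis estimator: e1 comes from a statistical model fit to
positive-region complete cases (g-computation), e0 from a mathematical
model built on external information (or from a sensitivity grid for
bounds). Competing estimators — complete-case mean and linear
extrapolation — are provided for comparison. All estimators are
survey-weighted; variance estimation is delegated to the resampling module.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .data import AnalysisDataset, REGION_CUT, AGE_MAX
from .reference import ReferenceTable, match_units

logger = logging.getLogger(__name__)

SATURATED = "saturated"
LINEAR = "linear"
COVARIATE = "covariate"  # main effects: age + gender + height + body_weight


class EstimationError(ValueError):
    pass


class PositivityError(EstimationError):
    """An age stratum required by a saturated fit has no complete cases."""


class ExtrapolationError(EstimationError):
    """A model was asked to predict outside its fitted support without the
    explicit allow-extrapolation flag."""


@dataclass
class OutcomeModel:
    """Fitted weighted outcome regression on complete cases.

    ``formula`` is one of {saturated, linear, covariate}. A saturated fit
    over the positive region carries one coefficient per age 8-17 (each
    equal to the survey-weighted mean of Y at that age); the linear form is
    ``b0 + b1*age``; the covariate form adds gender, height and body weight
    main effects.
    """

    formula: str
    beta: dict
    fit_region: str  # {"positive_only", "all_complete_cases"}
    weighted: bool = True
    fitted_ages: tuple = ()
    n_dropped_missing_covariates: int = 0

    def predict(self, df: pd.DataFrame, allow_extrapolation: bool = False) -> np.ndarray:
        ages = df["age"].to_numpy()
        if self.formula == SATURATED:
            out = np.empty(len(df))
            for i, a in enumerate(ages):
                if int(a) not in self.beta:
                    raise ExtrapolationError(
                        f"saturated model has no coefficient for age {int(a)}"
                    )
                out[i] = self.beta[int(a)]
            return out
        lo, hi = min(self.fitted_ages), max(self.fitted_ages)
        outside = (ages < lo) | (ages > hi)
        if outside.any() and not allow_extrapolation:
            raise ExtrapolationError(
                f"prediction requested for ages outside the fitted range {lo}-{hi}; "
                "pass allow_extrapolation=True to extrapolate deliberately"
            )
        if outside.any():
            logger.warning("extrapolating predictions for %d units outside ages %d-%d",
                           int(outside.sum()), lo, hi)
        pred = self.beta["intercept"] + self.beta["age"] * ages
        if self.formula == COVARIATE:
            male = (df["gender"].to_numpy() == "male").astype(float)
            pred = (pred + self.beta["gender_male"] * male
                    + self.beta["height"] * df["height"].to_numpy()
                    + self.beta["body_weight"] * df["body_weight"].to_numpy())
        return pred


@dataclass
class EstimateResult:
    """A point estimate of mu (or of a regional mean) with optional CI."""

    method: str
    point: float
    ci_lower: float | None = None
    ci_upper: float | None = None
    components: dict = field(default_factory=dict)
    b_resamples: int = 0
    n: int = 0
    log: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "point": self.point,
            "ci_lower": self.ci_lower,
            "ci_upper": self.ci_upper,
            "components": self.components,
            "b_resamples": self.b_resamples,
            "n": self.n,
            "log": self.log,
        }


def _weighted_mean(y: np.ndarray, w: np.ndarray) -> float:
    return float(np.sum(w * y) / np.sum(w))


def complete_case_mean(ds: AnalysisDataset) -> EstimateResult:
    """Survey-weighted mean of observed SBP (ignores the missing-data problem).

    Biased for mu whenever SBP and missingness are dependent — here upward,
    because the never-observed ages 2-7 have lower SBP.
    """
    cc = ds.df[ds.df["r"] == 1]
    if len(cc) == 0:
        raise EstimationError("no complete cases")
    point = _weighted_mean(cc["sbp"].to_numpy(), cc["w"].to_numpy())
    return EstimateResult(method="complete_case", point=point, n=ds.n,
                          log={"n_complete": len(cc)})


def fit_outcome_model(
    ds: AnalysisDataset,
    formula: str = SATURATED,
    fit_region: str = "positive_only",
) -> OutcomeModel:
    """Weighted least-squares outcome regression on complete cases.

    The saturated fit is computed in closed form: the coefficient for age x
    is the survey-weighted mean of Y among complete cases of age x (every
    age in the fit region must have at least one complete case). Parametric
    fits use statsmodels WLS with the survey weights as regression weights.
    Units with missing height/body weight are dropped from the covariate
    fit only, with a logged count.
    """
    df = ds.df
    if fit_region == "positive_only":
        df = df[df["x_star"] == 1]
    elif fit_region != "all_complete_cases":
        raise EstimationError(f"unknown fit_region: {fit_region}")
    cc = df[df["r"] == 1]
    if len(cc) == 0:
        raise EstimationError("no complete cases in the fit region")

    if formula == SATURATED:
        ages_region = np.sort(df["age"].unique())
        beta = {}
        for a in ages_region:
            sub = cc[cc["age"] == a]
            if len(sub) == 0:
                raise PositivityError(f"no complete cases at age {a} for the saturated fit")
            beta[int(a)] = _weighted_mean(sub["sbp"].to_numpy(), sub["w"].to_numpy())
        return OutcomeModel(formula=SATURATED, beta=beta, fit_region=fit_region,
                            fitted_ages=tuple(int(a) for a in ages_region))

    n_dropped = 0
    if formula == LINEAR:
        X = sm.add_constant(cc["age"].to_numpy(float))
        names = ["intercept", "age"]
    elif formula == COVARIATE:
        full = cc[["age", "gender", "height", "body_weight"]].copy()
        keep = full["height"].notna() & full["body_weight"].notna()
        n_dropped = int((~keep).sum())
        if n_dropped:
            logger.info("covariate fit: dropped %d complete cases with missing "
                        "height/body weight", n_dropped)
        cc = cc[keep.to_numpy()]
        if len(cc) == 0:
            raise EstimationError("no complete cases with full covariates")
        male = (cc["gender"] == "male").astype(float).to_numpy()
        X = sm.add_constant(np.column_stack([
            cc["age"].to_numpy(float), male,
            cc["height"].to_numpy(float), cc["body_weight"].to_numpy(float),
        ]))
        names = ["intercept", "age", "gender_male", "height", "body_weight"]
    else:
        raise EstimationError(f"unknown formula: {formula}")
    fit = sm.WLS(cc["sbp"].to_numpy(), X, weights=cc["w"].to_numpy()).fit()
    beta = dict(zip(names, (float(b) for b in fit.params)))
    return OutcomeModel(formula=formula, beta=beta, fit_region=fit_region,
                        fitted_ages=tuple(int(a) for a in np.sort(cc["age"].unique())),
                        n_dropped_missing_covariates=n_dropped)


def gcomp_mean(
    ds: AnalysisDataset,
    model: OutcomeModel,
    target_region: str = "positive_only",
    allow_extrapolation: bool = False,
) -> EstimateResult:
    """g-computation: predict SBP for every unit in the target region
    (observed and missing alike) and take the survey-weighted average.

    With the saturated model and ``target_region="positive_only"`` this is
    the positive-region mean e1. With the linear model and
    ``target_region="all"`` it is the extrapolation estimator (requires
    ``allow_extrapolation=True``: the linear fit is projected below age 8).
    """
    df = ds.df
    if target_region == "positive_only":
        df = df[df["x_star"] == 1]
    elif target_region != "all":
        raise EstimationError(f"unknown target_region: {target_region}")
    if len(df) == 0:
        raise EstimationError("no units in the target region")
    pred = model.predict(df, allow_extrapolation=allow_extrapolation)
    point = _weighted_mean(pred, df["w"].to_numpy())
    method = "extrapolation" if target_region == "all" else "gcomp"
    return EstimateResult(method=method, point=point, n=len(df),
                          log={"formula": model.formula})


def region_probability(ds: AnalysisDataset) -> tuple[float, float]:
    """Survey-weighted region shares (p1, p0); p1 + p0 = 1 exactly."""
    return ds.region_shares(weighted=True)


def mathematical_region_mean(
    ds: AnalysisDataset,
    table: ReferenceTable,
    rng: np.random.Generator,
    draws_per_unit: int = 1,
    lms_table: pd.DataFrame | None = None,
) -> EstimateResult:
    """Mathematical-model estimate of the nonpositive-region mean e0.

    Each X*=0 unit is matched to its reference cell and imputed with the
    average of ``draws_per_unit`` normal draws; e0 is the survey-weighted
    mean of the per-unit imputations.
    """
    idx = np.flatnonzero(ds.df["x_star"].to_numpy() == 0)
    if len(idx) == 0:
        raise EstimationError("no nonpositive-region units to impute")
    m = match_units(ds, table, units=idx, lms_table=lms_table)
    mu = m["mu"].to_numpy()
    sigma = m["sigma"].to_numpy()
    draws = mu[:, None] + sigma[:, None] * rng.standard_normal((len(idx), draws_per_unit))
    imputed = draws.mean(axis=1)
    w = ds.df["w"].to_numpy()[idx]
    point = _weighted_mean(imputed, w)
    return EstimateResult(method="mathematical_region_mean", point=point, n=len(idx),
                          log={"draws_per_unit": draws_per_unit})


def synthesis_mean(e1: float, e0: float, p1: float) -> float:
    """Combine regional means: ``e1*p1 + e0*(1 - p1)``."""
    if not (0.0 <= p1 <= 1.0):
        raise EstimationError(f"p1 must lie in [0, 1], got {p1}")
    return e1 * p1 + e0 * (1.0 - p1)


def synthesis_point(
    ds: AnalysisDataset,
    table: ReferenceTable,
    rng: np.random.Generator,
    formula: str = SATURATED,
    draws_per_unit: int = 1,
    lms_table: pd.DataFrame | None = None,
) -> EstimateResult:
    """One-shot synthesis estimate (no resampling): e1 from g-computation in
    the positive region, e0 from the mathematical model, combined by the
    region shares."""
    model = fit_outcome_model(ds, formula=formula, fit_region="positive_only")
    e1 = gcomp_mean(ds, model, target_region="positive_only").point
    e0 = mathematical_region_mean(ds, table, rng, draws_per_unit=draws_per_unit,
                                  lms_table=lms_table).point
    p1, p0 = region_probability(ds)
    point = synthesis_mean(e1, e0, p1)
    return EstimateResult(method="synthesis", point=point, n=ds.n,
                          components={"e1": e1, "e0": e0, "p1": p1})


def bounds_curve(ds: AnalysisDataset, e1: float, e0_grid) -> pd.DataFrame:
    """Sensitivity analysis: mu(e0) = e1*p1 + e0*p0 over a grid of plausible
    nonpositive-region means. Affine in e0 with slope p0; the grid endpoints
    give the bounds."""
    grid = np.asarray(list(e0_grid), dtype=float)
    if len(grid) == 0:
        raise EstimationError("empty e0 grid")
    p1, p0 = region_probability(ds)
    mu = e1 * p1 + grid * p0
    return pd.DataFrame({"e0": grid, "mu": mu})


def aipw_positive_mean(
    ds: AnalysisDataset,
    propensity_formula: str = SATURATED,
    outcome_formula: str = SATURATED,
    truncation_floor: float = 0.01,
) -> EstimateResult:
    """Augmented IPW estimate of the positive-region mean e1.

    Fits a weighted logistic missingness model pi(V) = Pr(R=1 | V) and a
    weighted outcome model m(V) on the positive region, then averages the
    doubly robust influence-type transformation

        r*y/pi - ((r - pi)/pi) * m(V)

    over X*=1 units with the survey weights. Consistent when either model
    is correctly specified. Fitted probabilities are truncated below at
    ``truncation_floor`` with a logged count.
    """
    pos = ds.df[ds.df["x_star"] == 1].copy()
    if len(pos) == 0:
        raise EstimationError("no positive-region units")
    if (pos["r"] == 1).sum() == 0:
        raise EstimationError("no complete cases in the positive region")

    r = pos["r"].to_numpy(float)
    w = pos["w"].to_numpy()

    def design(formula: str, frame: pd.DataFrame) -> np.ndarray:
        if formula == SATURATED:
            ages = np.arange(REGION_CUT, AGE_MAX + 1)
            return (frame["age"].to_numpy()[:, None] == ages[None, :]).astype(float)
        if formula == LINEAR:
            return sm.add_constant(frame["age"].to_numpy(float))
        if formula == COVARIATE:
            male = (frame["gender"] == "male").astype(float).to_numpy()
            return sm.add_constant(np.column_stack([
                frame["age"].to_numpy(float), male,
                frame["height"].to_numpy(float), frame["body_weight"].to_numpy(float),
            ]))
        if formula == "intercept":
            return np.ones((len(frame), 1))
        raise EstimationError(f"unknown formula: {formula}")

    if propensity_formula == SATURATED:
        # closed form: weighted observation rate per age (robust to separation
        # when an age stratum is fully observed)
        ages_arr = pos["age"].to_numpy()
        pi_hat = np.empty(len(pos))
        for a in np.unique(ages_arr):
            mask = ages_arr == a
            pi_hat[mask] = np.sum(w[mask] * r[mask]) / np.sum(w[mask])
    else:
        Xp = design(propensity_formula, pos)
        glm = sm.GLM(r, Xp, family=sm.families.Binomial(), var_weights=w)
        pi_hat = np.asarray(glm.fit().predict(Xp))
    n_trunc = int((pi_hat < truncation_floor).sum())
    if n_trunc:
        logger.warning("aipw: truncated %d fitted probabilities below %.3g",
                       n_trunc, truncation_floor)
    pi_hat = np.clip(pi_hat, truncation_floor, 1.0)

    cc_mask = r == 1
    if outcome_formula == COVARIATE:
        keep = pos["height"].notna().to_numpy() & pos["body_weight"].notna().to_numpy()
    else:
        keep = np.ones(len(pos), dtype=bool)
    Xo = design(outcome_formula, pos)
    fit_mask = cc_mask & keep
    if fit_mask.sum() == 0:
        raise EstimationError("no complete cases with full covariates for the outcome model")
    wls = sm.WLS(pos["sbp"].to_numpy()[fit_mask], Xo[fit_mask], weights=w[fit_mask]).fit()
    m_hat = Xo @ np.asarray(wls.params)
    bad = ~np.isfinite(m_hat)
    if bad.any():
        # units with missing covariates get a neutral augmentation term
        m_hat[bad] = _weighted_mean(m_hat[~bad], w[~bad])
        logger.info("aipw: %d units with missing covariates given the mean augmentation", int(bad.sum()))

    y = np.nan_to_num(pos["sbp"].to_numpy(), nan=0.0)
    inf = r * y / pi_hat - ((r - pi_hat) / pi_hat) * m_hat
    point = _weighted_mean(inf, w)
    return EstimateResult(method="aipw_e1", point=point, n=len(pos),
                          log={"n_truncated": n_trunc})
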