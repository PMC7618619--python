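"""Point estimators: complete-case, g-computation, synthesis, bounds, AIPW."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from hypothesis import given, settings, strategies as st

from possynth import (
    ReferenceTable,
    bounds_curve,
    complete_case_mean,
    fit_outcome_model,
    gcomp_mean,
    mathematical_region_mean,
    region_probability,
    synthesis_mean,
    synthesis_point,
    aipw_positive_mean,
    SimulationConfig,
    simulate_population,
    true_mean,
)
from possynth.estimators import (
    EstimationError,
    ExtrapolationError,
    PositivityError,
)
from .conftest import make_dataset, random_dataset


def test_complete_case_weighted_mean_examples():
    ds = make_dataset(ages=[9, 10], sbp=[100.0, 120.0], w=[1.0, 3.0])
    assert complete_case_mean(ds).point == pytest.approx(115.0)
    ds_eq = make_dataset(ages=[9, 10, 11], sbp=[100.0, 110.0, 90.0])
    assert complete_case_mean(ds_eq).point == pytest.approx(100.0)


def test_complete_case_matches_direct_summation_oracle():
    ds = random_dataset(np.random.default_rng(0), n=50)
    cc = ds.df[ds.df["r"] == 1]
    oracle = np.sum(cc["w"] * cc["sbp"]) / np.sum(cc["w"])
    assert complete_case_mean(ds).point == pytest.approx(oracle, abs=1e-12)


def test_complete_case_requires_observed_outcomes():
    ds = make_dataset(ages=[3, 4], sbp=[np.nan, np.nan])
    with pytest.raises(EstimationError):
        complete_case_mean(ds)


def test_saturated_fit_equals_stratum_means():
    ds = make_dataset(ages=[8, 8, 9, 9], sbp=[95.0, 105.0, 105.0, 115.0],
                      w=[1.0, 1.0, 1.0, 3.0])
    model = fit_outcome_model(ds, "saturated")
    assert model.beta[8] == pytest.approx(100.0)
    assert model.beta[9] == pytest.approx(112.5)


def test_saturated_fit_matches_per_age_oracle_and_statsmodels():
    ds = random_dataset(np.random.default_rng(1), n=120)
    model = fit_outcome_model(ds, "saturated")
    cc = ds.df[(ds.df["r"] == 1) & (ds.df["x_star"] == 1)]
    for a, beta in model.beta.items():
        sub = cc[cc["age"] == a]
        oracle = np.sum(sub["w"] * sub["sbp"]) / np.sum(sub["w"])
        assert beta == pytest.approx(oracle, abs=1e-10)
    # cross-check against a WLS fit on age indicators
    X = pd.get_dummies(cc["age"]).to_numpy(float)
    wls = sm.WLS(cc["sbp"].to_numpy(), X, weights=cc["w"].to_numpy()).fit()
    ages = np.sort(cc["age"].unique())
    for a, b_hat in zip(ages, wls.params):
        assert model.beta[int(a)] == pytest.approx(b_hat, abs=1e-8)


def test_saturated_fit_raises_on_empty_age_stratum():
    ds = make_dataset(ages=[8, 9, 9], sbp=[100.0, np.nan, np.nan])
    with pytest.raises(PositivityError, match="age 9"):
        fit_outcome_model(ds, "saturated")


def test_linear_fit_recovers_noiseless_law():
    ages = np.array([8, 9, 10, 11, 12, 13])
    ds = make_dataset(ages=ages, sbp=80.0 + 2.0 * ages)
    model = fit_outcome_model(ds, "linear")
    assert model.beta["intercept"] == pytest.approx(80.0, abs=1e-8)
    assert model.beta["age"] == pytest.approx(2.0, abs=1e-10)


def test_covariate_fit_drops_and_counts_incomplete_covariates():
    ds = make_dataset(
        ages=[8, 9, 10, 11], sbp=[100.0, 104.0, 102.0, 106.0],
        height=[130.0, 135.0, np.nan, 140.0],
        body_weight=[30.0, 33.0, 35.0, 38.0],
        gender=["male", "female", "male", "female"],
    )
    model = fit_outcome_model(ds, "covariate")
    assert model.n_dropped_missing_covariates == 1


def test_gcomp_weighted_average_of_stratum_means():
    ds = make_dataset(ages=[8, 8, 9, 9], sbp=[100.0, np.nan, 110.0, np.nan])
    model = fit_outcome_model(ds, "saturated")
    assert gcomp_mean(ds, model, "positive_only").point == pytest.approx(105.0)


def test_gcomp_linear_over_all_ages_uniform():
    ages = np.arange(2, 18)
    sbp = np.where(ages >= 8, 80.0 + 2.0 * ages, np.nan)
    ds = make_dataset(ages=ages, sbp=sbp)
    model = fit_outcome_model(ds, "linear")
    est = gcomp_mean(ds, model, "all", allow_extrapolation=True)
    assert est.point == pytest.approx(80.0 + 2.0 * ages.mean(), abs=1e-8)  # 99.0
    assert est.method == "extrapolation"


def test_gcomp_matches_predict_then_average_oracle():
    ds = random_dataset(np.random.default_rng(4), n=80)
    model = fit_outcome_model(ds, "saturated")
    pos = ds.df[ds.df["x_star"] == 1]
    pred = np.array([model.beta[int(a)] for a in pos["age"]])
    oracle = np.sum(pos["w"].to_numpy() * pred) / pos["w"].sum()
    assert gcomp_mean(ds, model, "positive_only").point == pytest.approx(oracle, abs=1e-12)


def test_extrapolation_guard_requires_explicit_flag():
    ages = np.arange(2, 18)
    sbp = np.where(ages >= 8, 80.0 + 2.0 * ages, np.nan)
    ds = make_dataset(ages=ages, sbp=sbp)
    linear = fit_outcome_model(ds, "linear")
    with pytest.raises(ExtrapolationError):
        gcomp_mean(ds, linear, "all")
    saturated = fit_outcome_model(ds, "saturated")
    with pytest.raises(ExtrapolationError, match="no coefficient for age"):
        gcomp_mean(ds, saturated, "all", allow_extrapolation=True)


def test_region_probability_examples_and_oracle():
    ds = make_dataset(ages=[5, 6, 9, 10], sbp=[np.nan, np.nan, 100.0, 101.0])
    assert region_probability(ds) == pytest.approx((0.5, 0.5))
    ds_w = make_dataset(ages=[9, 5], sbp=[100.0, np.nan], w=[1.0, 3.0])
    assert region_probability(ds_w) == pytest.approx((0.25, 0.75))
    ds_r = random_dataset(np.random.default_rng(6), n=70)
    w = ds_r.df["w"].to_numpy()
    oracle = np.sum(w[ds_r.df["x_star"] == 1]) / w.sum()
    p1, p0 = region_probability(ds_r)
    assert p1 == pytest.approx(oracle, abs=1e-12)
    assert p1 + p0 == 1.0


def _point_mass_table(p50=95.0):
    rows = [{"age": a, "gender": g, "height_pct": 50, "p50": p50, "p90": p50}
            for a in range(2, 8) for g in ("male", "female")]
    return ReferenceTable(pd.DataFrame(rows))


def test_mathematical_region_mean_degenerate_table_is_exact():
    ds = make_dataset(ages=[3, 5, 9], sbp=[np.nan, np.nan, 100.0], w=[1.0, 2.0, 1.0])
    est = mathematical_region_mean(ds, _point_mass_table(95.0), np.random.default_rng(0))
    assert est.point == pytest.approx(95.0)


def test_mathematical_region_mean_lln_against_matched_mu():
    cfg = SimulationConfig(n=400, seed=3)
    ds = simulate_population(cfg)
    from possynth import emit_reference_table, match_units

    table = emit_reference_table(cfg)
    idx = np.flatnonzero(ds.df["x_star"].to_numpy() == 0)
    m = match_units(ds, table, units=idx)
    w = ds.df["w"].to_numpy()[idx]
    closed_form = np.sum(w * m["mu"].to_numpy()) / w.sum()
    est = mathematical_region_mean(ds, table, np.random.default_rng(8), draws_per_unit=4000)
    se = np.sqrt(np.sum((w / w.sum()) ** 2)) * m["sigma"].max() / np.sqrt(4000)
    assert est.point == pytest.approx(closed_form, abs=5 * max(se, 1e-3))


def test_mathematical_region_mean_requires_nonpositive_units():
    ds = make_dataset(ages=[9, 10], sbp=[100.0, 101.0])
    with pytest.raises(EstimationError):
        mathematical_region_mean(ds, _point_mass_table(), np.random.default_rng(0))


@pytest.mark.parametrize("e1, e0, p1, expected",
                         [(110.0, 90.0, 0.5, 100.0), (110.0, 90.0, 1.0, 110.0),
                          (110.0, 90.0, 0.0, 90.0)])
def test_synthesis_mean_combination(e1, e0, p1, expected):
    assert synthesis_mean(e1, e0, p1) == pytest.approx(expected)


def test_synthesis_mean_rejects_invalid_share():
    with pytest.raises(EstimationError):
        synthesis_mean(100.0, 90.0, 1.2)


@settings(derandomize=True, max_examples=60)
@given(e1=st.floats(70, 130), e0=st.floats(70, 130), d=st.floats(0, 10),
       p1=st.floats(0, 1))
def test_synthesis_mean_monotone_and_bounded(e1, e0, d, p1):
    base = synthesis_mean(e1, e0, p1)
    assert synthesis_mean(e1 + d, e0, p1) >= base - 1e-9
    assert synthesis_mean(e1, e0 + d, p1) >= base - 1e-9
    assert min(e1, e0) - 1e-9 <= base <= max(e1, e0) + 1e-9


def test_synthesis_point_equals_full_imputation_oracle(sim_ds, sim_table):
    # build a fully imputed copy: model predictions in the positive region,
    # matched draws in the nonpositive region; its weighted mean must equal
    # e1*p1 + e0*p0 computed from the same components
    from possynth import match_units

    res = synthesis_point(sim_ds, sim_table, np.random.default_rng(21), draws_per_unit=1)
    e1, e0, p1 = (res.components[k] for k in ("e1", "e0", "p1"))
    assert res.point == pytest.approx(synthesis_mean(e1, e0, p1), abs=1e-12)
    w = sim_ds.df["w"].to_numpy()
    xs = sim_ds.df["x_star"].to_numpy()
    filled = np.where(xs == 1, e1, e0)
    oracle = np.sum(w * filled) / w.sum()
    assert res.point == pytest.approx(oracle, abs=1e-10)


def test_bounds_curve_is_affine_with_slope_p0(sim_ds):
    e1 = 105.0
    curve = bounds_curve(sim_ds, e1, [70.0, 95.0, 120.0])
    p1, p0 = region_probability(sim_ds)
    slopes = np.diff(curve["mu"]) / np.diff(curve["e0"])
    assert slopes == pytest.approx([p0, p0], abs=1e-12)
    second_diff = np.diff(curve["mu"], n=2)
    assert abs(second_diff).max() < 1e-12
    # e0 = e1 on the grid reproduces e1
    ident = bounds_curve(sim_ds, e1, [e1])
    assert ident["mu"].iloc[0] == pytest.approx(e1, abs=1e-12)


def test_aipw_reduces_to_weighted_mean_without_missingness():
    ds = make_dataset(ages=[8, 9, 10, 11], sbp=[100.0, 104.0, 108.0, 112.0],
                      w=[1.0, 2.0, 1.0, 2.0])
    est = aipw_positive_mean(ds, propensity_formula="saturated",
                             outcome_formula="saturated")
    oracle = complete_case_mean(ds).point
    assert est.point == pytest.approx(oracle, abs=1e-10)


def test_aipw_saturated_equals_saturated_gcomp():
    # with discrete age and saturated models on both sides, AIPW collapses
    # algebraically to the stratified-mean g-computation estimate
    for seed in range(5):
        ds = random_dataset(np.random.default_rng(seed), n=150)
        model = fit_outcome_model(ds, "saturated")
        gc = gcomp_mean(ds, model, "positive_only").point
        ai = aipw_positive_mean(ds, "saturated", "saturated").point
        assert ai == pytest.approx(gc, abs=1e-8)


def test_aipw_double_robustness_under_single_misspecification():
    """Bias stays within Monte-Carlo error of 0 when exactly one of the two
    nuisance models is wrong (an intercept-only fit is misspecified here
    because both SBP and missingness depend on age)."""
    true_e1 = true_mean(SimulationConfig(), region=1)
    n_rep = 200
    ests = {"good_pi": np.empty(n_rep), "good_outcome": np.empty(n_rep)}
    for rep in range(n_rep):
        ds = simulate_population(SimulationConfig(n=2000, seed=50_000 + rep))
        ests["good_pi"][rep] = aipw_positive_mean(
            ds, propensity_formula="linear", outcome_formula="intercept").point
        ests["good_outcome"][rep] = aipw_positive_mean(
            ds, propensity_formula="intercept", outcome_formula="linear").point
    for label, vals in ests.items():
        bias = vals.mean() - true_e1
        mcse = vals.std(ddof=1) / np.sqrt(n_rep)
        assert abs(bias) < 3 * mcse, f"{label}: bias {bias:.4f} vs mcse {mcse:.4f}"


def test_complete_case_biased_upward_when_young_ages_are_masked():
    cfg = SimulationConfig(n=4000, seed=77)
    ds = simulate_population(cfg)
    cc = complete_case_mean(ds).point
    assert cc > true_mean(cfg) + 3.0  # deterministic masking of low-SBP ages
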