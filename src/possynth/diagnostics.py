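"""Positive-region agreement diagnostic for the mathematical model.

The external information also covers ages 8-17, where SBP is (mostly)
observed, so the mathematical model can be checked against the statistical
model on its overlap: per age, compare the survey-weighted complete-case
mean with the survey-weighted mean of mathematical-model draws for the same
resample, and summarise the paired differences over resamples. The check is
a null diagnostic of the external information on the positive region; it
cannot assess the mathematical model's validity in the nonpositive region,
where no comparison is possible.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .data import AnalysisDataset, AGE_MAX, REGION_CUT
from .bootstrap import ResampleConfig, resample_indices, _Arrays
from .reference import ReferenceTable, CoverageError


def model_agreement(
    ds: AnalysisDataset,
    table: ReferenceTable,
    cfg: ResampleConfig,
    lms_table=None,
) -> pd.DataFrame:
    """Per-age comparison of statistical vs mathematical model means.

    For each age 8-17 present in the data: ``stat_mean`` is the weighted
    complete-case mean, ``math_mean`` the weighted mean of reference-model
    draws over all positive-region units of that age (complete cases and
    missing alike, matching how the model is deployed). ``diff = stat_mean
    - math_mean`` with its point estimate and 95% CI taken as the median
    and 2.5/97.5 percentiles of the paired within-resample differences.

    No multiplicity adjustment is applied across ages: this is a
    diagnostic display, not a family of formal tests.
    """
    pos_ages = np.sort(ds.df.loc[ds.df["x_star"] == 1, "age"].unique())
    missing_cells = {
        (int(a), g)
        for a in pos_ages
        for g in ds.df.loc[ds.df["age"] == a, "gender"].unique()
    } - table.coverage
    if missing_cells:
        raise CoverageError(
            f"reference table lacks positive-region cells: {sorted(missing_cells)[:5]}"
        )
    arr = _Arrays(ds, table, match_positive=True, lms_table=lms_table)
    rng = np.random.default_rng(cfg.seed)
    nb = AGE_MAX + 1

    def per_age(idx: np.ndarray, w_s: np.ndarray):
        """(stat, math) per-age weighted means for one (re)sample."""
        age, r, xs = arr.age[idx], arr.r[idx], arr.xs[idx]
        y, mu, sigma = arr.y[idx], arr.mu[idx], arr.sigma[idx]
        pos = xs == 1
        cc = pos & (r == 1)
        w_cc = np.bincount(age[cc], weights=w_s[cc], minlength=nb)
        wy_cc = np.bincount(age[cc], weights=(w_s * y)[cc], minlength=nb)
        eps = rng.standard_normal((int(pos.sum()), cfg.draws_per_unit))
        draws = (mu[pos, None] + sigma[pos, None] * eps).mean(axis=1)
        w_pos = np.bincount(age[pos], weights=w_s[pos], minlength=nb)
        wd_pos = np.bincount(age[pos], weights=w_s[pos] * draws, minlength=nb)
        ok = (w_cc > 0) & (w_pos > 0)
        with np.errstate(invalid="ignore", divide="ignore"):
            sm_ = np.where(ok, wy_cc / np.where(w_cc > 0, w_cc, 1.0), np.nan)
            mm_ = np.where(ok, wd_pos / np.where(w_pos > 0, w_pos, 1.0), np.nan)
        return sm_, mm_

    # point values on the full sample; CI from paired within-resample diffs
    full_idx = np.arange(arr.n)
    stat_pt, math_pt = per_age(full_idx, arr.w)
    diffs = np.full((cfg.b, nb), np.nan)
    for it in range(cfg.b):
        idx, w_s = resample_indices(arr.n, arr.w, cfg.scheme, rng)
        sm_, mm_ = per_age(idx, w_s)
        diffs[it] = sm_ - mm_

    rows = []
    for a in pos_ages:
        d = diffs[:, a]
        d = d[~np.isnan(d)]
        if len(d) == 0 or np.isnan(stat_pt[a]) or np.isnan(math_pt[a]):
            continue
        lo, hi = np.percentile(d, [2.5, 97.5])
        rows.append({
            "age": int(a),
            "stat_mean": float(stat_pt[a]),
            "math_mean": float(math_pt[a]),
            "diff": float(stat_pt[a] - math_pt[a]),
            "ci_lower": float(lo),
            "ci_upper": float(hi),
        })
    return pd.DataFrame(rows)


def flag_disagreement(dt: pd.DataFrame) -> pd.DataFrame:
    """Ages whose 95% CI for (statistical - mathematical) excludes zero,
    with the direction of the discrepancy."""
    if not {"ci_lower", "ci_upper"}.issubset(dt.columns):
        raise ValueError("diagnostic table lacks CI columns")
    flagged = dt[(dt["ci_lower"] > 0) | (dt["ci_upper"] < 0)].copy()
    flagged["direction"] = np.where(flagged["ci_upper"] < 0, "stat < math", "stat > math")
    return flagged[["age", "diff", "ci_lower", "ci_upper", "direction"]].reset_index(drop=True)


def long_format(dt: pd.DataFrame) -> pd.DataFrame:
    """Plot-ready long table (age, model, value) for figure-style displays."""
    stat = dt[["age", "stat_mean"]].rename(columns={"stat_mean": "value"})
    stat["model"] = "statistical"
    math = dt[["age", "math_mean"]].rename(columns={"math_mean": "value"})
    math["model"] = "mathematical"
    return pd.concat([stat, math], ignore_index=True)[["age", "model", "value"]]
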