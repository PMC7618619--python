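"""Analysis data model for outcome-missing-by-design survey data.

The unit of analysis is a child aged 2-17 with a systolic blood pressure
(SBP) outcome that may be missing, a survey sampling weight, and covariates
(gender, height, body weight). The age range splits into a *positive region*
(ages 8-17, where SBP has a nonzero probability of being observed) and a
*nonpositive region* (ages 2-7, where SBP is never observed by design).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

AGE_MIN = 2
AGE_MAX = 17
REGION_CUT = 8  # first age of the positive region

#: canonical column order of the analysis table
COLUMNS = ["unit_id", "age", "gender", "height", "body_weight", "sbp", "r", "x_star", "w"]

_GENDER_CODES = {
    "1": "male", "2": "female",  # NHANES RIAGENDR convention
    "m": "male", "male": "male",
    "f": "female", "female": "female",
}


class SchemaError(ValueError):
    """A required column is absent or has the wrong type."""


class ValidationError(ValueError):
    """Record-level invariant violated (negative weight, bad age, ...)."""


def normalize_gender(value) -> str:
    """Map NHANES numeric codes (1/2) or string labels to {male, female}."""
    if pd.isna(value):
        raise ValidationError("gender is missing")
    if isinstance(value, (int, np.integer, float, np.floating)):
        value = str(int(value))
    key = str(value).strip().lower()
    if key not in _GENDER_CODES:
        raise ValidationError(f"unrecognised gender code: {value!r}")
    return _GENDER_CODES[key]


def derive_sbp(readings: Sequence) -> float:
    """Average up to three SBP readings; missing if fewer than two are present.

    Parameters
    ----------
    readings : sequence of mm Hg values, NaN/None where a reading was not taken.

    Returns
    -------
    float
        Arithmetic mean of the non-missing readings when at least two are
        available, otherwise ``nan``.
    """
    if len(readings) > 3:
        raise ValidationError("at most three SBP readings are supported")
    vals = []
    for x in readings:
        if x is None or (isinstance(x, float) and np.isnan(x)):
            continue
        if pd.isna(x):
            continue
        try:
            v = float(x)
        except (TypeError, ValueError) as exc:
            raise ValidationError(f"non-numeric SBP reading: {x!r}") from exc
        if v < 0:
            raise ValidationError(f"negative SBP reading: {v}")
        vals.append(v)
    if len(vals) < 2:
        return float("nan")
    return float(np.mean(vals))


def assign_region(age: int) -> int:
    """Positivity-region indicator: 1 for ages 8-17, 0 for ages 2-7."""
    age = int(age)
    if age < AGE_MIN or age > AGE_MAX:
        raise ValidationError(f"age {age} outside supported range {AGE_MIN}-{AGE_MAX}")
    return int(age >= REGION_CUT)


@dataclass
class AnalysisDataset:
    """Unit-level analysis table.

    Wraps a DataFrame with columns ``unit_id, age, gender, height,
    body_weight, sbp, r, x_star, w``. Invariants (checked on construction):
    ``r=1`` iff ``sbp`` observed, ``w>0``, ``x_star = 1[8 <= age <= 17]``,
    unique ``unit_id``.
    """

    df: pd.DataFrame
    source: str = "unknown"
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        df = self.df
        missing_cols = [c for c in COLUMNS if c not in df.columns]
        if missing_cols:
            raise SchemaError(f"missing columns: {missing_cols}")
        df = df[COLUMNS].reset_index(drop=True)
        if len(df) == 0:
            raise ValidationError("dataset is empty")
        if df["unit_id"].duplicated().any():
            dupes = df.loc[df["unit_id"].duplicated(), "unit_id"].tolist()
            raise ValidationError(f"duplicate unit_ids: {dupes[:5]}")
        bad_w = df.loc[~(df["w"] > 0), "unit_id"].tolist()
        if bad_w:
            raise ValidationError(f"nonpositive weights for units: {bad_w[:10]}")
        ages = df["age"].to_numpy()
        if (ages < AGE_MIN).any() or (ages > AGE_MAX).any():
            bad = df.loc[(ages < AGE_MIN) | (ages > AGE_MAX), "unit_id"].tolist()
            raise ValidationError(f"ages outside {AGE_MIN}-{AGE_MAX} for units: {bad[:10]}")
        expect_xs = (ages >= REGION_CUT).astype(int)
        if not np.array_equal(df["x_star"].to_numpy(int), expect_xs):
            raise ValidationError("x_star inconsistent with age-region rule")
        r = df["r"].to_numpy(int)
        sbp_obs = df["sbp"].notna().to_numpy()
        if not np.array_equal(r == 1, sbp_obs):
            raise ValidationError("r inconsistent with sbp missingness")
        df["gender"] = [normalize_gender(g) for g in df["gender"]]
        df["age"] = df["age"].astype(int)
        df["r"] = df["r"].astype(int)
        df["x_star"] = df["x_star"].astype(int)
        for c in ("height", "body_weight", "sbp", "w"):
            df[c] = df[c].astype(float)
        self.df = df

    @property
    def n(self) -> int:
        return len(self.df)

    def missing_fraction(self, weighted: bool = False, region: int | None = None) -> float:
        """Fraction of units with the outcome missing (r=0)."""
        df = self.df if region is None else self.df[self.df["x_star"] == region]
        miss = (df["r"] == 0).to_numpy(float)
        if weighted:
            w = df["w"].to_numpy()
            return float(np.sum(w * miss) / np.sum(w))
        return float(miss.mean())

    def region_shares(self, weighted: bool = True) -> tuple[float, float]:
        """(Pr(X*=1), Pr(X*=0)); survey-weighted by default; sums to 1 exactly."""
        xs = self.df["x_star"].to_numpy(float)
        w = self.df["w"].to_numpy() if weighted else np.ones(self.n)
        p1 = float(np.sum(w * xs) / np.sum(w))
        return p1, 1.0 - p1


def from_records(
    df: pd.DataFrame,
    source: str = "frame",
    derive_indicators: bool = True,
) -> AnalysisDataset:
    """Build an :class:`AnalysisDataset` from a raw frame.

    When ``derive_indicators`` is true, ``r`` is derived from ``sbp``
    missingness and ``x_star`` from the age-region rule.
    """
    df = df.copy()
    if "unit_id" not in df.columns:
        df["unit_id"] = np.arange(len(df))
    if derive_indicators:
        df["r"] = df["sbp"].notna().astype(int)
        df["x_star"] = [assign_region(a) for a in df["age"]]
    for col in ("height", "body_weight"):
        if col not in df.columns:
            df[col] = np.nan
    return AnalysisDataset(df=df, source=source)


def load_dataset(
    path,
    mapping: Mapping[str, str] | None = None,
    format: str = "csv",
    sbp_reading_columns: Sequence[str] | None = None,
) -> AnalysisDataset:
    """Read an analysis table from CSV (or a single SAS transport file).

    Parameters
    ----------
    path : file path.
    mapping : optional {canonical name: file column} renaming. Canonical
        names: unit_id, age, gender, height, body_weight, sbp, w.
    format : "csv" (comma-separated, header row, UTF-8, ''/NA missing)
        or "xpt" (SAS transport, e.g. an NHANES file).
    sbp_reading_columns : when given, the SBP outcome is derived from these
        (up to three) reading columns via :func:`derive_sbp` instead of a
        pre-derived ``sbp`` column.
    """
    if format == "csv":
        raw = pd.read_csv(path, na_values=["", "NA"], keep_default_na=True,
                          float_precision="round_trip")
    elif format == "xpt":
        raw = pd.read_sas(path, format="xport")
    else:
        raise SchemaError(f"unknown format: {format}")
    if mapping:
        inverse = {v: k for k, v in mapping.items()}
        raw = raw.rename(columns=inverse)
    if sbp_reading_columns:
        absent = [c for c in sbp_reading_columns if c not in raw.columns]
        if absent:
            raise SchemaError(f"missing SBP reading columns: {absent}")
        raw["sbp"] = [
            derive_sbp(row) for row in raw[list(sbp_reading_columns)].to_numpy()
        ]
    required = ["age", "gender", "sbp", "w"]
    absent = [c for c in required if c not in raw.columns]
    if absent:
        raise SchemaError(f"missing required columns: {absent}")
    ds = from_records(raw, source=str(path))
    p1, p0 = ds.region_shares()
    logger.info(
        "loaded %s: n=%d, missing fraction %.3f (weighted %.3f), region shares p1=%.3f p0=%.3f",
        path, ds.n, ds.missing_fraction(), ds.missing_fraction(weighted=True), p1, p0,
    )
    return ds


def save_dataset(ds: AnalysisDataset, path) -> None:
    """Write the analysis table as CSV (the load/save round trip is lossless)."""
    # %.17g is round-trip exact for doubles, so save -> load -> save is stable
    ds.df.to_csv(path, index=False, na_rep="", float_format="%.17g")


def check_positivity(ds: AnalysisDataset, stratifiers: Iterable[str] = ("age",)) -> pd.DataFrame:
    """Report complete-case support per stratum.

    One row per observed stratum of ``stratifiers``. Within the positive
    region a stratum is flagged (``violation=True``) when it contains no
    complete cases. The nonpositive region is reported as a whole: under a
    deterministic positivity violation every X*=0 stratum must have zero
    complete cases, recorded in the ``deterministic_nonpositive`` column.
    """
    stratifiers = list(stratifiers)
    df = ds.df
    rows = []
    for keys, grp in df.groupby(["x_star"] + stratifiers, sort=True):
        region, *strata = keys
        n_cc = int((grp["r"] == 1).sum())
        in_pos = bool(region == 1)
        rows.append(
            dict(zip(stratifiers, strata))
            | {
                "region": int(region),
                "n": len(grp),
                "n_complete": n_cc,
                "violation": in_pos and n_cc == 0,
                "deterministic_nonpositive": (not in_pos) and n_cc == 0,
            }
        )
    report = pd.DataFrame(rows)
    return report
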