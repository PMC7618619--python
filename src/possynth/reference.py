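"""External-information mathematical model for SBP imputation.

Published pediatric blood-pressure tables report the median (P50) and the
90th percentile (P90) of SBP for each age x gender x height-percentile cell.
The mathematical model treats each cell as a normal distribution with
``mu = P50`` and ``sigma = (P90 - P50) / z`` where ``z`` is the standard
normal 0.90 quantile, and imputes SBP in the nonpositive region by random
draws from the cell matched to each child.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .data import AnalysisDataset, normalize_gender

logger = logging.getLogger(__name__)

#: standard normal 0.90 quantile, computed at runtime to full double precision
Z90: float = float(stats.norm.ppf(0.90))

DEFAULT_HEIGHT_COLUMNS = (5, 10, 25, 50, 75, 90, 95)


class CoverageError(KeyError):
    """The reference table lacks a cell required by the data."""


class ReferenceTableError(ValueError):
    """Malformed reference table."""


@dataclass
class ReferenceTable:
    """Rows of (age, gender, height_pct, p50, p90), unique on the key triple."""

    df: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.df.copy()
        required = ["age", "gender", "height_pct", "p50", "p90"]
        absent = [c for c in required if c not in df.columns]
        if absent:
            raise ReferenceTableError(f"missing columns: {absent}")
        df["gender"] = [normalize_gender(g) for g in df["gender"]]
        df["age"] = df["age"].astype(int)
        df["height_pct"] = df["height_pct"].astype(int)
        for c in ("p50", "p90"):
            df[c] = df[c].astype(float)
        bad_pct = df[(df["height_pct"] <= 0) | (df["height_pct"] >= 100)]
        if len(bad_pct):
            raise ReferenceTableError(
                f"height_pct outside (0,100) in rows: {bad_pct.index.tolist()[:5]}"
            )
        key = ["age", "gender", "height_pct"]
        if df.duplicated(subset=key).any():
            dup = df.loc[df.duplicated(subset=key), key].to_dict("records")
            raise ReferenceTableError(f"duplicate keys: {dup[:5]}")
        bad = df[df["p90"] < df["p50"]]
        if len(bad):
            rows = bad[key].to_dict("records")
            raise ReferenceTableError(f"p90 < p50 in rows: {rows[:5]}")
        self.df = df.reset_index(drop=True)
        self._index = {
            (int(a), g, int(h)): i
            for i, (a, g, h) in enumerate(zip(df["age"], df["gender"], df["height_pct"]))
        }

    @property
    def coverage(self) -> set[tuple[int, str]]:
        """Set of (age, gender) cells present."""
        return {(int(a), g) for a, g in zip(self.df["age"], self.df["gender"])}

    def columns_for(self, age: int, gender: str) -> np.ndarray:
        """Available height-percentile column labels for one (age, gender) cell."""
        sub = self.df[(self.df["age"] == age) & (self.df["gender"] == gender)]
        if len(sub) == 0:
            raise CoverageError(f"reference table does not cover (age={age}, gender={gender})")
        return np.sort(sub["height_pct"].to_numpy())

    def row(self, age: int, gender: str, height_pct: int) -> pd.Series:
        try:
            return self.df.iloc[self._index[(int(age), gender, int(height_pct))]]
        except KeyError as exc:
            raise CoverageError(
                f"no row for (age={age}, gender={gender}, height_pct={height_pct})"
            ) from exc


def load_reference_table(path) -> ReferenceTable:
    """Read a reference table CSV with columns age,gender,height_pct,p50,p90."""
    return ReferenceTable(pd.read_csv(path, na_values=["", "NA"]))


def save_reference_table(table: ReferenceTable, path) -> None:
    table.df.to_csv(path, index=False)


def normal_params(row) -> tuple[float, float]:
    """(mu, sigma) of the normal distribution implied by a reference row.

    mu equals the median P50; sigma is recovered from the 90th percentile as
    ``(P90 - P50) / Phi^{-1}(0.90)``. A degenerate row (P90 == P50) yields a
    point mass (sigma = 0).
    """
    p50 = float(row["p50"])
    p90 = float(row["p90"])
    return p50, (p90 - p50) / Z90


def nearest_percentile_column(p: float, columns) -> int:
    """Column label minimising |column - p|; ties break toward the smaller label."""
    cols = np.sort(np.asarray(list(columns)))
    if len(cols) == 0:
        raise ReferenceTableError("no percentile columns available")
    dist = np.abs(cols - p)
    return int(cols[int(np.argmin(dist))])  # argmin returns first (smaller) on ties


def height_percentile(
    ds: AnalysisDataset,
    unit_index: int,
    lms_table: pd.DataFrame | None = None,
) -> float:
    """Height percentile of one unit within its (age, gender) stratum.

    Empirical mode (default): the survey-weighted fraction of units in the
    same stratum with height <= the unit's height, times 100 (ties count).
    External mode: when an LMS growth-reference table (columns
    age, gender, L, M, S) is supplied, evaluates the LMS z-score and the
    normal CDF instead.

    Returns ``nan`` for a unit with missing height (the caller routes such
    units to the median column; see :func:`match_units`).
    """
    row = ds.df.iloc[unit_index]
    h = row["height"]
    if pd.isna(h):
        return float("nan")
    if lms_table is not None:
        sub = lms_table[
            (lms_table["age"] == row["age"]) & (lms_table["gender"] == row["gender"])
        ]
        if len(sub) == 0:
            raise CoverageError(
                f"LMS table does not cover (age={row['age']}, gender={row['gender']})"
            )
        L, M, S = (float(sub.iloc[0][c]) for c in ("L", "M", "S"))
        if abs(L) < 1e-12:
            z = np.log(h / M) / S
        else:
            z = ((h / M) ** L - 1.0) / (L * S)
        return float(100.0 * stats.norm.cdf(z))
    stratum = ds.df[(ds.df["age"] == row["age"]) & (ds.df["gender"] == row["gender"])]
    stratum = stratum[stratum["height"].notna()]
    if len(stratum) == 0:
        raise ValueError(f"empty height stratum for (age={row['age']}, gender={row['gender']})")
    w = stratum["w"].to_numpy()
    le = (stratum["height"].to_numpy() <= h).astype(float)
    return float(100.0 * np.sum(w * le) / np.sum(w))


def match_units(
    ds: AnalysisDataset,
    table: ReferenceTable,
    units: np.ndarray | None = None,
    lms_table: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Match units to reference rows; returns per-unit (mu, sigma).

    For each unit: compute its height percentile, pick the nearest available
    height-percentile column in its (age, gender) cell, and convert the
    matched row to normal parameters. Units with missing height are routed
    to the height_pct = 50 column (their count is logged).

    Parameters
    ----------
    units : positional indices into ``ds.df`` (default: all units).

    Returns
    -------
    DataFrame indexed like ``units`` with columns unit_id, height_pct, mu, sigma.
    """
    if units is None:
        units = np.arange(ds.n)
    units = np.asarray(units, dtype=int)
    df = ds.df
    wanted = np.zeros(len(df), dtype=bool)
    wanted[units] = True

    pct = np.full(len(df), np.nan)
    if lms_table is not None:
        for i in units:
            pct[i] = height_percentile(ds, int(i), lms_table=lms_table)
    else:
        # weighted ECDF per (age, gender) stratum, vectorised via sort + cumsum
        ages = df["age"].to_numpy()
        genders = df["gender"].to_numpy()
        heights = df["height"].to_numpy()
        weights = df["w"].to_numpy()
        for (age, gender), idx in df.groupby(["age", "gender"], sort=False).indices.items():
            sel = idx[wanted[idx] & ~np.isnan(heights[idx])]
            if len(sel) == 0:
                continue
            stratum = idx[~np.isnan(heights[idx])]
            order = np.argsort(heights[stratum], kind="stable")
            h_sorted = heights[stratum][order]
            cumw = np.cumsum(weights[stratum][order])
            total = cumw[-1]
            # side="right" credits the full weight of tied heights ("<=" rule)
            pos = np.searchsorted(h_sorted, heights[sel], side="right")
            pct[sel] = 100.0 * cumw[pos - 1] / total

    out = []
    n_missing_height = 0
    cols_cache: dict[tuple[int, str], np.ndarray] = {}
    for i in units:
        age = int(df["age"].iat[i])
        gender = df["gender"].iat[i]
        key = (age, gender)
        if key not in cols_cache:
            cols_cache[key] = table.columns_for(age, gender)
        cols = cols_cache[key]
        p = pct[i]
        if np.isnan(p):
            n_missing_height += 1
            col = 50 if 50 in cols else nearest_percentile_column(50, cols)
        else:
            col = int(cols[int(np.argmin(np.abs(cols - p)))])
        mu, sigma = normal_params(table.row(age, gender, col))
        out.append({"unit_id": df["unit_id"].iat[i], "height_pct": col, "mu": mu, "sigma": sigma})
    if n_missing_height:
        logger.info("match_units: %d units with missing height routed to the median column",
                    n_missing_height)
    return pd.DataFrame(out, index=units)


def draw_sbp(
    unit_index: int,
    ds: AnalysisDataset,
    table: ReferenceTable,
    rng: np.random.Generator,
    lms_table: pd.DataFrame | None = None,
) -> float:
    """One imputed SBP draw for a unit from its matched normal distribution.

    A degenerate matched cell (sigma = 0) returns mu exactly. Reproducible
    under a fixed ``rng`` state; raises :class:`CoverageError` when the
    table lacks the unit's (age, gender) cell.
    """
    m = match_units(ds, table, units=np.array([unit_index]), lms_table=lms_table).iloc[0]
    if m["sigma"] == 0:
        return float(m["mu"])
    return float(rng.normal(m["mu"], m["sigma"]))
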