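"""Synthetic NHANES-like populations with known truth.

Generates unit-level data emulating the motivating survey: children aged
2-17 with gender, height, body weight, survey weights, and SBP that is
never observed below age 8 (deterministic positivity violation) and
missing at random given age within ages 8-17. A matched reference table
(optionally perturbed by a constant shift) is emitted from the same
generative law, so the mathematical model's external information can be
made exactly accurate (delta = 0) or deliberately wrong (delta != 0).

The default scenario: ages uniform on 2-17, SBP rising 1.5 mm Hg per year
with a small gender and height effect and residual SD 10 mm Hg, roughly 8%
missingness among ages 8-17, and survey weights from a shifted gamma
distribution independent of SBP given age (so the weighted estimand equals
the generative mean).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit

from .data import AnalysisDataset, AGE_MIN, AGE_MAX, REGION_CUT, from_records
from .reference import ReferenceTable, Z90, DEFAULT_HEIGHT_COLUMNS

AGES = np.arange(AGE_MIN, AGE_MAX + 1)


class ConfigError(ValueError):
    pass


@dataclass
class SimulationConfig:
    n: int = 2000
    age_probs: tuple = tuple(np.full(len(AGES), 1.0 / len(AGES)))  # over ages 2..17
    gender_prob: float = 0.5  # male share
    # height ~ Normal(h0 + h1*age + h2*male, height_sd), cm
    height_intercept: float = 78.0
    height_age: float = 5.5
    height_male: float = 2.0
    height_sd: float = 7.0
    # body weight ~ Normal(bw0 + bw1*height, bodyweight_sd), kg
    bodyweight_intercept: float = -45.0
    bodyweight_height: float = 0.65
    bodyweight_sd: float = 4.5
    # SBP ~ Normal(s0 + s_age*age + s_male*male + s_height*height, sbp_sd), mm Hg
    sbp_intercept: float = 80.0
    sbp_age: float = 1.5
    sbp_male: float = 2.0
    sbp_height: float = 0.05
    sbp_sd: float = 10.0
    # Pr(R=1 | age) = expit(m0 + m1*(age-12)) for ages 8-17; 0 below 8
    missingness_intercept: float = 2.5
    missingness_age: float = -0.05
    # survey weight = weight_shift + Gamma(weight_shape, weight_scale)
    weight_shift: float = 0.5
    weight_shape: float = 2.0
    weight_scale: float = 0.75
    table_perturbation: float = 0.0  # delta added to emitted reference means
    seed: int = 0

    def __post_init__(self) -> None:
        p = np.asarray(self.age_probs, dtype=float)
        if len(p) != len(AGES) or (p < 0).any() or not np.isclose(p.sum(), 1.0):
            raise ConfigError("age_probs must be a distribution over ages 2-17")
        self.age_probs = tuple(float(x) for x in p / p.sum())
        if self.n < 1:
            raise ConfigError("n must be >= 1")
        if self.sbp_sd < 0 or self.height_sd < 0 or self.bodyweight_sd < 0:
            raise ConfigError("standard deviations must be nonnegative")
        if not (0.0 <= self.gender_prob <= 1.0):
            raise ConfigError("gender_prob must lie in [0, 1]")
        if self.weight_shift <= 0 and self.weight_shape <= 0:
            raise ConfigError("survey weights must be positive")
        pos_mass = float(np.asarray(self.age_probs)[AGES >= REGION_CUT].sum())
        if pos_mass > 0:
            obs = self.obs_prob(AGES[AGES >= REGION_CUT])
            mass = np.asarray(self.age_probs)[AGES >= REGION_CUT]
            if float(np.sum(mass * obs)) == 0.0:
                raise ConfigError(
                    "degenerate config: positive-region mass exists but the "
                    "observation probability is zero everywhere in it"
                )

    def obs_prob(self, age) -> np.ndarray:
        """Pr(R=1 | age): logistic in age for 8-17, exactly 0 below 8."""
        age = np.asarray(age, dtype=float)
        eta = self.missingness_intercept + self.missingness_age * (age - 12.0)
        p = expit(eta)
        return np.where(age >= REGION_CUT, p, 0.0)

    def mean_height(self, age, male) -> np.ndarray:
        return (self.height_intercept + self.height_age * np.asarray(age, float)
                + self.height_male * np.asarray(male, float))

    def mean_sbp_given(self, age, male, height) -> np.ndarray:
        return (self.sbp_intercept + self.sbp_age * np.asarray(age, float)
                + self.sbp_male * np.asarray(male, float)
                + self.sbp_height * np.asarray(height, float))

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def simulate_population(cfg: SimulationConfig) -> AnalysisDataset:
    """Draw one synthetic sample; reproducible under ``cfg.seed``."""
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n
    age = rng.choice(AGES, size=n, p=np.asarray(cfg.age_probs))
    male = rng.random(n) < cfg.gender_prob
    height = rng.normal(cfg.mean_height(age, male), cfg.height_sd)
    body_weight = rng.normal(
        cfg.bodyweight_intercept + cfg.bodyweight_height * height, cfg.bodyweight_sd
    )
    sbp = rng.normal(cfg.mean_sbp_given(age, male, height), cfg.sbp_sd)
    observed = rng.random(n) < cfg.obs_prob(age)
    sbp = np.where(observed, sbp, np.nan)
    w = cfg.weight_shift + rng.gamma(cfg.weight_shape, cfg.weight_scale, size=n)
    df = pd.DataFrame({
        "unit_id": np.arange(n),
        "age": age,
        "gender": np.where(male, "male", "female"),
        "height": height,
        "body_weight": body_weight,
        "sbp": sbp,
        "w": w,
    })
    return from_records(df, source=f"simulated(seed={cfg.seed})")


def true_mean(cfg: SimulationConfig, mc_draws: int | None = None,
              region: int | None = None) -> float | tuple[float, float]:
    """Population mean SBP under the generative law.

    The SBP law is linear in (age, gender, height), so the mean has the
    closed form ``sum_a p_a * E[SBP | age=a]``. Restrict with ``region``
    (1: ages 8-17, 0: ages 2-7). When ``mc_draws`` is given, returns a
    Monte-Carlo estimate and its standard error instead.
    """
    if mc_draws is not None:
        rng = np.random.default_rng(cfg.seed + 1_000_003)
        age = rng.choice(AGES, size=mc_draws, p=np.asarray(cfg.age_probs))
        male = rng.random(mc_draws) < cfg.gender_prob
        height = rng.normal(cfg.mean_height(age, male), cfg.height_sd)
        sbp = rng.normal(cfg.mean_sbp_given(age, male, height), cfg.sbp_sd)
        if region is not None:
            keep = (age >= REGION_CUT) if region == 1 else (age < REGION_CUT)
            sbp = sbp[keep]
        return float(sbp.mean()), float(sbp.std(ddof=1) / np.sqrt(len(sbp)))
    p = np.asarray(cfg.age_probs)
    if region is not None:
        mask = (AGES >= REGION_CUT) if region == 1 else (AGES < REGION_CUT)
        if p[mask].sum() == 0:
            raise ConfigError(f"no mass in region {region}")
        p = np.where(mask, p, 0.0) / p[mask].sum()
    pm = cfg.gender_prob
    eh = pm * cfg.mean_height(AGES, 1) + (1 - pm) * cfg.mean_height(AGES, 0)
    cond = (cfg.sbp_intercept + cfg.sbp_age * AGES + cfg.sbp_male * pm
            + cfg.sbp_height * eh)
    return float(np.sum(p * cond))


def emit_reference_table(
    cfg: SimulationConfig,
    height_bins=DEFAULT_HEIGHT_COLUMNS,
    ages=None,
) -> ReferenceTable:
    """Reference table consistent with the generative law (up to delta).

    Each (age, gender, height-percentile) cell gets ``p50`` equal to the
    conditional mean SBP at that exact height percentile plus the
    perturbation delta, and ``p90 = p50 + z * sbp_sd``, so
    ``normal_params`` recovers the generative conditional distribution
    exactly when delta = 0.
    """
    if ages is None:
        ages = AGES
    rows = []
    for a in ages:
        for male, gender in ((1, "male"), (0, "female")):
            mh = cfg.mean_height(a, male)
            for pct in height_bins:
                h_q = mh + cfg.height_sd * stats.norm.ppf(pct / 100.0)
                p50 = float(cfg.mean_sbp_given(a, male, h_q)) + cfg.table_perturbation
                rows.append({
                    "age": int(a), "gender": gender, "height_pct": int(pct),
                    "p50": p50, "p90": p50 + Z90 * cfg.sbp_sd,
                })
    return ReferenceTable(pd.DataFrame(rows))


def simulate_study(cfg: SimulationConfig, outdir) -> dict:
    """Write the analysis CSV, the reference CSV, and a truth JSON.

    Returns the truth record (true mean, regional means, config hash, seed).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ds = simulate_population(cfg)
    table = emit_reference_table(cfg)
    from .data import save_dataset

    save_dataset(ds, outdir / "analysis.csv")
    table.df.to_csv(outdir / "reference.csv", index=False, float_format="%.17g")
    truth = {
        "true_mean": true_mean(cfg),
        "true_e1": true_mean(cfg, region=1),
        "true_e0": true_mean(cfg, region=0),
        "n": cfg.n,
        "seed": cfg.seed,
        "config_hash": cfg.config_hash(),
    }
    with open(outdir / "truth.json", "w") as fh:
        json.dump(truth, fh, indent=2)
    return truth
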