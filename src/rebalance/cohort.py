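"""Synthetic cohort generation and cohort-table plumbing.

A cohort table is a plain :class:`pandas.DataFrame` with one row per
participant and a fixed schema: demographic and socio-economic predictors,
a rare binary outcome (evidence of undiagnosed diabetes), and a positive
case weight.  The generator draws predictors from configurable marginals
(defaulting to a published health-survey cohort of 4677 adults with ~3%
outcome prevalence) and the outcome from a logistic model whose intercept
is calibrated to hit a target prevalence.

Predictors default to mutually independent draws; real survey data carry
correlations (age with marital status, income with education, ...) that
this generator deliberately omits, since only marginals are published.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

#: canonical column order of a cohort table
COLUMNS = ["gender", "age", "race", "education", "marital", "pir", "bmi",
           "outcome", "weight"]
PREDICTORS = ["gender", "age", "race", "education", "marital", "pir", "bmi"]

GENDER_LEVELS = ["Male", "Female"]
RACE_LEVELS = ["Mexican American", "Other Hispanic", "Non-Hispanic White",
               "Non-Hispanic Black", "Other"]
EDUCATION_LEVELS = ["<9th grade", "9th-11th grade", "High school",
                    "Some college", "College graduate or above"]
MARITAL_LEVELS = ["Married", "Widowed", "Divorced", "Separated",
                  "Never married", "Living with partner"]

#: fields that may legitimately contain missing values
MISSABLE = ("education", "marital")

# marginal frequencies of the emulated cohort (Total column of its
# descriptive table); age is drawn uniformly within decade bands
GENDER_P = [0.479, 0.521]
AGE_BANDS = [(20, 30), (30, 40), (40, 50), (50, 60), (60, 70), (70, 85)]
AGE_BAND_P = [0.205, 0.195, 0.203, 0.157, 0.141, 0.099]
RACE_P = [0.188, 0.104, 0.481, 0.172, 0.055]
EDUCATION_P = [0.111, 0.158, 0.234, 0.283, 0.214]
MARITAL_P = [0.518, 0.050, 0.107, 0.035, 0.196, 0.094]
PIR_MEAN, PIR_SD = 2.46, 1.65
BMI_MEAN, BMI_SD = 28.77, 6.67


def child_seed(seed: int, *tags) -> int:
    """Stable per-stage seed derived from a global seed and string tags.

    Stages drawing from their own named child seed can be rerun
    independently, and adding a stage never perturbs another's stream.
    """
    key = ":".join([str(int(seed))] + [str(t) for t in tags])
    digest = hashlib.sha256(key.encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


@dataclass
class EffectConfig:
    """Log-odds effects of the outcome model.

    Default signs follow the emulated cohort's descriptive contrasts:
    risk rises with age, BMI, and Mexican American (and, mildly,
    Non-Hispanic Black) race; falls with education level and family
    poverty-income ratio.  Continuous terms are centred at the cohort
    means so that the intercept stays interpretable; the intercept itself
    is calibrated at generation time so expected prevalence equals
    ``target_prevalence``.
    """

    age_per_year: float = 0.045
    bmi_per_unit: float = 0.115
    pir_per_unit: float = -0.15
    education_per_level: float = -0.2
    gender_female: float = 0.0
    race_effects: dict = field(default_factory=lambda: {
        "Mexican American": 0.85,
        "Other Hispanic": 0.10,
        "Non-Hispanic White": 0.0,
        "Non-Hispanic Black": 0.35,
        "Other": 0.10,
    })
    target_prevalence: float = 0.03
    intercept: float | None = None  # None -> calibrated to target_prevalence

    def validate(self):
        vals = [self.age_per_year, self.bmi_per_unit, self.pir_per_unit,
                self.education_per_level, self.gender_female,
                self.target_prevalence]
        vals += list(self.race_effects.values())
        if self.intercept is not None:
            vals.append(self.intercept)
        if not all(np.isfinite(v) for v in vals):
            raise ValueError("effect config contains non-finite values")
        if not 0.0 < self.target_prevalence < 1.0:
            raise ValueError("target_prevalence must be in (0, 1)")

    def to_dict(self):
        return asdict(self)

    @classmethod
    def from_dict(cls, d):
        d = dict(d)
        if "race_effects" in d and d["race_effects"] is not None:
            d["race_effects"] = dict(d["race_effects"])
        return cls(**d)


def _empty_table() -> pd.DataFrame:
    df = pd.DataFrame({
        "gender": pd.Categorical([], categories=GENDER_LEVELS),
        "age": pd.Series([], dtype=int),
        "race": pd.Categorical([], categories=RACE_LEVELS),
        "education": pd.Categorical([], categories=EDUCATION_LEVELS,
                                    ordered=True),
        "marital": pd.Categorical([], categories=MARITAL_LEVELS),
        "pir": pd.Series([], dtype=float),
        "bmi": pd.Series([], dtype=float),
        "outcome": pd.Series([], dtype=int),
        "weight": pd.Series([], dtype=float),
    })
    return df[COLUMNS]


def linear_predictor(table: pd.DataFrame, config: EffectConfig) -> np.ndarray:
    """Centred log-odds linear predictor (without intercept).

    Missing education/marital contribute their centred mean (zero), so
    injected missingness does not shift the calibrated prevalence.
    """
    lp = np.zeros(len(table))
    lp += config.age_per_year * (table["age"].to_numpy(float) - 46.0)
    lp += config.bmi_per_unit * (table["bmi"].to_numpy(float) - BMI_MEAN)
    lp += config.pir_per_unit * (table["pir"].to_numpy(float) - PIR_MEAN)
    edu = pd.Categorical(table["education"],
                         categories=EDUCATION_LEVELS).codes.astype(float)
    edu[edu < 0] = 2.0  # missing -> centre
    lp += config.education_per_level * (edu - 2.0)
    lp += np.where(table["gender"].astype(str) == "Female",
                   config.gender_female, 0.0)
    race_eff = np.array([config.race_effects.get(r, 0.0) for r in RACE_LEVELS])
    mean_race = float(race_eff @ np.asarray(RACE_P))
    codes = pd.Categorical(table["race"], categories=RACE_LEVELS).codes
    lp += race_eff[codes] - mean_race
    return lp


def calibrate_intercept(lp: np.ndarray, target: float) -> float:
    """Intercept c such that mean(expit(c + lp)) equals ``target``."""
    if lp.size == 0:
        return float(np.log(target / (1 - target)))
    f = lambda c: float(expit(c + lp).mean()) - target
    return float(brentq(f, -40.0, 15.0, xtol=1e-12))


def generate_cohort(n: int, config: EffectConfig | None = None,
                    seed: int = 0) -> pd.DataFrame:
    """Generate ``n`` independent participants.

    Predictors are drawn from the default marginals; the outcome is
    Bernoulli with probability ``expit(intercept + linear_predictor)``.
    Covariates and outcome use separate child seeds, so raising an effect
    size changes outcomes but leaves the covariate draw untouched.
    """
    if n < 0:
        raise ValueError("n must be nonnegative")
    config = config or EffectConfig()
    config.validate()
    if n == 0:
        return _empty_table()

    rng_x = np.random.default_rng(child_seed(seed, "covariates"))
    gender = rng_x.choice(len(GENDER_LEVELS), size=n, p=_norm(GENDER_P))
    band = rng_x.choice(len(AGE_BANDS), size=n, p=_norm(AGE_BAND_P))
    lo = np.array([b[0] for b in AGE_BANDS])[band]
    hi = np.array([b[1] for b in AGE_BANDS])[band]
    age = rng_x.integers(0, hi - lo, endpoint=False) + lo  # integer years
    race = rng_x.choice(len(RACE_LEVELS), size=n, p=_norm(RACE_P))
    education = rng_x.choice(len(EDUCATION_LEVELS), size=n,
                             p=_norm(EDUCATION_P))
    marital = rng_x.choice(len(MARITAL_LEVELS), size=n, p=_norm(MARITAL_P))
    pir = np.clip(rng_x.normal(PIR_MEAN, PIR_SD, size=n), 0.0, 5.0)
    bmi = np.clip(rng_x.normal(BMI_MEAN, BMI_SD, size=n), 14.0, 70.0)

    table = pd.DataFrame({
        "gender": pd.Categorical.from_codes(gender, GENDER_LEVELS),
        "age": age.astype(int),
        "race": pd.Categorical.from_codes(race, RACE_LEVELS),
        "education": pd.Categorical.from_codes(education, EDUCATION_LEVELS,
                                               ordered=True),
        "marital": pd.Categorical.from_codes(marital, MARITAL_LEVELS),
        "pir": np.round(pir, 2),
        "bmi": np.round(bmi, 2),
    })
    lp = linear_predictor(table, config)
    intercept = (config.intercept if config.intercept is not None
                 else calibrate_intercept(lp, config.target_prevalence))
    p = expit(intercept + lp)
    rng_y = np.random.default_rng(child_seed(seed, "outcome"))
    table["outcome"] = (rng_y.random(n) < p).astype(int)
    table["weight"] = 1.0
    return table[COLUMNS]


def _norm(p):
    p = np.asarray(p, dtype=float)
    return p / p.sum()


def inject_missing(table: pd.DataFrame, rates: dict[str, float],
                   seed: int = 0) -> pd.DataFrame:
    """Blank eligible cells independently at the given per-field rates.

    Only ``education`` and ``marital`` may receive missingness; the
    outcome and the never-missing predictors are untouched.
    """
    for fld, rate in rates.items():
        if fld not in MISSABLE:
            raise ValueError(f"field {fld!r} may not receive missingness")
        if not 0.0 <= rate <= 1.0:
            raise ValueError(f"rate for {fld!r} must be in [0, 1]")
    out = table.copy()
    rng = np.random.default_rng(child_seed(seed, "missing"))
    for fld in MISSABLE:  # fixed order keeps the stream stable
        rate = rates.get(fld, 0.0)
        if rate == 0.0 or len(out) == 0:
            continue
        mask = rng.random(len(out)) < rate
        out.loc[mask, fld] = np.nan
    return out


def split_train_test(table: pd.DataFrame, n_train: int,
                     seed: int = 0) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simple random (unstratified) split without replacement.

    ``n_train`` is an explicit row count; the two outputs partition the
    input exactly and keep the original row labels.
    """
    n = len(table)
    if not 0 <= n_train <= n:
        raise ValueError(f"n_train={n_train} out of range for n={n}")
    rng = np.random.default_rng(child_seed(seed, "split"))
    perm = rng.permutation(n)
    train = table.iloc[np.sort(perm[:n_train])]
    test = table.iloc[np.sort(perm[n_train:])]
    return train, test


def case_count(table: pd.DataFrame) -> int:
    return int((table["outcome"] == 1).sum())


def control_count(table: pd.DataFrame) -> int:
    return int((table["outcome"] == 0).sum())


def validate_cohort(table: pd.DataFrame) -> None:
    """Schema and invariant checks; raises ``ValueError`` on violation."""
    missing_cols = [c for c in COLUMNS if c not in table.columns]
    if missing_cols:
        raise ValueError(f"cohort table lacks columns: {missing_cols}")
    for c in ("outcome", "age", "bmi"):
        if table[c].isna().any():
            raise ValueError(f"column {c!r} must never be missing")
    if not set(pd.unique(table["outcome"])) <= {0, 1}:
        raise ValueError("outcome must be binary 0/1")
    if (table["weight"].to_numpy(float) <= 0).any():
        raise ValueError("weights must be positive")


# ---------------------------------------------------------------------------
# CSV interface: header row, empty string = missing, UTF-8, '.' decimals
# ---------------------------------------------------------------------------

def write_cohort_csv(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False, na_rep="", encoding="utf-8")


def read_cohort_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, encoding="utf-8")
    if "weight" not in df.columns:
        df["weight"] = 1.0
    df["gender"] = pd.Categorical(df["gender"], categories=GENDER_LEVELS)
    df["race"] = pd.Categorical(df["race"], categories=RACE_LEVELS)
    df["education"] = pd.Categorical(df["education"],
                                     categories=EDUCATION_LEVELS, ordered=True)
    df["marital"] = pd.Categorical(df["marital"], categories=MARITAL_LEVELS)
    df["age"] = df["age"].astype(int)
    df["outcome"] = df["outcome"].astype(int)
    df["weight"] = df["weight"].astype(float)
    return df[COLUMNS]


def split_xyw(table: pd.DataFrame):
    """(X, y, w) view of a cohort table for the estimator layer."""
    X = table[PREDICTORS]
    y = table["outcome"].to_numpy(int)
    w = table["weight"].to_numpy(float)
    return X, y, w
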