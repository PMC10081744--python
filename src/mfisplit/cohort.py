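"""Synthetic NSQIP-like elective-surgery cohorts.

The real study population (ACS NSQIP 2018 Participant Use Files) is
membership-restricted, so this module generates schema-compatible cohorts
with the marginal structure the analysis assumes: a median mFI near 0.08
driven mostly by low-impact indicators, a destination distribution heavily
dominated by discharge to home, and a *planted* dependence of discharge
destination on frailty in which high-impact indicators carry more weight
than low-impact ones.

Destinations are assigned through a latent care-intensity score

    s = w_high * (#high deficits) + w_low * (#low deficits)
        + w_age * age' + w_asa * asa' + w_wrvu * wrvu' + Normal(0, noise_sd)

(primed covariates standardized) cut at 8 ordered thresholds into the
9-category destination taxonomy, ordered home -> death by care intensity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .frailty import HIGH_IMPACT, INDICATORS, LOW_IMPACT

__all__ = [
    "SPECIALTIES",
    "DESTINATIONS",
    "COHORT_COLUMNS",
    "CohortSpec",
    "generate_cohort",
    "assign_destination",
    "thresholds_for_marginals",
    "write_cohort_csv",
    "read_cohort_csv",
]

#: The nine surgical specialties modelled, plus (downstream) their composite.
SPECIALTIES: tuple[str, ...] = (
    "cardiac",
    "general",
    "gynecology",
    "neurosurgery",
    "orthopedics",
    "ENT",
    "thoracic",
    "urology",
    "vascular",
)

#: Discharge destinations ordered by increasing care intensity; this order is
#: both the latent-scale binning order and the fixed class-label order.
DESTINATIONS: tuple[str, ...] = (
    "home",
    "home_with_facility",
    "multi_level_facility",
    "unskilled_facility",
    "rehab",
    "skilled_facility",
    "acute_care",
    "hospice",
    "death",
)

SEXES: tuple[str, ...] = ("male", "female")

COHORT_COLUMNS: tuple[str, ...] = (
    ("record_id", "specialty")
    + INDICATORS
    + ("age", "sex", "wrvu", "asa_class", "destination")
)

#: Independent variables of the prediction models (exclusion criterion scope).
INDEPENDENT_COLUMNS: tuple[str, ...] = INDICATORS + ("age", "sex", "wrvu", "asa_class")

# Covariate distribution constants (loose Table-1-style targets: age median
# ~63-66y, wRVU median ~20.7, ASA mode 3, ~44% male in the population).
AGE_MEAN, AGE_SD, AGE_MIN, AGE_MAX = 63.0, 15.0, 18, 100
WRVU_LOG_MU, WRVU_LOG_SIGMA = math.log(20.7), 0.4
ASA_PROBS: tuple[float, ...] = (0.05, 0.25, 0.50, 0.17, 0.03)
MALE_FRACTION = 0.44

# Theoretical moments used to standardize covariates on the latent scale.
_WRVU_MEAN = math.exp(WRVU_LOG_MU + WRVU_LOG_SIGMA**2 / 2)
_WRVU_SD = _WRVU_MEAN * math.sqrt(math.exp(WRVU_LOG_SIGMA**2) - 1)
_ASA_MEAN = sum(p * (i + 1) for i, p in enumerate(ASA_PROBS))
_ASA_SD = math.sqrt(
    sum(p * (i + 1) ** 2 for i, p in enumerate(ASA_PROBS)) - _ASA_MEAN**2
)

# Default per-indicator prevalences: high-impact deficits are rare (median
# high-only mFI 0), low-impact ones common enough that the median total count
# is 1 deficit (median mFI 1/13 ~ 0.077, low-only median 1/6 ~ 0.17).
DEFAULT_PREVALENCE: dict[str, float] = {
    **{name: 0.02 for name in HIGH_IMPACT},
    **{name: 0.15 for name in LOW_IMPACT},
}

#: Rough elective-inpatient case mix over the nine specialties.
DEFAULT_SPECIALTY_MIX: dict[str, float] = {
    "cardiac": 0.04,
    "general": 0.30,
    "gynecology": 0.09,
    "neurosurgery": 0.10,
    "orthopedics": 0.20,
    "ENT": 0.06,
    "thoracic": 0.04,
    "urology": 0.09,
    "vascular": 0.08,
}

#: Target population destination marginals (home-heavy, death rare).
POPULATION_MARGINALS: dict[str, float] = {
    "home": 0.911,
    "home_with_facility": 0.005,
    "multi_level_facility": 0.0002,
    "unskilled_facility": 0.001,
    "rehab": 0.029,
    "skilled_facility": 0.048,
    "acute_care": 0.003,
    "hospice": 0.0005,
    "death": 0.003,
}

# Latent-scale cutpoints frozen from thresholds_for_marginals(...) under the
# default planted-effect weights (see docs/methods.md); regenerate with the
# helper if weights or marginal targets change.
POPULATION_THRESHOLDS: tuple[float, ...] = (
    2.5271, 2.5763, 2.578, 2.5885, 2.9241, 4.3605, 4.7476, 4.8426,
)

#: Near-uniform destination cutpoints for fast-training "balanced-ish" tests.
BALANCED_THRESHOLDS: tuple[float, ...] = (
    -0.9756, -0.3945, 0.0434, 0.4274, 0.805, 1.205, 1.6784, 2.3429,
)


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of one synthetic cohort draw.

    ``w_high``/``w_low`` are the latent-scale weights per high-/low-impact
    deficit; the default 3:1 ratio plants the asymmetry the prediction
    experiments are designed to detect.
    """

    n_records: int = 20_000
    specialty_mix: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_SPECIALTY_MIX)
    )
    indicator_prevalence: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PREVALENCE)
    )
    w_high: float = 1.5
    w_low: float = 0.5
    w_age: float = 0.3
    w_asa: float = 0.5
    w_wrvu: float = 0.2
    noise_sd: float = 1.0
    destination_thresholds: tuple[float, ...] = POPULATION_THRESHOLDS
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_records < 1:
            raise ValueError("n_records must be >= 1")
        mix = self.specialty_mix
        if set(mix) - set(SPECIALTIES):
            raise ValueError(f"unknown specialties: {sorted(set(mix) - set(SPECIALTIES))}")
        if not mix or any(p < 0 for p in mix.values()):
            raise ValueError("specialty_mix must be a nonempty sub-probability vector")
        total = sum(mix.values())
        if not math.isclose(total, 1.0, abs_tol=1e-6):
            raise ValueError(f"specialty_mix must sum to 1 (got {total})")
        prev = self.indicator_prevalence
        if set(prev) != set(INDICATORS):
            raise ValueError("indicator_prevalence must cover the 13 indicators")
        if any(not 0 <= p <= 1 for p in prev.values()):
            raise ValueError("prevalences must lie in [0, 1]")
        t = self.destination_thresholds
        if len(t) != len(DESTINATIONS) - 1:
            raise ValueError(f"need {len(DESTINATIONS) - 1} thresholds, got {len(t)}")
        if any(b <= a for a, b in zip(t, t[1:])):
            raise ValueError("destination_thresholds must be strictly increasing")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must lie in [0, 1)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")

    @classmethod
    def population(cls, n_records: int = 20_000, seed: int = 0, **overrides) -> "CohortSpec":
        """Home-heavy marginals matching the study population structure."""
        return cls(n_records=n_records, seed=seed, **overrides)

    @classmethod
    def balanced(cls, n_records: int = 5_000, seed: int = 0, **overrides) -> "CohortSpec":
        """Near-uniform destination marginals for fast training tests."""
        overrides.setdefault("destination_thresholds", BALANCED_THRESHOLDS)
        return cls(n_records=n_records, seed=seed, **overrides)

    def with_null_effect(self) -> "CohortSpec":
        """Equalize high/low weights (keeping their mean) — no planted asymmetry."""
        w = (self.w_high + self.w_low) / 2
        return replace(self, w_high=w, w_low=w)


def assign_destination(
    latent: float | np.ndarray, thresholds: Sequence[float]
) -> np.ndarray:
    """Ordinal binning of latent care-intensity scores into destination labels.

    A value below the first cutpoint maps to ``home``, above the last to
    ``death``; a value exactly on a cutpoint goes to the higher category.
    """
    t = np.asarray(thresholds, dtype=float)
    if t.ndim != 1 or len(t) != len(DESTINATIONS) - 1 or np.any(np.diff(t) <= 0):
        raise ValueError("thresholds must be 8 strictly increasing cutpoints")
    idx = np.searchsorted(t, np.asarray(latent, dtype=float), side="right")
    return np.asarray(DESTINATIONS, dtype=object)[idx]


def _latent_scores(
    spec: CohortSpec,
    n_high: np.ndarray,
    n_low: np.ndarray,
    age: np.ndarray,
    asa: np.ndarray,
    wrvu: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    z_age = (age - AGE_MEAN) / AGE_SD
    z_asa = (asa - _ASA_MEAN) / _ASA_SD
    z_wrvu = (wrvu - _WRVU_MEAN) / _WRVU_SD
    return (
        spec.w_high * n_high
        + spec.w_low * n_low
        + spec.w_age * z_age
        + spec.w_asa * z_asa
        + spec.w_wrvu * z_wrvu
        + rng.normal(0.0, spec.noise_sd, size=len(age))
    )


def generate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Draw one cohort as a DataFrame in the canonical CSV schema.

    Reproducible: the same spec (including seed) yields an identical frame.
    Missingness, when requested, is injected completely at random over the
    independent variables only (never specialty or destination), mirroring
    the analysis' sole exclusion criterion.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_records

    specialties = sorted(spec.specialty_mix)  # fixed draw order
    probs = np.array([spec.specialty_mix[s] for s in specialties])
    specialty = rng.choice(np.asarray(specialties, dtype=object), size=n, p=probs / probs.sum())

    flags = {
        name: (rng.random(n) < spec.indicator_prevalence[name]).astype(np.int8)
        for name in INDICATORS
    }
    n_high = np.sum([flags[k] for k in HIGH_IMPACT], axis=0)
    n_low = np.sum([flags[k] for k in LOW_IMPACT], axis=0)

    age = np.clip(
        np.round(
            stats.truncnorm.rvs(
                (AGE_MIN - AGE_MEAN) / AGE_SD,
                (AGE_MAX - AGE_MEAN) / AGE_SD,
                loc=AGE_MEAN,
                scale=AGE_SD,
                size=n,
                random_state=rng,
            )
        ),
        AGE_MIN,
        AGE_MAX,
    ).astype(np.int64)
    sex = np.where(rng.random(n) < MALE_FRACTION, "male", "female").astype(object)
    wrvu = rng.lognormal(WRVU_LOG_MU, WRVU_LOG_SIGMA, size=n)
    asa = rng.choice(np.arange(1, 6), size=n, p=ASA_PROBS)

    latent = _latent_scores(spec, n_high, n_low, age, asa, wrvu, rng)
    destination = assign_destination(latent, spec.destination_thresholds)

    df = pd.DataFrame({"record_id": [f"R{i:06d}" for i in range(n)], "specialty": specialty})
    for name in INDICATORS:
        df[name] = pd.array(flags[name], dtype="Int8")
    df["age"] = pd.array(age, dtype="Int64")
    df["sex"] = sex
    df["wrvu"] = np.round(wrvu, 2)
    df["asa_class"] = pd.array(asa, dtype="Int64")
    df["destination"] = destination

    if spec.missing_rate > 0:
        mask = rng.random((n, len(INDEPENDENT_COLUMNS))) < spec.missing_rate
        for j, col in enumerate(INDEPENDENT_COLUMNS):
            if col == "wrvu":
                df.loc[mask[:, j], col] = np.nan
            elif col == "sex":
                df.loc[mask[:, j], col] = None
            else:
                df.loc[mask[:, j], col] = pd.NA
    # object columns hold NaN for missing; normalize to pd.NA via string dtype
    df["sex"] = df["sex"].astype("string")
    df["specialty"] = df["specialty"].astype("string")
    df["destination"] = df["destination"].astype("string")
    df["record_id"] = df["record_id"].astype("string")
    return df


def thresholds_for_marginals(
    spec: CohortSpec,
    marginals: Mapping[str, float] = None,
    n_calibration: int = 400_000,
    seed: int = 12345,
) -> tuple[float, ...]:
    """Latent-scale cutpoints whose induced destination marginals match a target.

    Simulates the latent score under ``spec``'s weights/prevalences and takes
    the cumulative-probability quantiles of the target marginal distribution.
    """
    if marginals is None:
        marginals = POPULATION_MARGINALS
    p = np.array([marginals[d] for d in DESTINATIONS], dtype=float)
    if np.any(p < 0) or p.sum() <= 0:
        raise ValueError("marginals must be nonnegative with positive total")
    cum = np.cumsum(p / p.sum())[:-1]
    calib = replace(
        spec, n_records=n_calibration, seed=seed, missing_rate=0.0,
        destination_thresholds=tuple(range(8)),  # unused placeholder
    )
    rng = np.random.default_rng(seed)
    n = n_calibration
    flags = {
        name: (rng.random(n) < calib.indicator_prevalence[name]).astype(np.int8)
        for name in INDICATORS
    }
    n_high = np.sum([flags[k] for k in HIGH_IMPACT], axis=0)
    n_low = np.sum([flags[k] for k in LOW_IMPACT], axis=0)
    age = stats.truncnorm.rvs(
        (AGE_MIN - AGE_MEAN) / AGE_SD, (AGE_MAX - AGE_MEAN) / AGE_SD,
        loc=AGE_MEAN, scale=AGE_SD, size=n, random_state=rng,
    )
    wrvu = rng.lognormal(WRVU_LOG_MU, WRVU_LOG_SIGMA, size=n)
    asa = rng.choice(np.arange(1, 6), size=n, p=ASA_PROBS)
    latent = _latent_scores(calib, n_high, n_low, age, asa, wrvu, rng)
    qs = np.quantile(latent, cum)
    # enforce strict monotonicity for near-duplicate quantiles
    for i in range(1, len(qs)):
        if qs[i] <= qs[i - 1]:
            qs[i] = np.nextafter(qs[i - 1], np.inf)
    return tuple(round(float(q), 4) for q in qs)


# ---------------------------------------------------------------------------
# CSV round trip

_READ_DTYPES = {
    "record_id": "string",
    "specialty": "string",
    **{name: "Int8" for name in INDICATORS},
    "age": "Int64",
    "sex": "string",
    "wrvu": "float64",
    "asa_class": "Int64",
    "destination": "string",
}


def write_cohort_csv(records: pd.DataFrame, path: str | Path) -> None:
    """Write a cohort in the canonical schema; missing values as empty fields."""
    missing = [c for c in COHORT_COLUMNS if c not in records.columns]
    if missing:
        raise ValueError(f"cohort frame lacks column(s): {missing}")
    records[list(COHORT_COLUMNS)].to_csv(path, index=False)


def read_cohort_csv(path: str | Path) -> pd.DataFrame:
    """Read a cohort CSV, validating schema and categorical labels.

    Malformed rows are reported with their (1-based, header-inclusive) line
    numbers and the offending values.
    """
    df = pd.read_csv(path, dtype=_READ_DTYPES)
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"cohort CSV lacks column(s): {missing}")
    df = df[list(COHORT_COLUMNS)]
    problems: list[str] = []

    def _check_labels(col: str, allowed: tuple[str, ...]) -> None:
        bad = df[col].notna() & ~df[col].isin(allowed)
        for idx in df.index[bad]:
            problems.append(f"line {idx + 2}: invalid {col} {df.at[idx, col]!r}")

    _check_labels("specialty", SPECIALTIES)
    _check_labels("destination", DESTINATIONS)
    _check_labels("sex", SEXES)
    for name in INDICATORS:
        bad = df[name].notna() & ~df[name].isin([0, 1])
        for idx in df.index[bad]:
            problems.append(f"line {idx + 2}: indicator {name} = {df.at[idx, name]!r} not 0/1")
    if problems:
        head = "; ".join(problems[:10])
        more = f" (+{len(problems) - 10} more)" if len(problems) > 10 else ""
        raise ValueError(f"malformed cohort rows: {head}{more}")
    return df
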