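"""Modified frailty index (mFI) arithmetic over 13 binary indicators.

The accumulating-deficits frailty index is the fraction of measured health
deficits present in a patient.  The 13-indicator mFI used here partitions
into 7 *high-impact* indicators (those with the strongest association with
30-day postoperative mortality) and 6 *low-impact* indicators.  Three
derived scores are provided:

* ``mfi``       — classic mFI, all 13 indicators weighted equally;
* split mFI     — the pair (high-impact fraction out of 7, low-impact
  fraction out of 6), used jointly as two model inputs;
* ``mfi_hat``   — a single weighted index, (beta * high count + low count) / 13,
  which up-weights high-impact deficits by a scalar ``beta`` and may exceed 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "HIGH_IMPACT",
    "LOW_IMPACT",
    "INDICATORS",
    "IndicatorPartition",
    "DEFAULT_PARTITION",
    "BETA_GRID",
    "DEFAULT_BETA",
    "normalize_indicator_name",
    "compute_mfi",
    "compute_split_mfi",
    "compute_mfi_hat",
    "add_frailty_scores",
    "score_csv",
]

#: High-impact indicators: severe physiologic-reserve deficits.
HIGH_IMPACT: tuple[str, ...] = (
    "ascites",
    "dialysis",
    "functional_status_dependent",
    "copd_history",
    "chf_history",
    "renal_failure",
    "ventilator_dependent",
)

#: Low-impact indicators: chronic comorbidities with weaker mortality association.
LOW_IMPACT: tuple[str, ...] = (
    "smoker",
    "diabetes",
    "disseminated_cancer",
    "dyspnea",
    "hypertension",
    "steroid_use",
)

#: Canonical order of the 13 indicators (high-impact first).
INDICATORS: tuple[str, ...] = HIGH_IMPACT + LOW_IMPACT

N_INDICATORS = len(INDICATORS)

#: Candidate beta multipliers for the weighted single index mfi_hat.
BETA_GRID: tuple[float, ...] = (1.5, 1.667, 1.75, 2.0)

#: Default beta: value selected on the composite cohort in the source study.
DEFAULT_BETA: float = 1.667

# Alias table mapping NSQIP-like column headers (lower-cased) onto the
# canonical vocabulary.  The source database names columns, not concepts.
_ALIASES: dict[str, str] = {
    "ascite": "ascites",
    "ascites": "ascites",
    "dialysis": "dialysis",
    "dialysis_2wk": "dialysis",
    "fnstatus": "functional_status_dependent",
    "fnstatus2": "functional_status_dependent",
    "functional_status": "functional_status_dependent",
    "hxcopd": "copd_history",
    "copd": "copd_history",
    "hxchf": "chf_history",
    "chf": "chf_history",
    "renafail": "renal_failure",
    "renal_failure_24h": "renal_failure",
    "ventilat": "ventilator_dependent",
    "ventilator": "ventilator_dependent",
    "smoke": "smoker",
    "current_smoker": "smoker",
    "diabetes_mellitus": "diabetes",
    "discancr": "disseminated_cancer",
    "hypermed": "hypertension",
    "htn": "hypertension",
    "steroid": "steroid_use",
    "steroid_1mo": "steroid_use",
}

# Dependent functional status (partial or total) codes the deficit as present.
_DEPENDENT_STATUS = {"partially dependent", "totally dependent", "dependent"}
_INDEPENDENT_STATUS = {"independent"}


def normalize_indicator_name(name: str) -> str:
    """Map a raw column header onto the canonical indicator vocabulary.

    Raises
    ------
    KeyError
        If the header matches no canonical name or alias.
    """
    key = name.strip().lower().replace(" ", "_").replace("-", "_")
    if key in INDICATORS:
        return key
    if key in _ALIASES:
        return _ALIASES[key]
    raise KeyError(f"unrecognized frailty indicator name: {name!r}")


def encode_functional_status(status: str) -> bool:
    """True iff the status string denotes a (partially/totally) dependent patient."""
    key = status.strip().lower()
    if key in _DEPENDENT_STATUS:
        return True
    if key in _INDEPENDENT_STATUS:
        return False
    raise ValueError(f"unrecognized functional status: {status!r}")


@dataclass(frozen=True)
class IndicatorPartition:
    """The fixed 7-high / 6-low taxonomy of the 13 mFI indicators."""

    high_impact: tuple[str, ...] = HIGH_IMPACT
    low_impact: tuple[str, ...] = LOW_IMPACT

    def __post_init__(self) -> None:
        high, low = set(self.high_impact), set(self.low_impact)
        if len(self.high_impact) != 7 or len(high) != 7:
            raise ValueError("high_impact must contain 7 distinct indicators")
        if len(self.low_impact) != 6 or len(low) != 6:
            raise ValueError("low_impact must contain 6 distinct indicators")
        if high & low:
            raise ValueError(f"overlapping indicators: {sorted(high & low)}")
        if high | low != set(INDICATORS):
            missing = set(INDICATORS) - (high | low)
            extra = (high | low) - set(INDICATORS)
            raise ValueError(
                f"partition must cover the 13 canonical indicators "
                f"(missing={sorted(missing)}, unknown={sorted(extra)})"
            )


DEFAULT_PARTITION = IndicatorPartition()


def _validate_flags(flags: Mapping[str, object]) -> dict[str, bool]:
    extra = set(flags) - set(INDICATORS)
    if extra:
        raise KeyError(f"unknown indicator name(s): {sorted(extra)}")
    missing = set(INDICATORS) - set(flags)
    if missing:
        raise KeyError(f"missing indicator flag(s): {sorted(missing)}")
    return {k: bool(flags[k]) for k in INDICATORS}


def compute_mfi(flags: Mapping[str, object]) -> float:
    """Classic 13-item mFI: deficits present / deficits measured, in [0, 1]."""
    v = _validate_flags(flags)
    return sum(v.values()) / N_INDICATORS


def compute_split_mfi(
    flags: Mapping[str, object],
    partition: IndicatorPartition = DEFAULT_PARTITION,
) -> tuple[float, float]:
    """(high-impact fraction of 7, low-impact fraction of 6)."""
    v = _validate_flags(flags)
    high = sum(v[k] for k in partition.high_impact)
    low = sum(v[k] for k in partition.low_impact)
    return high / len(partition.high_impact), low / len(partition.low_impact)


def compute_mfi_hat(
    flags: Mapping[str, object],
    partition: IndicatorPartition = DEFAULT_PARTITION,
    beta: float = DEFAULT_BETA,
) -> float:
    """Weighted single index (beta * high count + low count) / 13.

    With ``beta`` > 1 high-impact deficits are up-weighted; the value may
    exceed 1 (upper bound (7*beta + 6)/13).  ``beta`` = 1 recovers the mFI.
    """
    if beta <= 0:
        raise ValueError(f"beta must be positive, got {beta}")
    v = _validate_flags(flags)
    high = sum(v[k] for k in partition.high_impact)
    low = sum(v[k] for k in partition.low_impact)
    return (beta * high + low) / N_INDICATORS


def add_frailty_scores(
    frame: pd.DataFrame,
    partition: IndicatorPartition = DEFAULT_PARTITION,
    beta: float = DEFAULT_BETA,
) -> pd.DataFrame:
    """Append mfi, mfi_high, mfi_low and mfi_hat columns to a cohort frame.

    The 13 indicator columns must be present (canonical names or aliases)
    and coded 0/1.  Scores are kept at full floating precision; rounding is
    a reporting concern.
    """
    if beta <= 0:
        raise ValueError(f"beta must be positive, got {beta}")
    renames = {}
    for col in frame.columns:
        try:
            canon = normalize_indicator_name(str(col))
        except KeyError:
            continue
        if canon != col:
            renames[col] = canon
    df = frame.rename(columns=renames)
    missing = [k for k in INDICATORS if k not in df.columns]
    if missing:
        raise KeyError(f"missing indicator column(s): {missing}")
    ind = df[list(INDICATORS)].astype(float)
    bad = ~ind.isin([0.0, 1.0]) & ind.notna()
    if bad.to_numpy().any():
        col = bad.any()[bad.any()].index[0]
        raise ValueError(f"indicator column {col!r} contains non-binary values")
    high = ind[list(partition.high_impact)].sum(axis=1, skipna=False)
    low = ind[list(partition.low_impact)].sum(axis=1, skipna=False)
    out = df.copy()
    out["mfi"] = (high + low) / N_INDICATORS
    out["mfi_high"] = high / len(partition.high_impact)
    out["mfi_low"] = low / len(partition.low_impact)
    out["mfi_hat"] = (beta * high + low) / N_INDICATORS
    return out


def score_csv(
    in_path: str | Path,
    out_path: str | Path,
    beta: float = DEFAULT_BETA,
    partition: IndicatorPartition = DEFAULT_PARTITION,
) -> pd.DataFrame:
    """Batch scorer: read a CSV with the 13 indicator columns (0/1), write it
    back with mfi, mfi_high, mfi_low, mfi_hat columns appended."""
    df = pd.read_csv(in_path)
    scored = add_frailty_scores(df, partition=partition, beta=beta)
    scored.to_csv(out_path, index=False)
    return scored
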