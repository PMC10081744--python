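"""Cohort preparation: inclusion filtering, destination-stratified
train/test splitting, median-cap partial balancing, and per-variant
feature encoding.

The only inclusion filter is completeness of the model's independent
variables (13 indicators + age, sex, wRVU, ASA class) and of the recorded
destination.  Within each specialty dataset (and the pooled composite),
destinations with fewer than 2 records are dropped so that every class can
appear in both halves of the split.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .cohort import DESTINATIONS, INDEPENDENT_COLUMNS, SPECIALTIES
from .frailty import DEFAULT_BETA, DEFAULT_PARTITION, IndicatorPartition, add_frailty_scores

__all__ = [
    "SpecialtyDataset",
    "SplitDataset",
    "ModelVariant",
    "VARIANTS",
    "FeatureMatrix",
    "FeatureEncoder",
    "filter_records",
    "stratified_split",
    "partial_balance",
    "encode_features",
]

COMPOSITE = "composite"


@dataclass(frozen=True)
class SpecialtyDataset:
    """Records of one specialty (or the pooled composite) after filtering."""

    name: str
    records: pd.DataFrame
    present_destinations: tuple[str, ...]

    @property
    def empty(self) -> bool:
        return len(self.records) == 0


@dataclass(frozen=True)
class SplitDataset:
    train: pd.DataFrame
    test: pd.DataFrame


@dataclass(frozen=True)
class ModelVariant:
    """Which frailty-index column(s) feed a model, besides the 4 covariates."""

    name: str
    index_features: tuple[str, ...]
    beta: float | None = None


#: The five model variants compared in the analysis.
VARIANTS: dict[str, ModelVariant] = {
    "single_mfi": ModelVariant("single_mfi", ("mfi",)),
    "split_mfi": ModelVariant("split_mfi", ("mfi_high", "mfi_low")),
    "high_only": ModelVariant("high_only", ("mfi_high",)),
    "low_only": ModelVariant("low_only", ("mfi_low",)),
    "mfi_hat": ModelVariant("mfi_hat", ("mfi_hat",), beta=DEFAULT_BETA),
}

COVARIATES: tuple[str, ...] = ("age", "sex", "wrvu", "asa_class")
_SCALED_COVARIATES: tuple[str, ...] = ("age", "wrvu", "asa_class")


def filter_records(records: pd.DataFrame) -> dict[str, SpecialtyDataset]:
    """Apply inclusion rules and build the 10 datasets (9 specialties + composite).

    Drops records missing any independent variable or the destination, then
    — within each dataset independently — drops destinations represented by
    fewer than 2 records.  A specialty with no surviving records yields an
    explicit empty dataset rather than an error.
    """
    cols = list(INDEPENDENT_COLUMNS) + ["destination"]
    complete = records.dropna(subset=cols)

    def _build(name: str, df: pd.DataFrame) -> SpecialtyDataset:
        counts = df["destination"].value_counts()
        present = tuple(d for d in DESTINATIONS if counts.get(d, 0) >= 2)
        kept = df[df["destination"].isin(present)].reset_index(drop=True)
        return SpecialtyDataset(name, kept, present)

    out = {s: _build(s, complete[complete["specialty"] == s]) for s in SPECIALTIES}
    out[COMPOSITE] = _build(COMPOSITE, complete)
    return out


def stratified_split(ds: SpecialtyDataset, seed: int) -> SplitDataset:
    """Random 50/50 split within each destination.

    Odd destination counts are floor/ceil split, the extra record going
    alternately to train then test as destinations are visited in taxonomy
    order; a destination with exactly 2 records yields one record per side.
    """
    counts = ds.records["destination"].value_counts()
    for d in ds.present_destinations:
        if counts.get(d, 0) < 2:
            raise ValueError(
                f"destination {d!r} has {counts.get(d, 0)} record(s); "
                "run filter_records first"
            )
    rng = np.random.default_rng(seed)
    train_parts, test_parts = [], []
    extra_to_train = True
    for dest in ds.present_destinations:
        block = ds.records[ds.records["destination"] == dest]
        order = rng.permutation(len(block))
        n = len(block)
        n_train = n // 2
        if n % 2 == 1:
            if extra_to_train:
                n_train += 1
            extra_to_train = not extra_to_train
        train_parts.append(block.iloc[order[:n_train]])
        test_parts.append(block.iloc[order[n_train:]])
    train = pd.concat(train_parts).reset_index(drop=True) if train_parts else ds.records.iloc[:0]
    test = pd.concat(test_parts).reset_index(drop=True) if test_parts else ds.records.iloc[:0]
    return SplitDataset(train=train, test=test)


def partial_balance(records: pd.DataFrame, seed: int) -> pd.DataFrame:
    """Cap over-represented destinations at the median per-destination count.

    Let m be the median of the per-destination record counts.  Destinations
    with more than m records are subsampled uniformly without replacement to
    ceil(m) records; the rest are kept whole.  This trims dominant classes
    (discharge home, above all) without inflating rare ones.
    """
    if len(records) == 0:
        raise ValueError("cannot balance an empty record set")
    counts = records["destination"].value_counts()
    m = float(np.median(counts.to_numpy()))
    cap = math.ceil(m)
    rng = np.random.default_rng(seed)
    parts = []
    for dest in DESTINATIONS:
        block = records[records["destination"] == dest]
        if len(block) == 0:
            continue
        if len(block) > m and len(block) > cap:
            keep = rng.choice(len(block), size=cap, replace=False)
            block = block.iloc[np.sort(keep)]
        parts.append(block)
    return pd.concat(parts).reset_index(drop=True)


@dataclass(frozen=True)
class FeatureMatrix:
    """Dense [0, 1]-scaled design matrix with one-hot destination labels."""

    X: np.ndarray
    columns: tuple[str, ...]
    y: np.ndarray  # one-hot, shape (n, n_classes)
    labels: np.ndarray  # destination strings, shape (n,)
    classes: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.X.shape != (len(self.labels), len(self.columns)):
            raise ValueError("X shape inconsistent with columns/labels")
        if self.y.shape != (len(self.labels), len(self.classes)):
            raise ValueError("y shape inconsistent with classes")


class FeatureEncoder:
    """Fit scaling bounds on training records; reuse them for test records.

    Features are the variant's frailty-score column(s) plus the four
    covariates.  Age, wRVU and ASA class are min-max scaled with
    training-set bounds (a constant training column scales to 0); sex is
    0/1; mFI-type scores are divided by their theoretical maximum so every
    column lives in [0, 1] on the training data.
    """

    def __init__(
        self,
        variant: ModelVariant,
        classes: Sequence[str],
        partition: IndicatorPartition = DEFAULT_PARTITION,
        beta: float | None = None,
    ) -> None:
        if isinstance(variant, str):
            variant = VARIANTS[variant]
        self.variant = variant
        self.partition = partition
        self.beta = beta if beta is not None else (variant.beta or DEFAULT_BETA)
        self.classes = tuple(classes)
        unknown = set(self.classes) - set(DESTINATIONS)
        if unknown:
            raise ValueError(f"unknown destination classes: {sorted(unknown)}")
        self.columns: tuple[str, ...] = variant.index_features + COVARIATES
        self.bounds_: dict[str, tuple[float, float]] | None = None

    # mfi/mfi_high/mfi_low are already fractions; mfi_hat's upper bound grows
    # with beta, so scale it by (7*beta + 6)/13.
    def _index_scale(self, col: str) -> float:
        if col == "mfi_hat":
            return (len(self.partition.high_impact) * self.beta + len(self.partition.low_impact)) / 13.0
        return 1.0

    def fit(self, train: pd.DataFrame) -> "FeatureEncoder":
        scored = add_frailty_scores(train, partition=self.partition, beta=self.beta)
        self.bounds_ = {}
        for col in _SCALED_COVARIATES:
            vals = scored[col].astype(float)
            self.bounds_[col] = (float(vals.min()), float(vals.max()))
        return self

    def transform(self, records: pd.DataFrame) -> FeatureMatrix:
        if self.bounds_ is None:
            raise RuntimeError("encoder not fitted")
        scored = add_frailty_scores(records, partition=self.partition, beta=self.beta)
        unseen = set(scored["destination"].dropna()) - set(self.classes)
        if unseen:
            raise ValueError(f"destination(s) absent from training classes: {sorted(unseen)}")
        n = len(scored)
        X = np.empty((n, len(self.columns)), dtype=float)
        for j, col in enumerate(self.columns):
            if col == "sex":
                X[:, j] = (scored["sex"] == "male").astype(float)
            elif col in _SCALED_COVARIATES:
                lo, hi = self.bounds_[col]
                vals = scored[col].astype(float).to_numpy()
                X[:, j] = 0.0 if hi == lo else np.clip((vals - lo) / (hi - lo), 0.0, 1.0)
            else:
                X[:, j] = scored[col].to_numpy(dtype=float) / self._index_scale(col)
        labels = scored["destination"].to_numpy(dtype=object)
        class_index = {c: k for k, c in enumerate(self.classes)}
        y = np.zeros((n, len(self.classes)), dtype=float)
        for i, lab in enumerate(labels):
            y[i, class_index[lab]] = 1.0
        return FeatureMatrix(X=X, columns=self.columns, y=y, labels=labels, classes=self.classes)

    def fit_transform(self, train: pd.DataFrame) -> FeatureMatrix:
        return self.fit(train).transform(train)


def encode_features(
    records: pd.DataFrame,
    variant: ModelVariant | str,
    partition: IndicatorPartition = DEFAULT_PARTITION,
    classes: Sequence[str] | None = None,
    beta: float | None = None,
) -> FeatureMatrix:
    """One-shot encoding: fit bounds on ``records`` and encode them.

    For the train-then-test workflow use :class:`FeatureEncoder` directly so
    the test matrix reuses the training bounds and column order.
    """
    if classes is None:
        seen = set(records["destination"].dropna())
        classes = tuple(d for d in DESTINATIONS if d in seen)
    enc = FeatureEncoder(variant, classes=classes, partition=partition, beta=beta)
    return enc.fit_transform(records)
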