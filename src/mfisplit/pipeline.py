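"""End-to-end experiment orchestration.

One call — :func:`run_experiment` — takes a cohort (synthetic spec or CSV
path) through filtering, destination-stratified splitting, median-cap
balancing, per-variant feature encoding, network training (fixed
architecture or greedy search), and evaluation, producing an
:class:`EvaluationReport` and, optionally, a directory of CSV/JSON
artifacts.  Every stage draws from an explicit seed, so a given
configuration reproduces byte-identical reports.

When the weighted single index (``mfi_hat``) is among the variants, its
beta multiplier is selected on the composite dataset by test accuracy and
the selected value is reused for every specialty.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .ann import (
    Architecture,
    SearchConfig,
    TrainConfig,
    desk_config,
    predict,
    save_model,
    search_architecture,
    train_mlp,
)
from .cohort import DESTINATIONS, SPECIALTIES, CohortSpec, generate_cohort, read_cohort_csv
from .frailty import BETA_GRID, DEFAULT_PARTITION, IndicatorPartition
from .prep import (
    COMPOSITE,
    FeatureEncoder,
    SpecialtyDataset,
    VARIANTS,
    filter_records,
    partial_balance,
    stratified_split,
)
from .stats import (
    AccuracyResult,
    ZTestResult,
    accuracy,
    destination_coverage,
    leave_one_out_compare,
    mortality_recall,
    percent_improvement,
    select_beta,
    two_prop_ztest,
)

__all__ = ["ExperimentConfig", "EvaluationReport", "run_experiment"]

ALL_DATASETS: tuple[str, ...] = SPECIALTIES + (COMPOSITE,)

DEFAULT_VARIANTS: tuple[str, ...] = ("single_mfi", "split_mfi", "high_only", "low_only")


@dataclass(frozen=True)
class ExperimentConfig:
    """Full specification of one reproducible experiment run."""

    cohort: CohortSpec | str | Path = field(default_factory=CohortSpec)
    datasets: tuple[str, ...] = ALL_DATASETS
    variants: tuple[str, ...] = DEFAULT_VARIANTS
    split_seed: int = 1
    balance_seed: int = 2
    model_seed: int = 3
    train: TrainConfig = field(default_factory=desk_config)
    search: SearchConfig | None = None
    fixed_hidden: tuple[int, ...] | None = None  # default: one layer of 2*inputs
    beta_grid: tuple[float, ...] = BETA_GRID
    balance_test: bool = True
    partition: IndicatorPartition = DEFAULT_PARTITION
    output_dir: str | Path | None = None

    def __post_init__(self) -> None:
        unknown = set(self.variants) - set(VARIANTS)
        if unknown:
            raise ValueError(f"unknown variant(s): {sorted(unknown)}")
        unknown_ds = set(self.datasets) - set(ALL_DATASETS)
        if unknown_ds:
            raise ValueError(f"unknown dataset(s): {sorted(unknown_ds)}")


@dataclass
class EvaluationReport:
    accuracies: dict[str, dict[str, AccuracyResult]]
    improvements: dict[str, float | None]
    ztests: dict[str, dict[str, ZTestResult]]
    coverage: dict[str, dict[str, float]]
    mortality: dict[str, dict[str, float | None]]
    leave_one_out: dict[str, dict[str, object]]
    selected_beta: float | None
    architectures: dict[str, dict[str, tuple[int, ...]]]
    skipped: dict[str, str]

    def accuracy_frame(self) -> pd.DataFrame:
        rows = []
        for ds, per_variant in self.accuracies.items():
            for variant, res in per_variant.items():
                rows.append(
                    dict(dataset=ds, variant=variant, n_test=res.n_test,
                         n_correct=res.n_correct,
                         accuracy_pct=round(100 * res.accuracy, 2))
                )
        return pd.DataFrame(rows)


def _model_seed(base: int, dataset: str, variant: str, beta: float | None) -> int:
    tag = f"{dataset}:{variant}:{beta}"
    return (base ^ zlib.crc32(tag.encode())) % (2**31)


def _train_and_score(
    cfg: ExperimentConfig,
    dataset: SpecialtyDataset,
    train_df: pd.DataFrame,
    test_df: pd.DataFrame,
    variant_name: str,
    beta: float | None,
):
    encoder = FeatureEncoder(
        VARIANTS[variant_name], classes=dataset.present_destinations,
        partition=cfg.partition, beta=beta,
    )
    train_fm = encoder.fit_transform(train_df)
    test_fm = encoder.transform(test_df)
    tcfg = replace(cfg.train, seed=_model_seed(cfg.model_seed, dataset.name, variant_name, beta))
    if cfg.search is not None:
        arch, model, _ = search_architecture(
            train_fm.X, train_fm.y, test_fm.X, test_fm.y, tcfg, cfg.search
        )
    else:
        hidden = cfg.fixed_hidden or (2 * train_fm.X.shape[1],)
        arch = Architecture(train_fm.X.shape[1], hidden, len(train_fm.classes))
        model = train_mlp(train_fm.X, train_fm.y, arch, tcfg)
    model.scaling_bounds = encoder.bounds_
    preds = predict(model, test_fm.X, classes=test_fm.classes)
    res = accuracy(preds, test_fm.labels, variant=variant_name, specialty=dataset.name)
    cov = destination_coverage(preds, test_fm.labels, dataset.present_destinations)
    mort = mortality_recall(preds, test_fm.labels)
    return model, arch, res, cov, mort


def run_experiment(cfg: ExperimentConfig) -> EvaluationReport:
    """Execute the full pipeline described in the module docstring."""
    if isinstance(cfg.cohort, (str, Path)):
        records = read_cohort_csv(cfg.cohort)
    else:
        records = generate_cohort(cfg.cohort)
    datasets = filter_records(records)

    out_dir = Path(cfg.output_dir) if cfg.output_dir is not None else None
    if out_dir is not None:
        (out_dir / "models").mkdir(parents=True, exist_ok=True)

    # --- beta selection on the composite dataset --------------------------
    selected_beta: float | None = None
    if "mfi_hat" in cfg.variants:
        comp = datasets[COMPOSITE]
        if len(comp.present_destinations) < 2:
            raise ValueError("composite dataset too degenerate for beta selection")
        split = stratified_split(comp, cfg.split_seed)
        train_df = partial_balance(split.train, cfg.balance_seed)
        test_df = (
            partial_balance(split.test, cfg.balance_seed + 1)
            if cfg.balance_test else split.test
        )
        per_beta = {}
        for beta in cfg.beta_grid:
            *_, res, _, _ = _train_and_score(cfg, comp, train_df, test_df, "mfi_hat", beta)
            per_beta[beta] = res.accuracy
        selected_beta = select_beta(per_beta)

    accuracies: dict[str, dict[str, AccuracyResult]] = {}
    coverage: dict[str, dict[str, float]] = {}
    mortality: dict[str, dict[str, float | None]] = {}
    architectures: dict[str, dict[str, tuple[int, ...]]] = {}
    skipped: dict[str, str] = {}

    for name in cfg.datasets:
        ds = datasets[name]
        if ds.empty:
            skipped[name] = "no records after filtering"
            continue
        if len(ds.present_destinations) < 2:
            skipped[name] = "fewer than 2 destinations present"
            continue
        split = stratified_split(ds, cfg.split_seed)
        train_df = partial_balance(split.train, cfg.balance_seed)
        test_df = (
            partial_balance(split.test, cfg.balance_seed + 1)
            if cfg.balance_test else split.test
        )
        if out_dir is not None:
            _write_manifest(out_dir, name, split.train, split.test)
            _write_balance_audit(out_dir, name, split.train, train_df, split.test, test_df)
        accuracies[name] = {}
        coverage[name] = {}
        mortality[name] = {}
        architectures[name] = {}
        for variant_name in cfg.variants:
            beta = selected_beta if variant_name == "mfi_hat" else None
            model, arch, res, cov, mort = _train_and_score(
                cfg, ds, train_df, test_df, variant_name, beta
            )
            accuracies[name][variant_name] = res
            coverage[name][variant_name] = cov
            mortality[name][variant_name] = mort
            architectures[name][variant_name] = arch.hidden_layers
            if out_dir is not None:
                save_model(model, out_dir / "models" / f"{name}_{variant_name}.json")

    improvements: dict[str, float | None] = {}
    ztests: dict[str, dict[str, ZTestResult]] = {}
    for name, per_variant in accuracies.items():
        ztests[name] = {}
        if "single_mfi" in per_variant and "split_mfi" in per_variant:
            single, spl = per_variant["single_mfi"], per_variant["split_mfi"]
            improvements[name] = percent_improvement(single.accuracy, spl.accuracy)
            ztests[name]["split_vs_single"] = two_prop_ztest(
                single.accuracy, single.n_test, spl.accuracy, spl.n_test
            )
        if "high_only" in per_variant and "low_only" in per_variant:
            hi, lo = per_variant["high_only"], per_variant["low_only"]
            ztests[name]["high_vs_low"] = two_prop_ztest(
                lo.accuracy, lo.n_test, hi.accuracy, hi.n_test
            )

    loo = leave_one_out_compare(
        {
            name: {v: r.accuracy for v, r in per_variant.items()}
            for name, per_variant in accuracies.items()
        }
    )

    report = EvaluationReport(
        accuracies=accuracies,
        improvements=improvements,
        ztests=ztests,
        coverage=coverage,
        mortality=mortality,
        leave_one_out=loo,
        selected_beta=selected_beta,
        architectures=architectures,
        skipped=skipped,
    )
    if out_dir is not None:
        _write_report(out_dir, report)
    return report


# ---------------------------------------------------------------------------
# Artifact writers (plain CSV/JSON, no timestamps: reruns are byte-identical)

def _write_manifest(out_dir: Path, name: str, train: pd.DataFrame, test: pd.DataFrame) -> None:
    manifest = pd.concat(
        [
            pd.DataFrame({"record_id": train["record_id"], "role": "train"}),
            pd.DataFrame({"record_id": test["record_id"], "role": "test"}),
        ]
    ).sort_values("record_id")
    manifest.to_csv(out_dir / f"manifest_{name}.csv", index=False)


def _write_balance_audit(
    out_dir: Path, name: str,
    train_before: pd.DataFrame, train_after: pd.DataFrame,
    test_before: pd.DataFrame, test_after: pd.DataFrame,
) -> None:
    rows = []
    for role, before, after in (
        ("train", train_before, train_after), ("test", test_before, test_after)
    ):
        b = before["destination"].value_counts()
        a = after["destination"].value_counts()
        for dest in DESTINATIONS:
            if b.get(dest, 0) or a.get(dest, 0):
                rows.append(
                    dict(role=role, destination=dest,
                         before=int(b.get(dest, 0)), after=int(a.get(dest, 0)))
                )
    pd.DataFrame(rows).to_csv(out_dir / f"balance_{name}.csv", index=False)


def _write_report(out_dir: Path, report: EvaluationReport) -> None:
    report.accuracy_frame().to_csv(out_dir / "accuracy.csv", index=False)
    imp_rows = [
        dict(dataset=k, improvement_pct=(None if v is None else round(v, 1)))
        for k, v in report.improvements.items()
    ]
    pd.DataFrame(imp_rows).to_csv(out_dir / "improvements.csv", index=False)
    z_rows = []
    for ds, tests in report.ztests.items():
        for comparison, zt in tests.items():
            z_rows.append(
                dict(dataset=ds, comparison=comparison,
                     p1=round(zt.p1, 4), p2=round(zt.p2, 4),
                     n1=zt.n1, n2=zt.n2,
                     p_one_tailed=round(zt.p_one_tailed, 4),
                     direction=zt.direction)
            )
    pd.DataFrame(z_rows).to_csv(out_dir / "ztests.csv", index=False)
    cov_rows = [
        dict(dataset=ds, variant=v, coverage=round(c, 3))
        for ds, per in report.coverage.items() for v, c in per.items()
    ]
    pd.DataFrame(cov_rows).to_csv(out_dir / "coverage.csv", index=False)
    loo_rows = []
    for ds, entry in report.leave_one_out.items():
        if entry.get("comparable"):
            loo_rows.append(
                dict(dataset=ds,
                     high_only_pct=round(100 * entry["high_only"], 2),
                     low_only_pct=round(100 * entry["low_only"], 2),
                     high_dominant=entry["high_dominant"], tie=entry["tie"],
                     split_ge_both=entry.get("split_ge_both"))
            )
    pd.DataFrame(loo_rows).to_csv(out_dir / "leave_one_out.csv", index=False)
    summary = {
        "selected_beta": report.selected_beta,
        "skipped": report.skipped,
        "architectures": {
            ds: {v: list(h) for v, h in per.items()}
            for ds, per in report.architectures.items()
        },
        "mortality_recall": report.mortality,
    }
    (out_dir / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
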