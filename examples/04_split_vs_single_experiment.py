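"""One full pipeline run: does splitting the mFI help on a planted cohort?

Generates a 20000-record synthetic cohort whose destinations depend three
times more strongly on high-impact than low-impact deficits, then runs the
composite dataset through filtering, stratified splitting, median-cap
balancing, and network training for four model variants.
"""

from mfisplit.ann import desk_config
from mfisplit.cohort import CohortSpec
from mfisplit.pipeline import ExperimentConfig, run_experiment

cfg = ExperimentConfig(
    cohort=CohortSpec(n_records=20_000, seed=11),
    datasets=("composite",),
    variants=("single_mfi", "split_mfi", "high_only", "low_only"),
    train=desk_config(),
)
report = run_experiment(cfg)

for variant, res in report.accuracies["composite"].items():
    print(f"{variant:12s} accuracy {100 * res.accuracy:5.2f}%  (n_test={res.n_test})")
print(f"\nsplit vs single improvement: {report.improvements['composite']:+.1f}%")
zt = report.ztests["composite"]["split_vs_single"]
print(f"one-tailed Z-test: p={zt.p_one_tailed:.4f} ({zt.direction})")
mort = report.mortality["composite"]["split_mfi"]
print(f"mortality recall (split model): {100 * mort:.1f}%")
print(
    "\nWith the planted 3:1 effect the split-index model outperforms the\n"
    "single-index one and the high-only model beats the low-only model —\n"
    "the qualitative pattern the analysis is designed to detect."
)
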