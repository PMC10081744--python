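# Methods

## The indices

The 13-indicator modified frailty index is the accumulating-deficits
fraction `mFI = k/13` for `k` deficits present. The fixed taxonomy splits
it into 7 high-impact indicators (ascites, dialysis within 2 weeks,
dependent functional status, history of COPD, recent congestive heart
failure, renal failure within 24 h, ventilator dependence) and 6 low-impact
ones (current smoker, diabetes, disseminated cancer, dyspnea,
hypertension/antihypertensives, recent steroid use), giving the split pair
`(high/7, low/6)` and the weighted single index

```
mFI^ = (β·high + low) / 13,      β ∈ {1.5, 1.667, 1.75, 2.0}, default 1.667
```

`mFI^` ranges up to `(7β+6)/13` (> 1). Identities maintained and tested
exhaustively over all 2^13 indicator vectors: `mFI = (7·mFI_high +
6·mFI_low)/13`; `mFI^(β=1) = mFI`; `mFI^` strictly increasing in β iff at
least one high-impact deficit is present. "Functional status" codes as a
deficit when the patient is partially or totally dependent. Raw NSQIP-style
column headers (`HXCOPD`, `FNSTATUS2`, …) are normalized through an alias
table. Scores are kept at full precision; rounding (accuracies to 2
decimals, improvements to 1, p-values to 4) happens only in reports.

## Synthetic cohort generator

The generator emulates the restricted source registry's schema and the
marginal structure the analysis depends on; it is not a demographic model.
Each record draws a specialty (9-way categorical, general surgery and
orthopedics dominant), 13 independent Bernoulli indicators, age (truncated
normal, mean 63, sd 15, bounds 18–100, integer), sex (44% male), wRVU
(lognormal with median 20.7, σ = 0.4) and ASA class (categorical on 1–5,
mode 3). Destination comes from a latent care-intensity score

```
s = w_high·(#high) + w_low·(#low) + w_age·age′ + w_asa·asa′ + w_wrvu·wrvu′ + ε,
ε ~ N(0, noise_sd),
```

(primed covariates standardized by their theoretical moments) cut at 8
ordered thresholds; a value on a cutpoint goes to the higher category. A
latent-ordinal design was chosen over a per-class multinomial because the
destination scale is ordered by care intensity and it makes "high-impact
deficits matter more" a single contrast `w_high` vs `w_low`.

Defaults (chosen once, before any experiment, as the study conditions):

| parameter | default | rationale |
|---|---|---|
| prevalence, high-impact | 0.02 each | high-only mFI has median 0 |
| prevalence, low-impact | 0.15 each | median deficit count 1 → median mFI 1/13 ≈ 0.077 (target ≈ 0.08), median low-only 1/6 ≈ 0.17 |
| `w_high`, `w_low` | 1.5, 0.5 | plants the 3:1 high:low asymmetry the experiments must detect |
| `w_age`, `w_asa`, `w_wrvu` | 0.3, 0.5, 0.2 | covariates informative but not dominant |
| `noise_sd` | 1.0 | keeps destination only partially predictable (accuracies in the 25–40% range after balancing, like the real task) |
| thresholds | frozen constants | latent quantiles matching the population marginals (home 91.1%, death 0.3%, …), computed once by `thresholds_for_marginals` at n = 400 000 |

A `balanced` preset swaps in near-uniform destination thresholds for fast
training tests. `with_null_effect()` equalizes `w_high = w_low = 1.0`
keeping total signal, for null-calibration runs. Missingness, when enabled,
is injected completely at random over independent variables only, because
the pipeline's sole exclusion rule is incomplete independent variables.

What the generator does **not** model: specialty-specific comorbidity
profiles or correlations between indicators, greater-than-additive
interactions, and any real demographic joint structure. Passing tests
therefore show that the pipeline detects a planted high/low asymmetry of
realistic magnitude under realistic marginals — not that the published
real-data accuracies are reproduced.

## Preparation pipeline

Per dataset (each of the 9 specialties and the pooled composite,
independently): drop incomplete records, drop destinations with fewer than
2 records (each class must reach both halves of the split; 2-record
destinations are retained and split 1/1 even though a single training
example is unstable), split 50/50 within each destination (odd counts
alternate the extra record between train and test in taxonomy order), then
partially balance train and test **separately**: destinations above the
median per-destination count are subsampled, uniformly without replacement,
to the median (ceiling of it when the median of an even number of counts is
fractional — the even case is a policy choice; the ceiling keeps at least
median-level representation). Splitting precedes balancing because that is
the stated order of the original protocol; balancing the test set as well
is unusual but follows the same text, and `balance_test=False` is available.

Encoding: the variant's index column(s) plus age, sex (0/1), wRVU and ASA
class. ASA is treated as a scaled ordinal scalar, not one-hot, since it
enters as one variable among five or six. Continuous covariates are min-max
scaled with training-set bounds (reused, with clipping, on test data; a
constant training column scales to 0); index columns are divided by their
theoretical maxima. Labels are one-hot over the dataset's present
destinations in taxonomy order.

## Network engine

Classic fully-connected MLP: sigmoid hidden and output units, squared-error
loss against one-hot targets, full-batch gradient descent (learning rate
0.1, momentum 0.9), weights initialized uniform [−0.5, 0.5] from the model
seed. Sigmoid + MSE (rather than softmax + cross-entropy) keeps the engine
aligned with the RMSE-based stopping protocol it implements. Prediction is
the argmax output unit; exact ties resolve to the lowest destination index.
Analytic gradients are verified against central finite differences (rel.
error ≤ 1e-5).

Stopping is evaluated at epoch checkpoints (multiples of `epoch_step` at or
after `min_epochs`): training RMSE < 0.05, or |ΔRMSE| < 1e-4 across a
10 000-epoch window (plateau), or `max_epochs`. The full-scale profile is
50 000/150 000/10 000 epochs; the desk profile used by the tests, examples
and acceptance script is 2 000/6 000/500 with a 500-epoch plateau window —
chosen as the package's standard scaled-down problem size. A divergence
guard halves the learning rate once before raising (with bounded sigmoid
outputs the loss cannot blow up in practice, but the guard documents the
contract).

Architecture search: depths 1 → 2 → 3; at each depth the new layer's width
is swept from ⌈n/3⌉ to 4n in steps of 1 node (configurable), where n is the
preceding layer's width — the printed range "13n to 4*n" in the source is
read as the standard ⅓·n–4·n sizing heuristic, and ⌈n/3⌉ is the only
constant affected if that reading is wrong. A sweep stops after two
successive candidates strictly worse than the best seen (a tie is not a
reduction); earlier layers stay frozen at their selected widths; the
globally best test accuracy wins, ties to the smaller total hidden size.
Selecting on the test set replicates the original (optimistic) protocol;
callers can pass a held-out validation matrix instead.

## Evaluation

Exact-match accuracy; relative improvement `100·(acc_b/acc_a − 1)`
(undefined when the reference accuracy is 0); one-tailed two-proportion
Z-test with **unpooled** (Wald) standard error — on the reconstructed
cardiac counts 16/52 vs 14/52 the unpooled form reproduces the printed
p = 0.3324 exactly, where the pooled form gives 0.3326; p is the upper-tail
normal probability of |z|, reported with a direction flag, and a degenerate
SE of 0 yields a flagged p = 0.5. No multiple-testing correction, matching
the original reporting. Destination coverage is the fraction of a dataset's
destinations with at least one correctly predicted test case; mortality
recall is recall of the death class (not-applicable when no deaths are in
the test set). β for mFI^ is selected by composite test accuracy (ties to
the smaller β) and reused for all specialties; models are retrained per β
candidate. The cardiac test size 52 is reconstructed from the published
accuracies (30.77% vs 26.92%, a 2-case difference).

## Experiment orchestration and problem sizes

`run_experiment` drives cohort → filter → split → balance → encode → train
→ evaluate for every requested dataset and variant, with explicit seeds for
split, balance and model stages (per-model seeds derive from a CRC of the
dataset/variant tag so variants are decorrelated but reproducible). Every
variant of a dataset trains on the identical balanced split — only feature
columns differ — preserving the controlled comparison. Artifacts (accuracy,
improvement, Z-test, coverage and leave-one-out CSVs; split manifests;
balance audits; JSON models) contain no timestamps, so identical
configurations produce byte-identical outputs.

Standard problem sizes: synthetic experiments use 20 000-record cohorts,
five cohort seeds, the composite dataset, the desk training profile and a
fixed single hidden layer of twice the input width. The fixed architecture
is deliberate for the variant contrast: the scientific comparison is
between input encodings at matched capacity, and the search protocol is
validated separately on its own fixtures. After the home-heavy marginals
are median-capped, these runs train on roughly 200 records and test on
roughly 200 — small enough to run the whole suite in about a minute, large
enough that the planted 3:1 asymmetry reliably dominates seed noise in the
5-seed means.

## Known limitations

* Synthetic cohorts share only marginal structure with the restricted
  registry; published real-data accuracies (and derived figures such as the
  0–0.795 observed mFI^ range or the 78% mortality recall) are replayed as
  reporting arithmetic where possible, not re-estimated.
* The generator's indicators are independent Bernoullis; real comorbidities
  cluster.
* Single train/test split by design (no cross-validation), and architecture
  selection on the test set, faithful to the protocol being reproduced.
* The two published improvement averages (18.3% overall, 19.1% excluding
  cardiac) do not follow from the published table by simple averaging under
  any rule tried here; they are not reproduced or targeted.
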