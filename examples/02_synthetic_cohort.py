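"""Generate a synthetic NSQIP-like cohort and inspect its marginal structure.

Draws 20000 elective-surgery records with the home-heavy population
destination marginals and prints the quantities the generator is calibrated
to: median frailty indices and the destination distribution.
"""

from mfisplit import CohortSpec, generate_cohort, write_cohort_csv
from mfisplit.frailty import add_frailty_scores

spec = CohortSpec.population(n_records=20_000, seed=0)
cohort = generate_cohort(spec)
scored = add_frailty_scores(cohort)

print(f"records: {len(cohort)}")
print(f"median mFI:          {scored['mfi'].median():.4f}   (target ~0.08)")
print(f"median high-only mFI: {scored['mfi_high'].median():.4f}  (target 0)")
print(f"median low-only mFI:  {scored['mfi_low'].median():.4f}  (target ~0.17)")
print("\ndestination marginals (%):")
fracs = cohort["destination"].value_counts(normalize=True) * 100
for dest, pct in fracs.items():
    print(f"  {dest:22s} {pct:6.2f}")

write_cohort_csv(cohort, "cohort_example.csv")
print("\nwrote cohort_example.csv (canonical CSV schema)")
print(
    "\nDischarge to home dominates (~91%), as in the real elective-surgery\n"
    "population; the pipeline's median-cap balancing exists precisely to\n"
    "keep the networks from overlearning that majority class."
)
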