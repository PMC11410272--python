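"""Per-SD performance metrics for one disease PRS on a synthetic cohort.

Simulates an ancestry-stratified cohort, then reports the standard
per-ancestry panel for the coronary-artery-disease-like score: odds ratio
per SD (logistic, adjusting for age and sex), hazard ratio per SD (Cox on
the age scale) and AUC of the score alone.  Metrics are gated: an
ancestry group needs at least 100 cases to show an estimate.
"""

from prsbench import SimulationConfig, align, auc, hr_per_sd, or_per_sd, simulate_cohort

sim = simulate_cohort(SimulationConfig(seed=1))
frame = align(sim.cohort, sim.scores, sim.diseases["CAD"])

print("CAD enhanced-like score, per ancestry group")
print(f"{'group':>6} {'n':>6} {'cases':>6} {'OR/SD':>16} {'HR/SD':>7} {'AUC':>7}")
for anc in ("EUR", "SAS", "AFR", "EAS"):
    sub = frame.subset((frame.data["ancestry"] == anc).to_numpy())
    o = or_per_sd(sub, "CAD", min_cases=100)
    if o.suppressed:
        print(f"{anc:>6} {o.n_total:>6} {o.n_cases:>6}   gated: {o.gate_reason}")
        continue
    h = hr_per_sd(sub, "CAD")
    a = auc(sub, "CAD")
    print(
        f"{anc:>6} {o.n_total:>6} {o.n_cases:>6} "
        f"{o.estimate:>6.2f} ({o.ci_low:.2f}-{o.ci_high:.2f}) "
        f"{h.estimate:>7.2f} {a.estimate:>7.3f}"
    )

print(
    "\nThe generator attenuates the true per-SD effect outside the EUR group"
    " (0.9x SAS, 0.85x EAS, 0.75x AFR), emulating reduced cross-ancestry"
    " transferability; groups with fewer than 100 cases are gated."
)
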