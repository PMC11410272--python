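"""Multi-PRS all-cause-mortality model and the 2:1 parent-offspring rule.

Forward-stepwise Cox selection over candidate scores on participants' own
survival and on their parents' lifespans; a score carried to a parent at
correlation 0.5 should show about half its own-mortality log-HR in the
parental model.
"""

from prsbench import (
    SimulationConfig,
    harrells_c_difference,
    parent_offspring_ratio,
    royston_r2,
    simulate_cohort,
    stepwise_mortality,
)
from prsbench.multivariate import _mortality_frame
from prsbench.simulate import MortalitySpec, QuantSpec

cfg = SimulationConfig(
    seed=5,
    n_per_ancestry={"EUR": 50000},
    diseases={},
    quants={f"score_{i}": QuantSpec(name=f"score_{i}", beta_per_sd=0.0) for i in range(4)},
    score_correlation={},
    mortality=MortalitySpec(log_hr_per_sd={"score_0": 0.2}),
    followup_years=(12.0, 16.0),
)
sim = simulate_cohort(cfg)

own = stepwise_mortality(sim.cohort, sim.scores, target="own")
par = stepwise_mortality(sim.cohort, sim.scores, target="parental")
print("selected (own):     ", own.selected)
print("selected (parental):", par.selected)
for name in own.selected:
    lo, hi = own.ci[name]
    print(f"  own log-HR per SD of {name}: {own.log_hr[name]:.3f} ({lo:.3f}-{hi:.3f})")
if "score_0" in own.log_hr and "score_0" in par.log_hr:
    r = parent_offspring_ratio(own, par, "score_0")
    print(f"own:parental log-HR ratio: {r['ratio']:.2f} "
          f"(95% CI {r['ci_low']:.2f}-{r['ci_high']:.2f}; polygenic expectation 2)")

frame, dur, ev, baseline = _mortality_frame(sim.cohort, sim.scores, "own")
if own.fit is not None:
    pi = own.fit.linear_predictor(frame[own.baseline_covariates + own.selected].to_numpy())
    from prsbench._cox import coxph_fit

    reduced = coxph_fit(frame[baseline].to_numpy(), dur, ev, names=baseline)
    pi_red = reduced.linear_predictor(frame[baseline].to_numpy())
    res = harrells_c_difference(pi, pi_red, dur, ev, n_bootstrap=200, seed=5)
    print(f"Harrell's C: full {res['c_full']:.4f}, baseline-only {res['c_reduced']:.4f}, "
          f"change {res['delta']:+.4f} (95% CI {res['ci_low']:+.4f} to {res['ci_high']:+.4f})")
    # PRS-only explained variation
    pi_prs = frame[own.selected].to_numpy() @ [own.log_hr[s] for s in own.selected]
    print(f"Royston R2_D of the PRS-only index: {royston_r2(pi_prs, dur, ev):.4f}")
print(
    "\nThe selected-score set should contain exactly the truly associated"
    " score; the small C change and R2_D illustrate that a significant"
    " mortality PRS still explains little individual-level variation."
)
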