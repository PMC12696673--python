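"""Full synthetic study: cohort simulation through group statistics.

Simulates 12 control-like and 9 aphasia-like subjects (raised detection
threshold) through both paradigms, extracts hold-phase responses, and runs
the group × paradigm mixed model with Sidak-corrected post-hoc contrasts.
"""

import aafadapt as aaf

shift = aaf.DEFAULT_SHIFT
sched = aaf.make_schedule("gradual")  # hold-trial index set, shared

trials = aaf.simulate_cohort(
    [aaf.default_nt_spec(shift), aaf.default_pwa_spec(shift)],
    [12, 9], seed=7, shift=shift,
)
resp = aaf.baseline_correct(trials)
hold = aaf.hold_average(resp, sched)

print("Cell means of the subject-level hold-phase F1 adaptive response:")
cells = aaf.cell_summaries(hold)
f1a = cells.query("formant == 'F1' and measure == 'adaptive'")
for _, r in f1a.iterrows():
    print(f"  {r['group']:3s} {r['paradigm']:8s}: {r['mean']:+8.2f} ({r['sd']:.2f}) Hz, "
          f"n={r['n']}")

trial_hold = resp[resp["trial"].isin(sched.analysis_hold_trials)]
model = aaf.fit_interaction_model(trial_hold, "adaptive_f1")
inter = model.terms["group:paradigm"]
print(f"\ngroup × paradigm interaction: t={inter['stat']:.2f}, p={inter['p']:.2g}")

print("\nSidak-corrected post-hoc contrasts (F1 adaptive):")
for c in aaf.posthoc_contrasts(model):
    flag = "*" if c.p_adj < 0.05 else " "
    print(f"  {c.label:22s} est {c.estimate:+8.2f} Hz  t={c.t:+6.2f}  "
          f"p_adj={c.p_adj:.3g} {flag}")

print("\nOnly the aphasia-like group differs between paradigms: a raised")
print("detection threshold lets the sudden step, but not the slow ramp,")
print("trigger adaptation.")
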