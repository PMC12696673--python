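"""Build a participant-specific perturbation from pre-test vowels.

Averages simulated pre-test productions into vowel centroids, derives the
/ε/→/æ/ shift vector, and prints the per-trial perturbation the gradual
and sudden schedules would apply.
"""

import aafadapt as aaf

params = aaf.SpeakerParams("demo", "NT", sigma_trial=10.0)
pretest = aaf.simulate_pretest(params, n_reps=25, seed=7)

c_eh = aaf.compute_centroid(pretest["eh"], "eh")
c_ae = aaf.compute_centroid(pretest["ae"], "ae")
shift = aaf.compute_shift_vector(c_eh, c_ae)
print(f"/ε/ centroid: F1={c_eh.f1:.1f} Hz, F2={c_eh.f2:.1f} Hz")
print(f"/æ/ centroid: F1={c_ae.f1:.1f} Hz, F2={c_ae.f2:.1f} Hz")
print(f"full shift:   ΔF1={shift.df1:+.1f} Hz, ΔF2={shift.df2:+.1f} Hz "
      f"(‖Δ‖={shift.norm:.1f} Hz)")

# the shift is applied fractionally per trial: zero during baseline,
# ramped (gradual) or stepped (sudden) to full magnitude, zero again
# during the after-effect block
for paradigm in ("gradual", "sudden"):
    sched = aaf.make_schedule(paradigm)
    print(f"\n{paradigm} schedule (trial: applied ΔF1, ΔF2):")
    for trial in (15, 31, 45, 60, 75, 100):
        df1, df2 = aaf.perturbation_at(sched, shift, trial)
        print(f"  trial {trial:3d} [{sched.phase_at(trial):>12s}]: "
              f"{df1:+7.1f} Hz, {df2:+7.1f} Hz")
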