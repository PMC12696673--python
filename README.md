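# aafadapt

Analysis toolkit for **altered auditory feedback (AAF) formant-adaptation
experiments**, built for studies of sensorimotor speech control in stroke
aphasia and neurotypical talkers.

In an AAF adaptation run a talker repeats /ε/ words ("hep", "head",
"heck") for 120 trials while the F1/F2 formants of the speech they hear
are shifted toward /æ/ (F1 up, F2 down), either **gradually** (30 baseline
trials, 30-trial linear ramp, 30-trial hold at full shift, 30 after-effect
trials) or **suddenly** (full shift from trial 31 through 90). Two
responses are measured per trial and referenced to each talker's own
baseline:

- **adaptive response** — the early-window (0–100 ms) formant value,
  reflecting trial-to-trial *feedforward* updating;
- **corrective response** — late window (200–300 ms) minus early window,
  reflecting within-trial *feedback* correction.

The package provides, as a plain Python library:

- `schedules` — participant-specific vowel centroids, the /ε/→/æ/ shift
  vector Δ = (ΔF1, ΔF2), and the gradual/sudden perturbation schedules;
- `simulate` — a generative state-space talker model with a detection
  threshold, for synthetic cohorts:
  `x_{t+1} = ρ·x_t − λ·ẽ_t`, `early_t = base + x_t + ε_t`,
  `late_t = early_t − g·ẽ_t + η_t`, where the auditory error `e_t` is acted
  on (`ẽ_t = e_t`) only after its trial-to-trial change has once exceeded
  the detection threshold θ;
- `responses` — window means, per-word baseline correction, hold-phase
  averaging and trial binning;
- `single_case` — the Crawford–Howell single-case comparison
  `t = (x − m̄)/(s·√((n+1)/n))`, df = n−1, with impairment classification;
- `group_stats` — group × paradigm mixed models on hold-phase trials,
  Sidak-corrected post-hoc contrasts, and Pearson correlations;
- `datasets` — packaged per-subject hold-phase tables from a published
  9-aphasia / 12-control study and a one-command audit that recomputes
  every derived statistic from them.

## Worked example

Simulating one talker with intact error detection (θ = 0) and one whose
detection threshold is raised to 0.6·‖Δ‖ (`examples/02_simulate_speaker.py`):

```
intact detection (θ=0):
  gradual : hold-phase F1 adaptive  -118.8 Hz, corrective  -10.9 Hz
  sudden  : hold-phase F1 adaptive  -120.4 Hz, corrective  -10.5 Hz

raised threshold (θ=0.6·‖Δ‖):
  gradual : hold-phase F1 adaptive    -2.1 Hz, corrective   -1.6 Hz
  sudden  : hold-phase F1 adaptive  -122.4 Hz, corrective  -10.4 Hz
```

The F1 perturbation is upward, so a negative adaptive response means the
talker is opposing it. The intact talker compensates regardless of how the
shift is introduced. The raised-threshold talker never registers the
slowly ramped error (≈ 6 Hz per trial), so the gradual run shows
essentially no adaptation — but the sudden 180 Hz step crosses the
threshold at onset and adaptation then proceeds normally. This is the
candidate mechanism for why people with aphasia can adapt better under
sudden than gradual perturbation schedules.

Scoring one stroke subject's gradual-paradigm response against the control
sample (`examples/04_single_case.py`):

```
SS9      corrective   -63.88  -2.70  0.010   yes
```

i.e. a corrective response of −63.88 Hz gives t(11) = −2.70 against the
control sample (n = 12, mean −1.92, SD 22.03); the probability that such a
score comes from the control population is 0.010, so this case is flagged
as impaired (abnormally large corrective response).

The other example scripts build schedules from simulated pre-test vowels,
run a full synthetic cohort through the group statistics, and audit the
packaged study tables (`python examples/05_reproduce_tables.py` prints
`total mismatches: 0`).

## Command line

A thin CLI mirrors the library for shell pipelines:

```sh
aafadapt simulate --seed 1 --n-nt 12 --n-pwa 9 --out trials.csv
aafadapt extract trials.csv --out responses.csv --hold-out hold.csv
aafadapt group-stats responses.csv --out stats.json
aafadapt deficit cases.csv controls.csv --out deficits.json
aafadapt reproduce-paper
```

See `docs/methods.md` for the model, its assumptions, parameter defaults
and known limitations.
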