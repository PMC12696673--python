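# Methods

## The experimental design being modelled

A formant-perturbation adaptation run has 120 trials of a single /ε/ word
family ("hep", "head", "heck", 40 occurrences each in a seeded balanced
order). Trials 1–30 are unperturbed baseline; trials 91–120 are
unperturbed after-effect trials. Between them the talker's auditory
feedback is shifted by a participant-specific vector
Δ = centroid(/æ/) − centroid(/ε/) with ΔF1 > 0 and ΔF2 < 0, scaled per
trial by the schedule fraction: the **gradual** schedule ramps linearly,
fraction (t−30)/30 over trials 31–60, then holds at 1.0 over 61–90; the
**sudden** schedule applies fraction 1.0 throughout trials 31–90. Trial
indexing is 1-based. The ramp is taken as strictly linear per trial; the
alternative (small discrete steps) is indistinguishable at the resolution
of any analysis here.

Both paradigms are analysed over the same positional window, trials 61–90
("the hold phase"), so each contributes 30 trials at full perturbation to
every statistic. Centroids come from 25 pre-test repetitions per vowel;
the shift-vector constructor rejects pre-tests whose /ε/ and /æ/ centroids
are inverted or coincident, since no valid perturbation direction exists.

Responses are computed per trial from two analysis windows of the vowel:
early (0–100 ms after vowel onset) and late (200–300 ms). Productions
shorter than 300 ms are rejected as production errors and simply drop out
of all means; there is no imputation. The adaptive response is the
early-window value minus the mean early-window value of the baseline
trials of the same (subject, paradigm, word) cell; correcting within word
absorbs coarticulation with the word-final consonant, and words are then
pooled with equal weight per trial for the hold average. The corrective
response is (late − early) minus the same cell's baseline mean of
(late − early). Baseline-phase responses therefore average exactly zero
within every cell by construction. Response values are in Hz throughout.

## Generative talker model

The simulator is a first-order linear state-space model of the
feedforward/feedback control loop, with one addition — an error-detection
gate. Per trial t, with feedforward state x₁ = 0 (an (F1, F2) vector):

    early_t  = base_word + x_t + ε_t          ε_t ~ N(0, σ_trial² I)
    heard_t  = early_t + P_t                  P_t = fraction_t · Δ
    e_t      = heard_t − base_word
    d_t      = d_{t−1}  or  ‖e_t − e_{t−1}‖ ≥ θ      (e_0 = 0, d_0 = false)
    ẽ_t      = e_t if d_t else 0
    late_t   = early_t − g·ẽ_t + η_t          η_t ~ N(0, σ_within² I)
    x_{t+1}  = ρ·x_t − λ·ẽ_t

The auditory error is referenced to the talker's own baseline target
(not the shifted target), the prediction-error convention of
feedforward/feedback models of speech production. The gate applies to
both the within-trial correction and the between-trial update: detection
is upstream of both subsystems.

**Why the gate is a latch on the error's change, not its level.** The
hypothesis the simulator embodies is that an impairment can raise the
minimum error needed for the speech system to *notice* it is erring: a
sudden full-magnitude shift is noticed at once, a slow ramp never is. A
gate on the error's instantaneous level cannot express this — under a
gradual schedule the baseline-referenced error still grows to full
magnitude once the ramp completes, so a level gate opens in both paradigms
and both hold phases settle on the same gated limit cycle, erasing any
paradigm difference (we verified this numerically: hold-phase adaptive
means differed by under 1 Hz between paradigms). Detection is therefore
modelled as a latch on the trial-to-trial change of the error: the ~6 Hz
per-trial increments of a ramp never reach a threshold of tens of Hz,
while a sudden step does, and once the error has been detected it is
processed normally for the rest of the run. With θ = 0 the latch engages
on the first trial and the model is the ordinary ungated state-space
learner; in particular, for a sudden schedule with ρ = 1, g = 0 and no
noise the state follows the closed form
x_t = −Δ·(1 − (1−λ)^(t−31)) for t ≥ 31, which the tests check to 1e−9.

### Parameters, defaults, and why

| parameter | meaning | default | rationale |
|---|---|---|---|
| base (F1, F2) | /ε/ target for "head", Hz | (550, 1900) | typical adult /ε/; "hep"/"heck" offset by ∓10 Hz (F1) and ±10 Hz (F2) to mimic coda coarticulation |
| Δ | full shift, Hz | (+150, −100) | a realistic /ε/→/æ/ displacement, ‖Δ‖ ≈ 180 Hz |
| λ | feedforward learning rate | 0.2 | adapts with a ~4-trial time constant; hold-phase responses land at the tens-of-Hz scale observed on this task |
| ρ | retention | 0.95 | slow forgetting; steady-state compensation λ/(1−ρ+λ) = 80 % of the shift |
| g | feedback gain | 0.3 | within-trial correction of ~30 % of the perceived error |
| θ | detection threshold, Hz | 0 (control-like), 0.6·‖Δ‖ (aphasia-like) | 0 = intact detection; 0.6·‖Δ‖ is far above any ramp increment and below the sudden step |
| σ_trial | between-trial production noise SD, Hz | 15 | typical token-to-token formant variability |
| σ_within | extra late-window noise SD, Hz | 8 | measurement/articulatory noise on the within-trial change |

Cohort simulation draws per-subject parameters once each from Gaussians
clipped to the valid range: λ ~ N(0.2, 0.1), ρ ~ N(0.95, 0.02),
g ~ N(0.3, 0.1), baseline F1/F2 ~ N(550, 20)/N(1900, 40). The spreads
were set so the *between-subject* SD of the hold-phase adaptive response
(~20 Hz) matches the 23–35 Hz SDs real control cohorts show on this task;
with materially tighter spreads a simulated cohort is unrealistically
homogeneous and even the ~2 Hz systematic hold-entry transient (a
first-order learner necessarily enters the hold slightly less adapted
after a ramp that ends at hold onset) becomes statistically detectable.
Default cohort sizes are 12 control-like and 9 aphasia-like subjects, each
completing both paradigms with administration order counterbalanced across
subjects. The aphasia-like default raises θ only; lowered feedback gain
and inflated sensory noise are equally plausible impairment loci and are
exposed as parameters, but the threshold account is the one that produces
a paradigm-dependent deficit, which is what the group analysis is built to
detect.

All randomness flows from a single integer seed; identical seeds give
identical trial tables.

### What the simulator does and does not emulate

It emulates the features the analysis pipeline consumes: per-trial
early/late window formant pairs, word-specific baselines, trial-to-trial
adaptive drift, within-trial corrective shifts, production noise, and the
group-level structure (two cohorts × two counterbalanced paradigms). It
does not synthesise waveforms or formant trajectories with consonant
transitions, does not model the pre/post sentence-reading washout, session
fatigue, token exclusions, or auditory acuity differences. Passing tests
on simulated cohorts therefore validate the *pipeline and statistics*
under a known generative mechanism — they are evidence about the method,
not about real talkers.

## Statistics

**Single-case comparison.** A case score x against a control sample
(n, m̄, s) uses t = (x − m̄)/(s·√((n+1)/n)) on n−1 df, which treats the
controls as a sample rather than a population. The reported p is the
Student-t tail beyond t in the observed direction — the point estimate of
the proportion of the control population scoring more extremely than the
case, and numerically identical to the point abnormality estimate of the
Bayesian formulation. Impairment is flagged in either direction at
p < 0.05, matching how published deficit tables bold both abnormally
large and abnormally small responses; note that flagging both directions
at the one-tailed 0.05 level carries a 10 % familywise false-flag rate by
construction, while the directional deficit test is calibrated at exactly
5 % (the Monte-Carlo calibration test measures the latter). Reported
probabilities are floored at 0.001, the printing convention of the
single-case programs in common use. The interval/credible-limit machinery
and the two-task dissociation test (which needs the controls'
between-task correlation) are not implemented.

**Group model.** One linear mixed model per formant × measure (four in
all) on trial-level hold-phase responses: fixed effects group, paradigm
and their interaction, random intercept per subject, fitted by REML
(statsmodels MixedLM) in a cell-means parameterisation. Main effects and
the interaction are 1-df Wald contrasts of the four cell means; the four
pairwise contrasts of interest (PWA gradual−NT gradual, PWA gradual−PWA
sudden, NT gradual−NT sudden, PWA sudden−NT sudden) are Sidak-corrected
over the family of four, p_adj = 1 − (1−p)⁴ (computed via expm1/log1p to
avoid underflow). Denominator df use the residual approximation
(trials − 4). For within-subject contrasts this is close to what a
finite-sample correction would give; for *between-group* contrasts it is
anti-conservative — with ~21 subjects the effective df is on the order of
the subject count, not the trial count — so between-group p-values should
be read qualitatively. Exact finite-sample df corrections were left out
deliberately: the group-level assertions made here are property-based
(type-I rate, power against the built-in mechanism), not numerical
reproductions. If the optimizer's Hessian is singular because the
random-intercept variance is pinned at zero, the fit falls back to OLS,
which is the same model at that boundary. A constant (e.g. all-zero)
response skips fitting entirely and reports zero effects.

**Correlations.** Pearson r between per-subject adaptive and corrective
hold means within group × paradigm, two-sided p from the t transform on
n−2 df (scipy).

## Packaged study tables and the audit

`aafadapt/data/` ships a transcription of a published 9-case/12-control
AAF study's per-subject hold-phase responses (both formants and
paradigms), the control-group summary rows, and the published derived
statistics (36 single-case t/p pairs, four correlations, the
gradual-paradigm impairment counts). `reproduce_paper()` recomputes every
derived number from the per-subject values and compares at printed
precision: t and r within ±0.005 (i.e. exact at two decimals), p within
±0.0015 (one unit in the third decimal — the published table contains
three p-values affected by its own rounding/flooring conventions, e.g. a
p of 2×10⁻⁵ printed as 0.001). The recomputed aphasia-group mean (SD)
rows also serve as an internal-consistency tripwire for the transcription
itself: a single corrupted cell breaks them.

## Numerical and testing choices

- Simulations in the test suite are sized to their purpose: 20-seed
  batches for calibration-style properties, 100,000 replicates for the
  single-case false-flag rate (SE ≈ 0.0007 at the 0.05 target), single
  seeds for mechanism demonstrations.
- Learning-rate recovery uses the applied perturbation as an instrument
  rather than ordinary least squares, because the production noise enters
  both the reconstructed state and the error and would otherwise attenuate
  the estimate.
- Window means use sample times relative to vowel onset, half-open
  windows [0, 100) and [200, 300) ms.
- Equality comparisons on published values happen after rounding to the
  printed precision, never on raw floats.

## Known limitations

- The simulator's aphasia-like deficit (complete non-adaptation under the
  gradual schedule) is sharper than real cohorts, where deficits are
  heterogeneous in kind and degree; it is a mechanism probe, not a
  calibrated patient model.
- Steady-state compensation of 80 % is at the high end for speech
  formant adaptation; the defaults prioritise a clean separation between
  adapted and non-adapted regimes over matching any particular cohort's
  compensation fraction.
- Between-group post-hoc contrasts inherit the residual-df approximation
  (see above).
- The word-cycling order and the ±10 Hz word offsets are conventions; the
  published task does not state its ordering.
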