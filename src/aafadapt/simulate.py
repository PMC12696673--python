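"""State-space simulator of formant productions under altered feedback.

Generates trial-level early/late-window formant values for synthetic
talkers, as a stand-in for recorded adaptation runs.  The generative model
is a first-order linear state-space with threshold gating on error
detection, the minimal mechanism consistent with a feedforward controller
(trial-to-trial adaptation) and a feedback controller (within-trial
correction):

with feedforward state ``x_1 = 0`` (an (F1, F2) vector, Hz), per trial t

    early_t  = baseline_word + x_t + ε_t,    ε_t ~ N(0, σ_trial²) I
    heard_t  = early_t + P_t                 (applied perturbation)
    e_t      = heard_t − baseline_word       (auditory prediction error)
    d_t      = d_{t−1} or ‖e_t − e_{t−1}‖₂ ≥ θ   (detection latch, e_0 = 0)
    ẽ_t      = e_t  if d_t  else 0           (gated error)
    late_t   = early_t − g·ẽ_t + η_t,        η_t ~ N(0, σ_within²) I
    x_{t+1}  = ρ·x_t − λ·ẽ_t

λ is the feedforward learning rate, ρ retention, g the within-trial
feedback gain, and θ an error-detection threshold in Hz (Euclidean norm in
F1×F2 space).  Detection is a latch on the trial-to-trial *change* of the
auditory error: errors are registered, and then acted on by both
subsystems, only once the error has at some point jumped by at least θ
within one trial.  θ = 0 keeps the gate permanently open (the usual
ungated state-space learner).  A raised θ models the hypothesised impaired
error detection in aphasia: a gradually ramped perturbation changes by a
few Hz per trial and never crosses the threshold, while a sudden
full-magnitude step does — after which errors are processed normally.

All randomness flows from a single integer seed; identical seeds give
identical trial tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .schedules import (
    PerturbationSchedule,
    ShiftVector,
    VowelCentroid,
    make_schedule,
    perturbation_at,
    word_sequence,
)

__all__ = [
    "SpeakerParams",
    "GroupSpec",
    "TRIAL_COLUMNS",
    "simulate_speaker",
    "simulate_pretest",
    "simulate_cohort",
    "default_nt_spec",
    "default_pwa_spec",
    "DEFAULT_SHIFT",
    "DEFAULT_VOWEL_TARGETS",
    "WORD_OFFSETS",
]

#: column order of a trial table (one row per production)
TRIAL_COLUMNS = [
    "subject_id",
    "group",
    "paradigm",
    "word",
    "trial",
    "phase",
    "early_f1",
    "early_f2",
    "late_f1",
    "late_f2",
]

#: default full-magnitude /ε/→/æ/ shift (Hz)
DEFAULT_SHIFT = ShiftVector(150.0, -100.0)

#: pre-test vowel targets (F1, F2) in Hz for an adult talker
DEFAULT_VOWEL_TARGETS = {
    "i": (300.0, 2300.0),
    "eh": (550.0, 1900.0),
    "ae": (700.0, 1800.0),
}

#: per-word offsets from the /ε/ target, mimicking coarticulation with the coda
WORD_OFFSETS = {
    "hep": (-10.0, 10.0),
    "head": (0.0, 0.0),
    "heck": (10.0, -10.0),
}


@dataclass(frozen=True)
class SpeakerParams:
    """Generative parameters of one simulated talker.

    ``baseline_f1``/``baseline_f2`` are the "head" targets; per-word
    offsets from :data:`WORD_OFFSETS` are added on top.  ``theta`` is the
    error-detection threshold in Hz; ``theta = 0`` detects every error.
    """

    subject_id: str
    group: str
    baseline_f1: float = 550.0
    baseline_f2: float = 1900.0
    lam: float = 0.2
    rho: float = 0.95
    g: float = 0.3
    theta: float = 0.0
    sigma_trial: float = 15.0
    sigma_within: float = 8.0

    def __post_init__(self) -> None:
        vals = (
            self.baseline_f1, self.baseline_f2, self.lam, self.rho,
            self.g, self.theta, self.sigma_trial, self.sigma_within,
        )
        if not all(np.isfinite(v) for v in vals):
            raise ValueError("speaker parameters must be finite")
        for name in ("lam", "rho", "g"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.theta < 0 or self.sigma_trial < 0 or self.sigma_within < 0:
            raise ValueError("theta and noise SDs must be nonnegative")


def simulate_speaker(
    params: SpeakerParams,
    schedule: PerturbationSchedule,
    shift: ShiftVector,
    seed: int,
) -> pd.DataFrame:
    """Simulate one 120-trial adaptation run for one talker.

    Returns a trial table (:data:`TRIAL_COLUMNS`) in trial order,
    deterministic given ``seed``.
    """
    rng = np.random.default_rng(seed)
    n = schedule.n_trials
    words = word_sequence(n, seed=seed)

    eps = rng.normal(0.0, params.sigma_trial, size=(n, 2))
    eta = rng.normal(0.0, params.sigma_within, size=(n, 2))

    x = np.zeros(2)
    prev_err = np.zeros(2)
    detected = False
    rows = []
    for t in range(1, n + 1):
        word = words[t - 1]
        off = WORD_OFFSETS[word]
        base = np.array([params.baseline_f1 + off[0], params.baseline_f2 + off[1]])
        early = base + x + eps[t - 1]
        pert = np.asarray(perturbation_at(schedule, shift, t))
        err = (early + pert) - base
        if np.linalg.norm(err - prev_err) >= params.theta:
            detected = True
        prev_err = err
        gated = err if detected else np.zeros(2)
        late = early - params.g * gated + eta[t - 1]
        rows.append(
            (
                params.subject_id, params.group, schedule.paradigm, word, t,
                schedule.phase_at(t),
                early[0], early[1], late[0], late[1],
            )
        )
        x = params.rho * x - params.lam * gated
    return pd.DataFrame(rows, columns=TRIAL_COLUMNS)


def simulate_pretest(
    params: SpeakerParams,
    n_reps: int = 25,
    seed: int = 0,
    vowel_targets: dict | None = None,
) -> dict:
    """Simulate the pre-test block: ``n_reps`` productions per vowel.

    Returns ``{vowel: [(f1, f2), ...]}`` with Gaussian production noise
    (``sigma_trial``) around each vowel target, suitable for
    :func:`~aafadapt.schedules.compute_centroid`.
    """
    if n_reps < 1:
        raise ValueError("need at least one pre-test repetition per vowel")
    targets = DEFAULT_VOWEL_TARGETS if vowel_targets is None else vowel_targets
    rng = np.random.default_rng(seed)
    out = {}
    for vowel, (f1, f2) in targets.items():
        noise = rng.normal(0.0, params.sigma_trial, size=(n_reps, 2))
        out[vowel] = [(f1 + a, f2 + b) for a, b in noise]
    return out


def recover_learning_rate(
    trials: pd.DataFrame,
    params: SpeakerParams,
    schedule: PerturbationSchedule,
    shift: ShiftVector,
) -> float:
    """Estimate the feedforward learning rate λ from one simulated run.

    Reconstructs the state as x̂_t = early_t − baseline_word and the
    auditory error as e_t = x̂_t + P_t, then solves the state update
    x̂_{t+1} − ρ·x̂_t = −λ·e_t for λ.  The perturbation P_t is used as the
    instrument, which removes the attenuation the production noise (shared
    between x̂_t and e_t) would otherwise cause; with zero noise the
    estimate is exact.  Assumes the detection gate was open (θ = 0 runs).
    """
    df = trials.sort_values("trial")
    offs = np.array([WORD_OFFSETS[w] for w in df["word"]])
    base = np.column_stack(
        [params.baseline_f1 + offs[:, 0], params.baseline_f2 + offs[:, 1]]
    )
    x_hat = df[["early_f1", "early_f2"]].to_numpy() - base
    pert = np.array(
        [perturbation_at(schedule, shift, int(t)) for t in df["trial"]]
    )
    err = x_hat + pert
    upd = x_hat[1:] - params.rho * x_hat[:-1]
    e, p, u = err[:-1].ravel(), pert[:-1].ravel(), upd.ravel()
    denom = p @ e
    if denom == 0:
        raise ValueError("no perturbed trials to identify the learning rate")
    return float(-(p @ u) / denom)


@dataclass(frozen=True)
class GroupSpec:
    """Distributional spec for drawing per-subject parameters of one group.

    ``dists`` maps a :class:`SpeakerParams` field to ``(mean, sd)``; a
    parameter absent from the map is fixed at the SpeakerParams default.
    Draws are Gaussian, clipped to each parameter's valid range, so an SD
    of 0 gives a degenerate (fixed) value.
    """

    group: str
    dists: dict = field(default_factory=dict)

    _BOUNDS = {
        "lam": (0.0, 1.0),
        "rho": (0.0, 1.0),
        "g": (0.0, 1.0),
        "theta": (0.0, np.inf),
        "sigma_trial": (0.0, np.inf),
        "sigma_within": (0.0, np.inf),
        "baseline_f1": (1.0, np.inf),
        "baseline_f2": (1.0, np.inf),
    }

    def draw(self, subject_id: str, rng: np.random.Generator) -> SpeakerParams:
        kwargs = {"subject_id": subject_id, "group": self.group}
        for name, (mean, sd) in self.dists.items():
            if name not in self._BOUNDS:
                raise ValueError(f"unknown speaker parameter {name!r}")
            lo, hi = self._BOUNDS[name]
            kwargs[name] = float(np.clip(rng.normal(mean, sd), lo, hi))
        return SpeakerParams(**kwargs)


#: between-subject spreads of the learning parameters; together with the
#: trial noise these put the subject-level hold-phase SD in the ~20 Hz
#: range reported for neurotypical cohorts on this task
_SUBJECT_DISTS = {
    "baseline_f1": (550.0, 20.0),
    "baseline_f2": (1900.0, 40.0),
    "lam": (0.2, 0.1),
    "rho": (0.95, 0.02),
    "g": (0.3, 0.1),
}


def default_nt_spec(shift: ShiftVector = DEFAULT_SHIFT) -> GroupSpec:
    """Neurotypical-like group: intact error detection (theta = 0)."""
    return GroupSpec(
        group="NT",
        dists={**_SUBJECT_DISTS, "theta": (0.0, 0.0)},
    )


def default_pwa_spec(shift: ShiftVector = DEFAULT_SHIFT) -> GroupSpec:
    """Aphasia-like group: raised error-detection threshold.

    theta = 0.6·‖shift‖ is far above the per-trial error change a gradual
    ramp produces (a few Hz, plus production noise) but below the sudden
    full-magnitude step, so the gradually introduced perturbation goes
    undetected while the sudden one crosses the threshold at onset.
    """
    return GroupSpec(
        group="PWA",
        dists={**_SUBJECT_DISTS, "theta": (0.6 * shift.norm, 0.0)},
    )


def simulate_cohort(
    group_specs,
    n_per_group,
    seed: int,
    shift: ShiftVector = DEFAULT_SHIFT,
    schedules=None,
) -> pd.DataFrame:
    """Simulate a full study: every subject runs both paradigms.

    Parameters
    ----------
    group_specs : sequence of GroupSpec
    n_per_group : int or sequence of int
        Subjects per group (the study design uses 12 NT and 9 PWA).
    seed : int
        Master seed; subject parameters and all trial noise derive from it.
    schedules : optional pair of PerturbationSchedule
        Defaults to the standard gradual and sudden schedules.  Paradigm
        administration order is counterbalanced across subjects within
        each group.

    Returns the concatenated trial table with one row per production.
    """
    if schedules is None:
        schedules = (make_schedule("gradual"), make_schedule("sudden"))
    if np.isscalar(n_per_group):
        n_per_group = [int(n_per_group)] * len(group_specs)
    if len(n_per_group) != len(group_specs):
        raise ValueError("n_per_group must match the number of group specs")
    if any(n < 1 for n in n_per_group):
        raise ValueError("need at least one subject per group")

    master = np.random.default_rng(seed)
    tables = []
    for spec, n_subj in zip(group_specs, n_per_group):
        for i in range(n_subj):
            sid = f"{spec.group}{i + 1:02d}"
            params = spec.draw(sid, master)
            order = schedules if i % 2 == 0 else schedules[::-1]
            for sched in order:
                run_seed = int(master.integers(0, 2**31 - 1))
                tables.append(simulate_speaker(params, sched, shift, run_seed))
    return pd.concat(tables, ignore_index=True)
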