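"""Perturbation schedules for formant-shift adaptation paradigms.

An adaptation run has 120 trials: 30 unperturbed baseline trials, a
perturbation block, and 30 unperturbed after-effect trials.  In the
*gradual* paradigm the perturbation ramps linearly over 30 trials and is
then held at maximum for 30 trials; in the *sudden* paradigm the full
perturbation is applied from trial 31 through trial 90.  The perturbation
itself is participant specific: the full-magnitude shift moves the talker's
/ε/ centroid toward their /æ/ centroid (F1 up, F2 down), scaled per trial
by the schedule fraction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "VowelCentroid",
    "ShiftVector",
    "PerturbationSchedule",
    "compute_centroid",
    "compute_shift_vector",
    "make_schedule",
    "perturbation_at",
    "word_sequence",
    "WORDS",
    "N_TRIALS",
]

#: target words carrying the /ε/ vowel, cycled across trials
WORDS = ("hep", "head", "heck")

N_TRIALS = 120
N_BASELINE = 30
N_RAMP = 30
N_HOLD = 30
N_AFTER = 30


@dataclass(frozen=True)
class VowelCentroid:
    """Mean (F1, F2) location of one vowel in formant space, in Hz."""

    vowel_label: str
    f1: float
    f2: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.f1) and np.isfinite(self.f2)):
            raise ValueError("centroid formants must be finite")
        if self.f1 <= 0:
            raise ValueError("F1 must be positive")
        if self.f2 <= self.f1:
            raise ValueError("F2 must exceed F1 for front vowels")


@dataclass(frozen=True)
class ShiftVector:
    """Full-magnitude formant perturbation (Hz): /ε/ pushed toward /æ/.

    ``df1`` must be positive and ``df2`` negative — the direction that makes
    "head" sound like "had".
    """

    df1: float
    df2: float

    def __post_init__(self) -> None:
        if self.df1 == 0 and self.df2 == 0:
            raise ValueError("degenerate zero-length shift vector")
        if self.df1 <= 0 or self.df2 >= 0:
            raise ValueError(
                "shift must increase F1 and decrease F2 (/ɛ/ toward /æ/); "
                f"got df1={self.df1}, df2={self.df2}"
            )

    @property
    def norm(self) -> float:
        """Euclidean magnitude of the shift in F1×F2 space (Hz)."""
        return float(np.hypot(self.df1, self.df2))


@dataclass(frozen=True)
class PerturbationSchedule:
    """Per-trial perturbation fraction and phase label for one paradigm.

    Attributes
    ----------
    paradigm : {"gradual", "sudden"}
    fractions : np.ndarray
        Length-120 array of values in [0, 1]; entry ``t-1`` applies to
        1-based trial ``t``.
    phases : tuple of str
        Phase label per trial: baseline / ramp / hold / after_effect for
        gradual, baseline / full / after_effect for sudden.
    analysis_hold_trials : tuple of int
        1-based indices of the 30 trials analysed as the hold phase
        (trials 61–90 in both paradigms).
    """

    paradigm: str
    fractions: np.ndarray
    phases: tuple
    analysis_hold_trials: tuple = field(
        default_factory=lambda: tuple(range(61, 91))
    )

    @property
    def n_trials(self) -> int:
        return len(self.fractions)

    def fraction_at(self, trial: int) -> float:
        """Perturbation fraction at a 1-based trial index."""
        if not 1 <= trial <= self.n_trials:
            raise IndexError(f"trial {trial} outside 1..{self.n_trials}")
        return float(self.fractions[trial - 1])

    def phase_at(self, trial: int) -> str:
        if not 1 <= trial <= self.n_trials:
            raise IndexError(f"trial {trial} outside 1..{self.n_trials}")
        return self.phases[trial - 1]

    def to_frame(self) -> pd.DataFrame:
        """Schedule as a tidy table with columns trial, phase, fraction."""
        return pd.DataFrame(
            {
                "trial": np.arange(1, self.n_trials + 1),
                "phase": list(self.phases),
                "fraction": self.fractions,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def compute_centroid(productions, vowel_label: str = "?") -> VowelCentroid:
    """Average a talker's pre-test productions of one vowel into a centroid.

    Parameters
    ----------
    productions : sequence of (f1, f2)
        Per-production average formant values in Hz, one pair per
        repetition of the vowel.
    vowel_label : str
        Label attached to the returned centroid.
    """
    arr = np.asarray(productions, dtype=float)
    if arr.size == 0:
        raise ValueError(
            f"no pre-test productions supplied for vowel {vowel_label!r}"
        )
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("productions must be (f1, f2) pairs")
    if not np.all(np.isfinite(arr)) or np.any(arr <= 0):
        raise ValueError("formant values must be finite and positive")
    f1, f2 = arr.mean(axis=0)
    return VowelCentroid(vowel_label, float(f1), float(f2))


def compute_shift_vector(c_eh: VowelCentroid, c_ae: VowelCentroid) -> ShiftVector:
    """Full-magnitude shift Δ = centroid(/æ/) − centroid(/ε/).

    Raises ``ValueError`` when the pre-test centroids are inconsistent with
    the /ε/→/æ/ direction (ΔF1 ≤ 0 or ΔF2 ≥ 0) or coincide.
    """
    df1 = c_ae.f1 - c_eh.f1
    df2 = c_ae.f2 - c_eh.f2
    return ShiftVector(df1, df2)


def make_schedule(
    paradigm: str,
    n_baseline: int = N_BASELINE,
    n_ramp: int = N_RAMP,
    n_hold: int = N_HOLD,
    n_after: int = N_AFTER,
) -> PerturbationSchedule:
    """Build the gradual or sudden perturbation schedule.

    Gradual: baseline (fraction 0), linear ramp reaching 1.0 on its last
    trial, hold at 1.0, after-effect at 0.  Sudden: the ramp and hold blocks
    are replaced by a single full-perturbation block at fraction 1.0.  The
    analysed hold phase is the 30 trials at positions 61–90 in both
    paradigms so the two contribute positionally identical windows.
    """
    if paradigm not in ("gradual", "sudden"):
        raise ValueError(f"unknown paradigm {paradigm!r}")

    baseline = np.zeros(n_baseline)
    after = np.zeros(n_after)
    if paradigm == "gradual":
        ramp = np.arange(1, n_ramp + 1) / n_ramp
        hold = np.ones(n_hold)
        fractions = np.concatenate([baseline, ramp, hold, after])
        phases = (
            ["baseline"] * n_baseline
            + ["ramp"] * n_ramp
            + ["hold"] * n_hold
            + ["after_effect"] * n_after
        )
    else:
        full = np.ones(n_ramp + n_hold)
        fractions = np.concatenate([baseline, full, after])
        phases = (
            ["baseline"] * n_baseline
            + ["full"] * (n_ramp + n_hold)
            + ["after_effect"] * n_after
        )
    hold_start = n_baseline + n_ramp + 1
    return PerturbationSchedule(
        paradigm=paradigm,
        fractions=fractions,
        phases=tuple(phases),
        analysis_hold_trials=tuple(range(hold_start, hold_start + n_hold)),
    )


def perturbation_at(
    schedule: PerturbationSchedule, shift: ShiftVector, trial: int
) -> tuple:
    """Applied (ΔF1, ΔF2) in Hz at a 1-based trial: fraction × full shift."""
    frac = schedule.fraction_at(trial)
    return (frac * shift.df1, frac * shift.df2)


def word_sequence(n_trials: int = N_TRIALS, seed: int = 0) -> list:
    """Balanced pseudo-random ordering of the /hVp/-family target words.

    Each of "hep", "head", "heck" appears exactly ``n_trials / 3`` times;
    the order is a seeded permutation so runs are reproducible.
    """
    if n_trials % len(WORDS):
        raise ValueError("n_trials must be divisible by the number of words")
    reps = n_trials // len(WORDS)
    seq = np.repeat(WORDS, reps)
    rng = np.random.default_rng(seed)
    return list(rng.permutation(seq))
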