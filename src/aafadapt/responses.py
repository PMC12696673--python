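"""Decompose productions into adaptive and corrective responses.

The adaptive (feedforward) response of a trial is its early-window
(0–100 ms) formant value referenced to the talker's own baseline; the
corrective (feedback) response is the within-trial change, late window
(200–300 ms) minus early window, likewise referenced to baseline.  Group
statistics use the per-subject mean over the 30 analysed hold-phase
trials.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .schedules import PerturbationSchedule

__all__ = [
    "RESPONSE_COLUMNS",
    "TrialTooShortError",
    "window_means",
    "baseline_correct",
    "hold_average",
    "bin_series",
]

RESPONSE_COLUMNS = [
    "subject_id",
    "group",
    "paradigm",
    "word",
    "trial",
    "phase",
    "adaptive_f1",
    "adaptive_f2",
    "corrective_f1",
    "corrective_f2",
]

EARLY_WINDOW_MS = (0.0, 100.0)
LATE_WINDOW_MS = (200.0, 300.0)

#: grouping cell for baseline normalisation — per word, to account for
#: coarticulation with the word-final consonant
_CELL = ["subject_id", "paradigm", "word"]


class TrialTooShortError(ValueError):
    """Raised when a production does not span the late analysis window."""


def window_means(trajectory) -> tuple:
    """Early- and late-window formant means of one production.

    Parameters
    ----------
    trajectory : array-like of shape (n_samples, 3)
        Columns ``(t_ms, f1, f2)``, time monotone increasing.  The
        production must span at least 300 ms; shorter tokens are the kind
        excluded as production errors and raise :class:`TrialTooShortError`.

    Returns
    -------
    (early_f1, early_f2, late_f1, late_f2)
        Means over 0 ≤ t < 100 ms and 200 ≤ t < 300 ms respectively.
    """
    arr = np.asarray(trajectory, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 3:
        raise ValueError("trajectory must have columns (t_ms, f1, f2)")
    t = arr[:, 0]
    if np.any(np.diff(t) < 0):
        raise ValueError("trajectory samples must be monotone in time")
    if t[-1] - t[0] < LATE_WINDOW_MS[1]:
        raise TrialTooShortError(
            f"production spans {t[-1] - t[0]:.0f} ms < {LATE_WINDOW_MS[1]:.0f} ms"
        )
    t0 = t - t[0]
    early = (t0 >= EARLY_WINDOW_MS[0]) & (t0 < EARLY_WINDOW_MS[1])
    late = (t0 >= LATE_WINDOW_MS[0]) & (t0 < LATE_WINDOW_MS[1])
    if not early.any() or not late.any():
        raise TrialTooShortError("no samples in an analysis window")
    e = arr[early, 1:].mean(axis=0)
    l = arr[late, 1:].mean(axis=0)
    return (float(e[0]), float(e[1]), float(l[0]), float(l[1]))


def baseline_correct(trials: pd.DataFrame) -> pd.DataFrame:
    """Turn a trial table into baseline-corrected response records.

    For every (subject, paradigm, word) cell, the mean of the baseline-phase
    trials defines that cell's reference:

    * ``adaptive_fk``   = early_fk − baseline mean early_fk
    * ``corrective_fk`` = (late_fk − early_fk) − baseline mean (late_fk − early_fk)

    so baseline-phase adaptive and corrective responses average exactly 0
    within each cell.  Raises ``ValueError`` naming the first cell that has
    no baseline trials.
    """
    df = trials.copy()
    for fk in ("f1", "f2"):
        df[f"corr_raw_{fk}"] = df[f"late_{fk}"] - df[f"early_{fk}"]

    base = df[df["phase"] == "baseline"]
    have = set(map(tuple, base[_CELL].drop_duplicates().itertuples(index=False)))
    for cell in map(tuple, df[_CELL].drop_duplicates().itertuples(index=False)):
        if cell not in have:
            raise ValueError(
                "no baseline trials for cell "
                f"(subject={cell[0]!r}, paradigm={cell[1]!r}, word={cell[2]!r})"
            )

    ref = base.groupby(_CELL)[
        ["early_f1", "early_f2", "corr_raw_f1", "corr_raw_f2"]
    ].mean()
    merged = df.join(ref, on=_CELL, rsuffix="_ref")

    out = df[["subject_id", "group", "paradigm", "word", "trial", "phase"]].copy()
    for fk in ("f1", "f2"):
        out[f"adaptive_{fk}"] = merged[f"early_{fk}"] - merged[f"early_{fk}_ref"]
        out[f"corrective_{fk}"] = (
            merged[f"corr_raw_{fk}"] - merged[f"corr_raw_{fk}_ref"]
        )
    return out[RESPONSE_COLUMNS]


def hold_average(
    responses: pd.DataFrame, schedule: PerturbationSchedule
) -> pd.DataFrame:
    """Per-subject hold-phase means, the dependent variable of the study.

    Averages adaptive and corrective responses over the schedule's 30
    analysed hold trials (positions 61–90), pooling words with equal weight
    per trial.  Returns a long table with one row per
    subject × paradigm × formant and columns ``adaptive_mean`` /
    ``corrective_mean`` (Hz).
    """
    hold = responses[responses["trial"].isin(schedule.analysis_hold_trials)]
    if hold.empty:
        raise ValueError("no trials in the analysed hold phase")
    keys = ["subject_id", "group", "paradigm"]
    rows = []
    for name, sub in hold.groupby(keys, sort=True):
        for formant in ("F1", "F2"):
            fk = formant.lower()
            rows.append(
                (*name, formant,
                 sub[f"adaptive_{fk}"].mean(), sub[f"corrective_{fk}"].mean())
            )
    return pd.DataFrame(
        rows, columns=keys + ["formant", "adaptive_mean", "corrective_mean"]
    )


def bin_series(series, bin_size: int = 6) -> np.ndarray:
    """Average a per-trial series in consecutive non-overlapping bins.

    With the default bin of six trials a 120-trial run yields 20 points,
    the resolution used to plot adaptation time courses.
    """
    arr = np.asarray(series, dtype=float)
    if arr.ndim != 1:
        raise ValueError("series must be one-dimensional")
    if bin_size < 1 or arr.size % bin_size:
        raise ValueError(
            f"bin size {bin_size} does not divide series length {arr.size}"
        )
    return arr.reshape(-1, bin_size).mean(axis=1)
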