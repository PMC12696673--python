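"""Single-case deficit statistics against a small control sample.

Implements the Crawford–Howell comparison of one case score with a control
sample of size *n*, which treats the controls as a sample rather than a
population:

    t = (x − m̄) / (s·sqrt((n + 1)/n)),   df = n − 1

The reported p is the Student-t tail probability in the observed direction
— the point estimate of the proportion of the control population that
would score more extremely than the case, identical to the posterior
point estimate of the Bayesian formulation of the test.  A case is flagged
impaired (abnormal) in either direction when that one-tailed probability
falls below alpha.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "ControlSample",
    "DeficitResult",
    "deficit_test",
    "classify_impairments",
    "CATEGORIES",
]

CATEGORIES = ("adaptive only", "corrective only", "both", "none")


@dataclass(frozen=True)
class ControlSample:
    """Summary of the control group on one measure: size, mean, SD."""

    n: int
    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("control sample needs n >= 2")
        if not self.sd > 0:
            raise ValueError("control SD must be positive")


@dataclass(frozen=True)
class DeficitResult:
    """Outcome of a single-case comparison."""

    t: float
    df: int
    p: float
    impaired: bool


def deficit_test(
    case_score: float, controls: ControlSample, alpha: float = 0.05
) -> DeficitResult:
    """Test whether one case score is abnormal for the control population.

    Parameters
    ----------
    case_score : float
        The case's score on the measure (same units as the controls).
    controls : ControlSample
    alpha : float
        Abnormality criterion on the one-tailed probability.

    Returns
    -------
    DeficitResult
        ``t`` keeps the sign of (case − control mean); ``p`` is the
        tail probability beyond ``t`` in the observed direction, so a case
        equal to the control mean gives p = 0.5.
    """
    if not np.isfinite(case_score):
        raise ValueError("case score must be finite")
    n = controls.n
    t = (case_score - controls.mean) / (controls.sd * np.sqrt((n + 1) / n))
    p = float(stats.t.sf(abs(t), df=n - 1))
    return DeficitResult(t=float(t), df=n - 1, p=p, impaired=p < alpha)


def classify_impairments(
    case_scores, controls_by_measure: dict, alpha: float = 0.05
) -> dict:
    """Classify cases by which measures show a deficit.

    Parameters
    ----------
    case_scores : mapping case_id -> {measure: score}
        Exactly two measures per case, ``"adaptive"`` and ``"corrective"``.
    controls_by_measure : {measure: ControlSample}
    alpha : float

    Returns
    -------
    dict with ``counts`` ({category: int} over :data:`CATEGORIES`),
    ``assignments`` ({case_id: category}) and ``results``
    ({case_id: {measure: DeficitResult}}).
    """
    counts = {c: 0 for c in CATEGORIES}
    assignments = {}
    results = {}
    for case_id, scores in case_scores.items():
        if set(scores) != set(controls_by_measure):
            raise ValueError(
                f"case {case_id!r} measures {sorted(scores)} do not match "
                f"control measures {sorted(controls_by_measure)}"
            )
        res = {
            m: deficit_test(scores[m], controls_by_measure[m], alpha=alpha)
            for m in scores
        }
        a, c = res["adaptive"].impaired, res["corrective"].impaired
        category = (
            "both" if a and c
            else "adaptive only" if a
            else "corrective only" if c
            else "none"
        )
        counts[category] += 1
        assignments[case_id] = category
        results[case_id] = res
    return {"counts": counts, "assignments": assignments, "results": results}
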