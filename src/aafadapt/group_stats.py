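"""Group-level statistics: cell summaries, the group × paradigm mixed
model on hold-phase trials, Sidak-corrected post-hoc contrasts, and
adaptive-vs-corrective Pearson correlations.

One model is fitted per formant × measure (four in total), on trial-level
hold-phase responses with group and paradigm as crossed two-level fixed
factors and a random intercept per subject.  The model is parameterised by
its four cell means, from which main effects, the interaction, and the
pairwise cell contrasts are Wald tests on linear combinations.  Denominator
degrees of freedom use the residual approximation (trials minus fixed
parameters); with ~30 hold trials per subject and paradigm this is close
to the trial-level df a finite-sample correction would report for
within-subject terms.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ContrastResult",
    "CorrelationResult",
    "InteractionModelResult",
    "cell_summaries",
    "fit_interaction_model",
    "posthoc_contrasts",
    "sidak_adjust",
    "pearson",
    "CONTRAST_LABELS",
]

#: cell order used in the cell-means parameterisation
_CELLS = [("NT", "gradual"), ("NT", "sudden"), ("PWA", "gradual"), ("PWA", "sudden")]

#: the four post-hoc contrasts of interest, as (label, plus-cell, minus-cell)
CONTRAST_LABELS = [
    "PWAgradual-NTgradual",
    "PWAgradual-PWAsudden",
    "NTgradual-NTsudden",
    "PWAsudden-NTsudden",
]
_CONTRAST_CELLS = {
    "PWAgradual-NTgradual": (("PWA", "gradual"), ("NT", "gradual")),
    "PWAgradual-PWAsudden": (("PWA", "gradual"), ("PWA", "sudden")),
    "NTgradual-NTsudden": (("NT", "gradual"), ("NT", "sudden")),
    "PWAsudden-NTsudden": (("PWA", "sudden"), ("NT", "sudden")),
}


@dataclass(frozen=True)
class ContrastResult:
    label: str
    estimate: float
    t: float
    df: float
    p: float
    p_adj: float


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    p: float
    n: int


@dataclass(frozen=True)
class InteractionModelResult:
    """Fitted group × paradigm model on one response measure.

    ``cell_means`` maps (group, paradigm) to the estimated cell mean;
    ``terms`` maps "group" / "paradigm" / "group:paradigm" to a dict with
    keys estimate, stat, df, p.
    """

    cell_means: dict
    cov: np.ndarray
    df_resid: float
    terms: dict
    degenerate: bool = False

    def _wald(self, c: np.ndarray) -> tuple:
        beta = np.array([self.cell_means[cell] for cell in _CELLS])
        est = float(c @ beta)
        if self.degenerate:
            return est, 0.0, 1.0
        se = float(np.sqrt(c @ self.cov @ c))
        t = est / se if se > 0 else 0.0
        p = float(2 * stats.t.sf(abs(t), self.df_resid))
        return est, t, p


def cell_summaries(hold: pd.DataFrame) -> pd.DataFrame:
    """Per-cell mean and sample SD of subject-level hold averages.

    Input is the long hold-summary table (one row per subject × paradigm ×
    formant, columns ``adaptive_mean``/``corrective_mean``); output has one
    row per group × paradigm × formant × measure with ``mean``, ``sd``
    (n−1 denominator) and ``n`` subjects.
    """
    required = {"group", "paradigm", "formant", "adaptive_mean", "corrective_mean"}
    if missing := required - set(hold.columns):
        raise ValueError(f"hold summary missing columns {sorted(missing)}")
    rows = []
    for (grp, par, fmt), sub in hold.groupby(["group", "paradigm", "formant"]):
        for measure, col in (("adaptive", "adaptive_mean"),
                             ("corrective", "corrective_mean")):
            vals = sub[col].to_numpy(dtype=float)
            if vals.size == 0:
                raise ValueError(f"empty cell {(grp, par, fmt, measure)}")
            sd = float(np.std(vals, ddof=1)) if vals.size > 1 else np.nan
            rows.append((grp, par, measure, fmt, float(vals.mean()), sd, vals.size))
    return pd.DataFrame(
        rows, columns=["group", "paradigm", "measure", "formant", "mean", "sd", "n"]
    )


def fit_interaction_model(
    trial_responses: pd.DataFrame, response: str
) -> InteractionModelResult:
    """Fit the mixed model ``response ~ group * paradigm + (1 | subject)``.

    Parameters
    ----------
    trial_responses : DataFrame
        Trial-level hold-phase responses with columns ``subject_id``,
        ``group``, ``paradigm`` and the response column.
    response : str
        Name of the response column (e.g. ``"adaptive_f1"``).

    Returns an :class:`InteractionModelResult` whose ``terms`` hold Wald
    tests for the group and paradigm main effects and their interaction
    (each 1 df in this 2 × 2 design).
    """
    df = trial_responses.dropna(subset=[response]).copy()
    groups = sorted(df["group"].unique())
    paradigms = sorted(df["paradigm"].unique())
    if groups != ["NT", "PWA"] or paradigms != ["gradual", "sudden"]:
        raise ValueError(
            "design must contain both groups (NT, PWA) and both paradigms "
            f"(gradual, sudden); got groups={groups}, paradigms={paradigms}"
        )

    y = df[response].to_numpy(dtype=float)
    cell_idx = pd.Series(
        list(zip(df["group"], df["paradigm"])), index=df.index
    )
    X = np.column_stack([(cell_idx == cell).to_numpy(float) for cell in _CELLS])

    if np.allclose(y, y[0]):
        # Degenerate (constant) response: every effect is exactly its
        # arithmetic value, no stochastic model to fit.
        means = {cell: float(y[0]) for cell in _CELLS}
        result = InteractionModelResult(
            cell_means=means,
            cov=np.zeros((4, 4)),
            df_resid=float(len(y) - 4),
            terms={},
            degenerate=True,
        )
    else:
        import warnings

        from statsmodels.regression.mixed_linear_model import MixedLM

        model = MixedLM(y, X, groups=df["subject_id"].to_numpy())
        fit = None
        with warnings.catch_warnings():
            # boundary (zero) random-effect variance is legitimate for
            # homogeneous simulated cohorts; not an error
            warnings.simplefilter("ignore")
            for method in (None, "powell", "cg"):
                try:
                    cand = (model.fit(reml=True) if method is None
                            else model.fit(reml=True, method=method))
                except np.linalg.LinAlgError:
                    continue
                cov_diag = np.diag(np.asarray(cand.cov_params())[:4, :4])
                if np.all(np.isfinite(cov_diag)) and np.all(cov_diag < 1e12):
                    fit = cand
                    break
        if fit is not None:
            params = np.asarray(fit.fe_params)
            cov = np.asarray(fit.cov_params())[:4, :4]
        else:
            # random-intercept variance pinned at zero made the mixed-model
            # Hessian singular; the model degenerates to OLS on cell means
            import statsmodels.api as sm

            ols = sm.OLS(y, X).fit()
            params = np.asarray(ols.params)
            cov = np.asarray(ols.cov_params())
        result = InteractionModelResult(
            cell_means=dict(zip(_CELLS, params)),
            cov=cov,
            df_resid=float(len(y) - 4),
            terms={},
        )

    c_group = np.array([-0.5, -0.5, 0.5, 0.5])
    c_paradigm = np.array([0.5, -0.5, 0.5, -0.5])
    c_inter = np.array([-1.0, 1.0, 1.0, -1.0])
    terms = {}
    for name, c in (("group", c_group), ("paradigm", c_paradigm),
                    ("group:paradigm", c_inter)):
        est, t, p = result._wald(c)
        terms[name] = {"estimate": est, "stat": t, "df": result.df_resid, "p": p}
    return InteractionModelResult(
        cell_means=result.cell_means,
        cov=result.cov,
        df_resid=result.df_resid,
        terms=terms,
        degenerate=result.degenerate,
    )


def sidak_adjust(p: float, m: int = 4) -> float:
    """Sidak familywise correction: p_adj = 1 − (1 − p)^m."""
    if not 0 <= p <= 1:
        raise ValueError("p must be in [0, 1]")
    # -expm1(m*log1p(-p)) == 1-(1-p)^m without underflow for tiny p
    if p == 1.0:
        return 1.0
    return float(-np.expm1(m * np.log1p(-p)))


def posthoc_contrasts(model: InteractionModelResult) -> list:
    """The four pairwise cell contrasts, Sidak-adjusted over the family.

    Contrasts: PWA gradual − NT gradual, PWA gradual − PWA sudden,
    NT gradual − NT sudden, PWA sudden − NT sudden.
    """
    out = []
    for label in CONTRAST_LABELS:
        plus, minus = _CONTRAST_CELLS[label]
        c = np.array([
            (1.0 if cell == plus else 0.0) - (1.0 if cell == minus else 0.0)
            for cell in _CELLS
        ])
        est, t, p = model._wald(c)
        out.append(
            ContrastResult(
                label=label, estimate=est, t=t, df=model.df_resid,
                p=p, p_adj=sidak_adjust(p, m=len(CONTRAST_LABELS)),
            )
        )
    return out


def pearson(x, y) -> CorrelationResult:
    """Pearson correlation with a two-sided p from the t transform.

    Used for the per-subject adaptive-vs-corrective association within a
    group and paradigm.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be one-dimensional and equal length")
    if x.size < 3:
        raise ValueError("need at least 3 pairs")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in x or y")
    r, p = stats.pearsonr(x, y)
    return CorrelationResult(r=float(r), p=float(p), n=int(x.size))
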