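"""Packaged reference data and the one-command study reproduction.

Ships transcriptions of the published per-subject hold-phase responses
(nine stroke subjects, SS1–SS9, both formants and paradigms), the
neurotypical control-group summary rows, and the published single-case
statistics, correlations, and impairment-classification counts.
:func:`reproduce_paper` recomputes every derived number from the
per-subject values and audits it against the printed one.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import pandas as pd

from .group_stats import cell_summaries, pearson
from .single_case import ControlSample, classify_impairments, deficit_test

__all__ = [
    "PaperFixture",
    "load_paper_fixture",
    "format_p",
    "reproduce_paper",
]

#: probabilities below this are reported as the floor itself, matching the
#: printing convention of the original single-case analysis program
P_FLOOR = 0.001

_TOL_STAT = 0.005   # |Δt|, |Δr| allowed before values count as mismatched
_TOL_P = 0.0015     # one unit in the third printed decimal


def _read(name: str) -> pd.DataFrame:
    with resources.files("aafadapt.data").joinpath(name).open() as fh:
        return pd.read_csv(fh)


@dataclass(frozen=True)
class PaperFixture:
    """Published per-subject values and group summaries.

    Attributes
    ----------
    pwa : DataFrame
        Hold-phase adaptive/corrective means (Hz) per stroke subject ×
        formant × paradigm.
    nt_summary : DataFrame
        Control-group n/mean/sd per formant × paradigm × measure.
    pwa_summary_printed : DataFrame
        The published aphasia-group rows, used only for auditing.
    single_case_printed : DataFrame
        Published single-case t and p for every F1 measure.
    correlations_printed : DataFrame
        Published adaptive-vs-corrective Pearson r (and p) per cell.
    classification_printed : DataFrame
        Published impairment-category counts (F1, gradual paradigm).
    """

    pwa: pd.DataFrame
    nt_summary: pd.DataFrame
    pwa_summary_printed: pd.DataFrame
    single_case_printed: pd.DataFrame
    correlations_printed: pd.DataFrame
    classification_printed: pd.DataFrame

    def control_sample(self, formant: str, paradigm: str, measure: str) -> ControlSample:
        row = self.nt_summary.query(
            "formant == @formant and paradigm == @paradigm and measure == @measure"
        )
        if len(row) != 1:
            raise KeyError((formant, paradigm, measure))
        r = row.iloc[0]
        return ControlSample(n=int(r["n"]), mean=float(r["mean"]), sd=float(r["sd"]))


def load_paper_fixture() -> PaperFixture:
    """Load the packaged transcription of the published tables."""
    return PaperFixture(
        pwa=_read("hold_phase_pwa.csv"),
        nt_summary=_read("nt_group_summary.csv"),
        pwa_summary_printed=_read("pwa_group_summary.csv"),
        single_case_printed=_read("single_case_f1_printed.csv"),
        correlations_printed=_read("pwa_correlations_printed.csv"),
        classification_printed=_read("classification_printed.csv"),
    )


def format_p(p: float, floor: float = P_FLOOR) -> float:
    """Round a tail probability to three decimals with a reporting floor."""
    return round(max(p, floor), 3)


def _pwa_hold_long(fixture: PaperFixture) -> pd.DataFrame:
    """Fixture rows in the hold-summary layout used by cell_summaries."""
    df = fixture.pwa.rename(
        columns={
            "subject": "subject_id",
            "adaptive": "adaptive_mean",
            "corrective": "corrective_mean",
        }
    ).copy()
    df["group"] = "PWA"
    return df


def reproduce_paper(fixture: PaperFixture | None = None, alpha: float = 0.05) -> dict:
    """Recompute every published derived statistic and audit it.

    From the per-subject hold-phase values this recomputes (a) all 36
    single-case F1 t/p values, (b) the gradual-paradigm impairment
    classification counts, (c) the four aphasia-group adaptive-vs-corrective
    correlations, and (d) the aphasia group mean (SD) rows — and compares
    each with the printed value.

    Returns a dict with keys ``single_case``, ``classification``,
    ``correlations``, ``group_rows`` (DataFrames/dicts of recomputed
    values with match flags) and ``n_mismatches``.
    """
    fx = load_paper_fixture() if fixture is None else fixture
    mismatches = 0

    # (a) single-case tests, F1
    sc_rows = []
    for _, row in fx.single_case_printed.iterrows():
        score = fx.pwa.query(
            "subject == @row.subject and formant == 'F1' "
            "and paradigm == @row.paradigm"
        )[row["measure"]].iloc[0]
        controls = fx.control_sample("F1", row["paradigm"], row["measure"])
        res = deficit_test(float(score), controls, alpha=alpha)
        ok = (
            abs(round(res.t, 2) - row["t"]) <= _TOL_STAT
            and abs(format_p(res.p) - row["p"]) <= _TOL_P
        )
        mismatches += not ok
        sc_rows.append(
            {
                "subject": row["subject"], "paradigm": row["paradigm"],
                "measure": row["measure"], "t": round(res.t, 2),
                "p": format_p(res.p), "impaired": res.impaired,
                "t_printed": row["t"], "p_printed": row["p"], "match": ok,
            }
        )
    single_case = pd.DataFrame(sc_rows)

    # (b) impairment classification, F1 gradual
    grad = fx.pwa.query("formant == 'F1' and paradigm == 'gradual'")
    cases = {
        r["subject"]: {"adaptive": r["adaptive"], "corrective": r["corrective"]}
        for _, r in grad.iterrows()
    }
    controls = {
        m: fx.control_sample("F1", "gradual", m) for m in ("adaptive", "corrective")
    }
    cls = classify_impairments(cases, controls, alpha=alpha)
    printed_counts = dict(
        zip(fx.classification_printed["category"], fx.classification_printed["count"])
    )
    cls_ok = cls["counts"] == printed_counts
    mismatches += not cls_ok
    classification = {
        "counts": cls["counts"],
        "assignments": cls["assignments"],
        "counts_printed": printed_counts,
        "match": cls_ok,
    }

    # (c) adaptive-vs-corrective correlations per formant × paradigm
    corr_rows = []
    for _, row in fx.correlations_printed.iterrows():
        sub = fx.pwa.query("formant == @row.formant and paradigm == @row.paradigm")
        res = pearson(sub["adaptive"], sub["corrective"])
        ok = abs(round(res.r, 2) - row["r"]) <= _TOL_STAT
        mismatches += not ok
        corr_rows.append(
            {
                "formant": row["formant"], "paradigm": row["paradigm"],
                "r": round(res.r, 2), "p": round(res.p, 2), "n": res.n,
                "r_printed": row["r"], "p_printed": row["p"], "match": ok,
            }
        )
    correlations = pd.DataFrame(corr_rows)

    # (d) aphasia group rows recomputed from the per-subject values
    summ = cell_summaries(_pwa_hold_long(fx))
    grp_rows = []
    for _, row in fx.pwa_summary_printed.iterrows():
        cell = summ.query(
            "formant == @row.formant and paradigm == @row.paradigm "
            "and measure == @row.measure"
        ).iloc[0]
        ok = (
            abs(round(cell["mean"], 2) - row["mean"]) <= _TOL_STAT
            and abs(round(cell["sd"], 2) - row["sd"]) <= _TOL_STAT
        )
        mismatches += not ok
        grp_rows.append(
            {
                "formant": row["formant"], "paradigm": row["paradigm"],
                "measure": row["measure"], "mean": round(cell["mean"], 2),
                "sd": round(cell["sd"], 2), "n": int(cell["n"]),
                "mean_printed": row["mean"], "sd_printed": row["sd"], "match": ok,
            }
        )
    group_rows = pd.DataFrame(grp_rows)

    return {
        "single_case": single_case,
        "classification": classification,
        "correlations": correlations,
        "group_rows": group_rows,
        "n_mismatches": int(mismatches),
    }
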