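"""Trial-table CSV round-tripping and YAML study configuration."""

from __future__ import annotations

import numpy as np
import pandas as pd
import yaml

from .simulate import TRIAL_COLUMNS, GroupSpec

__all__ = [
    "load_trial_table",
    "write_trial_table",
    "load_cohort_config",
    "DEFAULT_CONFIG",
]

_NUMERIC = ["early_f1", "early_f2", "late_f1", "late_f2"]

#: schedule and cohort defaults mirroring the study design
DEFAULT_CONFIG = {
    "schedule": {"n_baseline": 30, "n_ramp": 30, "n_hold": 30, "n_after": 30},
    "cohort": {"n_nt": 12, "n_pwa": 9},
    "shift": {"df1": 150.0, "df2": -100.0},
}


def write_trial_table(records: pd.DataFrame, path) -> None:
    """Write a trial table as CSV with the canonical column order."""
    missing = [c for c in TRIAL_COLUMNS if c not in records.columns]
    if missing:
        raise ValueError(f"trial table missing columns {missing}")
    records[TRIAL_COLUMNS].to_csv(path, index=False)


def load_trial_table(path) -> pd.DataFrame:
    """Load a trial table CSV, validating schema and values.

    Raises ``ValueError`` naming the offending row for non-numeric or
    non-finite formant values, and listing any missing/extra columns.
    """
    df = pd.read_csv(path, dtype={"subject_id": str})
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
    extra = [c for c in df.columns if c not in TRIAL_COLUMNS]
    if missing or extra:
        raise ValueError(
            f"bad trial table header: missing={missing}, unexpected={extra}"
        )
    for col in _NUMERIC:
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.index[~np.isfinite(vals)]
        if len(bad):
            # +2: 1-based line numbers plus the header line
            raise ValueError(
                f"non-numeric value in column {col!r} at row {bad[0] + 2}"
            )
        df[col] = vals.astype(float)
    df["trial"] = df["trial"].astype(int)
    return df[TRIAL_COLUMNS]


def load_cohort_config(path) -> dict:
    """Read a YAML study config, filling unspecified keys with defaults.

    Recognised sections: ``schedule`` (phase lengths), ``cohort``
    (``n_nt``/``n_pwa`` and optional per-group parameter distributions
    under ``nt``/``pwa`` as ``{param: [mean, sd]}``), ``shift``.
    """
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    cfg = {k: dict(v) for k, v in DEFAULT_CONFIG.items()}
    for section, values in user.items():
        if section not in cfg:
            raise ValueError(f"unknown config section {section!r}")
        cfg[section].update(values or {})
    for key in ("nt", "pwa"):
        dists = cfg["cohort"].get(key)
        if dists is not None:
            cfg["cohort"][key] = GroupSpec(
                group=key.upper(),
                dists={k: tuple(v) for k, v in dists.items()},
            )
    return cfg
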