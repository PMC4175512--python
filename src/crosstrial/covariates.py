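"""Resolution of named baseline covariates to numeric columns.

Patient tables use clinical encodings (ECOG grade as an integer, number of
disease sites as a 3-level category, sex as F/M).  Matching, balance testing
and outcome models all work on 0/1 indicator features; this module maps a
feature name to its indicator so every consumer derives them identically.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

#: canonical column order for a patient-level trial table
PATIENT_COLUMNS = [
    "patient_id",
    "arm",
    "age",
    "sex",
    "ecog",
    "time_since_dx_ge3y",
    "n_disease_sites",
    "distant_mets",
    "prior_ssa",
    "prior_chemo",
    "pfs_time",
    "pfs_event",
    "os_time",
    "os_event",
    "crossover_time",
]

SITE_LEVELS = ("1", "2", "3+")


def feature(records: pd.DataFrame, name: str) -> pd.Series:
    """Return the numeric feature `name` as a float Series.

    Recognised derived names: ``female``, ``ecog0``, ``ecog1``, ``ecog2``,
    ``n_sites_2``, ``n_sites_ge3``, ``age_gt_64`` (and generally
    ``age_gt_<x>``).  Any other name must be an existing numeric column.
    """
    if name == "female":
        return (records["sex"] == "F").astype(float)
    if name.startswith("ecog") and name[4:].isdigit():
        return (records["ecog"] == int(name[4:])).astype(float)
    if name == "n_sites_2":
        return (records["n_disease_sites"] == "2").astype(float)
    if name == "n_sites_ge3":
        return (records["n_disease_sites"] == "3+").astype(float)
    if name.startswith("age_gt_"):
        return (records["age"] > float(name[7:])).astype(float)
    if name == "dx_ge3y":
        return pd.to_numeric(records["time_since_dx_ge3y"]).astype(float)
    if name in records.columns:
        return pd.to_numeric(records[name], errors="raise").astype(float)
    raise KeyError(f"covariate {name!r} cannot be resolved from the patient table")


def linear_predictor(records: pd.DataFrame, coefficients: dict[str, float]) -> np.ndarray:
    """Linear combination of named features, used as a log-hazard offset."""
    lp = np.zeros(len(records))
    for name, coef in coefficients.items():
        lp += coef * feature(records, name).to_numpy()
    return lp
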