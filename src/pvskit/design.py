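"""Predictor preparation shared by the cohort simulator and the GLM fitter.

Continuous predictors are centered on their sample median; body-mass index
is z-transformed (its skewed distribution motivates the different
treatment); categorical covariates expand to indicator columns against
fixed reference levels (sex: female; diagnosis: CN; medication codes: 0).
Interaction terms are written ``"a:b"`` and are products of the two
prepared (centered, optionally scaled) columns, so a subject sitting at
both medians contributes exactly zero to the interaction.

The simulator builds its linear predictor through this module, which is
what makes simulated coefficients directly recoverable by the fitter under
the same convention.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "BIOMARKERS",
    "CONTINUOUS_PREDICTORS",
    "CATEGORY_LEVELS",
    "prepare_columns",
    "term_column",
]

#: Plasma biomarkers, all expressed in ng/mL.
BIOMARKERS = [
    "cortisol",
    "ace",
    "tnf_a",
    "tnfr2",
    "trail",
    "crp",
    "il6r",
    "mmp2",
    "mmp9",
]

#: Continuous predictors that are median-centered (BMI handled separately).
CONTINUOUS_PREDICTORS = BIOMARKERS + ["age", "hippocampal_volume"]

CATEGORY_LEVELS = {
    "sex": ["F", "M"],
    "diagnosis": ["CN", "MCI", "AD"],
    "medication_history": [0, 1, 2, 3],
    "medication_current": [0, 1, 2],
    "apoe4_copies": [0, 1, 2],
}


def prepare_columns(df: pd.DataFrame, standardize: bool = False) -> pd.DataFrame:
    """Transform raw cohort columns into model-ready predictor columns.

    Parameters
    ----------
    df:
        Raw per-subject table (see :class:`pvskit.synthetic.CohortSpec`
        for the schema).  Only columns present in ``df`` are prepared.
    standardize:
        If True, centered continuous predictors are additionally divided
        by their sample standard deviation so coefficients are per-SD.
        BMI is always z-transformed regardless.

    Returns
    -------
    DataFrame indexed like ``df`` with columns such as ``cortisol``
    (centered), ``age``, ``bmi_z``, ``hippocampal_volume``, ``sex_male``,
    ``diagnosis_mci``, ``diagnosis_ad``, ``med_history_1`` ...,
    ``med_current_1`` ..., ``apoe4_positive``.
    """
    out = pd.DataFrame(index=df.index)
    for col in CONTINUOUS_PREDICTORS:
        if col not in df.columns:
            continue
        x = df[col].astype(float)
        centered = x - x.median()
        if standardize:
            sd = x.std(ddof=1)
            if sd > 0:
                centered = centered / sd
        out[col] = centered
    if "bmi" in df.columns:
        bmi = df["bmi"].astype(float)
        sd = bmi.std(ddof=1)
        if sd == 0:
            raise ValueError("zero-variance column: bmi")
        out["bmi_z"] = (bmi - bmi.mean()) / sd
    if "sex" in df.columns:
        out["sex_male"] = (df["sex"].astype(str).str.upper().str[0] == "M").astype(float)
    if "diagnosis" in df.columns:
        dx = df["diagnosis"].astype(str)
        out["diagnosis_mci"] = (dx == "MCI").astype(float)
        out["diagnosis_ad"] = (dx == "AD").astype(float)
    if "medication_history" in df.columns:
        mh = df["medication_history"].astype(int)
        for level in (1, 2, 3):
            out[f"med_history_{level}"] = (mh == level).astype(float)
    if "medication_current" in df.columns:
        mc = df["medication_current"].astype(int)
        for level in (1, 2):
            out[f"med_current_{level}"] = (mc == level).astype(float)
    if "apoe4_copies" in df.columns:
        out["apoe4_positive"] = (df["apoe4_copies"].astype(int) >= 1).astype(float)
    return out


def term_column(prepared: pd.DataFrame, term: str) -> np.ndarray:
    """Resolve a model term name to its numeric column.

    ``"intercept"`` gives a column of ones; ``"a:b"`` the elementwise
    product of prepared columns ``a`` and ``b``; anything else must name a
    prepared column directly.
    """
    if term == "intercept":
        return np.ones(len(prepared))
    if ":" in term:
        a, b = term.split(":", 1)
        for part in (a, b):
            if part not in prepared.columns:
                raise KeyError(f"unknown term component {part!r}")
        return prepared[a].to_numpy() * prepared[b].to_numpy()
    if term not in prepared.columns:
        raise KeyError(f"unknown term {term!r}")
    return prepared[term].to_numpy()
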