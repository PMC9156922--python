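"""Printed reference data for the 10-athlete treadmill study this pipeline reproduces.

Three kinds of reference values are bundled:

* ``subjects()`` — the published subject-characteristics table (sex, age,
  mass, standing unaffected-leg length and unloaded affected-leg length at
  the recommended prosthesis height for each model).
* ``study_design_rows()`` — an emulation of the study's trial design: 10
  subjects x 27 occupied (model, stiffness category, height) cells x speeds
  3-7 m/s, with the published per-cell subject counts, the trials lost to
  force-plate saturation or incomplete speed series, and the non-integer
  height offsets used when a subject's residual-limb length limited the
  +/-2 cm adjustment.  Which *specific* subjects occupy the reduced-height
  cells is not published, so subjects are assigned deterministically
  (lowest ids first); the analysed-trial total (704) and the covariate
  structure match the published design.
* ``reference_coefficients()`` / ``reference_speed_summary()`` — the
  published mixed-model fixed-effect tables for the six responses and the
  published per-speed mean values, used by the ``reproduce`` workflow as
  the comparison standard.
"""

from __future__ import annotations

import pandas as pd

__all__ = [
    "subjects",
    "study_design_rows",
    "reference_coefficients",
    "reference_speed_summary",
    "RSP_MODELS",
    "STIFFNESS_CATS",
    "SPEEDS_MPS",
]

RSP_MODELS = ("Catapult", "Sprinter", "Xtend")
STIFFNESS_CATS = ("-1", "Rec", "+1")
SPEEDS_MPS = (3.0, 4.0, 5.0, 6.0, 7.0)

# subject id, sex, age (yr), mass (kg), UL length (m), AL length with
# Catapult / Sprinter / Xtend at recommended height (m)
_SUBJECTS = [
    (1, "male", 23, 82.59, 1.00, 1.04, 1.05, 1.04),
    (2, "male", 25, 87.87, 0.88, 0.94, 0.92, 0.96),
    (3, "female", 29, 75.62, 0.94, 1.01, 0.96, 1.01),
    (4, "male", 31, 74.38, 1.01, 1.04, 1.03, 1.03),
    (5, "male", 22, 71.69, 0.90, 0.94, 0.92, 0.93),
    (6, "male", 33, 92.66, 0.99, 1.05, 1.05, 1.05),
    (7, "male", 34, 66.69, 0.96, 1.04, 1.00, 1.01),
    (8, "male", 37, 90.73, 0.95, 1.02, 1.01, 1.00),
    (9, "female", 29, 58.25, 0.81, 0.86, 0.88, 0.87),
    (10, "female", 21, 59.51, 0.84, 0.88, 0.88, 0.88),
]


def subjects() -> pd.DataFrame:
    """Published subject characteristics as a DataFrame (one row per subject)."""
    return pd.DataFrame(
        _SUBJECTS,
        columns=[
            "subject",
            "sex",
            "age_yr",
            "mass_kg",
            "ul_length_m",
            "al_length_catapult_m",
            "al_length_sprinter_m",
            "al_length_xtend_m",
        ],
    )


# Design cells: (model, stiffness category, nominal height offset cm,
# n subjects, mods). Each mod applies to one subject of the cell (assigned in
# order, subject index 0, 1, ... within the cell) and overrides that
# subject's speed list and/or height offset.  Speed overrides encode the
# published footnotes: incomplete speed series and saturated (excluded)
# force trials.
_ALL = SPEEDS_MPS
_36 = (3.0, 4.0, 5.0, 6.0)
_35 = (3.0, 4.0, 5.0)
_4567 = (4.0, 5.0, 6.0, 7.0)
_56 = (5.0, 6.0)

_DESIGN_CELLS = [
    # --- lowered height (-2 cm nominal) ---
    ("Catapult", "-1", -2.0, 5, [{"speeds": _56}, {"height": -1.8}, {"height": -1.3}]),
    ("Catapult", "Rec", -2.0, 2, []),
    ("Catapult", "+1", -2.0, 2, []),
    ("Sprinter", "-1", -2.0, 2, []),
    ("Sprinter", "Rec", -2.0, 5, []),
    ("Sprinter", "+1", -2.0, 2, []),
    ("Xtend", "-1", -2.0, 2, []),
    ("Xtend", "Rec", -2.0, 3, [{"height": -1.0}]),
    ("Xtend", "+1", -2.0, 5, [{"speeds": _36}, {"speeds": _36}, {"speeds": _36}]),
    # --- recommended height ---
    ("Catapult", "-1", 0.0, 10, [{"speeds": _36}]),
    ("Catapult", "Rec", 0.0, 10, [{"speeds": _36}]),
    ("Catapult", "+1", 0.0, 10, [{"speeds": _36}, {"speeds": _36}]),
    ("Sprinter", "-1", 0.0, 10, []),
    ("Sprinter", "Rec", 0.0, 10, [{"speeds": _4567}]),
    ("Sprinter", "+1", 0.0, 10, []),
    ("Xtend", "-1", 0.0, 10, [{"speeds": _36}]),
    ("Xtend", "Rec", 0.0, 10, [{"speeds": _36}]),
    ("Xtend", "+1", 0.0, 10, [{"speeds": _36}, {"speeds": _36}]),
    # --- raised height (+2 cm nominal) ---
    ("Catapult", "-1", 2.0, 5, [{"speeds": _36}, {"speeds": _35}]),
    ("Catapult", "Rec", 2.0, 2, []),
    ("Catapult", "+1", 2.0, 2, []),
    ("Sprinter", "-1", 2.0, 2, [{"speeds": _35}]),
    ("Sprinter", "Rec", 2.0, 5, [{"height": 0.8}]),
    ("Sprinter", "+1", 2.0, 2, [{"height": 1.0}]),
    ("Xtend", "-1", 2.0, 2, []),
    ("Xtend", "Rec", 2.0, 3, []),
    ("Xtend", "+1", 2.0, 4, [{"speeds": _36}]),
]


def study_design_rows() -> pd.DataFrame:
    """Trial-level covariate table emulating the study design (704 rows).

    Columns: subject, rsp_model, stiffness_cat, height_offset_cm, speed_mps.
    """
    rows = []
    for model, cat, height, n, mods in _DESIGN_CELLS:
        for i in range(n):
            speeds = _ALL
            h = height
            if i < len(mods):
                speeds = mods[i].get("speeds", speeds)
                h = mods[i].get("height", h)
            for v in speeds:
                rows.append((i + 1, model, cat, float(h), v))
    return pd.DataFrame(
        rows,
        columns=["subject", "rsp_model", "stiffness_cat", "height_offset_cm", "speed_mps"],
    )


# ---------------------------------------------------------------------------
# Published mixed-model fixed-effect tables (six responses x 12 terms).
# Tuples: (term, estimate, ci_lo, ci_hi, se, t, p).  p-values printed as
# "< 2e-16" are stored as 2e-16.

_T3_T4 = {
    "al_contact_length_m": [
        ("intercept", 0.53, 0.49, 0.57, 0.022, 24.36, 9.99e-15),
        ("model [Sprinter]", 0.010, -0.015, 0.036, 0.013, 0.79, 0.43),
        ("model [Xtend]", -0.037, -0.062, -0.011, 0.013, -2.78, 0.0056),
        ("stiffness cat [Rec]", -0.034, -0.059, -0.0088, 0.013, -2.63, 0.0088),
        ("stiffness cat [+1]", -0.064, -0.090, -0.038, 0.013, -4.85, 1.55e-6),
        ("height [cm]", 0.0040, -0.0047, 0.013, 0.0045, 0.89, 0.37),
        ("speed [m s^-1]", 0.066, 0.062, 0.070, 0.0022, 29.43, 2e-16),
        ("model [Sprinter]*speed [m s^-1]", 0.00036, -0.0046, 0.0053, 0.0025, 0.14, 0.89),
        ("model [Xtend]*speed [m s^-1]", 0.0016, -0.0034, 0.0066, 0.0026, 0.62, 0.54),
        ("stiffness cat [Rec]*speed [m s^-1]", 0.0022, -0.0027, 0.0071, 0.0025, 0.88, 0.38),
        ("stiffness cat [+1]*speed [m s^-1]", 0.0039, -0.0011, 0.0090, 0.0026, 1.53, 0.13),
        ("height [cm]*speed [m s^-1]", 0.00035, -0.0014, 0.0020, 0.00087, 0.40, 0.69),
    ],
    "al_favg_bw": [
        ("intercept", 1.17, 1.06, 1.29, 0.058, 20.28, 5.83e-14),
        ("model [Sprinter]", 0.14, 0.066, 0.21, 0.036, 3.78, 0.00017),
        ("model [Xtend]", 0.12, 0.050, 0.19, 0.036, 3.34, 0.00089),
        ("stiffness cat [Rec]", 0.0035, -0.066, 0.073, 0.036, 0.10, 0.92),
        ("stiffness cat [+1]", 0.076, 0.0051, 0.15, 0.037, 2.09, 0.037),
        ("height [cm]", -0.022, -0.046, 0.0022, 0.012, -1.77, 0.077),
        ("speed [m s^-1]", 0.078, 0.066, 0.090, 0.062, 12.56, 2e-16),
        ("model [Sprinter]*speed [m s^-1]", 0.00050, -0.013, 0.014, 0.0070, 0.072, 0.94),
        ("model [Xtend]*speed [m s^-1]", 0.0095, -0.0042, 0.023, 0.0071, 1.35, 0.18),
        ("stiffness cat [Rec]*speed [m s^-1]", 0.0025, -0.011, 0.016, 0.0069, 0.37, 0.72),
        ("stiffness cat [+1]*speed [m s^-1]", -0.0057, -0.020, 0.0082, 0.0071, -0.80, 0.43),
        ("height [cm]*speed [m s^-1]", -0.0023, -0.0070, 0.0024, 0.0024, -0.97, 0.33),
    ],
    "al_fstep_hz": [
        ("intercept", 2.12, 1.97, 2.27, 0.079, 26.84, 2e-16),
        ("model [Sprinter]", -0.23, -0.35, -0.11, 0.061, -3.75, 0.00019),
        ("model [Xtend]", -0.13, -0.25, -0.015, 0.061, -2.19, 0.029),
        ("stiffness cat [Rec]", 0.093, -0.025, 0.21, 0.060, 1.54, 0.12),
        ("stiffness cat [+1]", 0.12, 0.00021, 0.24, 0.062, 1.95, 0.052),
        ("height [cm]", -0.015, -0.056, 0.026, 0.021, -0.72, 0.47),
        ("speed [m s^-1]", 0.27, 0.25, 0.29, 0.010, 26.14, 2e-16),
        ("model [Sprinter]*speed [m s^-1]", 0.022, -0.00070, 0.045, 0.012, 1.89, 0.060),
        ("model [Xtend]*speed [m s^-1]", 0.0025, -0.021, 0.026, 0.012, 0.21, 0.83),
        ("stiffness cat [Rec]*speed [m s^-1]", -0.024, -0.047, -0.0014, 0.012, -2.07, 0.039),
        ("stiffness cat [+1]*speed [m s^-1]", -0.026, -0.050, -0.0030, 0.012, -2.20, 0.029),
        ("height [cm]*speed [m s^-1]", -0.0061, -0.014, 0.0018, 0.0041, -1.50, 0.13),
    ],
    "si_contact_length_pct": [
        ("intercept", -6.08, -9.50, -2.66, 1.75, -3.48, 0.0016),
        ("model [Sprinter]", -0.24, -2.82, 2.34, 1.32, -0.18, 0.86),
        ("model [Xtend]", 6.90, 4.31, 9.48, 1.33, 5.20, 2.69e-7),
        ("stiffness cat [Rec]", 4.72, 2.17, 7.27, 1.31, 3.61, 0.00033),
        ("stiffness cat [+1]", 6.40, 3.79, 9.01, 1.34, 4.78, 2.17e-6),
        ("height [cm]", -2.07, -2.95, -1.19, 0.45, -4.57, 5.86e-6),
        ("speed [m s^-1]", 0.14, -0.31, 0.58, 0.23, 0.60, 0.55),
        ("model [Sprinter]*speed [m s^-1]", -0.29, -0.79, 0.21, 0.26, -1.12, 0.26),
        ("model [Xtend]*speed [m s^-1]", -0.81, -1.31, -0.30, 0.26, -3.11, 0.0020),
        ("stiffness cat [Rec]*speed [m s^-1]", -0.46, -0.95, 0.035, 0.25, -1.81, 0.071),
        ("stiffness cat [+1]*speed [m s^-1]", -0.43, -0.94, 0.074, 0.26, -1.67, 0.096),
        ("height [cm]*speed [m s^-1]", 0.13, -0.045, 0.30, 0.088, 1.43, 0.15),
    ],
    "si_favg_pct": [
        ("intercept", 15.03, 9.78, 20.28, 2.71, 5.55, 4.33e-7),
        ("model [Sprinter]", -10.07, -14.97, -5.17, 2.52, -4.00, 7.00e-5),
        ("model [Xtend]", -5.42, -10.33, -0.51, 2.52, -2.15, 0.032),
        ("stiffness cat [Rec]", 0.77, -4.07, 5.61, 2.49, 0.31, 0.76),
        ("stiffness cat [+1]", -1.18, -6.14, 3.78, 2.55, -0.46, 0.64),
        ("height [cm]", 3.86, 2.18, 5.53, 0.86, 4.48, 8.58e-6),
        ("speed [m s^-1]", -0.054, -0.89, 0.78, 0.43, -0.13, 0.90),
        ("model [Sprinter]*speed [m s^-1]", -0.061, -1.01, 0.89, 0.49, -0.13, 0.90),
        ("model [Xtend]*speed [m s^-1]", -0.94, -1.90, 0.020, 0.49, -1.91, 0.057),
        ("stiffness cat [Rec]*speed [m s^-1]", -0.053, -0.99, 0.88, 0.48, -0.11, 0.91),
        ("stiffness cat [+1]*speed [m s^-1]", 0.24, -0.72, 1.21, 0.49, 0.49, 0.62),
        ("height [cm]*speed [m s^-1]", 0.088, -0.24, 0.41, 0.17, 0.53, 0.60),
    ],
    "si_fstep_pct": [
        ("intercept", -2.32, -5.60, 0.97, 1.70, -1.37, 0.17),
        ("model [Sprinter]", 5.23, 1.78, 8.69, 1.78, 2.94, 0.0034),
        ("model [Xtend]", 2.99, -0.48, 6.46, 1.78, 1.68, 0.094),
        ("stiffness cat [Rec]", -1.03, -4.45, 2.40, 1.76, -0.58, 0.56),
        ("stiffness cat [+1]", -2.79, -6.30, 0.71, 1.80, -1.55, 0.12),
        ("height [cm]", 1.98, 0.80, 3.17, 0.61, 3.27, 0.0011),
        ("speed [m s^-1]", 0.75, 0.16, 1.35, 0.30, 2.48, 0.013),
        ("model [Sprinter]*speed [m s^-1]", -0.89, -1.56, -0.22, 0.34, -2.59, 0.0098),
        ("model [Xtend]*speed [m s^-1]", -0.25, -0.93, 0.43, 0.35, -0.72, 0.47),
        ("stiffness cat [Rec]*speed [m s^-1]", 0.57, -0.092, 1.23, 0.34, 1.68, 0.094),
        ("stiffness cat [+1]*speed [m s^-1]", 0.89, 0.21, 1.57, 0.35, 2.54, 0.011),
        ("height [cm]*speed [m s^-1]", 0.10, -0.13, 0.33, 0.12, 0.87, 0.39),
    ],
}


def reference_coefficients(response: str) -> pd.DataFrame:
    """Published fixed-effect table for one response.

    ``response`` is one of the six canonical analysis-table column names
    (``al_contact_length_m``, ``al_favg_bw``, ``al_fstep_hz``,
    ``si_contact_length_pct``, ``si_favg_pct``, ``si_fstep_pct``).
    """
    if response not in _T3_T4:
        raise KeyError(f"unknown response {response!r}; known: {sorted(_T3_T4)}")
    return pd.DataFrame(
        _T3_T4[response],
        columns=["term", "estimate", "ci_lo", "ci_hi", "se", "t", "p"],
    )


def reference_speed_summary() -> pd.DataFrame:
    """Published per-speed mean values (affected leg and f_step SI endpoints)."""
    rows = [
        (3.0, "al_contact_length_m", 0.67),
        (7.0, "al_contact_length_m", 0.95),
        (3.0, "al_favg_bw", 1.49),
        (7.0, "al_favg_bw", 1.82),
        (3.0, "al_fstep_hz", 2.91),
        (7.0, "al_fstep_hz", 3.97),
        (3.0, "si_fstep_pct", 1.90),
        (7.0, "si_fstep_pct", 5.21),
    ]
    return pd.DataFrame(rows, columns=["speed_mps", "quantity", "value"])
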