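"""Linear mixed-effects models of prosthesis configuration effects.

Six responses are modelled from the trial-level analysis table: the
affected-leg contact length, stance-average vertical force (in body
weights) and step frequency, and the between-leg symmetry index of each.
Every model shares one fixed-effect structure —

    response ~ model + stiffness + height + speed
               + model:speed + stiffness:speed + height:speed
               + (1 | subject)

with treatment (dummy) coding, reference levels Catapult (prosthesis
model) and the -1 stiffness category, prosthesis height as signed
centimetres from the recommended height, speed uncentred in m/s, and a
subject random intercept.  Estimation is by REML through
``statsmodels`` ``MixedLM``; inference is Wald-t with residual degrees of
freedom (n - p).  Singular (boundary) random-effect variances are flagged
in the result, not rejected, since small-sample random-intercept models
legitimately hit the boundary on subsets.

The fixed-effect design matrix has a fixed, documented column order (see
:data:`TERMS`); coefficient rows are named accordingly, e.g.
``model [Xtend]`` or ``height [cm]*speed [m s^-1]``.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as _stats

from . import reference
from .reference import RSP_MODELS, SPEEDS_MPS, STIFFNESS_CATS

__all__ = [
    "TERMS",
    "RESPONSES",
    "LmmSpec",
    "CoefTable",
    "build_design",
    "build_design_row",
    "fit_lmm",
    "fit_all",
    "summarize_by_speed",
    "predict",
    "compare_to_reference",
]

logger = logging.getLogger(__name__)

#: fixed-effect design columns, in reporting order
TERMS = (
    "intercept",
    "model [Sprinter]",
    "model [Xtend]",
    "stiffness cat [Rec]",
    "stiffness cat [+1]",
    "height [cm]",
    "speed [m s^-1]",
    "model [Sprinter]*speed [m s^-1]",
    "model [Xtend]*speed [m s^-1]",
    "stiffness cat [Rec]*speed [m s^-1]",
    "stiffness cat [+1]*speed [m s^-1]",
    "height [cm]*speed [m s^-1]",
)

#: the six modelled responses (canonical analysis-table columns)
RESPONSES = (
    "al_contact_length_m",
    "al_favg_bw",
    "al_fstep_hz",
    "si_contact_length_pct",
    "si_favg_pct",
    "si_fstep_pct",
)

#: reporting significance threshold
ALPHA = 0.05


@dataclass
class LmmSpec:
    """Model specification for one response (shared structure for all six)."""

    response: str
    reference_model: str = "Catapult"
    reference_stiffness: str = "-1"
    group: str = "subject"
    reml: bool = True


@dataclass
class CoefTable:
    """Fitted fixed effects: estimate, 95% CI, s.e., t and p per term."""

    response: str
    table: pd.DataFrame  # columns: term, estimate, ci_lo, ci_hi, se, t, p
    df_resid: int = 0
    subject_var: float = np.nan
    resid_var: float = np.nan
    singular: bool = False
    converged: bool = True

    def estimate(self, term: str) -> float:
        sub = self.table.loc[self.table["term"] == term, "estimate"]
        if sub.empty:
            raise KeyError(f"unknown term {term!r}")
        return float(sub.iloc[0])

    def significant_terms(self, alpha: float = ALPHA) -> list[str]:
        return list(self.table.loc[self.table["p"] < alpha, "term"])

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def build_design_row(
    rsp_model: str, stiffness_cat: str, height_offset_cm: float, speed_mps: float
) -> dict:
    """Design values for one covariate combination, keyed by term name."""
    if rsp_model not in RSP_MODELS:
        raise ValueError(f"unseen RSP model level {rsp_model!r}; known: {RSP_MODELS}")
    if stiffness_cat not in STIFFNESS_CATS:
        raise ValueError(
            f"unseen stiffness category level {stiffness_cat!r}; known: {STIFFNESS_CATS}"
        )
    m_spr = 1.0 if rsp_model == "Sprinter" else 0.0
    m_xt = 1.0 if rsp_model == "Xtend" else 0.0
    s_rec = 1.0 if stiffness_cat == "Rec" else 0.0
    s_p1 = 1.0 if stiffness_cat == "+1" else 0.0
    h = float(height_offset_cm)
    v = float(speed_mps)
    return {
        "intercept": 1.0,
        "model [Sprinter]": m_spr,
        "model [Xtend]": m_xt,
        "stiffness cat [Rec]": s_rec,
        "stiffness cat [+1]": s_p1,
        "height [cm]": h,
        "speed [m s^-1]": v,
        "model [Sprinter]*speed [m s^-1]": m_spr * v,
        "model [Xtend]*speed [m s^-1]": m_xt * v,
        "stiffness cat [Rec]*speed [m s^-1]": s_rec * v,
        "stiffness cat [+1]*speed [m s^-1]": s_p1 * v,
        "height [cm]*speed [m s^-1]": h * v,
    }


def build_design(rows: pd.DataFrame) -> pd.DataFrame:
    """Treatment-coded fixed-effect design matrix with :data:`TERMS` columns.

    Reference levels: Catapult (model) and -1 (stiffness category); height
    passes through as signed numeric cm (non-integer offsets untouched);
    interactions are elementwise products with uncentred speed.
    """
    for model in rows["rsp_model"].unique():
        if model not in RSP_MODELS:
            raise ValueError(f"unseen RSP model level {model!r}; known: {RSP_MODELS}")
    for cat in rows["stiffness_cat"].unique():
        if cat not in STIFFNESS_CATS:
            raise ValueError(
                f"unseen stiffness category level {cat!r}; known: {STIFFNESS_CATS}"
            )
    m_spr = (rows["rsp_model"] == "Sprinter").astype(float).to_numpy()
    m_xt = (rows["rsp_model"] == "Xtend").astype(float).to_numpy()
    s_rec = (rows["stiffness_cat"] == "Rec").astype(float).to_numpy()
    s_p1 = (rows["stiffness_cat"] == "+1").astype(float).to_numpy()
    h = rows["height_offset_cm"].astype(float).to_numpy()
    v = rows["speed_mps"].astype(float).to_numpy()
    cols = {
        "intercept": np.ones(len(rows)),
        "model [Sprinter]": m_spr,
        "model [Xtend]": m_xt,
        "stiffness cat [Rec]": s_rec,
        "stiffness cat [+1]": s_p1,
        "height [cm]": h,
        "speed [m s^-1]": v,
        "model [Sprinter]*speed [m s^-1]": m_spr * v,
        "model [Xtend]*speed [m s^-1]": m_xt * v,
        "stiffness cat [Rec]*speed [m s^-1]": s_rec * v,
        "stiffness cat [+1]*speed [m s^-1]": s_p1 * v,
        "height [cm]*speed [m s^-1]": h * v,
    }
    return pd.DataFrame(cols, index=rows.index)[list(TERMS)]


def _check_full_rank(X: pd.DataFrame) -> None:
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        # identify aliased columns via QR pivoting on the correlation structure
        _, R = np.linalg.qr(X.to_numpy())
        diag = np.abs(np.diag(R))
        aliased = [X.columns[i] for i in range(X.shape[1]) if diag[i] < 1e-10 * diag.max()]
        raise ValueError(f"rank-deficient design: aliased terms {aliased or 'unresolved'}")


def fit_lmm(rows: pd.DataFrame, spec: LmmSpec) -> CoefTable:
    """REML fit of one response's mixed model; Wald-t inference.

    Requires at least two subjects and a full-rank design.  A residual
    variance at machine zero (noise-free simulated data) is handled by an
    exact least-squares solve with the inference columns set to NaN.
    """
    y = rows[spec.response].astype(float).to_numpy()
    X = build_design(rows)
    groups = rows[spec.group]
    if groups.nunique() < 2:
        raise ValueError("need >= 2 subjects for a random-intercept model")
    _check_full_rank(X)

    n, p = X.shape
    df_resid = n - p

    # degenerate (noise-free) data: exact solve, no stochastic inference
    beta_ls, _, _, _ = np.linalg.lstsq(X.to_numpy(), y, rcond=None)
    resid = y - X.to_numpy() @ beta_ls
    if float(np.var(resid)) < 1e-20:
        tab = pd.DataFrame(
            {
                "term": list(TERMS),
                "estimate": beta_ls,
                "ci_lo": beta_ls,
                "ci_hi": beta_ls,
                "se": 0.0,
                "t": np.nan,
                "p": np.nan,
            }
        )
        return CoefTable(
            response=spec.response,
            table=tab,
            df_resid=df_resid,
            subject_var=0.0,
            resid_var=0.0,
            singular=True,
        )

    model = sm.MixedLM(y, X, groups=groups)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        result = model.fit(reml=spec.reml)
    if not result.converged:
        raise RuntimeError(
            "mixed-model fit did not converge; "
            f"optimizer message: {getattr(result, 'mle_retvals', None)}"
        )

    est = np.asarray(result.fe_params)
    se = np.asarray(result.bse_fe)
    tval = est / se
    tq = _stats.t.ppf(0.975, df_resid)
    pval = 2.0 * _stats.t.sf(np.abs(tval), df_resid)
    subject_var = float(np.squeeze(result.cov_re.to_numpy()))
    singular = subject_var < 1e-10 * max(float(result.scale), 1e-300)
    if singular:
        logger.warning(
            "%s: random-intercept variance at boundary (singular fit)", spec.response
        )
    tab = pd.DataFrame(
        {
            "term": list(TERMS),
            "estimate": est,
            "ci_lo": est - tq * se,
            "ci_hi": est + tq * se,
            "se": se,
            "t": tval,
            "p": pval,
        }
    )
    return CoefTable(
        response=spec.response,
        table=tab,
        df_resid=df_resid,
        subject_var=subject_var,
        resid_var=float(result.scale),
        singular=singular,
    )


def fit_all(rows: pd.DataFrame, responses: Iterable[str] = RESPONSES) -> dict:
    """Fit the shared model structure for each requested response."""
    return {r: fit_lmm(rows, LmmSpec(response=r)) for r in responses}


def summarize_by_speed(
    rows: pd.DataFrame, speeds: Iterable[float] = SPEEDS_MPS
) -> pd.DataFrame:
    """Unweighted per-speed means of the per-leg metrics and symmetry indices.

    One row per analysed speed with the trial count ``n``; empty speed
    cells are omitted with a warning.
    """
    quantities = [
        "al_contact_length_m",
        "ul_contact_length_m",
        "al_favg_bw",
        "ul_favg_bw",
        "al_fstep_hz",
        "ul_fstep_hz",
        "si_contact_length_pct",
        "si_favg_pct",
        "si_fstep_pct",
    ]
    present = [q for q in quantities if q in rows.columns]
    out = []
    for v in speeds:
        cell = rows[rows["speed_mps"] == v]
        if cell.empty:
            logger.warning("no trials at %.1f m/s; cell omitted", v)
            continue
        rec = {"speed_mps": v, "n": len(cell)}
        rec.update({q: float(cell[q].mean()) for q in present})
        out.append(rec)
    return pd.DataFrame(out)


def predict(coefs: CoefTable, covariates: Mapping) -> float:
    """Population-level prediction (random intercept at zero).

    ``covariates`` must provide ``rsp_model``, ``stiffness_cat``,
    ``height_offset_cm`` and ``speed_mps``.  Terms absent from the table
    are treated as dropped from the model; a table term that is not a known
    design column is an error.
    """
    values = build_design_row(
        covariates["rsp_model"],
        covariates["stiffness_cat"],
        covariates.get("height_offset_cm", 0.0),
        covariates["speed_mps"],
    )
    total = 0.0
    for _, row in coefs.table.iterrows():
        term = row["term"]
        if term not in values:
            raise KeyError(f"unknown term {term!r} in coefficient table")
        total += float(row["estimate"]) * values[term]
    return total


def compare_to_reference(
    fits: Mapping[str, CoefTable], speed_summary: Optional[pd.DataFrame] = None
) -> pd.DataFrame:
    """Compare fitted coefficients (and per-speed means) with the published values.

    Returns a long table: one row per (response, term) with the computed
    estimate, the published estimate and their difference; if a per-speed
    summary is given, additional rows compare the published per-speed means.
    """
    recs = []
    for resp, coefs in fits.items():
        ref = reference.reference_coefficients(resp).set_index("term")
        for _, row in coefs.table.iterrows():
            term = row["term"]
            if term not in ref.index:
                continue
            expected = float(ref.loc[term, "estimate"])
            recs.append(
                {
                    "quantity": resp,
                    "term": term,
                    "computed": float(row["estimate"]),
                    "expected": expected,
                    "difference": float(row["estimate"]) - expected,
                }
            )
    if speed_summary is not None and not speed_summary.empty:
        ref_means = reference.reference_speed_summary()
        indexed = speed_summary.set_index("speed_mps")
        for _, row in ref_means.iterrows():
            v, q = row["speed_mps"], row["quantity"]
            if v in indexed.index and q in indexed.columns:
                computed = float(indexed.loc[v, q])
                recs.append(
                    {
                        "quantity": f"mean {q} @ {v:g} m/s",
                        "term": "",
                        "computed": computed,
                        "expected": float(row["value"]),
                        "difference": computed - float(row["value"]),
                    }
                )
    return pd.DataFrame(recs)
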