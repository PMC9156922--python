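"""Per-step running metrics, per-leg trial means and between-leg symmetry.

For constant-speed treadmill running, average speed factors as

    v = L_step * f_step        (step length x step frequency)
    f_step = 1 / (t_c + t_a)   (one step = one stance + the following aerial phase)
    L_step = L_c * F_avg

where ``t_c`` is contact time, ``t_a`` the subsequent aerial time, ``L_c``
the contact length (forward distance the centre of mass travels during
stance; on a treadmill estimated as belt_speed * t_c) and ``F_avg`` the
stance-average vertical GRF normalised to body weight.  Combining,
``v = L_c * F_avg * f_step`` — an identity that holds exactly under
steady-state impulse balance and serves as an internal consistency check on
measured data.

Between-leg asymmetry of a metric X is summarised by the symmetry index

    SI = (X_UL - X_AL) / (0.5 * (X_UL + X_AL)) * 100%

with X_UL / X_AL the unaffected- and affected-leg values: 0% is perfect
symmetry and positive values mean the unaffected leg is larger.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence, Union

import numpy as np

from .sigproc import AFFECTED, UNAFFECTED, UNKNOWN, GrfTrial, StanceEvent

__all__ = [
    "StepRecord",
    "TrialRow",
    "step_metrics",
    "symmetry_index",
    "aggregate_trial",
    "STANDARD_GRAVITY",
    "METRICS",
]

logger = logging.getLogger(__name__)

STANDARD_GRAVITY = 9.81  # m s^-2, used to normalise force to body weight

#: canonical metric keys in reporting order
METRICS = ("contact_length", "favg", "fstep")


@dataclass
class StepRecord:
    """Derived metrics for one step (one stance + the following aerial phase)."""

    leg: str
    t_c: float  # s
    t_a: float  # s
    f_step: float  # Hz
    L_step: float  # m
    L_c: float  # m
    F_avg: float  # body weights


@dataclass
class TrialRow:
    """One row of the statistical analysis table.

    Per-leg trial means of the three metrics, their symmetry indices, and the
    trial covariates used by the mixed models: subject, prosthesis model
    (Catapult / Sprinter / Xtend), stiffness category (-1 / Rec / +1),
    signed height offset from the recommended prosthesis height (cm) and
    belt speed (m/s).
    """

    subject: str
    rsp_model: str
    stiffness_cat: str
    height_offset_cm: float
    speed_mps: float
    al_contact_length_m: float
    ul_contact_length_m: float
    al_favg_bw: float
    ul_favg_bw: float
    al_fstep_hz: float
    ul_fstep_hz: float
    si_contact_length_pct: float
    si_favg_pct: float
    si_fstep_pct: float
    excluded: bool = False


def step_metrics(
    events: Sequence[StanceEvent],
    trial: GrfTrial,
    g: float = STANDARD_GRAVITY,
) -> list[StepRecord]:
    """Convert labelled stance events into per-step metrics.

    F_avg is the mean of the force samples over ``[touchdown, takeoff)``
    divided by body weight; L_c = belt_speed * t_c; f_step = 1/(t_c + t_a);
    L_step = belt_speed / f_step.  The final stance (no following aerial
    phase) is dropped, as are events with an unknown leg label (their count
    is logged).
    """
    body_weight = trial.body_mass * g
    records: list[StepRecord] = []
    n_unknown = 0
    for ev in events:
        if ev.t_a is None:
            continue
        if ev.leg == UNKNOWN:
            n_unknown += 1
            continue
        favg = float(np.mean(trial.force[ev.touchdown : ev.takeoff])) / body_weight
        t_step = ev.t_c + ev.t_a
        f_step = 1.0 / t_step
        records.append(
            StepRecord(
                leg=ev.leg,
                t_c=ev.t_c,
                t_a=ev.t_a,
                f_step=f_step,
                L_step=trial.belt_speed / f_step,
                L_c=trial.belt_speed * ev.t_c,
                F_avg=favg,
            )
        )
    if n_unknown:
        logger.info("excluded %d step(s) with unknown leg label", n_unknown)
    if not records:
        raise ValueError("no usable steps after exclusions")
    return records


def symmetry_index(x_ul: float, x_al: float) -> float:
    """Symmetry index in percent: (X_UL - X_AL) / (0.5 (X_UL + X_AL)) * 100.

    0% indicates perfect symmetry; positive values indicate a larger
    unaffected-leg value.  For positive inputs the value lies in
    (-200, 200]; it is undefined when the two values cancel.
    """
    denom = 0.5 * (x_ul + x_al)
    if denom == 0:
        raise ValueError("undefined SI: X_UL + X_AL = 0")
    return (x_ul - x_al) / denom * 100.0


def aggregate_trial(
    steps: Sequence[StepRecord],
    subject: str = "",
    rsp_model: str = "",
    stiffness_cat: str = "",
    height_offset_cm: float = 0.0,
    speed_mps: float = 0.0,
    window: Union[int, str] = 16,
    min_steps_per_leg: int = 4,
) -> TrialRow:
    """Aggregate per-step metrics to one analysis-table row.

    The analysis window defaults to the last 16 labelled steps (the
    trial-success criterion: 16 consecutive steps maintaining position on
    the treadmill); pass ``window="all"`` to use every step.  Per-leg means
    are arithmetic means over the window; each SI is computed from the two
    per-leg means (not as a mean of per-step SIs).
    """
    steps = list(steps)
    if window != "all":
        steps = steps[-int(window):]
    by_leg: dict[str, list[StepRecord]] = {AFFECTED: [], UNAFFECTED: []}
    for s in steps:
        if s.leg in by_leg:
            by_leg[s.leg].append(s)
    for leg in (AFFECTED, UNAFFECTED):
        if len(by_leg[leg]) < min_steps_per_leg:
            raise ValueError(
                f"too few usable steps on {leg} leg: "
                f"{len(by_leg[leg])} < {min_steps_per_leg}"
            )

    def leg_mean(leg: str, attr: str) -> float:
        return float(np.mean([getattr(s, attr) for s in by_leg[leg]]))

    al_lc, ul_lc = leg_mean(AFFECTED, "L_c"), leg_mean(UNAFFECTED, "L_c")
    al_fa, ul_fa = leg_mean(AFFECTED, "F_avg"), leg_mean(UNAFFECTED, "F_avg")
    al_fs, ul_fs = leg_mean(AFFECTED, "f_step"), leg_mean(UNAFFECTED, "f_step")
    return TrialRow(
        subject=subject,
        rsp_model=rsp_model,
        stiffness_cat=stiffness_cat,
        height_offset_cm=height_offset_cm,
        speed_mps=speed_mps,
        al_contact_length_m=al_lc,
        ul_contact_length_m=ul_lc,
        al_favg_bw=al_fa,
        ul_favg_bw=ul_fa,
        al_fstep_hz=al_fs,
        ul_fstep_hz=ul_fs,
        si_contact_length_pct=symmetry_index(ul_lc, al_lc),
        si_favg_pct=symmetry_index(ul_fa, al_fa),
        si_fstep_pct=symmetry_index(ul_fs, al_fs),
    )
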