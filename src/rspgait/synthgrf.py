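"""Synthetic treadmill trials with known ground truth.

Two generators make every pipeline stage testable without the study's raw
recordings:

* :func:`simulate_trial` builds a vertical-GRF signal as alternating-leg
  half-sine stance bumps ``F(t) = F_peak sin(pi t / t_c)`` separated by true
  zero-force aerial phases, plus per-leg marker traces sufficient for leg
  labelling.  Unless overridden, ``F_peak`` enforces steady-running impulse
  balance — stance-average force equals body weight times
  ``(t_c + t_a)/t_c`` — so the speed identity ``v = L_c * F_avg * f_step``
  holds exactly on the ground truth.  Measurement noise, baseline drift and
  sensor saturation are applied *after* the truth is captured, mirroring a
  transducer's physical signal path.
* :func:`simulate_trial_table` draws analysis-table responses from a linear
  mixed model with known fixed-effect coefficients, subject random
  intercepts and residual noise, over the study's trial design (10 subjects
  x prosthesis configurations x speeds 3-7 m/s) or any user design.

Both are deterministic under their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Union

import numpy as np
import pandas as pd

from . import reference
from .gaitmetrics import METRICS, STANDARD_GRAVITY, symmetry_index
from .sigproc import AFFECTED, UNAFFECTED, GrfTrial, MarkerTrial

__all__ = [
    "SimStepParams",
    "SimTrialConfig",
    "SimTruth",
    "LmmSimConfig",
    "simulate_trial",
    "simulate_trial_table",
]

#: marker height (m) during the marker's own stance
_MARKER_STANCE_Z = 0.05
#: additional marker height at mid-swing
_MARKER_SWING_RISE = 0.10


@dataclass
class SimStepParams:
    """Timing and peak parameters of one simulated step."""

    leg: str
    t_c: float  # contact time, s
    t_a: float  # subsequent aerial time, s
    peak_scale: Optional[float] = None  # F_peak / body weight; None -> impulse balance

    def __post_init__(self) -> None:
        if self.t_c <= 0 or self.t_a < 0 or self.t_c + self.t_a <= 0:
            raise ValueError("need t_c > 0, t_a >= 0")
        duty = self.t_c / (self.t_c + self.t_a)
        if not 0 < duty <= 1:
            raise ValueError("duty factor must lie in (0, 1]")


@dataclass
class Asymmetry:
    """Fractional between-leg offsets: unaffected leg x(1+d), affected x(1-d)."""

    t_c: float = 0.0
    t_a: float = 0.0
    peak: float = 0.0

    def factor(self, leg: str, which: str) -> float:
        d = getattr(self, which)
        return 1.0 + d if leg == UNAFFECTED else 1.0 - d


@dataclass
class SimTrialConfig:
    """Configuration of one synthetic constant-speed trial.

    ``base_t_c``/``base_t_a`` are the leg-averaged contact and aerial times;
    ``asymmetry`` splits them (and the stance peak) multiplicatively between
    legs.  ``n_steps`` defaults to 16, the trial-success criterion of the
    study protocol (16 consecutive steps holding position on the belt).
    """

    belt_speed: float = 3.0  # m/s
    body_mass: float = 76.0  # kg
    gravity: float = STANDARD_GRAVITY
    sample_rate_force: float = 1000.0
    sample_rate_marker: float = 200.0
    n_steps: int = 16
    base_t_c: float = 0.2  # s
    base_t_a: float = 0.12  # s
    peak_scale: Optional[float] = None
    asymmetry: Asymmetry = field(default_factory=Asymmetry)
    noise_sd: float = 0.0  # N
    drift: str = "none"  # none | linear | sinusoidal
    drift_amplitude: float = 0.0  # N
    saturation_level: Optional[float] = None  # N
    first_leg: str = AFFECTED
    pad: float = 0.3  # leading/trailing aerial padding, s
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sample_rate_force <= 0 or self.sample_rate_marker <= 0:
            raise ValueError("sample rates must be > 0")
        if self.n_steps < 2:
            raise ValueError("n_steps must be >= 2")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.drift not in ("none", "linear", "sinusoidal"):
            raise ValueError(f"unknown drift kind {self.drift!r}")
        if self.saturation_level is not None and (
            self.saturation_level < self.body_mass * self.gravity
        ):
            raise ValueError(
                "saturation_level below body weight would clip the whole stance; "
                "signal would be unusable"
            )


@dataclass
class SimTruth:
    """Ground truth captured before noise, drift and saturation.

    ``per_step`` has one row per step (columns: step, leg, t_c, t_a,
    f_step_hz, contact_length_m, favg_bw, t_touchdown_s); ``leg_means`` maps
    leg -> metric -> trial mean; ``si`` maps metric -> symmetry index (%).
    Metric keys are ``contact_length``, ``favg``, ``fstep``.
    """

    steps: list[SimStepParams]
    per_step: pd.DataFrame
    leg_means: dict
    si: dict


def _step_sequence(cfg: SimTrialConfig) -> list[SimStepParams]:
    legs = [AFFECTED, UNAFFECTED] if cfg.first_leg == AFFECTED else [UNAFFECTED, AFFECTED]
    steps = []
    for i in range(cfg.n_steps):
        leg = legs[i % 2]
        steps.append(
            SimStepParams(
                leg=leg,
                t_c=cfg.base_t_c * cfg.asymmetry.factor(leg, "t_c"),
                t_a=cfg.base_t_a * cfg.asymmetry.factor(leg, "t_a"),
                peak_scale=cfg.peak_scale,
            )
        )
    return steps


def _peak_force(step: SimStepParams, cfg: SimTrialConfig) -> float:
    """Stance peak in N: impulse balance unless peak_scale overrides."""
    bw = cfg.body_mass * cfg.gravity
    if step.peak_scale is None:
        base = (np.pi / 2.0) * bw * (step.t_c + step.t_a) / step.t_c
    else:
        base = step.peak_scale * bw
    return base * cfg.asymmetry.factor(step.leg, "peak")


def simulate_trial(
    cfg: SimTrialConfig,
) -> tuple[GrfTrial, MarkerTrial, SimTruth]:
    """Generate one synthetic trial: force signal, marker traces and truth."""
    if cfg.base_t_c * min(
        cfg.asymmetry.factor(AFFECTED, "t_c"), cfg.asymmetry.factor(UNAFFECTED, "t_c")
    ) < 4.0 / cfg.sample_rate_force:
        raise ValueError("t_c shorter than 4 force samples cannot be simulated")

    steps = _step_sequence(cfg)
    bw = cfg.body_mass * cfg.gravity

    # stance start times on a continuous timeline
    t = cfg.pad
    touchdowns, takeoffs, peaks = [], [], []
    for step in steps:
        touchdowns.append(t)
        takeoffs.append(t + step.t_c)
        peaks.append(_peak_force(step, cfg))
        t += step.t_c + step.t_a
    duration = t + cfg.pad

    # --- truth (captured before noise / drift / saturation) ---
    truth_rows = []
    for i, step in enumerate(steps):
        favg_bw = (2.0 / np.pi) * peaks[i] / bw  # mean of the half-sine
        truth_rows.append(
            {
                "step": i,
                "leg": step.leg,
                "t_c": step.t_c,
                "t_a": step.t_a,
                "f_step_hz": 1.0 / (step.t_c + step.t_a),
                "contact_length_m": cfg.belt_speed * step.t_c,
                "favg_bw": favg_bw,
                "t_touchdown_s": touchdowns[i],
            }
        )
    per_step = pd.DataFrame(truth_rows)
    col = {"contact_length": "contact_length_m", "favg": "favg_bw", "fstep": "f_step_hz"}
    leg_means = {
        leg: {
            m: float(per_step.loc[per_step["leg"] == leg, col[m]].mean()) for m in METRICS
        }
        for leg in (AFFECTED, UNAFFECTED)
    }
    si = {
        m: symmetry_index(leg_means[UNAFFECTED][m], leg_means[AFFECTED][m]) for m in METRICS
    }
    truth = SimTruth(steps=steps, per_step=per_step, leg_means=leg_means, si=si)

    # --- force signal ---
    n_force = int(round(duration * cfg.sample_rate_force))
    tf = np.arange(n_force) / cfg.sample_rate_force
    force = np.zeros(n_force)
    # the half-sine is evaluated at a half-sample phase offset: a touchdown
    # falls between samples in general, and this keeps the discrete bump
    # time-symmetric instead of grid-aligned at one edge
    half_dt = 0.5 / cfg.sample_rate_force
    for td, to, pk, step in zip(touchdowns, takeoffs, peaks, steps):
        in_stance = (tf >= td) & (tf < to)
        force[in_stance] = pk * np.sin(
            np.pi * (tf[in_stance] - td + half_dt) / step.t_c
        )

    rng = np.random.default_rng(cfg.seed)
    if cfg.noise_sd > 0:
        force = force + rng.normal(0.0, cfg.noise_sd, size=n_force)
    if cfg.drift == "linear" and cfg.drift_amplitude:
        force = force + cfg.drift_amplitude * tf / duration
    elif cfg.drift == "sinusoidal" and cfg.drift_amplitude:
        force = force + cfg.drift_amplitude * np.sin(2.0 * np.pi * tf / duration)
    if cfg.saturation_level is not None:
        force = np.minimum(force, cfg.saturation_level)

    grf = GrfTrial(
        force=force,
        sample_rate=cfg.sample_rate_force,
        body_mass=cfg.body_mass,
        belt_speed=cfg.belt_speed,
    )

    # --- markers: low and flat during own stance, sinusoidal arc in swing ---
    n_marker = int(round(duration * cfg.sample_rate_marker))
    tm = np.arange(n_marker) / cfg.sample_rate_marker
    traces = {}
    for leg in (AFFECTED, UNAFFECTED):
        z = np.full(n_marker, _MARKER_STANCE_Z + _MARKER_SWING_RISE)
        own = [i for i, s in enumerate(steps) if s.leg == leg]
        for i in own:
            z[(tm >= touchdowns[i]) & (tm < takeoffs[i])] = _MARKER_STANCE_Z
        for a, b in zip(own, own[1:]):  # swing between consecutive own stances
            swing = (tm >= takeoffs[a]) & (tm < touchdowns[b])
            phase = (tm[swing] - takeoffs[a]) / (touchdowns[b] - takeoffs[a])
            z[swing] = _MARKER_STANCE_Z + _MARKER_SWING_RISE * np.sin(np.pi * phase)
        traces[leg] = z
    markers = MarkerTrial(
        affected=traces[AFFECTED],
        unaffected=traces[UNAFFECTED],
        sample_rate=cfg.sample_rate_marker,
    )
    return grf, markers, truth


# ---------------------------------------------------------------------------
# analysis-table simulation for the mixed-model stage


@dataclass
class LmmSimConfig:
    """Configuration of a synthetic analysis table with known coefficients.

    ``coefficients`` maps response column name -> {term name -> true value};
    term names must match the design-matrix columns (``intercept``,
    ``model [Sprinter]`` ... ``height [cm]*speed [m s^-1]``; reference
    levels Catapult and the -1 stiffness category).  Responses not listed
    are generated with all-zero coefficients.  ``design`` is a covariate
    table (subject, rsp_model, stiffness_cat, height_offset_cm, speed_mps);
    by default the emulated study design (10 subjects, 704 trials).
    """

    coefficients: dict = field(default_factory=dict)
    n_subjects: int = 10
    design: Optional[pd.DataFrame] = None
    subject_sd: Union[float, dict] = 0.0
    residual_sd: Union[float, dict] = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for sd in (self.subject_sd, self.residual_sd):
            vals = sd.values() if isinstance(sd, dict) else [sd]
            if any(v < 0 for v in vals):
                raise ValueError("subject_sd and residual_sd must be >= 0")


#: the six canonical response columns of the analysis table
RESPONSES = (
    "al_contact_length_m",
    "al_favg_bw",
    "al_fstep_hz",
    "si_contact_length_pct",
    "si_favg_pct",
    "si_fstep_pct",
)


def _sd_for(sd: Union[float, dict], response: str) -> float:
    return float(sd.get(response, 0.0)) if isinstance(sd, dict) else float(sd)


def simulate_trial_table(cfg: LmmSimConfig) -> pd.DataFrame:
    """Draw an analysis table from a known linear mixed model.

    Each response is the design-row linear predictor under treatment coding
    (references: Catapult model, -1 stiffness category) plus a subject
    random intercept and residual noise.  Deterministic under ``cfg.seed``.
    """
    from .asymstats import TERMS, build_design  # late import avoids a cycle

    if cfg.design is not None:
        design = cfg.design.copy()
    else:
        design = reference.study_design_rows()
        design = design[design["subject"] <= cfg.n_subjects].reset_index(drop=True)

    for resp, beta in cfg.coefficients.items():
        if resp not in RESPONSES:
            raise ValueError(f"unknown response name {resp!r}")
        for term in beta:
            if term not in TERMS:
                raise ValueError(f"unknown coefficient term name {term!r}")

    X = build_design(design)  # DataFrame with TERMS columns
    rng = np.random.default_rng(cfg.seed)
    subjects = sorted(design["subject"].unique())
    out = design.copy()
    for resp in RESPONSES:
        beta = cfg.coefficients.get(resp, {})
        bvec = np.array([beta.get(term, 0.0) for term in TERMS])
        mu = X.to_numpy() @ bvec
        ssd = _sd_for(cfg.subject_sd, resp)
        rsd = _sd_for(cfg.residual_sd, resp)
        intercepts = dict(zip(subjects, rng.normal(0.0, ssd, size=len(subjects))))
        b = out["subject"].map(intercepts).to_numpy() if ssd > 0 else 0.0
        eps = rng.normal(0.0, rsd, size=len(out)) if rsd > 0 else 0.0
        out[resp] = mu + b + eps
    # non-response TrialRow columns kept for format completeness
    out["excluded"] = False
    return out
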