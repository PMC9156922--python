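"""Conditioning and event detection for treadmill vertical ground-reaction-force signals.

The raw observable is one trial's vertical GRF sampled uniformly (typically
1000 Hz) while a subject runs at constant belt speed.  This module

* removes slow force-transducer baseline drift using the aerial phases of the
  signal itself (during flight the true vertical force is zero, so whatever
  the transducer reports there *is* the baseline);
* applies the conventional zero-phase fourth-order Butterworth low-pass
  (30 Hz for force, 6 Hz for marker trajectories);
* segments the signal into stance phases with a 20 N threshold, with
  hysteresis-style debouncing against filter ringing; and
* labels each stance with the leg in contact, using the vertical positions of
  markers on the foot and on the distal end of the running-specific
  prosthesis (the leg whose marker sits lowest during a stance is the leg on
  the belt).

Conventions: 0-based sample indices, half-open stance intervals
``[touchdown, takeoff)``, seconds and newtons throughout.  Threshold
comparison is ``>=`` on entry and ``<`` on exit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
from scipy import signal as _sps

__all__ = [
    "GrfTrial",
    "MarkerTrial",
    "StanceEvent",
    "TrialQC",
    "lowpass",
    "lowpass_trial",
    "correct_drift",
    "detect_stance",
    "assign_legs",
    "is_saturated",
    "DriftError",
    "AFFECTED",
    "UNAFFECTED",
    "UNKNOWN",
]

logger = logging.getLogger(__name__)

AFFECTED = "affected"
UNAFFECTED = "unaffected"
UNKNOWN = "unknown"

#: default force threshold (N) separating stance from flight
CONTACT_THRESHOLD_N = 20.0
#: shortest believable stance at the fastest analysed speeds
MIN_CONTACT_S = 0.05
#: shortest believable aerial phase; sub-threshold dips shorter than this are
#: treated as noise inside a stance
MIN_AERIAL_S = 0.02


class DriftError(ValueError):
    """Raised when no aerial baseline is available for drift correction."""


@dataclass
class GrfTrial:
    """One trial's vertical GRF signal plus acquisition metadata.

    ``force`` is in newtons, uniformly sampled at ``sample_rate`` Hz.
    ``height_offset_cm`` is the prosthesis height relative to the
    recommended height (signed; non-integer offsets occur when a subject's
    residual-limb length limited the adjustment).
    """

    force: np.ndarray
    sample_rate: float
    body_mass: float
    belt_speed: float
    subject: str = ""
    rsp_model: str = ""
    stiffness_cat: str = ""
    height_offset_cm: float = 0.0

    def __post_init__(self) -> None:
        self.force = np.asarray(self.force, dtype=float)
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be > 0")
        if self.body_mass <= 0:
            raise ValueError("body_mass must be > 0")
        if self.belt_speed <= 0:
            raise ValueError("belt_speed must be > 0")

    @property
    def duration(self) -> float:
        return self.force.size / self.sample_rate


@dataclass
class MarkerTrial:
    """Per-leg vertical marker positions (m), time-aligned to the trial start.

    One scalar trace per leg: the foot marker for the unaffected leg and the
    marker on the distal end of the prosthesis for the affected leg.  Sampled
    at its own (usually lower) rate.
    """

    affected: np.ndarray
    unaffected: np.ndarray
    sample_rate: float

    def __post_init__(self) -> None:
        self.affected = np.asarray(self.affected, dtype=float)
        self.unaffected = np.asarray(self.unaffected, dtype=float)
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be > 0")


@dataclass
class StanceEvent:
    """One detected ground contact: ``[touchdown, takeoff)`` in sample indices.

    ``t_a`` is the aerial time from this takeoff to the next touchdown, or
    ``None`` for the final event of a trial.
    """

    touchdown: int
    takeoff: int
    leg: str = UNKNOWN
    t_c: float = 0.0
    t_a: Optional[float] = None

    def __post_init__(self) -> None:
        if self.takeoff <= self.touchdown:
            raise ValueError("takeoff must be after touchdown")


@dataclass
class TrialQC:
    """Per-trial quality-control summary emitted by the detection stage."""

    n_events: int = 0
    n_discarded_bursts: int = 0
    n_merged_gaps: int = 0
    n_edge_discarded: int = 0
    saturated: bool = False
    notes: list = field(default_factory=list)


def lowpass(x: np.ndarray, cutoff: float, sample_rate: float, order: int = 4) -> np.ndarray:
    """Zero-phase Butterworth low-pass filter.

    The filter is applied forward and backward (``filtfilt``) so event
    timings are not shifted; the effective magnitude response is the squared
    ``order``-th order Butterworth. DC gain is exactly 1.
    """
    if cutoff >= sample_rate / 2:
        raise ValueError(
            f"cutoff {cutoff} Hz must be below the Nyquist frequency {sample_rate / 2} Hz"
        )
    if cutoff <= 0:
        raise ValueError("cutoff must be > 0")
    b, a = _sps.butter(order, cutoff, btype="low", fs=sample_rate)
    return _sps.filtfilt(b, a, np.asarray(x, dtype=float))


def lowpass_trial(trial: GrfTrial, cutoff: float = 30.0, order: int = 4) -> GrfTrial:
    """Return a copy of the trial with its force signal low-pass filtered."""
    return replace(trial, force=lowpass(trial.force, cutoff, trial.sample_rate, order))


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Half-open [start, stop) index ranges where a boolean mask is True."""
    if mask.size == 0:
        return []
    padded = np.concatenate(([False], mask, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    return list(zip(edges[::2], edges[1::2]))


def _aerial_runs(
    force: np.ndarray, sample_rate: float, threshold: float, min_aerial: float
) -> list[tuple[int, int]]:
    min_len = max(1, int(round(min_aerial * sample_rate)))
    return [(a, b) for a, b in _runs(force < threshold) if b - a >= min_len]


def correct_drift(
    trial: GrfTrial,
    threshold: float = CONTACT_THRESHOLD_N,
    min_aerial: float = MIN_AERIAL_S,
) -> GrfTrial:
    """Remove slow transducer baseline drift using aerial-phase force levels.

    During flight the true vertical force is zero, so the recorded force in
    each aerial phase samples the instrument baseline.  The baseline is
    estimated as the piecewise-linear interpolation through the median force
    of each detected aerial phase, anchored at the phase midpoint and
    extended flat to the signal edges, then subtracted.

    Raises
    ------
    DriftError
        If fewer than two aerial phases are found (a fully saturated or
        non-running signal has no aerial baseline to estimate).
    """
    force = trial.force
    aerial = _aerial_runs(force, trial.sample_rate, threshold, min_aerial)
    if len(aerial) < 2:
        raise DriftError(
            "no aerial baseline available: found "
            f"{len(aerial)} aerial phase(s), need at least 2"
        )
    anchors_x = np.array([(a + b - 1) / 2.0 for a, b in aerial])
    anchors_y = np.array([np.median(force[a:b]) for a, b in aerial])
    baseline = np.interp(np.arange(force.size), anchors_x, anchors_y)
    return replace(trial, force=force - baseline)


def detect_stance(
    trial: GrfTrial,
    threshold: float = CONTACT_THRESHOLD_N,
    min_contact: float = MIN_CONTACT_S,
    min_aerial: float = MIN_AERIAL_S,
    qc: Optional[TrialQC] = None,
) -> list[StanceEvent]:
    """Segment a (conditioned) force signal into stance events.

    A stance starts at the first sample ``>= threshold`` after an aerial
    phase and ends before the first sample ``< threshold``.  Two debounce
    rules reject noise: sub-threshold dips shorter than ``min_aerial`` are
    merged into the surrounding stance, and supra-threshold bursts shorter
    than ``min_contact`` are discarded.  Stances touching either signal edge
    are incomplete and discarded.  Aerial time ``t_a`` is measured from each
    takeoff to the next touchdown; the final event has ``t_a = None``.

    An empty signal or one with no threshold crossings yields an empty list;
    the caller decides whether that constitutes a failed trial.
    """
    force = trial.force
    fs = trial.sample_rate
    if qc is None:
        qc = TrialQC()
    if force.size == 0:
        return []

    runs = _runs(force >= threshold)
    if not runs:
        return []

    # merge stances separated by sub-min_aerial gaps (mid-stance dips)
    gap_len = max(1, int(round(min_aerial * fs)))
    merged: list[list[int]] = []
    for a, b in runs:
        if merged and a - merged[-1][1] < gap_len:
            merged[-1][1] = b
            qc.n_merged_gaps += 1
        else:
            merged.append([a, b])

    # discard too-short bursts (filter ringing, spikes)
    contact_len = max(1, int(round(min_contact * fs)))
    kept = []
    for a, b in merged:
        if b - a >= contact_len:
            kept.append((a, b))
        else:
            qc.n_discarded_bursts += 1

    # discard incomplete stances at the signal edges
    complete = []
    for a, b in kept:
        if a == 0 or b == force.size:
            qc.n_edge_discarded += 1
        else:
            complete.append((a, b))

    events: list[StanceEvent] = []
    for i, (a, b) in enumerate(complete):
        t_a = (complete[i + 1][0] - b) / fs if i + 1 < len(complete) else None
        events.append(StanceEvent(touchdown=a, takeoff=b, t_c=(b - a) / fs, t_a=t_a))
    qc.n_events = len(events)
    return events


def assign_legs(
    events: list[StanceEvent],
    markers: Optional[MarkerTrial],
    force_sample_rate: float,
    fallback_first_leg: str = AFFECTED,
) -> list[StanceEvent]:
    """Label each stance with the leg in contact.

    For each stance the per-leg marker traces are averaged over the stance
    interval (marker samples nearest-matched to force time); the leg whose
    marker is lowest is on the belt.  Running steps alternate legs, so a
    marker-based label equal to the previous event's label is treated as a
    violation: the event is labelled ``unknown`` and a warning is logged.

    With no marker data at all, labels fall back to strict alternation
    seeded by ``fallback_first_leg``.
    """
    if markers is None:
        out = []
        legs = (
            [AFFECTED, UNAFFECTED]
            if fallback_first_leg == AFFECTED
            else [UNAFFECTED, AFFECTED]
        )
        for i, ev in enumerate(events):
            out.append(replace(ev, leg=legs[i % 2]))
        return out

    ratio = markers.sample_rate / force_sample_rate
    n_marker = min(markers.affected.size, markers.unaffected.size)
    out = []
    prev_leg: Optional[str] = None
    for ev in events:
        lo = int(round(ev.touchdown * ratio))
        hi = int(round(ev.takeoff * ratio))
        hi = max(hi, lo + 1)
        if lo >= n_marker:
            out.append(replace(ev, leg=UNKNOWN))
            logger.warning(
                "no marker data for stance [%d, %d); leg unknown", ev.touchdown, ev.takeoff
            )
            continue
        hi = min(hi, n_marker)
        mean_aff = float(np.mean(markers.affected[lo:hi]))
        mean_unaff = float(np.mean(markers.unaffected[lo:hi]))
        leg = AFFECTED if mean_aff < mean_unaff else UNAFFECTED
        if prev_leg is not None and leg == prev_leg:
            logger.warning(
                "alternation violation at stance [%d, %d): marker resolves to %s twice; "
                "labelling unknown",
                ev.touchdown,
                ev.takeoff,
                leg,
            )
            out.append(replace(ev, leg=UNKNOWN))
            prev_leg = None
            continue
        out.append(replace(ev, leg=leg))
        prev_leg = leg
    return out


def is_saturated(force: np.ndarray, saturation_level: Optional[float], min_run: int = 3) -> bool:
    """True if the signal sits at the saturation ceiling for >= min_run samples.

    Saturated trials are flagged and excluded from aggregation rather than
    analysed, since clipped stance peaks bias the stance-average force.
    """
    if saturation_level is None:
        return False
    at_ceiling = np.asarray(force) >= saturation_level - 1e-9
    return any(b - a >= min_run for a, b in _runs(at_ceiling))
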