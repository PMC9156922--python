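"""End-to-end processing of one raw trial: conditioning -> events -> metrics.

Order of operations: saturation screening on the raw signal, baseline
drift correction from aerial phases, 20 N stance detection on the
drift-corrected (unfiltered) force, zero-phase low-pass filtering (force
30 Hz, markers 6 Hz) for the force values entering the metrics,
marker-based leg labelling, per-step metrics and trial aggregation.

Stance edges are detected on the unfiltered signal because the zero-phase
30 Hz Butterworth spreads the stance flanks by roughly 3 ms on each side,
which biases a 20 N threshold crossing outward by ~3 samples at 1000 Hz;
on the raw signal the crossing sits within one sample of the analytic
half-sine solution.  F_avg uses the filtered samples within the detected
stance, consistent with filtering force before computing metrics.
"""

from __future__ import annotations

from typing import Optional

from .gaitmetrics import StepRecord, TrialRow, aggregate_trial, step_metrics
from .io import RunConfig
from .sigproc import (
    GrfTrial,
    MarkerTrial,
    StanceEvent,
    TrialQC,
    assign_legs,
    correct_drift,
    detect_stance,
    is_saturated,
    lowpass,
    lowpass_trial,
)

__all__ = ["process_trial", "trial_to_row"]


def process_trial(
    trial: GrfTrial,
    markers: Optional[MarkerTrial] = None,
    config: Optional[RunConfig] = None,
    saturation_level: Optional[float] = None,
) -> tuple[list[StanceEvent], list[StepRecord], TrialQC]:
    """Run the signal path on one trial.

    Returns the labelled stance events, per-step metrics and a QC record.
    A saturated trial is flagged and returned with no events or steps; the
    caller excludes it from aggregation.
    """
    cfg = config or RunConfig()
    qc = TrialQC()
    level = saturation_level if saturation_level is not None else cfg.saturation_level_n
    if is_saturated(trial.force, level):
        qc.saturated = True
        qc.notes.append("force signal saturated; trial excluded")
        return [], [], qc

    corrected = correct_drift(trial, threshold=cfg.threshold_n, min_aerial=cfg.min_aerial_s)
    filtered = lowpass_trial(corrected, cutoff=cfg.force_cutoff_hz, order=cfg.filter_order)
    events = detect_stance(
        corrected,
        threshold=cfg.threshold_n,
        min_contact=cfg.min_contact_s,
        min_aerial=cfg.min_aerial_s,
        qc=qc,
    )
    if markers is not None:
        markers = MarkerTrial(
            affected=lowpass(markers.affected, cfg.marker_cutoff_hz, markers.sample_rate,
                             cfg.filter_order),
            unaffected=lowpass(markers.unaffected, cfg.marker_cutoff_hz, markers.sample_rate,
                               cfg.filter_order),
            sample_rate=markers.sample_rate,
        )
    events = assign_legs(events, markers, trial.sample_rate)
    steps = step_metrics(events, filtered, g=cfg.g) if events else []
    return events, steps, qc


def trial_to_row(
    trial: GrfTrial, steps: list[StepRecord], config: Optional[RunConfig] = None
) -> TrialRow:
    """Aggregate one processed trial into an analysis-table row."""
    cfg = config or RunConfig()
    return aggregate_trial(
        steps,
        subject=trial.subject,
        rsp_model=trial.rsp_model,
        stiffness_cat=trial.stiffness_cat,
        height_offset_cm=trial.height_offset_cm,
        speed_mps=trial.belt_speed,
        window=cfg.window,
        min_steps_per_leg=cfg.min_steps_per_leg,
    )
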