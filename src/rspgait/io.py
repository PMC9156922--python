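"""File formats and run configuration.

Three delimited-text formats tie the pipeline stages together:

* **raw trial files** — ``#``-prefixed ``key = value`` metadata lines
  followed by a delimited table with a ``force_n`` column (and optional
  ``marker_affected_m`` / ``marker_unaffected_m`` columns at their own,
  lower sample rate: marker values appear every ``force_rate/marker_rate``-th
  row, other cells empty).  Comma or tab delimited, auto-detected.
* **step files** — the same metadata header plus one row per detected step.
* **analysis tables** — plain CSV, one trial per row, canonical column
  names (see :data:`CANONICAL_COLUMNS`); arbitrary source headers (e.g. a
  deposited supplementary table) are accepted through a user-supplied
  column mapping, and category labels are normalised (typographic minus,
  case) on ingestion.

Values are written at full float precision so every write→read round trip
is exact.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
import yaml

from .gaitmetrics import StepRecord, TrialRow
from .sigproc import GrfTrial, MarkerTrial

__all__ = [
    "RunConfig",
    "write_raw_trial",
    "read_raw_trial",
    "write_steps",
    "read_steps",
    "write_analysis_table",
    "read_analysis_table",
    "rows_to_frame",
    "CANONICAL_COLUMNS",
]

logger = logging.getLogger(__name__)

_REQUIRED_META = (
    "subject",
    "rsp_model",
    "stiffness_cat",
    "height_offset_cm",
    "speed_mps",
    "body_mass_kg",
    "sample_rate_hz",
)

#: canonical analysis-table columns (covariates, per-leg means, symmetry indices)
CANONICAL_COLUMNS = (
    "subject",
    "rsp_model",
    "stiffness_cat",
    "height_offset_cm",
    "speed_mps",
    "al_contact_length_m",
    "ul_contact_length_m",
    "al_favg_bw",
    "ul_favg_bw",
    "al_fstep_hz",
    "ul_fstep_hz",
    "si_contact_length_pct",
    "si_favg_pct",
    "si_fstep_pct",
)

_REQUIRED_TABLE = (
    "subject",
    "rsp_model",
    "stiffness_cat",
    "height_offset_cm",
    "speed_mps",
    "al_contact_length_m",
    "al_favg_bw",
    "al_fstep_hz",
    "si_contact_length_pct",
    "si_favg_pct",
    "si_fstep_pct",
)

_MODEL_ALIASES = {"catapult": "Catapult", "sprinter": "Sprinter", "xtend": "Xtend"}
_STIFFNESS_ALIASES = {
    "-1": "-1",
    "rec": "Rec",
    "recommended": "Rec",
    "0": "Rec",
    "+1": "+1",
    "1": "+1",
}


@dataclass
class RunConfig:
    """Pipeline settings; defaults are the study's processing constants.

    30 Hz / 6 Hz fourth-order zero-phase Butterworth cut-offs for force and
    markers, a 20 N contact threshold, debounce windows for stance
    detection, the 16-step analysis window and g for body-weight
    normalisation.  Loadable from a YAML file whose keys are exactly these
    field names; unknown keys are rejected.
    """

    force_cutoff_hz: float = 30.0
    marker_cutoff_hz: float = 6.0
    filter_order: int = 4
    threshold_n: float = 20.0
    min_contact_s: float = 0.05
    min_aerial_s: float = 0.02
    window: Union[int, str] = 16
    min_steps_per_leg: int = 4
    g: float = 9.81
    seed: int = 0
    allowed_speeds: Sequence[float] = (3.0, 4.0, 5.0, 6.0, 7.0)
    column_mapping: Mapping[str, str] = field(default_factory=dict)
    saturation_level_n: Optional[float] = None
    log_level: str = "info"

    def __post_init__(self) -> None:
        for name in ("force_cutoff_hz", "marker_cutoff_hz", "threshold_n"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.filter_order < 1:
            raise ValueError("filter_order must be >= 1")
        if self.window != "all" and int(self.window) < 1:
            raise ValueError('window must be a positive step count or "all"')
        if self.log_level not in ("debug", "info", "warn", "warning"):
            raise ValueError(f"unknown log_level {self.log_level!r}")
        self.allowed_speeds = tuple(float(v) for v in self.allowed_speeds)
        self.column_mapping = dict(self.column_mapping)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path) -> None:
        data = asdict(self)
        data["allowed_speeds"] = list(self.allowed_speeds)
        data["column_mapping"] = dict(self.column_mapping)
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))


def _fmt(x: float) -> str:
    return format(float(x), ".17g")


def _detect_delimiter(line: str) -> str:
    return "\t" if "\t" in line else ","


def _meta_lines(meta: Mapping[str, object]) -> list[str]:
    return [f"# {k} = {v}" for k, v in meta.items()]


def write_raw_trial(
    path,
    trial: GrfTrial,
    markers: Optional[MarkerTrial] = None,
    delimiter: str = ",",
    saturation_level: Optional[float] = None,
) -> None:
    """Write one trial (and optional markers) as a delimited-text file."""
    meta = {
        "subject": trial.subject,
        "rsp_model": trial.rsp_model,
        "stiffness_cat": trial.stiffness_cat,
        "height_offset_cm": _fmt(trial.height_offset_cm),
        "speed_mps": _fmt(trial.belt_speed),
        "body_mass_kg": _fmt(trial.body_mass),
        "sample_rate_hz": _fmt(trial.sample_rate),
    }
    stride = None
    if markers is not None:
        ratio = trial.sample_rate / markers.sample_rate
        stride = int(round(ratio))
        if abs(ratio - stride) > 1e-9:
            raise ValueError("force sample rate must be an integer multiple of marker rate")
        meta["marker_sample_rate_hz"] = _fmt(markers.sample_rate)
    if saturation_level is not None:
        meta["saturation_level_n"] = _fmt(saturation_level)

    lines = _meta_lines(meta)
    header = ["force_n"]
    if markers is not None:
        header += ["marker_affected_m", "marker_unaffected_m"]
    lines.append(delimiter.join(header))
    n_marker = 0 if markers is None else min(markers.affected.size, markers.unaffected.size)
    for i, f in enumerate(trial.force):
        row = [_fmt(f)]
        if markers is not None:
            j = i // stride
            if i % stride == 0 and j < n_marker:
                row += [_fmt(markers.affected[j]), _fmt(markers.unaffected[j])]
            else:
                row += ["", ""]
        lines.append(delimiter.join(row))
    Path(path).write_text("\n".join(lines) + "\n")


def _parse_header(path) -> tuple[dict, list[str], int]:
    meta: dict = {}
    lines = Path(path).read_text().splitlines()
    i = 0
    for i, line in enumerate(lines):
        if not line.startswith("#"):
            break
        key, _, value = line[1:].partition("=")
        meta[key.strip()] = value.strip()
    return meta, lines, i


def read_raw_trial(path) -> tuple[GrfTrial, Optional[MarkerTrial], dict]:
    """Parse a raw trial file -> (GrfTrial, MarkerTrial or None, metadata dict)."""
    meta, lines, first = _parse_header(path)
    for key in _REQUIRED_META:
        if key not in meta:
            raise ValueError(f"missing metadata: {key}")
    delim = _detect_delimiter(lines[first])
    header = lines[first].split(delim)
    try:
        force_col = header.index("force_n")
    except ValueError:
        raise ValueError(f"{path}: no force_n column in header {header}")
    has_markers = "marker_affected_m" in header
    force, m_aff, m_unaff = [], [], []
    for lineno, line in enumerate(lines[first + 1 :], start=first + 2):
        if not line.strip():
            continue
        cells = line.split(delim)
        try:
            force.append(float(cells[force_col]))
        except (ValueError, IndexError):
            raise ValueError(f"{path}:{lineno}: non-numeric force sample {cells!r}")
        if has_markers:
            a = cells[header.index("marker_affected_m")]
            u = cells[header.index("marker_unaffected_m")]
            if a.strip():
                m_aff.append(float(a))
                m_unaff.append(float(u))
    trial = GrfTrial(
        force=np.array(force),
        sample_rate=float(meta["sample_rate_hz"]),
        body_mass=float(meta["body_mass_kg"]),
        belt_speed=float(meta["speed_mps"]),
        subject=meta["subject"],
        rsp_model=meta["rsp_model"],
        stiffness_cat=meta["stiffness_cat"],
        height_offset_cm=float(meta["height_offset_cm"]),
    )
    markers = None
    if has_markers and m_aff:
        if "marker_sample_rate_hz" not in meta:
            raise ValueError("missing metadata: marker_sample_rate_hz")
        markers = MarkerTrial(
            affected=np.array(m_aff),
            unaffected=np.array(m_unaff),
            sample_rate=float(meta["marker_sample_rate_hz"]),
        )
    logger.debug("%s: %d force samples, delimiter %r", path, len(force), delim)
    return trial, markers, meta


_STEP_COLUMNS = ("leg", "t_c_s", "t_a_s", "f_step_hz", "L_step_m", "L_c_m", "F_avg_bw")


def write_steps(path, steps: Sequence[StepRecord], trial: GrfTrial) -> None:
    """Write per-step metrics with the trial's metadata header."""
    meta = {
        "subject": trial.subject,
        "rsp_model": trial.rsp_model,
        "stiffness_cat": trial.stiffness_cat,
        "height_offset_cm": _fmt(trial.height_offset_cm),
        "speed_mps": _fmt(trial.belt_speed),
        "body_mass_kg": _fmt(trial.body_mass),
        "sample_rate_hz": _fmt(trial.sample_rate),
    }
    lines = _meta_lines(meta)
    lines.append(",".join(_STEP_COLUMNS))
    for s in steps:
        lines.append(
            ",".join(
                [s.leg]
                + [_fmt(v) for v in (s.t_c, s.t_a, s.f_step, s.L_step, s.L_c, s.F_avg)]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_steps(path) -> tuple[list[StepRecord], dict]:
    """Parse a step file -> (StepRecord list, metadata dict)."""
    meta, lines, first = _parse_header(path)
    header = lines[first].split(",")
    idx = {name: header.index(name) for name in _STEP_COLUMNS}
    steps = []
    for line in lines[first + 1 :]:
        if not line.strip():
            continue
        c = line.split(",")
        steps.append(
            StepRecord(
                leg=c[idx["leg"]],
                t_c=float(c[idx["t_c_s"]]),
                t_a=float(c[idx["t_a_s"]]),
                f_step=float(c[idx["f_step_hz"]]),
                L_step=float(c[idx["L_step_m"]]),
                L_c=float(c[idx["L_c_m"]]),
                F_avg=float(c[idx["F_avg_bw"]]),
            )
        )
    return steps, meta


def rows_to_frame(rows: Iterable[TrialRow]) -> pd.DataFrame:
    """Analysis-table DataFrame from TrialRow records, canonical column order."""
    df = pd.DataFrame([asdict(r) for r in rows])
    order = [c for c in CANONICAL_COLUMNS if c in df.columns] + ["excluded"]
    return df[order]


def write_analysis_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False, float_format="%.17g")


def _normalise_stiffness(value: object, rowno: int) -> str:
    s = str(value).strip().replace("−", "-").replace("–", "-")
    key = s.lower()
    if key not in _STIFFNESS_ALIASES:
        raise ValueError(f"row {rowno}: unknown stiffness category value {value!r}")
    return _STIFFNESS_ALIASES[key]


def _normalise_model(value: object, rowno: int) -> str:
    key = str(value).strip().lower()
    if key not in _MODEL_ALIASES:
        raise ValueError(f"row {rowno}: unknown RSP model value {value!r}")
    return _MODEL_ALIASES[key]


def read_analysis_table(
    path,
    mapping: Optional[Mapping[str, str]] = None,
    allowed_speeds: Optional[Sequence[float]] = (3.0, 4.0, 5.0, 6.0, 7.0),
) -> pd.DataFrame:
    """Read and normalise an analysis table.

    ``mapping`` maps source column names to canonical ones (for tables with
    arbitrary headers).  Categorical labels are normalised — typographic
    minus signs, case — to {Catapult, Sprinter, Xtend} and {-1, Rec, +1}.
    Rows flagged in an ``excluded`` column are dropped, as are rows at
    speeds outside ``allowed_speeds`` (pass ``None`` to keep all); both
    exclusions are logged.
    """
    df = pd.read_csv(path)
    if mapping:
        df = df.rename(columns=dict(mapping))
    missing = [c for c in _REQUIRED_TABLE if c not in df.columns]
    if missing:
        raise ValueError(f"unmappable required column(s): {missing}")
    df["rsp_model"] = [
        _normalise_model(v, i) for i, v in enumerate(df["rsp_model"], start=2)
    ]
    df["stiffness_cat"] = [
        _normalise_stiffness(v, i) for i, v in enumerate(df["stiffness_cat"], start=2)
    ]
    if "excluded" in df.columns:
        flag = (
            df["excluded"]
            .astype(str)
            .str.strip()
            .str.lower()
            .isin(("1", "true", "yes", "1.0"))
        )
        if flag.any():
            logger.info("dropping %d excluded/saturated row(s)", int(flag.sum()))
        df = df[~flag]
    if allowed_speeds is not None:
        keep = df["speed_mps"].astype(float).isin([float(v) for v in allowed_speeds])
        if (~keep).any():
            logger.info(
                "dropping %d row(s) at speeds outside %s",
                int((~keep).sum()),
                list(allowed_speeds),
            )
        df = df[keep]
    return df.reset_index(drop=True)
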