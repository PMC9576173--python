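"""Shared data model, units, and delimited-text readers/writers.

Units follow catheterization-lab convention throughout the package:
pressures in mmHg, volumes in mL, times in seconds from recording start
(intervals reported in ms), stiffness in mmHg/mL.  Body-surface-area
indexing divides a measurement by BSA in m².

File formats are plain comma-separated UTF-8 text with one header row:

* pressure waveform: ``time_s,pressure_mmHg``
* R-wave annotations: ``r_time_s``
* per-beat volume curves: ``beat,time_s,volume_ml`` (beat indices 1..n)
* cohort table: see :data:`COHORT_REQUIRED_COLUMNS` /
  :data:`COHORT_OPTIONAL_COLUMNS`
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

TIME_POINTS = ("T1", "T2", "T3", "T4")
PRESSURE_TIME_POINTS = ("T2", "T3")  # invasive pressure exists post-transseptal only
RHYTHMS = ("paroxysmal", "persistent")


class ValidationError(ValueError):
    """Raised when an input file or object violates a model invariant."""


def _as_float_array(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1:
        raise ValidationError(f"{name} must be one-dimensional, got shape {arr.shape}")
    return arr


@dataclass
class PressureRecording:
    """Raw sampled LA pressure with ECG R-wave annotations.

    The clinical recorder supplies R-wave timing; no QRS detection is
    performed here.  Annotation times must lie within the recording span;
    an out-of-span annotation is an error, never silently clipped.
    """

    patient_id: str
    time_point: str
    sample_rate: float
    samples: np.ndarray
    r_wave_times: np.ndarray

    def __post_init__(self) -> None:
        if self.time_point not in TIME_POINTS:
            raise ValidationError(f"unknown time point {self.time_point!r}")
        if not self.sample_rate > 0:
            raise ValidationError("sample_rate must be positive")
        self.samples = _as_float_array(self.samples, "samples")
        self.r_wave_times = _as_float_array(self.r_wave_times, "r_wave_times")
        if self.samples.size < 2 * self.sample_rate:
            raise ValidationError(
                f"recording too short: {self.samples.size} samples "
                f"< 2 s at {self.sample_rate} Hz"
            )
        bad = np.flatnonzero(~np.isfinite(self.samples))
        if bad.size:
            raise ValidationError(f"non-finite pressure sample at row {bad[0]}")
        if self.r_wave_times.size < 2:
            raise ValidationError("at least 2 R-wave annotations are required")
        if np.any(np.diff(self.r_wave_times) <= 0):
            raise ValidationError("R-wave times must be strictly increasing")
        span = self.duration
        if self.r_wave_times[0] < 0 or self.r_wave_times[-1] > span:
            raise ValidationError(
                f"annotation outside span: R-wave times must lie in [0, {span:.6g}] s"
            )

    @property
    def duration(self) -> float:
        """Recording span in seconds."""
        return (self.samples.size - 1) / self.sample_rate

    @property
    def time(self) -> np.ndarray:
        return np.arange(self.samples.size) / self.sample_rate


@dataclass
class VolumeCurveSet:
    """Per-beat LA volume curves exported from 3-D echo segmentation.

    ``beats`` is a list of ``(times, volumes)`` pairs, one per cardiac
    cycle, times in seconds within the beat, volumes in mL.
    """

    patient_id: str
    time_point: str
    beats: list[tuple[np.ndarray, np.ndarray]]
    volume_rate: float = 20.0

    def __post_init__(self) -> None:
        if self.time_point not in TIME_POINTS:
            raise ValidationError(f"unknown time point {self.time_point!r}")
        if not self.beats:
            raise ValidationError("at least one beat is required")
        checked = []
        for i, (t, v) in enumerate(self.beats):
            t = _as_float_array(t, f"beat {i + 1} times")
            v = _as_float_array(v, f"beat {i + 1} volumes")
            if t.size == 0:
                raise ValidationError(f"beat {i + 1} is empty")
            if t.size != v.size:
                raise ValidationError(f"beat {i + 1}: time/volume length mismatch")
            if np.any(np.diff(t) <= 0):
                raise ValidationError(f"beat {i + 1}: times must be strictly increasing")
            bad = np.flatnonzero(~(v > 0))
            if bad.size:
                raise ValidationError(
                    f"beat {i + 1}: non-positive volume at sample {bad[0]} "
                    f"({v[bad[0]]!r} mL)"
                )
            checked.append((t, v))
        self.beats = checked

    @property
    def n_beats(self) -> int:
        return len(self.beats)


@dataclass
class PatientRecord:
    """One patient's per-time-point data for the four procedural time points.

    Invasive pressure exists only at T2/T3 (after transseptal puncture);
    3-D volume curves exist at T1–T4.
    """

    patient_id: str
    rhythm: str
    bsa: float
    laa_width_max: float
    laa_depth_max: float
    pressure: dict[str, PressureRecording] = field(default_factory=dict)
    volumes: dict[str, VolumeCurveSet] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.rhythm not in RHYTHMS:
            raise ValidationError(f"rhythm must be one of {RHYTHMS}, got {self.rhythm!r}")
        if not self.bsa > 0:
            raise ValidationError("bsa must be positive")
        if not (self.laa_width_max > 0 and self.laa_depth_max > 0):
            raise ValidationError("LAA dimensions must be positive")
        for tp in self.pressure:
            if tp not in PRESSURE_TIME_POINTS:
                raise ValidationError(
                    f"pressure recording at {tp}: invasive pressure exists only at "
                    f"{PRESSURE_TIME_POINTS}"
                )
        for tp in self.volumes:
            if tp not in TIME_POINTS:
                raise ValidationError(f"unknown volume time point {tp!r}")


# ---------------------------------------------------------------------------
# cohort table schema
# ---------------------------------------------------------------------------

COHORT_REQUIRED_COLUMNS = [
    "patient_id",
    "rhythm",
    "bsa_m2",
    "laa_width_cm",
    "laa_depth_cm",
    "laa_width_idx",
    "laa_depth_idx",
    "lap_mean_t2",
    "vmax_idx_t1",
    "stiff_t2",
    "stiff_t3",
    "delta_stiff",
]

COHORT_OPTIONAL_COLUMNS = (
    [f"{v}_{tp.lower()}" for v in ("vmax_idx", "vmin_idx", "tev_idx", "tef") for tp in TIME_POINTS]
    + [
        f"{v}_{tp.lower()}"
        for v in (
            "lap_max",
            "lap_min",
            "v_peak",
            "t_to_v_peak_ms",
            "t_to_v_peak_pct_rr",
            "filling_dpdt",
            "rr_mean_ms",
        )
        for tp in PRESSURE_TIME_POINTS
    ]
    + ["lap_mean_t3", "reservoir_a_t1", "reservoir_k_t1"]
)


def validate_cohort_table(table: pd.DataFrame) -> pd.DataFrame:
    """Validate schema and row invariants of a cohort table.

    Checks: known columns only, all required columns present, unique
    patient ids, valid rhythms, and ``delta_stiff == stiff_t3 - stiff_t2``
    row-wise.
    """
    known = set(COHORT_REQUIRED_COLUMNS) | set(COHORT_OPTIONAL_COLUMNS)
    unknown = [c for c in table.columns if c not in known]
    if unknown:
        raise ValidationError(
            f"unknown cohort column(s) {unknown}; expected a subset of "
            f"{COHORT_REQUIRED_COLUMNS + COHORT_OPTIONAL_COLUMNS}"
        )
    missing = [c for c in COHORT_REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise ValidationError(f"missing required cohort column(s) {missing}")
    if table["patient_id"].duplicated().any():
        dup = table.loc[table["patient_id"].duplicated(), "patient_id"].iloc[0]
        raise ValidationError(f"duplicated patient_id {dup!r}")
    if len(table):
        bad_rhythm = ~table["rhythm"].isin(RHYTHMS)
        if bad_rhythm.any():
            raise ValidationError(
                f"invalid rhythm value {table.loc[bad_rhythm, 'rhythm'].iloc[0]!r}"
            )
        resid = table["delta_stiff"] - (table["stiff_t3"] - table["stiff_t2"])
        if np.any(np.abs(resid.to_numpy(float)) > 1e-9):
            row = int(np.argmax(np.abs(resid.to_numpy(float))))
            raise ValidationError(
                f"delta_stiff != stiff_t3 - stiff_t2 at row {row} "
                f"(patient {table['patient_id'].iloc[row]!r})"
            )
    return table


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

_FLOAT_FMT = "%.17g"  # round-trips IEEE doubles exactly


def _read_csv(path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such file: {path}")
    return pd.read_csv(path, float_precision="round_trip")


def read_pressure_recording(
    waveform_path,
    annotation_path,
    sample_rate: float,
    patient_id: str = "",
    time_point: str = "T2",
) -> PressureRecording:
    """Read a sampled pressure trace and its R-wave annotation file."""
    if not sample_rate > 0:
        raise ValidationError("sample_rate must be positive")
    wf = _read_csv(waveform_path)
    ann = _read_csv(annotation_path)
    for col in ("time_s", "pressure_mmHg"):
        if col not in wf.columns:
            raise ValidationError(f"waveform file missing column {col!r}")
    if "r_time_s" not in ann.columns:
        raise ValidationError("annotation file missing column 'r_time_s'")
    t = wf["time_s"].to_numpy(float)
    if np.any(np.diff(t) <= 0):
        row = int(np.flatnonzero(np.diff(t) <= 0)[0]) + 1
        raise ValidationError(f"non-monotonic time column at row {row}")
    return PressureRecording(
        patient_id=patient_id,
        time_point=time_point,
        sample_rate=sample_rate,
        samples=wf["pressure_mmHg"].to_numpy(float),
        r_wave_times=ann["r_time_s"].to_numpy(float),
    )


def write_pressure_recording(rec: PressureRecording, waveform_path, annotation_path) -> None:
    pd.DataFrame({"time_s": rec.time, "pressure_mmHg": rec.samples}).to_csv(
        waveform_path, index=False, float_format=_FLOAT_FMT
    )
    pd.DataFrame({"r_time_s": rec.r_wave_times}).to_csv(
        annotation_path, index=False, float_format=_FLOAT_FMT
    )


def read_volume_curves(
    path, patient_id: str = "", time_point: str = "T1", volume_rate: float = 20.0
) -> VolumeCurveSet:
    """Read per-beat volume curves; beat indices must be contiguous from 1."""
    df = _read_csv(path)
    for col in ("beat", "time_s", "volume_ml"):
        if col not in df.columns:
            raise ValidationError(f"volume file missing column {col!r}")
    bad = np.flatnonzero(~(df["volume_ml"].to_numpy(float) > 0))
    if bad.size:
        raise ValidationError(
            f"non-positive volume at row {bad[0] + 1} "
            f"({df['volume_ml'].iloc[bad[0]]!r} mL)"
        )
    beat_ids = sorted(df["beat"].unique())
    if beat_ids != list(range(1, len(beat_ids) + 1)):
        raise ValidationError(f"beat indices must be contiguous from 1, got {beat_ids}")
    beats = []
    for b in beat_ids:
        sub = df[df["beat"] == b].sort_values("time_s")
        beats.append((sub["time_s"].to_numpy(float), sub["volume_ml"].to_numpy(float)))
    return VolumeCurveSet(
        patient_id=patient_id, time_point=time_point, beats=beats, volume_rate=volume_rate
    )


def write_volume_curves(vset: VolumeCurveSet, path) -> None:
    frames = [
        pd.DataFrame({"beat": i + 1, "time_s": t, "volume_ml": v})
        for i, (t, v) in enumerate(vset.beats)
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_cohort_table(path) -> pd.DataFrame:
    """Read and validate a cohort table CSV."""
    df = _read_csv(path)
    return validate_cohort_table(df)


def write_cohort_table(table: pd.DataFrame, path) -> None:
    validate_cohort_table(table)
    table.to_csv(path, index=False, float_format=_FLOAT_FMT)


def index_by_bsa(value: float, bsa: float):
    """Index a measurement by body surface area: ``value / bsa`` (per m²)."""
    if np.any(np.asarray(bsa) <= 0):
        raise ValidationError("bsa must be positive")
    return value / bsa
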