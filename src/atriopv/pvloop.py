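"""Pressure-volume loop construction and chamber stiffness dP/dV.

The composite pressure cycle (time-referenced to the R-wave) and the
composite volume cycle (phase-referenced) are resampled to a common
temporal resolution, then the pressure cycle is circularly shifted so the
v-wave peak coincides with the volume maximum -- both mark the instant just
before mitral valve opening, which pins down the echo acquisition's
temporal ambiguity.  Chamber stiffness is the linear slope between the
endpoints of the ascending (reservoir/filling) limb of the resulting loop.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import ValidationError
from .pressure import CompositePressureCycle
from .volume import CompositeVolumeCycle

V_WINDOW = (0.25, 0.90)  # v-peak search window, fraction of cycle


@dataclass
class PVLoop:
    """Temporally aligned pressure-volume pairs over one cycle."""

    pressure: np.ndarray  # mmHg
    volume: np.ndarray  # mL
    applied_shift: float  # ms, circular pressure shift used for alignment
    cycle_length: float  # s
    time_point: str = "T2"
    patient_id: str = ""

    def __post_init__(self) -> None:
        self.pressure = np.asarray(self.pressure, dtype=float)
        self.volume = np.asarray(self.volume, dtype=float)
        if self.pressure.size != self.volume.size:
            raise ValidationError("pressure/volume length mismatch")

    @property
    def n_points(self) -> int:
        return self.pressure.size


@dataclass
class StiffnessResult:
    """Linear stiffness dP/dV over the filling limb endpoints."""

    dpdv: float  # mmHg/mL
    p_start: float
    p_end: float
    v_start: float
    v_end: float
    time_point: str = "T2"
    patient_id: str = ""


def resample_pair(
    pressure_composite: CompositePressureCycle,
    volume_composite: CompositeVolumeCycle,
    n_points: int | None = None,
    min_support_fraction: float = 0.5,
) -> tuple[np.ndarray, np.ndarray]:
    """Interpolate both composites onto ``n_points`` over one cycle.

    The default resolution is one sample per millisecond of the mean
    volume-acquisition cycle length, i.e. ``round(cycle length in ms)``
    points per loop.  The pressure composite is truncated at the support
    floor first, so its span is the representative cycle rather than the
    longest one.
    """
    if n_points is None:
        n_points = int(round(volume_composite.mean_cycle_length * 1e3))
    if n_points < 16:
        raise ValidationError(f"n_points must be >= 16, got {n_points}")
    p_vals = pressure_composite.truncated(min_support_fraction)
    # fractional position within each cycle, endpoint excluded (periodic)
    target = np.arange(n_points) / n_points
    p = np.interp(target, np.arange(p_vals.size) / p_vals.size, p_vals)
    v = np.interp(target, volume_composite.phase_grid, volume_composite.values, period=1.0)
    return p, v


def _windowed_argmax(x: np.ndarray, window: tuple[float, float]) -> int:
    n = x.size
    lo = int(np.ceil(window[0] * n))
    hi = max(lo + 1, int(np.floor(window[1] * n)))
    return lo + int(np.argmax(x[lo:hi]))


def _check_peak_not_degenerate(x: np.ndarray, name: str) -> None:
    # a plateau of near-identical maxima wider than 5% of the cycle makes
    # the alignment ill-posed
    tol = 1e-12 * max(1.0, float(np.ptp(x)))
    at_max = np.abs(x - np.max(x)) <= tol
    # longest contiguous run, circularly
    doubled = np.concatenate([at_max, at_max])
    best = run = 0
    for flag in doubled:
        run = run + 1 if flag else 0
        best = max(best, run)
    if min(best, x.size) > 0.05 * x.size:
        raise ValidationError(f"degenerate peak: {name} maximum is a plateau")


def align_by_vpeak(
    pressure: np.ndarray,
    volume: np.ndarray,
    cycle_length: float,
    v_window: tuple[float, float] = V_WINDOW,
    time_point: str = "T2",
    patient_id: str = "",
) -> PVLoop:
    """Circularly shift the pressure cycle so v-peak meets volume maximum.

    The shift is the minimal-magnitude signed rotation; it is recorded in
    ms on the loop (``applied_shift``).
    """
    p = np.asarray(pressure, dtype=float)
    v = np.asarray(volume, dtype=float)
    if p.size != v.size:
        raise ValidationError("pressure/volume length mismatch")
    n = p.size
    _check_peak_not_degenerate(p, "pressure")
    _check_peak_not_degenerate(v, "volume")
    p_peak = _windowed_argmax(p, v_window)
    v_peak = int(np.argmax(v))
    shift = (v_peak - p_peak + n // 2) % n - n // 2
    return PVLoop(
        pressure=np.roll(p, shift),
        volume=v,
        applied_shift=shift / n * cycle_length * 1e3,
        cycle_length=cycle_length,
        time_point=time_point,
        patient_id=patient_id,
    )


def stiffness(
    loop: PVLoop,
    method: str = "endpoints",
    limb_start: str = "volume_min",
    min_tev: float = 1.0,
) -> StiffnessResult:
    """Chamber stiffness from the ascending limb of the aligned loop.

    The filling limb runs from the volume-minimum point (mitral closure;
    or the pressure minimum with ``limb_start="pressure_min"``) to the
    volume-maximum point (just before mitral opening), traversed in cycle
    order with wrap-around.  ``method="endpoints"`` takes the two-point
    slope between the limb endpoints; ``method="regression"`` fits
    ordinary least squares through every limb point instead.
    """
    if method not in ("endpoints", "regression"):
        raise ValidationError(f"unknown stiffness method {method!r}")
    if limb_start not in ("volume_min", "pressure_min"):
        raise ValidationError(f"unknown limb_start {limb_start!r}")
    n = loop.n_points
    i_end = int(np.argmax(loop.volume))
    if limb_start == "volume_min":
        i_start = int(np.argmin(loop.volume))
    else:
        i_start = int(np.argmin(loop.pressure))
    dv = loop.volume[i_end] - loop.volume[i_start]
    if dv < min_tev:
        raise ValidationError(
            f"insufficient emptying volume: Vmax - Vmin = {dv:.3g} mL < {min_tev} mL"
        )
    if method == "endpoints":
        slope = (loop.pressure[i_end] - loop.pressure[i_start]) / dv
    else:
        span = (i_end - i_start) % n
        idx = (i_start + np.arange(span + 1)) % n
        slope = float(np.polyfit(loop.volume[idx], loop.pressure[idx], 1)[0])
    return StiffnessResult(
        dpdv=float(slope),
        p_start=float(loop.pressure[i_start]),
        p_end=float(loop.pressure[i_end]),
        v_start=float(loop.volume[i_start]),
        v_end=float(loop.volume[i_end]),
        time_point=loop.time_point,
        patient_id=loop.patient_id,
    )


def delta_stiffness(pre: StiffnessResult, post: StiffnessResult) -> float:
    """Stiffness change post - pre (T3 - T2) for one patient, mmHg/mL."""
    if pre.patient_id != post.patient_id:
        raise ValidationError(
            f"mismatched patient ids: {pre.patient_id!r} vs {post.patient_id!r}"
        )
    return post.dpdv - pre.dpdv


def build_loop(
    pressure_composite: CompositePressureCycle,
    volume_composite: CompositeVolumeCycle,
    n_points: int | None = None,
    min_support_fraction: float = 0.5,
    time_point: str = "T2",
    patient_id: str = "",
) -> PVLoop:
    """Resample and align a composite pair into a PV loop."""
    p, v = resample_pair(pressure_composite, volume_composite, n_points, min_support_fraction)
    return align_by_vpeak(
        p, v, volume_composite.mean_cycle_length, time_point=time_point, patient_id=patient_id
    )
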