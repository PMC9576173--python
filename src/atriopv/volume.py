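"""LA volume processing: phase averaging of per-beat volume curves,
volumetric indices, and the reservoir-phase exponential fit V = A·e^(Kt).

Volume beats are aligned by *phase* (fraction of beat duration), unlike the
pressure module's absolute-time averaging: echo volume curves are sparse
(~20 samples/s) and beat-length variation is better absorbed by mapping
each beat onto a common [0, 1) phase grid before averaging.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .io import ValidationError, VolumeCurveSet

DEFAULT_N_PHASES = 200


@dataclass
class CompositeVolumeCycle:
    """Phase-averaged LA volume cycle.

    ``phase_grid`` holds N equally spaced phases on [0, 1) (phase 0 and
    phase 1 describe the same cardiac event, the R-wave); ``values`` the
    mean volume per phase in mL.
    """

    phase_grid: np.ndarray
    values: np.ndarray
    n_beats: int
    mean_cycle_length: float  # s

    def __post_init__(self) -> None:
        self.phase_grid = np.asarray(self.phase_grid, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.phase_grid.size < 8:
            raise ValidationError("composite needs >= 8 phase points")
        if self.phase_grid.size != self.values.size:
            raise ValidationError("phase_grid/values length mismatch")
        if np.any(~(self.values > 0)):
            raise ValidationError("composite volumes must all be positive")
        if not self.mean_cycle_length > 0:
            raise ValidationError("mean_cycle_length must be positive")


@dataclass
class VolumeIndices:
    """Vmax (before mitral opening), Vmin (before mitral closure), TEV, TEF."""

    v_max: float  # mL
    v_min: float  # mL
    tev: float  # mL, v_max - v_min
    tef: float  # fraction, tev / v_max


@dataclass
class ReservoirFit:
    """Exponential reservoir parameters from V = A·e^(Kt)."""

    a: float  # mL, initial value
    k: float  # 1/s, growth constant
    rmse: float  # mL, volume-domain residual RMSE


def phase_average_volumes(
    curve_set: VolumeCurveSet, n_points: int = DEFAULT_N_PHASES
) -> CompositeVolumeCycle:
    """Phase-average beats onto a common grid.

    Each beat's time axis is mapped to phase ``(t - t0)/(t_end - t0)``,
    linearly interpolated onto ``n_points`` equally spaced phases on
    [0, 1), and averaged across beats.
    """
    if n_points < 8:
        raise ValidationError("n_points must be >= 8")
    grid = np.arange(n_points) / n_points
    resampled = []
    durations = []
    for i, (t, v) in enumerate(curve_set.beats):
        if t.size < 4:
            raise ValidationError(f"beat {i + 1} has fewer than 4 samples")
        dur = t[-1] - t[0]
        if dur <= 0:
            raise ValidationError(f"beat {i + 1} has zero duration")
        phase = (t - t[0]) / dur
        resampled.append(np.interp(grid, phase, v))
        durations.append(dur)
    return CompositeVolumeCycle(
        phase_grid=grid,
        values=np.mean(resampled, axis=0),
        n_beats=len(resampled),
        mean_cycle_length=float(np.mean(durations)),
    )


def volume_indices(composite: CompositeVolumeCycle) -> VolumeIndices:
    """Vmax/Vmin/TEV/TEF from the composite cycle."""
    v_max = float(np.max(composite.values))
    v_min = float(np.min(composite.values))
    if v_max == v_min:
        raise ValidationError("no emptying detected: composite volume is flat")
    tev = v_max - v_min
    return VolumeIndices(v_max=v_max, v_min=v_min, tev=tev, tef=tev / v_max)


def extract_filling_segment(
    composite: CompositeVolumeCycle,
) -> tuple[np.ndarray, np.ndarray]:
    """The reservoir (filling) arc: contiguous phases from Vmin to Vmax.

    Wraps across phase 0 when the volume minimum falls near the R-wave
    boundary.  Times start at 0 at the Vmin phase and are scaled by the
    mean cycle length, ready for :func:`fit_reservoir_exponential`.
    """
    volume_indices(composite)  # propagate flat-composite error
    n = composite.values.size
    i_min = int(np.argmin(composite.values))
    i_max = int(np.argmax(composite.values))
    span = (i_max - i_min) % n
    idx = (i_min + np.arange(span + 1)) % n
    t = np.arange(span + 1) / n * composite.mean_cycle_length
    return t, composite.values[idx]


def fit_reservoir_exponential(
    times, volumes, method: str = "loglinear"
) -> ReservoirFit:
    """Fit V = A·e^(Kt) to the filling volume segment.

    The default log-linear fit regresses log(V) on t by ordinary least
    squares, which is deterministic and needs no initialization;
    ``method="nonlinear"`` refines it by volume-domain nonlinear least
    squares.  RMSE is always reported against volumes in mL.
    """
    t = np.asarray(times, dtype=float)
    v = np.asarray(volumes, dtype=float)
    if t.size != v.size:
        raise ValidationError("times/volumes length mismatch")
    if t.size < 3:
        raise ValidationError("need >= 3 points for the reservoir fit")
    if np.any(~(v > 0)):
        raise ValidationError("volumes must all be positive")
    if method not in ("loglinear", "nonlinear"):
        raise ValidationError(f"unknown fit method {method!r}")

    k, log_a = np.polyfit(t, np.log(v), 1)
    a = float(np.exp(log_a))
    k = float(k)
    if method == "nonlinear":
        res = least_squares(
            lambda p: p[0] * np.exp(p[1] * t) - v,
            x0=[a, k],
            method="lm",
            xtol=1e-15,
            ftol=1e-15,
            gtol=1e-15,
        )
        a, k = float(res.x[0]), float(res.x[1])
    rmse = float(np.sqrt(np.mean((a * np.exp(k * t) - v) ** 2)))
    return ReservoirFit(a=a, k=k, rmse=rmse)


def process_volumes(
    curve_set: VolumeCurveSet, n_points: int = DEFAULT_N_PHASES, fit_method: str = "loglinear"
) -> tuple[CompositeVolumeCycle, VolumeIndices, ReservoirFit]:
    """Phase-average, derive indices, and fit the reservoir exponential."""
    composite = phase_average_volumes(curve_set, n_points)
    indices = volume_indices(composite)
    t, v = extract_filling_segment(composite)
    fit = fit_reservoir_exponential(t, v, method=fit_method)
    return composite, indices, fit
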