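"""LA pressure processing: FFT band-pass filtering, R-wave-referenced cycle
segmentation, time averaging, and pressure feature extraction.

The composite pressure cycle is built by superimposing truncated per-cycle
waveforms referenced to the preceding R-wave and averaging at each offset
over the cycles that reach it.  This works for both regular rhythms and
atrial fibrillation, where cycle lengths vary: early offsets are supported
by every cycle, late offsets only by the longer ones, so feature extraction
truncates the composite at a configurable support floor (default half of
the contributing cycles).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .io import PressureRecording, ValidationError

DEFAULT_BAND = (0.4, 10.0)  # Hz; respiration below, artifact above


def bandpass_fft(
    samples,
    sample_rate: float,
    f_lo: float = DEFAULT_BAND[0],
    f_hi: float = DEFAULT_BAND[1],
) -> np.ndarray:
    """Rectangular FFT band-pass retaining [f_lo, f_hi] (inclusive) plus DC.

    The discrete Fourier transform of the trace is computed, bins whose
    absolute frequency falls inside the passband are kept, the 0 Hz bin is
    kept so the mean pressure is preserved, every other bin is zeroed
    symmetrically over positive and negative frequencies, and the inverse
    transform (real part by construction) is returned at the same length.
    No window or taper is applied.
    """
    x = np.asarray(samples, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValidationError("need a one-dimensional signal of >= 2 samples")
    if not np.all(np.isfinite(x)):
        raise ValidationError("non-finite sample in input")
    if not (0 < f_lo < f_hi):
        raise ValidationError(f"need 0 < f_lo < f_hi, got ({f_lo}, {f_hi})")
    if sample_rate <= 2 * f_hi:
        raise ValidationError(
            f"sample rate {sample_rate} Hz violates Nyquist for f_hi = {f_hi} Hz"
        )
    spec = np.fft.rfft(x)
    freqs = np.fft.rfftfreq(x.size, d=1.0 / sample_rate)
    keep = (freqs == 0.0) | ((freqs >= f_lo) & (freqs <= f_hi))
    spec[~keep] = 0.0
    return np.fft.irfft(spec, n=x.size)


def segment_cycles(recording: PressureRecording) -> list[np.ndarray]:
    """Split a recording into per-R-R-interval segments.

    Each segment starts at the sample nearest its R-wave and ends one
    sample before the next R-wave's nearest sample.  Data before the first
    and after the last annotation are discarded.
    """
    fs = recording.sample_rate
    idx = np.rint(recording.r_wave_times * fs).astype(int)
    idx = np.clip(idx, 0, recording.samples.size - 1)
    segments = []
    for i0, i1 in zip(idx[:-1], idx[1:]):
        if i1 - i0 < 2:
            raise ValidationError(
                f"R-R interval of {i1 - i0} samples between annotations at "
                f"{i0 / fs:.3f}s and {i1 / fs:.3f}s is too short"
            )
        segments.append(recording.samples[i0:i1].copy())
    return segments


@dataclass
class CompositePressureCycle:
    """R-wave-referenced average cycle.

    ``values[k]`` is the mean pressure at offset ``k`` samples from the
    R-wave over the ``support_counts[k]`` cycles long enough to reach that
    offset; the composite spans the longest contributing cycle.
    """

    sample_rate: float
    values: np.ndarray
    support_counts: np.ndarray
    rr_lengths: np.ndarray  # contributing cycle lengths, s

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.support_counts = np.asarray(self.support_counts, dtype=int)
        self.rr_lengths = np.asarray(self.rr_lengths, dtype=float)
        if self.values.size != self.support_counts.size:
            raise ValidationError("values/support_counts length mismatch")
        if np.any(np.diff(self.support_counts) > 0):
            raise ValidationError("support_counts must be non-increasing")

    @property
    def n_cycles(self) -> int:
        return int(self.support_counts[0])

    @property
    def rr_mean(self) -> float:
        """Mean contributing cycle length, s."""
        return float(np.mean(self.rr_lengths))

    def truncated(self, min_support_fraction: float = 0.5) -> np.ndarray:
        """Composite restricted to offsets with sufficient cycle support."""
        if not 0 < min_support_fraction <= 1:
            raise ValidationError("min_support_fraction must be in (0, 1]")
        floor = min_support_fraction * self.n_cycles
        keep = self.support_counts >= floor
        return self.values[keep]


def time_average_cycles(
    segments: Sequence[np.ndarray],
    sample_rate: float,
    rr_lengths: Sequence[float] | None = None,
) -> CompositePressureCycle:
    """Average segments at each offset from the R-wave (variable denominator).

    ``composite[k]`` is the arithmetic mean of ``seg[k]`` over all segments
    of length > k, so truncated short cycles still contribute to the early
    part of the composite.
    """
    if len(segments) == 0:
        raise ValidationError("no segments to average")
    segs = [np.asarray(s, dtype=float) for s in segments]
    lengths = np.array([s.size for s in segs])
    max_len = int(lengths.max())
    sums = np.zeros(max_len)
    counts = np.zeros(max_len, dtype=int)
    for s in segs:
        sums[: s.size] += s
        counts[: s.size] += 1
    if rr_lengths is None:
        rr_lengths = lengths / sample_rate
    return CompositePressureCycle(
        sample_rate=sample_rate,
        values=sums / counts,
        support_counts=counts,
        rr_lengths=np.asarray(rr_lengths, dtype=float),
    )


@dataclass
class PressureFeatures:
    """Scalar features of a composite pressure cycle (clinical-report units)."""

    lap_mean: float  # mmHg
    lap_max: float
    lap_min: float
    v_peak: float  # mmHg, v-wave peak
    t_to_v_peak: float  # ms from R-wave
    t_to_v_peak_pct_rr: float  # % of mean RR
    filling_dpdt: float  # mmHg/s, v-wave ascending limb
    rr_mean: float  # ms


def extract_pressure_features(
    composite: CompositePressureCycle,
    min_support_fraction: float = 0.5,
    v_window: tuple[float, float] = (0.25, 0.90),
    dpdt_method: str = "ols",
) -> PressureFeatures:
    """Extract LAP features from a composite cycle.

    The composite is first truncated to offsets supported by at least
    ``min_support_fraction`` of the contributing cycles.  The v-wave peak
    is the global maximum over offsets in ``v_window`` (fractions of the
    mean RR), which excludes a late a-wave or early systolic artifact from
    masquerading as the v-wave.  ``filling_dpdt`` is the slope of the
    v-wave ascending limb, from the last local minimum preceding the peak
    (or the window start when the limb is monotone) to the peak --
    ordinary least squares by default, two-point difference with
    ``dpdt_method="two_point"``.
    """
    vals = composite.truncated(min_support_fraction)
    if vals.size < 2:
        raise ValidationError("truncated composite too short")
    if np.max(vals) == np.min(vals):
        raise ValidationError("no identifiable v-wave: composite is flat")
    if dpdt_method not in ("ols", "two_point"):
        raise ValidationError(f"unknown dpdt_method {dpdt_method!r}")

    fs = composite.sample_rate
    rr_mean_s = composite.rr_mean
    lo = int(np.ceil(v_window[0] * rr_mean_s * fs))
    hi = min(vals.size - 1, int(np.floor(v_window[1] * rr_mean_s * fs)))
    lo = min(lo, vals.size - 2)
    if hi <= lo:
        hi = lo + 1
    window = vals[lo : hi + 1]
    v_idx = lo + int(np.argmax(window))
    v_peak = float(vals[v_idx])

    # ascending limb start: last sample before the peak that is <= both
    # neighbours; fall back to the search-window start for monotone limbs
    limb_start = lo
    for i in range(v_idx - 1, 0, -1):
        if vals[i] <= vals[i - 1] and vals[i] <= vals[i + 1]:
            limb_start = i
            break
    limb_start = min(limb_start, v_idx - 1)

    t = np.arange(limb_start, v_idx + 1) / fs
    p = vals[limb_start : v_idx + 1]
    if dpdt_method == "ols" and p.size > 2:
        slope = float(np.polyfit(t, p, 1)[0])
    else:
        slope = float((p[-1] - p[0]) / (t[-1] - t[0]))

    return PressureFeatures(
        lap_mean=float(np.mean(vals)),
        lap_max=float(np.max(vals)),
        lap_min=float(np.min(vals)),
        v_peak=v_peak,
        t_to_v_peak=v_idx / fs * 1e3,
        t_to_v_peak_pct_rr=100.0 * (v_idx / fs) / rr_mean_s,
        filling_dpdt=slope,
        rr_mean=rr_mean_s * 1e3,
    )


def process_recording(
    recording: PressureRecording,
    f_lo: float = DEFAULT_BAND[0],
    f_hi: float = DEFAULT_BAND[1],
    min_support_fraction: float = 0.5,
) -> tuple[CompositePressureCycle, PressureFeatures]:
    """Filter, segment, average, and extract features in one pass."""
    filtered = bandpass_fft(recording.samples, recording.sample_rate, f_lo, f_hi)
    rec = PressureRecording(
        patient_id=recording.patient_id,
        time_point=recording.time_point,
        sample_rate=recording.sample_rate,
        samples=filtered,
        r_wave_times=recording.r_wave_times,
    )
    segments = segment_cycles(rec)
    composite = time_average_cycles(segments, recording.sample_rate)
    features = extract_pressure_features(composite, min_support_fraction)
    return composite, features
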