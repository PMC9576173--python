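"""Synthetic LA hemodynamics with known ground truth.

Generates raw pressure recordings, per-beat volume curves, single patients,
and full LAAO cohorts so that every pipeline stage has a download-free test
surface.  All generators are pure functions of (params, seed).

The pressure model is deliberately simple: a baseline plus Gaussian bumps
for the a-wave (sinus rhythm only, late diastole) and the v-wave (end of
reservoir filling), with sinusoidal respiratory modulation, a powerline
tone, and white noise.  Wave centers sit at fixed fractions of the *mean*
RR interval in absolute time for every cycle -- the v-peak tracks
ventricular systole, which varies far less than the RR interval in atrial
fibrillation -- so R-wave-referenced averaging of truncated cycles
reconstructs the clean template in the noise-free limit.

The volume curve is constructed *from* the clean pressure template through
the ground-truth compliance during the filling (reservoir) phase:

    V(t) = Vmin + (P(t) - P_start) / stiffness

with the v-wave amplitude solved in closed form so that the pressure rise
over the limb equals stiffness x (Vmax - Vmin) exactly.  This embeds the
filling-limb dP/dV in the data by construction, making stiffness recovery
a well-posed end-to-end test.  During emptying the volume descends to Vmin
along a smooth monotone arc (with a late active-emptying component in
sinus rhythm).
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io import (
    PatientRecord,
    PressureRecording,
    ValidationError,
    VolumeCurveSet,
    write_cohort_table,
    write_pressure_recording,
    write_volume_curves,
)

FILLING_START_FRAC = 0.05  # phase of Vmin (mitral closure), fraction of cycle


@dataclass
class WaveformParams:
    """Pressure-waveform generator settings (defaults match a typical
    LAAO patient: RR 999 ms, LAP baseline 19 mmHg, v-peak ~30 mmHg at 54%
    RR, mechanical-ventilation respiration at 0.2 Hz)."""

    rr_mean: float = 0.999  # s
    rr_cv: float = 0.0  # 0 regular, ~0.2 AF
    rhythm: str = "sinus"  # "sinus" | "af"
    lap_baseline: float = 19.0  # mmHg
    a_amp: float = 4.0  # mmHg; zeroed for AF
    a_center_frac: float = 0.88  # fraction of mean RR
    a_width: float = 0.05  # s
    v_amp: float = 11.0  # mmHg
    v_center_frac: float = 0.54
    v_width: float = 0.09  # s
    resp_freq: float = 0.2  # Hz (12 breaths/min)
    resp_amp: float = 3.0  # mmHg
    noise_sd: float = 1.0  # mmHg
    powerline_freq: float = 60.0  # Hz
    powerline_amp: float = 0.5  # mmHg
    n_cycles: int = 20
    sample_rate: float = 977.0  # Hz

    def __post_init__(self) -> None:
        if not self.rr_mean > 0.3:
            raise ValidationError("rr_mean must exceed 0.3 s")
        if not 0.25 < self.v_center_frac < 0.9:
            raise ValidationError("v_center_frac must be in (0.25, 0.9)")
        if self.sample_rate < 200:
            raise ValidationError("sample_rate must be >= 200 Hz")
        if self.rhythm not in ("sinus", "af"):
            raise ValidationError(f"unknown rhythm {self.rhythm!r}")
        if self.rhythm == "af":
            self.a_amp = 0.0


def af_waveform(**overrides) -> WaveformParams:
    """AF preset: irregular RR (CV 0.2), no a-wave."""
    defaults = dict(rhythm="af", rr_cv=0.2, a_amp=0.0)
    defaults.update(overrides)
    return WaveformParams(**defaults)


def _gauss(tau: np.ndarray, center: float, width: float) -> np.ndarray:
    return np.exp(-0.5 * ((tau - center) / width) ** 2)


def pressure_template(wp: WaveformParams, tau) -> np.ndarray:
    """Clean single-cycle pressure at offsets ``tau`` (s) from the R-wave."""
    tau = np.asarray(tau, dtype=float)
    p = np.full_like(tau, wp.lap_baseline)
    p += wp.v_amp * _gauss(tau, wp.v_center_frac * wp.rr_mean, wp.v_width)
    if wp.a_amp:
        p += wp.a_amp * _gauss(tau, wp.a_center_frac * wp.rr_mean, wp.a_width)
    return p


def solve_v_amplitude(
    wp: WaveformParams,
    stiffness: float,
    tev: float,
    phi_start: float = FILLING_START_FRAC,
    strict: bool = False,
) -> WaveformParams:
    """Return waveform params whose v-wave amplitude makes the filling-limb
    pressure rise equal ``stiffness * tev`` exactly.

    The pressure rise from the filling-limb start (phase ``phi_start``) to
    the v-peak is affine in the v-wave amplitude, so the consistent
    amplitude has a closed form.  A solved amplitude wildly different from
    the configured one (outside 1/3x .. 3x) signals inconsistent
    parameters: warning by default, error when ``strict``.
    """
    if stiffness <= 0 or tev <= 0:
        raise ValidationError("stiffness and tev must be positive")
    t_start = phi_start * wp.rr_mean
    t_peak = wp.v_center_frac * wp.rr_mean
    dgv = _gauss(np.array(t_peak), t_peak, wp.v_width) - _gauss(
        np.array(t_start), t_peak, wp.v_width
    )
    dga = 0.0
    if wp.a_amp:
        c = wp.a_center_frac * wp.rr_mean
        dga = float(
            _gauss(np.array(t_peak), c, wp.a_width) - _gauss(np.array(t_start), c, wp.a_width)
        )
    v_amp = (stiffness * tev - wp.a_amp * dga) / float(dgv)
    if v_amp <= 0:
        raise ValidationError("solved v-wave amplitude is non-positive")
    ratio = v_amp / wp.v_amp
    if not 1 / 3 <= ratio <= 3:
        msg = (
            f"v-wave amplitude rescaled {wp.v_amp:.2f} -> {v_amp:.2f} mmHg to match "
            f"stiffness {stiffness} mmHg/mL with TEV {tev} mL"
        )
        if strict:
            raise ValidationError(msg)
        warnings.warn(msg, stacklevel=2)
    return dataclasses.replace(wp, v_amp=float(v_amp))


def generate_pressure_recording(
    wp: WaveformParams, seed: int, patient_id: str = "", time_point: str = "T2"
) -> tuple[PressureRecording, np.ndarray]:
    """Synthesize a raw recording; also return the clean one-cycle template.

    Per cycle the RR interval is gamma-distributed with mean ``rr_mean``
    and coefficient of variation ``rr_cv`` (fixed when rr_cv = 0).  The
    returned template is the noise-free, respiration-free single cycle
    sampled at the recording rate -- the ground truth for composite tests.
    """
    rng = np.random.default_rng(seed)
    fs = wp.sample_rate
    if wp.rr_cv == 0:
        rr = np.full(wp.n_cycles, wp.rr_mean)
    else:
        shape = 1.0 / wp.rr_cv**2
        rr = rng.gamma(shape, wp.rr_mean / shape, size=wp.n_cycles)
        rr = np.clip(rr, 0.4 * wp.rr_mean, 2.5 * wp.rr_mean)
    lead_in = 0.5
    r_times = lead_in + np.concatenate([[0.0], np.cumsum(rr)])
    # annotations come from the recorder, quantized to its sample grid;
    # this also makes noise-free cycles sample-identical to the template
    r_times = np.rint(r_times * fs) / fs
    duration = r_times[-1] + 0.3
    n = int(round(duration * fs)) + 1
    t = np.arange(n) / fs

    clean = np.empty(n)
    # reference each region to its preceding R-wave (virtual cycle before
    # the first annotation, open-ended after the last)
    refs = np.concatenate([[lead_in - wp.rr_mean], r_times])
    edges = np.concatenate([[0.0], r_times, [duration + 1.0]])
    for i, ref in enumerate(refs):
        m = (t >= edges[i]) & (t < edges[i + 1])
        clean[m] = pressure_template(wp, t[m] - ref)

    noisy = (
        clean
        + wp.resp_amp * np.sin(2 * np.pi * wp.resp_freq * t)
        + wp.powerline_amp * np.sin(2 * np.pi * wp.powerline_freq * t)
        + wp.noise_sd * rng.standard_normal(n)
    )
    rec = PressureRecording(
        patient_id=patient_id,
        time_point=time_point,
        sample_rate=fs,
        samples=noisy,
        r_wave_times=r_times,
    )
    template = pressure_template(wp, np.arange(int(round(wp.rr_mean * fs))) / fs)
    return rec, template


@dataclass
class PatientParams:
    """Ground-truth parameters for one synthetic LAAO patient."""

    patient_id: str = "P01"
    rhythm: str = "paroxysmal"  # paroxysmal (sinus) | persistent (AF)
    stiffness_pre: float = 0.41  # mmHg/mL, filling-limb dP/dV at T2
    stiffness_post: float = 0.64  # mmHg/mL at T3
    v_min: float = 60.0  # mL
    v_max: float = 90.0  # mL
    bsa: float = 2.1  # m^2
    laa_depth: float = 2.90  # cm (indexed ~1.38 cm/m^2)
    laa_width: float = 2.14  # cm
    waveform: WaveformParams = field(default_factory=WaveformParams)
    volume_rate: float = 20.0  # volumes/s
    volume_noise: float = 0.02  # multiplicative sd
    n_beats: int = 5  # beats per volume acquisition set
    t1_scale: tuple[float, float] = (0.95, 0.95)  # (v_max, v_min) multipliers
    t4_scale: tuple[float, float] = (1.02, 0.93)

    def __post_init__(self) -> None:
        if self.stiffness_pre <= 0 or self.stiffness_post <= 0:
            raise ValidationError("stiffness values must be positive")
        if not self.v_max > self.v_min > 0:
            raise ValidationError("need v_max > v_min > 0")
        if self.rhythm == "persistent" and self.waveform.rhythm != "af":
            self.waveform = dataclasses.replace(
                self.waveform, rhythm="af", rr_cv=max(self.waveform.rr_cv, 0.2), a_amp=0.0
            )

    @property
    def tev(self) -> float:
        return self.v_max - self.v_min


def _emptying_profile(u: np.ndarray, rhythm: str) -> np.ndarray:
    """Monotone descent fraction over emptying phase u in [0, 1]."""

    def smoothstep(x):
        x = np.clip(x, 0.0, 1.0)
        return 3 * x**2 - 2 * x**3

    if rhythm == "sinus":
        # passive emptying, diastasis plateau, then active (booster) emptying
        return 0.65 * smoothstep(u / 0.5) + 0.35 * smoothstep((u - 0.7) / 0.3)
    return smoothstep(u)


def volume_phase_curve(
    pp: PatientParams,
    stiffness: float,
    v_scale: tuple[float, float] = (1.0, 1.0),
    n_dense: int = 4096,
    phi_start: float = FILLING_START_FRAC,
) -> tuple[np.ndarray, np.ndarray, WaveformParams]:
    """Ground-truth volume over one cycle on a dense phase grid [0, 1).

    Filling (phase ``phi_start`` to the v-peak phase) is constructed from
    the clean pressure template through ``stiffness``; emptying descends
    smoothly back to Vmin.  Returns (phases, volumes, consistent waveform
    params with the solved v-wave amplitude).
    """
    v_max = pp.v_max * v_scale[0]
    v_min = pp.v_min * v_scale[1]
    if v_max <= v_min:
        raise ValidationError("scaled v_max must exceed v_min")
    tev = v_max - v_min
    wp = solve_v_amplitude(pp.waveform, stiffness, tev, phi_start)
    rr = wp.rr_mean
    phi_v = wp.v_center_frac
    phi = phi_start + np.arange(n_dense) / n_dense  # one cycle starting at Vmin
    vol = np.empty(n_dense)
    filling = phi <= phi_v
    p_start = float(pressure_template(wp, np.array(phi_start * rr)))
    vol[filling] = v_min + (pressure_template(wp, phi[filling] * rr) - p_start) / stiffness
    u = (phi[~filling] - phi_v) / (1.0 + phi_start - phi_v)
    vol[~filling] = v_max - tev * _emptying_profile(u, wp.rhythm)
    # reorder onto [0, 1)
    phase = np.mod(phi, 1.0)
    order = np.argsort(phase, kind="mergesort")
    return phase[order], vol[order], wp


def generate_volume_curves(
    pp: PatientParams,
    stiffness: float,
    seed: int,
    v_scale: tuple[float, float] = (1.0, 1.0),
    time_point: str = "T1",
    n_beats: int | None = None,
) -> VolumeCurveSet:
    """Sample noisy per-beat volume curves at the echo volume rate."""
    rng = np.random.default_rng(seed)
    phase, vol, wp = volume_phase_curve(pp, stiffness, v_scale)
    n_beats = pp.n_beats if n_beats is None else n_beats
    if wp.rr_cv == 0:
        durs = np.full(n_beats, wp.rr_mean)
    else:
        shape = 1.0 / wp.rr_cv**2
        durs = np.clip(
            rng.gamma(shape, wp.rr_mean / shape, size=n_beats),
            0.4 * wp.rr_mean,
            2.5 * wp.rr_mean,
        )
    beats = []
    for dur in durs:
        n_samp = max(4, int(round(pp.volume_rate * dur))) + 1
        t = np.linspace(0.0, dur, n_samp)
        v = np.interp(t / dur, phase, vol, period=1.0)
        # bounded multiplicative measurement error: at most +-volume_noise
        v = v * (1.0 + pp.volume_noise * rng.uniform(-1.0, 1.0, n_samp))
        beats.append((t, np.maximum(v, 1e-3)))
    return VolumeCurveSet(
        patient_id=pp.patient_id,
        time_point=time_point,
        beats=beats,
        volume_rate=pp.volume_rate,
    )


def generate_patient(pp: PatientParams, seed: int) -> tuple[PatientRecord, dict]:
    """One synthetic patient: T2/T3 pressure recordings plus T1-T4 volume
    sets, with a serializable ground-truth record."""
    children = np.random.SeedSequence(seed).generate_state(6) % (2**31)
    wp_pre = solve_v_amplitude(pp.waveform, pp.stiffness_pre, pp.tev)
    wp_post = solve_v_amplitude(pp.waveform, pp.stiffness_post, pp.tev)
    rec_pre, tpl_pre = generate_pressure_recording(
        wp_pre, int(children[0]), pp.patient_id, "T2"
    )
    rec_post, tpl_post = generate_pressure_recording(
        wp_post, int(children[1]), pp.patient_id, "T3"
    )
    volumes = {
        "T1": generate_volume_curves(pp, pp.stiffness_pre, int(children[2]), pp.t1_scale, "T1"),
        "T2": generate_volume_curves(pp, pp.stiffness_pre, int(children[3]), (1, 1), "T2"),
        "T3": generate_volume_curves(pp, pp.stiffness_post, int(children[4]), (1, 1), "T3"),
        "T4": generate_volume_curves(pp, pp.stiffness_post, int(children[5]), pp.t4_scale, "T4"),
    }
    patient = PatientRecord(
        patient_id=pp.patient_id,
        rhythm=pp.rhythm,
        bsa=pp.bsa,
        laa_width_max=pp.laa_width,
        laa_depth_max=pp.laa_depth,
        pressure={"T2": rec_pre, "T3": rec_post},
        volumes=volumes,
    )
    truth = {
        "patient_id": pp.patient_id,
        "rhythm": pp.rhythm,
        "stiffness_pre": pp.stiffness_pre,
        "stiffness_post": pp.stiffness_post,
        "delta_stiffness": pp.stiffness_post - pp.stiffness_pre,
        "v_min": pp.v_min,
        "v_max": pp.v_max,
        "tev": pp.tev,
        "tef": pp.tev / pp.v_max,
        "bsa": pp.bsa,
        "laa_depth_idx": pp.laa_depth / pp.bsa,
        "laa_width_idx": pp.laa_width / pp.bsa,
        "rr_mean_ms": pp.waveform.rr_mean * 1e3,
        "t_to_v_peak_ms": pp.waveform.v_center_frac * pp.waveform.rr_mean * 1e3,
        "v_peak_pre": float(np.max(tpl_pre)),
        "v_peak_post": float(np.max(tpl_post)),
        "seed": int(seed),
    }
    return patient, truth


# ---------------------------------------------------------------------------
# cohort level
# ---------------------------------------------------------------------------


@dataclass
class CohortParams:
    """Distributional settings for a synthetic LAAO cohort.

    Marginals are centered on a typical 25-patient LAAO population:
    log-normal baseline stiffness (median 0.41 mmHg/mL), normal stiffness
    change (mean +0.22, sd 0.17 mmHg/mL), log-normal indexed LAA depth
    (median 1.38 cm/m^2).  A Gaussian copula with correlation ``rho``
    couples indexed LAA depth to the stiffness change; its implied
    Spearman correlation is (6/pi)·asin(rho/2).
    """

    n_patients: int = 25
    rho: float = 0.7  # Gaussian-copula correlation, LAA depth idx vs delta
    frac_persistent: float = 0.52
    delta_mean: float = 0.22  # mmHg/mL
    delta_sd: float = 0.17
    stiff_pre_median: float = 0.41
    stiff_pre_logsd: float = 0.703
    rho_lap_stiff: float = 0.5  # latent corr of LAP_mean with baseline stiffness
    laa_depth_idx_median: float = 1.38  # cm/m^2
    laa_depth_idx_logsd: float = 0.1595
    laa_width_idx_median: float = 1.02
    laa_width_idx_logsd: float = 0.1286
    bsa_median: float = 2.1
    bsa_logsd: float = 0.1487
    lap_mean_median: float = 23.4
    lap_mean_logsd: float = 0.169
    vmax_idx_median: float = 44.6
    vmax_idx_logsd: float = 0.4004
    stiff_floor: float = 0.05

    def __post_init__(self) -> None:
        if self.n_patients < 5:
            raise ValidationError("n_patients must be >= 5")
        if not -1 <= self.rho <= 1:
            raise ValidationError("rho must be in [-1, 1]")


def implied_spearman(rho: float) -> float:
    """Population Spearman correlation of a Gaussian copula with
    correlation ``rho``: (6/pi)·asin(rho/2)."""
    return 6.0 / np.pi * np.arcsin(rho / 2.0)


def sample_cohort_parameters(cp: CohortParams, seed: int) -> pd.DataFrame:
    """Draw per-patient latent ground truth as a valid cohort table.

    The returned frame has exactly the cohort-table schema, so it feeds
    the statistical layer directly; it is also the ground truth against
    which pipeline estimates are scored.
    """
    rng = np.random.default_rng(seed)
    n = cp.n_patients
    z1 = rng.standard_normal(n)  # drives indexed LAA depth
    z2 = cp.rho * z1 + np.sqrt(max(0.0, 1 - cp.rho**2)) * rng.standard_normal(n)
    z_lap = rng.standard_normal(n)
    z_stiff = cp.rho_lap_stiff * z_lap + np.sqrt(
        max(0.0, 1 - cp.rho_lap_stiff**2)
    ) * rng.standard_normal(n)

    laa_depth_idx = cp.laa_depth_idx_median * np.exp(cp.laa_depth_idx_logsd * z1)
    delta = cp.delta_mean + cp.delta_sd * z2
    stiff_pre = cp.stiff_pre_median * np.exp(cp.stiff_pre_logsd * z_stiff)
    # keep post-occlusion stiffness physical: the change cannot push the
    # chamber below a residual stiffness floor (rarely binding)
    delta = np.maximum(delta, cp.stiff_floor - stiff_pre)
    stiff_post = stiff_pre + delta
    lap_mean = cp.lap_mean_median * np.exp(cp.lap_mean_logsd * z_lap)
    bsa = cp.bsa_median * np.exp(cp.bsa_logsd * rng.standard_normal(n))
    laa_width_idx = cp.laa_width_idx_median * np.exp(
        cp.laa_width_idx_logsd * rng.standard_normal(n)
    )
    vmax_idx = cp.vmax_idx_median * np.exp(cp.vmax_idx_logsd * rng.standard_normal(n))
    persistent = rng.random(n) < cp.frac_persistent

    return pd.DataFrame(
        {
            "patient_id": [f"P{i + 1:03d}" for i in range(n)],
            "rhythm": np.where(persistent, "persistent", "paroxysmal"),
            "bsa_m2": bsa,
            "laa_width_cm": laa_width_idx * bsa,
            "laa_depth_cm": laa_depth_idx * bsa,
            "laa_width_idx": laa_width_idx,
            "laa_depth_idx": laa_depth_idx,
            "lap_mean_t2": lap_mean,
            "vmax_idx_t1": vmax_idx,
            "stiff_t2": stiff_pre,
            "stiff_t3": stiff_post,
            "delta_stiff": stiff_post - stiff_pre,
        }
    )


def _patient_params_from_row(row: pd.Series, cp: CohortParams, wp: WaveformParams | None) -> PatientParams:
    base_wp = wp if wp is not None else WaveformParams()
    vmax = row["vmax_idx_t1"] * row["bsa_m2"] / 0.95  # T1 is the scaled-down set
    vmin = vmax * 0.68
    return PatientParams(
        patient_id=row["patient_id"],
        rhythm=row["rhythm"],
        stiffness_pre=row["stiff_t2"],
        stiffness_post=row["stiff_t3"],
        v_min=vmin,
        v_max=vmax,
        bsa=row["bsa_m2"],
        laa_depth=row["laa_depth_cm"],
        laa_width=row["laa_width_cm"],
        waveform=dataclasses.replace(base_wp),
    )


def generate_cohort(
    cp: CohortParams,
    seed: int,
    out_dir=None,
    waveform: WaveformParams | None = None,
) -> tuple[pd.DataFrame, list[tuple[PatientRecord, dict]] | None]:
    """Sample a cohort; optionally emit per-patient files plus truth table.

    With ``out_dir`` set, each patient's T2/T3 pressure waveform +
    annotation CSVs and T1-T4 volume CSVs are written under
    ``out_dir/<patient_id>/`` together with a per-patient ``truth.json``,
    and the latent ground-truth cohort table is written to
    ``out_dir/truth.csv``.
    """
    table = sample_cohort_parameters(cp, seed)
    patient_seeds = np.random.SeedSequence([seed, 1]).generate_state(cp.n_patients) % (2**31)
    patients = None
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        patients = []
        for (_, row), pseed in zip(table.iterrows(), patient_seeds):
            pp = _patient_params_from_row(row, cp, waveform)
            patient, truth = generate_patient(pp, int(pseed))
            pdir = out_dir / pp.patient_id
            pdir.mkdir(exist_ok=True)
            for tp, rec in patient.pressure.items():
                write_pressure_recording(
                    rec, pdir / f"pressure_{tp.lower()}.csv", pdir / f"rwaves_{tp.lower()}.csv"
                )
            for tp, vset in patient.volumes.items():
                write_volume_curves(vset, pdir / f"volumes_{tp.lower()}.csv")
            with open(pdir / "truth.json", "w") as fh:
                json.dump(truth, fh, indent=1, sort_keys=True)
            patients.append((patient, truth))
        write_cohort_table(table, out_dir / "truth.csv")
    return table, patients
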