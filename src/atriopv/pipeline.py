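"""End-to-end orchestration: raw recordings -> composites -> PV loop ->
stiffness, per patient and per cohort."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .io import PatientRecord, PressureRecording, VolumeCurveSet, index_by_bsa
from .pressure import process_recording
from .pvloop import StiffnessResult, build_loop, delta_stiffness, stiffness
from .volume import DEFAULT_N_PHASES, process_volumes


def estimate_stiffness(
    pressure_rec: PressureRecording,
    volume_set: VolumeCurveSet,
    n_phases: int = DEFAULT_N_PHASES,
    n_points: int | None = None,
) -> StiffnessResult:
    """Filter/average the pressure, phase-average the volumes, build the
    aligned PV loop, and return filling-limb stiffness."""
    p_comp, _ = process_recording(pressure_rec)
    v_comp, _, _ = process_volumes(volume_set, n_points=n_phases)
    loop = build_loop(
        p_comp,
        v_comp,
        n_points=n_points,
        time_point=pressure_rec.time_point,
        patient_id=pressure_rec.patient_id,
    )
    return stiffness(loop)


def analyze_patient(patient: PatientRecord, n_phases: int = DEFAULT_N_PHASES) -> dict:
    """Full per-patient analysis across the four procedural time points.

    Returns pressure features (T2/T3), volume indices and reservoir fits
    (T1-T4, BSA-indexed where the cohort table wants them), stiffness at
    T2 and T3, and the stiffness change.
    """
    out: dict = {"patient_id": patient.patient_id, "rhythm": patient.rhythm}
    out["laa_width_idx"] = index_by_bsa(patient.laa_width_max, patient.bsa)
    out["laa_depth_idx"] = index_by_bsa(patient.laa_depth_max, patient.bsa)

    composites = {}
    for tp, rec in patient.pressure.items():
        comp, feats = process_recording(rec)
        composites[tp] = comp
        out[f"pressure_features_{tp}"] = feats
    for tp, vset in patient.volumes.items():
        v_comp, idx, fit = process_volumes(vset, n_points=n_phases)
        out[f"volume_composite_{tp}"] = v_comp
        out[f"volume_indices_{tp}"] = idx
        out[f"reservoir_fit_{tp}"] = fit
        out[f"vmax_idx_{tp}"] = index_by_bsa(idx.v_max, patient.bsa)

    results = {}
    for tp in ("T2", "T3"):
        if tp in composites and tp in patient.volumes:
            loop = build_loop(
                composites[tp],
                out[f"volume_composite_{tp}"],
                time_point=tp,
                patient_id=patient.patient_id,
            )
            results[tp] = stiffness(loop)
            out[f"stiffness_{tp}"] = results[tp]
    if "T2" in results and "T3" in results:
        out["delta_stiffness"] = delta_stiffness(results["T2"], results["T3"])
    return out


def patient_cohort_row(analysis: dict, bsa: float, lap_mean_t2: float | None = None) -> dict:
    """Flatten an :func:`analyze_patient` result into a cohort-table row."""
    feats_t2 = analysis.get("pressure_features_T2")
    row = {
        "patient_id": analysis["patient_id"],
        "rhythm": analysis["rhythm"],
        "bsa_m2": bsa,
        "laa_width_cm": analysis["laa_width_idx"] * bsa,
        "laa_depth_cm": analysis["laa_depth_idx"] * bsa,
        "laa_width_idx": analysis["laa_width_idx"],
        "laa_depth_idx": analysis["laa_depth_idx"],
        "lap_mean_t2": lap_mean_t2 if lap_mean_t2 is not None else feats_t2.lap_mean,
        "vmax_idx_t1": analysis["vmax_idx_T1"],
        "stiff_t2": analysis["stiffness_T2"].dpdv,
        "stiff_t3": analysis["stiffness_T3"].dpdv,
    }
    row["delta_stiff"] = row["stiff_t3"] - row["stiff_t2"]
    return row


def analyze_cohort_records(patients: list[PatientRecord], bsas: list[float]) -> pd.DataFrame:
    """Run the full pipeline over a list of patient records."""
    rows = []
    for patient, bsa in zip(patients, bsas):
        rows.append(patient_cohort_row(analyze_patient(patient), bsa))
    return pd.DataFrame(rows)
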