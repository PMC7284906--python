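"""End-to-end study processing.

Glues the stages together for a whole study: per-run targeted measurement,
treated-vs-control detection with QC-batch normalization, calibration of
the standards, and the final per-compound group-comparison table.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .extract import detect_peaks, extract_xic, select_precursor_peak
from .formula import isotope_pattern, ppm_window
from .identify import (
    DetectionParams,
    detect_compound,
    isotope_pattern_score,
    measured_envelope,
    validate_fragments,
)
from .panel import TargetCompound
from .quantify import CalibrationCurve, fit_calibration, normalize_to_reference, summarize_study
from .spectra import Run

__all__ = [
    "measure_run",
    "detect_study",
    "calibrate_study",
    "quantify_study",
    "process_study",
]


def measure_run(
    run: Run,
    panel: list[TargetCompound],
    params: DetectionParams = DetectionParams(),
) -> pd.DataFrame:
    """Integrated precursor area per panel compound for one run.

    One row per compound: area/apex/bounds of the precursor peak nearest
    the expected RT (largest if no RT is known), NaNs when no peak is
    found. Extraction centers on the exact computed [M-H]- m/z.
    """
    rows = []
    for target in panel:
        xic = extract_xic(run, ppm_window(target.theoretical_mz, params.mz_tol_ppm))
        peaks = detect_peaks(xic, min_snr=params.min_snr, min_points=params.min_points)
        peak = select_precursor_peak(peaks, target.expected_rt)
        rows.append(
            {
                "sample_id": run.sample_id,
                "compound": target.name,
                "area": peak.area if peak else float("nan"),
                "apex_rt": peak.apex_rt if peak else float("nan"),
                "rt_start": peak.rt_start if peak else float("nan"),
                "rt_end": peak.rt_end if peak else float("nan"),
                "height": peak.height if peak else float("nan"),
                "signal_to_noise": peak.signal_to_noise if peak else float("nan"),
            }
        )
    return pd.DataFrame(rows)


def _pair_control(
    sheet: pd.DataFrame, row: pd.Series
) -> str | None:
    """sample_id of the untreated control matching a treated test sample."""
    match = sheet[
        (sheet["role"] == "test")
        & (sheet["treatment"] == "untreated")
        & (sheet["group"] == row["group"])
        & (sheet["matrix"] == row["matrix"])
        & (sheet["replicate"] == row["replicate"])
    ]
    if match.empty:
        return None
    return str(match.iloc[0]["sample_id"])


def detect_study(
    runs: dict[str, Run],
    sample_sheet: pd.DataFrame,
    panel: list[TargetCompound],
    params: DetectionParams = DetectionParams(),
    validate: bool = False,
) -> pd.DataFrame:
    """Detection decisions for every treated test sample × panel compound.

    Drug-derived compounds are gated against the paired untreated control
    of the same group/matrix/replicate; endogenous compounds (present in
    every sample by nature) are detected without the control veto. With
    ``validate=True`` each decision also carries the isotope-envelope score
    and the subformula fragment-explanation score with its median ppm
    deviation.
    """
    rows = []
    treated = sample_sheet[
        (sample_sheet["role"] == "test") & (sample_sheet["treatment"] == "treated")
    ]
    for _, sample in treated.iterrows():
        run = runs[sample["sample_id"]]
        control_id = _pair_control(sample_sheet, sample)
        control = runs.get(control_id) if control_id else None
        for target in panel:
            decision = detect_compound(
                run,
                None if target.endogenous else control,
                target,
                params,
            )
            row = {
                "sample_id": sample["sample_id"],
                "compound": target.name,
                "detected": decision.detected,
                "area": decision.precursor.area if decision.precursor else float("nan"),
                "apex_rt": decision.precursor.apex_rt if decision.precursor else float("nan"),
                "n_fragments": decision.n_fragments,
                "fragments_total": decision.fragments_total,
                "control_veto": decision.control_veto,
                "control_area": decision.control_area,
            }
            if validate and decision.precursor is not None:
                envelope = measured_envelope(run, target, decision.precursor.apex_rt)
                iso = (
                    isotope_pattern_score(
                        envelope,
                        isotope_pattern(target.formula, adduct="[M-H]-"),
                        mz_tol_ppm=params.mz_tol_ppm,
                    )
                    if envelope
                    else None
                )
                score = validate_fragments(
                    target, list(decision.fragments_present), isotope_score=iso
                )
                row.update(
                    {
                        "isotope_score": iso,
                        "fragment_score": score.fragment_score,
                        "median_ppm_deviation": score.median_ppm_deviation,
                    }
                )
            rows.append(row)
    return pd.DataFrame(rows)


def calibrate_study(
    runs: dict[str, Run],
    sample_sheet: pd.DataFrame,
    panel: list[TargetCompound],
    compounds: list[str] | None = None,
    params: DetectionParams = DetectionParams(),
) -> dict[str, CalibrationCurve]:
    """Fit the dilution-series calibration for each standard compound."""
    calibrants = sample_sheet[sample_sheet["role"] == "calibrant"]
    if calibrants.empty:
        raise ValueError("sample sheet contains no calibrant runs")
    by_name = {t.name: t for t in panel}
    if compounds is None:
        compounds = list(by_name)
    curves: dict[str, CalibrationCurve] = {}
    for name in compounds:
        target = by_name[name]
        points = []
        for _, sample in calibrants.iterrows():
            run = runs[sample["sample_id"]]
            measured = measure_run(run, [target], params)
            area = measured["area"].iloc[0]
            if pd.notna(area):
                points.append((float(sample["calibrant_concentration"]), float(area)))
        if len(points) >= 3:
            curves[name] = fit_calibration(points, compound=name)
    return curves


def quantify_study(
    runs: dict[str, Run],
    sample_sheet: pd.DataFrame,
    panel: list[TargetCompound],
    params: DetectionParams = DetectionParams(),
    qc_compound: str = "FdUMP",
) -> pd.DataFrame:
    """Reference-normalized measurements for every treated test sample.

    Each sample's areas are divided by the QC reference-standard area of
    its replicate batch (the QC run with the same replicate number).
    Raises with the batch name when a batch has no QC run.
    """
    qc_rows = sample_sheet[sample_sheet["role"] == "qc"]
    qc_target = [t for t in panel if t.name == qc_compound]
    if not qc_target:
        raise ValueError(f"panel must contain the {qc_compound} reference compound")
    qc_areas: dict[int, float] = {}
    for _, sample in qc_rows.iterrows():
        area = measure_run(runs[sample["sample_id"]], qc_target, params)["area"].iloc[0]
        if pd.notna(area) and area > 0:
            qc_areas[int(sample["replicate"])] = float(area)

    rows = []
    treated = sample_sheet[
        (sample_sheet["role"] == "test") & (sample_sheet["treatment"] == "treated")
    ]
    for _, sample in treated.iterrows():
        batch = int(sample["replicate"])
        if batch not in qc_areas:
            raise ValueError(f"no QC reference run for replicate batch {batch}")
        reference = qc_areas[batch]
        measured = measure_run(runs[sample["sample_id"]], panel, params)
        for _, m in measured.iterrows():
            if pd.isna(m["area"]):
                continue
            rows.append(
                {
                    "sample_id": m["sample_id"],
                    "compound": m["compound"],
                    "area": m["area"],
                    "reference_area": reference,
                    "ratio": normalize_to_reference(m["area"], reference),
                }
            )
    return pd.DataFrame(rows, columns=["sample_id", "compound", "area", "reference_area", "ratio"])


@dataclass
class StudyReport:
    detections: pd.DataFrame
    measurements: pd.DataFrame
    calibrations: dict[str, CalibrationCurve]
    summary: pd.DataFrame


def process_study(
    runs: dict[str, Run],
    sample_sheet: pd.DataFrame,
    panel: list[TargetCompound],
    params: DetectionParams = DetectionParams(),
    calibration_compounds: list[str] | None = None,
    alpha: float = 0.05,
    fdr: bool = False,
) -> StudyReport:
    """Full pipeline: detect, quantify, calibrate, compare."""
    detections = detect_study(runs, sample_sheet, panel, params)
    measurements = quantify_study(runs, sample_sheet, panel, params)
    has_cal = (sample_sheet["role"] == "calibrant").any()
    calibrations = (
        calibrate_study(
            runs,
            sample_sheet,
            panel,
            compounds=calibration_compounds or ["5-FU", "FdUMP"],
            params=params,
        )
        if has_cal
        else {}
    )
    summary = summarize_study(detections, measurements, sample_sheet, alpha=alpha, fdr=fdr)
    return StudyReport(
        detections=detections,
        measurements=measurements,
        calibrations=calibrations,
        summary=summary,
    )
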