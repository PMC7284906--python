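"""Detection decisions and identity validation.

A compound is called *detected* in a treated sample when its precursor peak
is found, enough of its fingerprint fragments co-elute, and — when the
paired untreated control is available — the same signal is absent from the
control. Identity is additionally validated by the agreement of the
measured precursor isotope envelope with theory and by explaining each
fragment as an elemental sub-multiset of the deprotonated precursor.

The isotope and fragment-explanation scores are this package's own 0–100
analogues of the commercial validation scores used in the emulated
workflow; their semantics (higher is better, 5 ppm deviation gate) are
preserved but the formulas are defined here, not reproduced.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from statistics import median

import numpy as np

from .extract import (
    PeakDetection,
    collect_fragment_evidence,
    detect_peaks,
    extract_xic,
    integrate_peak,
    select_precursor_peak,
)
from .formula import (
    IsotopePattern,
    enumerate_subformulas,
    monoisotopic_mass,
    ppm_window,
    ppm_deviation,
)
from .masses import ELECTRON_MASS
from .panel import TargetCompound
from .spectra import Run

__all__ = [
    "DetectionParams",
    "DetectionDecision",
    "ValidationScore",
    "detect_compound",
    "isotope_pattern_score",
    "validate_fragments",
    "measured_envelope",
]


@dataclass(frozen=True)
class DetectionParams:
    """Tunable thresholds of the detection rule."""

    mz_tol_ppm: float = 5.0  # precursor/fragment extraction tolerance
    rt_tol: float = 0.1  # minutes, fragment co-elution gate
    min_fragments: int = 1  # fingerprint fragments required
    veto_fraction: float = 0.1  # control XIC area fraction that vetoes
    min_snr: float = 3.0
    min_points: int = 3


@dataclass(frozen=True)
class DetectionDecision:
    """Outcome of the treated-vs-control detection rule for one compound."""

    compound: str
    sample_id: str
    detected: bool
    precursor: PeakDetection | None = None
    fragments_present: tuple[float, ...] = ()
    fragments_total: int = 0
    control_veto: bool = False
    control_area: float = 0.0

    @property
    def n_fragments(self) -> int:
        return len(self.fragments_present)


def detect_compound(
    treated: Run,
    control: Run | None,
    target: TargetCompound,
    params: DetectionParams = DetectionParams(),
) -> DetectionDecision:
    """Apply the full detection rule for one compound in one sample.

    Detected iff (1) a precursor XIC peak is found — the one nearest the
    expected RT when known, else the largest; (2) at least
    ``min_fragments`` fingerprint fragments co-elute within ``rt_tol`` of
    the precursor apex; and (3) if a paired untreated control run is given,
    the control's XIC area over the same window and RT bounds stays below
    ``veto_fraction`` times the treated area. Extraction centers on the
    exact computed [M-H]- m/z.
    """
    window = ppm_window(target.theoretical_mz, params.mz_tol_ppm)
    xic = extract_xic(treated, window, ms_level=1)
    peaks = detect_peaks(xic, min_snr=params.min_snr, min_points=params.min_points)
    peak = select_precursor_peak(peaks, target.expected_rt)
    if peak is None:
        return DetectionDecision(
            compound=target.name,
            sample_id=treated.sample_id,
            detected=False,
            fragments_total=len(target.fragments),
        )

    evidence = collect_fragment_evidence(
        treated, target, peak, rt_tol=params.rt_tol, mz_tol_ppm=params.mz_tol_ppm
    )
    present = tuple(mz for mz, det in evidence.items() if det is not None)

    veto = False
    control_area = 0.0
    if control is not None:
        ctrl_xic = extract_xic(control, window, ms_level=1)
        if len(ctrl_xic) >= 2:
            lo = max(peak.rt_start, float(ctrl_xic.rt[0]))
            hi = min(peak.rt_end, float(ctrl_xic.rt[-1]))
            if lo < hi:
                control_area = integrate_peak(ctrl_xic, (lo, hi))
        if peak.area > 0 and control_area > params.veto_fraction * peak.area:
            veto = True

    detected = (
        len(present) >= params.min_fragments
        and not veto
    )
    return DetectionDecision(
        compound=target.name,
        sample_id=treated.sample_id,
        detected=detected,
        precursor=peak,
        fragments_present=present,
        fragments_total=len(target.fragments),
        control_veto=veto,
        control_area=control_area,
    )


def measured_envelope(
    run: Run, target: TargetCompound, apex_rt: float, rt_tol: float = 0.05
) -> list[tuple[float, float]]:
    """Centroids of the SIM scan nearest the precursor apex.

    Returns the (m/z, intensity) list of the target's own SIM scan closest
    in RT to ``apex_rt`` — the measured isotope envelope to score.
    """
    best = None
    for s in run.ms1_spectra():
        if s.sim_window is None or not s.sim_window.contains(target.precursor_mz):
            continue
        if best is None or abs(s.retention_time - apex_rt) < abs(
            best.retention_time - apex_rt
        ):
            best = s
    if best is None or abs(best.retention_time - apex_rt) > rt_tol:
        return []
    return list(zip(best.mz.tolist(), best.intensity.tolist()))


def isotope_pattern_score(
    measured: list[tuple[float, float]],
    theoretical: IsotopePattern,
    mz_tol_ppm: float = 5.0,
) -> float:
    """0–100 agreement between a measured and theoretical isotope envelope.

    Theoretical peaks are matched to the nearest measured centroid within
    the ppm tolerance; both envelopes are normalized to their base peak and
    the score is ``100 * (1 - L1distance / L1norm(theory))``, clipped to
    [0, 100]. An unmatched monoisotopic peak scores 0 outright.
    """
    if not measured:
        raise ValueError("measured envelope is empty")
    theo = theoretical.base_peak_normalized()
    meas_mz = np.array([m for m, _ in measured])
    meas_int = np.array([i for _, i in measured], dtype=float)
    base = meas_int.max()
    if base <= 0:
        return 0.0
    meas_rel = meas_int / base

    matched = np.zeros(len(theo))
    for k, (mz, _) in enumerate(theo):
        devs = np.abs(meas_mz - mz)
        j = int(devs.argmin())
        if devs[j] <= mz * mz_tol_ppm * 1e-6:
            matched[k] = meas_rel[j]
        elif k == 0:
            return 0.0  # monoisotopic peak unmatched
    theo_rel = np.array([ab for _, ab in theo])
    distance = np.abs(matched - theo_rel).sum() / theo_rel.sum()
    return float(np.clip(100.0 * (1.0 - distance), 0.0, 100.0))


@dataclass(frozen=True)
class ValidationScore:
    """Identity-validation summary for one compound in one sample."""

    compound: str
    isotope_score: float | None  # 0-100, None when no envelope measured
    fragment_score: float  # 0-100: share of fragments explained
    median_ppm_deviation: float | None  # None when nothing explained
    explained: int
    total: int
    explanations: dict[float, str] = field(default_factory=dict)

    @property
    def passes(self) -> bool:
        """5 ppm median-deviation gate on explained fragments."""
        return (
            self.median_ppm_deviation is not None
            and abs(self.median_ppm_deviation) <= 5.0
        )


def validate_fragments(
    target: TargetCompound,
    observed_fragments: list[float],
    tol_ppm: float = 10.0,
    isotope_score: float | None = None,
) -> ValidationScore:
    """Explain observed fragment m/z as subformulas of the precursor anion.

    Each observed fragment is *explained* when at least one elemental
    sub-multiset of the deprotonated target composition matches its anion
    m/z within ``tol_ppm``. The fragment score is 100 × explained/total
    (0 for an empty list); the median signed ppm deviation is taken over
    each explained fragment's best subformula.
    """
    parent = target.ion_composition()
    explanations: dict[float, str] = {}
    deviations: list[float] = []
    for frag in observed_fragments:
        candidates = enumerate_subformulas(parent, frag, tol_ppm=tol_ppm)
        if not candidates:
            continue
        best = candidates[0]
        explanations[frag] = best.hill_formula()
        deviations.append(
            ppm_deviation(frag, monoisotopic_mass(best) + ELECTRON_MASS)
        )
    total = len(observed_fragments)
    explained = len(explanations)
    return ValidationScore(
        compound=target.name,
        isotope_score=isotope_score,
        fragment_score=100.0 * explained / total if total else 0.0,
        median_ppm_deviation=median(deviations) if deviations else None,
        explained=explained,
        total=total,
        explanations=explanations,
    )
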