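"""Targeted chromatogram extraction and peak integration.

From a run and a fingerprint panel: inclusion lists, ppm-windowed extracted
ion chromatograms (XICs), local-maximum peak detection with valley/baseline
boundaries, trapezoidal baseline-subtracted integration, and collection of
co-eluting MS2 fragment evidence over the precursor's integration bounds.

Peak boundaries are deliberately simple and fully documented (walk from the
apex to the nearest valley or baseline return): the workflow this package
automates delegated peak picking to interactive software, so the boundary
rule here is the package's own definition.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .formula import MzWindow, ppm_window, sim_window
from .panel import TargetCompound
from .spectra import Run

__all__ = [
    "Chromatogram",
    "PeakDetection",
    "build_inclusion_list",
    "extract_xic",
    "detect_peaks",
    "integrate_peak",
    "collect_fragment_evidence",
]


@dataclass(frozen=True)
class Chromatogram:
    """Intensity vs retention time within one m/z window."""

    rt: np.ndarray  # minutes, strictly increasing
    intensity: np.ndarray
    window: MzWindow
    ms_level: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "rt", np.asarray(self.rt, dtype=float))
        object.__setattr__(self, "intensity", np.asarray(self.intensity, dtype=float))
        if self.rt.shape != self.intensity.shape:
            raise ValueError("rt and intensity arrays differ in length")
        if self.rt.size > 1 and np.any(np.diff(self.rt) <= 0):
            raise ValueError("chromatogram RT must be strictly increasing")
        if np.any(self.intensity < 0):
            raise ValueError("chromatogram intensities must be non-negative")

    def __len__(self) -> int:
        return self.rt.size


@dataclass(frozen=True)
class PeakDetection:
    """One integrated chromatographic peak."""

    apex_rt: float
    rt_start: float
    rt_end: float
    area: float  # intensity * minutes, baseline-subtracted
    height: float
    signal_to_noise: float

    def __post_init__(self) -> None:
        if not self.rt_start < self.apex_rt < self.rt_end:
            raise ValueError("apex must lie strictly inside the peak bounds")
        if self.area < 0:
            raise ValueError("peak area must be non-negative")


def build_inclusion_list(
    targets: list[TargetCompound], isolation_width: float = 4.0
) -> pd.DataFrame:
    """tSIM inclusion list: one SIM window per panel compound.

    The ``scan_filter`` column is formatted like the instrument's scan
    filter display, four decimals with an en dash.
    """
    if not targets:
        raise ValueError("empty target list")
    names = [t.name for t in targets]
    if len(set(names)) != len(names):
        raise ValueError("duplicate compound names in target list")
    rows = []
    for t in targets:
        window = sim_window(t.precursor_mz, isolation_width)
        rows.append(
            {
                "name": t.name,
                "precursor_mz": t.precursor_mz,
                "window_low": window.low,
                "window_high": window.high,
                "scan_filter": f"{window.low:.4f}–{window.high:.4f}",
            }
        )
    return pd.DataFrame(rows)


def extract_xic(
    run: Run,
    window: MzWindow,
    ms_level: int = 1,
    precursor_filter: float | None = None,
    precursor_tol_ppm: float = 5.0,
) -> Chromatogram:
    """Extracted ion chromatogram: one point per qualifying spectrum.

    A spectrum qualifies when its MS level matches; MS1 SIM scans must have
    an isolation window overlapping the request (scans that could not have
    observed the window contribute nothing rather than zeros), and MS2
    extraction is restricted to scans whose precursor target matches
    ``precursor_filter`` within ``precursor_tol_ppm``.
    """
    rts: list[float] = []
    intensities: list[float] = []
    for s in run.spectra:
        if s.ms_level != ms_level:
            continue
        if ms_level == 1 and s.sim_window is not None and not s.sim_window.overlaps(window):
            continue
        if ms_level == 2 and precursor_filter is not None:
            if s.precursor_target is None:
                continue
            if abs(s.precursor_target - precursor_filter) > precursor_filter * precursor_tol_ppm * 1e-6:
                continue
        rts.append(s.retention_time)
        intensities.append(s.intensity_in(window))
    return Chromatogram(
        rt=np.array(rts), intensity=np.array(intensities), window=window, ms_level=ms_level
    )


def estimate_noise(xic: Chromatogram) -> float:
    """Robust noise level: scaled MAD of the lowest-quartile intensities."""
    if len(xic) == 0:
        return 0.0
    q = np.quantile(xic.intensity, 0.25)
    low = xic.intensity[xic.intensity <= q]
    if low.size == 0:
        return 0.0
    mad = np.median(np.abs(low - np.median(low)))
    return float(1.4826 * mad)


def detect_peaks(
    xic: Chromatogram, min_snr: float = 3.0, min_points: int = 3
) -> list[PeakDetection]:
    """Local maxima above the noise floor, with valley/baseline bounds.

    The noise estimate is the scaled median absolute deviation of the
    lowest intensity quartile. Candidate apexes are strict local maxima
    exceeding ``min_snr`` times the noise; bounds extend from the apex to
    the nearest valley (intensity rising again) or baseline return
    (intensity at or below the noise floor). Peaks spanning fewer than
    ``min_points`` samples are discarded. Returned sorted by area, largest
    first.
    """
    if min_points < 3:
        raise ValueError("min_points must be at least 3")
    n = len(xic)
    if n < min_points:
        return []
    y = xic.intensity
    noise = estimate_noise(xic)
    floor = max(noise, 1e-12 * (y.max() if y.size else 1.0))
    threshold = min_snr * floor

    apexes = [
        i
        for i in range(1, n - 1)
        if y[i] > threshold and y[i] >= y[i - 1] and y[i] > y[i + 1]
    ]
    peaks: list[PeakDetection] = []
    for i in apexes:
        left = i
        while left > 0 and y[left - 1] < y[left] and y[left - 1] > floor:
            left -= 1
        if left > 0 and y[left - 1] <= floor:
            left -= 1  # include the baseline-return point
        right = i
        while right < n - 1 and y[right + 1] < y[right] and y[right + 1] > floor:
            right += 1
        if right < n - 1 and y[right + 1] <= floor:
            right += 1
        if right - left + 1 < min_points or left >= i or right <= i:
            continue
        area = integrate_peak(xic, (xic.rt[left], xic.rt[right]))
        snr = float(y[i] / floor) if floor > 0 else float("inf")
        peaks.append(
            PeakDetection(
                apex_rt=float(xic.rt[i]),
                rt_start=float(xic.rt[left]),
                rt_end=float(xic.rt[right]),
                area=area,
                height=float(y[i]),
                signal_to_noise=snr,
            )
        )
    peaks.sort(key=lambda p: p.area, reverse=True)
    return peaks


def integrate_peak(xic: Chromatogram, bounds: tuple[float, float]) -> float:
    """Baseline-subtracted trapezoidal area over ``bounds``.

    A straight baseline is drawn between the chromatogram's intensities at
    the two bound RTs and subtracted; negative excursions are floored at
    zero before integrating. Area units: intensity * minutes.
    """
    lo, hi = bounds
    if lo >= hi:
        raise ValueError(f"inverted integration bounds ({lo}, {hi})")
    if len(xic) == 0:
        return 0.0
    if lo < xic.rt[0] - 1e-9 or hi > xic.rt[-1] + 1e-9:
        raise ValueError("integration bounds outside the chromatogram RT range")
    mask = (xic.rt >= lo) & (xic.rt <= hi)
    rt = xic.rt[mask]
    y = xic.intensity[mask]
    if rt.size < 2:
        return 0.0
    baseline = y[0] + (y[-1] - y[0]) * (rt - rt[0]) / max(rt[-1] - rt[0], 1e-12)
    corrected = np.maximum(y - baseline, 0.0)
    return float(np.trapezoid(corrected, rt))


def select_precursor_peak(
    peaks: list[PeakDetection], expected_rt: float | None
) -> PeakDetection | None:
    """The peak nearest the expected RT when known, else the largest."""
    if not peaks:
        return None
    if expected_rt is None:
        return peaks[0]  # detect_peaks sorts by area
    return min(peaks, key=lambda p: abs(p.apex_rt - expected_rt))


def collect_fragment_evidence(
    run: Run,
    target: TargetCompound,
    precursor_peak: PeakDetection,
    rt_tol: float = 0.1,
    mz_tol_ppm: float = 5.0,
) -> dict[float, PeakDetection | None]:
    """Co-eluting MS2 evidence for each fingerprint fragment.

    Each fragment's precursor-filtered MS2 XIC is integrated over the
    precursor's RT bounds (shared bounds, so the combined precursor +
    product "total area" is well defined). A fragment counts as present —
    non-None value — when its apex falls within ``rt_tol`` minutes of the
    precursor apex and its area is positive above the local noise.
    """
    evidence: dict[float, PeakDetection | None] = {}
    for frag_mz in target.fragments:
        xic = extract_xic(
            run,
            ppm_window(frag_mz, mz_tol_ppm),
            ms_level=2,
            precursor_filter=target.precursor_mz,
            precursor_tol_ppm=mz_tol_ppm,
        )
        evidence[frag_mz] = None
        if len(xic) < 2:
            continue
        lo = max(precursor_peak.rt_start, float(xic.rt[0]))
        hi = min(precursor_peak.rt_end, float(xic.rt[-1]))
        if lo >= hi:
            continue
        mask = (xic.rt >= lo) & (xic.rt <= hi)
        if mask.sum() < 2 or not xic.intensity[mask].any():
            continue
        apex_idx = np.argmax(np.where(mask, xic.intensity, -np.inf))
        apex_rt = float(xic.rt[apex_idx])
        if abs(apex_rt - precursor_peak.apex_rt) > rt_tol:
            continue
        area = integrate_peak(xic, (lo, hi))
        noise = estimate_noise(xic)
        height = float(xic.intensity[apex_idx])
        if area <= 0 or height <= noise:
            continue
        if not lo < apex_rt < hi:
            continue
        evidence[frag_mz] = PeakDetection(
            apex_rt=apex_rt,
            rt_start=lo,
            rt_end=hi,
            area=area,
            height=height,
            signal_to_noise=height / noise if noise > 0 else float("inf"),
        )
    return evidence
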