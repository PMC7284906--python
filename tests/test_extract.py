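"""Extraction tests: inclusion lists, XICs, peak detection and integration."""

import math

import numpy as np
import pytest

from tsimquant.extract import (
    Chromatogram,
    build_inclusion_list,
    collect_fragment_evidence,
    detect_peaks,
    extract_xic,
    integrate_peak,
    select_precursor_peak,
)
from tsimquant.formula import MzWindow, ppm_window
from tsimquant.simulate import AcquisitionParams, AnalyteSpec, simulate_run
from tsimquant.spectra import Run, Spectrum

from conftest import gaussian_chromatogram


# --------------------------------------------------------------------------
# inclusion list


def test_inclusion_list_has_one_window_per_target(panel):
    table = build_inclusion_list(panel, isolation_width=4.0)
    assert len(table) == 8
    fdump = table[table["name"] == "FdUMP"].iloc[0]
    assert fdump["window_low"] == pytest.approx(323.024)
    assert fdump["window_high"] == pytest.approx(327.024)
    assert fdump["scan_filter"] == "323.0240–327.0240"


def test_inclusion_list_window_geometry_for_panel(panel):
    """All window pairs are disjoint except TMP/FdUMP, whose precursors sit
    3.976 m/z apart: their 4 m/z windows share a sliver of 0.024 m/z, far
    from either precursor or its envelope."""
    table = build_inclusion_list(panel, isolation_width=4.0)
    rows = sorted(zip(table["window_low"], table["window_high"], table["name"]))
    for (lo1, hi1, n1), (lo2, hi2, n2) in zip(rows, rows[1:]):
        if {n1, n2} == {"TMP", "FdUMP"}:
            assert 0 < hi1 - lo2 < 0.03
        else:
            assert hi1 < lo2


def test_inclusion_list_rejects_duplicates(fdump):
    with pytest.raises(ValueError, match="duplicate"):
        build_inclusion_list([fdump, fdump])


def test_inclusion_list_single_target_window(fdump):
    table = build_inclusion_list([fdump], isolation_width=2.0)
    assert table.iloc[0]["window_low"] == pytest.approx(324.024)


# --------------------------------------------------------------------------
# XIC extraction


def _one_scan_run(mz, intensity, rt=1.0):
    return Run(
        [Spectrum(1, rt, np.array([mz]), np.array([intensity]))], "one"
    )


def test_extract_xic_captures_lone_centroid():
    run = _one_scan_run(129.0106, 5000.0)
    xic = extract_xic(run, ppm_window(129.0106, 5))
    assert len(xic) == 1
    assert xic.intensity[0] == 5000.0


def test_extract_xic_disjoint_window_gives_zero_point():
    run = _one_scan_run(129.0106, 5000.0)
    xic = extract_xic(run, MzWindow(200.0, 201.0))
    assert len(xic) == 1
    assert xic.intensity[0] == 0.0


def test_extract_xic_skips_nonoverlapping_sim_scans(fdump):
    """SIM scans that could not observe the window contribute no points."""
    scans = [
        Spectrum(1, 1.0, np.array([325.024]), np.array([100.0]),
                 sim_window=MzWindow(323.024, 327.024)),
        Spectrum(1, 1.001, np.array([129.01]), np.array([50.0]),
                 sim_window=MzWindow(127.01, 131.01)),
    ]
    xic = extract_xic(Run(scans, "two"), ppm_window(325.024, 5))
    assert len(xic) == 1


def test_extract_xic_ms2_precursor_filter():
    scans = [
        Spectrum(2, 1.0, np.array([96.969]), np.array([10.0]), precursor_target=325.024),
        Spectrum(2, 1.001, np.array([96.969]), np.array([20.0]), precursor_target=307.033),
    ]
    xic = extract_xic(
        Run(scans, "ms2"), ppm_window(96.969, 10), ms_level=2, precursor_filter=325.024
    )
    assert len(xic) == 1
    assert xic.intensity[0] == 10.0


def test_xic_linearity_under_intensity_scaling(clean_fdump_run, fdump):
    run, _ = clean_fdump_run
    scaled = Run(
        [
            Spectrum(s.ms_level, s.retention_time, s.mz, s.intensity * 2.0,
                     s.sim_window, s.precursor_target, s.collision_label)
            for s in run.spectra
        ],
        "scaled",
    )
    window = ppm_window(fdump.theoretical_mz, 5)
    x1 = extract_xic(run, window)
    x2 = extract_xic(scaled, window)
    a1 = integrate_peak(x1, (x1.rt[0], x1.rt[-1]))
    a2 = integrate_peak(x2, (x2.rt[0], x2.rt[-1]))
    assert a2 == pytest.approx(2.0 * a1, rel=1e-12)


# --------------------------------------------------------------------------
# peak detection


def test_detect_peaks_flat_zero_signal():
    xic = Chromatogram(
        rt=np.linspace(1, 2, 50), intensity=np.zeros(50),
        window=MzWindow(99, 101), ms_level=1,
    )
    assert detect_peaks(xic) == []


def test_detect_peaks_single_gaussian():
    xic = gaussian_chromatogram(1000.0, 0.05, apex=1.5)
    peaks = detect_peaks(xic)
    assert len(peaks) == 1
    assert peaks[0].apex_rt == pytest.approx(1.5, abs=0.011)
    assert peaks[0].rt_start < 1.5 < peaks[0].rt_end
    assert peaks[0].height == pytest.approx(1000.0, rel=1e-6)


def test_detect_peaks_resolves_two_separated_gaussians():
    rt = np.arange(1.0, 2.0, 0.005)
    y = 1000 * np.exp(-0.5 * ((rt - 1.25) / 0.03) ** 2) + 800 * np.exp(
        -0.5 * ((rt - 1.75) / 0.03) ** 2
    )
    xic = Chromatogram(rt=rt, intensity=y, window=MzWindow(99, 101), ms_level=1)
    peaks = detect_peaks(xic)
    assert len(peaks) == 2
    apexes = sorted(p.apex_rt for p in peaks)
    assert apexes[0] == pytest.approx(1.25, abs=0.01)
    assert apexes[1] == pytest.approx(1.75, abs=0.01)
    assert peaks[0].area > peaks[1].area  # sorted by area


def test_detect_peaks_min_points_guard():
    xic = gaussian_chromatogram(1000.0, 0.05)
    with pytest.raises(ValueError):
        detect_peaks(xic, min_points=2)


def test_select_precursor_peak_prefers_expected_rt():
    xic = gaussian_chromatogram(1000.0, 0.03, apex=1.3)
    big = detect_peaks(xic)[0]
    small_xic = gaussian_chromatogram(500.0, 0.03, apex=1.8)
    small = detect_peaks(small_xic)[0]
    assert select_precursor_peak([big, small], expected_rt=1.8) is small
    assert select_precursor_peak([big, small], expected_rt=None) is big
    assert select_precursor_peak([], expected_rt=1.0) is None


# --------------------------------------------------------------------------
# integration


def test_integrate_rectangle():
    rt = np.array([0.9, 1.0, 1.5, 2.0, 2.1])
    y = np.array([0.0, 100.0, 100.0, 100.0, 0.0])
    xic = Chromatogram(rt=rt, intensity=y, window=MzWindow(99, 101), ms_level=1)
    assert integrate_peak(xic, (0.9, 2.1)) == pytest.approx(100.0, rel=0.11)


def test_integrate_noiseless_gaussian_within_1pct():
    xic = gaussian_chromatogram(1000.0, 0.05, apex=1.5)
    area = integrate_peak(xic, (1.5 - 4 * 0.05, 1.5 + 4 * 0.05))
    assert area == pytest.approx(1000.0 * 0.05 * math.sqrt(2 * math.pi), rel=0.01)


def test_integrate_all_zero_signal():
    xic = Chromatogram(
        rt=np.linspace(0, 1, 20), intensity=np.zeros(20),
        window=MzWindow(99, 101), ms_level=1,
    )
    assert integrate_peak(xic, (0.1, 0.9)) == 0.0


def test_integrate_inverted_bounds_raise():
    xic = gaussian_chromatogram(10.0, 0.05)
    with pytest.raises(ValueError, match="nverted"):
        integrate_peak(xic, (2.0, 1.0))


def test_integrate_bounds_outside_range_raise():
    xic = gaussian_chromatogram(10.0, 0.05, apex=1.5)
    with pytest.raises(ValueError, match="outside"):
        integrate_peak(xic, (0.0, 10.0))


def test_area_recovery_over_random_parameterizations():
    """100 random (A, sigma) noiseless peaks integrate to A*sigma*sqrt(2pi)."""
    rng = np.random.default_rng(1234)
    for _ in range(100):
        amplitude = rng.uniform(1e3, 1e6)
        sigma = rng.uniform(0.01, 0.1)
        xic = gaussian_chromatogram(amplitude, sigma, apex=2.0)
        area = integrate_peak(xic, (2.0 - 4 * sigma, 2.0 + 4 * sigma))
        assert area == pytest.approx(
            amplitude * sigma * math.sqrt(2 * math.pi), rel=0.01
        )


# --------------------------------------------------------------------------
# fragment evidence


def test_fragment_evidence_all_present_in_simulated_run(clean_fdump_run, fdump):
    run, _ = clean_fdump_run
    xic = extract_xic(run, ppm_window(fdump.theoretical_mz, 5))
    peak = detect_peaks(xic)[0]
    evidence = collect_fragment_evidence(run, fdump, peak)
    assert all(v is not None for v in evidence.values())
    assert set(evidence) == set(fdump.fragments)


def test_fragment_evidence_empty_without_ms2(fdump):
    analyte = AnalyteSpec(compound=fdump, concentration=1.0, rt_jitter_sd=0.0)
    acq = AcquisitionParams(trigger_threshold=1e30)  # nothing ever triggers
    run, _ = simulate_run([analyte], acquisition=acq, seed=3)
    xic = extract_xic(run, ppm_window(fdump.theoretical_mz, 5))
    peak = detect_peaks(xic)[0]
    evidence = collect_fragment_evidence(run, fdump, peak)
    assert all(v is None for v in evidence.values())


def test_fragment_spike_far_from_precursor_apex_excluded(fdump):
    """An MS2 fragment eluting away from the precursor apex is not evidence."""
    precursor_scans = [
        Spectrum(1, rt, np.array([fdump.theoretical_mz]),
                 np.array([1e5 * math.exp(-0.5 * ((rt - 1.4) / 0.03) ** 2)]),
                 sim_window=fdump.sim_window)
        for rt in np.arange(1.2, 1.6, 0.01)
    ]
    # fragment trace peaking 0.15 min late, inside the precursor bounds
    ms2_scans = [
        Spectrum(2, rt + 0.001, np.array([96.969]),
                 np.array([1e4 * math.exp(-0.5 * ((rt - 1.55) / 0.03) ** 2)]),
                 precursor_target=fdump.precursor_mz)
        for rt in np.arange(1.2, 1.6, 0.01)
    ]
    spectra = sorted(precursor_scans + ms2_scans, key=lambda s: s.retention_time)
    run = Run(spectra, "spiked")
    xic = extract_xic(run, ppm_window(fdump.theoretical_mz, 5))
    peak = detect_peaks(xic)[0]
    evidence = collect_fragment_evidence(run, fdump, peak, rt_tol=0.1)
    assert evidence[96.969] is None
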