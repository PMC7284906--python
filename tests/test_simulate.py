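"""Simulator tests: determinism, area conservation, study layout."""

import hashlib

import numpy as np
import pytest

from tsimquant.extract import extract_xic, integrate_peak
from tsimquant.formula import ppm_window
from tsimquant.panel import builtin_panel
from tsimquant.simulate import (
    DILUTION_SERIES,
    AcquisitionParams,
    AnalyteSpec,
    MatrixSpec,
    biological_scatter,
    default_study_design,
    simulate_run,
    simulate_study,
)
from tsimquant.spectra import write_run


def _digest(run, tmp_path, name):
    path = write_run(run, tmp_path / name)
    return hashlib.sha256(path.read_bytes()).hexdigest()


def test_zero_concentration_produces_no_analyte_peaks(fdump):
    analyte = AnalyteSpec(compound=fdump, concentration=0.0)
    run, manifest = simulate_run([analyte], seed=1)
    assert manifest.empty
    assert len(run) > 0  # SIM windows still scheduled
    assert all(s.mz.size == 0 for s in run.ms1_spectra())
    assert not list(run.ms2_spectra())


def test_same_seed_bit_identical_different_seed_differs(fdump, tmp_path):
    analyte = AnalyteSpec(compound=fdump, concentration=1.0)
    matrix = MatrixSpec(baseline_noise=500.0)
    runs = [simulate_run([analyte], matrix, seed=s)[0] for s in (5, 5, 6)]
    d1, d2, d3 = (_digest(r, tmp_path, f"r{i}.run.jsonl") for i, r in enumerate(runs))
    assert d1 == d2
    assert d1 != d3


def test_noiseless_xic_area_matches_manifest(clean_fdump_run, fdump):
    run, manifest = clean_fdump_run
    xic = extract_xic(run, ppm_window(fdump.theoretical_mz, 5))
    area = integrate_peak(xic, (xic.rt[0], xic.rt[-1]))
    assert area == pytest.approx(manifest["true_area"].iloc[0], rel=0.01)


def test_xic_apex_within_one_cycle_of_manifest(clean_fdump_run, fdump):
    run, manifest = clean_fdump_run
    xic = extract_xic(run, ppm_window(fdump.theoretical_mz, 5))
    apex = xic.rt[int(np.argmax(xic.intensity))]
    assert abs(apex - manifest["apex_rt"].iloc[0]) <= AcquisitionParams().cycle_time


def test_total_envelope_conservation_at_zero_noise(fdump):
    """Summed analyte intensity across all scans equals the manifest total."""
    analyte = AnalyteSpec(compound=fdump, concentration=2.0, rt_jitter_sd=0.0)
    acq = AcquisitionParams(mz_error_ppm_sd=0.0)
    run, manifest = simulate_run([analyte], acquisition=acq, seed=0)
    cycle = acq.cycle_time
    total = sum(s.intensity.sum() for s in run.ms1_spectra()) * cycle
    assert total == pytest.approx(manifest["true_total_area"].iloc[0], rel=0.01)


def test_ms2_triggered_only_on_intense_precursor(fdump):
    strong = AnalyteSpec(compound=fdump, concentration=1.0)
    run, _ = simulate_run([strong], seed=2)
    ms2 = list(run.ms2_spectra())
    assert ms2
    assert all(s.precursor_target == fdump.precursor_mz for s in ms2)
    # every MS2 precursor lies inside the corresponding SIM window
    assert all(fdump.sim_window.contains(s.precursor_target) for s in ms2)
    weak = AnalyteSpec(compound=fdump, concentration=1e-6)
    run, _ = simulate_run([weak], seed=2)
    assert not list(run.ms2_spectra())


def test_elution_order_follows_panel_retention_times(panel):
    """Apex RTs preserve the configured elution order of the panel."""
    analytes = [
        AnalyteSpec(compound=t, concentration=1.0, rt_jitter_sd=0.0)
        for t in panel
        if t.expected_rt is not None
    ]
    _, manifest = simulate_run(analytes, seed=0)
    order = manifest.sort_values("apex_rt")["compound"].tolist()
    assert order.index("FdUMP") < order.index("TMP") < order.index("5-FU")
    assert order.index("5-FU") < order.index("FURD") < order.index("FdURD")


def test_analyte_inclusion_list_mismatch_raises(panel_by_name):
    fdump = panel_by_name["FdUMP"]
    other = builtin_panel()  # fresh objects, same names
    with pytest.raises(ValueError, match="inclusion-list"):
        simulate_run(
            [AnalyteSpec(compound=fdump, concentration=1.0)],
            targets=[t for t in other if t.name == "FdUMP"],
        )


# --------------------------------------------------------------------------
# whole-study simulation


@pytest.fixture(scope="module")
def small_study():
    return simulate_study(default_study_design(replicates=2), seed=42)


def test_dilution_series_layout(small_study):
    assert len(DILUTION_SERIES) == 10
    assert DILUTION_SERIES[0] == 100.0
    assert DILUTION_SERIES[-1] == pytest.approx(0.1953125)
    cal = small_study.sample_sheet[small_study.sample_sheet["role"] == "calibrant"]
    assert len(cal) == 10
    assert sorted(cal["calibrant_concentration"]) == sorted(DILUTION_SERIES)


def test_qc_reference_per_replicate_batch(small_study):
    qc = small_study.sample_sheet[small_study.sample_sheet["role"] == "qc"]
    assert sorted(qc["replicate"]) == [1, 2]
    assert (qc["calibrant_concentration"] == 0.780).all()


def test_untreated_runs_lack_drug_derived_analytes(small_study):
    sheet = small_study.sample_sheet
    manifest = small_study.manifest
    untreated = sheet[(sheet["role"] == "test") & (sheet["treatment"] == "untreated")]
    present = manifest[manifest["sample_id"].isin(untreated["sample_id"])]
    assert set(present["compound"]) <= {"dUMP", "TMP"}
    assert {"dUMP", "TMP"} <= set(present["compound"])


def test_futp_fdutp_absent_everywhere(small_study):
    assert not set(small_study.manifest["compound"]) & {"FUTP", "FdUTP"}


def test_configured_group_fold_change_by_construction(small_study):
    manifest = small_study.manifest
    sheet = small_study.sample_sheet.set_index("sample_id")
    rows = manifest[manifest["compound"] == "FdUMP"].copy()
    rows["group"] = rows["sample_id"].map(sheet["group"])
    rows["treatment"] = rows["sample_id"].map(sheet["treatment"])
    rows = rows[(rows["treatment"] == "treated") & rows["group"].isin(["parental", "resistant"])]
    # design sets resistant FdUMP mean to 0.4x parental; scatter is CV 20%
    ratio = (
        rows[rows.group == "resistant"]["concentration"].mean()
        / rows[rows.group == "parental"]["concentration"].mean()
    )
    assert 0.2 < ratio < 0.8


def test_biological_scatter_is_mean_preserving():
    rng = np.random.default_rng(0)
    draws = biological_scatter(rng, mean=2.0, cv=0.2, size=20000)
    assert draws.min() > 0
    assert draws.mean() == pytest.approx(2.0, rel=0.01)
    assert draws.std() / draws.mean() == pytest.approx(0.2, rel=0.05)


def test_analyte_spec_validation(fdump):
    with pytest.raises(ValueError):
        AnalyteSpec(compound=fdump, concentration=-1.0)
    with pytest.raises(ValueError):
        AnalyteSpec(compound=fdump, concentration=1.0, fragment_yields=(0.5,))
    with pytest.raises(ValueError):
        AnalyteSpec(compound=fdump, concentration=1.0, peak_width_sigma=0.0)
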