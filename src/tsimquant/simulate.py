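"""Ground-truth simulator of tSIM-ddMS2 acquisitions.

Emulates the study design the package targets: scheduled MS1 SIM scans over
±2 m/z inclusion windows around each panel precursor, data-dependent MS2
scans triggered when a precursor is observed, Gaussian chromatographic
elution of polar analytes in the 1.4–2.1 min range, a two-fold calibrant
dilution series from 100 down to 0.195 ng/µL, a 0.780 ng/µL reference
standard injected per replicate batch, and parental/resistant ×
treated/untreated test samples with log-normal biological scatter.

Every run comes with a ground-truth manifest (true areas, apex RTs,
concentrations) so each downstream stage can be tested against what was
actually put in.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .formula import isotope_pattern
from .panel import TargetCompound, builtin_panel
from .spectra import Run, Spectrum, SAMPLE_SHEET_COLUMNS

__all__ = [
    "AnalyteSpec",
    "MatrixSpec",
    "AcquisitionParams",
    "StudyDesign",
    "StudyResult",
    "simulate_run",
    "simulate_study",
    "default_study_design",
    "biological_scatter",
    "DILUTION_SERIES",
]

# Two-fold serial dilution, 100 down to 0.195 ng/µL (10 calibrant levels).
DILUTION_SERIES: tuple[float, ...] = tuple(100.0 / 2**k for k in range(10))

QC_CONCENTRATION = 0.780  # ng/µL reference-standard level
QC_COMPOUND = "FdUMP"


@dataclass(frozen=True)
class AcquisitionParams:
    """Instrument-style schedule parameters for the simulated runs."""

    rt_start: float = 0.8  # minutes
    rt_end: float = 2.6
    cycle_time: float = 0.015  # minutes per SIM+ddMS2 duty cycle (~0.9 s)
    isolation_width: float = 4.0  # m/z, tSIM window
    ms2_isolation: float = 1.2
    trigger_threshold: float = 1e4  # counts; precursor intensity to fire MS2
    loop_count: int = 4  # max MS2 events per cycle
    mz_error_ppm_sd: float = 1.0  # centroid mass-error model
    collision_label: str = "HCD 25"
    ms1_resolution: int = 120_000
    ms2_resolution: int = 15_000

    def metadata(self) -> dict:
        return {
            "ms1_resolution": self.ms1_resolution,
            "ms2_resolution": self.ms2_resolution,
            "isolation_width": self.isolation_width,
            "ms2_isolation": self.ms2_isolation,
            "loop_count": self.loop_count,
            "collision_label": self.collision_label,
            "cycle_time_min": self.cycle_time,
        }


@dataclass(frozen=True)
class AnalyteSpec:
    """One analyte to put into a simulated run.

    ``response_factor`` is defined on the monoisotopic extracted-ion trace:
    the area of the monoisotopic XIC equals concentration × response_factor
    at zero noise; heavier isotopologues ride on top at their natural
    abundance ratios. ``fragment_yields`` are MS2 fragment intensities
    relative to the instantaneous precursor intensity.
    """

    compound: TargetCompound
    concentration: float  # ng/µL
    expected_rt: float | None = None  # minutes; default = compound's RT
    rt_jitter_sd: float = 0.01  # minutes
    peak_width_sigma: float = 0.03  # minutes
    response_factor: float = 2e5  # monoisotopic area counts·min per ng/µL
    fragment_yields: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if self.concentration < 0:
            raise ValueError("concentration must be non-negative")
        if self.peak_width_sigma <= 0 or self.response_factor <= 0:
            raise ValueError("peak width and response factor must be positive")
        if self.fragment_yields is not None:
            if len(self.fragment_yields) != len(self.compound.fragments):
                raise ValueError(
                    f"{self.compound.name}: fragment_yields length mismatch"
                )
            if any(not 0 <= y <= 1 for y in self.fragment_yields):
                raise ValueError("fragment yields must be in [0, 1]")

    def yields(self) -> tuple[float, ...]:
        if self.fragment_yields is not None:
            return self.fragment_yields
        return tuple(0.5 / (k + 1) for k in range(len(self.compound.fragments)))

    def rt(self) -> float:
        if self.expected_rt is not None:
            return self.expected_rt
        if self.compound.expected_rt is not None:
            return self.compound.expected_rt
        return 1.7  # polar analytes elute early; generic default


@dataclass(frozen=True)
class MatrixSpec:
    """Background of the biological matrix: interferents and noise.

    ``interference_peaks`` are (m/z, apex intensity, apex RT, sigma_min)
    Gaussians of near-isobaric co-eluting junk. ``baseline_noise`` sets the
    scale of additive chemical noise: each scan gains Poisson-many random
    centroids with exponentially distributed intensity at that scale, and
    every real centroid gains |N(0, baseline_noise)| counts.
    """

    interference_peaks: tuple[tuple[float, float, float, float], ...] = ()
    baseline_noise: float = 0.0

    def __post_init__(self) -> None:
        if self.baseline_noise < 0:
            raise ValueError("noise level must be non-negative")
        if any(i[1] < 0 for i in self.interference_peaks):
            raise ValueError("interference intensities must be non-negative")


def _gauss(t: float, apex: float, sigma: float, amplitude: float) -> float:
    z = (t - apex) / sigma
    if abs(z) > 6.0:
        return 0.0
    return amplitude * math.exp(-0.5 * z * z)


def simulate_run(
    analytes: list[AnalyteSpec],
    matrix: MatrixSpec | None = None,
    acquisition: AcquisitionParams | None = None,
    seed: int = 0,
    sample_id: str = "sim",
    targets: list[TargetCompound] | None = None,
) -> tuple[Run, pd.DataFrame]:
    """Simulate one tSIM-ddMS2 acquisition; return the run and its manifest.

    SIM windows are scheduled for every target on the inclusion list
    (default: the compounds of ``analytes``, so zero-concentration analytes
    still get their windows — the instrument does not know they are
    absent). The manifest lists one row per analyte actually present with
    its true monoisotopic XIC area, total envelope area and apex RT.
    """
    matrix = matrix or MatrixSpec()
    acq = acquisition or AcquisitionParams()
    if targets is None:
        targets = [a.compound for a in analytes]
    names = [t.name for t in targets]
    if len(set(names)) != len(names):
        raise ValueError("duplicate targets on the inclusion list")
    by_target = {t.name: t for t in targets}
    for a in analytes:
        if a.compound.name in by_target and by_target[a.compound.name] is not a.compound:
            raise ValueError(
                f"analyte {a.compound.name} does not match the inclusion-list target"
            )

    rng = np.random.default_rng(seed)

    # Per-analyte precomputation: apex RT (one jitter draw per run), Gaussian
    # amplitude on the monoisotopic trace, isotope envelope relative to it.
    active = []
    manifest_rows = []
    for a in analytes:
        apex = a.rt() + (rng.normal(0.0, a.rt_jitter_sd) if a.rt_jitter_sd > 0 else 0.0)
        if a.concentration <= 0:
            continue
        area = a.concentration * a.response_factor
        amplitude = area / (a.peak_width_sigma * math.sqrt(2 * math.pi))
        pattern = isotope_pattern(a.compound.formula, adduct="[M-H]-")
        mono_ab = pattern.peaks[0][1]
        envelope = tuple((mz, ab / mono_ab) for mz, ab in pattern.peaks)
        # only envelope peaks inside the compound's SIM window are acquired
        acquired = sum(
            r for mz, r in envelope if a.compound.sim_window.contains(mz)
        )
        active.append((a, apex, amplitude, envelope))
        manifest_rows.append(
            {
                "sample_id": sample_id,
                "compound": a.compound.name,
                "concentration": a.concentration,
                "true_area": area,
                "true_total_area": area * acquired,
                "apex_rt": apex,
            }
        )

    ppm_sd = acq.mz_error_ppm_sd * 1e-6
    noise = matrix.baseline_noise
    spectra: list[Spectrum] = []
    n_cycles = int(round((acq.rt_end - acq.rt_start) / acq.cycle_time))
    slot = acq.cycle_time / (len(targets) + acq.loop_count + 1)

    for c in range(n_cycles):
        t = acq.rt_start + c * acq.cycle_time
        scan_idx = 0
        triggers: list[tuple[TargetCompound, AnalyteSpec, float]] = []
        for target in targets:
            window = target.sim_window
            mzs: list[float] = []
            ints: list[float] = []
            for a, apex, amplitude, envelope in active:
                height = _gauss(t, apex, a.peak_width_sigma, amplitude)
                if height <= 0.0:
                    continue
                if a.compound.name == target.name and height > acq.trigger_threshold:
                    triggers.append((target, a, height))
                for mz, rel in envelope:
                    if window.contains(mz):
                        obs = mz * (1.0 + rng.normal(0.0, ppm_sd)) if ppm_sd > 0 else mz
                        mzs.append(obs)
                        ints.append(height * rel)
            for mz, intensity, rt0, sigma in matrix.interference_peaks:
                if window.contains(mz):
                    height = _gauss(t, rt0, sigma, intensity)
                    if height > 0.0:
                        mzs.append(mz * (1.0 + rng.normal(0.0, ppm_sd)) if ppm_sd > 0 else mz)
                        ints.append(height)
            if noise > 0.0:
                ints = [i + abs(rng.normal(0.0, noise)) for i in ints]
                for _ in range(rng.poisson(1.0)):
                    mzs.append(rng.uniform(window.low, window.high))
                    ints.append(rng.exponential(noise))
            mz_arr, int_arr = _as_centroid_arrays(mzs, ints)
            spectra.append(
                Spectrum(
                    ms_level=1,
                    retention_time=t + scan_idx * slot,
                    mz=mz_arr,
                    intensity=int_arr,
                    sim_window=window,
                )
            )
            scan_idx += 1
        for target, a, height in triggers[: acq.loop_count]:
            yields = a.yields()
            mzs = []
            ints = []
            for frag_mz, y in zip(target.fragments, yields):
                obs = frag_mz * (1.0 + rng.normal(0.0, ppm_sd)) if ppm_sd > 0 else frag_mz
                intensity = y * height
                if noise > 0.0:
                    intensity += abs(rng.normal(0.0, noise))
                mzs.append(obs)
                ints.append(intensity)
            mz_arr, int_arr = _as_centroid_arrays(mzs, ints)
            spectra.append(
                Spectrum(
                    ms_level=2,
                    retention_time=t + scan_idx * slot,
                    mz=mz_arr,
                    intensity=int_arr,
                    precursor_target=target.precursor_mz,
                    collision_label=acq.collision_label,
                )
            )
            scan_idx += 1

    run = Run(spectra=spectra, sample_id=sample_id, metadata=acq.metadata())
    manifest = pd.DataFrame(
        manifest_rows,
        columns=[
            "sample_id",
            "compound",
            "concentration",
            "true_area",
            "true_total_area",
            "apex_rt",
        ],
    )
    return run, manifest


def _as_centroid_arrays(mzs: list[float], ints: list[float]) -> tuple[np.ndarray, np.ndarray]:
    """Sort centroids by m/z and merge coincident ones (strict ordering)."""
    if not mzs:
        return np.array([]), np.array([])
    order = np.argsort(mzs)
    mz = np.asarray(mzs, dtype=float)[order]
    intensity = np.asarray(ints, dtype=float)[order]
    keep_mz: list[float] = []
    keep_int: list[float] = []
    for m, i in zip(mz, intensity):
        if keep_mz and m - keep_mz[-1] <= 1e-9:
            keep_int[-1] += i
        else:
            keep_mz.append(m)
            keep_int.append(i)
    return np.array(keep_mz), np.array(keep_int)


def biological_scatter(
    rng: np.random.Generator, mean: float, cv: float, size: int | None = None
):
    """Mean-preserving log-normal replicate-to-replicate variation.

    Draws are log-normal with E[X] = ``mean`` and coefficient of variation
    ``cv`` — concentrations stay positive and group means equal the
    configured values, so configured fold changes are fold changes of
    expectations.
    """
    if mean <= 0:
        return np.zeros(size) if size is not None else 0.0
    sigma = math.sqrt(math.log(1.0 + cv * cv))
    return mean * rng.lognormal(mean=-0.5 * sigma * sigma, sigma=sigma, size=size)


# ---------------------------------------------------------------------------
# Whole-study simulation


@dataclass(frozen=True)
class StudyDesign:
    """Layout of a simulated comparative study.

    ``means`` maps group -> matrix -> compound -> mean concentration in
    treated samples (ng/µL). Untreated controls carry the endogenous
    compounds at the same means and none of the drug-derived ones.
    """

    means: dict[str, dict[str, dict[str, float]]]
    panel: list[TargetCompound] = field(default_factory=builtin_panel)
    replicates: int = 10
    cv: float = 0.20  # biological coefficient of variation
    include_untreated: bool = True
    include_calibration: bool = True
    calibration_compounds: tuple[str, ...] = ("5-FU", "FdUMP")
    calibration_levels: tuple[float, ...] = DILUTION_SERIES
    qc_compound: str = QC_COMPOUND
    qc_concentration: float = QC_CONCENTRATION
    acquisition: AcquisitionParams = AcquisitionParams()
    matrix_spec: MatrixSpec = MatrixSpec()
    response_factor: float = 2e5
    peak_width_sigma: float = 0.03
    rt_jitter_sd: float = 0.01

    def groups(self) -> list[str]:
        return list(self.means)

    def matrices(self) -> list[str]:
        first = next(iter(self.means.values()))
        return list(first)


@dataclass
class StudyResult:
    runs: dict[str, Run]
    sample_sheet: pd.DataFrame
    manifest: pd.DataFrame


def default_study_design(**overrides) -> StudyDesign:
    """The study conditions emulated by default.

    Ten biological replicates per group; in the resistant group the
    fluorinated metabolites FdUMP, FURD and (in media) FdURD sit at 0.4× the
    parental mean while 5-FU and the endogenous nucleotides are unchanged;
    FUTP and FdUTP are absent everywhere (below detection in the emulated
    study); FdURD appears only in media. Calibration runs a two-fold
    dilution series (100…0.195 ng/µL) of 5-FU and FdUMP, and every
    replicate batch carries a 0.780 ng/µL FdUMP reference injection.
    """
    parental_lysate = {
        "5-FU": 5.0,
        "FdUMP": 2.0,
        "FURD": 1.0,
        "FdURD": 0.0,
        "FUTP": 0.0,
        "FdUTP": 0.0,
        "dUMP": 1.5,
        "TMP": 1.2,
    }
    parental_media = dict(parental_lysate, FdURD=0.8, dUMP=1.8)
    reduced = {"FdUMP", "FURD", "FdURD"}
    fold = 0.4
    resistant_lysate = {
        k: v * (fold if k in reduced else 1.0) for k, v in parental_lysate.items()
    }
    resistant_media = {
        k: v * (fold if k in reduced else 1.0) for k, v in parental_media.items()
    }
    means = {
        "parental": {"lysate": parental_lysate, "media": parental_media},
        "resistant": {"lysate": resistant_lysate, "media": resistant_media},
    }
    overrides.setdefault("means", means)
    overrides.setdefault("matrix_spec", default_matrix())
    return StudyDesign(**overrides)


def default_matrix() -> MatrixSpec:
    """Biological-matrix background used by the default study conditions.

    A handful of near-isobaric interferents — inside the SIM windows but
    outside the 5 ppm extraction windows, eluting away from the analytes —
    plus additive chemical noise three orders of magnitude below a typical
    analyte apex, emulating the crowded low-mass region of lysate and media
    extracts.
    """
    return MatrixSpec(
        interference_peaks=(
            (326.2, 8e5, 1.1, 0.05),  # inside the FdUMP SIM window
            (128.3, 6e5, 1.9, 0.08),  # inside the 5-FU SIM window
            (306.5, 4e5, 1.6, 0.06),  # inside the dUMP SIM window
        ),
        baseline_noise=2000.0,
    )


def _analyte(
    design: StudyDesign, compound: TargetCompound, concentration: float
) -> AnalyteSpec:
    return AnalyteSpec(
        compound=compound,
        concentration=concentration,
        rt_jitter_sd=design.rt_jitter_sd,
        peak_width_sigma=design.peak_width_sigma,
        response_factor=design.response_factor,
    )


def simulate_study(design: StudyDesign, seed: int = 0) -> StudyResult:
    """Simulate every run of a study; returns runs, sample sheet, manifest."""
    if not design.means:
        raise ValueError("study design names no groups")
    rng = np.random.default_rng(seed)
    panel = {t.name: t for t in design.panel}
    runs: dict[str, Run] = {}
    sheet_rows: list[dict] = []
    manifests: list[pd.DataFrame] = []

    def add_run(sample_id, analytes, group, treatment, matrix, replicate, role, conc=None):
        run_seed = int(rng.integers(0, 2**31 - 1))
        run, manifest = simulate_run(
            analytes,
            matrix=design.matrix_spec,
            acquisition=design.acquisition,
            seed=run_seed,
            sample_id=sample_id,
            targets=design.panel,
        )
        runs[sample_id] = run
        manifests.append(manifest)
        sheet_rows.append(
            {
                "sample_id": sample_id,
                "group": group,
                "treatment": treatment,
                "matrix": matrix,
                "replicate": replicate,
                "role": role,
                "calibrant_concentration": conc,
            }
        )

    # calibrant dilution series (standards in processed media, exact levels)
    if design.include_calibration:
        cal_compounds = [panel[n] for n in design.calibration_compounds]
        for level in design.calibration_levels:
            analytes = [_analyte(design, c, level) for c in cal_compounds]
            add_run(
                f"cal_{level:g}",
                analytes,
                group="standard",
                treatment="untreated",
                matrix="media",
                replicate=1,
                role="calibrant",
                conc=level,
            )

    # one QC reference injection per replicate batch
    qc = panel[design.qc_compound]
    for rep in range(1, design.replicates + 1):
        add_run(
            f"qc_r{rep}",
            [_analyte(design, qc, design.qc_concentration)],
            group="standard",
            treatment="untreated",
            matrix="media",
            replicate=rep,
            role="qc",
            conc=design.qc_concentration,
        )

    # test samples
    for group, by_matrix in design.means.items():
        for matrix, compound_means in by_matrix.items():
            for rep in range(1, design.replicates + 1):
                treatments = ["treated"] + (
                    ["untreated"] if design.include_untreated else []
                )
                for treatment in treatments:
                    analytes = []
                    for name, mean in compound_means.items():
                        compound = panel[name]
                        if treatment == "untreated" and not compound.endogenous:
                            conc = 0.0
                        else:
                            conc = float(biological_scatter(rng, mean, design.cv))
                        analytes.append(_analyte(design, compound, conc))
                    sample_id = f"{group}_{treatment[:3]}_{matrix[:3]}_r{rep}"
                    add_run(sample_id, analytes, group, treatment, matrix, rep, "test")

    sheet = pd.DataFrame(sheet_rows, columns=SAMPLE_SHEET_COLUMNS)
    manifest = (
        pd.concat(manifests, ignore_index=True)
        if manifests
        else pd.DataFrame(
            columns=["sample_id", "compound", "concentration", "true_area", "true_total_area", "apex_rt"]
        )
    )
    return StudyResult(runs=runs, sample_sheet=sheet, manifest=manifest)
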