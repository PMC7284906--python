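"""Data model and I/O for centroided tSIM-ddMS2 acquisitions.

Two on-disk representations are supported:

* a lossless line-delimited JSON fixture format (``.run.jsonl``) — one
  header record then one record per spectrum — used throughout the test
  suite and by the simulator;
* mzML as the interchange path, read and written by a compact
  centroided-data serializer/parser in this module (64-bit and 32-bit float
  arrays, optional zlib compression on read).

Retention times are stored in minutes everywhere; the mzML layer converts
from/to whatever unit the file declares.
"""

from __future__ import annotations

import base64
import json
import struct
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .formula import MzWindow

__all__ = [
    "Spectrum",
    "Run",
    "read_run",
    "write_run",
    "read_sample_sheet",
    "write_sample_sheet",
    "SAMPLE_SHEET_COLUMNS",
]


@dataclass
class Spectrum:
    """One centroided scan with its acquisition provenance."""

    ms_level: int
    retention_time: float  # minutes
    mz: np.ndarray
    intensity: np.ndarray
    sim_window: MzWindow | None = None  # MS1 SIM isolation window
    precursor_target: float | None = None  # MS2 precursor m/z
    collision_label: str = ""

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.ms_level not in (1, 2):
            raise ValueError("ms_level must be 1 or 2")
        if self.mz.shape != self.intensity.shape:
            raise ValueError("mz and intensity arrays differ in length")
        if self.mz.size and np.any(np.diff(self.mz) <= 0):
            raise ValueError("mz array must be strictly increasing")
        if np.any(self.intensity < 0):
            raise ValueError("intensities must be non-negative")
        if self.ms_level == 2 and self.precursor_target is None:
            raise ValueError("MS2 spectrum requires a precursor target m/z")

    def intensity_in(self, window: MzWindow) -> float:
        """Summed centroid intensity inside an m/z window."""
        lo = np.searchsorted(self.mz, window.low, side="left")
        hi = np.searchsorted(self.mz, window.high, side="right")
        return float(self.intensity[lo:hi].sum())


@dataclass
class Run:
    """An RT-ordered acquisition for one injected sample."""

    spectra: list[Spectrum]
    sample_id: str
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        rts = [s.retention_time for s in self.spectra]
        if any(b < a for a, b in zip(rts, rts[1:])):
            raise ValueError("spectra must be in non-decreasing RT order")

    def __len__(self) -> int:
        return len(self.spectra)

    def ms1_spectra(self) -> Iterable[Spectrum]:
        return (s for s in self.spectra if s.ms_level == 1)

    def ms2_spectra(self) -> Iterable[Spectrum]:
        return (s for s in self.spectra if s.ms_level == 2)


# ---------------------------------------------------------------------------
# Fixture format (line-delimited JSON)


def _spectrum_record(s: Spectrum) -> dict:
    return {
        "type": "spectrum",
        "ms_level": s.ms_level,
        "rt": s.retention_time,
        "mz": s.mz.tolist(),
        "intensity": s.intensity.tolist(),
        "sim_window": [s.sim_window.low, s.sim_window.high] if s.sim_window else None,
        "precursor_target": s.precursor_target,
        "collision_label": s.collision_label,
    }


def _write_fixture(run: Run, path: Path) -> None:
    with path.open("w") as fh:
        header = {
            "type": "run",
            "format": "tsimquant-fixture-v1",
            "sample_id": run.sample_id,
            "metadata": run.metadata,
        }
        fh.write(json.dumps(header) + "\n")
        for s in run.spectra:
            fh.write(json.dumps(_spectrum_record(s)) + "\n")


def _read_fixture(path: Path) -> Run:
    spectra: list[Spectrum] = []
    sample_id = path.stem
    metadata: dict = {}
    with path.open() as fh:
        for i, line in enumerate(fh):
            line = line.strip()
            if not line:
                continue
            try:
                rec = json.loads(line)
            except json.JSONDecodeError as exc:
                raise IOError(f"{path}: malformed record at line {i + 1}") from exc
            if rec.get("type") == "run":
                sample_id = rec.get("sample_id", sample_id)
                metadata = rec.get("metadata", {})
                continue
            window = rec.get("sim_window")
            try:
                spectra.append(
                    Spectrum(
                        ms_level=rec["ms_level"],
                        retention_time=rec["rt"],
                        mz=np.array(rec["mz"], dtype=float),
                        intensity=np.array(rec["intensity"], dtype=float),
                        sim_window=MzWindow(*window) if window else None,
                        precursor_target=rec.get("precursor_target"),
                        collision_label=rec.get("collision_label", ""),
                    )
                )
            except (KeyError, ValueError) as exc:
                raise IOError(f"{path}: invalid spectrum at line {i + 1}: {exc}") from exc
    return Run(spectra=spectra, sample_id=sample_id, metadata=metadata)


# ---------------------------------------------------------------------------
# mzML

_NS = "http://psi.hupo.org/ms/mzml"


def _b64(values: np.ndarray) -> str:
    return base64.b64encode(struct.pack(f"<{values.size}d", *values)).decode()


def _cv(parent: ET.Element, accession: str, name: str, value: str = "", **extra: str) -> None:
    attrs = {"cvRef": "MS", "accession": accession, "name": name, "value": value}
    attrs.update(extra)
    ET.SubElement(parent, "cvParam", attrs)


def _binary_array(parent: ET.Element, values: np.ndarray, accession: str, name: str, unit: tuple[str, str, str]) -> None:
    encoded = _b64(values)
    arr = ET.SubElement(
        parent, "binaryDataArray", {"encodedLength": str(len(encoded))}
    )
    _cv(arr, "MS:1000523", "64-bit float")
    _cv(arr, "MS:1000576", "no compression")
    _cv(arr, accession, name, unitCvRef=unit[0], unitAccession=unit[1], unitName=unit[2])
    ET.SubElement(arr, "binary").text = encoded


def _write_mzml(run: Run, path: Path) -> None:
    root = ET.Element(
        "mzML",
        {
            "xmlns": _NS,
            "version": "1.1.0",
            "id": run.sample_id,
        },
    )
    cv_list = ET.SubElement(root, "cvList", {"count": "2"})
    ET.SubElement(cv_list, "cv", {"id": "MS", "fullName": "PSI-MS", "URI": "https://raw.githubusercontent.com/HUPO-PSI/psi-ms-CV/master/psi-ms.obo"})
    ET.SubElement(cv_list, "cv", {"id": "UO", "fullName": "UNIT-ONTOLOGY", "URI": "http://ontologies.berkeleybop.org/uo.obo"})
    fdesc = ET.SubElement(root, "fileDescription")
    fcontent = ET.SubElement(fdesc, "fileContent")
    _cv(fcontent, "MS:1000579", "MS1 spectrum")
    _cv(fcontent, "MS:1000580", "MSn spectrum")
    _cv(fcontent, "MS:1000127", "centroid spectrum")
    soft_list = ET.SubElement(root, "softwareList", {"count": "1"})
    ET.SubElement(soft_list, "software", {"id": "tsimquant", "version": "0.1.0"})
    ic_list = ET.SubElement(root, "instrumentConfigurationList", {"count": "1"})
    ET.SubElement(ic_list, "instrumentConfiguration", {"id": "IC1"})
    dp_list = ET.SubElement(root, "dataProcessingList", {"count": "1"})
    dp = ET.SubElement(dp_list, "dataProcessing", {"id": "DP1"})
    pm = ET.SubElement(dp, "processingMethod", {"order": "1", "softwareRef": "tsimquant"})
    _cv(pm, "MS:1000544", "Conversion to mzML")

    run_el = ET.SubElement(
        root, "run", {"id": run.sample_id, "defaultInstrumentConfigurationRef": "IC1"}
    )
    spec_list = ET.SubElement(
        run_el,
        "spectrumList",
        {"count": str(len(run.spectra)), "defaultDataProcessingRef": "DP1"},
    )
    minute_unit = ("UO", "UO:0000031", "minute")
    mz_unit = ("MS", "MS:1000040", "m/z")
    int_unit = ("MS", "MS:1000131", "number of detector counts")
    for i, s in enumerate(run.spectra):
        spec = ET.SubElement(
            spec_list,
            "spectrum",
            {
                "index": str(i),
                "id": f"scan={i + 1}",
                "defaultArrayLength": str(s.mz.size),
            },
        )
        _cv(spec, "MS:1000511", "ms level", str(s.ms_level))
        _cv(spec, "MS:1000127", "centroid spectrum")
        if s.ms_level == 1:
            if s.sim_window is not None:
                _cv(spec, "MS:1000582", "SIM spectrum")
            else:
                _cv(spec, "MS:1000579", "MS1 spectrum")
        else:
            _cv(spec, "MS:1000580", "MSn spectrum")
        scan_list = ET.SubElement(spec, "scanList", {"count": "1"})
        _cv(scan_list, "MS:1000795", "no combination")
        scan = ET.SubElement(scan_list, "scan")
        _cv(
            scan,
            "MS:1000016",
            "scan start time",
            repr(s.retention_time),
            unitCvRef=minute_unit[0],
            unitAccession=minute_unit[1],
            unitName=minute_unit[2],
        )
        if s.sim_window is not None:
            swl = ET.SubElement(scan, "scanWindowList", {"count": "1"})
            sw = ET.SubElement(swl, "scanWindow")
            _cv(sw, "MS:1000501", "scan window lower limit", repr(s.sim_window.low), unitCvRef="MS", unitAccession="MS:1000040", unitName="m/z")
            _cv(sw, "MS:1000500", "scan window upper limit", repr(s.sim_window.high), unitCvRef="MS", unitAccession="MS:1000040", unitName="m/z")
        if s.ms_level == 2:
            plist = ET.SubElement(spec, "precursorList", {"count": "1"})
            prec = ET.SubElement(plist, "precursor")
            iso = ET.SubElement(prec, "isolationWindow")
            _cv(iso, "MS:1000827", "isolation window target m/z", repr(s.precursor_target), unitCvRef="MS", unitAccession="MS:1000040", unitName="m/z")
            sil = ET.SubElement(prec, "selectedIonList", {"count": "1"})
            si = ET.SubElement(sil, "selectedIon")
            _cv(si, "MS:1000744", "selected ion m/z", repr(s.precursor_target), unitCvRef="MS", unitAccession="MS:1000040", unitName="m/z")
            act = ET.SubElement(prec, "activation")
            _cv(act, "MS:1000422", "beam-type collision-induced dissociation")
            if s.collision_label:
                _cv(act, "MS:1000045", "collision energy", s.collision_label.split()[-1])
        arrays = ET.SubElement(spec, "binaryDataArrayList", {"count": "2"})
        _binary_array(arrays, s.mz, "MS:1000514", "m/z array", mz_unit)
        _binary_array(arrays, s.intensity, "MS:1000515", "intensity array", int_unit)

    ET.indent(root)
    tree = ET.ElementTree(root)
    tree.write(path, xml_declaration=True, encoding="utf-8")


def _strip(tag: str) -> str:
    return tag.rsplit("}", 1)[-1]


def _decode_binary_array(arr_el: ET.Element, default_length: int) -> np.ndarray:
    dtype = "d"
    compressed = False
    text = ""
    for child in arr_el.iter():
        tag = _strip(child.tag)
        if tag == "cvParam":
            acc = child.get("accession")
            if acc == "MS:1000521":
                dtype = "f"  # 32-bit float
            elif acc == "MS:1000574":
                compressed = True  # zlib
        elif tag == "binary":
            text = child.text or ""
    raw = base64.b64decode(text)
    if compressed:
        import zlib

        raw = zlib.decompress(raw)
    values = np.frombuffer(raw, dtype=np.dtype("<" + dtype)).astype(float)
    if default_length and values.size != default_length:
        raise IOError(
            f"binary array length {values.size} != declared {default_length}"
        )
    return values


def _read_mzml(path: Path) -> Run:
    spectra: list[Spectrum] = []
    run_id = path.stem.replace(".run", "")
    for _, el in ET.iterparse(str(path)):
        tag = _strip(el.tag)
        if tag == "run":
            run_id = el.get("id", run_id)
        if tag != "spectrum":
            continue
        index = el.get("index", str(len(spectra)))
        cv = {
            p.get("accession"): p.get("value", "")
            for p in el.iter()
            if _strip(p.tag) == "cvParam"
        }
        if "MS:1000128" in cv:
            raise IOError(
                f"{path}: spectrum {index} is profile mode; only centroided "
                "data are supported"
            )
        try:
            ms_level = int(cv["MS:1000511"])
            rt_value = float(cv["MS:1000016"])
        except KeyError as exc:
            raise IOError(f"{path}: spectrum {index} lacks {exc} metadata") from exc
        rt_minutes = rt_value
        for p in el.iter():
            if _strip(p.tag) == "cvParam" and p.get("accession") == "MS:1000016":
                if "second" in (p.get("unitName") or "minute"):
                    rt_minutes = rt_value / 60.0
                break
        window = None
        if "MS:1000582" in cv and "MS:1000501" in cv and "MS:1000500" in cv:
            window = MzWindow(float(cv["MS:1000501"]), float(cv["MS:1000500"]))
        precursor = None
        collision = ""
        if ms_level == 2:
            value = cv.get("MS:1000744", cv.get("MS:1000827"))
            if value is None:
                raise IOError(f"{path}: MS2 spectrum {index} lacks a precursor m/z")
            precursor = float(value)
            if "MS:1000045" in cv:
                collision = f"HCD {float(cv['MS:1000045']):g}"
        arrays: dict[str, np.ndarray] = {}
        declared = int(el.get("defaultArrayLength", 0))
        for arr_el in el.iter():
            if _strip(arr_el.tag) != "binaryDataArray":
                continue
            accs = {
                p.get("accession")
                for p in arr_el.iter()
                if _strip(p.tag) == "cvParam"
            }
            values = _decode_binary_array(arr_el, declared)
            if "MS:1000514" in accs:
                arrays["mz"] = values
            elif "MS:1000515" in accs:
                arrays["intensity"] = values
        if set(arrays) != {"mz", "intensity"}:
            raise IOError(f"{path}: spectrum {index} lacks m/z or intensity array")
        spectra.append(
            Spectrum(
                ms_level=ms_level,
                retention_time=rt_minutes,
                mz=arrays["mz"],
                intensity=arrays["intensity"],
                sim_window=window,
                precursor_target=precursor,
                collision_label=collision,
            )
        )
        el.clear()
    spectra.sort(key=lambda s: s.retention_time)
    return Run(spectra=spectra, sample_id=run_id)


# ---------------------------------------------------------------------------
# Public I/O surface


def write_run(run: Run, path: str | Path, format: str | None = None) -> Path:
    """Serialize a run as the JSONL fixture format or mzML.

    The format is inferred from the suffix when not given: ``.mzML`` →
    mzML, anything else → fixture.
    """
    path = Path(path)
    if format is None:
        format = "mzML" if path.suffix.lower() == ".mzml" else "fixture"
    if format == "fixture":
        _write_fixture(run, path)
    elif format == "mzML":
        _write_mzml(run, path)
    else:
        raise ValueError(f"unknown run format {format!r}")
    return path


def read_run(path: str | Path) -> Run:
    """Load a run from the fixture format or mzML (auto-detected)."""
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such run file: {path}")
    if path.suffix.lower() == ".mzml":
        return _read_mzml(path)
    return _read_fixture(path)


# ---------------------------------------------------------------------------
# Sample sheet

SAMPLE_SHEET_COLUMNS = [
    "sample_id",
    "group",
    "treatment",
    "matrix",
    "replicate",
    "role",
    "calibrant_concentration",
]

_ROLES = {"test", "calibrant", "qc", "blank"}


def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    """Load and validate the per-sample metadata CSV."""
    sheet = pd.read_csv(path)
    missing = set(SAMPLE_SHEET_COLUMNS) - set(sheet.columns)
    if missing:
        raise ValueError(f"sample sheet missing column(s): {sorted(missing)}")
    return validate_sample_sheet(sheet)


def validate_sample_sheet(sheet: pd.DataFrame) -> pd.DataFrame:
    bad_roles = set(sheet["role"]) - _ROLES
    if bad_roles:
        raise ValueError(f"unknown sample role(s): {sorted(bad_roles)}")
    if sheet["sample_id"].duplicated().any():
        dupes = sheet.loc[sheet["sample_id"].duplicated(), "sample_id"].tolist()
        raise ValueError(f"duplicate sample id(s): {dupes}")
    calibrants = sheet[sheet["role"] == "calibrant"]
    if calibrants["calibrant_concentration"].isna().any():
        raise ValueError("calibrant rows must carry a concentration")
    if (sheet["replicate"].fillna(1) < 1).any():
        raise ValueError("replicate numbers start at 1")
    return sheet


def write_sample_sheet(sheet: pd.DataFrame, path: str | Path) -> Path:
    validate_sample_sheet(sheet)
    sheet.to_csv(path, index=False, columns=SAMPLE_SHEET_COLUMNS)
    return Path(path)
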