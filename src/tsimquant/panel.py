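"""The target-compound fingerprint panel.

A :class:`TargetCompound` bundles everything needed to find and verify one
analyte: its neutral formula, the deprotonated precursor m/z, the fragment
m/z fingerprint, the expected retention time and the SIM isolation window.
The built-in panel covers 5-fluorouracil, five of its metabolites (FdUMP,
FURD, FdURD, FUTP, FdUTP) and the endogenous nucleotides dUMP and TMP;
custom panels load from a TSV/CSV with the same columns.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from io import StringIO
from pathlib import Path

import pandas as pd

from .formula import (
    ElementalComposition,
    MzWindow,
    mz_deprotonated,
    parse_formula,
    ppm_deviation,
    sim_window,
)

__all__ = ["TargetCompound", "load_panel", "builtin_panel", "DEFAULT_ISOLATION_WIDTH"]

DEFAULT_ISOLATION_WIDTH = 4.0  # m/z, the tSIM quadrupole isolation width

_MZ_SANITY_PPM = 5.0


@dataclass(frozen=True)
class TargetCompound:
    """Per-analyte identification and extraction fingerprint."""

    name: str
    formula: ElementalComposition
    precursor_mz: float
    fragments: tuple[float, ...] = ()
    expected_rt: float | None = None  # minutes
    adduct: str = "[M-H]-"
    sim_window: MzWindow = None  # type: ignore[assignment]
    endogenous: bool = False
    catalog_mz: float | None = None

    def __post_init__(self) -> None:
        if self.sim_window is None:
            object.__setattr__(
                self, "sim_window", sim_window(self.precursor_mz, DEFAULT_ISOLATION_WIDTH)
            )
        theoretical = mz_deprotonated(self.formula)
        dev = ppm_deviation(self.precursor_mz, theoretical)
        if abs(dev) > _MZ_SANITY_PPM:
            raise ValueError(
                f"{self.name}: precursor m/z {self.precursor_mz} is {dev:+.1f} ppm "
                f"from the computed [M-H]- value {theoretical:.5f}"
            )
        if any(f >= self.precursor_mz + 0.5 for f in self.fragments):
            raise ValueError(f"{self.name}: fragment heavier than the precursor")
        if not self.sim_window.contains(self.precursor_mz):
            raise ValueError(f"{self.name}: SIM window excludes the precursor")

    @property
    def theoretical_mz(self) -> float:
        """Exact [M-H]- m/z from the pinned mass table."""
        return mz_deprotonated(self.formula)

    def ion_composition(self) -> ElementalComposition:
        """Composition of the deprotonated anion (fragment search parent)."""
        return self.formula.remove("H")


def _panel_from_frame(table: pd.DataFrame, isolation_width: float) -> list[TargetCompound]:
    targets = []
    for row in table.itertuples(index=False):
        fragments = tuple(
            float(x) for x in str(row.fragments).split(";") if x.strip()
        )
        rt = getattr(row, "expected_rt", None)
        rt = None if rt is None or pd.isna(rt) else float(rt)
        catalog = getattr(row, "catalog_mz", None)
        catalog = None if catalog is None or pd.isna(catalog) else float(catalog)
        targets.append(
            TargetCompound(
                name=str(row.name),
                formula=parse_formula(str(row.formula)),
                precursor_mz=float(row.precursor_mz),
                fragments=fragments,
                expected_rt=rt,
                adduct=getattr(row, "adduct", "[M-H]-"),
                sim_window=sim_window(float(row.precursor_mz), isolation_width),
                endogenous=bool(getattr(row, "endogenous", 0)),
                catalog_mz=catalog,
            )
        )
    names = [t.name for t in targets]
    if len(set(names)) != len(names):
        raise ValueError("panel contains duplicate compound names")
    return targets


def load_panel(
    path: str | Path, isolation_width: float = DEFAULT_ISOLATION_WIDTH
) -> list[TargetCompound]:
    """Load a fingerprint panel from TSV (or CSV by ``.csv`` suffix)."""
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    table = pd.read_csv(path, sep=sep, comment="#")
    required = {"name", "formula", "precursor_mz", "fragments"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"panel file missing column(s): {sorted(missing)}")
    return _panel_from_frame(table, isolation_width)


def builtin_panel(
    isolation_width: float = DEFAULT_ISOLATION_WIDTH,
    names: list[str] | None = None,
) -> list[TargetCompound]:
    """The built-in eight-compound 5-FU metabolite panel.

    ``names`` restricts to a subset (order preserved), e.g. for faster
    simulations that only need a few targets.
    """
    text = resources.files("tsimquant.data").joinpath("panel.tsv").read_text()
    table = pd.read_csv(StringIO(text), sep="\t", comment="#")
    targets = _panel_from_frame(table, isolation_width)
    if names is not None:
        by_name = {t.name: t for t in targets}
        unknown = set(names) - set(by_name)
        if unknown:
            raise KeyError(f"unknown panel compound(s): {sorted(unknown)}")
        targets = [by_name[n] for n in names]
    return targets
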