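"""Pinned atomic-mass and isotope-abundance table.

All mass arithmetic in the package goes through this module so that results
are reproducible against one fixed standard table (IUPAC-CIAAW isotopic
compositions with AME atomic masses), shipped as package data.
"""

from __future__ import annotations

import functools
from importlib import resources

__all__ = [
    "ELECTRON_MASS",
    "PROTON_MASS",
    "MASS_TABLE_VERSION",
    "isotopes_of",
    "monoisotopic_mass_of_element",
    "known_elements",
]

# CODATA 2018 values, Da.
ELECTRON_MASS = 0.000548579909
PROTON_MASS = 1.007276466621

MASS_TABLE_VERSION = "IUPAC-CIAAW-2013/AME2016"


@functools.lru_cache(maxsize=1)
def _load_table() -> dict[str, list[tuple[int, float, float]]]:
    """Parse the shipped isotope TSV into {element: [(A, mass, abundance)]}.

    Isotope lists are ordered by mass number; abundances for each element
    sum to 1 within the rounding of the source table.
    """
    table: dict[str, list[tuple[int, float, float]]] = {}
    text = resources.files("tsimquant.data").joinpath("isotopes.tsv").read_text()
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#") or line.startswith("element\t"):
            continue
        element, mass_number, mass, abundance = line.split("\t")
        table.setdefault(element, []).append(
            (int(mass_number), float(mass), float(abundance))
        )
    for isotopes in table.values():
        isotopes.sort()
    return table


def known_elements() -> frozenset[str]:
    """Element symbols covered by the pinned table."""
    return frozenset(_load_table())


def isotopes_of(element: str) -> list[tuple[int, float, float]]:
    """(mass number, exact mass, abundance) triples for one element."""
    try:
        return list(_load_table()[element])
    except KeyError:
        raise KeyError(f"element {element!r} is not in the pinned mass table") from None


def monoisotopic_mass_of_element(element: str) -> float:
    """Exact mass of the most abundant isotope, in Da."""
    return max(isotopes_of(element), key=lambda iso: iso[2])[1]
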