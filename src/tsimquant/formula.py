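"""Elemental-formula mass engine.

Covers everything the targeted workflow needs from a molecular formula:
parsing Hill-notation strings, monoisotopic and deprotonated ([M-H]-) m/z,
natural-abundance isotope envelopes by sparse convolution, ppm and
SIM-isolation m/z windows, and exhaustive-but-pruned subformula enumeration
used to explain fragment ions as pieces of their precursor.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass
from typing import Iterator, Mapping

from .masses import (
    ELECTRON_MASS,
    PROTON_MASS,
    isotopes_of,
    known_elements,
    monoisotopic_mass_of_element,
)

__all__ = [
    "ElementalComposition",
    "IonSpecies",
    "IsotopePattern",
    "MzWindow",
    "FormulaError",
    "parse_formula",
    "monoisotopic_mass",
    "mz_deprotonated",
    "isotope_pattern",
    "ppm_window",
    "sim_window",
    "enumerate_subformulas",
]

# Hill order: C first, H second, the rest alphabetical.
_HILL_HEAD = ("C", "H")
_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


class FormulaError(ValueError):
    """Raised for malformed or chemically impossible formulas."""


@dataclass(frozen=True)
class ElementalComposition:
    """Immutable element -> count multiset; the unit of all mass math."""

    counts: Mapping[str, int]

    def __post_init__(self) -> None:
        counts = dict(self.counts)
        if not counts:
            raise FormulaError("empty composition")
        unknown = set(counts) - known_elements()
        if unknown:
            raise FormulaError(f"unknown element symbol(s): {sorted(unknown)}")
        for element, n in counts.items():
            if not isinstance(n, int) or n < 0:
                raise FormulaError(f"count for {element} must be a non-negative int")
        if all(n == 0 for n in counts.values()):
            raise FormulaError("composition must contain at least one atom")
        object.__setattr__(
            self, "counts", {e: n for e, n in counts.items() if n > 0}
        )

    def __getitem__(self, element: str) -> int:
        return self.counts.get(element, 0)

    def __iter__(self) -> Iterator[tuple[str, int]]:
        return iter(self.counts.items())

    @property
    def atom_count(self) -> int:
        return sum(self.counts.values())

    def hill_formula(self) -> str:
        """Canonical Hill-notation string ('C' then 'H' then alphabetical)."""
        ordered = [e for e in _HILL_HEAD if e in self.counts]
        ordered += sorted(e for e in self.counts if e not in _HILL_HEAD)
        return "".join(
            f"{e}{self.counts[e]}" if self.counts[e] > 1 else e for e in ordered
        )

    def remove(self, element: str, n: int = 1) -> "ElementalComposition":
        """Composition with `n` atoms of `element` removed."""
        if self[element] < n:
            raise FormulaError(
                f"cannot remove {n} x {element} from {self.hill_formula()}"
            )
        counts = dict(self.counts)
        counts[element] -= n
        return ElementalComposition(counts)

    def __contains__(self, other: "ElementalComposition") -> bool:
        """Component-wise sub-multiset test."""
        return all(self[e] >= n for e, n in other)


@dataclass(frozen=True)
class IonSpecies:
    """A charged species: neutral composition plus adduct bookkeeping.

    Only the deprotonated anion [M-H]- is required by the negative-mode
    workflow; the type exists so other adducts can be added later.
    """

    composition: ElementalComposition
    adduct: str = "[M-H]-"
    charge: int = -1

    def __post_init__(self) -> None:
        if self.adduct != "[M-H]-":
            raise FormulaError(f"unsupported adduct {self.adduct!r}")
        if self.charge != -1:
            raise FormulaError("[M-H]- carries charge -1")
        if self.composition["H"] < 1:
            raise FormulaError("[M-H]- requires at least one hydrogen")

    @property
    def mz(self) -> float:
        return mz_deprotonated(self.composition)

    def ion_composition(self) -> ElementalComposition:
        """Elemental composition of the anion itself (neutral minus one H)."""
        return self.composition.remove("H")


@dataclass(frozen=True)
class IsotopePattern:
    """Ordered isotopologue envelope: (m/z, absolute abundance) pairs."""

    peaks: tuple[tuple[float, float], ...]
    truncation: float

    def __post_init__(self) -> None:
        mzs = [mz for mz, _ in self.peaks]
        if any(b <= a for a, b in zip(mzs, mzs[1:])):
            raise ValueError("isotope pattern m/z must be strictly increasing")

    @property
    def monoisotopic_mz(self) -> float:
        return self.peaks[0][0]

    def total_abundance(self) -> float:
        return sum(ab for _, ab in self.peaks)

    def base_peak_normalized(self) -> tuple[tuple[float, float], ...]:
        base = max(ab for _, ab in self.peaks)
        return tuple((mz, ab / base) for mz, ab in self.peaks)


@dataclass(frozen=True)
class MzWindow:
    """Half-open-by-convention [low, high] m/z interval in Da."""

    low: float
    high: float

    def __post_init__(self) -> None:
        if not self.low < self.high:
            raise ValueError(f"invalid window [{self.low}, {self.high}]")

    @property
    def center(self) -> float:
        return 0.5 * (self.low + self.high)

    @property
    def width(self) -> float:
        return self.high - self.low

    def contains(self, mz: float) -> bool:
        return self.low <= mz <= self.high

    def overlaps(self, other: "MzWindow") -> bool:
        return self.low <= other.high and other.low <= self.high


def parse_formula(text: str) -> ElementalComposition:
    """Parse a Hill-notation molecular formula such as ``C9H12FN2O8P``.

    No parentheses, charges or isotope labels: element symbols each followed
    by an optional positive integer, repeats summed.
    """
    text = text.strip()
    if not text:
        raise FormulaError("empty formula string")
    counts: dict[str, int] = {}
    pos = 0
    for match in _TOKEN.finditer(text):
        if match.start() != pos:
            raise FormulaError(f"cannot parse formula {text!r} at {text[pos:]!r}")
        pos = match.end()
        element, digits = match.groups()
        if element not in known_elements():
            raise FormulaError(f"unknown element symbol {element!r} in {text!r}")
        n = int(digits) if digits else 1
        if n <= 0:
            raise FormulaError(f"zero count for {element} in {text!r}")
        counts[element] = counts.get(element, 0) + n
    if pos != len(text):
        raise FormulaError(f"cannot parse formula {text!r} at {text[pos:]!r}")
    return ElementalComposition(counts)


def monoisotopic_mass(comp: ElementalComposition) -> float:
    """Sum of most-abundant-isotope exact masses, in Da."""
    return sum(n * monoisotopic_mass_of_element(e) for e, n in comp)


def mz_deprotonated(comp: ElementalComposition) -> float:
    """[M-H]- m/z: neutral monoisotopic mass minus one proton.

    The electron stays with the anion, so this equals the mass of the
    composition minus a hydrogen atom plus one electron — the convention
    that matters at the ~0.5 mDa level probed by 5 ppm gates on small ions.
    """
    if comp["H"] < 1:
        raise FormulaError("cannot deprotonate a composition without hydrogen")
    return monoisotopic_mass(comp) - PROTON_MASS


# ---------------------------------------------------------------------------
# Isotope envelope by sparse convolution, aggregated by nominal mass.

_PRUNE = 1e-12  # absolute probability floor kept during convolution


def _element_distribution(element: str, n: int) -> dict[int, tuple[float, float]]:
    """Isotope distribution of n atoms of one element.

    Keys are total nucleon numbers; values are (probability,
    probability-weighted exact mass) so centroids fall out of the aggregate.
    """
    isotopes = isotopes_of(element)
    dist: dict[int, tuple[float, float]] = {0: (1.0, 0.0)}
    for _ in range(n):
        nxt: dict[int, tuple[float, float]] = {}
        for a_tot, (p, pm) in dist.items():
            mean_mass = pm / p
            for a, mass, ab in isotopes:
                if ab == 0.0:
                    continue
                q = p * ab
                if q < _PRUNE:
                    continue
                key = a_tot + a
                acc_p, acc_pm = nxt.get(key, (0.0, 0.0))
                nxt[key] = (acc_p + q, acc_pm + q * (mean_mass + mass))
        dist = nxt
    return dist


def _convolve(
    a: dict[int, tuple[float, float]], b: dict[int, tuple[float, float]]
) -> dict[int, tuple[float, float]]:
    out: dict[int, tuple[float, float]] = {}
    for ka, (pa, ma) in a.items():
        for kb, (pb, mb) in b.items():
            q = pa * pb
            if q < _PRUNE:
                continue
            key = ka + kb
            acc_p, acc_m = out.get(key, (0.0, 0.0))
            # weighted masses add as p_a*p_b*(mean_a + mean_b)
            out[key] = (acc_p + q, acc_m + pb * ma + pa * mb)
    return out


def isotope_pattern(
    comp: ElementalComposition,
    adduct: str | None = None,
    truncation: float = 1e-3,
) -> IsotopePattern:
    """Natural-abundance isotopologue envelope of a composition.

    Exact per-element distributions are convolved and aggregated by nominal
    mass (isotopologues sharing a nucleon count merge into one centroid at
    their abundance-weighted mean mass — what a centroided high-resolution
    scan shows at the resolutions used here). ``adduct='[M-H]-'`` computes
    the envelope of the anion: one hydrogen removed, electron mass added.

    Peaks in the low-abundance tail are dropped smallest-first while the
    total probability removed stays below ``truncation``, so the surviving
    abundances always sum to within ``truncation`` of 1.
    """
    if not 0.0 < truncation <= 0.01:
        raise ValueError("truncation must be in (0, 0.01]")
    mz_shift = 0.0
    if adduct == "[M-H]-":
        comp = comp.remove("H")
        mz_shift = ELECTRON_MASS
    elif adduct is not None:
        raise FormulaError(f"unsupported adduct {adduct!r}")

    dist: dict[int, tuple[float, float]] = {0: (1.0, 0.0)}
    for element, n in comp:
        dist = _convolve(dist, _element_distribution(element, n))

    peaks = sorted(
        (pm / p + mz_shift, p) for a, (p, pm) in dist.items() if p > 0.0
    )
    # truncate the tail without ever discarding more than `truncation` total
    order = sorted(range(len(peaks)), key=lambda i: peaks[i][1])
    base = max(ab for _, ab in peaks)
    dropped = 0.0
    drop: set[int] = set()
    for i in order[:-1]:  # never drop the base peak
        ab = peaks[i][1]
        if ab >= truncation * base or dropped + ab > truncation:
            break
        dropped += ab
        drop.add(i)
    kept = tuple(p for i, p in enumerate(peaks) if i not in drop)
    return IsotopePattern(peaks=kept, truncation=truncation)


# ---------------------------------------------------------------------------
# m/z windows


def ppm_window(mz: float, tol_ppm: float) -> MzWindow:
    """Symmetric relative window: mz * (1 ± tol/1e6)."""
    if mz <= 0 or tol_ppm <= 0:
        raise ValueError("mz and tolerance must be positive")
    return MzWindow(mz * (1 - tol_ppm * 1e-6), mz * (1 + tol_ppm * 1e-6))


def sim_window(target_mz: float, isolation_width: float) -> MzWindow:
    """Absolute isolation window centered on the target precursor."""
    if isolation_width <= 0:
        raise ValueError("isolation width must be positive")
    half = 0.5 * isolation_width
    return MzWindow(target_mz - half, target_mz + half)


# ---------------------------------------------------------------------------
# Subformula enumeration (fragment explanation)


def _heteroatom_count(comp: ElementalComposition) -> int:
    return sum(n for e, n in comp if e not in ("C", "H"))


def enumerate_subformulas(
    parent: ElementalComposition,
    observed_mz: float,
    tol_ppm: float = 10.0,
) -> list[ElementalComposition]:
    """All nonempty sub-multisets of ``parent`` whose anion m/z matches.

    A fragment anion's m/z is its monoisotopic mass plus one electron. The
    search is a depth-first walk over per-element counts with
    mass-remaining pruning, exhaustive within the tolerance. Results are
    sorted by |ppm deviation| then by heteroatom count (fewest first), the
    tie-break used when a single explanation must be reported.

    An empty list means the fragment cannot be a piece of this precursor.
    """
    if observed_mz <= 0:
        raise ValueError("observed m/z must be positive")
    target = observed_mz - ELECTRON_MASS  # neutral-fragment monoisotopic mass
    half = observed_mz * tol_ppm * 1e-6
    low, high = target - half, target + half

    elements = sorted(
        parent.counts, key=lambda e: monoisotopic_mass_of_element(e), reverse=True
    )
    masses = [monoisotopic_mass_of_element(e) for e in elements]
    max_counts = [parent[e] for e in elements]
    # max mass attainable from elements[i:]
    suffix_max = [0.0] * (len(elements) + 1)
    for i in range(len(elements) - 1, -1, -1):
        suffix_max[i] = suffix_max[i + 1] + masses[i] * max_counts[i]

    found: list[tuple[float, int, ElementalComposition]] = []
    counts: list[int] = []

    def walk(i: int, mass: float) -> None:
        if mass > high:
            return
        if mass + suffix_max[i] < low:
            return
        if i == len(elements):
            if low <= mass <= high and mass > 0.0:
                comp = ElementalComposition(
                    {e: c for e, c in zip(elements, counts) if c > 0}
                )
                dev = (mass + ELECTRON_MASS - observed_mz) / observed_mz * 1e6
                found.append((abs(dev), _heteroatom_count(comp), comp))
            return
        for c in range(max_counts[i] + 1):
            counts.append(c)
            walk(i + 1, mass + c * masses[i])
            counts.pop()

    walk(0, 0.0)
    found.sort(key=lambda t: (t[0], t[1], t[2].hill_formula()))
    return [comp for _, _, comp in found]


def ppm_deviation(observed_mz: float, reference_mz: float) -> float:
    """Signed relative deviation in parts per million."""
    return (observed_mz - reference_mz) / reference_mz * 1e6
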