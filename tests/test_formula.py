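"""Mass-engine tests: parsing, exact masses, envelopes, windows, subformulas.

The isotope-envelope and subformula operations are checked against
independent brute-force enumeration oracles.
"""

import itertools
import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tsimquant.formula import (
    ElementalComposition,
    FormulaError,
    IonSpecies,
    enumerate_subformulas,
    isotope_pattern,
    monoisotopic_mass,
    mz_deprotonated,
    parse_formula,
    ppm_window,
    sim_window,
)
from tsimquant.masses import ELECTRON_MASS, PROTON_MASS, isotopes_of


# --------------------------------------------------------------------------
# parsing


@pytest.mark.parametrize(
    "text,expected",
    [
        ("C4H3FN2O2", {"C": 4, "H": 3, "F": 1, "N": 2, "O": 2}),
        ("H2O", {"H": 2, "O": 1}),
        ("C9H12FN2O8P", {"C": 9, "H": 12, "F": 1, "N": 2, "O": 8, "P": 1}),
        ("CH4", {"C": 1, "H": 4}),
        ("NaCl", {"Na": 1, "Cl": 1}),
    ],
)
def test_parse_formula(text, expected):
    assert parse_formula(text).counts == expected


@pytest.mark.parametrize("bad", ["", "Xx2", "C0H4", "C-1", "c4", "C4 H3", "H2O)"])
def test_parse_formula_rejects_malformed(bad):
    with pytest.raises(FormulaError):
        parse_formula(bad)


@given(
    st.dictionaries(
        st.sampled_from(["C", "H", "N", "O", "P", "F", "S"]),
        st.integers(min_value=1, max_value=40),
        min_size=1,
        max_size=7,
    )
)
@settings(max_examples=100, deadline=None)
def test_formula_roundtrips_through_hill_notation(counts):
    comp = ElementalComposition(counts)
    assert parse_formula(comp.hill_formula()).counts == comp.counts


def test_composition_invariants():
    with pytest.raises(FormulaError):
        ElementalComposition({})
    with pytest.raises(FormulaError):
        ElementalComposition({"C": 0})
    with pytest.raises(FormulaError):
        ElementalComposition({"Zz": 1})
    with pytest.raises(FormulaError):
        ElementalComposition({"C": -2})


# --------------------------------------------------------------------------
# monoisotopic mass and [M-H]-


def test_monoisotopic_mass_water():
    # 2 x 1.0078250 + 15.9949146 from the pinned table
    assert monoisotopic_mass(parse_formula("H2O")) == pytest.approx(18.0106, abs=1e-4)


def test_monoisotopic_mass_carbon_is_exact():
    assert monoisotopic_mass(parse_formula("C")) == 12.0


def test_monoisotopic_mass_fluorouracil():
    assert monoisotopic_mass(parse_formula("C4H3FN2O2")) == pytest.approx(
        130.0179, abs=5e-4
    )


def test_mz_deprotonated_examples():
    assert mz_deprotonated(parse_formula("H2O")) == pytest.approx(17.0033, abs=1e-4)
    mz = mz_deprotonated(parse_formula("C4H3FN2O2"))
    assert abs(mz - 129.0109) / 129.0109 * 1e6 < 5
    mz = mz_deprotonated(parse_formula("C9H12FN2O8P"))
    assert abs(mz - 325.024) / 325.024 * 1e6 < 5


def test_mz_deprotonated_requires_hydrogen():
    with pytest.raises(FormulaError):
        mz_deprotonated(parse_formula("CO2"))


def test_deprotonation_roundtrip_exact():
    for text in ["H2O", "C4H3FN2O2", "C9H12FN2O8P", "C10H15N2O8P"]:
        comp = parse_formula(text)
        assert abs(
            mz_deprotonated(comp) + PROTON_MASS - monoisotopic_mass(comp)
        ) < 1e-9


def test_ion_species_validation():
    with pytest.raises(FormulaError):
        IonSpecies(parse_formula("CO2"))  # no H to remove
    with pytest.raises(FormulaError):
        IonSpecies(parse_formula("H2O"), adduct="[M+H]+")
    ion = IonSpecies(parse_formula("C4H3FN2O2"))
    assert ion.mz == pytest.approx(129.0106, abs=1e-3)
    assert ion.ion_composition()["H"] == 2


# --------------------------------------------------------------------------
# isotope envelopes vs brute-force isotopologue enumeration


def brute_force_pattern(comp, mz_shift=0.0):
    """Expand every isotopologue combination; aggregate by nucleon count."""
    per_atom = []
    for element, n in comp:
        per_atom.extend([isotopes_of(element)] * n)
    bins = {}
    for combo in itertools.product(*per_atom):
        a = sum(iso[0] for iso in combo)
        mass = sum(iso[1] for iso in combo)
        prob = math.prod(iso[2] for iso in combo)
        p, pm = bins.get(a, (0.0, 0.0))
        bins[a] = (p + prob, pm + prob * mass)
    return sorted((pm / p + mz_shift, p) for a, (p, pm) in bins.items())


@pytest.mark.parametrize("formula", ["C", "H2O", "CH4", "C2H5Cl", "C4H3FN2O2"])
def test_isotope_pattern_matches_enumeration_oracle(formula):
    comp = parse_formula(formula)
    assert comp.atom_count <= 12
    pattern = isotope_pattern(comp, truncation=1e-3)
    oracle = dict(
        (round(mz, 6), ab) for mz, ab in brute_force_pattern(comp)
    )
    for mz, ab in pattern.peaks:
        key = min(oracle, key=lambda k: abs(k - mz))
        assert abs(key - mz) < 1e-6
        assert abs(oracle[key] - ab) < 1e-6


def test_isotope_pattern_carbon():
    pattern = isotope_pattern(parse_formula("C"))
    assert pattern.peaks[0] == pytest.approx((12.0, 0.9893), abs=1e-6)
    assert pattern.peaks[1][0] == pytest.approx(13.0034, abs=1e-4)
    assert pattern.peaks[1][1] == pytest.approx(0.0107, abs=1e-6)


def test_isotope_pattern_hydrogen_deuterium_tail():
    pattern = isotope_pattern(parse_formula("H"), truncation=1e-5)
    assert pattern.peaks[0][1] > 0.999
    assert pattern.peaks[1][1] == pytest.approx(1.15e-4, rel=0.01)


@pytest.mark.parametrize("formula", ["C4H3FN2O2", "C9H12FN2O8P", "C9H14FN2O15P3"])
def test_isotope_pattern_conserves_probability(formula):
    for truncation in (1e-3, 1e-2):
        pattern = isotope_pattern(parse_formula(formula), truncation=truncation)
        assert 1.0 - truncation <= pattern.total_abundance() <= 1.0 + 1e-12


def test_isotope_pattern_deprotonated_adduct_shifts_mz():
    comp = parse_formula("C4H3FN2O2")
    neutral = isotope_pattern(comp)
    anion = isotope_pattern(comp, adduct="[M-H]-")
    # (M - H + e) differs from (M - proton) only by the 13.6 eV H binding
    # energy, ~1.5e-8 Da
    assert anion.monoisotopic_mz == pytest.approx(mz_deprotonated(comp), abs=1e-7)
    # removing one H barely changes the envelope shape
    assert anion.peaks[1][1] / anion.peaks[0][1] == pytest.approx(
        neutral.peaks[1][1] / neutral.peaks[0][1], rel=0.01
    )


# --------------------------------------------------------------------------
# windows


def test_ppm_window_examples():
    w = ppm_window(129.0109, 5)
    assert w.low == pytest.approx(129.01025, abs=1e-5)
    assert w.high == pytest.approx(129.01155, abs=1e-5)
    w = ppm_window(100.0, 10)
    assert (w.low, w.high) == (pytest.approx(99.999), pytest.approx(100.001))


@given(
    mz=st.floats(min_value=50, max_value=2000),
    tol=st.floats(min_value=0.1, max_value=100),
    factor=st.floats(min_value=1.01, max_value=10),
)
@settings(max_examples=50, deadline=None)
def test_ppm_window_width_monotone(mz, tol, factor):
    base = ppm_window(mz, tol).width
    assert ppm_window(mz * factor, tol).width > base
    assert ppm_window(mz, tol * factor).width > base


def test_sim_window_examples():
    w = sim_window(325.024, 4.0)
    assert (w.low, w.high) == (pytest.approx(323.024), pytest.approx(327.024))
    w = sim_window(245.057, 4.0)
    assert (w.low, w.high) == (pytest.approx(243.057), pytest.approx(247.057))
    w = sim_window(100, 2)
    assert (w.low, w.high) == (99, 101)


# --------------------------------------------------------------------------
# subformula enumeration vs exhaustive oracle


def brute_force_subformulas(parent, observed_mz, tol_ppm):
    elements = list(parent.counts)
    results = []
    for combo in itertools.product(*(range(parent[e] + 1) for e in elements)):
        if not any(combo):
            continue
        comp = ElementalComposition(
            {e: c for e, c in zip(elements, combo) if c > 0}
        )
        anion_mz = monoisotopic_mass(comp) + ELECTRON_MASS
        if abs(anion_mz - observed_mz) <= observed_mz * tol_ppm * 1e-6:
            results.append(comp.hill_formula())
    return sorted(results)


@pytest.mark.parametrize(
    "parent,observed,tol",
    [
        ("C2H6O", 17.0033, 10),
        ("C2H6O", 45.0, 5000),  # wide window, many matches
        ("C9H11FN2O8P", 96.969, 10),
        ("C9H11FN2O8P", 195.006, 10),
    ],
)
def test_enumerate_subformulas_matches_bruteforce(parent, observed, tol):
    comp = parse_formula(parent)
    fast = sorted(c.hill_formula() for c in enumerate_subformulas(comp, observed, tol))
    assert fast == brute_force_subformulas(comp, observed, tol)


def test_enumerate_subformulas_hydroxide():
    hits = enumerate_subformulas(parse_formula("C2H6O"), 17.0033, 10)
    assert [c.hill_formula() for c in hits] == ["HO"]


def test_enumerate_subformulas_phosphate_from_fdump():
    parent = parse_formula("C9H12FN2O8P").remove("H")
    hits = enumerate_subformulas(parent, 96.969, 10)
    assert {"H2O4P"} <= {c.hill_formula() for c in hits}


def test_enumerate_subformulas_unreachable_mass():
    assert enumerate_subformulas(parse_formula("C"), 500.0, 100) == []


def test_all_fdump_fragments_explained():
    parent = parse_formula("C9H12FN2O8P").remove("H")
    for frag in (195.006, 129.01, 96.969, 78.959):
        assert enumerate_subformulas(parent, frag, 10), f"{frag} unexplained"
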