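"""Elemental-composition and m/z arithmetic for fixed-charge derivatized fatty acids.

Everything downstream of the mass spectrometer rests on four primitives
implemented here:

* neutral compositions of (possibly deuterated) straight-chain fatty acids,
* precursor m/z of the derivatized, singly charged cation (amide coupling of
  the reagent amine to the carboxylic acid, i.e. loss of water),
* ozone-induced dissociation (OzID) product ions: one aldehyde/Criegee pair
  per carbon-carbon double bond, with the Criegee ion exactly one oxygen
  heavier than the aldehyde ion,
* aggregated isotope patterns for intensity corrections.

Double-bond positions are counted from the methyl terminus (n-x notation):
the bond joins carbons x and x+1. Cleavage at that bond loses the methyl-side
fragment C_x H_(2x-2m) (m = double bonds fully contained in the lost piece)
and retains the charge-carrying oxo-acid fragment plus one oxygen.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from importlib import resources
from itertools import combinations
from typing import Iterable, Iterator, Sequence

import numpy as np
from pyteomics import mass as _pmass

__all__ = [
    "ELECTRON_MASS",
    "ElementMassTable",
    "ELEMENTS",
    "DoubleBond",
    "FattyAcidSpecies",
    "DerivatizationAgent",
    "OzidTransition",
    "OzidTransitionSet",
    "builtin_agents",
    "load_agents",
    "neutral_composition",
    "monoisotopic_mass",
    "precursor_composition",
    "precursor_mz",
    "ozid_transitions",
    "isotope_pattern",
    "enumerate_double_bond_patterns",
    "count_double_bond_patterns",
    "export_transitions",
]

ELECTRON_MASS = _pmass.nist_mass["e*"][0][0]

# monoisotopic masses of a few frequently used neutrals
MASS_O = _pmass.nist_mass["O"][16][0]
MASS_H2O = _pmass.calculate_mass(formula="H2O")
MASS_CH2 = _pmass.calculate_mass(formula="CH2")


class InvalidSpeciesError(ValueError):
    """A fatty-acid description violates a chemical invariant."""


class ConfigurationError(ValueError):
    """A search/agent configuration is inconsistent or incomplete."""


@dataclass(frozen=True)
class ElementMassTable:
    """Monoisotopic masses and isotope abundances, keyed by element symbol.

    ``isotopes[element]`` is a list of ``(mass_da, abundance)`` sorted by mass.
    The monoisotopic mass of an element is the mass of its most abundant
    isotope. Abundances per element sum to one.
    """

    isotopes: dict
    electron_mass: float = ELECTRON_MASS

    @classmethod
    def from_nist(cls, elements: Iterable[str] = ("H", "C", "N", "O", "S", "I")) -> "ElementMassTable":
        table = {}
        for el in elements:
            iso = [
                (m, ab)
                for num, (m, ab) in _pmass.nist_mass[el].items()
                if num != 0 and ab > 0
            ]
            iso.sort(key=lambda t: t[0])
            table[el] = iso
        # deuterium as a pseudo-element for labeled internal standards
        table["D"] = [(_pmass.nist_mass["H"][2][0], 1.0)]
        return cls(isotopes=table)

    def monoisotopic(self, element: str) -> float:
        return max(self.isotopes[element], key=lambda t: t[1])[0]

    def validate(self, tol: float = 1e-9) -> None:
        for el, iso in self.isotopes.items():
            total = sum(ab for _, ab in iso)
            if abs(total - 1.0) > tol:
                raise ValueError(f"isotope abundances of {el} sum to {total}, not 1")


ELEMENTS = ElementMassTable.from_nist()


# ---------------------------------------------------------------------------
# species model
# ---------------------------------------------------------------------------

CONFIGURATIONS = ("cis", "trans", "unknown")


@dataclass(frozen=True, order=True)
class DoubleBond:
    """A C=C bond at ``position`` carbons from the methyl terminus (n-x)."""

    position: int
    configuration: str = "unknown"

    def __post_init__(self):
        if self.position < 2:
            raise InvalidSpeciesError(
                f"double bond position {self.position} would place the bond at the "
                "methyl carbon"
            )
        if self.configuration not in CONFIGURATIONS:
            raise InvalidSpeciesError(f"unknown configuration {self.configuration!r}")


@dataclass(frozen=True)
class FattyAcidSpecies:
    """A fatty acid at the double-bond-position level of structural detail.

    ``double_bonds`` are ordered by ascending position from the methyl
    terminus. ``branch_class`` records chain topology inferred from retention
    behaviour (the branch point itself is never localized here).
    ``deuterium_count`` supports labeled internal standards; label positions
    do not affect mass, so only the count is stored.
    """

    carbons: int
    double_bonds: tuple = ()
    branch_class: str = "straight"
    deuterium_count: int = 0

    def __post_init__(self):
        object.__setattr__(self, "double_bonds", tuple(sorted(self.double_bonds)))
        if self.carbons < 4:
            raise InvalidSpeciesError(f"chain of {self.carbons} carbons is unsupported")
        if self.branch_class not in ("straight", "branched", "unknown"):
            raise InvalidSpeciesError(f"bad branch class {self.branch_class!r}")
        positions = [b.position for b in self.double_bonds]
        if len(set(positions)) != len(positions):
            raise InvalidSpeciesError("duplicate double bond positions")
        for b in self.double_bonds:
            if b.position > self.carbons - 2:
                raise InvalidSpeciesError(
                    f"bond at n-{b.position} involves the carboxyl carbon of a "
                    f"C{self.carbons} chain"
                )
        for a, b in zip(positions, positions[1:]):
            if b - a < 2:
                raise InvalidSpeciesError(
                    f"bonds at n-{a} and n-{b} would form a cumulated diene"
                )
        h = 2 * self.carbons - 2 * len(self.double_bonds)
        if self.deuterium_count < 0 or self.deuterium_count > h:
            raise InvalidSpeciesError(
                f"{self.deuterium_count} deuteriums exceed the {h} available hydrogens"
            )

    @property
    def n_double_bonds(self) -> int:
        return len(self.double_bonds)

    @property
    def positions(self) -> tuple:
        return tuple(b.position for b in self.double_bonds)

    @property
    def sum_composition(self) -> tuple:
        return (self.carbons, self.n_double_bonds)

    def with_configuration(self, configuration: str) -> "FattyAcidSpecies":
        bonds = tuple(replace(b, configuration=configuration) for b in self.double_bonds)
        return replace(self, double_bonds=bonds)


@dataclass(frozen=True)
class DerivatizationAgent:
    """A fixed-charge derivatization reagent identified by a four-letter code.

    ``cation_composition`` is the elemental composition of the intact reagent
    cation (e.g. C12H13N2 for AMPP); ``cation_mz`` is its monoisotopic m/z,
    i.e. the composition mass minus one electron.
    """

    code: str
    cation_composition: dict

    def __post_init__(self):
        if len(self.code) != 4:
            raise ConfigurationError(f"agent code {self.code!r} must be 4 characters")
        object.__setattr__(
            self, "cation_composition", dict(_pmass.Composition(self.cation_composition))
        )

    @property
    def cation_mz(self) -> float:
        return _pmass.calculate_mass(composition=_pmass.Composition(self.cation_composition)) - ELECTRON_MASS


def builtin_agents() -> dict:
    """The shipped agent table (AMPP and its photolabile iodo analog)."""
    return load_agents(resources.files("ozfad.data") / "agents.tsv")


def load_agents(path) -> dict:
    """Read a delimited agent table with columns code, formula, charge."""
    agents = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        idx = {name: i for i, name in enumerate(header)}
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            row = line.rstrip("\n").split("\t")
            code = row[idx["code"]]
            charge = int(row[idx["charge"]])
            if charge != 1:
                raise ConfigurationError("only singly charged agent cations are supported")
            agents[code] = DerivatizationAgent(code, _pmass.Composition(formula=row[idx["formula"]]))
    return agents


# ---------------------------------------------------------------------------
# composition and m/z arithmetic
# ---------------------------------------------------------------------------

def neutral_composition(fa: FattyAcidSpecies) -> dict:
    """Elemental composition of the underivatized acid: C_c H_(2c-2d-k) D_k O_2."""
    h = 2 * fa.carbons - 2 * fa.n_double_bonds - fa.deuterium_count
    comp = {"C": fa.carbons, "H": h, "O": 2}
    if fa.deuterium_count:
        comp["H[2]"] = fa.deuterium_count
        if comp["H"] == 0:
            del comp["H"]
    return comp


def monoisotopic_mass(composition: dict) -> float:
    return _pmass.calculate_mass(composition=_pmass.Composition(composition))


def precursor_composition(fa: FattyAcidSpecies, agent: DerivatizationAgent) -> dict:
    """Composition of the derivatized cation: acid + reagent cation - H2O."""
    comp = _pmass.Composition(neutral_composition(fa))
    comp += _pmass.Composition(agent.cation_composition)
    comp -= _pmass.Composition(formula="H2O")
    if any(v < 0 for v in comp.values()):
        raise InvalidSpeciesError("derivatization would remove more atoms than present")
    return dict(comp)


def precursor_mz(fa: FattyAcidSpecies, agent: DerivatizationAgent) -> float:
    """Singly charged monoisotopic m/z of the derivatized fatty acid."""
    return monoisotopic_mass(precursor_composition(fa, agent)) - ELECTRON_MASS


@dataclass(frozen=True)
class OzidTransition:
    position: int
    aldehyde_mz: float
    criegee_mz: float

    @property
    def product_mz(self) -> tuple:
        return (self.aldehyde_mz, self.criegee_mz)


@dataclass(frozen=True)
class OzidTransitionSet:
    """Precursor m/z plus the diagnostic aldehyde/Criegee pair per double bond."""

    precursor_mz: float
    transitions: tuple

    @property
    def product_mz(self) -> tuple:
        out = []
        for t in self.transitions:
            out.extend(t.product_mz)
        return tuple(out)

    def __len__(self) -> int:
        return 2 * len(self.transitions)


def _methyl_fragment_composition(x: int, contained_bonds: int) -> dict:
    return {"C": x, "H": 2 * x - 2 * contained_bonds}


def ozid_transitions(fa: FattyAcidSpecies, agent: DerivatizationAgent) -> OzidTransitionSet:
    """Predict OzID product ions for every double bond of ``fa``.

    Cleavage at the bond n-x loses the methyl-terminal fragment C_x H_(2x-2m)
    (m = number of other double bonds at positions y < x, i.e. fully contained
    in the lost fragment) and leaves the charge-tagged aldehyde; the Criegee
    ion retains one further oxygen.
    """
    pmz = precursor_mz(fa, agent)
    transitions = []
    positions = fa.positions
    for x in positions:
        m = sum(1 for y in positions if y < x)
        loss = monoisotopic_mass(_methyl_fragment_composition(x, m))
        aldehyde = pmz - loss + MASS_O
        transitions.append(OzidTransition(x, aldehyde, aldehyde + MASS_O))
    return OzidTransitionSet(pmz, tuple(transitions))


def product_composition(fa: FattyAcidSpecies, agent: DerivatizationAgent, x: int, criegee: bool = False) -> dict:
    """Elemental composition of the charged OzID product for cleavage at n-x."""
    m = sum(1 for y in fa.positions if y < x)
    comp = _pmass.Composition(precursor_composition(fa, agent))
    comp -= _pmass.Composition(_methyl_fragment_composition(x, m))
    comp += _pmass.Composition({"O": 2 if criegee else 1})
    return dict(comp)


# ---------------------------------------------------------------------------
# isotope patterns
# ---------------------------------------------------------------------------

def _convolve_tracked(p1, m1, p2, m2, n_keep):
    """Convolve two (probability, probability-weighted-mass) offset arrays."""
    n = min(len(p1) + len(p2) - 1, n_keep)
    p = np.zeros(n)
    m = np.zeros(n)
    for i, (pi, mi) in enumerate(zip(p1, m1)):
        if pi == 0.0 and mi == 0.0:
            continue
        hi = min(n - i, len(p2))
        if hi <= 0:
            break
        p[i : i + hi] += pi * p2[:hi]
        m[i : i + hi] += pi * m2[:hi] + mi * p2[:hi]
    return p, m


def isotope_pattern(composition: dict, n_peaks: int = 5) -> list:
    """Aggregated isotope pattern of a composition.

    Returns ``[(mass_offset_da, relative_abundance), ...]`` for the first
    ``n_peaks`` nucleon-number offsets, abundances normalized so the
    monoisotopic (base) peak is 1 and offsets ascending. Isotopologues that
    share a nucleon offset are merged; the reported mass offset is their
    abundance-weighted mean.
    """
    if n_peaks < 1:
        raise ValueError("n_peaks must be >= 1")
    comp = {k: v for k, v in dict(_pmass.Composition(composition)).items() if v}
    if not comp:
        raise ValueError("empty composition has no isotope pattern")
    # accumulated distribution over nucleon offsets, tracking expected mass
    p_tot = np.array([1.0])
    m_tot = np.array([0.0])
    for el, count in comp.items():
        if el.endswith("]"):  # explicit isotope such as H[2]: no distribution
            continue
        iso = ELEMENTS.isotopes[el]
        mono = ELEMENTS.monoisotopic(el)
        # per-atom distribution indexed by nucleon offset from the monoisotope
        max_off = max(int(round(m - mono)) for m, _ in iso)
        p_el = np.zeros(max_off + 1)
        m_el = np.zeros(max_off + 1)
        for m_iso, ab in iso:
            k = int(round(m_iso - mono))
            p_el[k] += ab
            m_el[k] += ab * (m_iso - mono)
        p_atom, m_atom = p_el, m_el
        # n-fold self-convolution by binary exponentiation
        n = count
        p_acc, m_acc = np.array([1.0]), np.array([0.0])
        while n:
            if n & 1:
                p_acc, m_acc = _convolve_tracked(p_acc, m_acc, p_atom, m_atom, n_peaks)
            n >>= 1
            if n:
                p_atom, m_atom = _convolve_tracked(p_atom, m_atom, p_atom, m_atom, n_peaks)
        p_tot, m_tot = _convolve_tracked(p_tot, m_tot, p_acc, m_acc, n_peaks)
    base = p_tot[0]
    out = []
    for k in range(min(n_peaks, len(p_tot))):
        if p_tot[k] <= 0:
            continue
        mean_off = k and m_tot[k] / p_tot[k]
        out.append((float(mean_off), float(p_tot[k] / base)))
    return out


# ---------------------------------------------------------------------------
# double-bond pattern enumeration
# ---------------------------------------------------------------------------

def _patterns(lo: int, hi: int, n: int) -> Iterator[tuple]:
    """Ascending position tuples in [lo, hi] with pairwise spacing >= 2."""
    if n == 0:
        yield ()
        return
    for x in range(lo, hi - 2 * (n - 1) + 1):
        for rest in _patterns(x + 2, hi, n - 1):
            yield (x,) + rest


def count_double_bond_patterns(carbons: int, n_db: int, min_position: int = 2) -> int:
    """Closed-form count of chemically feasible position sets."""
    free = (carbons - 2) - min_position + 2 - n_db
    if n_db < 0 or free < n_db:
        return 1 if n_db == 0 else 0
    return math.comb(free, n_db)


def enumerate_double_bond_patterns(
    carbons: int,
    n_db: int,
    mode: str = "de_novo",
    library: Sequence[Sequence[int]] | None = None,
    min_position: int = 2,
    max_position: int | None = None,
) -> list:
    """Enumerate candidate double-bond position sets for an exhaustive search.

    ``de_novo`` yields every chemically feasible set: positions between
    ``min_position`` (default n-2; methyl-terminal n-1 bonds are excluded)
    and carbons-2, with pairwise spacing >= 2 so conjugated dienes are
    included but cumulated dienes (allenes) are not. ``library`` restricts to
    the supplied sets; ``streamlined`` searches de novo up to three double
    bonds and falls back to the library beyond.
    """
    if n_db < 0:
        raise ValueError("n_db must be >= 0")
    hi = carbons - 2 if max_position is None else max_position
    if mode == "streamlined":
        mode = "de_novo" if n_db <= 3 else "library"
    if mode == "de_novo":
        return [tuple(p) for p in _patterns(min_position, hi, n_db)]
    if mode == "library":
        if library is None:
            raise ConfigurationError("library mode requires a pattern library")
        out = []
        for pat in library:
            pat = tuple(sorted(pat))
            if len(pat) != n_db:
                continue
            if pat and (pat[0] < min_position or pat[-1] > hi):
                continue
            if any(b - a < 2 for a, b in zip(pat, pat[1:])):
                continue
            out.append(pat)
        return out
    raise ConfigurationError(f"unknown search mode {mode!r}")


def species_from_pattern(carbons: int, pattern: Sequence[int]) -> FattyAcidSpecies:
    return FattyAcidSpecies(carbons, tuple(DoubleBond(x) for x in pattern))


def export_transitions(species_agent_pairs, path) -> None:
    """Write a delimited transition table loadable by external review tools."""
    from .nomenclature import shorthand_name

    with open(path, "w") as fh:
        fh.write("species\tprecursor_mz\tproduct_mz\tion_type\tposition\n")
        for fa, agent in species_agent_pairs:
            ts = ozid_transitions(fa, agent)
            name = shorthand_name(fa)
            for t in ts.transitions:
                fh.write(f"{name}\t{ts.precursor_mz:.4f}\t{t.aldehyde_mz:.4f}\taldehyde\t{t.position}\n")
                fh.write(f"{name}\t{ts.precursor_mz:.4f}\t{t.criegee_mz:.4f}\tcriegee\t{t.position}\n")
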