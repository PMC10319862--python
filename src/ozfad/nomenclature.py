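"""Fatty-acid naming: shorthand (n-nomenclature) and systematic names.

Shorthand counts double-bond positions from the methyl terminus
(``FA 18:1n-9 cis``); systematic names count from the carboxyl carbon with
Z/E descriptors (``9Z-octadecenoic acid``), the delta position being
carbons - n-position. ``parse_shorthand`` inverts ``shorthand_name`` exactly.
"""

from __future__ import annotations

import re

from .chem import DoubleBond, FattyAcidSpecies, InvalidSpeciesError

__all__ = ["shorthand_name", "systematic_name", "parse_shorthand", "ParseError"]


class ParseError(ValueError):
    pass


_STEMS = {
    12: "dodec", 13: "tridec", 14: "tetradec", 15: "pentadec", 16: "hexadec",
    17: "heptadec", 18: "octadec", 19: "nonadec", 20: "eicos", 21: "heneicos",
    22: "docos", 23: "tricos", 24: "tetracos", 25: "pentacos", 26: "hexacos",
    27: "heptacos", 28: "octacos", 29: "nonacos", 30: "triacont",
}

_UNSAT_SUFFIX = {
    1: "enoic", 2: "adienoic", 3: "atrienoic", 4: "atetraenoic",
    5: "apentaenoic", 6: "ahexaenoic", 7: "aheptaenoic", 8: "aoctaenoic",
}

_CONF_LETTER = {"cis": "c", "trans": "t"}
_CONF_ZE = {"cis": "Z", "trans": "E"}


def shorthand_name(fa: FattyAcidSpecies) -> str:
    """``FA c:d`` with methyl-referenced positions, e.g. ``FA 20:3n-6,9,15``.

    A single trailing ``cis``/``trans`` is used when all bonds share a known
    configuration; mixed configurations are rendered per position
    (``n-6c,9t``); unknown configurations are omitted.
    """
    label = f"d{fa.deuterium_count}" if fa.deuterium_count else ""
    head = f"FA {fa.carbons}:{fa.n_double_bonds}{label}"
    if not fa.double_bonds:
        return head
    confs = {b.configuration for b in fa.double_bonds}
    if confs <= {"unknown"}:
        pos = ",".join(str(b.position) for b in fa.double_bonds)
        return f"{head}n-{pos}"
    if len(confs) == 1:
        pos = ",".join(str(b.position) for b in fa.double_bonds)
        return f"{head}n-{pos} {next(iter(confs))}"
    pos = ",".join(
        f"{b.position}{_CONF_LETTER.get(b.configuration, '')}" for b in fa.double_bonds
    )
    return f"{head}n-{pos}"


def systematic_name(fa: FattyAcidSpecies) -> str:
    """Carboxyl-referenced name, e.g. ``5Z,11Z,14Z-eicosatrienoic acid``."""
    stem = _STEMS.get(fa.carbons)
    if stem is None:
        raise InvalidSpeciesError(
            f"no systematic stem name for a C{fa.carbons} chain (supported: 12-30)"
        )
    d = fa.n_double_bonds
    if d == 0:
        return f"{stem}anoic acid"
    deltas = sorted(
        (fa.carbons - b.position, _CONF_ZE.get(b.configuration, ""))
        for b in fa.double_bonds
    )
    prefix = ",".join(f"{pos}{ze}" for pos, ze in deltas)
    return f"{prefix}-{stem}{_UNSAT_SUFFIX[d]} acid"


_SHORTHAND_RE = re.compile(
    r"^\s*(?:FA\s*)?(?P<c>\d+):(?P<d>\d+)(?:d(?P<deut>\d+))?"
    r"(?:\s*n[-−–](?P<pos>\d+[ct]?(?:,\d+[ct]?)*))?"
    r"(?:\s*(?P<conf>cis|trans|c|t))?\s*$"
)


def parse_shorthand(text: str) -> FattyAcidSpecies:
    """Parse shorthand such as ``FA 18:1n-9 cis``, ``20:3n-6,9,15`` or ``18:1n-9c``."""
    m = _SHORTHAND_RE.match(text)
    if not m:
        token = text.strip().split()[-1] if text.strip() else text
        raise ParseError(f"cannot parse fatty acid shorthand {text!r} (near {token!r})")
    carbons = int(m.group("c"))
    n_db = int(m.group("d"))
    deut = int(m.group("deut") or 0)
    global_conf = {"c": "cis", "t": "trans", None: None}.get(m.group("conf"), m.group("conf"))
    bonds = []
    if m.group("pos"):
        for item in m.group("pos").split(","):
            mm = re.match(r"^(\d+)([ct]?)$", item)
            pos = int(mm.group(1))
            conf = {"c": "cis", "t": "trans", "": None}[mm.group(2)]
            if conf is None:
                conf = global_conf or "unknown"
            bonds.append(DoubleBond(pos, conf))
    if bonds and len(bonds) != n_db:
        raise ParseError(
            f"{text!r}: {len(bonds)} positions listed for {n_db} double bonds"
        )
    if n_db and not bonds:
        # sum-composition shorthand (positions unassigned) is not a full species
        raise ParseError(f"{text!r} lists no double bond positions for n_db={n_db}")
    try:
        return FattyAcidSpecies(carbons, tuple(bonds), deuterium_count=deut)
    except InvalidSpeciesError as exc:
        raise ParseError(f"{text!r}: {exc}") from exc
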