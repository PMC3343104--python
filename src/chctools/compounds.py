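"""Cuticular-hydrocarbon compound descriptors and the CHC naming grammar.

Fly CHC literature uses several interchangeable shorthands for the same
molecule: ``nC23`` (a straight-chain alkane), ``7-T`` (7-tricosene, a C23
monoene), ``7,11-HD`` (7,11-heptacosadiene, a C27 diene), ``2-MeC26``
(2-methylhexacosane, 27 carbons counting the methyl branch) and raw
elemental formulas such as ``C27H52`` from intact-fly mass spectrometry.
This module parses those names into a structured :class:`CompoundDescriptor`
so downstream analyses can reason about carbon-chain length and compound
class without caring which instrument produced the label.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace

__all__ = [
    "CompoundDescriptor",
    "parse_compound_name",
    "canonical_name",
    "default_panel",
]

#: chain-length aliases used for monoenes/dienes in the GC/MS literature:
#: T = tricos- (C23), P = pentacos- (C25), H = heptacos- (C27), N = nonacos- (C29)
_ALIAS_TO_CARBON = {"T": 23, "P": 25, "H": 27, "N": 29}
_CARBON_TO_ALIAS = {v: k for k, v in _ALIAS_TO_CARBON.items()}

_CLASSES = ("alkane", "monoene", "diene", "methyl-branched", "oxygenated", "other")


@dataclass(frozen=True)
class CompoundDescriptor:
    """Identity and structure of one CHC compound.

    ``carbon_count`` counts every carbon, including methyl branches
    (2-MeC26 carries 27). ``is_identified_hydrocarbon`` controls whether the
    compound enters the relative-quantitation denominator; oxygenated
    compounds that appear reproducibly in profiles (e.g. C27H54O2) are
    treated as identified by default but can be switched off per descriptor.
    """

    name: str
    compound_class: str
    carbon_count: int
    n_double_bonds: int = 0
    double_bond_positions: tuple[int, ...] = field(default=())
    methyl_position: int | None = None
    is_identified_hydrocarbon: bool = True

    def __post_init__(self) -> None:
        if self.compound_class not in _CLASSES:
            raise ValueError(f"unknown compound class {self.compound_class!r}")
        if self.carbon_count < 1:
            raise ValueError("carbon_count must be >= 1")
        if self.n_double_bonds < 0:
            raise ValueError("n_double_bonds must be >= 0")


_RE_ALKANE = re.compile(r"^nC(\d+)$")
_RE_CN = re.compile(r"^C(\d+):(\d+)$")
_RE_MONOENE_ALIAS = re.compile(r"^(\d+)-([TPHN])$")
_RE_MONOENE_CN = re.compile(r"^(\d+)-C(\d+):1$")
_RE_DIENE_ALIAS = re.compile(r"^(\d+),(\d+)-([TPHN])D$")
_RE_DIENE_CN = re.compile(r"^(\d+),(\d+)-C(\d+):2$")
_RE_METHYL = re.compile(r"^2-MeC(\d+)$")
_RE_FORMULA = re.compile(r"^C(\d+)H(\d+)(?:O(\d+))?$")


def parse_compound_name(name: str) -> CompoundDescriptor:
    """Parse a CHC shorthand or elemental formula into a descriptor.

    Raises ``ValueError`` for names outside the supported grammar; such
    compounds need an explicit descriptor row supplied by the caller.
    """
    raw = name
    # tolerate subscript markup, e.g. "2-MeC_26_"
    name = name.replace("_", "").strip()

    if m := _RE_ALKANE.match(name):
        return CompoundDescriptor(raw, "alkane", int(m.group(1)))
    if m := _RE_CN.match(name):
        carbons, dbs = int(m.group(1)), int(m.group(2))
        cls = {0: "alkane", 1: "monoene", 2: "diene"}.get(dbs, "other")
        return CompoundDescriptor(raw, cls, carbons, dbs)
    if m := _RE_MONOENE_ALIAS.match(name):
        return CompoundDescriptor(
            raw, "monoene", _ALIAS_TO_CARBON[m.group(2)], 1, (int(m.group(1)),)
        )
    if m := _RE_MONOENE_CN.match(name):
        return CompoundDescriptor(raw, "monoene", int(m.group(2)), 1, (int(m.group(1)),))
    if m := _RE_DIENE_ALIAS.match(name):
        pos = (int(m.group(1)), int(m.group(2)))
        return CompoundDescriptor(raw, "diene", _ALIAS_TO_CARBON[m.group(3)], 2, pos)
    if m := _RE_DIENE_CN.match(name):
        pos = (int(m.group(1)), int(m.group(2)))
        return CompoundDescriptor(raw, "diene", int(m.group(3)), 2, pos)
    if m := _RE_METHYL.match(name):
        # the methyl carbon counts toward chain length: 2-MeC26 -> 27 carbons
        return CompoundDescriptor(
            raw, "methyl-branched", int(m.group(1)) + 1, 0, (), methyl_position=2
        )
    if m := _RE_FORMULA.match(name):
        carbons, hydrogens = int(m.group(1)), int(m.group(2))
        if m.group(3) is not None:
            return CompoundDescriptor(raw, "oxygenated", carbons)
        dou = (2 * carbons + 2 - hydrogens) // 2
        cls = {0: "alkane", 1: "monoene", 2: "diene"}.get(dou, "other")
        return CompoundDescriptor(raw, cls, carbons, max(dou, 0))
    raise ValueError(f"compound name {name!r} is outside the supported grammar; "
                     "supply an explicit descriptor")


def canonical_name(desc: CompoundDescriptor) -> str:
    """Reconstruct the canonical shorthand for a descriptor.

    Round-trips with :func:`parse_compound_name` over the supported grammar:
    parsing the canonical name reproduces the same structural fields.
    """
    c = desc.carbon_count
    if desc.compound_class == "alkane":
        return f"nC{c}"
    if desc.compound_class == "monoene" and desc.double_bond_positions:
        pos = desc.double_bond_positions[0]
        if c in _CARBON_TO_ALIAS:
            return f"{pos}-{_CARBON_TO_ALIAS[c]}"
        return f"{pos}-C{c}:1"
    if desc.compound_class == "diene" and len(desc.double_bond_positions) == 2:
        p1, p2 = desc.double_bond_positions
        if c in _CARBON_TO_ALIAS:
            return f"{p1},{p2}-{_CARBON_TO_ALIAS[c]}D"
        return f"{p1},{p2}-C{c}:2"
    if desc.compound_class == "methyl-branched" and desc.methyl_position == 2:
        return f"2-MeC{c - 1}"
    # formula-only and positionless compounds keep their original label
    return desc.name


def default_panel(
    n_compounds: int = 26, carbon_range: tuple[int, int] = (21, 29)
) -> list[CompoundDescriptor]:
    """A GC/MS-like CHC panel over a carbon-chain range.

    Emulates a female fly cuticular profile: straight-chain alkanes at every
    length, 7-monoenes and 7,11-dienes at odd lengths, 9-monoenes and
    5,9-dienes at the longer odd lengths, 2-methyl alkanes at even lengths,
    and one oxygenated compound at C27. Candidates are ordered by carbon
    count and truncated (or padded with longer alkanes) to ``n_compounds``.
    """
    if n_compounds < 1:
        raise ValueError("n_compounds must be >= 1")
    lo, hi = carbon_range
    if lo < 1 or hi < lo:
        raise ValueError("invalid carbon_range")
    names: list[str] = []
    for c in range(lo, hi + 1):
        names.append(f"nC{c}")
        if c % 2 == 1:
            names.append(canonical_name(
                CompoundDescriptor(f"7-C{c}:1", "monoene", c, 1, (7,))))
            if c >= 23:
                names.append(canonical_name(
                    CompoundDescriptor(f"7,11-C{c}:2", "diene", c, 2, (7, 11))))
            if c >= 25:
                names.append(canonical_name(
                    CompoundDescriptor(f"9-C{c}:1", "monoene", c, 1, (9,))))
                names.append(canonical_name(
                    CompoundDescriptor(f"5,9-C{c}:2", "diene", c, 2, (5, 9))))
        else:
            names.append(f"2-MeC{c - 1}")
        if c == 27:
            names.append("C27H54O2")
    extra = hi + 1
    while len(names) < n_compounds:
        names.append(f"nC{extra}")
        extra += 1
    return [parse_compound_name(nm) for nm in names[:n_compounds]]


def descriptor_map(descriptors: list[CompoundDescriptor]) -> dict[str, CompoundDescriptor]:
    """Index descriptors by their (original) name."""
    return {d.name: d for d in descriptors}


def with_identified_flag(desc: CompoundDescriptor, identified: bool) -> CompoundDescriptor:
    """Copy a descriptor with the identified-hydrocarbon flag switched."""
    return replace(desc, is_identified_hydrocarbon=identified)
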