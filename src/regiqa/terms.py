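"""Identities of partitioned energy terms.

An IQA partition assigns the total electronic energy of an N-atom system
to one intra-atomic term per atom (``E_intra``, decomposable into kinetic
and same-basin potential components) and one interatomic term per
unordered atom pair (``V_inter``, decomposable into a classical
electrostatic part ``V_cl``, an exchange-correlation part ``V_xc`` and,
for dispersion-corrected functionals, a pairwise ``V_D3``).  Interacting
Quantum Fragments (IQF) sums interatomic terms between two disjoint
groups of atoms.  This module provides the hashable keys naming those
terms and the fragment schemes used for IQF aggregation.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Mapping, Union

import yaml

from .errors import SchemaError

_ATOM_RE = re.compile(r"^([a-z]{1,2})([0-9]+)$")


@dataclass(frozen=True, order=True)
class AtomLabel:
    """One atom, named element-symbol + 1-based index, e.g. ``n1``, ``c4``.

    Comparison and rendering are case-insensitive (stored lowercase), the
    convention used in published REG-IQA tables.
    """

    element: str
    index: int

    def __post_init__(self) -> None:
        if not self.element.isalpha():
            raise SchemaError(f"invalid element symbol {self.element!r}")
        object.__setattr__(self, "element", self.element.lower())
        if self.index < 1:
            raise SchemaError(f"atom index must be >= 1, got {self.index}")

    @classmethod
    def parse(cls, text: str) -> "AtomLabel":
        m = _ATOM_RE.match(text.strip().lower())
        if m is None:
            raise SchemaError(f"cannot parse atom label {text!r}")
        return cls(m.group(1), int(m.group(2)))

    def __str__(self) -> str:
        return f"{self.element}{self.index}"


class TermType(str, Enum):
    """Kinds of partitioned energy terms.

    ``E_intra``/``T``/``Vee``/``Ven`` with a single participant are
    intra-atomic; every two-participant type is interatomic (``Vee`` and
    ``Ven`` occur in both roles); ``E_tot`` carries no participants.
    """

    E_INTRA = "E_intra"
    T = "T"
    VEE = "Vee"
    VEN = "Ven"
    VNE = "Vne"
    VNN = "Vnn"
    VCOUL = "Vcoul"
    VX = "Vx"
    VC = "Vc"
    V_CL = "V_cl"
    V_XC = "V_xc"
    V_D3 = "V_D3"
    V_INTER = "V_inter"
    V_CT = "V_ct"
    V_PL = "V_pl"
    E_TOT = "E_tot"

    @classmethod
    def parse(cls, text: str) -> "TermType":
        try:
            return _TYPE_LOOKUP[text.strip().lower()]
        except KeyError:
            raise SchemaError(f"unknown term type {text!r}") from None


_TYPE_LOOKUP = {t.value.lower(): t for t in TermType}

#: allowed participant counts per term type
ARITY: Mapping[TermType, frozenset] = {
    TermType.E_INTRA: frozenset({1}),
    TermType.T: frozenset({1}),
    TermType.VEE: frozenset({1, 2}),
    TermType.VEN: frozenset({1, 2}),
    TermType.VNE: frozenset({2}),
    TermType.VNN: frozenset({2}),
    TermType.VCOUL: frozenset({2}),
    TermType.VX: frozenset({2}),
    TermType.VC: frozenset({2}),
    TermType.V_CL: frozenset({2}),
    TermType.V_XC: frozenset({2}),
    TermType.V_D3: frozenset({2}),
    TermType.V_INTER: frozenset({2}),
    TermType.V_CT: frozenset({2}),
    TermType.V_PL: frozenset({2}),
    TermType.E_TOT: frozenset({0}),
}

#: term types that can occur interatomically (and so aggregate over fragments)
PAIR_TYPES = frozenset(t for t, a in ARITY.items() if 2 in a)

Participant = Union[AtomLabel, str]


def _participant_sort_key(p: Participant):
    if isinstance(p, AtomLabel):
        return (0, p.element, p.index)
    return (1, str(p), 0)


def _render_participant(p: Participant) -> str:
    return str(p)


@dataclass(frozen=True)
class TermKey:
    """Identity of one energy term: type plus zero, one or two participants.

    Pair participants are stored in canonical sorted order so that a term
    read as ``V_cl(b2,a1)`` compares equal to ``V_cl(a1,b2)``.
    Participants are atoms for atomistic profiles or group names (plain
    strings) for fragment profiles; mixing the two in one key is invalid.
    """

    term_type: TermType
    participants: tuple = ()

    def __post_init__(self) -> None:
        parts = tuple(self.participants)
        arity = ARITY[self.term_type]
        if len(parts) not in arity:
            raise SchemaError(
                f"term type {self.term_type.value} takes {sorted(arity)} "
                f"participants, got {len(parts)}"
            )
        kinds = {isinstance(p, AtomLabel) for p in parts}
        if len(kinds) > 1:
            raise SchemaError("cannot mix atoms and fragment names in one term")
        if len(parts) == 2:
            if parts[0] == parts[1]:
                raise SchemaError(f"pair term needs two distinct participants, got {parts}")
            parts = tuple(sorted(parts, key=_participant_sort_key))
        object.__setattr__(self, "participants", parts)

    # -- constructors -------------------------------------------------
    @classmethod
    def intra(cls, term_type: TermType, atom: Participant) -> "TermKey":
        return cls(term_type, (atom,))

    @classmethod
    def pair(cls, term_type: TermType, a: Participant, b: Participant) -> "TermKey":
        return cls(term_type, (a, b))

    @classmethod
    def total(cls) -> "TermKey":
        return cls(TermType.E_TOT, ())

    @classmethod
    def parse(cls, text: str) -> "TermKey":
        """Parse a rendered key such as ``V_cl(n1,c4)`` or ``E_tot``."""
        text = text.strip()
        if "(" not in text:
            return cls(TermType.parse(text), ())
        if not text.endswith(")"):
            raise SchemaError(f"cannot parse term key {text!r}")
        head, _, inner = text[:-1].partition("(")
        parts = []
        for tok in inner.split(","):
            tok = tok.strip()
            if not tok:
                continue
            try:
                parts.append(AtomLabel.parse(tok))
            except SchemaError:
                parts.append(tok)
        return cls(TermType.parse(head), tuple(parts))

    # -- predicates ---------------------------------------------------
    @property
    def is_total(self) -> bool:
        return self.term_type is TermType.E_TOT

    @property
    def is_intra(self) -> bool:
        return len(self.participants) == 1

    @property
    def is_pair(self) -> bool:
        return len(self.participants) == 2

    def label(self) -> str:
        if not self.participants:
            return self.term_type.value
        inner = ",".join(_render_participant(p) for p in self.participants)
        return f"{self.term_type.value}({inner})"

    def __str__(self) -> str:
        return self.label()

    def sort_key(self):
        """Deterministic ordering used for tie-breaks and file output."""
        return (self.term_type.value, tuple(_participant_sort_key(p) for p in self.participants))


class FragmentScheme:
    """Named disjoint groups of atoms for IQF aggregation.

    Groups must be pairwise disjoint and non-empty; published analyses
    that reuse an atom across nested groups are run as separate schemes.
    """

    def __init__(self, groups: Mapping[str, Iterable[AtomLabel]]):
        clean: dict[str, frozenset[AtomLabel]] = {}
        for name, atoms in groups.items():
            atomset = frozenset(
                a if isinstance(a, AtomLabel) else AtomLabel.parse(a) for a in atoms
            )
            if not atomset:
                raise SchemaError(f"fragment group {name!r} is empty")
            clean[str(name)] = atomset
        names = sorted(clean)
        for i, gi in enumerate(names):
            for gj in names[i + 1 :]:
                shared = clean[gi] & clean[gj]
                if shared:
                    raise SchemaError(
                        f"fragment groups {gi!r} and {gj!r} overlap on "
                        f"{sorted(str(a) for a in shared)}"
                    )
        self.groups: dict[str, frozenset[AtomLabel]] = clean

    def __iter__(self):
        return iter(sorted(self.groups))

    def __len__(self) -> int:
        return len(self.groups)

    def __getitem__(self, name: str) -> frozenset[AtomLabel]:
        return self.groups[name]

    def __eq__(self, other) -> bool:
        return isinstance(other, FragmentScheme) and self.groups == other.groups

    def atoms(self) -> frozenset[AtomLabel]:
        out: frozenset[AtomLabel] = frozenset()
        for atomset in self.groups.values():
            out = out | atomset
        return out

    def validate_against(self, profile) -> None:
        """Raise if any grouped atom never appears in the profile's terms."""
        known = profile.atom_labels
        missing = [str(a) for a in sorted(self.atoms() - known)]
        if missing:
            raise SchemaError(f"fragment atoms not present in profile: {missing}")

    # -- YAML round trip ----------------------------------------------
    @classmethod
    def from_yaml(cls, path) -> "FragmentScheme":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
        if not isinstance(raw, Mapping):
            raise SchemaError("fragment scheme file must map group name -> atom list")
        return cls({name: list(atoms) for name, atoms in raw.items()})

    def to_yaml(self, path) -> None:
        data = {name: sorted(str(a) for a in atoms) for name, atoms in self.groups.items()}
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)
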