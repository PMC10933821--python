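"""In-memory container for a partitioned energy profile over a PES segment.

A profile holds, for each of M geometries along a control coordinate s
(here a collective dihedral progress variable), the value of every
partitioned energy term in hartree, plus optionally a per-point atom
table with QTAIM-style charges (e) and Cartesian positions (bohr).
"""

from __future__ import annotations

from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .errors import CompletenessError, OrderingError, SchemaError
from .terms import AtomLabel, TermKey, TermType

ATOM_COLUMNS = ["q", "x", "y", "z"]


class EnergyProfile:
    """Partitioned energies over an ordered set of PES points.

    Parameters
    ----------
    s : array-like, shape (M,)
        Control-coordinate values, strictly monotonic.  s is metadata: it
        orders the points and defines segments but never enters the REG
        regression itself.
    terms : mapping of TermKey -> array-like, shape (M,)
        Energy series in hartree; every key must cover every point.
    atoms : pandas.DataFrame, optional
        Indexed by (point_index, atom label string) with columns
        ``q, x, y, z``; must cover every atom appearing in any term key
        at every point.
    metadata : dict, optional
        Free-form (system name, segment description).
    """

    def __init__(
        self,
        s,
        terms: Mapping[TermKey, "np.ndarray"],
        atoms: Optional[pd.DataFrame] = None,
        metadata: Optional[dict] = None,
    ):
        self.s = np.asarray(s, dtype=float)
        if self.s.ndim != 1 or self.s.size == 0:
            raise SchemaError("control coordinate must be a non-empty 1-D array")
        m = self.s.size
        if m > 1:
            ds = np.diff(self.s)
            if not (np.all(ds > 0) or np.all(ds < 0)):
                raise OrderingError("control coordinate s must be strictly monotonic")
        data: dict[TermKey, np.ndarray] = {}
        for key, values in terms.items():
            if not isinstance(key, TermKey):
                raise SchemaError(f"term keys must be TermKey, got {key!r}")
            arr = np.asarray(values, dtype=float)
            if arr.shape != (m,):
                raise CompletenessError(
                    f"term {key} has {arr.size} values but the profile has {m} points"
                )
            data[key] = arr
        if not data:
            raise SchemaError("profile must contain at least one term")
        self._terms = data
        self.metadata = dict(metadata or {})
        self.atoms = self._check_atoms(atoms)

    # ------------------------------------------------------------------
    def _check_atoms(self, atoms: Optional[pd.DataFrame]) -> Optional[pd.DataFrame]:
        if atoms is None:
            return None
        atoms = atoms.copy()
        if list(atoms.columns) != ATOM_COLUMNS:
            missing = [c for c in ATOM_COLUMNS if c not in atoms.columns]
            if missing:
                raise SchemaError(f"atom table missing columns {missing}")
            atoms = atoms[ATOM_COLUMNS]
        if atoms.index.nlevels != 2:
            raise SchemaError("atom table must be indexed by (point_index, atom)")
        points = atoms.index.get_level_values(0).unique()
        covered = {str(a).lower() for a in atoms.index.get_level_values(1)}
        needed = {str(a) for a in self.atom_labels}
        if len(points) != self.m_points:
            raise CompletenessError(
                f"atom table covers {len(points)} points, profile has {self.m_points}"
            )
        missing = sorted(needed - covered)
        if missing:
            raise CompletenessError(f"atom table missing atoms {missing}")
        return atoms

    # ------------------------------------------------------------------
    @property
    def m_points(self) -> int:
        return int(self.s.size)

    @property
    def term_keys(self) -> list[TermKey]:
        return sorted(self._terms, key=TermKey.sort_key)

    @property
    def atom_labels(self) -> frozenset[AtomLabel]:
        out = set()
        for key in self._terms:
            for p in key.participants:
                if isinstance(p, AtomLabel):
                    out.add(p)
        return frozenset(out)

    @property
    def has_stored_total(self) -> bool:
        return TermKey.total() in self._terms

    def __contains__(self, key: TermKey) -> bool:
        return key in self._terms

    def __len__(self) -> int:
        return len(self._terms)

    def values(self, key: TermKey) -> np.ndarray:
        try:
            return self._terms[key]
        except KeyError:
            raise CompletenessError(f"term {key} not present in profile") from None

    def get(self, key: TermKey, default=None):
        return self._terms.get(key, default)

    def e_tot(self) -> np.ndarray:
        """Stored total-energy series, or the sum of the partition if absent."""
        stored = self._terms.get(TermKey.total())
        if stored is not None:
            return stored
        from .algebra import total_energy  # local import to avoid a cycle

        return total_energy(self)

    def keys_of_type(self, *types: TermType) -> list[TermKey]:
        wanted = set(types)
        return [k for k in self.term_keys if k.term_type in wanted]

    # ------------------------------------------------------------------
    def subset(self, start: int, stop: int) -> "EnergyProfile":
        """Contiguous sub-profile over points [start, stop)."""
        if not (0 <= start < stop <= self.m_points):
            raise SchemaError(f"invalid segment [{start}, {stop}) for M={self.m_points}")
        terms = {k: v[start:stop] for k, v in self._terms.items()}
        atoms = None
        if self.atoms is not None:
            points = self.atoms.index.get_level_values(0).unique()[start:stop]
            atoms = self.atoms.loc[points]
        return EnergyProfile(self.s[start:stop], terms, atoms=atoms, metadata=self.metadata)

    def with_terms(self, extra: Mapping[TermKey, "np.ndarray"]) -> "EnergyProfile":
        terms = dict(self._terms)
        terms.update(extra)
        return EnergyProfile(self.s, terms, atoms=self.atoms, metadata=self.metadata)

    # ------------------------------------------------------------------
    def charge(self, atom: AtomLabel, point: int) -> float:
        if self.atoms is None:
            raise SchemaError("profile carries no atom table")
        points = self.atoms.index.get_level_values(0).unique()
        return float(self.atoms.loc[(points[point], str(atom)), "q"])

    def distance(self, a: AtomLabel, b: AtomLabel, point: int) -> float:
        """Interatomic distance in bohr at one PES point."""
        if self.atoms is None:
            raise SchemaError("profile carries no atom table")
        points = self.atoms.index.get_level_values(0).unique()
        pa = self.atoms.loc[(points[point], str(a)), ["x", "y", "z"]].to_numpy(dtype=float)
        pb = self.atoms.loc[(points[point], str(b)), ["x", "y", "z"]].to_numpy(dtype=float)
        return float(np.linalg.norm(pa - pb))

    # ------------------------------------------------------------------
    def equals(self, other: "EnergyProfile", atol: float = 0.0) -> bool:
        """Exact (default) or tolerant comparison of two profiles."""
        if not isinstance(other, EnergyProfile):
            return False
        if self.m_points != other.m_points:
            return False
        if not np.allclose(self.s, other.s, rtol=0.0, atol=atol):
            return False
        if set(self._terms) != set(other._terms):
            return False
        for key, vals in self._terms.items():
            if not np.allclose(vals, other._terms[key], rtol=0.0, atol=atol):
                return False
        if (self.atoms is None) != (other.atoms is None):
            return False
        if self.atoms is not None:
            a, b = self.atoms.sort_index(), other.atoms.sort_index()
            if not a.index.equals(b.index):
                return False
            if not np.allclose(a.to_numpy(float), b.to_numpy(float), rtol=0.0, atol=atol):
                return False
        return True

    def __repr__(self) -> str:
        name = self.metadata.get("system", "profile")
        return (
            f"<EnergyProfile {name!r}: M={self.m_points}, "
            f"{len(self._terms)} terms, atoms={'yes' if self.atoms is not None else 'no'}>"
        )
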