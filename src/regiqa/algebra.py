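"""IQA/IQF energy algebra.

Totals compose additively from one intra-atomic term per atom and one
interatomic term per unordered atom pair.  Because pairs are stored
once (unordered), no factor 1/2 appears anywhere: the conventional 1/2
in the ordered-pair double sum exists only to undo double counting.

The interatomic energy splits into a classical electrostatic part, an
exchange-correlation part and (for dispersion-corrected functionals) a
pairwise dispersion term.  The classical part further splits into a
monopolar charge-transfer term q_A*q_B/r_AB and a polarisation
remainder.  Fragment (IQF) terms are plain sums of the member pairwise
terms between two disjoint atom groups.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np

from .errors import CompletenessError, ConsistencyError, SchemaError
from .profile import EnergyProfile
from .terms import PAIR_TYPES, AtomLabel, FragmentScheme, TermKey, TermType

#: pair term types forming the interatomic partition when V_inter itself
#: is absent (dispersion optional, missing rows count as zero)
_INTER_PARTS = (TermType.V_CL, TermType.V_XC, TermType.V_D3)


def total_energy(profile: EnergyProfile, point: Optional[int] = None):
    """Recompose the total energy from the additive partition.

    Sums every ``E_intra`` term and every unordered-pair interatomic
    term (``V_inter`` where stored, otherwise ``V_cl + V_xc [+ V_D3]``).
    Returns the full series, or a scalar for a single ``point``.
    """
    intra = profile.keys_of_type(TermType.E_INTRA)
    if not intra:
        raise CompletenessError("profile has no E_intra terms; cannot recompose the total")
    total = np.zeros(profile.m_points)
    for key in intra:
        total = total + profile.values(key)

    inter_keys = profile.keys_of_type(TermType.V_INTER)
    if inter_keys:
        for key in inter_keys:
            total = total + profile.values(key)
    else:
        for term_type in _INTER_PARTS:
            for key in profile.keys_of_type(term_type):
                total = total + profile.values(key)
    if point is not None:
        return float(total[point])
    return total


@dataclass
class InterComponents:
    """Components of one interatomic energy (hartree).

    ``v_cl``/``v_xc`` are required; ``v_d3`` defaults to zero.  When the
    raw electrostatic components (nucleus-nucleus, the two
    electron-nucleus attractions and the electron-only Coulomb
    repulsion) or the exchange/correlation pair are supplied, the
    composition identities are cross-checked.
    """

    v_cl: float
    v_xc: float
    v_d3: float = 0.0
    v_nn: Optional[float] = None
    v_en: Optional[float] = None
    v_ne: Optional[float] = None
    v_coul: Optional[float] = None
    v_x: Optional[float] = None
    v_c: Optional[float] = None


def compose_inter(components: InterComponents, tolerance: float = 1e-8) -> float:
    """Total interatomic energy ``V_cl + V_xc + V_D3``.

    Raw components, when present, must satisfy
    ``V_cl = V_nn + V_en + V_ne + V_coul`` and ``V_xc = V_x + V_c``
    within ``tolerance``; a violation raises :class:`ConsistencyError`
    reporting the residual.
    """
    c = components
    raw_cl = (c.v_nn, c.v_en, c.v_ne, c.v_coul)
    if all(v is not None for v in raw_cl):
        residual = abs(c.v_cl - sum(raw_cl))
        if residual > tolerance:
            raise ConsistencyError(
                f"V_cl differs from Vnn+Ven+Vne+Vcoul by {residual:.3e} hartree"
            )
    if c.v_x is not None and c.v_c is not None:
        residual = abs(c.v_xc - (c.v_x + c.v_c))
        if residual > tolerance:
            raise ConsistencyError(f"V_xc differs from Vx+Vc by {residual:.3e} hartree")
    return c.v_cl + c.v_xc + c.v_d3


@dataclass(frozen=True)
class CtPlSplit:
    """Charge-transfer / polarisation split of a classical interaction.

    ``v_pl`` is defined as the remainder, so ``v_ct + v_pl`` restores
    the input ``v_cl`` exactly up to one floating-point rounding of the
    subtraction.
    """

    v_ct: float
    v_pl: float
    q_a: float
    q_b: float
    r_ab: float

    @property
    def v_cl(self) -> float:
        return self.v_ct + self.v_pl


def ct_pl_split(v_cl: float, q_a: float, q_b: float, r_ab: float) -> CtPlSplit:
    """Split V_cl into monopolar charge transfer q_A q_B / r_AB and remainder.

    All quantities in atomic units (charges in e, distance in bohr,
    energies in hartree).
    """
    if not r_ab > 0:
        raise SchemaError(f"interatomic distance must be positive, got {r_ab}")
    v_ct = q_a * q_b / r_ab
    return CtPlSplit(v_ct=v_ct, v_pl=v_cl - v_ct, q_a=q_a, q_b=q_b, r_ab=r_ab)


def add_ct_pl_terms(profile: EnergyProfile) -> EnergyProfile:
    """Derive V_ct and V_pl series for every V_cl pair from the atom table.

    Charges and positions are taken per PES point (QTAIM-style
    populations in the source data); no charge model is computed here.
    """
    if profile.atoms is None:
        raise SchemaError("charge-transfer split needs a per-point atom table")
    extra: dict[TermKey, np.ndarray] = {}
    for key in profile.keys_of_type(TermType.V_CL):
        if not key.is_pair or not all(isinstance(p, AtomLabel) for p in key.participants):
            continue
        a, b = key.participants
        v_cl = profile.values(key)
        v_ct = np.empty(profile.m_points)
        for m in range(profile.m_points):
            split = ct_pl_split(
                float(v_cl[m]), profile.charge(a, m), profile.charge(b, m), profile.distance(a, b, m)
            )
            v_ct[m] = split.v_ct
        extra[TermKey.pair(TermType.V_CT, a, b)] = v_ct
        extra[TermKey.pair(TermType.V_PL, a, b)] = v_cl - v_ct
    return profile.with_terms(extra)


def aggregate_fragments(
    profile: EnergyProfile,
    scheme: FragmentScheme,
    term_types: Optional[Iterable[TermType]] = None,
) -> EnergyProfile:
    """Aggregate pairwise terms into fragment-pair (IQF) terms.

    For every unordered pair of groups and every interatomic term type,
    the fragment term at each point is the sum of the member pairwise
    terms with one atom in each group.  Intra-group pair terms and
    group-internal intra-atomic terms are not part of the between-group
    interaction.  The (stored or recomposed) total-energy series is
    carried over so REG can run directly on the result.
    """
    scheme.validate_against(profile)
    if term_types is None:
        wanted = PAIR_TYPES
    else:
        wanted = frozenset(term_types)

    membership: dict[AtomLabel, str] = {}
    for name in scheme:
        for atom in scheme[name]:
            membership[atom] = name

    out: dict[TermKey, np.ndarray] = {}
    for key in profile.term_keys:
        if not key.is_pair or key.term_type not in wanted:
            continue
        a, b = key.participants
        if not (isinstance(a, AtomLabel) and isinstance(b, AtomLabel)):
            continue
        ga, gb = membership.get(a), membership.get(b)
        if ga is None or gb is None or ga == gb:
            continue
        frag_key = TermKey.pair(key.term_type, ga, gb)
        if frag_key in out:
            out[frag_key] = out[frag_key] + profile.values(key)
        else:
            out[frag_key] = profile.values(key).copy()

    if not out:
        raise SchemaError("no between-group pairwise terms found for this scheme")
    out[TermKey.total()] = np.asarray(profile.e_tot(), dtype=float).copy()
    meta = dict(profile.metadata)
    meta["aggregation"] = f"IQF over groups {sorted(scheme.groups)}"
    return EnergyProfile(profile.s, out, metadata=meta)
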