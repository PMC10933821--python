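"""Synthetic energy-profile generator with known statistical structure.

Real REG-IQA inputs come from wavefunction partitioning of DFT scans, a
pipeline far beyond desk scale.  The generator emulates exactly the
structure the analysis relies on: an additive partition whose terms sum
to the total energy bit-exactly at every point, a monotone barrier- or
line-shaped total-energy profile, prescribed per-term regression slopes
summing to one, per-term constant offsets (exercising translation
invariance) and Gaussian noise projected so the partition stays exact.

Profiles are ordered transition-state first, minimum last, matching the
sign convention under which positive REG favours the formation of the
final conformer.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import SchemaError
from .profile import ATOM_COLUMNS, EnergyProfile
from .terms import AtomLabel, FragmentScheme, TermKey, TermType

_ELEMENT_CYCLE = ("c", "n", "o", "h")
_SLOPE_SUM_TOL = 1e-12


@dataclass
class SyntheticSpec:
    """Recipe for one synthetic profile.

    Parameters
    ----------
    n_atoms : int
        Atoms in the fictitious system (>= 2); the partition holds one
        intra-atomic term per atom and V_cl/V_xc/V_D3 per pair.
    m_points : int
        PES points (>= 3, the regression minimum).
    total_shape : {"linear", "barrier"} or array of samples
        Total-energy profile over s in [0, 1]; "barrier" is a monotone
        quadratic decaying from ``amplitude`` to 0 (TS first, minimum
        last), "linear" decays linearly.
    amplitude : float
        Barrier height in hartree; 0.02 (~52 kJ/mol) is typical of a
        conformational rotation barrier.
    true_slopes : mapping TermKey -> float, optional
        Ground-truth regression slopes; must sum to 1 over the complete
        partition.  Drawn randomly (and normalised) when omitted.
    noise_sigma : float
        Per-term Gaussian noise amplitude in hartree, mean-projected per
        point so the partition stays exact.
    offset_scale : float
        Scale of the per-term constant offsets (hartree).
    seed : int
        Seed for numpy's default (PCG64) generator; identical seeds give
        bit-identical profiles.
    with_atoms : bool
        Also emit per-point charges and jittered-chain coordinates.
    """

    n_atoms: int = 6
    m_points: int = 15
    total_shape: object = "barrier"
    amplitude: float = 0.02
    true_slopes: Optional[Mapping[TermKey, float]] = None
    noise_sigma: float = 0.0
    offset_scale: float = 1e-2
    seed: int = 0
    with_atoms: bool = True

    def __post_init__(self):
        if self.n_atoms < 2:
            raise SchemaError(f"need at least 2 atoms, got {self.n_atoms}")
        if self.m_points < 3:
            raise SchemaError(f"need at least 3 PES points, got {self.m_points}")
        if self.noise_sigma < 0:
            raise SchemaError("noise_sigma must be non-negative")


@dataclass
class GroundTruth:
    """What the generator actually realised (for recovery tests)."""

    spec: SyntheticSpec
    atoms: list
    slopes: dict
    offsets: dict
    base_total: np.ndarray  # noiseless shape series before the offset shift
    e_tot: np.ndarray  # stored total (= base + sum of offsets, exactly)


def _partition_keys(atoms: Sequence[AtomLabel]) -> list:
    keys = [TermKey.intra(TermType.E_INTRA, a) for a in atoms]
    for i, a in enumerate(atoms):
        for b in atoms[i + 1 :]:
            for tt in (TermType.V_CL, TermType.V_XC, TermType.V_D3):
                keys.append(TermKey.pair(tt, a, b))
    return keys


def _shape_series(spec: SyntheticSpec, s: np.ndarray) -> np.ndarray:
    if isinstance(spec.total_shape, str):
        if spec.total_shape == "barrier":
            return spec.amplitude * (1.0 - s) ** 2
        if spec.total_shape == "linear":
            return spec.amplitude * (1.0 - s)
        raise SchemaError(f"unknown total_shape {spec.total_shape!r}")
    samples = np.asarray(spec.total_shape, dtype=float)
    if samples.shape != s.shape:
        raise SchemaError(
            f"custom total_shape has {samples.size} samples, expected {s.size}"
        )
    return samples


def generate_profile(spec: SyntheticSpec):
    """Realise a synthetic profile and its ground truth.

    Each term is ``slope_i * base(s) + offset_i + eps_i(s)`` with the
    noise mean-projected per point so the terms sum exactly to the
    stored total energy (which therefore equals ``base`` shifted by the
    constant sum of offsets — REG is invariant to that shift).
    """
    rng = np.random.default_rng(spec.seed)
    atoms = [
        AtomLabel(_ELEMENT_CYCLE[i % len(_ELEMENT_CYCLE)], i + 1) for i in range(spec.n_atoms)
    ]
    keys = _partition_keys(atoms)
    k = len(keys)

    s = np.linspace(0.0, 1.0, spec.m_points)
    base = _shape_series(spec, s)

    if spec.true_slopes is not None:
        unknown = set(spec.true_slopes) - set(keys)
        if unknown:
            raise SchemaError(f"slopes given for unknown terms: {sorted(map(str, unknown))}")
        absent = [key for key in keys if key not in spec.true_slopes]
        if absent:
            raise SchemaError(f"slopes missing for terms: {[str(k) for k in absent[:5]]}")
        slopes = np.array([float(spec.true_slopes[key]) for key in keys])
        if abs(slopes.sum() - 1.0) > _SLOPE_SUM_TOL:
            raise SchemaError(f"true slopes must sum to 1, got {slopes.sum():.15f}")
    else:
        slopes = rng.normal(loc=1.0 / k, scale=1.0 / k, size=k)
        slopes[-1] += 1.0 - slopes.sum()

    offsets = rng.normal(0.0, spec.offset_scale, size=k)
    eps = np.zeros((k, spec.m_points))
    if spec.noise_sigma > 0:
        eps = rng.normal(0.0, spec.noise_sigma, size=(k, spec.m_points))
        eps -= eps.mean(axis=0, keepdims=True)  # per-point sum is exactly 0

    values = slopes[:, None] * base[None, :] + offsets[:, None] + eps
    e_tot = values.sum(axis=0)  # exact float sum: the partition closes bitwise

    terms = {key: values[i] for i, key in enumerate(keys)}
    terms[TermKey.total()] = e_tot

    atom_table = None
    if spec.with_atoms:
        atom_table = _chain_atoms(rng, atoms, spec.m_points)

    profile = EnergyProfile(
        s,
        terms,
        atoms=atom_table,
        metadata={"system": f"synthetic-{spec.seed}", "generator": "regiqa.simulate"},
    )
    truth = GroundTruth(
        spec=spec,
        atoms=atoms,
        slopes={key: float(slopes[i]) for i, key in enumerate(keys)},
        offsets={key: float(offsets[i]) for i, key in enumerate(keys)},
        base_total=base,
        e_tot=e_tot,
    )
    return profile, truth


def _chain_atoms(rng, atoms, m_points) -> pd.DataFrame:
    """Charges and coordinates on a jittered linear chain (bohr)."""
    base_q = rng.normal(0.0, 0.3, size=len(atoms))
    rows = []
    for point in range(m_points):
        jitter = rng.normal(0.0, 0.05, size=(len(atoms), 3))
        dq = rng.normal(0.0, 0.005, size=len(atoms))
        for i, atom in enumerate(atoms):
            rows.append(
                {
                    "point_index": point,
                    "atom": str(atom),
                    "q": base_q[i] + dq[i],
                    "x": 2.5 * i + jitter[i, 0],
                    "y": jitter[i, 1],
                    "z": jitter[i, 2],
                }
            )
    frame = pd.DataFrame(rows).set_index(["point_index", "atom"])[ATOM_COLUMNS]
    return frame.astype(float)


def generate_balance_like(
    seed: int = 0, m_points: int = 21, noise_sigma: float = 1e-5
):
    """A molecular-balance-like profile with designated dominant terms.

    Twelve atoms arranged as an amide motif (n1, c4, o5) facing a second
    carbonyl (c22, o23): the amide electrostatic pair V_cl(n1,c4) gets
    the dominant positive slope, the amide-nitrogen steric term
    E_intra(n1) the dominant negative one, and the carbonyl...carbonyl
    pairs V_cl(o5,c22) / V_cl(c4,c22) counterbalance at +/-0.7.  The
    returned fragment scheme holds singleton groups (A, B) on the
    carbonyl oxygen/carbon and two multi-atom groups (E, F) around each
    carbonyl, exercising the fragment-aggregation and ratio paths.
    """
    labels = ["n1", "c2", "h3", "c4", "o5", "h6", "c22", "o23", "c24", "h25", "h26", "h27"]
    atoms = [AtomLabel.parse(t) for t in labels]
    keys = _partition_keys(atoms)

    designated = {
        TermKey.pair(TermType.V_CL, AtomLabel.parse("n1"), AtomLabel.parse("c4")): 4.7,
        TermKey.intra(TermType.E_INTRA, AtomLabel.parse("n1")): -2.3,
        TermKey.pair(TermType.V_CL, AtomLabel.parse("o5"), AtomLabel.parse("c22")): 0.7,
        TermKey.pair(TermType.V_CL, AtomLabel.parse("c4"), AtomLabel.parse("c22")): -0.7,
    }
    rng = np.random.default_rng(seed)
    rest = [key for key in keys if key not in designated]
    small = rng.uniform(-0.05, 0.05, size=len(rest))
    small += (1.0 - sum(designated.values()) - small.sum()) / len(rest)
    slopes = dict(designated)
    slopes.update({key: float(v) for key, v in zip(rest, small)})
    total = sum(slopes.values())
    first = rest[0]
    slopes[first] += 1.0 - total  # absorb rounding so the sum is exactly 1

    spec = SyntheticSpec(
        n_atoms=len(atoms),
        m_points=m_points,
        total_shape="barrier",
        amplitude=0.02,
        true_slopes=None,  # installed below with the custom atom labels
        noise_sigma=noise_sigma,
        seed=seed,
    )
    profile, truth = _generate_with_atoms(spec, atoms, slopes)

    scheme = FragmentScheme(
        {
            "A": ["o5"],
            "B": ["c22"],
            "E": ["n1", "c2", "c4"],
            "F": ["o23", "c24", "h25"],
        }
    )
    return profile, scheme, truth


def _generate_with_atoms(spec: SyntheticSpec, atoms, slopes_map):
    """generate_profile with caller-chosen atom labels and slopes."""
    rng = np.random.default_rng(spec.seed)
    keys = _partition_keys(atoms)
    slopes = np.array([slopes_map[key] for key in keys])
    if abs(slopes.sum() - 1.0) > _SLOPE_SUM_TOL:
        raise SchemaError(f"slopes must sum to 1, got {slopes.sum():.15f}")
    s = np.linspace(0.0, 1.0, spec.m_points)
    base = _shape_series(spec, s)
    offsets = rng.normal(0.0, spec.offset_scale, size=len(keys))
    eps = np.zeros((len(keys), spec.m_points))
    if spec.noise_sigma > 0:
        eps = rng.normal(0.0, spec.noise_sigma, size=eps.shape)
        eps -= eps.mean(axis=0, keepdims=True)
    values = slopes[:, None] * base[None, :] + offsets[:, None] + eps
    e_tot = values.sum(axis=0)
    terms = {key: values[i] for i, key in enumerate(keys)}
    terms[TermKey.total()] = e_tot
    atom_table = _chain_atoms(rng, atoms, spec.m_points) if spec.with_atoms else None
    profile = EnergyProfile(
        s,
        terms,
        atoms=atom_table,
        metadata={"system": f"balance-like-{spec.seed}", "generator": "regiqa.simulate"},
    )
    truth = GroundTruth(
        spec=spec,
        atoms=list(atoms),
        slopes={key: float(slopes[i]) for i, key in enumerate(keys)},
        offsets={key: float(offsets[i]) for i, key in enumerate(keys)},
        base_total=base,
        e_tot=e_tot,
    )
    return profile, truth
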