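"""CSV interchange for energy profiles and YAML fragment schemes.

Term table schema (comma-separated, UTF-8, one row per term per point)::

    point_index,s,term_type,atom_a,atom_b,energy_hartree

``atom_b`` is empty for intra-atomic terms and both atom columns are
empty for ``E_tot`` rows.  For fragment profiles the atom columns carry
group names instead of atom labels.  The optional companion atom table
has columns ``point_index,atom,q,x,y,z`` (charge in e, positions in
bohr); by default it lives next to the term table with an
``.atoms.csv`` suffix.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .errors import CompletenessError, OrderingError, SchemaError
from .profile import ATOM_COLUMNS, EnergyProfile
from .terms import AtomLabel, FragmentScheme, TermKey, TermType

TERM_COLUMNS = ["point_index", "s", "term_type", "atom_a", "atom_b", "energy_hartree"]
ATOM_FILE_COLUMNS = ["point_index", "atom"] + ATOM_COLUMNS

#: hartree -> kJ/mol, fixed at 4 decimal places for reporting
HARTREE_TO_KJMOL = 2625.4996


def default_atoms_path(path) -> Path:
    path = Path(path)
    return path.with_name(path.stem + ".atoms.csv")


def _parse_participant(token: str):
    try:
        return AtomLabel.parse(token)
    except SchemaError:
        return token.strip()  # fragment/group name


def read_profile(path, atoms_path=None, metadata: Optional[dict] = None) -> EnergyProfile:
    """Read and validate an energy profile from the CSV interchange schema.

    Pair orientation in the file is irrelevant (keys are canonicalised);
    duplicate (point, term) rows and terms missing at some points are
    rejected.  If ``atoms_path`` is not given, the default companion file
    is read when it exists.
    """
    path = Path(path)
    frame = pd.read_csv(path, dtype={"atom_a": str, "atom_b": str}, float_precision="round_trip")
    missing = [c for c in TERM_COLUMNS if c not in frame.columns]
    if missing:
        raise SchemaError(f"term table {path.name} missing column(s) {missing}")

    point_order = frame["point_index"].drop_duplicates().tolist()
    s_by_point: dict = {}
    series: dict[TermKey, dict] = {}
    for row in frame.itertuples(index=False):
        s_val = float(row.s)
        prev = s_by_point.setdefault(row.point_index, s_val)
        if prev != s_val:
            raise SchemaError(
                f"point {row.point_index} has conflicting s values {prev} and {s_val}"
            )
        term_type = TermType.parse(str(row.term_type))
        parts = []
        for token in (row.atom_a, row.atom_b):
            if token is None or (isinstance(token, float) and np.isnan(token)):
                continue
            token = str(token).strip()
            if token:
                parts.append(_parse_participant(token))
        key = TermKey(term_type, tuple(parts))
        per_point = series.setdefault(key, {})
        if row.point_index in per_point:
            raise SchemaError(f"duplicate row for term {key} at point {row.point_index}")
        per_point[row.point_index] = float(row.energy_hartree)

    m = len(point_order)
    offenders = []
    for key, per_point in series.items():
        absent = [p for p in point_order if p not in per_point]
        if absent:
            offenders.append(f"{key} at point(s) {absent}")
    if offenders:
        raise CompletenessError(
            "term(s) present at some points but missing at others: " + "; ".join(offenders)
        )

    s = np.array([s_by_point[p] for p in point_order], dtype=float)
    if m > 1:
        ds = np.diff(s)
        if not (np.all(ds > 0) or np.all(ds < 0)):
            raise OrderingError(f"control coordinate s in {path.name} is not strictly monotonic")

    terms = {
        key: np.array([per_point[p] for p in point_order], dtype=float)
        for key, per_point in series.items()
    }

    atoms = None
    if atoms_path is None and default_atoms_path(path).exists():
        atoms_path = default_atoms_path(path)
    if atoms_path is not None:
        atoms = read_atom_table(atoms_path, point_order)
    return EnergyProfile(s, terms, atoms=atoms, metadata=metadata or {"source": str(path)})


def read_atom_table(path, point_order=None) -> pd.DataFrame:
    path = Path(path)
    frame = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in ATOM_FILE_COLUMNS if c not in frame.columns]
    if missing:
        raise SchemaError(f"atom table {path.name} missing column(s) {missing}")
    frame["atom"] = frame["atom"].map(lambda a: str(AtomLabel.parse(str(a))))
    frame = frame.set_index(["point_index", "atom"])[ATOM_COLUMNS].astype(float)
    if frame.index.duplicated().any():
        raise SchemaError(f"atom table {path.name} has duplicate (point, atom) rows")
    return frame


def write_profile(profile: EnergyProfile, path, atoms_path=None) -> None:
    """Write a profile to the CSV schema; energies keep full precision.

    Round-tripping through :func:`read_profile` reproduces the profile
    bit-identically (energies are written with 17 significant digits).
    A profile carrying an atom table is written as two files.
    """
    if profile.m_points < 1:
        raise SchemaError("refusing to write an empty profile")
    path = Path(path)
    rows = []
    for point in range(profile.m_points):
        s_val = profile.s[point]
        for key in profile.term_keys:
            parts = [str(p) for p in key.participants]
            rows.append(
                {
                    "point_index": point,
                    "s": f"{s_val:.17g}",
                    "term_type": key.term_type.value,
                    "atom_a": parts[0] if len(parts) > 0 else "",
                    "atom_b": parts[1] if len(parts) > 1 else "",
                    "energy_hartree": f"{profile.values(key)[point]:.17g}",
                }
            )
    pd.DataFrame(rows, columns=TERM_COLUMNS).to_csv(path, index=False)
    if profile.atoms is not None:
        atoms_path = Path(atoms_path) if atoms_path is not None else default_atoms_path(path)
        out = profile.atoms.reset_index()
        out.columns = ATOM_FILE_COLUMNS
        # remap stored point labels onto 0..M-1 to match the term table
        order = {p: i for i, p in enumerate(profile.atoms.index.get_level_values(0).unique())}
        out["point_index"] = out["point_index"].map(order)
        for col in ATOM_COLUMNS:
            out[col] = out[col].map(lambda v: f"{v:.17g}")
        out.to_csv(atoms_path, index=False)


def read_fragment_scheme(path) -> FragmentScheme:
    return FragmentScheme.from_yaml(path)


def write_fragment_scheme(scheme: FragmentScheme, path) -> None:
    scheme.to_yaml(path)


# ----------------------------------------------------------------------
@dataclass
class ValidationReport:
    """Per-point additivity residuals and component-identity checks.

    ``residuals[m]`` is |E_tot(m) - sum of intra terms - sum of pair
    terms| in hartree; ``flagged_points`` lists points exceeding the
    tolerance.  ``identity_checks`` maps a named identity (e.g.
    ``"E_intra = T + Vee + Ven"``) to its maximum absolute residual when
    the raw components are present.
    """

    tolerance: float
    residuals: np.ndarray
    flagged_points: list = field(default_factory=list)
    identity_checks: dict = field(default_factory=dict)
    notes: list = field(default_factory=list)

    @property
    def ok(self) -> bool:
        if self.flagged_points:
            return False
        return all(v <= self.tolerance for v in self.identity_checks.values())

    def summary(self) -> str:
        lines = [
            f"additivity residual: max {np.max(self.residuals):.3e} hartree "
            f"(tolerance {self.tolerance:.1e})",
        ]
        if self.flagged_points:
            lines.append(f"flagged points: {self.flagged_points}")
        for name, value in sorted(self.identity_checks.items()):
            status = "ok" if value <= self.tolerance else "FAIL"
            lines.append(f"identity {name}: max residual {value:.3e} [{status}]")
        for note in self.notes:
            lines.append(f"note: {note}")
        lines.append("PASS" if self.ok else "FAIL")
        return "\n".join(lines)


def validate_profile(profile: EnergyProfile, tolerance: float = 1e-8) -> ValidationReport:
    """Check the additive partition and component identities of a profile.

    The headline check is that the stored total energy equals the sum of
    all intra-atomic terms plus all unordered-pair interatomic terms at
    every point.  When raw components are present, the intra-atomic
    (kinetic + same-basin potentials), interatomic (classical +
    exchange-correlation [+ dispersion]) and electron-repulsion
    (Coulomb + exchange + correlation) identities are also checked.
    Missing dispersion rows count as zero.
    """
    from .algebra import total_energy

    report = ValidationReport(tolerance=tolerance, residuals=np.zeros(profile.m_points))
    if profile.has_stored_total:
        recomposed = total_energy(profile)
        report.residuals = np.abs(profile.values(TermKey.total()) - recomposed)
        report.flagged_points = [
            int(i) for i in np.nonzero(report.residuals > tolerance)[0]
        ]
    else:
        report.notes.append("no stored E_tot; additivity not checkable")

    pair_keys = [k for k in profile.term_keys if k.is_pair]
    has_d3 = any(k.term_type is TermType.V_D3 for k in pair_keys)
    if any(k.term_type in (TermType.V_CL, TermType.V_XC) for k in pair_keys) and not has_d3:
        report.notes.append("no dispersion (V_D3) terms present; treated as 0 for every pair")

    # intra identity: E_intra = T + Vee^AA + Ven^AA
    intra_res = []
    for key in profile.keys_of_type(TermType.E_INTRA):
        atom = key.participants[0]
        t = profile.get(TermKey.intra(TermType.T, atom))
        vee = profile.get(TermKey.intra(TermType.VEE, atom))
        ven = profile.get(TermKey.intra(TermType.VEN, atom))
        if t is None or vee is None or ven is None:
            continue
        intra_res.append(np.max(np.abs(profile.values(key) - (t + vee + ven))))
    if intra_res:
        report.identity_checks["E_intra = T + Vee + Ven"] = float(max(intra_res))

    # interatomic identity: V_inter = V_cl + V_xc [+ V_D3]
    inter_res = []
    for key in profile.keys_of_type(TermType.V_INTER):
        a, b = key.participants
        vcl = profile.get(TermKey.pair(TermType.V_CL, a, b))
        vxc = profile.get(TermKey.pair(TermType.V_XC, a, b))
        if vcl is None or vxc is None:
            continue
        vd3 = profile.get(TermKey.pair(TermType.V_D3, a, b))
        total = vcl + vxc + (vd3 if vd3 is not None else 0.0)
        inter_res.append(np.max(np.abs(profile.values(key) - total)))
    if inter_res:
        report.identity_checks["V_inter = V_cl + V_xc + V_D3"] = float(max(inter_res))

    # electron-electron repulsion: Vee^AB = Vcoul + Vx + Vc
    vee_res = []
    for key in profile.keys_of_type(TermType.VEE):
        if not key.is_pair:
            continue
        a, b = key.participants
        vcoul = profile.get(TermKey.pair(TermType.VCOUL, a, b))
        vx = profile.get(TermKey.pair(TermType.VX, a, b))
        vc = profile.get(TermKey.pair(TermType.VC, a, b))
        if vcoul is None or vx is None or vc is None:
            continue
        vee_res.append(np.max(np.abs(profile.values(key) - (vcoul + vx + vc))))
    if vee_res:
        report.identity_checks["Vee = Vcoul + Vx + Vc"] = float(max(vee_res))

    return report
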