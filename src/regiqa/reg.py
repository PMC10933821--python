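"""Relative Energy Gradient (REG) analysis.

For M geometries along a control coordinate, each partitioned energy
term E_i is regressed on the total energy E_tot by ordinary least
squares after mean-centring both series over the segment:

    m_REG,i = (E_tot~ . E_i~) / (E_tot~ . E_tot~)

where ``~`` denotes subtraction of the segment mean.  The slope is
dimensionless; summed over a complete additive partition it equals 1
exactly (linearity of least squares).  Terms whose regression has a
coefficient of determination R^2 below a threshold (default 0.8) are
flagged inadmissible.  The control coordinate never enters the
numerics; it only orders points and delimits the segment.

Ranking convention: profiles are ordered so the final point is the
conformer whose formation is under study (e.g. transition state first,
lowest-energy closed conformer last); then positive REG values favour
formation and negative values oppose it.

The module follows the model/results idiom: ``REG(profile).fit()``
returns a :class:`REGResults` carrying entries, ranks, ratios and a
``summary()`` table.  The functions :func:`reg_values`,
:func:`rank_and_filter`, :func:`reg_ratio` and
:func:`cross_system_compare` are thin wrappers over those objects.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import CompletenessError, DegenerateSegmentError, PreconditionError
from .profile import EnergyProfile
from .terms import TermKey, TermType


@dataclass(frozen=True)
class RegEntry:
    """REG slope and correlation diagnostics for one energy term."""

    key: TermKey
    reg: float
    pearson_r: float  # NaN when the term has zero variance
    r_squared: float
    admissible: bool
    rank: int  # 1 = most positive slope
    zero_variance: bool = False


@dataclass
class RatioEntry:
    """REG Ratio of one term: reference REG_max divided by the term's REG.

    The self-ratio of the reference term is exactly 1.  Terms whose REG
    magnitude falls below ``floor`` give numerically meaningless ratios
    and are flagged ``unstable`` (the computed value is still reported).
    """

    key: TermKey
    reg: float
    ratio: float
    reference_reg: float
    reference_key: Optional[TermKey] = None
    unstable: bool = False


class REG:
    """REG model over an energy profile segment.

    Parameters
    ----------
    profile : EnergyProfile
        Profile whose terms are regressed on its total energy.
    segment : (start, stop), optional
        Half-open point range; default is the whole profile (published
        analyses typically use a single TS-to-minimum segment).
    r2_threshold : float
        Admissibility threshold on R^2 (default 0.8).
    """

    def __init__(
        self,
        profile: EnergyProfile,
        segment: Optional[tuple] = None,
        r2_threshold: float = 0.8,
    ):
        self.profile = profile
        self.segment = tuple(segment) if segment is not None else (0, profile.m_points)
        self.r2_threshold = float(r2_threshold)
        start, stop = self.segment
        if not (0 <= start < stop <= profile.m_points):
            raise PreconditionError(
                f"segment {self.segment} invalid for a profile with M={profile.m_points}"
            )

    @property
    def m_points(self) -> int:
        return self.segment[1] - self.segment[0]

    def fit(self) -> "REGResults":
        start, stop = self.segment
        if self.m_points < 3:
            raise PreconditionError(
                f"REG regression needs at least 3 points, segment has {self.m_points}"
            )
        x = np.asarray(self.profile.e_tot(), dtype=float)[start:stop]
        xc = x - x.mean()
        sxx = float(xc @ xc)
        if sxx == 0.0:
            raise DegenerateSegmentError("total energy has zero variance over the segment")

        raw = []
        for key in self.profile.term_keys:
            if key.is_total:
                continue
            y = self.profile.values(key)[start:stop]
            yc = y - y.mean()
            syy = float(yc @ yc)
            sxy = float(xc @ yc)
            slope = sxy / sxx
            if syy == 0.0:
                raw.append((key, 0.0, math.nan, math.nan, True))
            else:
                r = sxy / math.sqrt(sxx * syy)
                raw.append((key, slope, r, r * r, False))

        raw.sort(key=lambda t: (-t[1],) + t[0].sort_key())
        entries = [
            RegEntry(
                key=key,
                reg=slope,
                pearson_r=r,
                r_squared=r2,
                admissible=(not zv) and r2 >= self.r2_threshold,
                rank=i + 1,
                zero_variance=zv,
            )
            for i, (key, slope, r, r2, zv) in enumerate(raw)
        ]
        return REGResults(
            entries=entries,
            segment=self.segment,
            m_points=self.m_points,
            r2_threshold=self.r2_threshold,
            metadata=dict(self.profile.metadata),
        )


@dataclass
class REGResults:
    """Fitted REG table: one entry per term, sorted most positive first."""

    entries: list
    segment: Optional[tuple] = None
    m_points: Optional[int] = None
    r2_threshold: float = 0.8
    metadata: dict = field(default_factory=dict)

    def __iter__(self):
        return iter(self.entries)

    def __len__(self) -> int:
        return len(self.entries)

    def lookup(self, key: TermKey) -> RegEntry:
        for entry in self.entries:
            if entry.key == key:
                return entry
        raise CompletenessError(f"no REG entry for term {key}")

    @property
    def reg_sum(self) -> float:
        """Sum of all slopes; equals 1 for a complete additive partition."""
        return float(sum(e.reg for e in self.entries))

    @property
    def max_positive(self) -> RegEntry:
        top = self.entries[0]
        if top.reg <= 0:
            raise PreconditionError("no positive REG value in this table")
        return top

    # ------------------------------------------------------------------
    def top(self, k: int = 5, admissible_only: bool = True) -> list:
        """The k most positive and k most negative entries, order preserved.

        Inadmissible entries (R^2 below threshold or zero variance) are
        excluded by default but remain retrievable on the full table.
        """
        if k < 1:
            raise PreconditionError(f"top-k selection needs k >= 1, got {k}")
        pool = [e for e in self.entries if e.admissible or not admissible_only]
        if not pool:
            warnings.warn(
                f"no entries admissible at R^2 >= {self.r2_threshold}; empty selection",
                stacklevel=2,
            )
            return []
        positives = pool[:k]
        negatives = pool[-k:] if len(pool) > k else []
        seen = {id(e) for e in positives}
        return positives + [e for e in negatives if id(e) not in seen]

    def ratios(
        self,
        reference_reg: Optional[float] = None,
        reference_key: Optional[TermKey] = None,
        floor: float = 1e-6,
    ) -> list:
        """REG Ratios: reference / REG_i for every entry.

        The reference defaults to this table's most positive REG value;
        for fragment (IQF) tables it is conventionally the most positive
        value of the fully atomistic analysis, passed explicitly.
        """
        if reference_reg is None:
            ref = self.max_positive
            reference_reg, reference_key = ref.reg, ref.key
        if not reference_reg > 0:
            raise PreconditionError(
                f"reference REG value must be positive, got {reference_reg}"
            )
        out = []
        for entry in self.entries:
            unstable = abs(entry.reg) < floor
            with np.errstate(divide="ignore"):
                value = reference_reg / entry.reg if entry.reg != 0 else math.inf
            out.append(
                RatioEntry(
                    key=entry.key,
                    reg=entry.reg,
                    ratio=float(value),
                    reference_reg=reference_reg,
                    reference_key=reference_key,
                    unstable=unstable,
                )
            )
        return out

    # ------------------------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "term": [e.key.label() for e in self.entries],
                "reg": [e.reg for e in self.entries],
                "pearson_r": [e.pearson_r for e in self.entries],
                "r_squared": [e.r_squared for e in self.entries],
                "admissible": [e.admissible for e in self.entries],
                "rank": [e.rank for e in self.entries],
            }
        )

    def summary(self, top_k: Optional[int] = 5, rounded: bool = True) -> str:
        from .reporting import format_reg_table

        return format_reg_table(self, top_k=top_k, rounded=rounded)

    @classmethod
    def from_entries(cls, pairs: Sequence, r2_threshold: float = 0.8, **kwargs) -> "REGResults":
        """Build a results table from (key, reg[, pearson_r]) tuples.

        Used to load published REG tables as fixtures; entries are
        re-sorted and re-ranked under the package's tie-break rules.
        """
        rows = []
        for item in pairs:
            key, slope = item[0], float(item[1])
            r = float(item[2]) if len(item) > 2 and item[2] is not None else math.nan
            rows.append((key, slope, r))
        rows.sort(key=lambda t: (-t[1],) + t[0].sort_key())
        entries = [
            RegEntry(
                key=key,
                reg=slope,
                pearson_r=r,
                r_squared=r * r if not math.isnan(r) else math.nan,
                admissible=(not math.isnan(r)) and r * r >= r2_threshold,
                rank=i + 1,
            )
            for i, (key, slope, r) in enumerate(rows)
        ]
        return cls(entries=entries, r2_threshold=r2_threshold, **kwargs)


# ----------------------------------------------------------------------
# functional wrappers
def reg_values(
    profile: EnergyProfile,
    segment: Optional[tuple] = None,
    r2_threshold: float = 0.8,
) -> REGResults:
    """Compute the REG table for a profile segment (model + fit in one call)."""
    return REG(profile, segment=segment, r2_threshold=r2_threshold).fit()


def rank_and_filter(table: REGResults, top_k: int) -> list:
    """The k most positive and k most negative admissible entries."""
    return table.top(top_k)


def reg_ratio(
    values: Iterable[RegEntry], reference_reg: float, floor: float = 1e-6
) -> list:
    """REG Ratios of a list of entries against an external positive reference."""
    table = REGResults(entries=list(values))
    return table.ratios(reference_reg=reference_reg, floor=floor)


@dataclass
class ComparisonMatrix:
    """Cross-system REG Ratio comparison for a fixed set of terms.

    ``frame`` holds one row per term and one column per system in the
    requested order; ``trends`` maps each term label to the direction of
    its ratio across that system order ("increasing", "decreasing",
    "mixed", or "undefined" for fewer than two systems).
    """

    frame: pd.DataFrame
    trends: dict


def cross_system_compare(
    tables: Mapping[str, Iterable[RatioEntry]],
    keys: Sequence[TermKey],
    system_order: Optional[Sequence[str]] = None,
) -> ComparisonMatrix:
    """Compare REG Ratios of chosen terms across systems.

    Every system must provide a ratio for every requested term; a
    missing one raises :class:`CompletenessError` naming both.
    """
    systems = list(system_order) if system_order is not None else list(tables)
    data: dict[str, list] = {}
    for system in systems:
        ratio_by_key = {r.key: r for r in tables[system]}
        column = []
        for key in keys:
            if key not in ratio_by_key:
                raise CompletenessError(f"system {system!r} has no ratio for term {key}")
            column.append(ratio_by_key[key].ratio)
        data[system] = column
    frame = pd.DataFrame(data, index=[k.label() for k in keys])
    trends = {}
    for key in keys:
        row = frame.loc[key.label()].to_numpy(dtype=float)
        if row.size < 2:
            trends[key.label()] = "undefined"
        elif np.all(np.diff(row) > 0):
            trends[key.label()] = "increasing"
        elif np.all(np.diff(row) < 0):
            trends[key.label()] = "decreasing"
        else:
            trends[key.label()] = "mixed"
    return ComparisonMatrix(frame=frame, trends=trends)
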