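"""Experiment-vs-computation agreement statistics.

NMR conformational equilibria give an experimental free energy through
dG = -RT ln K with K the closed/open population ratio; solvation-model
fits turn these into experimental conformer energy differences that can
be benchmarked against computed ones via RMSE and the squared Pearson
correlation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .errors import PreconditionError, SchemaError

#: molar gas constant, J mol^-1 K^-1
R_GAS = 8.31446


def rmse(a, b) -> float:
    """Root mean squared error between two equal-length value vectors."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or a.size < 1:
        raise SchemaError(f"RMSE needs two equal-length vectors, got {a.shape} and {b.shape}")
    return float(np.sqrt(np.mean((a - b) ** 2)))


def squared_correlation(a, b) -> float:
    """Squared Pearson correlation coefficient of two value vectors."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise SchemaError(f"correlation needs two equal-length vectors, got {a.shape} and {b.shape}")
    if a.size < 3:
        raise PreconditionError(f"correlation needs at least 3 pairs, got {a.size}")
    if np.var(a) == 0.0 or np.var(b) == 0.0:
        raise PreconditionError("correlation undefined for a zero-variance vector")
    r = stats.pearsonr(a, b).statistic
    return float(r * r)


def free_energy_from_populations(ratio_closed_open: float, temperature: float) -> float:
    """Free energy difference -RT ln(K) in kJ/mol from a population ratio."""
    if not ratio_closed_open > 0:
        raise SchemaError(f"population ratio must be positive, got {ratio_closed_open}")
    if not temperature > 0:
        raise SchemaError(f"temperature must be positive, got {temperature}")
    return -R_GAS * temperature * np.log(ratio_closed_open) / 1000.0


@dataclass
class EnergyDifferenceSet:
    """Paired experimental / computed conformer energy differences (kJ/mol).

    One experimental column and one or more computed columns (for
    example closed-minus-open differences taken against different open
    reference conformers), all over the same labelled systems.
    """

    labels: list
    de_exp: np.ndarray
    de_calc: dict = field(default_factory=dict)

    def __post_init__(self):
        self.de_exp = np.asarray(self.de_exp, dtype=float)
        n = self.de_exp.size
        if n < 2 or len(self.labels) != n:
            raise SchemaError("need >= 2 labelled systems with one experimental value each")
        clean = {}
        for name, column in self.de_calc.items():
            col = np.asarray(column, dtype=float)
            if col.shape != (n,):
                raise SchemaError(
                    f"computed column {name!r} has length {col.size}, expected {n}"
                )
            clean[str(name)] = col
        self.de_calc = clean

    @classmethod
    def from_csv(cls, path) -> "EnergyDifferenceSet":
        """Read ``label,de_exp,<calc-column>...`` (kJ/mol throughout)."""
        frame = pd.read_csv(Path(path))
        for column in ("label", "de_exp"):
            if column not in frame.columns:
                raise SchemaError(f"energy-difference table missing column {column!r}")
        calc_cols = [c for c in frame.columns if c not in ("label", "de_exp")]
        if not calc_cols:
            raise SchemaError("energy-difference table has no computed column")
        return cls(
            labels=frame["label"].astype(str).tolist(),
            de_exp=frame["de_exp"].to_numpy(dtype=float),
            de_calc={c: frame[c].to_numpy(dtype=float) for c in calc_cols},
        )

    # ------------------------------------------------------------------
    def rmse(self, column: str) -> float:
        return rmse(self.de_exp, self._column(column))

    def r_squared(self, column: str) -> float:
        return squared_correlation(self.de_exp, self._column(column))

    def _column(self, name: str) -> np.ndarray:
        try:
            return self.de_calc[name]
        except KeyError:
            raise SchemaError(f"no computed column {name!r}") from None

    def summary(self) -> pd.DataFrame:
        """RMSE and R^2 of every computed column against experiment."""
        rows = {}
        for name in self.de_calc:
            try:
                r2 = self.r_squared(name)
            except PreconditionError:
                r2 = np.nan
            rows[name] = {"rmse_kj_mol": self.rmse(name), "r_squared": r2}
        return pd.DataFrame(rows).T
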