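"""Published reference tables for two carbonyl-probing balance series.

Shipped as package data: the experimental/computed conformer energy
differences for the formamide (1-X) balances, and the published
atomistic top-10 REG tables and fragment (IQF) REG values for both the
formamide (1-X) and N-formylproline (2-Y) series, transcribed at their
printed precision (REG to 1-2 decimals, Pearson R to 2 decimals).

Fragment group letters follow the published convention: A/B are the
single carbonyl oxygen and opposing carbonyl carbon, C/D the two C=O
units, E/F the wider shells around each carbonyl (including the
substituent).
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .compare import EnergyDifferenceSet
from .reg import REGResults
from .terms import AtomLabel, TermKey, TermType

FORMAMIDE_SYSTEMS = ("1-H", "1-Me", "1-OMe", "1-NMe2")
PROLINE_SYSTEMS = ("2-NO2", "2-CN", "2-H", "2-OMe", "2-NMe2")


def _data_path(name: str):
    return resources.files("regiqa.data").joinpath(name)


def load_energy_differences() -> EnergyDifferenceSet:
    """Experimental vs computed conformer energy differences (kJ/mol).

    ``de_lecc_botec`` compares the lowest-energy closed conformer with
    the intuition-drawn ("back of the envelope") open conformer,
    ``de_lecc_leoc`` with the true lowest-energy open conformer.
    """
    with resources.as_file(_data_path("energy_differences_1x.csv")) as path:
        return EnergyDifferenceSet.from_csv(path)


def load_reference_reg() -> dict:
    """Published atomistic top-10 REG tables, one results object per system."""
    with resources.as_file(_data_path("atomistic_reg_top10.csv")) as path:
        frame = pd.read_csv(path, dtype={"atom_a": str, "atom_b": str})
    out: dict[str, REGResults] = {}
    for system, group in frame.groupby("system", sort=False):
        rows = []
        for row in group.itertuples(index=False):
            term_type = TermType.parse(row.term_type)
            parts = [
                AtomLabel.parse(tok)
                for tok in (row.atom_a, row.atom_b)
                if isinstance(tok, str) and tok.strip()
            ]
            rows.append((TermKey(term_type, tuple(parts)), float(row.reg), float(row.r)))
        out[str(system)] = REGResults.from_entries(rows, metadata={"system": str(system)})
    return out


def load_reference_fragment_reg() -> dict:
    """Published fragment (IQF) REG values per system, group pairs A-F."""
    with resources.as_file(_data_path("fragment_reg.csv")) as path:
        frame = pd.read_csv(path)
    out: dict[str, REGResults] = {}
    for system, group in frame.groupby("system", sort=False):
        rows = [
            (TermKey.pair(TermType.parse(r.term_type), str(r.group_a), str(r.group_b)), float(r.reg))
            for r in group.itertuples(index=False)
        ]
        out[str(system)] = REGResults.from_entries(rows, metadata={"system": str(system)})
    return out


def reference_reg_max(system: str) -> float:
    """Most positive published atomistic REG value of one system."""
    return load_reference_reg()[system].max_positive.reg
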