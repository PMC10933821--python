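"""Human-readable and CSV report writers.

Reports follow the published presentation: REG values to 1 decimal and
Pearson R to 2 decimals in ranked tables, fragment REG to 2 decimals
with integer REG Ratios in ratio tables; rounding is half-up at the
printed precision and can be disabled for full machine precision.
"""

from __future__ import annotations

import decimal
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd


def round_half_up(value: float, ndigits: int = 0) -> float:
    """Decimal half-up rounding (0.5 away from zero), as in printed tables."""
    quantum = decimal.Decimal(1).scaleb(-ndigits)
    d = decimal.Decimal(repr(float(value))).quantize(
        quantum, rounding=decimal.ROUND_HALF_UP
    )
    return float(d)


def _fmt(value: float, ndigits: int, rounded: bool) -> str:
    if value != value:  # NaN
        return "-"
    if not rounded:
        return f"{value:.12g}"
    return f"{round_half_up(value, ndigits):.{ndigits}f}"


def format_reg_table(results, top_k: Optional[int] = 5, rounded: bool = True) -> str:
    """Ranked TERM / REG / R table (most negative at top, like the source tables)."""
    entries = results.top(top_k) if top_k is not None else list(results.entries)
    shown = sorted(entries, key=lambda e: e.reg)
    name = results.metadata.get("system", "")
    header = f"{'TERM':<18}{'REG':>8}{'R':>8}"
    lines = [f"REG table {name}".rstrip(), header, "-" * len(header)]
    for entry in shown:
        lines.append(
            f"{entry.key.label():<18}"
            f"{_fmt(entry.reg, 1, rounded):>8}"
            f"{_fmt(entry.pearson_r, 2, rounded):>8}"
        )
    lines.append(f"(M = {results.m_points}, R^2 threshold {results.r2_threshold})")
    return "\n".join(lines)


def reg_table_frame(results, rounded: bool = False) -> pd.DataFrame:
    frame = results.to_frame()
    if rounded:
        frame["reg"] = frame["reg"].map(lambda v: round_half_up(v, 1))
        frame["pearson_r"] = frame["pearson_r"].map(lambda v: round_half_up(v, 2))
    return frame


def format_ratio_table(
    ratios_by_system: Mapping[str, Iterable],
    keys: Optional[Sequence] = None,
    rounded: bool = True,
) -> str:
    """Ratio report: one REG / REG-Ratio column pair per system.

    REG printed to 2 decimals, ratios to the nearest integer; unstable
    entries (near-zero REG) are marked with ``*``.
    """
    systems = list(ratios_by_system)
    indexed = {s: {r.key: r for r in ratios_by_system[s]} for s in systems}
    if keys is None:
        keys = list(indexed[systems[0]])
    head = f"{'Term':<14}" + "".join(f"{s + ' REG':>12}{'Ratio':>9}" for s in systems)
    lines = [head, "-" * len(head)]
    for key in keys:
        cells = [f"{key.label():<14}"]
        for system in systems:
            entry = indexed[system].get(key)
            if entry is None:
                cells.append(f"{'-':>12}{'-':>9}")
                continue
            mark = "*" if entry.unstable else ""
            ratio = _fmt(entry.ratio, 0, rounded) if rounded else f"{entry.ratio:.12g}"
            cells.append(f"{_fmt(entry.reg, 2, rounded):>12}{ratio + mark:>9}")
        lines.append("".join(cells))
    return "\n".join(lines)


def ratio_table_frame(ratios_by_system: Mapping[str, Iterable], rounded: bool = False) -> pd.DataFrame:
    rows = []
    for system, ratios in ratios_by_system.items():
        for entry in ratios:
            ratio = round_half_up(entry.ratio, 0) if rounded else entry.ratio
            reg = round_half_up(entry.reg, 2) if rounded else entry.reg
            rows.append(
                {
                    "system": system,
                    "term": entry.key.label(),
                    "reg": reg,
                    "ratio": ratio,
                    "unstable": entry.unstable,
                }
            )
    return pd.DataFrame(rows)


def format_comparison(diffs, rounded: bool = True) -> str:
    """Agreement report: RMSE (kJ/mol) and R^2 per computed column."""
    summary = diffs.summary()
    lines = [f"{'column':<18}{'RMSE (kJ/mol)':>15}{'R^2':>8}"]
    for name, row in summary.iterrows():
        rmse_txt = _fmt(row["rmse_kj_mol"], 1, rounded)
        r2_txt = _fmt(row["r_squared"], 2, rounded)
        lines.append(f"{name:<18}{rmse_txt:>15}{r2_txt:>8}")
    return "\n".join(lines)
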