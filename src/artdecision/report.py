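"""Formatting and delimited-text writers for baseline, PSA, and OWSA output."""

from __future__ import annotations

import math
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

import pandas as pd

from .decision_model import baseline_tables
from .owsa import TornadoTable
from .parameters import ParameterSet
from .psa import PSAResult

__all__ = [
    "format_percent",
    "format_dollars",
    "write_baseline_tables",
    "write_psa_summary",
    "write_tornado",
]


def _check_finite(value: float) -> None:
    if not math.isfinite(value):
        raise ValueError(f"cannot format non-finite value {value!r}")


def format_percent(value: float) -> str:
    """Fraction -> percent with two decimals, half-up: 0.928846 -> '92.88%'."""
    _check_finite(value)
    q = Decimal(repr(value * 100)).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP)
    return f"{q}%"


def format_dollars(value: float) -> str:
    """Dollars to the nearest integer, half-up, thousands-separated: 6484.4 -> '$6,484'."""
    _check_finite(value)
    q = Decimal(repr(value)).quantize(Decimal("1"), rounding=ROUND_HALF_UP)
    sign = "-" if q < 0 else ""
    return f"{sign}${abs(int(q)):,}"


_RATE_COLS = {
    "soc_pregnancy", "cs_ti_pregnancy", "delta_pregnancy",
    "soc_live_birth", "cs_ti_live_birth", "delta_live_birth",
}


def _format_frame(frame: pd.DataFrame) -> pd.DataFrame:
    out = frame.copy()
    for col in out.columns:
        if col == "age_band":
            continue
        fmt = format_percent if col in _RATE_COLS else format_dollars
        out[col] = out[col].map(fmt)
    return out


def write_baseline_tables(params: ParameterSet, outdir: str | Path) -> tuple[Path, Path]:
    """Write formatted baseline rate and cost tables; returns the two paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rates, cost = baseline_tables(params)
    p2 = outdir / "table2_baseline.csv"
    p3 = outdir / "table3_baseline.csv"
    _format_frame(rates).to_csv(p2, index=False)
    _format_frame(cost).to_csv(p3, index=False)
    return p2, p3


def write_psa_summary(
    result: PSAResult, outdir: str | Path, save_draws: bool = False
) -> Path:
    """Write the PSA summary as 'mean (lo-hi)' cells plus the labeled baseline.

    With ``save_draws`` the raw per-draw outcome matrix is written alongside
    for audit.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for rec in result.summary.to_dict("records"):
        is_rate = rec["outcome"] in {"pregnancy", "live_birth"}
        fmt = format_percent if is_rate else format_dollars
        rows.append(
            {
                "outcome": rec["outcome"],
                "series": rec["series"],
                "age_band": rec["age_band"],
                "mc_mean_95ci": f"{fmt(rec['mean'])} ({fmt(rec['lo'])}–{fmt(rec['hi'])})",
                "baseline_closed_form": fmt(rec["baseline"]),
            }
        )
    path = outdir / "psa_summary.csv"
    pd.DataFrame(rows).to_csv(path, index=False)
    if save_draws:
        result.draws.to_csv(outdir / "psa_draws.csv", index=False)
    return path


def write_tornado(tornado: TornadoTable, outdir: str | Path) -> Path:
    """Write one tornado table as CSV (full precision)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    band_slug = (
        tornado.age_band.value.replace("<", "lt").replace(">", "gt").replace("-", "_")
    )
    path = outdir / f"tornado_{tornado.outcome}_{band_slug}.csv"
    tornado.table.to_csv(path, index=False)
    return path
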