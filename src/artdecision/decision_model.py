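"""Closed-form evaluation of the treatment decision tree.

Two strategies are compared for couples with unexplained infertility:

* **SOC** — up to ``n_iui`` IUI cycles, then up to ``n_ivf`` IVF-ICSI cycles.
* **CS-TI** — a capacitation-score test first: a low score routes the couple
  straight to the IVF-ICSI sequence; a normal score routes to ``n_iui`` timed
  IUI cycles (age-independent per-cycle probability) followed by the IVF-ICSI
  sequence.

Per-cycle conception probabilities are constant across repeated cycles and
cycles are independent, so every outcome below has a capped-geometric closed
form.  Live birth is conditional on clinical pregnancy, with the conditional
probability determined by the conceiving modality (timed IUI uses the IUI
live-birth probability).  Costs are unit cost times expected cycles; the
score test itself carries no cost.
"""

from __future__ import annotations

import dataclasses
import enum

import pandas as pd

from .parameters import AGE_BANDS, AgeBand, ParameterDraw, ParameterSet

__all__ = [
    "Strategy",
    "StrategyOutcome",
    "ComparisonRow",
    "strategy_outcome",
    "cumulative_pregnancy",
    "modality_split",
    "cumulative_live_birth",
    "expected_cycle_counts",
    "costs",
    "evaluate",
    "baseline_tables",
]


class Strategy(str, enum.Enum):
    SOC = "SOC"
    CS_TI = "CS-TI"

    @classmethod
    def coerce(cls, value: "Strategy | str") -> "Strategy":
        if isinstance(value, cls):
            return value
        label = str(value).strip().upper().replace("_", "-")
        for s in cls:
            if s.value == label:
                return s
        raise ValueError(f"unknown strategy {value!r}; expected 'SOC' or 'CS-TI'")


def _fail(p: float, n: int) -> float:
    """Probability of failing all n independent cycles at per-cycle p."""
    return (1.0 - p) ** n


def _expected_attempts(p: float, n: int) -> float:
    """Expected cycles used, stopping at first success or at the cap n.

    Equals sum_{k=0}^{n-1} (1-p)^k.
    """
    if p == 0.0:
        return float(n)
    return (1.0 - _fail(p, n)) / p


@dataclasses.dataclass(frozen=True)
class StrategyOutcome:
    """All closed-form outcomes for one strategy and age band."""

    strategy: Strategy
    age_band: AgeBand
    cum_pregnancy: float
    cum_live_birth: float
    preg_via_iui: float
    preg_via_tiui: float
    preg_via_ivf: float
    e_iui_cycles: float
    e_ivf_cycles: float
    cost_iui: float
    cost_ivf: float
    cost_total: float


@dataclasses.dataclass(frozen=True)
class ComparisonRow:
    """Both strategies for one age band plus CS-TI minus SOC deltas."""

    age_band: AgeBand
    soc: StrategyOutcome
    cs_ti: StrategyOutcome
    d_pregnancy: float
    d_live_birth: float
    d_cost_iui: float
    d_cost_ivf: float
    d_cost_total: float


def strategy_outcome(
    strategy: Strategy | str, draw: ParameterDraw, age: AgeBand | str
) -> StrategyOutcome:
    """Evaluate the full tree for one strategy and age band."""
    strategy = Strategy.coerce(strategy)
    band = AgeBand.coerce(age)
    p_ivf = draw.p_ivf[band]
    n_iui, n_ivf = draw.n_iui, draw.n_ivf

    if strategy is Strategy.SOC:
        p_first = draw.p_iui[band]
        via_iui = 1.0 - _fail(p_first, n_iui)
        via_tiui = 0.0
        reach_ivf = _fail(p_first, n_iui)
        e_iui = _expected_attempts(p_first, n_iui)
    else:
        q_normal = 1.0 - draw.p_low_cs
        via_iui = 0.0
        via_tiui = q_normal * (1.0 - _fail(draw.p_tiui, n_iui))
        reach_ivf = draw.p_low_cs + q_normal * _fail(draw.p_tiui, n_iui)
        e_iui = q_normal * _expected_attempts(draw.p_tiui, n_iui)

    via_ivf = reach_ivf * (1.0 - _fail(p_ivf, n_ivf))
    e_ivf = reach_ivf * _expected_attempts(p_ivf, n_ivf)

    cum_preg = via_iui + via_tiui + via_ivf
    cum_lb = (via_iui + via_tiui) * draw.l_iui[band] + via_ivf * draw.l_ivf[band]
    cost_iui = draw.c_iui * e_iui
    cost_ivf = draw.c_ivf * e_ivf

    return StrategyOutcome(
        strategy=strategy,
        age_band=band,
        cum_pregnancy=cum_preg,
        cum_live_birth=cum_lb,
        preg_via_iui=via_iui,
        preg_via_tiui=via_tiui,
        preg_via_ivf=via_ivf,
        e_iui_cycles=e_iui,
        e_ivf_cycles=e_ivf,
        cost_iui=cost_iui,
        cost_ivf=cost_ivf,
        cost_total=cost_iui + cost_ivf,
    )


def cumulative_pregnancy(
    strategy: Strategy | str, draw: ParameterDraw, age: AgeBand | str
) -> float:
    """Probability of a clinical pregnancy within the full cycle sequence."""
    return strategy_outcome(strategy, draw, age).cum_pregnancy


def modality_split(
    strategy: Strategy | str, draw: ParameterDraw, age: AgeBand | str
) -> tuple[float, float, float]:
    """Probability of conceiving via (IUI, timed IUI, IVF); sums to the cumulative rate."""
    out = strategy_outcome(strategy, draw, age)
    return out.preg_via_iui, out.preg_via_tiui, out.preg_via_ivf


def cumulative_live_birth(
    strategy: Strategy | str, draw: ParameterDraw, age: AgeBand | str
) -> float:
    """Probability of a live birth: modality split weighted by conditional rates."""
    return strategy_outcome(strategy, draw, age).cum_live_birth


def expected_cycle_counts(
    strategy: Strategy | str, draw: ParameterDraw, age: AgeBand | str
) -> tuple[float, float]:
    """Expected (IUI cycles, IVF cycles) used per couple."""
    out = strategy_outcome(strategy, draw, age)
    return out.e_iui_cycles, out.e_ivf_cycles


def costs(
    strategy: Strategy | str, draw: ParameterDraw, age: AgeBand | str
) -> StrategyOutcome:
    """Outcome with cost fields populated (unit cost times expected cycles)."""
    return strategy_outcome(strategy, draw, age)


def evaluate(draw: ParameterDraw, age: AgeBand | str) -> ComparisonRow:
    """Both strategies for one age band plus all CS-TI minus SOC deltas."""
    band = AgeBand.coerce(age)
    soc = strategy_outcome(Strategy.SOC, draw, band)
    cs = strategy_outcome(Strategy.CS_TI, draw, band)
    return ComparisonRow(
        age_band=band,
        soc=soc,
        cs_ti=cs,
        d_pregnancy=cs.cum_pregnancy - soc.cum_pregnancy,
        d_live_birth=cs.cum_live_birth - soc.cum_live_birth,
        d_cost_iui=cs.cost_iui - soc.cost_iui,
        d_cost_ivf=cs.cost_ivf - soc.cost_ivf,
        d_cost_total=cs.cost_total - soc.cost_total,
    )


def baseline_tables(params: ParameterSet) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Full-precision baseline outcome tables (rates, costs), one row per band.

    The first frame carries cumulative pregnancy and live-birth rates per
    strategy with deltas; the second carries IUI/IVF/total costs per strategy
    with deltas.  Formatting to printed precision is the report layer's job.
    """
    draw = params.baseline_draw()
    rate_rows, cost_rows = [], []
    for band in AGE_BANDS:
        row = evaluate(draw, band)
        rate_rows.append(
            {
                "age_band": band.value,
                "soc_pregnancy": row.soc.cum_pregnancy,
                "cs_ti_pregnancy": row.cs_ti.cum_pregnancy,
                "delta_pregnancy": row.d_pregnancy,
                "soc_live_birth": row.soc.cum_live_birth,
                "cs_ti_live_birth": row.cs_ti.cum_live_birth,
                "delta_live_birth": row.d_live_birth,
            }
        )
        cost_rows.append(
            {
                "age_band": band.value,
                "soc_iui_cost": row.soc.cost_iui,
                "cs_ti_iui_cost": row.cs_ti.cost_iui,
                "delta_iui_cost": row.d_cost_iui,
                "soc_ivf_cost": row.soc.cost_ivf,
                "cs_ti_ivf_cost": row.cs_ti.cost_ivf,
                "delta_ivf_cost": row.d_cost_ivf,
                "soc_total_cost": row.soc.cost_total,
                "cs_ti_total_cost": row.cs_ti.cost_total,
                "delta_total_cost": row.d_cost_total,
            }
        )
    return pd.DataFrame(rate_rows), pd.DataFrame(cost_rows)
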