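"""One-way (univariate) sensitivity analysis and tornado tables.

Each uncertain parameter is pushed to its low and high endpoint with all
other parameters held at baseline; the outcome swing (absolute difference)
ranks influence.  For an age-banded outcome only that band's own banded
parameters are varied, alongside the scalar parameters.
"""

from __future__ import annotations

import dataclasses
from typing import Callable, Iterable, Mapping

import pandas as pd

from .decision_model import ComparisonRow, evaluate
from .parameters import AGE_BANDS, AgeBand, ParameterSet

__all__ = ["TornadoTable", "OUTCOMES", "run_owsa", "most_influential", "top_parameter_counts"]

# Outcome id -> extractor from a ComparisonRow.  Deltas are CS-TI minus SOC.
OUTCOMES: dict[str, Callable[[ComparisonRow], float]] = {
    "pregnancy_delta": lambda r: r.d_pregnancy,
    "live_birth_delta": lambda r: r.d_live_birth,
    "iui_cost_delta": lambda r: r.d_cost_iui,
    "ivf_cost_delta": lambda r: r.d_cost_ivf,
    "total_cost_delta": lambda r: r.d_cost_total,
    "soc_pregnancy": lambda r: r.soc.cum_pregnancy,
    "soc_live_birth": lambda r: r.soc.cum_live_birth,
    "soc_iui_cost": lambda r: r.soc.cost_iui,
    "soc_ivf_cost": lambda r: r.soc.cost_ivf,
    "soc_total_cost": lambda r: r.soc.cost_total,
    "cs_ti_pregnancy": lambda r: r.cs_ti.cum_pregnancy,
    "cs_ti_live_birth": lambda r: r.cs_ti.cum_live_birth,
    "cs_ti_iui_cost": lambda r: r.cs_ti.cost_iui,
    "cs_ti_ivf_cost": lambda r: r.cs_ti.cost_ivf,
    "cs_ti_total_cost": lambda r: r.cs_ti.cost_total,
}

DELTA_OUTCOMES = (
    "pregnancy_delta",
    "live_birth_delta",
    "iui_cost_delta",
    "ivf_cost_delta",
    "total_cost_delta",
)


@dataclasses.dataclass(frozen=True)
class TornadoTable:
    """Per-parameter outcome swings for one outcome and age band.

    ``table`` has columns ``param``, ``at_low``, ``at_high``, ``influence``
    and is sorted by influence descending, ties broken by canonical parameter
    order (so a degenerate all-zero tornado keeps table order).
    """

    outcome: str
    age_band: AgeBand
    table: pd.DataFrame

    @property
    def degenerate(self) -> bool:
        """True when no parameter moves the outcome at all."""
        return bool((self.table["influence"] == 0).all())


def _varied_keys(param_set: ParameterSet, band: AgeBand) -> list[str]:
    """Uncertain keys relevant to one band: scalars plus that band's own rows."""
    keys = []
    for key in param_set.uncertain_keys():
        if "/" in key:
            _, label = key.split("/", 1)
            if label != band.value:
                continue
        keys.append(key)
    return keys


def run_owsa(param_set: ParameterSet, outcome: str, age: AgeBand | str) -> TornadoTable:
    """Evaluate ``outcome`` at each parameter's range endpoints, rank by swing."""
    if outcome not in OUTCOMES:
        raise ValueError(
            f"unknown outcome {outcome!r}; expected one of {sorted(OUTCOMES)}"
        )
    band = AgeBand.coerce(age)
    extract = OUTCOMES[outcome]
    rows = []
    for key in _varied_keys(param_set, band):
        est = param_set[key]
        at_low = extract(evaluate(param_set.draw_with({key: est.low}), band))
        at_high = extract(evaluate(param_set.draw_with({key: est.high}), band))
        rows.append(
            {
                "param": key,
                "at_low": at_low,
                "at_high": at_high,
                "influence": abs(at_high - at_low),
            }
        )
    table = pd.DataFrame(rows)
    table = table.sort_values("influence", ascending=False, kind="stable").reset_index(
        drop=True
    )
    return TornadoTable(outcome=outcome, age_band=band, table=table)


def most_influential(tornado: TornadoTable) -> str:
    """Top-ranked parameter; with an all-tied table this is the first in canonical order."""
    if len(tornado.table) == 0:
        raise ValueError("empty tornado table")
    return str(tornado.table.iloc[0]["param"])


def top_parameter_counts(
    param_set: ParameterSet,
    outcomes: Iterable[str] = DELTA_OUTCOMES,
    bands: Iterable[AgeBand | str] = AGE_BANDS,
) -> Mapping[str, int]:
    """Across an outcome x age grid, count how often each parameter ranks first.

    The grid is configurable; banded parameter keys are collapsed to their id
    (e.g. ``p_iui/<35`` counts as ``p_iui``) so age-specific winners aggregate.
    """
    counts: dict[str, int] = {}
    for outcome in outcomes:
        for band in bands:
            winner = most_influential(run_owsa(param_set, outcome, band))
            pid = winner.split("/", 1)[0]
            counts[pid] = counts.get(pid, 0) + 1
    return counts
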