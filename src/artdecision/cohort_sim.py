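"""Patient-level microsimulation of the treatment tree (brute-force oracle).

Each simulated couple consumes a fixed-length block of uniforms in a
documented order — score-test draw, one draw per potential IUI cycle, one per
potential IVF cycle, live-birth draw — regardless of strategy or early
success.  Unused draws are burned.  This makes trajectories replayable and
makes the vectorized cohort simulation bit-identical to aggregating
:func:`simulate_couple` over the same generator.
"""

from __future__ import annotations

import csv
import dataclasses
import math
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .decision_model import Strategy
from .parameters import AgeBand, ParameterDraw

__all__ = [
    "CoupleTrajectory",
    "EmpiricalOutcome",
    "draws_per_couple",
    "simulate_couple",
    "simulate_cohort",
    "write_trajectories",
]


@dataclasses.dataclass(frozen=True)
class CoupleTrajectory:
    strategy: Strategy
    age_band: AgeBand
    cap_score_low: bool | None  # None under SOC (test not performed)
    iui_cycles: int
    ivf_cycles: int
    conceived: bool
    modality: str | None  # 'iui' | 'tiui' | 'ivf' | None
    live_birth: bool
    cost_iui: float
    cost_ivf: float
    cost_accrued: float


@dataclasses.dataclass(frozen=True)
class EmpiricalOutcome:
    """Cohort aggregate with standard errors (binomial for rates, sample SE for means)."""

    n_couples: int
    preg_rate: float
    live_birth_rate: float
    preg_via_iui: float
    preg_via_tiui: float
    preg_via_ivf: float
    mean_iui_cycles: float
    mean_ivf_cycles: float
    mean_cost_iui: float
    mean_cost_ivf: float
    mean_cost_total: float
    se_preg: float
    se_live_birth: float
    se_iui_cycles: float
    se_ivf_cycles: float
    se_cost_total: float


def draws_per_couple(draw: ParameterDraw) -> int:
    """Uniforms consumed per couple: score test + every potential cycle + live birth."""
    return 2 + draw.n_iui + draw.n_ivf


def _first_success(u: Sequence[float], p: float) -> tuple[bool, int]:
    """(conceived, cycles attempted) for a capped Bernoulli cycle sequence."""
    for k, uk in enumerate(u):
        if uk < p:
            return True, k + 1
    return False, len(u)


def simulate_couple(
    strategy: Strategy | str,
    draw: ParameterDraw,
    age: AgeBand | str,
    rng: np.random.Generator,
) -> CoupleTrajectory:
    """Simulate one couple; consumes exactly :func:`draws_per_couple` uniforms."""
    strategy = Strategy.coerce(strategy)
    band = AgeBand.coerce(age)
    n_iui, n_ivf = draw.n_iui, draw.n_ivf
    u = rng.random(2 + n_iui + n_ivf)
    u_cap = u[0]
    u_iui = u[1 : 1 + n_iui]
    u_ivf = u[1 + n_iui : 1 + n_iui + n_ivf]
    u_lb = u[-1]

    if strategy is Strategy.SOC:
        cap_low: bool | None = None
        do_iui, p_insem, insem_modality = True, draw.p_iui[band], "iui"
    else:
        cap_low = bool(u_cap < draw.p_low_cs)
        do_iui, p_insem, insem_modality = not cap_low, draw.p_tiui, "tiui"

    iui_cycles = 0
    conceived = False
    modality: str | None = None
    if do_iui and n_iui > 0:
        conceived, iui_cycles = _first_success(u_iui, p_insem)
        if conceived:
            modality = insem_modality

    ivf_cycles = 0
    if not conceived and n_ivf > 0:
        conceived, ivf_cycles = _first_success(u_ivf, draw.p_ivf[band])
        if conceived:
            modality = "ivf"
    elif not conceived:
        ivf_cycles = 0

    if conceived:
        l_cond = draw.l_ivf[band] if modality == "ivf" else draw.l_iui[band]
        live_birth = bool(u_lb < l_cond)
    else:
        live_birth = False

    cost_iui = draw.c_iui * iui_cycles
    cost_ivf = draw.c_ivf * ivf_cycles
    return CoupleTrajectory(
        strategy=strategy,
        age_band=band,
        cap_score_low=cap_low,
        iui_cycles=iui_cycles,
        ivf_cycles=ivf_cycles,
        conceived=conceived,
        modality=modality,
        live_birth=live_birth,
        cost_iui=cost_iui,
        cost_ivf=cost_ivf,
        cost_accrued=cost_iui + cost_ivf,
    )


def _capped_cycles(u: np.ndarray, p: float | np.ndarray, active: np.ndarray):
    """Vectorized capped Bernoulli sequence over the columns of ``u``.

    Returns (conceived, cycles) arrays; inactive rows get (False, 0).
    """
    n, n_cycles = u.shape
    if n_cycles == 0:
        return np.zeros(n, bool), np.zeros(n, np.int64)
    success = u < p
    any_success = success.any(axis=1)
    first = np.argmax(success, axis=1)  # 0 when no success; masked below
    cycles = np.where(any_success, first + 1, n_cycles)
    conceived = active & any_success
    cycles = np.where(active, cycles, 0)
    return conceived, cycles


def simulate_cohort(
    n: int,
    strategy: Strategy | str,
    draw: ParameterDraw,
    age: AgeBand | str,
    seed: int | np.random.Generator | None = None,
) -> EmpiricalOutcome:
    """Aggregate ``n`` independent couple trajectories (vectorized, seeded).

    Consumes the same uniform stream, in the same order, as ``n`` successive
    calls to :func:`simulate_couple` on a generator seeded identically.
    """
    if n < 1:
        raise ValueError(f"cohort size must be >= 1, got {n}")
    strategy = Strategy.coerce(strategy)
    band = AgeBand.coerce(age)
    rng = np.random.default_rng(seed)
    n_iui, n_ivf = draw.n_iui, draw.n_ivf

    u = rng.random((n, 2 + n_iui + n_ivf))
    u_cap = u[:, 0]
    u_iui = u[:, 1 : 1 + n_iui]
    u_ivf = u[:, 1 + n_iui : 1 + n_iui + n_ivf]
    u_lb = u[:, -1]

    if strategy is Strategy.SOC:
        active_iui = np.ones(n, bool)
        p_insem = draw.p_iui[band]
        tiui = False
    else:
        cap_low = u_cap < draw.p_low_cs
        active_iui = ~cap_low
        p_insem = draw.p_tiui
        tiui = True

    conceived_insem, iui_cycles = _capped_cycles(u_iui, p_insem, active_iui)
    conceived_ivf, ivf_cycles = _capped_cycles(u_ivf, draw.p_ivf[band], ~conceived_insem)
    conceived = conceived_insem | conceived_ivf

    l_cond = np.where(conceived_ivf, draw.l_ivf[band], draw.l_iui[band])
    live = conceived & (u_lb < l_cond)

    cost_iui = draw.c_iui * iui_cycles
    cost_ivf = draw.c_ivf * ivf_cycles
    cost_total = cost_iui + cost_ivf

    def rate_se(p: float) -> float:
        return math.sqrt(p * (1.0 - p) / n)

    def mean_se(x: np.ndarray) -> float:
        if n < 2:
            return 0.0
        return float(x.std(ddof=1) / math.sqrt(n))

    preg = float(conceived.mean())
    lb = float(live.mean())
    return EmpiricalOutcome(
        n_couples=n,
        preg_rate=preg,
        live_birth_rate=lb,
        preg_via_iui=0.0 if tiui else float(conceived_insem.mean()),
        preg_via_tiui=float(conceived_insem.mean()) if tiui else 0.0,
        preg_via_ivf=float(conceived_ivf.mean()),
        mean_iui_cycles=float(iui_cycles.mean()),
        mean_ivf_cycles=float(ivf_cycles.mean()),
        mean_cost_iui=float(cost_iui.mean()),
        mean_cost_ivf=float(cost_ivf.mean()),
        mean_cost_total=float(cost_total.mean()),
        se_preg=rate_se(preg),
        se_live_birth=rate_se(lb),
        se_iui_cycles=mean_se(iui_cycles.astype(float)),
        se_ivf_cycles=mean_se(ivf_cycles.astype(float)),
        se_cost_total=mean_se(cost_total.astype(float)),
    )


def write_trajectories(path: str | Path, trajectories: Iterable[CoupleTrajectory]) -> None:
    """Dump trajectories as CSV for inspection or fixtures."""
    fields = [f.name for f in dataclasses.fields(CoupleTrajectory)]
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(fields)
        for t in trajectories:
            row = dataclasses.asdict(t)
            row["strategy"] = t.strategy.value
            row["age_band"] = t.age_band.value
            writer.writerow([row[f] for f in fields])
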