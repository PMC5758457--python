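"""Probabilistic sensitivity analysis: parameter-level Monte Carlo.

Every uncertain parameter is sampled independently from its fitted
distribution (beta for probabilities, zero-truncated normal for costs), the
closed-form tree is evaluated on each draw, and outcomes are summarized with
Monte Carlo means and percentile 95% credibility intervals.  For nonlinear
outcomes the Monte Carlo mean need not equal the baseline evaluation, so the
summary reports both, labeled.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .decision_model import evaluate
from .parameters import AGE_BANDS, ParameterDraw, ParameterSet

__all__ = ["PSAResult", "sample_draw", "run_psa", "OUTCOME_FIELDS"]

# Outcome ids -> how to pull (soc, cs_ti, delta) from a ComparisonRow.
OUTCOME_FIELDS = {
    "pregnancy": ("cum_pregnancy", "d_pregnancy"),
    "live_birth": ("cum_live_birth", "d_live_birth"),
    "iui_cost": ("cost_iui", "d_cost_iui"),
    "ivf_cost": ("cost_ivf", "d_cost_ivf"),
    "total_cost": ("cost_total", "d_cost_total"),
}
SERIES = ("soc", "cs_ti", "delta")


def _column(outcome: str, series: str, band_label: str) -> str:
    return f"{outcome}|{series}|{band_label}"


@dataclasses.dataclass(frozen=True)
class PSAResult:
    """Monte Carlo summary plus the per-draw outcome matrix kept for audit."""

    n_draws: int
    seed: int | None
    draws: pd.DataFrame  # n_draws x (outcome|series|band) matrix
    summary: pd.DataFrame  # long: outcome, series, age_band, mean, lo, hi, baseline

    def interval(self, outcome: str, series: str, band_label: str) -> tuple[float, float]:
        row = self.summary[
            (self.summary.outcome == outcome)
            & (self.summary.series == series)
            & (self.summary.age_band == band_label)
        ]
        rec = row.iloc[0]
        return float(rec["lo"]), float(rec["hi"])


def sample_draw(param_set: ParameterSet, rng: np.random.Generator) -> ParameterDraw:
    """One independent joint sample of every uncertain parameter.

    Parameters are sampled in canonical table order, so the draw sequence is
    deterministic given the generator state.
    """
    specs = param_set.fitted_distributions()
    values = {key: float(specs[key].sample(rng)) for key in param_set.uncertain_keys()}
    return param_set.draw_with(values)


def _sample_matrix(
    param_set: ParameterSet, n_draws: int, rng: np.random.Generator
) -> dict[str, np.ndarray]:
    specs = param_set.fitted_distributions()
    return {
        key: np.asarray(specs[key].sample(rng, n_draws), dtype=float)
        for key in param_set.uncertain_keys()
    }


def run_psa(param_set: ParameterSet, n_draws: int, seed: int | None) -> PSAResult:
    """Run the Monte Carlo: sample, evaluate, summarize.

    Sampling is vectorized per parameter (canonical order) for speed; draw
    ``i`` of the resulting joint sample is identical in distribution to
    repeated :func:`sample_draw` calls.
    """
    if n_draws < 2:
        raise ValueError(f"n_draws must be >= 2, got {n_draws}")
    rng = np.random.default_rng(seed)
    samples = _sample_matrix(param_set, n_draws, rng)
    keys = param_set.uncertain_keys()

    columns = [
        _column(outcome, series, band.value)
        for outcome in OUTCOME_FIELDS
        for series in SERIES
        for band in AGE_BANDS
    ]
    matrix = np.empty((n_draws, len(columns)))
    col_index = {c: j for j, c in enumerate(columns)}

    for i in range(n_draws):
        draw = param_set.draw_with({k: samples[k][i] for k in keys})
        for band in AGE_BANDS:
            row = evaluate(draw, band)
            for outcome, (field, dfield) in OUTCOME_FIELDS.items():
                matrix[i, col_index[_column(outcome, "soc", band.value)]] = getattr(
                    row.soc, field
                )
                matrix[i, col_index[_column(outcome, "cs_ti", band.value)]] = getattr(
                    row.cs_ti, field
                )
                matrix[i, col_index[_column(outcome, "delta", band.value)]] = getattr(
                    row, dfield
                )

    draws_df = pd.DataFrame(matrix, columns=columns)

    base_draw = param_set.baseline_draw()
    base_rows = {band: evaluate(base_draw, band) for band in AGE_BANDS}
    records = []
    lo_q, hi_q = np.percentile(matrix, [2.5, 97.5], axis=0)
    means = matrix.mean(axis=0)
    # constant columns (point-mass parameters) must summarize exactly
    const = matrix.max(axis=0) == matrix.min(axis=0)
    means[const] = matrix[0, const]
    lo_q[const] = matrix[0, const]
    hi_q[const] = matrix[0, const]
    for outcome, (field, dfield) in OUTCOME_FIELDS.items():
        for series in SERIES:
            for band in AGE_BANDS:
                j = col_index[_column(outcome, series, band.value)]
                base_row = base_rows[band]
                if series == "soc":
                    baseline = getattr(base_row.soc, field)
                elif series == "cs_ti":
                    baseline = getattr(base_row.cs_ti, field)
                else:
                    baseline = getattr(base_row, dfield)
                records.append(
                    {
                        "outcome": outcome,
                        "series": series,
                        "age_band": band.value,
                        "mean": means[j],
                        "lo": lo_q[j],
                        "hi": hi_q[j],
                        "baseline": baseline,
                    }
                )
    summary = pd.DataFrame.from_records(records)
    return PSAResult(n_draws=n_draws, seed=seed, draws=draws_df, summary=summary)
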