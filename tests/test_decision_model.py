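import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from artdecision import (
    AGE_BANDS,
    AgeBand,
    ParameterDraw,
    Strategy,
    baseline_tables,
    costs,
    cumulative_live_birth,
    cumulative_pregnancy,
    evaluate,
    expected_cycle_counts,
    modality_split,
    strategy_outcome,
)

from _oracle import enumerate_expectations
from _printed import COST_CELLS, RATE_CELLS

BAND_UNDER_35 = AgeBand.UNDER_35


def random_draw(rng: np.random.Generator) -> ParameterDraw:
    def banded():
        return {b: float(rng.uniform(0.01, 0.99)) for b in AGE_BANDS}

    return ParameterDraw(
        c_iui=float(rng.uniform(0, 10_000)),
        c_ivf=float(rng.uniform(0, 50_000)),
        p_low_cs=float(rng.uniform(0, 1)),
        p_tiui=float(rng.uniform(0.01, 0.99)),
        p_iui=banded(),
        p_ivf=banded(),
        l_iui=banded(),
        l_ivf=banded(),
    )


class TestAgainstEnumerationOracle:
    """Closed forms vs exhaustive path enumeration (independent oracle)."""

    @pytest.mark.parametrize("strategy", list(Strategy))
    @pytest.mark.parametrize("band", list(AGE_BANDS))
    def test_baseline_all_cells(self, baseline_draw, strategy, band):
        got = strategy_outcome(strategy, baseline_draw, band)
        exp = enumerate_expectations(strategy, baseline_draw, band)
        assert got.cum_pregnancy == pytest.approx(exp["preg"], abs=1e-12)
        assert got.cum_live_birth == pytest.approx(exp["live_birth"], abs=1e-12)
        assert got.preg_via_iui == pytest.approx(exp["via_iui"], abs=1e-12)
        assert got.preg_via_tiui == pytest.approx(exp["via_tiui"], abs=1e-12)
        assert got.preg_via_ivf == pytest.approx(exp["via_ivf"], abs=1e-12)
        assert got.e_iui_cycles == pytest.approx(exp["e_iui_cycles"], abs=1e-12)
        assert got.e_ivf_cycles == pytest.approx(exp["e_ivf_cycles"], abs=1e-12)
        assert got.cost_iui == pytest.approx(exp["cost_iui"], rel=1e-12)
        assert got.cost_ivf == pytest.approx(exp["cost_ivf"], rel=1e-12)

    def test_random_draws(self):
        rng = np.random.default_rng(99)
        for _ in range(25):
            draw = random_draw(rng)
            for strategy in Strategy:
                band = AGE_BANDS[int(rng.integers(5))]
                got = strategy_outcome(strategy, draw, band)
                exp = enumerate_expectations(strategy, draw, band)
                assert got.cum_pregnancy == pytest.approx(exp["preg"], abs=1e-12)
                assert got.cum_live_birth == pytest.approx(exp["live_birth"], abs=1e-12)
                assert got.e_iui_cycles == pytest.approx(exp["e_iui_cycles"], abs=1e-12)
                assert got.e_ivf_cycles == pytest.approx(exp["e_ivf_cycles"], abs=1e-12)


class TestPublishedBaselineCells:
    def test_soc_pregnancy_under_35(self, baseline_draw):
        assert 100 * cumulative_pregnancy("SOC", baseline_draw, "<35") == pytest.approx(
            92.88, abs=0.01
        )

    def test_cs_ti_pregnancy_under_35(self, baseline_draw):
        assert 100 * cumulative_pregnancy("CS-TI", baseline_draw, "<35") == pytest.approx(
            94.22, abs=0.01
        )

    def test_live_birth_under_35(self, baseline_draw):
        assert 100 * cumulative_live_birth("SOC", baseline_draw, "<35") == pytest.approx(
            68.54, abs=0.01
        )
        assert 100 * cumulative_live_birth("CS-TI", baseline_draw, "<35") == pytest.approx(
            66.16, abs=0.01
        )

    def test_costs_under_35(self, baseline_draw):
        assert costs("SOC", baseline_draw, "<35").cost_iui == pytest.approx(6484, abs=1)
        assert costs("CS-TI", baseline_draw, "<35").cost_ivf == pytest.approx(14708, abs=1)

    def test_deltas_under_35(self, baseline_draw):
        row = evaluate(baseline_draw, "<35")
        assert 100 * row.d_pregnancy == pytest.approx(1.34, abs=0.01)
        assert row.d_cost_ivf == pytest.approx(-3410, abs=1)

    def test_baseline_tables_against_all_printed_cells(self, params):
        rates, cost = baseline_tables(params)
        rates = rates.set_index("age_band")
        cost = cost.set_index("age_band")
        for (col, band), expected in RATE_CELLS.items():
            assert 100 * rates.loc[band, col] == pytest.approx(expected, abs=0.01), (col, band)
        for (col, band), expected in COST_CELLS.items():
            assert cost.loc[band, col] == pytest.approx(expected, abs=1), (col, band)


class TestDerivedValues:
    """Values frozen from the enumeration/simulation oracle (not published)."""

    def test_modality_split_soc_under_35(self, baseline_draw):
        via_iui, via_tiui, via_ivf = modality_split("SOC", baseline_draw, "<35")
        assert via_iui == pytest.approx(0.40944, abs=1e-4)
        assert via_tiui == 0.0
        assert via_ivf == pytest.approx(0.51937, abs=1e-4)

    def test_expected_cycles_soc_under_35(self, baseline_draw):
        e_iui, e_ivf = expected_cycle_counts("SOC", baseline_draw, "<35")
        assert e_iui == pytest.approx(2.5429, abs=1e-4)
        assert e_ivf == pytest.approx(1.0265, abs=1e-4)


class TestTrivialCases:
    def _zero_preg(self, baseline_draw):
        zero = {b: 0.0 for b in AGE_BANDS}
        return dataclasses.replace(
            baseline_draw, p_tiui=0.0, p_low_cs=0.0, p_iui=zero, p_ivf=zero
        )

    @pytest.mark.parametrize("strategy", list(Strategy))
    def test_no_conception_possible(self, baseline_draw, strategy):
        draw = self._zero_preg(baseline_draw)
        assert cumulative_pregnancy(strategy, draw, "<35") == 0.0
        # every cycle consumed: 3 IUI + 3 IVF
        out = costs(Strategy.SOC, draw, "<35")
        assert out.cost_total == pytest.approx(3 * draw.c_iui + 3 * draw.c_ivf, rel=1e-12)

    def test_iui_only_geometric(self, baseline_draw):
        draw = dataclasses.replace(baseline_draw, p_ivf={b: 0.0 for b in AGE_BANDS})
        assert cumulative_pregnancy("SOC", draw, "<35") == pytest.approx(
            1 - 0.839**3, abs=1e-12
        )

    def test_certain_live_birth_equals_pregnancy(self, baseline_draw):
        ones = {b: 1.0 for b in AGE_BANDS}
        draw = dataclasses.replace(baseline_draw, l_iui=ones, l_ivf=ones)
        for strategy in Strategy:
            assert cumulative_live_birth(strategy, draw, "38-40") == pytest.approx(
                cumulative_pregnancy(strategy, draw, "38-40"), abs=1e-15
            )

    def test_all_low_scores_route_to_ivf(self, baseline_draw):
        draw = dataclasses.replace(baseline_draw, p_low_cs=1.0)
        via_iui, via_tiui, _ = modality_split("CS-TI", draw, "<35")
        assert via_iui == 0.0 and via_tiui == 0.0
        e_iui, _ = expected_cycle_counts("CS-TI", draw, "<35")
        assert e_iui == 0.0

    def test_first_cycle_success(self, baseline_draw):
        ones = {b: 1.0 for b in AGE_BANDS}
        draw = dataclasses.replace(
            baseline_draw, p_iui=ones, p_ivf=ones, p_tiui=1.0
        )
        e_iui, e_ivf = expected_cycle_counts("SOC", draw, "<35")
        assert (e_iui, e_ivf) == (1.0, 0.0)

    def test_coincident_strategies_zero_deltas(self, baseline_draw):
        draw = dataclasses.replace(
            baseline_draw, p_low_cs=0.0, p_tiui=baseline_draw.p_iui[BAND_UNDER_35]
        )
        row = evaluate(draw, "<35")
        for delta in (row.d_pregnancy, row.d_live_birth, row.d_cost_iui,
                      row.d_cost_ivf, row.d_cost_total):
            assert delta == pytest.approx(0.0, abs=1e-12)

    def test_unknown_age_band_errors(self, baseline_draw):
        with pytest.raises(ValueError, match="age band"):
            cumulative_pregnancy("SOC", baseline_draw, "95+")

    def test_unknown_strategy_errors(self, baseline_draw):
        with pytest.raises(ValueError, match="strategy"):
            cumulative_pregnancy("SOX", baseline_draw, "<35")


class TestInvariants:
    def test_conservation_over_random_draws(self):
        rng = np.random.default_rng(7)
        for _ in range(1000):
            draw = random_draw(rng)
            band = AGE_BANDS[int(rng.integers(5))]
            for strategy in Strategy:
                out = strategy_outcome(strategy, draw, band)
                split_sum = out.preg_via_iui + out.preg_via_tiui + out.preg_via_ivf
                assert abs(split_sum - out.cum_pregnancy) < 1e-12
                assert out.cum_live_birth <= out.cum_pregnancy + 1e-15
                assert out.cost_total == pytest.approx(
                    out.cost_iui + out.cost_ivf, rel=1e-9
                )
                assert 0 <= out.e_iui_cycles <= draw.n_iui
                assert 0 <= out.e_ivf_cycles <= draw.n_ivf

    @given(
        p_iui=st.floats(0, 1), p_ivf=st.floats(0, 1),
        p_tiui=st.floats(0, 1), p_low=st.floats(0, 1),
        l_iui=st.floats(0, 1), l_ivf=st.floats(0, 1),
    )
    @settings(max_examples=100, deadline=None)
    def test_conservation_property(self, p_iui, p_ivf, p_tiui, p_low, l_iui, l_ivf):
        draw = ParameterDraw(
            c_iui=2550, c_ivf=17651, p_low_cs=p_low, p_tiui=p_tiui,
            p_iui={b: p_iui for b in AGE_BANDS},
            p_ivf={b: p_ivf for b in AGE_BANDS},
            l_iui={b: l_iui for b in AGE_BANDS},
            l_ivf={b: l_ivf for b in AGE_BANDS},
        )
        for strategy in Strategy:
            out = strategy_outcome(strategy, draw, "<35")
            total = out.preg_via_iui + out.preg_via_tiui + out.preg_via_ivf
            assert abs(total - out.cum_pregnancy) < 1e-12
            assert 0.0 <= out.cum_pregnancy <= 1.0 + 1e-12

    def test_pregnancy_monotone_in_cycle_probabilities(self, baseline_draw):
        base = cumulative_pregnancy("SOC", baseline_draw, "38-40")
        for field in ("p_iui", "p_ivf"):
            bumped_map = dict(getattr(baseline_draw, field))
            bumped_map[AgeBand.AGE_38_40] = min(1.0, bumped_map[AgeBand.AGE_38_40] + 0.05)
            bumped = dataclasses.replace(baseline_draw, **{field: bumped_map})
            assert cumulative_pregnancy("SOC", bumped, "38-40") >= base

    def test_iui_cost_non_increasing_in_p_iui(self, baseline_draw):
        base_cost = costs("SOC", baseline_draw, "<35").cost_iui
        bumped_map = dict(baseline_draw.p_iui)
        bumped_map[BAND_UNDER_35] += 0.05
        bumped = dataclasses.replace(baseline_draw, p_iui=bumped_map)
        assert costs("SOC", bumped, "<35").cost_iui <= base_cost

    def test_cs_ti_dominates_pregnancy_at_baseline(self, baseline_draw):
        for band in AGE_BANDS:
            row = evaluate(baseline_draw, band)
            assert row.cs_ti.cum_pregnancy >= row.soc.cum_pregnancy

    def test_no_ivf_reduces_to_capped_geometric(self, baseline_draw):
        draw = dataclasses.replace(baseline_draw, n_ivf=0)
        for band in AGE_BANDS:
            p = baseline_draw.p_iui[band]
            assert cumulative_pregnancy("SOC", draw, band) == pytest.approx(
                1 - (1 - p) ** 3, abs=1e-12
            )
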