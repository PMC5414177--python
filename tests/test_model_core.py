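"""Single-cell engine: growth, CDK accumulation, triggers, division."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from samsizer.model_core import (Event, ModelParams, Phase, SizeDependence,
                                 advance_cell, cdk_production_rate,
                                 divide_cell, effective_threshold, grow_step,
                                 new_cell)

G = math.log(2.0) / 24.0


def run_to_division(cell, params):
    """Advance until the DIVIDED event; returns (cell, hours elapsed)."""
    for _ in range(100000):
        cell, event = advance_cell(cell, params)
        if event is Event.DIVIDED:
            return cell, cell.age
    raise AssertionError("no division")


class TestGrowStep:
    def test_doubles_over_doubling_time(self):
        assert grow_step(20.0, G, 24.0) == pytest.approx(40.0)

    def test_zero_growth_identity(self):
        assert grow_step(33.3, 0.0, 5.0) == 33.3

    def test_closed_form_value(self):
        # 30 * e^{0.05}, high-precision reference
        assert grow_step(30.0, 0.05, 1.0) == pytest.approx(
            31.53813289128072, rel=1e-12)

    @pytest.mark.parametrize("size,dt", [(-1.0, 1.0), (0.0, 1.0),
                                         (10.0, 0.0), (10.0, -2.0)])
    def test_invalid_inputs(self, size, dt):
        with pytest.raises(ValueError):
            grow_step(size, 0.03, dt)


class TestCdkProductionRate:
    def test_size_independent_mode(self):
        p = ModelParams(size_dependence=SizeDependence.NONE, pCDK=2.5)
        assert cdk_production_rate(7.0, p) == 2.5
        assert cdk_production_rate(700.0, p) == 2.5

    def test_proportional_mode_doubles_with_size(self):
        p = ModelParams(size_dependence=SizeDependence.PCDK_PROP_SIZE,
                        pCDK=2.0, size_ref=20.0)
        assert cdk_production_rate(40.0, p) == pytest.approx(
            2 * cdk_production_rate(20.0, p))

    def test_sublinear_exponent(self):
        p = ModelParams(size_dependence=SizeDependence.PCDK_PROP_SIZE,
                        pCDK=1.0, size_exponent=0.67, size_ref=20.0)
        ratio = cdk_production_rate(160.0, p) / cdk_production_rate(20.0, p)
        assert ratio == pytest.approx(8.0 ** 0.67, rel=1e-12)
        assert ratio == pytest.approx(4.03, rel=1e-2)

    def test_inverse_mode(self):
        p = ModelParams(size_dependence=SizeDependence.PCDK_INV_SIZE,
                        pCDK=3.0, size_ref=20.0)
        assert cdk_production_rate(40.0, p) == pytest.approx(1.5)

    def test_rejects_nonpositive_size_and_bad_selector(self):
        p = ModelParams()
        with pytest.raises(ValueError):
            cdk_production_rate(0.0, p)
        with pytest.raises(ValueError):
            cdk_production_rate(10.0, p, which="X")


class TestEffectiveThreshold:
    def test_plain_threshold(self):
        p = ModelParams(T_division=123.0)
        assert effective_threshold(5.0, p) == 123.0

    def test_inverse_dilution(self):
        p = ModelParams(size_dependence=SizeDependence.THRESHOLD_INV_SIZE,
                        T_division=100.0, size_ref=20.0)
        assert effective_threshold(20.0, p) == pytest.approx(100.0)
        assert effective_threshold(40.0, p) == pytest.approx(50.0)

    def test_proportional_variant(self):
        p = ModelParams(size_dependence=SizeDependence.THRESHOLD_PROP_SIZE,
                        T_division=100.0, size_ref=20.0)
        assert effective_threshold(40.0, p) == pytest.approx(200.0)


class TestAdvanceCell:
    def test_timer_divides_after_strict_threshold_plus_mitosis(self):
        # pCDK=1, T=24: 25 unit steps to strictly exceed 24, then one
        # mitosis step -> division at t = 26 h
        p = ModelParams(pCDK=1.0, T_division=24.0,
                        size_dependence=SizeDependence.NONE)
        cell = new_cell(20.0, p, g=G, d=50.0)
        cell, hours = run_to_division(cell, p)
        assert hours == pytest.approx(26.0)

    def test_zero_step_leaves_state_unchanged(self):
        p = ModelParams()
        cell = new_cell(20.0, p, g=G, d=50.0)
        out, event = advance_cell(cell, p, dt=0.0)
        assert event is Event.NONE
        assert out.size == cell.size and out.cdk == cell.cdk
        assert out.age == cell.age

    def test_input_state_not_mutated(self):
        p = ModelParams()
        cell = new_cell(20.0, p, g=G, d=50.0)
        advance_cell(cell, p)
        assert cell.age == 0.0 and cell.cdk == 0.0

    def test_growth_continues_cdk_frozen_during_mitosis(self):
        p = ModelParams(pCDK=10.0, T_division=5.0, mitosis_steps=3,
                        size_dependence=SizeDependence.NONE)
        cell = new_cell(20.0, p, g=G, d=50.0)
        cell, event = advance_cell(cell, p)
        assert event is Event.DIVISION_TRIGGERED
        cdk_at_trigger, size_at_trigger = cell.cdk, cell.size
        cell, event = advance_cell(cell, p)
        assert event is Event.NONE
        assert cell.cdk == cdk_at_trigger
        assert cell.size > size_at_trigger

    def test_two_transition_records_g1s_and_resets_accumulator(self):
        p = ModelParams(two_transition=True, pCDK_S=30.0, pCDK_M=30.0,
                        T_g1s=100.0, T_g2m=200.0,
                        size_dependence=SizeDependence.NONE)
        cell = new_cell(20.0, p, g=G, d=50.0)
        seen_g1s = False
        for _ in range(1000):
            cell, event = advance_cell(cell, p)
            if event is Event.G1S_TRANSITION:
                seen_g1s = True
                assert cell.phase is Phase.S_G2_M
                assert cell.cdk == 0.0
                assert cell.g1s_time == pytest.approx(cell.age)
                assert cell.g1s_size == pytest.approx(cell.size)
            if event is Event.DIVIDED:
                break
        assert seen_g1s and event is Event.DIVIDED

    @pytest.mark.parametrize("mode", [SizeDependence.NONE,
                                      SizeDependence.PCDK_PROP_SIZE,
                                      SizeDependence.THRESHOLD_INV_SIZE])
    def test_more_production_never_lengthens_interphase(self, mode):
        base = ModelParams(size_dependence=mode, pCDK=2.0, T_division=80.0)
        lengths = []
        for pcdk in (2.0, 2.5, 3.0, 4.0, 6.0):
            p = ModelParams(size_dependence=mode, pCDK=pcdk,
                            T_division=80.0)
            cell = new_cell(20.0, p, g=G, d=50.0)
            _, hours = run_to_division(cell, p)
            lengths.append(hours)
        assert lengths == sorted(lengths, reverse=True) or \
            all(a >= b for a, b in zip(lengths, lengths[1:]))

    def test_higher_threshold_never_shortens_interphase(self):
        lengths = []
        for T in (40.0, 60.0, 80.0, 120.0):
            p = ModelParams(size_dependence=SizeDependence.PCDK_PROP_SIZE,
                            pCDK=3.0, T_division=T)
            cell = new_cell(20.0, p, g=G, d=50.0)
            _, hours = run_to_division(cell, p)
            lengths.append(hours)
        assert all(b >= a for a, b in zip(lengths, lengths[1:]))


class TestSizerContinuousLimit:
    def test_added_size_matches_adder_closed_form_first_order(self):
        # size added per cycle -> g*T*size_ref/pCDK as dt -> 0
        T, pcdk = 100.0, 3.0
        target = G * T * 20.0 / pcdk
        errors = []
        for dt in (1.0, 0.1, 0.01):
            p = ModelParams(dt=dt, pCDK=pcdk, T_division=T,
                            size_dependence=SizeDependence.PCDK_PROP_SIZE)
            cell = new_cell(20.0, p, g=G, d=50.0)
            cell, _ = run_to_division(cell, p)
            errors.append(abs((cell.size - 20.0) - target))
        assert errors[0] > errors[1] > errors[2]
        assert errors[2] < 0.05 * target

    def test_added_size_independent_of_birth_size(self):
        p = ModelParams(dt=0.01, pCDK=3.0, T_division=100.0,
                        size_dependence=SizeDependence.PCDK_PROP_SIZE)
        added = []
        for b in (12.0, 20.0, 33.0):
            cell = new_cell(b, p, g=G, d=50.0)
            cell, _ = run_to_division(cell, p)
            added.append(cell.size - b)
        assert max(added) - min(added) < 0.02 * added[1]


class TestDivideCell:
    @staticmethod
    def _post_mitotic(size, d):
        p = ModelParams(pCDK=1000.0, T_division=1.0,
                        size_dependence=SizeDependence.NONE)
        cell = new_cell(size, p, g=G, d=d)
        cell, event = advance_cell(cell, p)
        cell, event = advance_cell(cell, p)
        assert event is Event.DIVIDED
        return cell, p

    def test_symmetric_halves(self):
        import numpy as np
        cell, p = self._post_mitotic(40.0, 50.0)
        cell.size = 40.0
        d1, d2 = divide_cell(cell, p, np.random.default_rng(0))
        assert d1.size == pytest.approx(20.0)
        assert d2.size == pytest.approx(20.0)

    def test_percentage_split(self):
        import numpy as np
        cell, p = self._post_mitotic(40.0, 60.0)
        cell.size = 40.0
        d1, d2 = divide_cell(cell, p, np.random.default_rng(0))
        assert d1.size == pytest.approx(24.0)
        assert d2.size == pytest.approx(16.0)

    @settings(max_examples=50, deadline=None)
    @given(size=st.floats(1.0, 500.0), d=st.floats(5.0, 95.0))
    def test_mass_conserved_and_daughters_reset(self, size, d):
        import numpy as np
        cell, p = self._post_mitotic(size, d)
        cell.size = size
        d1, d2 = divide_cell(cell, p, np.random.default_rng(1))
        assert d1.size + d2.size == pytest.approx(size, rel=1e-12)
        for daughter in (d1, d2):
            assert daughter.cdk == 0.0
            assert daughter.age == 0.0
            assert daughter.parent_id == cell.lineage_id

    def test_division_before_mitosis_completion_is_an_error(self):
        import numpy as np
        p = ModelParams()
        cell = new_cell(20.0, p, g=G, d=50.0)
        with pytest.raises(RuntimeError):
            divide_cell(cell, p, np.random.default_rng(0))


class TestModelParamsValidation:
    @pytest.mark.parametrize("kwargs", [
        {"dt": 0.0}, {"pCDK": -1.0}, {"d_mean": 0.0}, {"d_mean": 100.0},
        {"g_sd": -0.1}, {"mitosis_steps": 0},
    ])
    def test_invalid_params_rejected(self, kwargs):
        with pytest.raises(ValueError):
            ModelParams(**kwargs)
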