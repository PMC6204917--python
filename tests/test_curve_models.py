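"""Unit and property tests for the parametric model evaluators."""

import json
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from navblock.curve_models import (
    BiexpFit,
    BoltzmannFit,
    HillFit,
    MonoexpFit,
    Polarity,
    StateBlockModel,
    apparent_ic50,
    fit_from_json,
    fit_to_json,
)

AVAIL = Polarity.AVAILABILITY
ACT = Polarity.ACTIVATION


class TestHill:
    @pytest.mark.parametrize("ic50,h", [(1.5, 2.8), (2.1, 3.4), (10.0, 1.0)])
    def test_half_maximal_at_ic50(self, ic50, h):
        assert HillFit(ic50, h).inhibition(ic50) == pytest.approx(0.5, abs=1e-15)

    def test_zero_concentration_gives_zero(self):
        assert HillFit(1.5, 2.8).inhibition(0.0) == 0.0

    def test_double_ic50_slope3(self):
        # 2^3 / (1 + 2^3) = 8/9, by hand
        assert HillFit(5.0, 3.0).inhibition(10.0) == pytest.approx(8 / 9, rel=1e-12)

    def test_monotone_in_concentration(self):
        c = np.geomspace(0.01, 100, 50)
        y = HillFit(2.5, 2.0).inhibition(c)
        assert np.all(np.diff(y) > 0)

    def test_negative_concentration_rejected(self):
        with pytest.raises(ValueError):
            HillFit(1.0, 1.0).inhibition(-0.1)

    @pytest.mark.parametrize("ic50,h", [(0.0, 1.0), (1.0, 0.0), (-2.0, 1.0)])
    def test_invalid_parameters_rejected(self, ic50, h):
        with pytest.raises(ValueError):
            HillFit(ic50, h)

    @given(h=st.floats(0.01, 10.0), ic50=st.floats(0.001, 1000.0))
    @settings(max_examples=100, derandomize=True)
    def test_half_point_exact_over_parameter_space(self, h, ic50):
        assert HillFit(ic50, h).inhibition(ic50) == pytest.approx(0.5, abs=1e-12)


class TestBoltzmann:
    def test_half_at_midpoint_both_polarities(self):
        for pol in (ACT, AVAIL):
            assert BoltzmannFit(-50.0, 6.0, pol).value(-50.0) == 0.5

    def test_availability_limits(self):
        f = BoltzmannFit(-62.0, 7.2, AVAIL)
        assert f.value(-200.0) == pytest.approx(1.0, abs=1e-8)
        assert f.value(100.0) == pytest.approx(0.0, abs=1e-8)

    def test_wt_availability_at_depolarized_holding(self):
        # 1/(1+exp((-45 - (-62))/7.2)) ≈ 0.086: mostly inactivated at −45 mV
        f = BoltzmannFit(-62.0, 7.2, AVAIL)
        assert f.value(-45.0) == pytest.approx(
            1 / (1 + math.exp(17 / 7.2)), rel=1e-12)
        assert f.value(-45.0) == pytest.approx(0.086, abs=5e-4)

    def test_polarity_fixes_monotonicity(self):
        v = np.arange(-120, 20, 5.0)
        act = BoltzmannFit(-41.9, 3.6, ACT).value(v)
        avail = BoltzmannFit(-69.7, 5.0, AVAIL).value(v)
        assert np.all(np.diff(act) > 0)
        assert np.all(np.diff(avail) < 0)

    @given(v_half=st.floats(-100, 0), k=st.floats(0.5, 15),
           vm=st.floats(-150, 50))
    @settings(max_examples=100, derandomize=True)
    def test_availability_mirrors_activation(self, v_half, k, vm):
        # equal (v_half, k): the two polarities are exact complements
        act = BoltzmannFit(v_half, k, ACT)
        avail = BoltzmannFit(v_half, k, AVAIL)
        assert act.value(vm) + avail.value(vm) == pytest.approx(1.0, abs=1e-9)

    def test_nonpositive_slope_rejected(self):
        with pytest.raises(ValueError):
            BoltzmannFit(-50.0, 0.0, ACT)


class TestExponentials:
    def test_biexp_boundary_values(self):
        f = BiexpFit(y0=0.0, plateau=1.0, k_fast=1 / 0.272, k_slow=1 / 8.72,
                     percent_fast=50.0)
        assert f.value(0.0) == pytest.approx(0.0, abs=1e-12)
        assert f.value(1e6) == pytest.approx(1.0, abs=1e-12)

    def test_biexp_reference_point(self):
        # vehicle fast/slow recovery constants, 70% fast, evaluated at 10 ms
        f = BiexpFit(y0=0.0, plateau=1.0, k_fast=1 / 0.00173,
                     k_slow=1 / 0.0688, percent_fast=70.0)
        assert f.value(0.01) == pytest.approx(0.738, abs=1e-3)

    @given(y0=st.floats(-2, 2), plateau=st.floats(-2, 2),
           pf=st.floats(0, 100), kf=st.floats(0.1, 100),
           ks=st.floats(0.001, 0.09))
    @settings(max_examples=100, derandomize=True)
    def test_span_conservation(self, y0, plateau, pf, kf, ks):
        f = BiexpFit(y0, plateau, kf, ks, pf)
        assert f.span_fast + f.span_slow == pytest.approx(y0 - plateau,
                                                          abs=1e-9)

    def test_rate_relabelling(self):
        f = BiexpFit(0.0, 1.0, k_fast=0.1, k_slow=10.0, percent_fast=30.0)
        assert f.k_fast == 10.0 and f.k_slow == 0.1
        assert f.percent_fast == 70.0

    def test_percent_fast_range_enforced(self):
        with pytest.raises(ValueError):
            BiexpFit(0.0, 1.0, 1.0, 0.1, percent_fast=120.0)

    def test_monoexp_initial_and_tau_point(self):
        f = MonoexpFit(y0=1.0, plateau=0.2, k=1 / 21.6)
        assert f.value(0.0) == 1.0
        assert f.tau_obs == pytest.approx(21.6)
        assert f.value(21.6) == pytest.approx(0.2 + 0.8 / math.e, rel=1e-12)

    def test_monoexp_invalid_rate(self):
        with pytest.raises(ValueError):
            MonoexpFit(1.0, 0.0, k=-0.5)

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            MonoexpFit(1.0, 0.0, 1.0).value(-1.0)


class TestStateBlockModel:
    avail = BoltzmannFit(-69.7, 5.0, AVAIL)

    def make(self, kr=12.7, ki=1.6):
        return StateBlockModel(kd_rest=kr, kd_inact=ki, availability=self.avail)

    def test_limits_are_the_state_kds(self):
        m = self.make()
        assert m.apparent_ic50(-200.0) == pytest.approx(m.kd_rest, rel=1e-6)
        assert m.apparent_ic50(100.0) == pytest.approx(m.kd_inact, rel=1e-6)

    def test_reference_apparent_ic50_at_minus80(self):
        # 1/(f_r/12.7 + (1-f_r)/1.6) with f_r = h∞(−80) ≈ 0.887 → ≈7.1 μM
        m = self.make()
        assert m.apparent_ic50(-80.0) == pytest.approx(7.12, abs=0.05)

    @given(vh=st.floats(-150, 50))
    @settings(max_examples=100, derandomize=True)
    def test_bounded_between_state_kds(self, vh):
        m = self.make()
        k = m.apparent_ic50(vh)
        assert m.kd_inact - 1e-12 <= k <= m.kd_rest + 1e-12

    def test_monotone_in_inactivated_fraction(self):
        m = self.make()
        vh = np.linspace(-120, 0, 60)
        k_app = np.array([m.apparent_ic50(v) for v in vh])
        assert np.all(np.diff(k_app) <= 1e-12)  # more inactivation → more potent

    def test_requires_availability_polarity(self):
        with pytest.raises(ValueError):
            StateBlockModel(12.0, 1.2, BoltzmannFit(-41.9, 3.6, ACT))


def test_evaluators_match_brute_force_formulas():
    """All evaluators agree with direct transcription of the equations
    on a 1,000-point random parameter grid."""
    rng = np.random.default_rng(42)
    for _ in range(1000):
        c = rng.uniform(0, 50)
        ic50, h = rng.uniform(0.1, 20), rng.uniform(0.2, 5)
        assert HillFit(ic50, h).inhibition(c) == pytest.approx(
            c ** h / (ic50 ** h + c ** h), rel=1e-12, abs=1e-12)

        vm, vh, k = rng.uniform(-120, 40), rng.uniform(-90, -30), rng.uniform(1, 12)
        assert BoltzmannFit(vh, k, AVAIL).value(vm) == pytest.approx(
            1 / (1 + math.exp((vm - vh) / k)), rel=1e-12)
        assert BoltzmannFit(vh, k, ACT).value(vm) == pytest.approx(
            1 / (1 + math.exp((vh - vm) / k)), rel=1e-12)

        t = rng.uniform(0, 30)
        y0, pl = rng.uniform(-1, 1), rng.uniform(-1, 1)
        kf, ks, pf = rng.uniform(1, 50), rng.uniform(0.01, 0.9), rng.uniform(0, 100)
        span_f = (y0 - pl) * pf * 0.01
        span_s = (y0 - pl) * (100 - pf) * 0.01
        expected = pl + span_f * math.exp(-kf * t) + span_s * math.exp(-ks * t)
        assert BiexpFit(y0, pl, kf, ks, pf).value(t) == pytest.approx(
            expected, rel=1e-12, abs=1e-12)

        km = rng.uniform(0.01, 2)
        assert MonoexpFit(y0, pl, km).value(t) == pytest.approx(
            (y0 - pl) * math.exp(-km * t) + pl, rel=1e-12, abs=1e-12)


@pytest.mark.parametrize("fit", [
    HillFit(2.5, 2.0, fixed_slope=True),
    BoltzmannFit(-69.7, 5.0, AVAIL),
    BiexpFit(0.0, 1.0, 1 / 0.272, 1 / 8.72, 50.0),
    MonoexpFit(1.0, 0.1, 1 / 21.6),
    StateBlockModel(12.0, 1.2, BoltzmannFit(-69.7, 5.0, AVAIL)),
])
def test_json_round_trip(fit):
    restored = fit_from_json(fit_to_json(fit))
    assert restored == fit
    # keys carry units
    payload = json.loads(fit_to_json(fit))
    assert any(key.endswith(("_uM", "_mV", "_per_s", "_s"))
               for key in payload if key != "model")


def test_json_unknown_model_rejected():
    with pytest.raises(ValueError):
        fit_from_json('{"model": "quartic"}')
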