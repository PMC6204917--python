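"""Fitter correctness: exact recovery, degenerate handling, determinism."""

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
)
from navblock.fitting import (
    bootstrap_hill_ic50,
    fit_biexponential,
    fit_boltzmann,
    fit_hill,
    fit_ic50_temperature_trend,
    fit_monoexponential,
    fit_state_model,
)

AVAIL = Polarity.AVAILABILITY
ACT = Polarity.ACTIVATION


def hill_curve(ic50, h, n=8, lo=0.1, hi=30.0):
    c = np.geomspace(lo, hi, n)
    return c, HillFit(ic50, h).inhibition(c)


class TestHillFitter:
    @pytest.mark.parametrize("ic50,h", [(1.5, 2.8), (2.5, 2.0), (3.7, 1.1)])
    def test_noiseless_recovery(self, ic50, h):
        res = fit_hill(*hill_curve(ic50, h))
        assert res.converged
        assert res.params.ic50 == pytest.approx(ic50, rel=1e-6)
        assert res.params.h == pytest.approx(h, rel=1e-6)

    def test_fixed_slope_recovery(self):
        c, y = hill_curve(2.1, 3.4)
        res = fit_hill(c, y, fix_slope=3.4)
        assert res.params.ic50 == pytest.approx(2.1, rel=1e-6)
        assert res.params.fixed_slope
        assert res.params.h == 3.4

    def test_zero_inhibition_flagged(self):
        c = np.geomspace(0.1, 30, 8)
        res = fit_hill(c, np.zeros_like(c))
        assert not res.converged
        assert "no concentration dependence" in res.message

    def test_too_few_concentrations(self):
        with pytest.raises(ValueError):
            fit_hill(np.array([1.0, 10.0]), np.array([0.2, 0.8]))
        # but two suffice when the slope is fixed
        c = np.array([1.0, 10.0])
        res = fit_hill(c, HillFit(3.0, 2.0).inhibition(c), fix_slope=2.0)
        assert res.params.ic50 == pytest.approx(3.0, rel=1e-6)

    def test_out_of_range_inhibition_rejected(self):
        c = np.geomspace(0.1, 30, 8)
        y = HillFit(2.0, 2.0).inhibition(c)
        y[-1] = 1.2
        with pytest.raises(ValueError):
            fit_hill(c, y)

    def test_deterministic(self):
        c, y = hill_curve(2.5, 2.0)
        y = y + np.sin(np.arange(8)) * 0.01  # fixed perturbation
        a, b = fit_hill(c, y), fit_hill(c, y)
        assert a.params == b.params and a.residual_ss == b.residual_ss

    def test_median_bias_under_noise(self):
        """σ = 0.03 on inhibition fractions, 6 cells/concentration:
        median |IC50 bias| stays under 10% across 100 replicates."""
        rng = np.random.default_rng(7)
        truth = HillFit(2.5, 2.0)
        c = np.geomspace(0.3, 30, 8)
        errs = []
        for _ in range(100):
            cells = np.repeat(c, 6)
            y = truth.inhibition(cells) + rng.normal(0, 0.03, cells.size)
            pooled = y.reshape(-1, 6).mean(axis=1).clip(0, 1)
            res = fit_hill(c, pooled)
            if res.converged:
                errs.append(abs(res.params.ic50 / truth.ic50 - 1))
        assert len(errs) >= 90
        assert np.median(errs) < 0.10

    def test_bootstrap_interval_covers_truth(self):
        rng = np.random.default_rng(3)
        c = np.repeat(np.geomspace(0.3, 30, 8), 6)
        y = (HillFit(2.5, 2.0).inhibition(c)
             + rng.normal(0, 0.03, c.size)).clip(0, 1)
        boot = bootstrap_hill_ic50(c, y, n_boot=100, seed=11)
        lo, hi = boot["ic50_uM_ci"]
        assert lo < 2.5 < hi


class TestBoltzmannFitter:
    @pytest.mark.parametrize("v_half,k,pol", [
        (-69.7, 5.0, AVAIL), (-41.9, 3.6, ACT), (-77.8, 5.8, AVAIL)])
    def test_noiseless_recovery(self, v_half, k, pol):
        v = np.arange(-120.0, 10.1, 5.0)
        truth = BoltzmannFit(v_half, k, pol)
        res = fit_boltzmann(v, truth.value(v), polarity=pol)
        assert res.converged
        assert res.params.v_half == pytest.approx(v_half, rel=1e-6)
        assert res.params.k == pytest.approx(k, rel=1e-6)

    def test_flat_curve_flagged(self):
        v = np.arange(-120.0, 10.1, 5.0)
        res = fit_boltzmann(v, np.full_like(v, 0.5), polarity=AVAIL)
        assert not res.converged

    def test_underdetermined_rejected(self):
        with pytest.raises(ValueError):
            fit_boltzmann(np.array([-80.0, -60.0]), np.array([0.9, 0.1]),
                          polarity=AVAIL)


class TestExponentialFitters:
    @pytest.mark.parametrize("tau", [21.6, 51.0])
    def test_monoexp_recovery(self, tau):
        t = np.arange(0.0, 120.1, 1.0)
        truth = MonoexpFit(1.0, 0.1, 1 / tau)
        res = fit_monoexponential(t, truth.value(t))
        assert res.converged
        assert res.params.tau_obs == pytest.approx(tau, rel=1e-6)

    def test_monoexp_constant_signal_flagged(self):
        res = fit_monoexponential(np.arange(10.0), np.ones(10))
        assert not res.converged

    def test_biexp_recovery(self):
        lags = np.geomspace(1e-3, 60.0, 20)
        truth = BiexpFit(0.0, 1.0, 1 / 0.272, 1 / 8.72, 50.0)
        res = fit_biexponential(lags, truth.value(lags))
        assert res.converged
        assert res.params.tau_slow == pytest.approx(8.72, rel=1e-6)
        assert res.params.tau_fast == pytest.approx(0.272, rel=1e-6)
        assert res.params.percent_fast == pytest.approx(50.0, rel=1e-6)

    def test_biexp_single_exponential_flagged(self):
        lags = np.geomspace(1e-3, 60.0, 20)
        y = MonoexpFit(0.0, 1.0, 1 / 0.5).value(lags)
        res = fit_biexponential(lags, y)
        assert res.converged
        assert res.message == "effectively monoexponential"

    def test_biexp_constant_signal_flagged(self):
        res = fit_biexponential(np.geomspace(1e-3, 60, 10), np.full(10, 0.4))
        assert not res.converged


class TestStateModelFitter:
    avail = BoltzmannFit(-69.7, 5.0, AVAIL)

    def test_reference_points_give_order_ten_ratio(self):
        """The four measured apparent IC50s vs holding potential resolve a
        roughly ten-fold resting/inactivated affinity separation."""
        pts = [(-100.0, 12.7), (-90.0, 10.3), (-80.0, 6.7), (-70.0, 2.9)]
        res = fit_state_model(pts, self.avail)
        assert res.converged
        ratio = res.params.fold_ratio
        assert 0.5 <= np.log10(ratio) <= 1.5
        assert res.params.kd_inact < res.params.kd_rest

    def test_round_trip_exact(self):
        truth = StateBlockModel(12.0, 1.2, self.avail)
        vh = [-110.0, -95.0, -80.0, -65.0]
        pts = [(v, truth.apparent_ic50(v)) for v in vh]
        res = fit_state_model(pts, self.avail)
        assert res.params.kd_rest == pytest.approx(12.0, rel=1e-9)
        assert res.params.kd_inact == pytest.approx(1.2, rel=1e-9)

    def test_single_point_rejected(self):
        with pytest.raises(ValueError):
            fit_state_model([(-80.0, 6.7)], self.avail)

    def test_identical_availabilities_rejected(self):
        with pytest.raises(ValueError, match="underdetermined"):
            fit_state_model([(-200.0, 12.0), (-190.0, 12.1)], self.avail)


class TestTemperatureTrend:
    def test_reference_triplet_slope(self):
        # potency loses ~0.2 μM per °C of warming over 20–33 °C
        res = fit_ic50_temperature_trend([(20, 2.1), (28, 3.4), (33, 4.7)])
        assert res.params.slope == pytest.approx(0.20, abs=0.01)
        assert res.params.slope > 0

    def test_exact_line_zero_residual(self):
        res = fit_ic50_temperature_trend([(20, 2.0), (25, 3.0), (30, 4.0)])
        assert res.residual_ss == pytest.approx(0.0, abs=1e-18)
        assert res.params.slope == pytest.approx(0.2)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            fit_ic50_temperature_trend([(20, 2.1)])
        with pytest.raises(ValueError):
            fit_ic50_temperature_trend([(20, 2.1), (20, 3.4)])


class TestRoundTripProperty:
    """fit(generate(θ)) = θ on noiseless data across the valid ranges."""

    @given(ic50=st.floats(0.2, 20.0), h=st.floats(0.5, 5.0))
    @settings(max_examples=200, derandomize=True, deadline=None)
    def test_hill(self, ic50, h):
        c = np.geomspace(ic50 / 30, ic50 * 30, 10)
        res = fit_hill(c, HillFit(ic50, h).inhibition(c))
        assert res.params.ic50 == pytest.approx(ic50, rel=1e-6)
        assert res.params.h == pytest.approx(h, rel=1e-6)

    @given(v_half=st.floats(-100.0, -20.0), k=st.floats(1.0, 12.0),
           pol=st.sampled_from([ACT, AVAIL]))
    @settings(max_examples=200, derandomize=True, deadline=None)
    def test_boltzmann(self, v_half, k, pol):
        v = np.arange(-140.0, 40.1, 5.0)
        res = fit_boltzmann(v, BoltzmannFit(v_half, k, pol).value(v),
                            polarity=pol)
        assert res.params.v_half == pytest.approx(v_half, rel=1e-6, abs=1e-5)
        assert res.params.k == pytest.approx(k, rel=1e-6)

    @given(tau=st.floats(5.0, 80.0), plateau=st.floats(0.0, 0.5))
    @settings(max_examples=200, derandomize=True, deadline=None)
    def test_monoexp(self, tau, plateau):
        t = np.arange(0.0, 300.1, 1.0)
        res = fit_monoexponential(t, MonoexpFit(1.0, plateau, 1 / tau).value(t))
        assert res.params.tau_obs == pytest.approx(tau, rel=1e-6)

    @given(tau_fast=st.floats(0.01, 0.5), ratio=st.floats(8.0, 100.0),
           pf=st.floats(25.0, 75.0))
    @settings(max_examples=200, derandomize=True, deadline=None)
    def test_biexp(self, tau_fast, ratio, pf):
        tau_slow = tau_fast * ratio
        lags = np.geomspace(tau_fast / 30, tau_slow * 6, 25)
        truth = BiexpFit(0.0, 1.0, 1 / tau_fast, 1 / tau_slow, pf)
        res = fit_biexponential(lags, truth.value(lags))
        assert res.converged
        assert res.params.tau_slow == pytest.approx(tau_slow, rel=1e-5)
        assert res.params.tau_fast == pytest.approx(tau_fast, rel=1e-5)
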