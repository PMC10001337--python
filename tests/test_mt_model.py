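"""Forward two-pool model: CW power equivalent, T1 constraint, signal."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.optimize import brentq

from utemt import MTProtocol, SaturationPulse, TwoPoolParams
from utemt.mt_model import (
    _slow_eigenvalue,
    fermi_cwpe,
    mt_signal_grid,
    r1_free_from_observed,
    ramani_signal,
)
from utemt.synthetic_data import MUSCLE


class TestFermiCWPE:
    def test_linearity_in_b1(self):
        p = SaturationPulse(power_deg=1000.0, offset_khz=5.0)
        with pytest.raises(ValueError):
            fermi_cwpe(p, 0.0)
        assert fermi_cwpe(p, 0.9) / fermi_cwpe(p, 1.0) == pytest.approx(0.9, rel=1e-12)

    def test_linearity_in_power(self):
        p500 = SaturationPulse(power_deg=500.0, offset_khz=5.0)
        p1000 = SaturationPulse(power_deg=1000.0, offset_khz=5.0)
        assert fermi_cwpe(p1000) / fermi_cwpe(p500) == pytest.approx(2.0, rel=1e-12)

    def test_time_domain_oracle(self):
        """RMS omega_1 over the prep period matches a direct discretised
        envelope computation (trapezoidal, 1e5 samples)."""
        p = SaturationPulse(power_deg=1000.0, offset_khz=5.0)
        tau = p.duration_ms * 1e-3
        a, b = p.shape.a_ms * 1e-3, p.shape.b_ms * 1e-3
        t = np.linspace(0, tau, 100001)
        f = 1 / (1 + np.exp((np.abs(t - tau / 2) - a) / b))
        om_max = math.radians(p.power_deg) / np.trapezoid(f, t)
        oracle = om_max * math.sqrt(
            np.trapezoid(f**2, t) / (p.prep_period_ms * 1e-3)
        )
        assert fermi_cwpe(p) == pytest.approx(oracle, rel=1e-6)


class TestObservedT1Constraint:
    def test_single_pool_limit(self):
        assert r1_free_from_observed(1.2, 1.0, 0.0, 50.0) == 1.2

    def test_equal_rate_degenerate_case(self):
        assert r1_free_from_observed(1.0, 1.0, 0.1, 50.0) == pytest.approx(
            1.0, rel=1e-12
        )

    def test_eigenvalue_oracle(self):
        """Closed form agrees with a bracketed root solve of the slow
        eigenvalue on muscle-like inputs (observed T1 = 972 ms)."""
        r1_obs, r1_b, f, k = 1.0 / 0.972, 1.0, 0.099, 50.0
        oracle = brentq(
            lambda x: _slow_eigenvalue(x, r1_b, k * f, k) - r1_obs,
            1e-6,
            1e3,
            xtol=1e-14,
            rtol=8.9e-16,
        )
        assert r1_free_from_observed(r1_obs, r1_b, f, k) == pytest.approx(
            oracle, rel=1e-8
        )

    @settings(deadline=None, derandomize=True, max_examples=200)
    @given(
        t1_obs_ms=st.floats(300.0, 2000.0),
        f=st.floats(0.0, 0.5),
        k=st.floats(5.0, 200.0),
        r1_b=st.floats(0.5, 2.0),
    )
    def test_self_consistency_property(self, t1_obs_ms, f, k, r1_b):
        """Substituting the derived free-pool rate back into the exchange
        matrix reproduces the observed rate to 1e-10 relative."""
        r1_obs = 1.0 / (t1_obs_ms * 1e-3)
        ra = r1_free_from_observed(r1_obs, r1_b, f, k)
        assert ra > 0
        back = _slow_eigenvalue(ra, r1_b, k * f, k)
        assert back == pytest.approx(r1_obs, rel=1e-10)


class TestRamaniSignal:
    def test_no_saturation_limit(self):
        """S -> m0 exactly as the saturation power vanishes."""
        params = MUSCLE.two_pool()
        p = SaturationPulse(power_deg=1e-9, offset_khz=50.0)
        assert ramani_signal(params, p) == pytest.approx(params.m0, rel=1e-12)

    def test_grid_ordering(self, mt_protocol, muscle_grid):
        """Signal strictly decreases with power and strictly increases with
        offset for muscle-like parameters (the layered saturation curves)."""
        assert np.all(np.diff(muscle_grid, axis=0) < 0)  # power 500->1500
        assert np.all(np.diff(muscle_grid, axis=1) > 0)  # offset 2->50 kHz

    def test_single_pool_weak_direct_saturation(self, mt_protocol):
        """With no bound pool, only weak direct saturation remains at
        50 kHz / 500 deg: signal within 1% of m0, matching the closed-form
        single-pool value S = m0/(1 + d)."""
        params = TwoPoolParams(
            m0=2.0, bound_ratio=0.0, k_exch=50.0, t2_free_ms=30.0,
            t2_bound_us=10.0, r1_obs=1.0 / 0.972,
        )
        pulse = mt_protocol.pulse(500.0, 50.0)
        s = ramani_signal(params, pulse)
        assert s == pytest.approx(params.m0, rel=0.01)
        omega1 = fermi_cwpe(pulse)
        d = (omega1 / (2 * math.pi * 50e3)) ** 2 / (params.r1_obs * 30e-3)
        assert s == pytest.approx(params.m0 / (1 + d), rel=1e-9)

    def test_on_resonance_rejected(self):
        with pytest.raises(ValueError):
            SaturationPulse(power_deg=1000.0, offset_khz=0.0)

    def test_b1_broadcast(self, mt_protocol):
        params = MUSCLE.two_pool()
        pulse = mt_protocol.pulse(1000.0, 5.0)
        b1 = np.array([0.9, 1.0, 1.1])
        out = ramani_signal(params, pulse, b1)
        assert out.shape == (3,)
        assert np.all(np.diff(out) < 0)  # more B1, more saturation

    def test_mmf_bound_ratio_identity(self):
        p = MUSCLE.two_pool()
        assert p.mmf_percent == pytest.approx(
            100 * p.bound_ratio / (1 + p.bound_ratio), abs=0
        )
        assert TwoPoolParams.bound_ratio_from_mmf(9.0) == pytest.approx(9 / 91.0)
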