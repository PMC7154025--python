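"""Lumped circuit: diode, Windkessel closed forms, LTI oracle, conservation."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from pulsetwin.circuit import (CircuitConfig, FluidProperties,
                               IntegrationFailure, LinearValve,
                               PorcineUpstream, RCRWindkessel, assemble_rhs,
                               diode_flow, lowpass_filter, rcr_outlet_update,
                               run_to_periodic)
from pulsetwin.metrics import Waveform, stroke_volume
from pulsetwin.presets import WINDKESSELS, get_preset
from pulsetwin.synthetic import PumpDriver, build_circuit_config

SALINE = FluidProperties(rho=1.0, mu=1.0)
PORCINE_WK = WINDKESSELS["porcine"]


class TestDiode:
    def test_reverse_bias_blocks(self):
        q = diode_flow(0.0, 10.0, r=0.028, eps_smooth=0.01)
        assert 0 <= q < 0.01 / 0.028

    def test_forward_conductance_printed_mitral_resistance(self):
        # dp = 2.8 mmHg through R_MV = 0.0280 mmHg s/mL -> 100 mL/s
        assert diode_flow(2.8, 0.0, r=0.0280) == pytest.approx(100.0, rel=1e-4)

    def test_continuous_and_monotone(self):
        dps = np.linspace(-5.0, 5.0, 2001)
        q = np.array([diode_flow(dp, 0.0, 0.028, 0.01) for dp in dps])
        assert np.all(np.diff(q) >= 0)
        assert np.max(np.abs(np.diff(q))) < 1.0  # no jumps


class TestWindkessel:
    def test_steady_state_pressure(self):
        # equilibrium under constant inflow Q0: p_in = Q0 (Rc + Rp)
        q0 = 80.0
        p_store = q0 * PORCINE_WK.r_p
        p_in, dp = rcr_outlet_update(PORCINE_WK, q0, p_store)
        assert dp == pytest.approx(0.0, abs=1e-12)
        assert p_in == pytest.approx(q0 * (PORCINE_WK.r_c + PORCINE_WK.r_p))

    def test_diastolic_decay_constant_porcine(self):
        # stored pressure decays as exp(-t / (Rp C)); Rp C = 1.31 * 0.915
        tau_expect = 1.31 * 0.915
        assert PORCINE_WK.tau == pytest.approx(1.19865, rel=1e-12)
        sol = solve_ivp(
            lambda t, y: [rcr_outlet_update(PORCINE_WK, 0.0, y[0])[1]],
            (0.0, 2.0), [80.0], rtol=1e-10, atol=1e-12, dense_output=True)
        p = sol.sol(np.array([0.0, 1.0]))[0]
        tau_measured = -1.0 / np.log(p[1] / p[0])
        assert tau_measured == pytest.approx(tau_expect, rel=1e-6)

    def test_parameters_positive(self):
        with pytest.raises(ValueError):
            RCRWindkessel(r_c=0.02, r_p=-1.0, c=0.9)


def _linear_config(r_valve=0.05):
    # 60 bpm so one period is exactly 1000 samples at 1 kHz and the DFT
    # harmonics of the oracle coincide with the true ones
    driver = PumpDriver(amplitude=120.0, width=0.3, period=1.0, baseline=10.0)
    return CircuitConfig(
        fluid=SALINE,
        upstream=PorcineUpstream(p_pump=driver),
        windkessel=PORCINE_WK,
        valve=LinearValve(r=r_valve),
        heart_rate_bpm=60.0,
    ), driver


def _lti_oracle(config, driver, n_samp):
    """Frequency-domain solution of the linear circuit: solve the 4x4 complex
    nodal system per harmonic of the pump pressure."""
    up, wk, lv = config.upstream, config.windkessel, config.valve
    T = config.period
    t = np.arange(n_samp) * 1e-3
    p_pump = np.array([driver(tt) for tt in t])
    P = np.fft.rfft(p_pump)
    omegas = 2 * np.pi * np.fft.rfftfreq(n_samp, d=1e-3)
    X = np.zeros((4, len(omegas)), dtype=complex)
    for k, w in enumerate(omegas):
        jw = 1j * w
        # unknowns: p_via, p_lv, p_store, q
        A = np.array([
            [jw * up.c_via + 1 / up.r1 + 1 / up.r2, -1 / up.r2, 0, 0],
            [-1 / up.r2, jw * config.c_lv + 1 / up.r2, 0, 1],
            [0, 0, jw * wk.c + 1 / wk.r_p, -1],
            [0, -1, 1, jw * lv.inertance + lv.r + wk.r_c],
        ], dtype=complex)
        b = np.array([P[k] / up.r1, 0, 0, 0], dtype=complex)
        X[:, k] = np.linalg.solve(A, b)
    return {name: np.fft.irfft(X[i], n=n_samp)
            for i, name in enumerate(["p_via", "p_lv", "p_store", "q"])}


class TestLinearValveOracle:
    def test_periodic_solution_matches_frequency_domain(self):
        config, driver = _linear_config()
        res = run_to_periodic(config, tol=1e-5, max_cycles=25)
        assert res.converged
        n = len(res.waveforms["q_ao"].t)
        oracle = _lti_oracle(config, driver, n)
        for name, sim in [("p_lv", res.waveforms["p_lv"].v),
                          ("p_store", res.waveforms["p_store"].v),
                          ("q", res.waveforms["q_ao"].v)]:
            ref = oracle[name if name != "q" else "q"]
            err = np.linalg.norm(sim - ref) / np.linalg.norm(ref)
            assert err < 5e-3, name

    def test_converges_within_ten_cycles(self):
        config, _ = _linear_config()
        res = run_to_periodic(config, tol=1e-3, max_cycles=10)
        assert res.converged
        assert res.n_cycles <= 10

    def test_output_grid_uniform_1khz_over_period(self):
        config, _ = _linear_config()
        res = run_to_periodic(config, tol=1e-3)
        t = res.waveforms["q_ao"].t
        assert len(t) == round(1000 * res.waveforms["q_ao"].t[-1] + 1000 * 1e-3)
        assert len(t) == 1000  # 60 bpm here; 70 bpm presets give 857
        assert np.allclose(np.diff(t), 1e-3)
        assert t[0] == 0.0

    def test_step_refinement_stable(self):
        # halving the max step leaves the converged cycle essentially unchanged
        config, _ = _linear_config()
        import dataclasses
        res1 = run_to_periodic(config, tol=1e-5, max_cycles=25)
        config2 = dataclasses.replace(config, max_step=5e-5)
        res2 = run_to_periodic(config2, tol=1e-5, max_cycles=25)
        q1, q2 = res1.waveforms["q_ao"].v, res2.waveforms["q_ao"].v
        assert np.linalg.norm(q1 - q2) / np.linalg.norm(q1) < 1e-3


class TestAssembleRHS:
    def test_rest_state_zero_derivative(self):
        config = CircuitConfig(
            fluid=SALINE,
            upstream=PorcineUpstream(p_pump=lambda t: 0.0),
            windkessel=PORCINE_WK,
            valve=LinearValve(r=0.05),
        )
        dy = assemble_rhs(config, np.zeros(5), 0.0)
        assert np.allclose(dy, 0.0)

    def test_nonfinite_state_raises_with_timestamp(self):
        config, _ = _linear_config()
        y = np.zeros(5)
        y[0] = np.nan
        with pytest.raises(IntegrationFailure, match="t = "):
            assemble_rhs(config, y, 0.123)

    def test_flux_balance_sign_convention(self):
        # raising the pump pressure alone must charge the VIA node
        config, _ = _linear_config()
        y = np.zeros(5)
        dy = assemble_rhs(config, y, 0.1)  # driver is positive at t=0.1
        assert dy[0] > 0


class TestConservation:
    def test_volume_conservation_at_nodes(self, porcine_twin):
        """Net volume into every compliance node over the converged cycle is
        below 0.1% of the stroke volume."""
        res = porcine_twin.result
        config = porcine_twin.config
        wf = res.waveforms
        t = wf["q_ao"].t
        sv = stroke_volume(wf["q_ao"])
        q = wf["q_ao"].v
        p_store = wf["p_store"].v
        p_lv = wf["p_lv"].v
        p_via = wf["p_via"].v
        up = config.upstream
        drv = np.array([up.p_pump(tt) for tt in t])
        flux = {
            "store": q - p_store / config.windkessel.r_p,
            "lv": (p_via - p_lv) / up.r2 - q,
            "via": (drv - p_via) / up.r1 - (p_via - p_lv) / up.r2,
        }
        for node, f in flux.items():
            net = abs(np.trapezoid(f, t))
            assert net < 1e-3 * sv, node

    def test_resistors_dissipate(self, porcine_twin):
        wf = porcine_twin.result.waveforms
        wk = porcine_twin.config.windkessel
        t = wf["q_ao"].t
        # peripheral branch energy flux is a square over resistance
        e_rp = np.trapezoid(wf["p_store"].v ** 2 / wk.r_p, t)
        e_rc = np.trapezoid(wf["q_ao"].v ** 2 * wk.r_c, t)
        assert e_rp >= 0 and e_rc >= 0 and e_rp > 0

    def test_sealed_valve_diastolic_decay_matches_rp_c(self, porcine_material):
        """With the pump off and the valve sealed (zero leak), the aortic
        store decays with the Windkessel time constant Rp*C within 5%."""
        from pulsetwin.valve import ValveParams
        valve = ValveParams(a_max=1.85, a_leak=0.0,
                            material=porcine_material)
        config = CircuitConfig(
            fluid=SALINE,
            upstream=PorcineUpstream(p_pump=lambda t: 0.0),
            windkessel=PORCINE_WK,
            valve=valve,
        )
        y0 = np.array([0.0, 0.0, 80.0, 0.0, 0.0])
        sol = solve_ivp(lambda t, y: assemble_rhs(config, y, t), (0.0, 1.0),
                        y0, method="LSODA", max_step=1e-3,
                        rtol=1e-9, atol=1e-10, t_eval=[0.0, 1.0])
        p0, p1 = sol.y[2]
        tau = -1.0 / np.log(p1 / p0)
        assert tau == pytest.approx(PORCINE_WK.tau, rel=0.05)
        assert abs(sol.y[4][-1]) < 1e-9  # no transvalvular flow

    def test_coupled_valve_timing(self, porcine_twin):
        """Opening starts when P_LV crosses above P_Ao; closure completes
        only after flow reversal."""
        wf = porcine_twin.result.waveforms
        theta = wf["theta"].v
        dp = wf["p_lv"].v - wf["p_ao"].v
        q = wf["q_ao"].v
        opening = np.where(np.diff(theta > 0.05, prepend=False))[0]
        i_open = opening[0]
        # at opening onset the transvalvular pressure is near zero crossing
        assert dp[i_open] > -0.5
        assert dp[max(i_open - 30, 0)] < dp[i_open]
        i_closed = np.where(theta > 0.5)[0][-1]  # last mostly-open sample
        i_reversal = np.where(q < 0)[0]
        assert len(i_reversal) > 0 and i_closed >= i_reversal[0] - 1
        assert np.all((theta >= 0.0) & (theta <= 1.0))


class TestLowpass:
    def test_dc_gain_unity(self):
        t = np.arange(0, 1, 1e-3)
        w = Waveform(t, np.full_like(t, 7.0))
        assert np.allclose(lowpass_filter(w, 100.0).v, 7.0, atol=1e-9)

    def test_stopband_attenuation(self):
        t = np.arange(0, 1, 1e-4)  # 10 kHz sampling
        w = Waveform(t, np.sin(2 * np.pi * 200.0 * t))
        out = lowpass_filter(w, 100.0)
        mid = slice(len(t) // 4, 3 * len(t) // 4)
        atten = np.max(np.abs(out.v[mid])) / 1.0
        assert atten < 10 ** (-20 / 20)  # > 20 dB down at 2x cutoff

    def test_linearity(self):
        t = np.arange(0, 1, 1e-3)
        rng = np.random.default_rng(0)
        a = Waveform(t, rng.standard_normal(len(t)))
        b = Waveform(t, np.sin(2 * np.pi * 30 * t))
        lhs = lowpass_filter(a.with_values(a.v + b.v), 100.0).v
        rhs = lowpass_filter(a, 100.0).v + lowpass_filter(b, 100.0).v
        assert np.allclose(lhs, rhs, atol=1e-10)

    def test_undersampled_signal_rejected(self):
        t = np.arange(0, 1, 1e-2)  # 100 Hz sampling < 2 * fc
        with pytest.raises(ValueError, match="coarse"):
            lowpass_filter(Waveform(t, np.zeros_like(t)), 100.0)
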