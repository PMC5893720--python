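import math
from dataclasses import replace

import numpy as np
import pytest

import ephyskit as ek
from ephyskit.trace import WindowSpec


def test_composite_cv():
    assert ek.composite_cv_qi(0.3, 0.2) == pytest.approx(0.36055512754639)
    assert ek.composite_cv_qi(0.0, 0.0) == 0.0


class TestSiteAmplitudes:
    def test_zero_cv_exact(self):
        rng = np.random.default_rng(0)
        s = ek.sample_site_amplitudes(5, -20.0, 0.0, 0.01, rng)
        np.testing.assert_array_equal(s.amplitudes, -20.0)
        assert s.iterations == 1

    def test_precision_contract(self):
        rng = np.random.default_rng(1)
        s = ek.sample_site_amplitudes(5, -20.0, 0.3, 0.01, rng)
        assert -20.2 <= s.mean <= -19.8
        assert 0.297 <= s.cv <= 0.303
        assert np.all(s.amplitudes < 0)

    def test_deterministic_given_seed(self):
        s1 = ek.sample_site_amplitudes(5, -20.0, 0.3, 0.01,
                                       np.random.default_rng(2))
        s2 = ek.sample_site_amplitudes(5, -20.0, 0.3, 0.01,
                                       np.random.default_rng(2))
        np.testing.assert_array_equal(s1.amplitudes, s2.amplitudes)

    def test_tighter_precision_needs_more_iterations(self):
        med = []
        for prec in (0.02, 0.002):
            its = [ek.sample_site_amplitudes(
                5, -20.0, 0.3, prec, np.random.default_rng(s)).iterations
                for s in range(10)]
            med.append(np.median(its))
        assert med[1] >= med[0]

    def test_iteration_cap(self):
        with pytest.raises(RuntimeError, match="closest achieved"):
            ek.sample_site_amplitudes(5, -20.0, 0.3, 1e-7,
                                      np.random.default_rng(3),
                                      max_iter=200)


class TestQuantalSim:
    def test_p_zero_silent(self):
        cfg = ek.QuantalSimConfig(p_release=0.0, n_trials=10, noise_sd=0.0)
        sweeps, table, _ = ek.simulate_quantal(cfg)
        assert table.empty
        assert all(np.all(tr.samples == 0) for tr in sweeps)

    def test_p_one_deterministic_peak(self):
        cfg = ek.QuantalSimConfig(p_release=1.0, cv_qs=0.0, sigma_ql=0.0,
                                  cv_qii=0.0, n_trials=5)
        sweeps, _, _ = ek.simulate_quantal(cfg)
        for tr in sweeps:
            # grid sampling clips the true peak by O(dt^2)
            assert tr.samples.min() == pytest.approx(-100.0, rel=1e-4)
        np.testing.assert_array_equal(sweeps[0].samples, sweeps[1].samples)

    def test_release_fraction_closed_form(self):
        cfg = ek.QuantalSimConfig(n_trials=150, seed=5)
        _, table, _ = ek.simulate_quantal(cfg)
        frac = table["trial"].nunique() / 150.0
        p_any = 1 - 0.5 ** 5
        se = math.sqrt(p_any * (1 - p_any) / 150)
        assert abs(frac - p_any) < 3 * se

    def test_binomial_variance_closed_form(self):
        """With no quantal variability the trial-peak variance is
        N P (1-P) Q_p^2 scaled by the window attenuation."""
        cfg = ek.QuantalSimConfig(cv_qs=0.0, sigma_ql=0.0, cv_qii=0.0,
                                  n_trials=10_000, dt=0.02, sweep_ms=8.0,
                                  seed=6)
        sweeps, _, _ = ek.simulate_quantal(cfg)
        unit, t_peak = ek.synexp_unit_peak(cfg.waveform)
        pw = WindowSpec(cfg.stim_time + t_peak - 0.05,
                        cfg.stim_time + t_peak + 0.05)
        peaks = ek.window_measure(sweeps, "avg", pw).values
        idx = sweeps[0].window_indices(pw)
        w = ek.synexp_eval(unit, sweeps[0].times()[idx]
                           - cfg.stim_time).mean()
        expect_var = 5 * 0.5 * 0.5 * 400.0 * w * w
        expect_mean = 5 * 0.5 * -20.0 * w
        assert peaks.mean() == pytest.approx(expect_mean, rel=0.02)
        assert peaks.var(ddof=1) == pytest.approx(expect_var, rel=0.06)

    def test_mpfa_protocol_recovers_sites(self):
        """Idealized protocol (no quantal variability, many trials)
        recovers the generating N and Q_p."""
        cfg = ek.QuantalSimConfig(cv_qs=0.0, sigma_ql=0.0, cv_qii=0.0,
                                  n_trials=2000, dt=0.02, sweep_ms=8.0)
        _, res, _ = ek.mpfa_from_sim(cfg, cv_qi=0.0, seed=7)
        assert res.params["N"] == pytest.approx(5.0, abs=0.4)
        assert res.params["Q_p"] == pytest.approx(-20.0, abs=1.0)

    def test_single_condition_fit_fails(self):
        pts, _ = ek.synth_mpfa_dataset(p_values=(0.5,), seed=8)
        from ephyskit.fitting import VarianceMeanModel
        with pytest.raises(ValueError):
            VarianceMeanModel(pts)


class TestRP:
    def test_first_event_initial_condition(self):
        p = ek.RPParams(r_inf=1.0, p_inf=0.14, delta=0.0, tau_r=131.0)
        r, pp, rp = ek.rp_event_values([10.0], p)
        assert rp[0] == pytest.approx(0.14)

    def test_delta_zero_keeps_p_constant(self):
        p = ek.RPParams(p_inf=0.14, delta=0.0)
        _, pp, _ = ek.rp_event_values(10.0 * np.arange(1, 50), p)
        np.testing.assert_allclose(pp, 0.14, atol=1e-12)

    def test_regular_train_fixed_point(self):
        p = ek.RPParams(r_inf=1.0, p_inf=0.14, delta=0.0, tau_r=131.0)
        r, _, _ = ek.rp_event_values(20.0 * np.arange(1, 201), p)
        assert r[-1] == pytest.approx(
            ek.rp_regular_train_fixed_point(20.0, p), abs=1e-10)

    def test_state_bounds_on_random_trains(self):
        rng = np.random.default_rng(9)
        for _ in range(20):
            params = ek.RPParams(
                r_inf=1.0, p_inf=rng.uniform(0, 1),
                delta=rng.uniform(0, 1), tau_r=rng.uniform(5, 200),
                tau_p=rng.uniform(5, 200))
            times = np.cumsum(rng.exponential(10.0, 100)) + 1.0
            r, pp, _ = ek.rp_event_values(times, params)
            assert np.all((r >= 0) & (r <= 1.0))
            assert np.all((pp >= 0) & (pp <= 1.0))

    def test_non_increasing_times_rejected(self):
        with pytest.raises(ValueError):
            ek.rp_event_values([5.0, 5.0], ek.RPParams())


class TestSTPTrain:
    def test_single_event_scales_by_pinf(self, unit_quantal):
        unit, _ = unit_quantal
        direct = ek.RPParams(p_inf=0.14, g_max=unit)
        tr = ek.stp_conductance_train([np.array([10.0])], direct, None,
                                      0.02, 50.0)
        assert tr.samples.max() == pytest.approx(0.14, rel=1e-3)
        assert tr.units == "nS"

    def test_two_identical_inputs_double(self, unit_quantal):
        unit, _ = unit_quantal
        direct = ek.RPParams(p_inf=0.14, g_max=unit)
        times = np.array([10.0, 30.0, 70.0])
        one = ek.stp_conductance_train([times], direct, None, 0.05, 100.0)
        two = ek.stp_conductance_train([times, times], direct, None,
                                       0.05, 100.0)
        np.testing.assert_allclose(two.samples, 2 * one.samples, rtol=1e-12)

    def test_depression_only_amplitudes_non_increasing(self, unit_quantal):
        """High-frequency burst through a depression-only synapse:
        successive direct-component response amplitudes shrink."""
        unit, _ = unit_quantal
        direct = ek.RPParams(r_inf=1.0, p_inf=0.14, delta=0.0, tau_r=131.0,
                             g_max=unit)
        times = 10.0 + 1000.0 / 85.6 * np.arange(12)  # ~85.6 Hz burst
        _, _, rp = ek.rp_event_values(times, direct)
        assert np.all(np.diff(rp) < 0)


class TestIAF:
    def test_rest_without_input(self):
        p = ek.IAFParams(dt=0.02, duration_ms=50.0)
        v, spikes = ek.iaf_simulate(p)
        np.testing.assert_allclose(v.samples, p.e_leak, atol=1e-9)
        assert spikes.size == 0

    def test_subthreshold_steady_state(self):
        p = ek.IAFParams(c_m=3.0, g_leak=1.0, e_leak=-75.0, v_thresh=-40.0,
                         v_reset=-65.0, dt=0.02, duration_ms=500.0)
        p.i_inj = ek.Trace(np.full(int(500 / 0.02), 20.0), dt=0.02,
                           units="pA")
        v, spikes = ek.iaf_simulate(p)
        assert spikes.size == 0
        assert v.samples[-1] == pytest.approx(-75.0 + 20.0 / 1.0, abs=1e-6)

    def test_constant_current_isi_closed_form(self):
        c_m, g_l, i0 = 3.0, 1.0, 50.0
        p = ek.IAFParams(c_m=c_m, g_leak=g_l, e_leak=-75.0, v_thresh=-40.0,
                         v_reset=-65.0, t_refrac=2.0, dt=0.02,
                         duration_ms=2000.0)
        p.i_inj = ek.Trace(np.full(int(2000 / 0.02), i0), dt=0.02,
                           units="pA")
        v, spikes = ek.iaf_simulate(p)
        e_inf = -75.0 + i0 / g_l
        isi = 2.0 + (c_m / g_l) * math.log((e_inf + 65.0) / (e_inf + 40.0))
        assert abs(np.diff(spikes).mean() - isi) < p.dt

    def test_dt_mismatch_rejected(self):
        g1 = ek.Trace(np.zeros(100), dt=0.02, units="nS")
        g2 = ek.Trace(np.zeros(100), dt=0.04, units="nS")
        with pytest.raises(ValueError):
            ek.iaf_simulate(ek.IAFParams(synapses=[(g1, 0.0), (g2, 0.0)]))


def test_iaf_step_refinement_convergence(iaf_protocol):
    """Conductance-train-driven firing converges under time-step refinement:
    equal spike counts and sub-dt spike-time agreement."""
    _, coarse = iaf_protocol(0.02)
    _, fine = iaf_protocol(0.002)
    assert coarse.size == fine.size > 10
    assert np.abs(coarse - fine).max() < 0.02


def test_pipeline_recursion_sim_detect_fit(unit_quantal):
    """Simulated quantal EPSCs -> event detection -> waveform fit recovers
    the configured quantal kinetics."""
    unit, t_peak = unit_quantal
    cfg = ek.QuantalSimConfig(p_release=1.0, cv_qs=0.05, sigma_ql=0.02,
                              cv_qii=0.0, n_trials=30, noise_sd=1.0,
                              sweep_ms=12.0, stim_time=2.0, seed=10)
    sweeps, _, _ = ek.simulate_quantal(cfg)
    cfgd = ek.DetectionConfig(level=20.0, baseline_win=1.0,
                              forward_offset=0.5, peak_win=1.0,
                              onset_win=1.0)
    n_hit = sum(
        any(e.accepted and abs(e.t_cross - 2.0) < 1.0
            for e in ek.detect_threshold(tr, cfgd)) for tr in sweeps)
    assert n_hit >= 28
    mean, _ = ek.average(sweeps)
    res = ek.fit_synexp(mean, WindowSpec(1.0, 10.0),
                        hold={"n": 1.0})
    assert res.params["t0"] == pytest.approx(2.0, abs=0.05)
    assert res.params["tau_d1"] == pytest.approx(unit.tau_d1, rel=0.2)
    assert res.params["tau_r"] == pytest.approx(unit.tau_r, rel=0.3)
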