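import numpy as np
import pytest

import ephyskit as ek


@pytest.fixture(scope="session")
def quantal_kinetics():
    """Standard fast-EPSC kinetics used across the detection/fit tests."""
    return ek.SynExpParams(t0=0.0, tau_r=0.116, n=1, a_d1=86.72,
                           tau_d1=0.36, a_d2=13.28, tau_d2=2.034)


@pytest.fixture(scope="session")
def unit_quantal(quantal_kinetics):
    unit, t_peak = ek.synexp_unit_peak(quantal_kinetics)
    return unit, t_peak


@pytest.fixture(scope="session")
def event_fixture():
    """20 EPSCs of -20 pA on noise SD 2 pA (SNR 10), >= 50 ms apart."""
    trace, truth = ek.synth_event_trace(
        20, amp_mean=-20.0, amp_sd=0.0, noise_sd=2.0, min_gap=50.0,
        duration_ms=1500.0, dt=0.02, seed=7)
    return trace, truth


@pytest.fixture(scope="session")
def detection_config():
    """Threshold-detector settings typical for miniature-EPSC search."""
    return ek.DetectionConfig(polarity="neg", level_mode="absolute",
                              level=6.0, baseline_win=5.0,
                              forward_offset=2.5, lowpass_fc=1.0)


@pytest.fixture(scope="session")
def epsc_template(unit_quantal):
    """3-ms unit-peak template with a 0.2-ms leading baseline."""
    unit, _ = unit_quantal
    t = 0.02 * np.arange(int(3.0 / 0.02))
    return ek.synexp_eval(unit, t - 0.2)


def match_times(detected, truth, tol_ms):
    """Greedy one-to-one matching; returns number of matched truth times."""
    detected = sorted(detected)
    used = set()
    n = 0
    for tk in truth:
        best = None
        for j, td in enumerate(detected):
            if j in used or abs(td - tk) > tol_ms:
                continue
            if best is None or abs(td - tk) < abs(detected[best] - tk):
                best = j
        if best is not None:
            used.add(best)
            n += 1
    return n


@pytest.fixture(scope="session")
def time_matcher():
    return match_times


def stp_iaf_protocol(dt, length=800.0):
    """Conductance-train-driven integrate-and-fire protocol: 4 Poisson
    inputs through depressing direct+spillover synapses plus a tonic
    inhibitory conductance."""
    from dataclasses import replace
    trains = [ek.poisson_times(ek.TrainSpec(30.0, length, 1.0, seed=s))
              for s in range(4)]
    unit, _ = ek.synexp_unit_peak(ek.SynExpParams(
        tau_r=0.2, n=1, a_d1=0.8, tau_d1=1.5, a_d2=0.2, tau_d2=10.0))

    def scale(u, f):
        return replace(u, a_d1=u.a_d1 * f, a_d2=u.a_d2 * f)

    direct = ek.RPParams(p_inf=0.14, tau_r=131.0, g_max=scale(unit, 4.0))
    spill = ek.RPParams(p_inf=0.68, tau_r=14.85, g_max=scale(unit, 1.0),
                        label="spillover")
    g = ek.stp_conductance_train(trains, direct, spill, dt, length)
    tonic = ek.Trace(np.full(g.n, 0.27), dt=dt, units="nS")
    params = ek.IAFParams(c_m=3.0, g_leak=0.7, e_leak=-75.0, v_thresh=-45.0,
                          v_reset=-65.0, t_refrac=2.0,
                          synapses=[(g, 0.0), (tonic, -75.0)])
    return ek.iaf_simulate(params)


@pytest.fixture(scope="session")
def iaf_protocol():
    return stp_iaf_protocol
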