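import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

import ephyskit as ek
from ephyskit.trace import WindowSpec
from scipy import stats


def make_set(arrs, sets=None, dt=1.0):
    traces = [ek.Trace(np.asarray(a, float), dt=dt) for a in arrs]
    return ek.SweepSet(traces, sets=sets or {})


class TestSelect:
    def test_or_combines_sets(self):
        ss = make_set([[0], [1], [2]], sets={"Fast": [1, 0, 1],
                                             "Fast2": [0, 1, 0]})
        assert len(ss.select("Fast OR Fast2")) == 3

    def test_all_excludes_setx(self):
        ss = make_set([[0], [1], [2]], sets={"SetX": [0, 0, 1]})
        sel = ss.select("All")
        assert [tr.samples[0] for tr in sel] == [0, 1]

    def test_contradiction_is_empty(self):
        ss = make_set([[0], [1]], sets={"Set1": [1, 1]})
        assert len(ss.select("Set1 AND NOT Set1")) == 0

    def test_unknown_set_named_in_error(self):
        ss = make_set([[0]], sets={"Set1": [1]})
        with pytest.raises(ValueError, match="Bogus"):
            ss.select("Bogus")


class TestBaseline:
    def test_constant_trace_zeroed(self):
        tr = ek.Trace(np.full(10, 5.0), dt=1.0)
        out = ek.baseline_subtract(tr, WindowSpec(0, 9))
        assert np.all(out.samples == 0)

    def test_partial_window_mean(self):
        tr = ek.Trace([1, 2, 3, 4], dt=1.0)
        out = ek.baseline_subtract(tr, WindowSpec(0, 1))
        np.testing.assert_allclose(out.samples, [-0.5, 0.5, 1.5, 2.5])

    def test_idempotent(self):
        rng = np.random.default_rng(0)
        tr = ek.Trace(rng.normal(10, 2, 100), dt=0.5)
        w = WindowSpec(0, 10)
        once = ek.baseline_subtract(tr, w)
        twice = ek.baseline_subtract(once, w)
        np.testing.assert_allclose(twice.samples, once.samples, atol=1e-12)

    def test_disjoint_window_errors(self):
        tr = ek.Trace([1, 2], dt=1.0)
        with pytest.raises(ValueError):
            ek.baseline_subtract(tr, WindowSpec(10, 20))


class TestSmoothBinomial:
    def test_zero_passes_identity(self):
        tr = ek.Trace([1.0, 5.0, 2.0], dt=1.0)
        np.testing.assert_array_equal(ek.smooth_binomial(tr, 0).samples,
                                      tr.samples)

    def test_impulse_one_pass(self):
        tr = ek.Trace([0, 0, 1, 0, 0], dt=1.0)
        np.testing.assert_allclose(ek.smooth_binomial(tr, 1).samples,
                                   [0, 0.25, 0.5, 0.25, 0])

    def test_n_passes_equal_composed_kernel(self):
        # oracle: direct convolution with the composed binomial kernel,
        # compared away from the edges
        rng = np.random.default_rng(1)
        y = rng.normal(size=64)
        tr = ek.Trace(y, dt=1.0)
        for n, kernel in [(2, np.array([1, 4, 6, 4, 1]) / 16.0)]:
            out = ek.smooth_binomial(tr, n).samples
            ref = np.convolve(y, kernel, mode="same")
            np.testing.assert_allclose(out[n:-n], ref[n:-n], atol=1e-12)


class TestLowpass:
    def test_dc_gain_unity(self):
        tr = ek.Trace(np.full(1000, 3.0), dt=0.02)
        np.testing.assert_allclose(ek.lowpass(tr, 1.0).samples, 3.0)

    def test_minus3db_at_fc(self):
        dt = 0.02
        f_c = 1.0  # kHz
        t = dt * np.arange(50000)
        tr = ek.Trace(np.sin(2 * np.pi * f_c * t), dt=dt)
        out = ek.lowpass(tr, f_c).samples[5000:-5000]
        ratio = out.std() / tr.samples[5000:-5000].std()
        assert ratio == pytest.approx(1 / np.sqrt(2), rel=0.02)

    def test_noise_variance_reduced(self):
        rng = np.random.default_rng(2)
        tr = ek.Trace(rng.normal(size=20000), dt=0.02)
        assert ek.lowpass(tr, 1.0).samples.var() < tr.samples.var()

    def test_fc_above_nyquist_errors(self):
        tr = ek.Trace(np.zeros(10), dt=0.02)
        with pytest.raises(ValueError):
            ek.lowpass(tr, 30.0)


class TestAlignInterp:
    def test_zero_offsets_identity(self):
        ss = make_set([[0, 1], [2, 3]])
        out = ek.align(ss, [0, 0])
        assert [tr.t_start for tr in out] == [0, 0]

    def test_offset_shifts_t_start(self):
        ss = make_set([[0, 1]])
        assert ek.align(ss, [5.0])[0].t_start == -5.0

    def test_offset_count_mismatch(self):
        with pytest.raises(ValueError):
            ek.align(make_set([[0, 1]]), [1.0, 2.0])

    def test_interpolation_exact_on_lines(self):
        t = 0.06 * np.arange(50)
        ss = ek.SweepSet([ek.Trace(2.0 * t + 1.0, dt=0.06)])
        out = ek.interpolate_common(ss, 0.02)
        np.testing.assert_allclose(out[0].samples,
                                   2.0 * out[0].times() + 1.0, atol=1e-12)

    def test_interpolation_second_order_bound(self):
        dt_in = 0.06
        t = dt_in * np.arange(200)
        omega = 2 * np.pi * 0.5  # rad/ms
        ss = ek.SweepSet([ek.Trace(np.sin(omega * t), dt=dt_in)])
        out = ek.interpolate_common(ss, 0.02)
        err = np.abs(out[0].samples - np.sin(omega * out[0].times()))
        assert err.max() <= dt_in ** 2 / 8 * omega ** 2 + 1e-12


class TestAverageCombine:
    def test_single_sweep(self):
        ss = make_set([[1.0, 2.0]])
        mean, stdv = ek.average(ss)
        np.testing.assert_array_equal(mean.samples, [1, 2])
        np.testing.assert_array_equal(stdv.samples, [0, 0])

    def test_two_sweeps(self):
        mean, stdv = ek.average(make_set([[0, 0], [2, 2]]))
        np.testing.assert_allclose(mean.samples, [1, 1])
        np.testing.assert_allclose(stdv.samples, np.sqrt(2) * np.ones(2))

    def test_residuals_average_to_zero(self):
        rng = np.random.default_rng(3)
        ss = make_set(list(rng.normal(size=(5, 20))))
        mean, _ = ek.average(ss)
        resid = [ek.pointwise_combine(tr, mean, "subtract") for tr in ss]
        np.testing.assert_allclose(np.mean([r.samples for r in resid], axis=0),
                                   0.0, atol=1e-12)

    def test_mismatched_grids_error(self):
        ss = make_set([[1, 2], [1, 2, 3]])
        with pytest.raises(ValueError, match="interpolate_common"):
            ek.average(ss)

    def test_subtract_self_is_zero(self):
        tr = ek.Trace([1.0, -2.0, 3.0], dt=1.0)
        assert np.all(ek.pointwise_combine(tr, tr, "subtract").samples == 0)

    def test_current_over_voltage_gives_ns(self):
        i = ek.Trace([60.0, 120.0], dt=1.0, units="pA")
        v = ek.Trace([60.0, 60.0], dt=1.0, units="mV")
        g = ek.pointwise_combine(i, v, "divide")
        assert g.units == "nS"
        np.testing.assert_allclose(g.samples, [1000.0, 2000.0])

    def test_divide_by_zero_errors(self):
        tr = ek.Trace([1.0, 2.0], dt=1.0)
        with pytest.raises(ZeroDivisionError):
            ek.pointwise_combine(tr, 0.0, "divide")


class TestClipConcat:
    def test_empty_interval_list_identity(self):
        tr = ek.Trace([1.0, 2.0, 3.0], dt=1.0)
        np.testing.assert_array_equal(ek.clip_segments(tr, []).samples,
                                      tr.samples)

    def test_flat_trace_unchanged(self):
        tr = ek.Trace(np.full(20, 4.0), dt=1.0)
        out = ek.clip_segments(tr, [WindowSpec(5, 10)])
        np.testing.assert_allclose(out.samples, 4.0)

    def test_artifact_removed(self):
        rng = np.random.default_rng(4)
        y = rng.normal(0, 1.0, 500)
        y[200:210] += 100.0  # artifact spike
        tr = ek.Trace(y, dt=0.02)
        out = ek.clip_segments(tr, [WindowSpec(0.02 * 199, 0.02 * 211)])
        assert np.abs(out.samples[199:212]).max() < 3.0

    def test_overlapping_intervals_error(self):
        tr = ek.Trace(np.zeros(100), dt=1.0)
        with pytest.raises(ValueError):
            ek.clip_segments(tr, [WindowSpec(5, 15), WindowSpec(10, 20)])

    def test_concatenate_values_and_length(self):
        out = ek.concatenate(make_set([[1, 2], [3]]))
        np.testing.assert_array_equal(out.samples, [1, 2, 3])
        many = make_set([np.zeros(50000)] * 17)
        assert ek.concatenate(many).n == 17 * 50000

    def test_concatenate_dt_mismatch(self):
        ss = ek.SweepSet([ek.Trace([1.0], dt=1.0), ek.Trace([2.0], dt=2.0)])
        with pytest.raises(ValueError):
            ek.concatenate(ss)


class TestHistogram:
    def test_single_value(self):
        centers, counts = ek.histogram([0.005], 0.01, 0.0)
        assert counts.tolist() == [1]
        assert centers[0] == pytest.approx(0.005)

    def test_count_preserved(self):
        rng = np.random.default_rng(5)
        v = rng.uniform(0, 1, 1000)
        _, counts = ek.histogram(v, 0.1, 0.0)
        assert counts.sum() == 1000

    def test_gaussian_chi2_not_rejected(self):
        rng = np.random.default_rng(6)
        v = rng.normal(0, 1, 20000)
        centers, counts = ek.histogram(v, 0.25, 0.0)
        p = stats.norm.cdf(centers + 0.125) - stats.norm.cdf(centers - 0.125)
        keep = 20000 * p > 10
        chi2 = ((counts[keep] - 20000 * p[keep]) ** 2 / (20000 * p[keep])).sum()
        assert chi2 < stats.chi2.ppf(0.99, keep.sum() - 1)


@settings(deadline=None, derandomize=True, max_examples=30)
@given(arrays(np.float64, st.integers(4, 64),
              elements=st.floats(-1e3, 1e3)),
       st.integers(0, 4))
def test_binomial_smoothing_equals_iterated_convolution(y, n):
    """Oracle: n passes of (1,2,1)/4 == direct convolution of the
    reflect-padded array, applied n times."""
    out = ek.smooth_binomial(ek.Trace(y, dt=1.0), n).samples
    ref = y.copy()
    for _ in range(n):
        padded = np.concatenate([ref[1:2], ref, ref[-2:-1]])
        ref = np.convolve(padded, [0.25, 0.5, 0.25], mode="valid")
    np.testing.assert_allclose(out, ref, atol=1e-9)


@settings(deadline=None, derandomize=True, max_examples=30)
@given(arrays(np.float64, st.integers(1, 200),
              elements=st.floats(-100, 100)),
       st.floats(0.01, 10.0))
def test_histogram_conserves_counts(values, bin_width):
    _, counts = ek.histogram(values, bin_width)
    assert counts.sum() == np.isfinite(values).sum()


def test_every_transform_appends_one_note():
    tr = ek.Trace(np.linspace(0, 1, 64), dt=0.5)
    transforms = [
        lambda t: ek.baseline_subtract(t, WindowSpec(0, 5)),
        lambda t: ek.smooth_binomial(t, 2),
        lambda t: ek.lowpass(t, 0.5),
        lambda t: ek.pointwise_combine(t, 2.0, "multiply"),
        lambda t: ek.clip_segments(t, [WindowSpec(5, 10)]),
        lambda t: ek.normalize(t),
        lambda t: ek.differentiate(t),
    ]
    for f in transforms:
        out = f(tr)
        assert len(out.notes) == len(tr.notes) + 1
        assert out.n == tr.n
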