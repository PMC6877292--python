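"""Leak-scoring contracts: fits, decoupling, AUC, rate recovery."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bbbflux.errors import FitError, TraceError
from bbbflux.paracellular import (
    ExponentialFit,
    blood_clearance_fit,
    compute_auc,
    decouple_sequential,
    estimate_leak_rate,
    extrapolate_fit,
    fit_exponential,
    subtract_background,
)
from bbbflux.stack_ops import IntensityTrace
from bbbflux.synthetic import TracerSpec

MINUTES = np.arange(0.0, 31.0)


def _growth_trace(a, b, c, times=MINUTES, t0=None):
    t0 = times[0] if t0 is None else t0
    return IntensityTrace(times, a + b * (1 - np.exp(-c * (times - t0))))


class TestSubtractBackground:
    def test_zero_background_identity(self):
        tr = IntensityTrace([0, 1], [5.0, 8.0])
        assert np.array_equal(subtract_background(tr, 0.0).values, tr.values)

    def test_constant_trace_to_zero(self):
        tr = IntensityTrace([0, 1, 2], [10.0, 10.0, 10.0])
        assert np.allclose(subtract_background(tr, 10.0).values, 0.0)

    def test_clipping_logged(self, caplog):
        tr = IntensityTrace([0, 1], [5.0, 8.0])
        import logging

        with caplog.at_level(logging.INFO, logger="bbbflux.paracellular"):
            out = subtract_background(tr, 6.0)
        assert np.allclose(out.values, [0.0, 2.0])
        assert "clipped 1" in caplog.text

    def test_overlarge_background_warns(self):
        tr = IntensityTrace([0, 1, 2], [10.0, 20.0, 30.0])
        with pytest.warns(UserWarning, match="mis-estimated"):
            subtract_background(tr, 25.0)


class TestFitExponential:
    def test_growth_recovery_to_four_decimals(self):
        tr = _growth_trace(0.0, 2.0, 0.05)
        fit = fit_exponential(tr, "saturating_growth")
        assert fit.a == pytest.approx(0.0, abs=1e-4)
        assert fit.b == pytest.approx(2.0, rel=1e-4)
        assert fit.c == pytest.approx(0.05, rel=1e-4)

    def test_constant_data_contract(self):
        tr = IntensityTrace(MINUTES, np.full_like(MINUTES, 4.2))
        fit = fit_exponential(tr, "saturating_growth")
        assert np.allclose(fit(MINUTES), 4.2, atol=1e-8)

    def test_decay_recovery_and_extrapolation(self):
        t = MINUTES
        tr = IntensityTrace(t, 1.0 + 5.0 * np.exp(-0.1 * t))
        fit = fit_exponential(tr, "decay")
        assert fit.c == pytest.approx(0.1, rel=1e-4)
        # closed form at t=60: 1 + 5 e^-6
        assert extrapolate_fit(fit, np.array([60.0]))[0] == pytest.approx(
            1.0124, abs=5e-4
        )

    def test_too_few_points_rejected(self):
        tr = IntensityTrace([0, 1, 2, 3], [1.0, 2.0, 3.0, 4.0])
        with pytest.raises(FitError):
            fit_exponential(tr)

    def test_noiseless_model_rmse_near_zero(self):
        tr = _growth_trace(1.0, 3.0, 0.2)
        assert fit_exponential(tr).rmse < 1e-8


class TestExtrapolate:
    def test_inside_window_matches_fit(self):
        tr = _growth_trace(0.5, 2.0, 0.08)
        fit = fit_exponential(tr)
        assert np.allclose(extrapolate_fit(fit, tr.times_min), tr.values,
                           atol=1e-6)

    def test_growth_asymptote(self):
        fit = ExponentialFit("saturating_growth", 1.0, 2.0, 0.1, 0.0, (0, 30))
        assert extrapolate_fit(fit, np.array([1e6]))[0] == pytest.approx(3.0)

    def test_decay_c_zero_constant(self):
        fit = ExponentialFit("decay", 1.0, 2.0, 0.0, 0.0, (0, 30))
        assert np.allclose(extrapolate_fit(fit, np.array([0.0, 50.0])), 3.0)

    def test_growth_extrapolation_never_decreases(self):
        fit = ExponentialFit("saturating_growth", 0.0, 5.0, 0.03, 0.0, (0, 30))
        t = np.linspace(0, 300, 100)
        assert (np.diff(extrapolate_fit(fit, t)) >= -1e-12).all()


def _two_compartment(spec, k, lam, c0, times):
    dt = np.maximum(times - spec.injection_time_min, 0.0)
    return np.where(
        times >= spec.injection_time_min,
        k * c0 / lam * (1 - np.exp(-lam * dt)),
        0.0,
    )


class TestDecoupling:
    def test_single_tracer_unchanged(self):
        spec = TracerSpec("a", 10.0, 1.0, 2.0, 32.0)
        tr = _growth_trace(0.0, 3.0, 0.02, np.arange(2.0, 33.0))
        out, fits = decouple_sequential([(spec, tr)])
        assert np.array_equal(out[0].values, tr.values)
        assert fits[0] == []

    def test_constructed_cancellation(self):
        """A successor equal to the predecessor's continuation corrects to ~0."""
        s1 = TracerSpec("a", 10.0, 1.0, 2.0, 32.0)
        s2 = TracerSpec("b", 0.365, 32.0, 33.0, 63.0)
        t1 = np.arange(2.0, 33.0)
        t2 = np.arange(33.0, 64.0)
        a, b, c = 0.0, 6.0, 0.02
        full = lambda t: a + b * (1 - np.exp(-c * (t - 2.0)))
        tr1 = IntensityTrace(t1, full(t1))
        tr2 = IntensityTrace(t2, full(t2))  # pure continuation, no own leak
        out, _ = decouple_sequential([(s1, tr1), (s2, tr2)])
        plateau = a + b
        assert np.abs(out[1].values.mean()) < 0.02 * plateau

    def test_three_tracer_alone_equivalence(self):
        """Corrected downstream AUC matches the tracer simulated alone (<5%)."""
        c0 = 2000.0
        specs = [
            TracerSpec("a", 10.0, 1.0, 2.0, 32.0),
            TracerSpec("b", 0.643, 32.0, 33.0, 63.0),
            TracerSpec("c", 0.365, 63.0, 64.0, 94.0),
        ]
        ks = {"a": 2e-6, "b": 6e-5, "c": 5e-4}
        lams = {"a": 0.005, "b": 0.02, "c": 0.04}
        times = np.arange(0.0, 95.0)
        comp = {
            s.name: _two_compartment(s, ks[s.name], lams[s.name], c0, times)
            for s in specs
        }
        total = sum(comp.values())
        pairs = []
        for s in specs:
            w = (times >= s.window_start_min) & (times <= s.window_end_min)
            pairs.append((s, IntensityTrace(times[w], total[w])))
        corrected, _ = decouple_sequential(pairs)
        for s, corr in zip(specs[1:], corrected[1:]):
            w = (times >= s.window_start_min) & (times <= s.window_end_min)
            alone = comp[s.name][w]
            auc_corr = np.trapezoid(corr.values, corr.times_min)
            auc_alone = np.trapezoid(alone, times[w])
            assert auc_corr == pytest.approx(auc_alone, rel=0.05)

    def test_order_asymmetry(self):
        """Earlier tracers are never altered by later ones."""
        s1 = TracerSpec("a", 10.0, 1.0, 2.0, 32.0)
        s2 = TracerSpec("b", 0.365, 32.0, 33.0, 63.0)
        tr1 = _growth_trace(0.0, 3.0, 0.02, np.arange(2.0, 33.0))
        tr2 = _growth_trace(0.0, 9.0, 0.05, np.arange(33.0, 64.0))
        out, _ = decouple_sequential([(s1, tr1), (s2, tr2)])
        assert np.array_equal(out[0].values, tr1.values)


class TestBloodClearance:
    def test_constant_blood(self):
        tr = IntensityTrace(MINUTES, np.full_like(MINUTES, 120.0),
                            compartment="blood")
        fit, norm = blood_clearance_fit(tr)
        assert np.allclose(norm.values, 1.0)
        assert np.allclose(fit(MINUTES), 120.0, atol=1e-6)

    def test_decay_rate_recovery(self):
        tr = IntensityTrace(MINUTES, 100.0 * np.exp(-0.02 * MINUTES),
                            compartment="blood")
        fit, _ = blood_clearance_fit(tr)
        assert fit.c == pytest.approx(0.02, rel=0.01)

    def test_normalization_gain_invariant(self):
        v = 100.0 * np.exp(-0.03 * MINUTES)
        _, n1 = blood_clearance_fit(IntensityTrace(MINUTES, v))
        _, n2 = blood_clearance_fit(IntensityTrace(MINUTES, 7.0 * v))
        assert np.allclose(n1.values, n2.values)

    def test_increasing_blood_warns(self):
        tr = IntensityTrace(MINUTES, 10.0 + MINUTES)
        with pytest.warns(UserWarning, match="injection timing"):
            blood_clearance_fit(tr)


class TestAuc:
    def test_zero_trace(self):
        tr = IntensityTrace(MINUTES, np.zeros_like(MINUTES), units="relative")
        assert compute_auc(tr, (0.0, 30.0)) == 0.0

    def test_constant_rectangle(self):
        tr = IntensityTrace(MINUTES, np.full_like(MINUTES, 0.5),
                            units="relative")
        assert compute_auc(tr, (0.0, 30.0)) == pytest.approx(15.0)

    def test_linear_ramp_exact(self):
        tr = IntensityTrace(MINUTES, MINUTES / 30.0, units="relative")
        assert compute_auc(tr, (0.0, 30.0)) == pytest.approx(15.0)

    def test_uncovered_window_rejected(self):
        tr = IntensityTrace(MINUTES, np.zeros_like(MINUTES))
        with pytest.raises(TraceError):
            compute_auc(tr, (10.0, 45.0))

    @settings(deadline=None, max_examples=25)
    @given(
        alpha=st.floats(-3, 3),
        beta=st.floats(-3, 3),
        seed=st.integers(0, 100),
    )
    def test_linearity(self, alpha, beta, seed):
        rng = np.random.default_rng(seed)
        x = rng.random(MINUTES.size)
        y = rng.random(MINUTES.size)
        w = (0.0, 30.0)
        lhs = compute_auc(IntensityTrace(MINUTES, alpha * x + beta * y), w)
        rhs = alpha * compute_auc(
            IntensityTrace(MINUTES, x), w
        ) + beta * compute_auc(IntensityTrace(MINUTES, y), w)
        assert lhs == pytest.approx(rhs, abs=1e-9)


class TestLeakRate:
    def _traces(self, k, lam=0.04, c0=2000.0):
        t = np.arange(1.0, 32.0)
        blood = c0 * np.exp(-lam * (t - 0.0))
        paren = k * c0 / lam * (1 - np.exp(-lam * t))
        return (
            IntensityTrace(t, paren),
            IntensityTrace(t, blood, compartment="blood"),
        )

    def test_zero_leak(self):
        p, b = self._traces(0.0)
        assert abs(estimate_leak_rate(p, b)) < 1e-6

    def test_recovery_within_one_percent(self):
        p, b = self._traces(0.01)
        assert estimate_leak_rate(p, b) == pytest.approx(0.01, rel=0.01)

    def test_linearity_in_parenchyma(self):
        p, b = self._traces(1e-3)
        k1 = estimate_leak_rate(p, b)
        p2 = IntensityTrace(p.times_min, 2.0 * p.values)
        assert estimate_leak_rate(p2, b) == pytest.approx(2 * k1, rel=1e-9)

    def test_zero_blood_rejected(self):
        p, b = self._traces(1e-3)
        zero_b = IntensityTrace(b.times_min, np.zeros_like(b.values))
        with pytest.raises(TraceError):
            estimate_leak_rate(p, zero_b)


def test_auc_strictly_increasing_in_k():
    """Noiseless AUC is monotone in the leak rate at fixed clearance."""
    from bbbflux.stack_ops import relative_change

    t = np.arange(1.0, 32.0)
    offset = 50.0
    aucs = []
    for k in [1e-4, 3e-4, 1e-3, 3e-3, 1e-2]:
        paren = k * 2000.0 / 0.04 * (1 - np.exp(-0.04 * t))
        rel = relative_change(IntensityTrace(t, paren),
                              baseline_offset=offset)
        aucs.append(compute_auc(rel, (1.0, 31.0)))
    assert all(a < b for a, b in zip(aucs, aucs[1:]))
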