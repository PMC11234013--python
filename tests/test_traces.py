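"""Trace processing: background, calibration, conversion, velocities."""

import dataclasses

import numpy as np
import pytest

import raddkit as rk
from raddkit.traces import FmaxEstimate

from conftest import K1_EXCESS, K2_CLEAVAGE


def trace_from(values, role="sample", times=None, **meta):
    values = np.asarray(values, dtype=float)
    if times is None:
        times = np.arange(len(values)) * 30.0
    return rk.KineticTrace("A1", times, values, role=role, meta=meta)


class TestKineticTrace:
    def test_rejects_irregular_grid(self):
        t = np.arange(10) * 30.0
        t[5] += 1.0
        with pytest.raises(ValueError, match="interval"):
            rk.KineticTrace("A1", t, np.zeros(10))

    def test_rejects_short_and_nonfinite(self):
        with pytest.raises(ValueError):
            rk.KineticTrace("A1", np.arange(5) * 30.0, np.zeros(5))
        vals = np.zeros(10)
        vals[3] = np.nan
        with pytest.raises(ValueError):
            rk.KineticTrace("A1", np.arange(10) * 30.0, vals)


class TestBackgroundSubtraction:
    def test_self_subtraction_zeroes(self):
        tr = trace_from(np.linspace(100, 500, 12))
        out = rk.subtract_background(tr, [tr])
        assert np.allclose(out.values, 0.0)

    def test_mean_of_negatives(self):
        tr = trace_from(np.full(12, 350.0))
        negs = [trace_from(np.full(12, 100.0), "negative_tc"),
                trace_from(np.full(12, 120.0), "negative_tc")]
        out = rk.subtract_background(tr, negs)
        # per-point arithmetic oracle
        expected = tr.values - (negs[0].values + negs[1].values) / 2
        assert np.array_equal(out.values, expected)
        assert np.allclose(out.values, 240.0)

    def test_requires_negatives_and_matching_grid(self):
        tr = trace_from(np.full(12, 350.0))
        with pytest.raises(ValueError):
            rk.subtract_background(tr, [])
        shifted = trace_from(np.full(12, 100.0), "negative_tc",
                             times=np.arange(12) * 30.0 + 7.0)
        with pytest.raises(ValueError, match="grid"):
            rk.subtract_background(tr, [shifted])
        # but interpolation is available
        out = rk.subtract_background(tr, [shifted], interpolate=True)
        assert np.allclose(out.values, 250.0)


class TestFmax:
    def test_constant_controls(self):
        c1 = trace_from(np.full(20, 8000.0), "endoq_tdu_control")
        c2 = trace_from(np.full(20, 8400.0), "endoq_tdu_control")
        assert rk.estimate_fmax([c1]).value == 8000.0
        est = rk.estimate_fmax([c1, c2])
        assert est.value == 8200.0 and est.at_plateau

    def test_exponential_tail_within_bound(self, grid_1h):
        # k * t_end >= 7 guarantees the tail mean is within 0.2 % of plateau
        k = 7.5 / grid_1h[-1]
        ctl = trace_from(8000.0 * -np.expm1(-k * grid_1h), "endoq_tdu_control", times=grid_1h)
        est = rk.estimate_fmax([ctl])
        assert est.value == pytest.approx(8000.0, rel=2e-3)

    def test_exp_fit_recovers_exact_plateau(self, grid_1h):
        ctl = trace_from(
            8000.0 * -np.expm1(-K2_CLEAVAGE * grid_1h), "endoq_tdu_control", times=grid_1h
        )
        est = rk.estimate_fmax([ctl], method="exp_fit")
        assert est.value == pytest.approx(8000.0, rel=1e-9)

    def test_not_at_plateau_flagged(self, grid_1h):
        slow = trace_from(
            8000.0 * -np.expm1(-2e-4 * grid_1h), "endoq_tdu_control", times=grid_1h
        )
        est = rk.estimate_fmax([slow])
        assert isinstance(est, FmaxEstimate) and not est.at_plateau


class TestConversion:
    def test_linearity_and_endpoints(self):
        tr = trace_from([0.0, 4000.0, 8000.0] + [8000.0] * 9)
        ct = rk.to_concentration(tr, fmax_ref=8000.0, a0=1.0)
        assert ct.product[0] == 0.0
        assert ct.product[1] == pytest.approx(0.5)
        assert ct.product[2] == pytest.approx(1.0)

    def test_clipping_counted(self):
        tr = trace_from(np.full(12, 10000.0))
        ct = rk.to_concentration(tr, fmax_ref=8000.0, a0=1.0)
        assert ct.n_clipped == 12 and np.allclose(ct.product, 1.05)

    def test_noiseless_roundtrip_reproduces_generating_curve(self, grid_1h):
        p = rk.SequentialParams(k1=K1_EXCESS, k2=K2_CLEAVAGE, a0=1.0)
        truth = rk.sequential_product(grid_1h, p)
        f_bg, f_max = 2000.0, 10000.0
        raw = trace_from(f_bg + (f_max - f_bg) * truth, times=grid_1h)
        neg = trace_from(np.full_like(grid_1h, f_bg), "negative_tc", times=grid_1h)
        ct = rk.to_concentration(rk.subtract_background(raw, [neg]), f_max - f_bg, 1.0)
        assert np.allclose(ct.product, truth, atol=1e-9)


class TestMaxSlope:
    def test_linear_trace_any_window(self):
        t = np.arange(20) * 30.0
        tr = trace_from(3.5 * t + 100.0, times=t)
        for w in (3, 5, 10):
            est = rk.max_slope_velocity(tr, window_points=w)
            assert est.v == pytest.approx(3.5, rel=1e-12)
            assert est.r2_window == pytest.approx(1.0)

    def test_exhaustive_window_oracle(self):
        rng = np.random.default_rng(42)
        t = np.arange(40) * 30.0
        y = np.cumsum(rng.uniform(-1.0, 3.0, size=40))
        tr = trace_from(y, times=t)
        w = 7
        est = rk.max_slope_velocity(tr, window_points=w)
        slopes = [np.polyfit(t[i : i + w], y[i : i + w], 1)[0] for i in range(len(t) - w + 1)]
        assert est.v == pytest.approx(max(slopes), rel=1e-10)
        assert est.window_start_index == int(np.argmax(slopes))

    def test_one_phase_bound_and_refinement(self):
        # max slope of an exponential rise is bounded by the initial derivative
        k, plateau = K2_CLEAVAGE, 1.0
        prev = 0.0
        for dt in (60.0, 30.0, 10.0, 1.0, 0.1):
            t = np.arange(0.0, 1200.0, dt)
            tr = trace_from(rk.one_phase_association(t, k, plateau), times=t)
            v = rk.max_slope_velocity(tr, window_points=3).v
            assert v <= plateau * k and v >= prev
            prev = v
        assert prev == pytest.approx(plateau * k, rel=1e-3)

    def test_affine_invariance_and_scaling(self):
        rng = np.random.default_rng(7)
        tr = trace_from(np.cumsum(rng.uniform(0, 2, 30)))
        base = rk.max_slope_velocity(tr, 5)
        shifted = rk.max_slope_velocity(dataclasses.replace(tr, values=tr.values + 500.0), 5)
        scaled = rk.max_slope_velocity(dataclasses.replace(tr, values=3.0 * tr.values), 5)
        assert shifted.v == pytest.approx(base.v, rel=1e-12)
        assert shifted.window_start_index == base.window_start_index
        assert scaled.v == pytest.approx(3.0 * base.v, rel=1e-12)

    def test_window_errors(self):
        tr = trace_from(np.arange(10.0))
        with pytest.raises(ValueError):
            rk.max_slope_velocity(tr, window_points=11)
        with pytest.raises(ValueError):
            rk.max_slope_velocity(tr, window_points=2)


class TestTrimAndEndpoint:
    def test_trim_identity_and_count(self, grid_1h):
        tr = trace_from(np.arange(grid_1h.size, dtype=float), times=grid_1h)
        assert np.array_equal(rk.trim_settling(tr, 0.0).times, tr.times)
        cut = rk.trim_settling(tr, 300.0)
        assert len(cut.times) == len(tr.times) - 10 and cut.times[0] == 300.0

    def test_trim_boundary_keeps_first_at_or_after(self, grid_1h):
        tr = trace_from(np.arange(grid_1h.size, dtype=float), times=grid_1h)
        cut = rk.trim_settling(tr, 299.0)
        assert cut.times[0] == 300.0

    def test_endpoint_rules(self):
        tr = trace_from(np.arange(12, dtype=float))
        assert rk.endpoint_signal(tr, tr.times[-1]) == 11.0
        assert rk.endpoint_signal(tr, 45.0) == 1.0  # last scan at or before 45 s
        with pytest.raises(ValueError):
            rk.endpoint_signal(tr, -5.0)
        const = trace_from(np.full(12, 7.0))
        assert rk.endpoint_signal(const, 200.0) == 7.0
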