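"""Parameter inference: round trips, degenerate designs, uncertainty."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

import raddkit as rk
from raddkit.fitting import FitError, confidence_interval

from conftest import IC50_REF, K1_EXCESS, K1_LOW, K2_CLEAVAGE, MM_KM, MM_VMAX


def conc_trace(times, product, well_id="A1", a0=1.0, role="sample", **meta):
    return rk.ConcentrationTrace(
        well_id=well_id, times=np.asarray(times, float), product=np.asarray(product, float),
        fmax_ref=8000.0, a0=a0, role=role, meta=meta,
    )


def one_phase_traces(times, k, plateau=1.0, n=3, sigma=0.0, rng=None):
    out = []
    for i in range(n):
        y = rk.one_phase_association(times, k, plateau)
        if sigma:
            y = y + rng.normal(0, sigma, size=times.shape)
        out.append(conc_trace(times, y, well_id=f"B{i+1}", role="endoq_tdu_control"))
    return out


def sequential_traces(times, k1, k2, a0=1.0, n=3, sigma=0.0, rng=None):
    out = []
    p = rk.SequentialParams(k1=k1, k2=k2, a0=a0)
    for i in range(n):
        y = rk.sequential_product(times, p)
        if sigma:
            y = y + rng.normal(0, sigma, size=times.shape)
        out.append(conc_trace(times, y, well_id=f"A{i+1}", a0=a0))
    return out


class TestOnePhaseFit:
    def test_noiseless_round_trip(self, grid_1h):
        fit = rk.fit_one_phase(one_phase_traces(grid_1h, K2_CLEAVAGE), plateau=1.0)
        assert fit.k == pytest.approx(K2_CLEAVAGE, rel=1e-6)
        assert fit.r2 == pytest.approx(1.0)
        assert fit.k_ci[0] <= fit.k <= fit.k_ci[1]

    def test_constant_zero_data_flagged(self, grid_1h):
        flat = [conc_trace(grid_1h, np.zeros_like(grid_1h))]
        try:
            fit = rk.fit_one_phase(flat, plateau=1.0)
            assert fit.at_bound and fit.k <= 1e-8
        except FitError:
            pass  # non-convergence diagnostic is equally acceptable

    def test_ci_coverage_under_noise(self, grid_1h):
        # 3 replicates, 121 points, sigma = 0.01 uM
        hits = 0
        reps = 100
        for seed in range(reps):
            rng = np.random.default_rng(seed)
            traces = one_phase_traces(grid_1h, K2_CLEAVAGE, sigma=0.01, rng=rng)
            fit = rk.fit_one_phase(traces, plateau=1.0)
            hits += fit.k_ci[0] <= K2_CLEAVAGE <= fit.k_ci[1]
        assert hits / reps >= 0.90


class TestSequentialFit:
    @pytest.mark.parametrize("k1_true", [K1_EXCESS, K1_LOW])
    def test_noiseless_round_trip(self, grid_1h, k1_true):
        traces = sequential_traces(grid_1h, k1_true, K2_CLEAVAGE)
        fit = rk.fit_sequential(traces, k2=K2_CLEAVAGE, a0=1.0)
        assert fit.k == pytest.approx(k1_true, rel=1e-6)
        assert fit.fixed == {"k2": K2_CLEAVAGE, "a0": 1.0}

    def test_fast_cleavage_limit_consistency(self, grid_1h):
        # data from a single first-order step; with k2 huge the sequential
        # model collapses and k1 must match the generating rate
        k = 1e-3
        traces = one_phase_traces(grid_1h, k, plateau=1.0)
        fit = rk.fit_sequential(traces, k2=1e3 * k, a0=1.0)
        assert fit.k == pytest.approx(k, rel=0.01)

    def test_identical_to_controls_diverges(self, grid_1h):
        # samples that look like cleavage-only controls: deamination is not
        # rate-limiting, so k1 runs to the upper bound and is flagged
        traces = one_phase_traces(grid_1h, K2_CLEAVAGE, plateau=1.0)
        fit = rk.fit_sequential(traces, k2=K2_CLEAVAGE, a0=1.0)
        assert fit.at_bound or fit.k > 1.0


class TestTwoStage:
    def test_round_trip_and_k2_fixed(self, grid_1h):
        controls = one_phase_traces(grid_1h, K2_CLEAVAGE)
        samples = sequential_traces(grid_1h, K1_EXCESS, K2_CLEAVAGE)
        res = rk.two_stage_single_turnover(controls, samples, a0=1.0, enzyme_uM=5.0, km_uM=MM_KM)
        assert res.endoq_fit.k == pytest.approx(K2_CLEAVAGE, rel=1e-6)
        assert res.deaminase_fit.k == pytest.approx(K1_EXCESS, rel=1e-6)
        assert res.deaminase_fit.fixed["k2"] == res.endoq_fit.k
        assert res.single_turnover and res.rate_label == "kcat"

    def test_low_enzyme_is_kobs(self, grid_1h):
        controls = one_phase_traces(grid_1h, K2_CLEAVAGE)
        samples = sequential_traces(grid_1h, K1_LOW, K2_CLEAVAGE)
        res = rk.two_stage_single_turnover(controls, samples, a0=1.0, enzyme_uM=1.0, km_uM=MM_KM)
        assert not res.single_turnover and res.rate_label == "kobs"

    def test_missing_controls_errors(self, grid_1h):
        samples = sequential_traces(grid_1h, K1_EXCESS, K2_CLEAVAGE)
        with pytest.raises(ValueError, match="stage 1"):
            rk.two_stage_single_turnover([], samples)

    def test_stage_coupling_sign(self, grid_1h):
        # overestimating the cleavage rate must push the deamination rate down
        samples = sequential_traces(grid_1h, K1_EXCESS, K2_CLEAVAGE)
        k1_at = lambda k2: rk.fit_sequential(samples, k2=k2, a0=1.0).k
        assert k1_at(1.1 * K2_CLEAVAGE) < k1_at(K2_CLEAVAGE)


class TestMMFit:
    @staticmethod
    def exact_table(s_levels=(1.0, 2.0, 4.0, 8.0, 16.0), n=3, sigma=0.0, rng=None):
        p = rk.MMParams(km=MM_KM, vmax=MM_VMAX)
        rows = []
        for s in s_levels:
            for i in range(n):
                v = float(rk.mm_velocity(s, p))
                if sigma:
                    v += rng.normal(0, sigma)
                rows.append({"substrate_uM": s, "v_uM_per_s": v, "replicate": i})
        return pd.DataFrame(rows)

    def test_noiseless_round_trip(self):
        fit = rk.fit_mm(self.exact_table(), enzyme=0.1)
        assert fit.km == pytest.approx(MM_KM, rel=1e-6)
        assert fit.vmax == pytest.approx(MM_VMAX, rel=1e-6)
        assert fit.kcat == pytest.approx(MM_VMAX / 0.1, rel=1e-6)
        assert fit.kcat * fit.enzyme == pytest.approx(fit.vmax, rel=1e-12)

    def test_noisy_recovery(self):
        # sigma = 5 % of Vmax per velocity point
        errs = []
        for seed in range(200):
            rng = np.random.default_rng(seed)
            fit = rk.fit_mm(self.exact_table(sigma=0.05 * MM_VMAX, rng=rng), enzyme=0.1)
            errs.append(abs(fit.km / MM_KM - 1.0))
        assert np.median(errs) < 0.15

    def test_flat_velocities_unidentifiable(self):
        table = pd.DataFrame(
            {"substrate_uM": [1.0, 2.0, 4.0, 8.0], "v_uM_per_s": [1e-4] * 4, "replicate": 0}
        )
        fit = rk.fit_mm(table, enzyme=0.1)
        assert fit.unidentifiable
        assert not np.isfinite(fit.km_ci[1])

    def test_needs_four_substrate_levels(self):
        with pytest.raises(ValueError, match="4 distinct"):
            rk.fit_mm(self.exact_table(s_levels=(1.0, 2.0, 4.0)), enzyme=0.1)


class TestPercentActivity:
    def test_basic_ratios(self):
        out = rk.percent_activity([2e-4, 1e-4, 0.0], 2e-4)
        assert np.allclose(out, [100.0, 50.0, 0.0])
        with pytest.raises(ValueError):
            rk.percent_activity([1.0], 0.0)


class TestIC50Fit:
    CONCS = (78.0, 155.0, 310.0, 450.0, 620.0)

    @classmethod
    def exact_points(cls, ic50=IC50_REF, hill=1.0, scale=1.0):
        p = rk.DoseResponseParams(ic50=ic50, hill=hill)
        return [(c * scale, float(rk.dose_response(c, p))) for c in cls.CONCS]

    def test_noiseless_round_trip(self):
        fit = rk.fit_ic50(self.exact_points())
        assert fit.ic50 == pytest.approx(IC50_REF, rel=1e-6)
        assert fit.hill == pytest.approx(1.0, rel=1e-5)
        assert fit.in_span and not fit.extrapolated
        assert fit.constraints == {"top": 100.0, "bottom": 0.0}

    def test_scale_equivariance(self):
        # doubling all concentrations (responses untouched) doubles the IC50
        base = rk.fit_ic50(self.exact_points())
        doubled = rk.fit_ic50(self.exact_points(scale=2.0))
        assert doubled.ic50 == pytest.approx(2.0 * base.ic50, rel=1e-6)
        assert doubled.hill == pytest.approx(base.hill, rel=1e-6)

    def test_all_high_responses_flagged(self):
        pts = [(c, 100.0) for c in self.CONCS]
        fit = rk.fit_ic50(pts)
        assert fit.extrapolated

    def test_needs_four_concentrations(self):
        with pytest.raises(ValueError, match="4 distinct"):
            rk.fit_ic50([(10.0, 90.0), (100.0, 50.0), (1000.0, 10.0)])


class TestConfidenceInterval:
    def test_zero_residual_zero_width(self):
        lo, hi = confidence_interval(1.0, 0.0, 100)
        assert lo == hi == 1.0

    def test_nesting_and_truncation(self):
        ci95 = confidence_interval(1.0, 0.5, 30, level=0.95, lower_bound=0.0)
        ci99 = confidence_interval(1.0, 0.5, 30, level=0.99, lower_bound=0.0)
        assert ci99[0] <= ci95[0] and ci99[1] >= ci95[1]
        assert ci95[0] >= 0.0

    def test_width_grows_with_noise(self, grid_1h):
        widths = []
        for sigma in (0.005, 0.02):
            w = []
            for seed in range(30):
                rng = np.random.default_rng(seed)
                traces = one_phase_traces(grid_1h, K2_CLEAVAGE, sigma=sigma, rng=rng)
                fit = rk.fit_one_phase(traces, plateau=1.0)
                w.append(fit.k_ci[1] - fit.k_ci[0])
            widths.append(np.mean(w))
        assert widths[1] > widths[0]
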