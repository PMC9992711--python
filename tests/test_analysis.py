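"""Ratio computation, normalization, exponential fitting and metrics."""

import math

import numpy as np
import pytest

from gqfret.analysis import (DoseResponseFit, FretrTrace, StepFit, _hill,
                             compute_fretr, compute_snr, fit_dose_response,
                             fit_single_step, fit_t50, fit_two_step,
                             normalize_trace, percent_metrics, summarize)
from gqfret.errors import DataError, NormalizationError, ValidationError
from gqfret.photometry import ChannelTraces

from conftest import biexp_trace


def make_trace(t, fretr, t_on=10.0, t_off=25.0):
    return FretrTrace(t=np.asarray(t, float), fretr=np.asarray(fretr, float),
                      t_on=t_on, t_off=t_off)


class TestComputeFretr:
    def test_substitution(self):
        ch = ChannelTraces(t=np.arange(3.0), cfp_c=np.ones(3),
                           yfp_c=np.full(3, 1.45))
        np.testing.assert_allclose(compute_fretr(ch, 0.45).fretr, 1.0)

    def test_zero_cfactor_is_plain_ratio(self):
        ch = ChannelTraces(t=np.arange(3.0), cfp_c=np.full(3, 2.0),
                           yfp_c=np.full(3, 3.0))
        np.testing.assert_allclose(compute_fretr(ch, 0.0).fretr, 1.5)

    def test_nonpositive_donor_rejected_with_index(self):
        cfp = np.ones(5)
        cfp[3] = 0.0
        ch = ChannelTraces(t=np.arange(5.0), cfp_c=cfp, yfp_c=np.ones(5))
        with pytest.raises(DataError) as err:
            compute_fretr(ch)
        assert err.value.index == 3


class TestNormalize:
    def test_constant_trace_is_degenerate(self):
        t = np.arange(0, 30.1, 0.1)
        with pytest.raises(NormalizationError):
            normalize_trace(make_trace(t, np.ones_like(t)), "decrease")

    def test_window_means_pinned(self):
        t = np.arange(0, 30.1, 0.1)
        y = np.interp(t, [0, 10, 20, 30], [0.9, 0.9, 0.4, 0.4])
        norm = normalize_trace(make_trace(t, y), "decrease")
        base = norm.value[(t >= 5) & (t < 10)]
        plat = norm.value[(t >= 20) & (t < 25)]
        assert base.mean() == pytest.approx(1.0, abs=1e-9)
        assert plat.mean() == pytest.approx(0.0, abs=1e-9)

    def test_increasing_trace_maps_plateau_to_two(self):
        t = np.arange(0, 30.1, 0.1)
        y = np.where(t >= 10, 0.75, 0.6)
        norm = normalize_trace(make_trace(t, y), "increase")
        plat = norm.value[(t >= 20) & (t < 25)]
        assert plat.mean() == pytest.approx(2.0, abs=1e-9)

    def test_idempotence(self):
        t = np.arange(0, 30.1, 0.1)
        y = np.where(t >= 10, 0.4, 1.0) + 0.001 * np.sin(t)
        n1 = normalize_trace(make_trace(t, y), "decrease")
        n2 = normalize_trace(
            FretrTrace(t=t, fretr=n1.value, t_on=10.0, t_off=25.0), "decrease")
        np.testing.assert_allclose(n2.value, n1.value, atol=1e-9)


class TestTwoStepFit:
    def test_noiseless_biexponential_recovery(self, wt_biexp):
        fit = fit_two_step(wt_biexp, "ON")
        assert fit.tau1 == pytest.approx(0.2, rel=0.02)
        assert fit.tau2 == pytest.approx(2.0, rel=0.02)

    @pytest.mark.parametrize("tau1", [0.1, 0.3, 0.5])
    @pytest.mark.parametrize("tau2", [1.0, 2.5, 4.0])
    def test_noiseless_bias_below_two_percent(self, tau1, tau2):
        fit = fit_two_step(biexp_trace(tau1, tau2), "ON")
        assert fit.tau1 == pytest.approx(tau1, rel=0.02)
        assert fit.tau2 == pytest.approx(tau2, rel=0.02)

    def test_pure_single_exponential_leaves_no_second_component(self):
        trace = biexp_trace(0.25, 2.0, frac1=1.0)
        fit = fit_two_step(trace, "ON")
        assert abs(fit.amp2) < 0.01
        assert fit.amp1 == pytest.approx(1.0, rel=0.05)
        assert fit.tau1 == pytest.approx(0.25, rel=0.02)

    def test_off_mode_uses_washout_mark(self):
        hz, t_off = 10.0, 25.0
        t = np.arange(0, 60.0001, 1 / hz)
        rel = np.clip(t - t_off, 0, None)
        value = np.where(
            t < t_off, 0.0,
            1 - 0.5 * np.exp(-rel / 0.5) - 0.5 * np.exp(-rel / 8.0))
        trace = biexp_trace(1, 1)  # container only
        from gqfret.analysis import NormalizedTrace
        tr = NormalizedTrace(t=t, value=value, direction="decrease",
                             t_on=10.0, t_off=t_off)
        fit = fit_two_step(tr, "OFF")
        assert fit.tau1 == pytest.approx(0.5, rel=0.05)
        assert fit.tau2 == pytest.approx(8.0, rel=0.05)

    def test_window_censoring_still_finite_for_slow_step(self):
        # GDPbetaS-like: tau2 far beyond the 15-s window end
        trace = biexp_trace(0.22, 9.6, response_s=30.0)
        fit = fit_two_step(trace, "ON")
        assert math.isfinite(fit.tau2) and fit.tau2 > 0
        assert fit.tau2 == pytest.approx(9.6, rel=0.30)


class TestSingleStepFit:
    def test_noiseless_exponential_within_one_percent(self):
        trace = biexp_trace(1.45, 1.45, frac1=1.0)
        fit = fit_single_step(trace, "ON")
        assert fit.tau1 == pytest.approx(1.45, rel=0.01)

    def test_injected_delay_recovered_within_one_sample(self):
        hz, t_on, delay = 10.0, 10.0, 0.25
        t = np.arange(0, 30.0001, 1 / hz)
        rel = np.clip(t - t_on - delay, 0, None)
        value = np.where(t < t_on + delay, 1.0, np.exp(-rel / 1.45))
        from gqfret.analysis import NormalizedTrace
        tr = NormalizedTrace(t=t, value=value, direction="decrease",
                             t_on=t_on, t_off=25.0)
        fit = fit_single_step(tr, "ON")
        assert abs(fit.delay - delay) <= 1 / hz

    def test_flat_trace_flagged_unidentifiable(self, rng):
        t = np.arange(0, 30.0001, 0.1)
        value = 1.0 + 1e-4 * rng.normal(size=t.size)
        from gqfret.analysis import NormalizedTrace
        tr = NormalizedTrace(t=t, value=value, direction="decrease",
                             t_on=10.0, t_off=25.0)
        fit = fit_single_step(tr, "ON")
        assert abs(fit.amp1) < 0.01
        assert "unidentifiable" in fit.flags


class TestSnr:
    def test_substitution(self):
        t = np.arange(0, 30.1, 0.1)
        base = 0.01 * np.resize([1.0, -1.0], t.size)  # sd ~0.01
        fretr = np.where(t >= 10, -1.0 + base, base)
        tr = make_trace(t, fretr)
        n = ((t >= 5) & (t < 10)).sum()
        sd = np.std(base[(t >= 5) & (t < 10)], ddof=1)
        expected = (1.0 + sd * 0) / (sd / math.sqrt(n))
        assert compute_snr(tr) == pytest.approx(expected, rel=0.05)

    def test_sd_mode_scales_by_sqrt_n(self):
        t = np.arange(0, 30.1, 0.1)
        rng = np.random.default_rng(0)
        fretr = np.where(t >= 10, 0.0, 1.0) + 0.01 * rng.normal(size=t.size)
        tr = make_trace(t, fretr)
        n = ((t >= 5) & (t < 10)).sum()
        assert compute_snr(tr, mode="sem") / compute_snr(tr, mode="sd") == \
            pytest.approx(math.sqrt(n))

    def test_zero_variability_gives_infinity(self):
        t = np.arange(0, 30.1, 0.1)
        tr = make_trace(t, np.where(t >= 10, 0.0, 1.0))
        assert compute_snr(tr) == math.inf


class TestPercentMetrics:
    def test_two_step_hand_computed(self):
        fit = StepFit(mode="ON", delay=0.0, tau1=0.2, amp1=0.3, tau2=2.0,
                      amp2=0.1)
        pct = percent_metrics(fit=fit, kind="two_step_on", max_amplitude=0.4)
        assert pct["step1_pct"] == pytest.approx(75.0)
        assert pct["step2_pct"] == pytest.approx(25.0)
        assert pct["remainder_pct"] == pytest.approx(0.0, abs=1e-9)

    def test_single_step_off_full_recovery(self):
        fit = StepFit(mode="OFF", delay=0.0, tau1=0.5, amp1=1.0)
        pct = percent_metrics(fit=fit, kind="single_step_off",
                              max_amplitude=1.0)
        assert pct["pct_off"] == pytest.approx(100.0)

    def test_single_step_on_uses_group_average(self):
        cell = biexp_trace(0.3, 0.3, frac1=1.0)
        group = biexp_trace(0.3, 0.3, frac1=1.0)
        scaled = cell.__class__(t=cell.t, value=1 + 0.5 * (cell.value - 1),
                                direction=cell.direction, t_on=cell.t_on,
                                t_off=cell.t_off)
        pct = percent_metrics(kind="single_step_on", cell_trace=scaled,
                              group_trace=group)
        assert pct["pct_on"] == pytest.approx(50.0, rel=1e-6)

    def test_zero_max_amplitude_rejected(self):
        fit = StepFit(mode="ON", delay=0.0, tau1=0.2, amp1=0.3)
        with pytest.raises(ValidationError):
            percent_metrics(fit=fit, kind="two_step_on", max_amplitude=0.0)


class TestDoseResponse:
    def test_exact_hill_data_recovered(self):
        conc = np.geomspace(0.01, 100, 7)
        resp = _hill(conc, 0.0, 1.0, 1.0, 1.0)
        fit = fit_dose_response(conc, resp)
        assert fit.ec50 == pytest.approx(1.0, rel=1e-6)
        assert fit.hill == pytest.approx(1.0, rel=1e-6)

    def test_half_maximal_at_ec50(self):
        fit = DoseResponseFit(ec50=2.0, hill=1.3, top=1.0, bottom=0.0)
        assert _hill(fit.ec50, fit.bottom, fit.top, fit.ec50, fit.hill) == \
            pytest.approx(0.5 * (fit.top + fit.bottom))

    def test_non_spanning_data_flagged(self):
        conc = np.geomspace(10, 1000, 5)
        resp = _hill(conc, 0.0, 1.0, 0.001, 1.0)  # all saturated
        fit = fit_dose_response(conc, resp)
        assert "extrapolated_ec50" in fit.flags

    def test_too_few_concentrations_rejected(self):
        with pytest.raises(ValidationError):
            fit_dose_response([1, 2, 3], [0.1, 0.2, 0.3])


class TestT50:
    def logistic(self, t, t50, width=1.5):
        return 1.0 / (1.0 + np.exp(-(t - t50) / width))

    def test_symmetric_logistic_center(self):
        t = np.arange(0, 24.0001, 1.0)
        t50, flags = fit_t50(t, self.logistic(t, 12.0))
        assert t50 == pytest.approx(12.0, abs=1e-6)
        assert flags == ()

    def test_time_shift_equivariance(self):
        t = np.arange(0, 40.0001, 1.0)
        a, _ = fit_t50(t, self.logistic(t, 12.0))
        b, _ = fit_t50(t, self.logistic(t, 19.0))
        assert b - a == pytest.approx(7.0, abs=1e-6)

    def test_noisy_logistic_within_one_second(self, rng):
        t = np.arange(0, 60.0001, 3.0)  # 0.33 Hz sampling
        errs = []
        for _ in range(20):
            y = self.logistic(t, 24.0) + 0.05 * rng.normal(size=t.size)
            t50, _ = fit_t50(t, y)
            errs.append(abs(t50 - 24.0))
        assert np.mean(errs) < 1.0


class TestSummarize:
    def test_identical_values_zero_sem(self):
        rows = summarize({"tau": [1.5, 1.5, 1.5]}, "cond")
        assert rows[0].sem == 0.0

    def test_sem_is_sd_over_sqrt_n(self, rng):
        vals = rng.normal(2.0, 0.5, 20)
        row = summarize({"tau": list(vals)}, "cond")[0]
        assert row.n == 20
        assert row.sem == pytest.approx(np.std(vals, ddof=1) / math.sqrt(20))

    def test_single_value_sem_is_nan(self):
        row = summarize({"tau": [1.0]}, "cond")[0]
        assert math.isnan(row.sem)
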