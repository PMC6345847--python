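"""Fit quality, rejection rules and event-time extraction."""

import numpy as np
import pytest

from lisca.fitting import (
    EventRecord,
    EventSet,
    ModelFit,
    apply_time_offset,
    classify_trace,
    extract_breakdown_time,
    extract_onset_time,
    fit_trace,
    ros_production_rate,
)
from lisca.imaging import Trace
from lisca.models import EarlyModelParams, LateModelParams
from lisca.synthetic import synthesize_trace

TIMES = np.arange(181) / 6.0


def _fit_from_params(kind, params, eta=1.0, domain=(0.0, 30.0)):
    return ModelFit(
        marker_kind=kind, params=params, eta=eta, sse=0.0, null_sse=1.0,
        converged=True, domain=domain, n_samples=181,
        n_params=6 if kind == "early" else 5,
        null_n_params=3 if kind == "early" else 1,
    )


class TestFitTrace:
    def test_noiseless_early_round_trip(self):
        true = EarlyModelParams(a0=800, a1=60, a2=2, t_b=11, tau_b=0.3, c=120)
        trace = synthesize_trace("early", true, noise_sd=0.0)
        fit = fit_trace(trace, "early")
        assert fit.converged
        assert fit.sse < 1e-9
        assert fit.params.t_b == pytest.approx(true.t_b, abs=1e-3)
        assert fit.params.tau_b == pytest.approx(true.tau_b, abs=1e-3)

    def test_noiseless_late_round_trip(self):
        true = LateModelParams(B=150, A=2500, t_h=16, tau_o=0.15, lam=0.08)
        trace = synthesize_trace("late", true, noise_sd=0.0)
        fit = fit_trace(trace, "late")
        assert fit.sse < 1e-6
        assert fit.params.t_h == pytest.approx(true.t_h, abs=1e-3)

    def test_eta_estimates_noise_scale(self):
        true = EarlyModelParams(a0=800, a1=60, a2=2, t_b=11, tau_b=0.3, c=120)
        trace = synthesize_trace("early", true, noise_sd=50.0, rng=3)
        fit = fit_trace(trace, "early")
        assert 35 < fit.eta < 65

    def test_too_few_samples_gives_rejection_record(self):
        trace = Trace(0, "LMP", TIMES[:5], np.ones(5))
        fit = fit_trace(trace, "early")
        assert fit.failure == "too-few-samples"
        assert classify_trace(fit) == "rejected:too-few-samples"

    def test_non_finite_input_raises(self):
        y = np.ones(181)
        y[5] = np.nan
        with pytest.raises(ValueError, match="finite"):
            fit_trace(Trace(0, "LMP", TIMES, y), "early")

    def test_reduced_problem_matches_grid_oracle(self, acceptance_module):
        gap = acceptance_module.sse_oracle_gap(202)
        assert gap <= 1e-6

    def test_fixing_unknown_parameter_rejected(self):
        trace = Trace(0, "LMP", TIMES, np.ones(181))
        with pytest.raises(ValueError, match="unknown parameter"):
            fit_trace(trace, "early", fixed={"t_h": 1.0})


class TestClassifyTrace:
    def test_zero_variance_trace_rejected_for_amplitude(self):
        fit = fit_trace(Trace(0, "LMP", TIMES, np.full(181, 42.0)), "late")
        assert classify_trace(fit) == "rejected:amplitude"

    def test_pure_noise_trace_rejected(self, rng):
        y = 100 + rng.standard_normal(181)
        for kind in ("early", "late"):
            fit = fit_trace(Trace(0, "x", TIMES, y), kind)
            assert classify_trace(fit).startswith("rejected")

    def test_clean_event_trace_accepted(self):
        true = LateModelParams(B=150, A=2500, t_h=16, tau_o=0.15, lam=0.05)
        trace = synthesize_trace("late", true, noise_sd=250.0, rng=5)
        fit = fit_trace(trace, "late")
        assert classify_trace(fit) == "accepted"


class TestBreakdownExtraction:
    def test_sharp_step_limit_recovers_t_b(self):
        p = EarlyModelParams(a0=800, a1=60, a2=2, t_b=12, tau_b=1e-4, c=120)
        rec = extract_breakdown_time(_fit_from_params("early", p, eta=0.0))
        assert rec.accepted
        assert abs(rec.t_event_h - 12.0) <= 1.0 / 60.0

    def test_parabola_only_trace_has_no_breakdown(self):
        p = EarlyModelParams(a0=100, a1=5, a2=0.5, t_b=60, tau_b=0.3, c=0)
        rec = extract_breakdown_time(_fit_from_params("early", p, eta=1.0))
        assert rec.quality == "rejected:no-breakdown"

    def test_threshold_monotonicity_in_kappa(self):
        p = EarlyModelParams(a0=2000, a1=0, a2=0, t_b=12, tau_b=0.5, c=100)
        fit = _fit_from_params("early", p, eta=20.0)
        t_prev = -np.inf
        for kappa in (1.0, 2.0, 3.0, 5.0, 8.0):
            rec = extract_breakdown_time(fit, kappa=kappa)
            assert rec.accepted
            assert rec.t_event_h >= t_prev
            t_prev = rec.t_event_h

    def test_offset_added_to_event_time(self):
        p = EarlyModelParams(a0=2000, a1=0, a2=0, t_b=12, tau_b=0.3, c=100)
        fit = _fit_from_params("early", p, eta=20.0)
        base = extract_breakdown_time(fit).t_event_h
        assert extract_breakdown_time(fit, offset=0.5).t_event_h == pytest.approx(
            base + 0.5
        )

    def test_wrong_kind_is_usage_error(self):
        p = LateModelParams(B=1, A=10, t_h=5, tau_o=0.1)
        with pytest.raises(ValueError, match="early"):
            extract_breakdown_time(_fit_from_params("late", p))


class TestOnsetExtraction:
    @pytest.mark.parametrize("t_h, tau_o", [(10.0, 1.0), (8.0, 0.25), (15.0, 0.05)])
    def test_pure_sigmoid_closed_form(self, t_h, tau_o):
        # tangent at half maximum has slope A/(4 tau) and meets B at t_h - 2 tau
        p = LateModelParams(B=10, A=90, t_h=t_h, tau_o=tau_o, lam=0.0)
        rec = extract_onset_time(_fit_from_params("late", p))
        assert rec.accepted
        assert rec.t_event_h == pytest.approx(t_h - 2 * tau_o, abs=1e-3)

    def test_step_limit_onset_approaches_t_h(self):
        p = LateModelParams(B=10, A=90, t_h=12, tau_o=1e-3, lam=0.0)
        rec = extract_onset_time(_fit_from_params("late", p))
        assert rec.t_event_h == pytest.approx(12.0, abs=5e-3)

    def test_flat_fit_is_degenerate(self):
        # half-rise far before the domain: the model is flat at B + A
        p = LateModelParams(B=10, A=90, t_h=-20, tau_o=0.5, lam=0.0)
        rec = extract_onset_time(_fit_from_params("late", p))
        assert rec.quality == "rejected:degenerate-onset"

    def test_wrong_kind_is_usage_error(self):
        p = EarlyModelParams(a0=1, t_b=5)
        with pytest.raises(ValueError, match="late"):
            extract_onset_time(_fit_from_params("early", p))


class TestRosRate:
    def test_linear_model_rate(self):
        p = EarlyModelParams(a0=0, a1=60, a2=0, t_b=1e5, tau_b=0.3, c=0)
        assert ros_production_rate(_fit_from_params("early", p)).rate == pytest.approx(
            60.0, rel=1e-9
        )

    def test_quadratic_model_rate_at_origin(self):
        p = EarlyModelParams(a0=0, a1=0, a2=36, t_b=1e5, tau_b=0.3, c=0)
        rate = ros_production_rate(_fit_from_params("early", p)).rate
        assert rate == pytest.approx(0.6, rel=1e-9)

    def test_constant_model_rate_zero(self):
        p = EarlyModelParams(a0=50, a1=0, a2=0, t_b=1e5, tau_b=0.3, c=0)
        assert ros_production_rate(_fit_from_params("early", p)).rate == pytest.approx(
            0.0, abs=1e-9
        )

    def test_evaluation_spacing_is_one_minute(self):
        p = EarlyModelParams(a0=0, a1=60, a2=0, t_b=1e5, tau_b=0.3, c=0)
        t0, t1 = ros_production_rate(_fit_from_params("early", p)).eval_times
        assert t1 - t0 == pytest.approx(1.0 / 60.0)


class TestTimeOffset:
    def _events(self):
        return EventSet(
            records=[
                EventRecord(1, "LMP", "breakdown", 10.0, "accepted"),
                EventRecord(2, "LMP", "breakdown", float("nan"), "rejected:no-breakdown"),
            ]
        )

    def test_zero_offset_is_identity(self):
        shifted = apply_time_offset(self._events(), 0.0)
        assert shifted.records[0].t_event_h == 10.0
        assert shifted.offset_applied

    def test_offset_shifts_accepted_events(self):
        shifted = apply_time_offset(self._events(), 0.5)
        assert shifted.records[0].t_event_h == pytest.approx(10.5)
        assert np.isnan(shifted.records[1].t_event_h)

    def test_double_application_guarded(self):
        shifted = apply_time_offset(self._events(), 0.5)
        with pytest.raises(RuntimeError, match="already applied"):
            apply_time_offset(shifted, 0.5)

    def test_negative_offset_rejected(self):
        with pytest.raises(ValueError):
            apply_time_offset(self._events(), -0.1)


class TestEquivariance:
    def test_time_shift_equivariance(self):
        true = EarlyModelParams(a0=2000, a1=0, a2=0, t_b=12, tau_b=0.3, c=100)
        base = synthesize_trace("early", true, noise_sd=0.0)
        delta = 2.0
        shifted = Trace(0, "LMP", base.times + delta, base.intensities)
        t0 = extract_breakdown_time(fit_trace(base, "early")).t_event_h
        t1 = extract_breakdown_time(fit_trace(shifted, "early")).t_event_h
        assert t1 - t0 == pytest.approx(delta, abs=1e-3)

    def test_intensity_scale_equivariance(self):
        true = LateModelParams(B=150, A=2500, t_h=14, tau_o=0.15, lam=0.05)
        trace = synthesize_trace("late", true, noise_sd=250.0, rng=8)
        scaled = Trace(0, "PMP", trace.times, 7.0 * trace.intensities)
        t0 = extract_onset_time(fit_trace(trace, "late")).t_event_h
        t1 = extract_onset_time(fit_trace(scaled, "late")).t_event_h
        assert t1 == pytest.approx(t0, abs=1e-3)
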