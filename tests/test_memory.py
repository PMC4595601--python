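import numpy as np
import pytest

from drest.delineate import BeatSeries
from drest.memory import (MemoryModel, compute_t90, fit_memory_model,
                          surrogate_rr)
from drest.synth import (SubjectProfile, generate_beat_series,
                         make_step_schedule)

LN10 = np.log(10.0)


def _model_from_weights(w, mean_rr_ms=1000.0):
    w = np.asarray(w, float)
    lag_s = np.arange(len(w)) * (mean_rr_ms / 1000.0)
    return MemoryModel(w, lag_s, max(60.0, lag_s[-1] + 1.0), 1.0, 0.0,
                       "Tpe", 0.0, mean_rr_ms)


def _beats(rr_ms):
    rr_ms = np.asarray(rr_ms, float)
    t = np.cumsum(rr_ms) / 1000.0
    n = len(t)
    return BeatSeries(t, rr_ms, np.full(n, 400.0), np.full(n, 90.0),
                      np.ones(n, bool))


class TestSurrogateRR:
    def test_delta_filter_is_identity(self):
        m = _model_from_weights([1.0, 0.0, 0.0])
        s = _beats(800.0 + 50.0 * np.sin(np.arange(50)))
        z = surrogate_rr(m, s)
        np.testing.assert_allclose(z.z_ms[z.valid], s.rr_ms[z.valid])

    def test_constant_rr_passes_through_any_weights(self):
        rng = np.random.default_rng(0)
        w = rng.random(40)
        w /= w.sum()
        m = _model_from_weights(w, 800.0)
        z = surrogate_rr(m, _beats(np.full(200, 800.0)))
        np.testing.assert_allclose(z.z_ms[z.valid], 800.0)

    def test_step_response_crosses_at_tau_ln10(self):
        """Exponential weights with tau = 30 s: a 1000->600 ms step is 90 %
        complete (z = 640 ms) about tau*ln10 = 69.1 s after the step."""
        tau = 30.0
        rr = np.concatenate([np.full(500, 1000.0), np.full(300, 600.0)])
        s = _beats(rr)
        # weights are beat-indexed; build them on the post-step beat spacing
        # (0.6 s), where the crossing is observed
        lag_s = np.arange(400) * 0.6
        w = np.exp(-lag_s / tau)
        m = MemoryModel(w / w.sum(), lag_s, 240.0, 1.0, 0.0, "Tpe", 0.0, 600.0)
        z = surrogate_rr(m, s)
        t_step = s.t[500]
        ok = z.valid & (s.t > t_step)
        t_cross = s.t[ok][np.argmax(z.z_ms[ok] <= 640.0)] - t_step
        assert t_cross == pytest.approx(tau * LN10, rel=0.10)

    def test_shift_equivariance(self):
        rng = np.random.default_rng(1)
        rr = 800.0 + 100.0 * rng.standard_normal(400).cumsum() / 20.0
        rr = np.clip(rr, 500.0, 1200.0)
        m = _model_from_weights(np.full(20, 0.05), 800.0)
        z0 = surrogate_rr(m, _beats(rr))
        shifted = _beats(rr)
        shifted = BeatSeries(shifted.t + 100.0, shifted.rr_ms, shifted.qt_ms,
                             shifted.tpe_ms, shifted.valid)
        z1 = surrogate_rr(m, shifted)
        np.testing.assert_allclose(z1.z_ms[z1.valid], z0.z_ms[z0.valid])


class TestComputeT90:
    def test_delta_weights_instant(self):
        assert compute_t90(_model_from_weights([1.0, 0.0])) == 0.0

    def test_exponential_weights_tau_ln10(self):
        tau = 30.0
        lag_s = np.arange(400) * 0.8
        w = np.exp(-lag_s / tau)
        m = MemoryModel(w / w.sum(), lag_s, 320.0, 1.0, 0.0, "Tpe", 0.0, 800.0)
        assert compute_t90(m) == pytest.approx(tau * LN10, rel=0.02)

    def test_degenerate_is_nan(self):
        m = _model_from_weights([0.5, 0.5])
        m.degenerate = True
        assert np.isnan(compute_t90(m))


class TestFitMemoryModel:
    def test_recovers_exponential_memory(self):
        """tau = 30 s generator, 2 ms noise: t90 within 15 %, rmse <= 3 ms."""
        rng = np.random.default_rng(5)
        t90_true = 30.0 * LN10
        p = SubjectProfile(drest_true=0.05, t90_true_s=t90_true,
                           noise_sd_ms=2.0, rr_mean_ms=850.0,
                           rr_step_schedule=make_step_schedule(rng, 2400, 850),
                           seed=17)
        gen = generate_beat_series(p, 2400.0)
        m = fit_memory_model(gen.series, target="Tpe")
        assert m.residual_rmse_ms <= 3.0
        assert compute_t90(m) == pytest.approx(t90_true, rel=0.15)

    def test_no_memory_concentrates_on_recent_beat(self, stepped_series):
        s = stepped_series.series
        nomem = BeatSeries(s.t, s.rr_ms, s.qt_ms,
                           40.0 + 0.05 * s.rr_ms, s.valid)
        m = fit_memory_model(nomem, target="Tpe")
        assert m.weights[0] > 0.9
        assert compute_t90(m) < 5.0

    def test_constant_rr_degenerate(self):
        rng = np.random.default_rng(2)
        n = 1500
        rr = np.full(n, 800.0)
        t = np.cumsum(rr) / 1000.0
        s = BeatSeries(t, rr, 400.0 + rng.normal(0, 2, n),
                       90.0 + rng.normal(0, 2, n), np.ones(n, bool))
        with pytest.warns(UserWarning, match="insufficient heart-rate"):
            m = fit_memory_model(s, target="Tpe")
        assert m.degenerate
        assert np.isnan(compute_t90(m))

    def test_t90_invariant_to_affine_target(self, stepped_series):
        s = stepped_series.series
        m0 = fit_memory_model(s, target="Tpe")
        scaled = BeatSeries(s.t, s.rr_ms, s.qt_ms, 3.0 * s.tpe_ms + 25.0,
                            s.valid)
        m1 = fit_memory_model(scaled, target="Tpe")
        assert compute_t90(m1) == pytest.approx(compute_t90(m0), rel=0.02)
        assert m1.g_slope == pytest.approx(3.0 * m0.g_slope, rel=0.02)

    def test_free_basis_path(self, stepped_series):
        m = fit_memory_model(stepped_series.series, target="Tpe",
                             basis="free", max_iter=10)
        assert m.weights.min() >= 0
        assert m.weights.sum() == pytest.approx(1.0, abs=1e-6)
        assert compute_t90(m) == pytest.approx(80.0, rel=0.35)

    def test_json_round_trip(self, stepped_series):
        m = fit_memory_model(stepped_series.series, target="Tpe")
        back = MemoryModel.from_json(m.to_json())
        np.testing.assert_allclose(back.weights, m.weights)
        assert compute_t90(back) == pytest.approx(compute_t90(m))

    def test_window_too_short_rejected(self, stepped_series):
        with pytest.raises(ValueError):
            fit_memory_model(stepped_series.series, window_s=30.0)
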