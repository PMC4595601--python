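"""Synthetic ECG study data with known ground truth.

Everything downstream estimators need to be validated against is generated
here with controllable truth: RR processes with sustained heart-rate
changes (the regime rate-adaptation and DRest estimation require), beat
series whose Tpe follows a known stationary slope against a known
exponential rate memory, raw 180 Hz waveforms whose per-beat QT/Tpe are
exact by construction, and two-group cohorts calibrated to the published
healthy / torsadogenic ranges.

Generator model per beat k (ms):

    z(k)   = lam_k * z(k-1) + (1 - lam_k) * rr(k),  lam_k = exp(-rr_k_s/tau)
    Tpe(k) = tpe0 + drest_true * (z(k) - 1000) + eps
    QT(k)  = qt_c_true * (z(k)/1000)^(1/3) + eps

with tau = t90_true / ln 10, so the Tpe step response completes 90 % of its
transition t90_true seconds after an abrupt RR change, and the stationary
QT is exactly Fridericia-invariant with corrected value ``qt_c_true``.
The memory here is a single continuous-time exponential; the estimator
fits a general FIR profile (a mixture of decays plus a delta, or a free
simplex profile), so recovery tests probe estimation rather than sharing
one parameterization — except that the estimator's single-exponential
refinement can represent this generator exactly, which is what makes the
noise-free closed loop exact.  RR reference for the Tpe intercept is
1000 ms, making ``tpe0_ms`` directly interpretable as Tpe at 60 bpm.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .delineate import BeatSeries
from .io import ECGRecord

__all__ = ["SubjectProfile", "GeneratedSeries", "generate_rr",
           "generate_beat_series", "synthesize_waveform", "generate_cohort",
           "make_step_schedule"]

RR_REF_MS = 1000.0

#: calibration bands (healthy: published 20-80 pct bounds; TdP: patient values)
HEALTHY_DREST = (0.025, 0.058)
TDP_DREST = (0.18, 0.22)
HEALTHY_T90_S = (90.0, 200.0)
TDP_T90_S = (251.0, 292.0)
HEALTHY_QTC_MS = (376.0, 467.0)
TDP_QTC_MS = (548.0, 436.0, 480.0)  # the three reported patients, cycled
HEALTHY_TPE0_MS = (82.0, 98.0)
TDP_TPE0_MS = (116.0, 77.0, 107.0)
HEALTHY_RR_MS = (776.0, 925.0)
TDP_RR_MS = (900.0, 1160.0)


@dataclass
class SubjectProfile:
    """Ground-truth parameters of one synthetic subject."""

    drest_true: float = 0.04
    t90_true_s: float = 80.0
    tpe0_ms: float = 90.0
    qt_c_true_ms: float = 400.0
    noise_sd_ms: float = 2.0
    rr_mean_ms: float = 850.0
    rr_step_schedule: tuple = ()  # ((time_s, new_level_ms), ...)
    seed: int = 0
    subject_id: str = "synthetic"
    group: str = "healthy"

    def __post_init__(self):
        if self.drest_true < 0 or self.noise_sd_ms < 0:
            raise ValueError("drest_true and noise_sd_ms must be >= 0")
        times = [t for t, _ in self.rr_step_schedule]
        if sorted(times) != times:
            raise ValueError("schedule times must be increasing")

    @property
    def tau_s(self) -> float:
        """Memory time constant: t90 = tau * ln 10."""
        return self.t90_true_s / np.log(10.0)


@dataclass
class GeneratedSeries:
    """Beat series plus the ground truth it was generated from."""

    series: BeatSeries
    z_true_ms: np.ndarray
    profile: SubjectProfile


def make_step_schedule(rng, duration_s: float, mean_rr_ms: float,
                       step_every_s: float = 300.0,
                       rel_amplitude: float = 0.10) -> tuple:
    """Piecewise-constant RR levels: a step every ~5 min, +-10 % of mean."""
    times = np.arange(step_every_s, duration_s, step_every_s)
    # alternate the sign of the swing so heart-rate changes are guaranteed
    signs = (-1.0) ** np.arange(len(times))
    levels = mean_rr_ms * (1.0 + rel_amplitude * signs
                           * rng.uniform(0.5, 1.0, len(times)))
    return tuple((float(t), float(lv)) for t, lv in zip(times, levels))


def generate_rr(profile: SubjectProfile, duration_s: float,
                ar_rho: float = 0.8, ar_sd_ms: float = 15.0,
                resp_amp_ms: float = 0.0, resp_freq_hz: float = 0.25,
                rng=None) -> np.ndarray:
    """Per-beat RR sequence: schedule levels + AR(1) variability (+ optional
    respiratory sinus modulation); all RR > 300 ms."""
    if rng is None:
        rng = np.random.default_rng(profile.seed)
    sched_t = np.array([0.0] + [t for t, _ in profile.rr_step_schedule])
    sched_lv = np.array([profile.rr_mean_ms]
                        + [lv for _, lv in profile.rr_step_schedule])

    noisy = profile.noise_sd_ms > 0
    sd_innov = ar_sd_ms * np.sqrt(1.0 - ar_rho**2) if noisy else 0.0
    rr = []
    t = 0.0
    e = 0.0
    while t < duration_s:
        level = sched_lv[np.searchsorted(sched_t, t, side="right") - 1]
        e = ar_rho * e + rng.normal(0.0, sd_innov) if noisy else 0.0
        val = level + e
        if resp_amp_ms > 0:
            val += resp_amp_ms * np.sin(2 * np.pi * resp_freq_hz * t)
        val = max(val, 301.0)
        rr.append(val)
        t += val / 1000.0
    return np.asarray(rr)


def _exp_filter(rr_ms: np.ndarray, tau_s: float) -> np.ndarray:
    """Continuous-time exponential memory sampled at beat times."""
    z = np.empty_like(rr_ms)
    z[0] = rr_ms[0]
    for k in range(1, len(rr_ms)):
        lam = np.exp(-(rr_ms[k] / 1000.0) / tau_s)
        z[k] = lam * z[k - 1] + (1.0 - lam) * rr_ms[k]
    return z


def generate_beat_series(profile: SubjectProfile, duration_s: float,
                         warmup_s: float = 600.0) -> GeneratedSeries:
    """Beat series with the generator's memory and stationary structure.

    A constant-RR warm-up (not returned) initializes the memory filter so
    the first returned beat already carries a converged z.
    """
    rng = np.random.default_rng(profile.seed)
    rr = generate_rr(profile, duration_s, rng=rng)
    n = len(rr)
    # warm-up: filter has seen the baseline level long before t=0
    n_warm = max(1, int(round(warmup_s / (profile.rr_mean_ms / 1000.0))))
    rr_full = np.concatenate([np.full(n_warm, profile.rr_mean_ms), rr])
    z = _exp_filter(rr_full, profile.tau_s)[n_warm:]

    eps_t = rng.normal(0.0, profile.noise_sd_ms, n) if profile.noise_sd_ms else 0.0
    eps_q = rng.normal(0.0, profile.noise_sd_ms, n) if profile.noise_sd_ms else 0.0
    tpe = profile.tpe0_ms + profile.drest_true * (z - RR_REF_MS) + eps_t
    qt = profile.qt_c_true_ms * np.cbrt(z / 1000.0) + eps_q
    t = np.cumsum(rr) / 1000.0
    series = BeatSeries(t=t, rr_ms=rr, qt_ms=qt, tpe_ms=tpe,
                        valid=np.ones(n, dtype=bool))
    return GeneratedSeries(series, z, profile)


# ---------------------------------------------------------------------------
# waveform synthesis

#: Gaussian lobe widths (ms) and amplitudes (mV) of the default morphology
_SIGMA_R_MS = 10.0
_SIGMA_P_MS = 22.0
_P_OFFSET_MS = 170.0
#: ground-truth QRS onset sits 3 sigma before the R apex (the point an
#: amplitude- or slope-threshold delineator identifies as the QRS foot)
_ONSET_SIGMAS = 3.0


def synthesize_waveform(series: BeatSeries, fs: float = 180.0,
                        lead_name: str = "V3", r_amp_mv: float = 1.0,
                        t_amp_mv: float = 0.30, p_amp_mv: float = 0.12,
                        noise_sd_mv: float = 0.0, baseline_amp_mv: float = 0.0,
                        baseline_freq_hz: float = 0.25,
                        rng=None) -> ECGRecord:
    """Render a beat series as a single-lead waveform.

    Each beat is a sum of Gaussian lobes: P, R, and a T wave constructed so
    that the delineation landmarks reproduce the requested intervals by
    construction: QRS onset (slope-threshold foot) falls 3 sigma before the
    R apex, the T apex at onset + QT - Tpe, and the tangent-method T end at
    onset + QT exactly (for a Gaussian T the steepest-tangent/baseline
    intersection is apex + 2 sigma, so sigma_T = Tpe/2).
    """
    bad = series.valid & ~(series.tpe_ms < series.qt_ms)
    if np.any(bad):
        raise ValueError("infeasible request: tpe_ms >= qt_ms on valid beats")
    if rng is None:
        rng = np.random.default_rng(0)
    t_end = series.t[-1] + 1.0
    t0 = max(0.0, series.t[0] - 0.5)
    n = int(round((t_end - t0) * fs))
    tt = t0 + np.arange(n) / fs
    x = np.zeros(n)

    sig_r = _SIGMA_R_MS / 1000.0
    for k in range(len(series)):
        r_t = series.t[k]
        x += r_amp_mv * _lobe(tt, r_t, sig_r)
        x += p_amp_mv * _lobe(tt, r_t - _P_OFFSET_MS / 1000.0, _SIGMA_P_MS / 1000.0)
        if not (np.isfinite(series.qt_ms[k]) and np.isfinite(series.tpe_ms[k])):
            continue
        onset = r_t - _ONSET_SIGMAS * sig_r
        qt_s = series.qt_ms[k] / 1000.0
        tpe_s = series.tpe_ms[k] / 1000.0
        sig_t = tpe_s / 2.0
        apex = onset + qt_s - tpe_s
        x += t_amp_mv * _lobe(tt, apex, sig_t)

    if baseline_amp_mv > 0:
        x += baseline_amp_mv * np.sin(2 * np.pi * baseline_freq_hz * tt)
    if noise_sd_mv > 0:
        x += rng.normal(0.0, noise_sd_mv, n)
    return ECGRecord(fs, [lead_name], x[None, :], start_time=t0)


def _lobe(t, center, sigma):
    return np.exp(-0.5 * ((t - center) / sigma) ** 2)


# ---------------------------------------------------------------------------
# cohorts

def generate_cohort(n_healthy: int = 25, n_tdp: int = 3, seed: int = 0,
                    duration_s: float = 1800.0,
                    noise_sd_ms: float = 2.0) -> list[SubjectProfile]:
    """Two-group cohort of subject profiles, deterministic under ``seed``.

    Healthy subjects draw DRest uniformly over the published healthy
    20-80 pct band and QTc over the healthy full range; torsadogenic
    subjects draw DRest over the reported TdP band while their QTc and
    Tpe scales cycle through the three reported patients (with small
    jitter), preserving the study's key qualitative feature that one TdP
    patient has a QTc inside the healthy range.
    """
    if n_healthy < 1 or n_tdp < 1:
        raise ValueError("need at least one subject per group")
    rng = np.random.default_rng(seed)
    profiles = []
    for i in range(n_healthy):
        mean_rr = rng.uniform(*HEALTHY_RR_MS)
        profiles.append(SubjectProfile(
            drest_true=rng.uniform(*HEALTHY_DREST),
            t90_true_s=rng.uniform(*HEALTHY_T90_S),
            tpe0_ms=rng.uniform(*HEALTHY_TPE0_MS),
            qt_c_true_ms=rng.uniform(*HEALTHY_QTC_MS),
            noise_sd_ms=noise_sd_ms,
            rr_mean_ms=mean_rr,
            rr_step_schedule=make_step_schedule(rng, duration_s, mean_rr),
            seed=int(rng.integers(0, 2**31 - 1)),
            subject_id=f"H{i + 1:02d}", group="healthy",
        ))
    for i in range(n_tdp):
        mean_rr = rng.uniform(*TDP_RR_MS)
        profiles.append(SubjectProfile(
            drest_true=rng.uniform(*TDP_DREST),
            t90_true_s=rng.uniform(*TDP_T90_S),
            tpe0_ms=TDP_TPE0_MS[i % 3] + rng.uniform(-2, 2),
            qt_c_true_ms=TDP_QTC_MS[i % 3] + rng.uniform(-3, 3),
            noise_sd_ms=noise_sd_ms,
            rr_mean_ms=mean_rr,
            rr_step_schedule=make_step_schedule(rng, duration_s, mean_rr),
            seed=int(rng.integers(0, 2**31 - 1)),
            subject_id=f"T{i + 1:02d}", group="tdp_sotalol",
        ))
    return profiles
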