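"""Beat detection and interval delineation.

QRS detection is a derivative-energy detector in the Pan-Tompkins family:
band-pass, differentiate, square, moving-window integrate, adaptive
threshold with a 200 ms refractory period.  Delineation then measures, per
beat,

* QRS onset — backward search from the R peak for the last point where the
  absolute signal derivative falls below 5.5 % of the beat's maximal
  upstroke slope (on a Gaussian-shaped R wave this crossing sits ~3 sigma
  before the peak, i.e. at the visual foot of the complex);
* T apex — extremum of the low-pass-filtered T window, refined by parabolic
  interpolation;
* T end — the tangent method: the steepest tangent on the descending T limb
  is intersected with the isoelectric baseline.

The tangent method is the dominant convention in Tpe work, which is why it
is used both here and for the simulated pseudo-ECGs, keeping clinical and
in-silico Tpe definitions identical.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .io import ECGRecord

__all__ = ["BeatSeries", "detect_beats", "delineate", "clean_series"]

#: derivative threshold for QRS onset, as a fraction of the max upstroke slope
QRS_ONSET_SLOPE_FRACTION = 3.0 * np.exp(-4.0)  # ~0.055; 3 sigma on a Gaussian R


@dataclass
class BeatSeries:
    """Per-beat interval measurements anchored at R-peak times.

    ``rr_ms[k]`` is the interval preceding beat ``k`` (nan for the first
    beat); ``qt_ms`` runs QRS onset to T end, ``tpe_ms`` T apex to T end.
    Invalid beats keep their slot with measurements set to nan and
    ``valid=False``.
    """

    t: np.ndarray
    rr_ms: np.ndarray
    qt_ms: np.ndarray
    tpe_ms: np.ndarray
    valid: np.ndarray

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.rr_ms = np.asarray(self.rr_ms, dtype=float)
        self.qt_ms = np.asarray(self.qt_ms, dtype=float)
        self.tpe_ms = np.asarray(self.tpe_ms, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        n = len(self.t)
        if not all(len(a) == n for a in (self.rr_ms, self.qt_ms, self.tpe_ms, self.valid)):
            raise ValueError("BeatSeries fields must have equal length")
        if n > 1 and np.any(np.diff(self.t) <= 0):
            raise ValueError("beat times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.t)

    def check(self) -> None:
        """Raise if any valid beat violates the series invariants."""
        v = self.valid
        if np.any(self.rr_ms[v] <= 0):
            raise ValueError("nonpositive RR on a valid beat")
        if np.any(~(self.tpe_ms[v] > 0) | ~(self.tpe_ms[v] < self.qt_ms[v])):
            raise ValueError("need 0 < Tpe < QT on valid beats")
        k = np.where(v[1:] & v[:-1])[0] + 1
        dt_ms = np.diff(self.t)[k - 1] * 1000.0
        if np.any(np.abs(self.rr_ms[k] - dt_ms) > 1.0):
            raise ValueError("rr_ms inconsistent with beat times (> 1 ms)")


def detect_beats(record: ECGRecord, lead: str) -> np.ndarray:
    """Locate R peaks on one lead; returns anchor times in seconds."""
    if record.duration < 10.0:
        raise ValueError("need at least 10 s of signal for beat detection")
    x = record.lead(lead)
    fs = record.sampling_rate

    if np.ptp(x) < 1e-9:
        warnings.warn("flat signal: no beats detected")
        return np.array([])

    sos = sps.butter(2, [5.0, min(25.0, 0.45 * fs)], btype="band", fs=fs, output="sos")
    bp = sps.sosfiltfilt(sos, x)
    energy = np.gradient(bp) ** 2
    win = max(1, int(round(0.12 * fs)))
    feat = np.convolve(energy, np.ones(win) / win, mode="same")

    refractory = int(round(0.2 * fs))
    # adaptive threshold: fraction of a rolling high quantile of the feature
    thr = 0.2 * np.quantile(feat, 0.99)
    peaks, _ = sps.find_peaks(feat, height=thr, distance=refractory)
    if len(peaks) == 0:
        warnings.warn("no beats detected")
        return np.array([])

    # snap each detection to the local extremum of the band-passed signal
    half = int(round(0.08 * fs))
    anchors = []
    for p in peaks:
        lo, hi = max(0, p - half), min(len(x), p + half + 1)
        seg = np.abs(bp[lo:hi])
        anchors.append(lo + int(np.argmax(seg)))
    anchors = np.unique(anchors)
    keep = [anchors[0]]
    for a in anchors[1:]:
        if a - keep[-1] >= refractory:
            keep.append(a)
    return record.start_time + np.asarray(keep) / fs


def delineate(record: ECGRecord, lead: str, anchors: np.ndarray) -> BeatSeries:
    """Measure RR, QT and Tpe for each anchored beat.

    Beats where any landmark search fails (window clipped at the record
    edge, no T wave) are kept with ``valid=False`` and nan measurements.
    """
    anchors = np.asarray(anchors, dtype=float)
    if len(anchors) < 2:
        raise ValueError("need at least 2 beats to define RR intervals")
    x = record.lead(lead)
    fs = record.sampling_rate
    t0 = record.start_time

    # low-pass for the T wave; gentle so the apex is not displaced
    sos = sps.butter(2, min(20.0, 0.4 * fs), btype="low", fs=fs, output="sos")
    xt = sps.sosfiltfilt(sos, x)
    dx = np.gradient(x) * fs   # mV/s
    dxt = np.gradient(xt) * fs

    n = len(anchors)
    rr = np.full(n, np.nan)
    rr[1:] = np.diff(anchors) * 1000.0
    qt = np.full(n, np.nan)
    tpe = np.full(n, np.nan)
    valid = np.zeros(n, dtype=bool)

    for k in range(n):
        r_idx = int(round((anchors[k] - t0) * fs))
        rr_k = rr[k] if np.isfinite(rr[k]) else (rr[k + 1] if k + 1 < n else 800.0)
        res = _delineate_one(x, xt, dx, dxt, fs, r_idx, rr_k)
        if res is None:
            continue
        onset_t, apex_t, end_t = res
        qt[k] = (end_t - onset_t) * 1000.0
        tpe[k] = (end_t - apex_t) * 1000.0
        valid[k] = np.isfinite(qt[k]) and np.isfinite(tpe[k]) and 0 < tpe[k] < qt[k]
        if not valid[k]:
            qt[k] = tpe[k] = np.nan
    return BeatSeries(anchors, rr, qt, tpe, valid)


def _delineate_one(x, xt, dx, dxt, fs, r_idx, rr_ms):
    n = len(x)

    # ---- QRS onset: backward slope-threshold search ----
    # anchor at the maximal upstroke (not the R apex, where dV/dt ~ 0) and
    # walk back to where the slope drops below the threshold fraction
    back = int(round(0.10 * fs))
    lo = r_idx - back
    if lo < 0 or r_idx >= n:
        return None
    seg_slope = np.abs(dx[lo:r_idx + 1])
    if seg_slope.size < 3:
        return None
    up_rel = int(np.argmax(seg_slope))
    thr = QRS_ONSET_SLOPE_FRACTION * float(seg_slope[up_rel])
    below = np.where(seg_slope[:up_rel + 1] <= thr)[0]
    k_on = below[-1] if below.size else 0
    onset_idx = lo + k_on
    # sub-sample refinement of the threshold crossing
    onset_pos = float(onset_idx)
    if k_on < up_rel and seg_slope[k_on + 1] > seg_slope[k_on]:
        onset_pos += (thr - seg_slope[k_on]) / (seg_slope[k_on + 1] - seg_slope[k_on])

    # ---- T window ----
    w_lo = r_idx + int(round(0.08 * fs))
    w_hi = r_idx + int(round(min(0.600, 0.7 * rr_ms / 1000.0) * fs))
    if w_hi >= n or w_hi - w_lo < 5:
        return None
    baseline = _baseline_level(x, fs, onset_idx)

    tw = xt[w_lo:w_hi] - baseline
    apex_rel = int(np.argmax(np.abs(tw)))
    sign = 1.0 if tw[apex_rel] >= 0 else -1.0
    amp = sign * tw[apex_rel]
    if amp < 0.02:  # < 20 uV: no usable T wave
        return None
    apex_idx = w_lo + apex_rel
    apex_t = (apex_idx + _parabolic_offset(sign * xt, apex_idx)) / fs

    # ---- tangent method on the descending limb ----
    d_lo = apex_idx + 1
    d_hi = min(w_hi + int(round(0.08 * fs)), n - 1)
    if d_hi - d_lo < 3:
        return None
    limb = sign * dxt[d_lo:d_hi]  # signed slope, mV/s
    j = int(np.argmin(limb))  # steepest descent
    tan_idx = d_lo + j
    slope = limb[j] / fs      # mV per sample
    if slope >= 0:
        return None
    val = sign * (xt[tan_idx] - baseline)
    end_idx_f = tan_idx + (-val / slope)  # baseline crossing of the tangent
    if not np.isfinite(end_idx_f) or end_idx_f <= apex_idx or end_idx_f > n:
        return None
    return onset_pos / fs, apex_t, end_idx_f / fs


def _baseline_level(x, fs, onset_idx):
    """Isoelectric level from the PR-ish segment just before QRS onset."""
    lo = max(0, onset_idx - int(round(0.04 * fs)))
    if lo == onset_idx:
        return float(x[onset_idx])
    return float(np.median(x[lo:onset_idx + 1]))


def _parabolic_offset(y, i):
    """Sub-sample apex refinement; offset in samples, clipped to (-1, 1)."""
    if i <= 0 or i >= len(y) - 1:
        return 0.0
    denom = y[i - 1] - 2.0 * y[i] + y[i + 1]
    if denom == 0:
        return 0.0
    off = 0.5 * (y[i - 1] - y[i + 1]) / denom
    return float(np.clip(off, -1.0, 1.0))


def clean_series(series: BeatSeries, window_beats: int = 60,
                 mad_limit: float = 5.0) -> BeatSeries:
    """Flag physiologically implausible or artefactual beats as invalid.

    Marks: RR outside [300, 2500] ms; QT or Tpe further than ``mad_limit``
    running MADs from a ``window_beats`` running median; beats adjacent to an
    ectopic pattern (RR change > 30 % followed by a compensatory change).
    Series shorter than the running window are returned unchanged with a
    warning.
    """
    n = len(series)
    valid = series.valid.copy()
    if n < window_beats:
        warnings.warn(f"series of {n} beats shorter than {window_beats}-beat "
                      "cleaning window; returned unchanged")
        return BeatSeries(series.t, series.rr_ms, series.qt_ms, series.tpe_ms, valid)

    with np.errstate(invalid="ignore"):
        # missing RR (e.g. the first beat) is not by itself disqualifying
        rr_bad = (series.rr_ms < 300.0) | (series.rr_ms > 2500.0)
        valid &= ~rr_bad.astype(bool)

        for vals in (series.qt_ms, series.tpe_ms):
            med = _running_median(vals, window_beats)
            mad = _running_median(np.abs(vals - med), window_beats)
            mad = np.where(mad < 1.0, 1.0, mad)  # floor: quantization scale
            valid &= ~(np.abs(vals - med) > mad_limit * mad)

        # ectopy: sudden RR drop/jump followed by a compensatory swing
        drr = np.diff(series.rr_ms) / series.rr_ms[:-1]
        for k in range(1, n - 1):
            if np.isfinite(drr[k - 1]) and np.isfinite(drr[k]):
                if abs(drr[k - 1]) > 0.3 and abs(drr[k]) > 0.3 and drr[k - 1] * drr[k] < 0:
                    valid[k - 1:k + 2] = False
    return BeatSeries(series.t, series.rr_ms, series.qt_ms, series.tpe_ms, valid)


def _running_median(x: np.ndarray, w: int) -> np.ndarray:
    import pandas as pd

    s = pd.Series(x)
    return s.rolling(w, min_periods=max(5, w // 4), center=True).median().to_numpy()
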