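"""ECG record and beat-series I/O.

Two interchange formats are supported for raw signals: a plain CSV dialect
(``time_s, lead1, lead2, ...`` with a header row, amplitudes in mV), which
round-trips bit-exactly, and read-only WFDB records (MIT-format ``.hea``
header plus ``.dat`` signal file, formats 16 and 212), the de-facto standard
for archived ECG.  Beat-interval series travel as
``beat_index, t_s, rr_ms, qt_ms, tpe_ms, valid`` CSV.

Lead selection follows the common practice of analysing the precordial lead
with the highest signal-to-noise ratio (typically V2-V4, where the T wave is
best delineable).  The SNR estimator builds a correlation-aligned median beat
template per lead and reports template-power over residual-power in dB.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ECGRecord",
    "LeadQuality",
    "read_record",
    "write_record",
    "read_beat_series_csv",
    "write_beat_series_csv",
    "rank_leads",
    "DEFAULT_CANDIDATE_LEADS",
]

#: Precordial leads where the T wave delineates best.
DEFAULT_CANDIDATE_LEADS = ("V2", "V3", "V4")


@dataclass
class ECGRecord:
    """Multi-lead ECG signal in physical units.

    Attributes
    ----------
    sampling_rate : float
        Samples per second (Hz).
    lead_names : list of str
        Ordered lead identifiers, one per signal row.
    signal : ndarray, shape (n_leads, n_samples)
        Amplitudes in mV.
    start_time : float
        Time of the first sample, seconds.
    """

    sampling_rate: float
    lead_names: list[str]
    signal: np.ndarray
    start_time: float = 0.0

    def __post_init__(self) -> None:
        self.signal = np.atleast_2d(np.asarray(self.signal, dtype=float))
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if self.signal.shape[0] != len(self.lead_names):
            raise ValueError(
                f"{len(self.lead_names)} lead names for "
                f"{self.signal.shape[0]} signal rows"
            )

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]

    @property
    def duration(self) -> float:
        """Record length in seconds (n_samples / sampling_rate)."""
        return self.n_samples / self.sampling_rate

    @property
    def time(self) -> np.ndarray:
        return self.start_time + np.arange(self.n_samples) / self.sampling_rate

    def lead(self, name: str) -> np.ndarray:
        try:
            idx = self.lead_names.index(name)
        except ValueError:
            raise KeyError(f"lead {name!r} not in record ({self.lead_names})") from None
        return self.signal[idx]

    def truncate(self, max_duration_s: float) -> "ECGRecord":
        """Return the leading excerpt of at most ``max_duration_s`` seconds."""
        n = min(self.n_samples, int(round(max_duration_s * self.sampling_rate)))
        return ECGRecord(self.sampling_rate, list(self.lead_names),
                         self.signal[:, :n].copy(), self.start_time)


@dataclass
class LeadQuality:
    """Per-lead signal quality: SNR in dB and whether beats were delineable."""

    lead_name: str
    snr_db: float
    delineable: bool = True


def read_record(path: str | os.PathLike, format: str = "csv") -> ECGRecord:
    """Read an ECG record from disk.

    Parameters
    ----------
    path : str
        For ``csv``, the CSV file; for ``wfdb``, the record path with or
        without the ``.hea`` extension.
    format : {"csv", "wfdb"}
    """
    if format == "csv":
        return _read_csv(path)
    if format == "wfdb":
        return _read_wfdb(os.fspath(path))
    raise ValueError(f"unknown format {format!r}")


def write_record(record: ECGRecord, path: str | os.PathLike) -> None:
    """Write the CSV dialect: ``time_s, lead1, ...``; full float precision."""
    cols = {"time_s": record.time}
    for i, name in enumerate(record.lead_names):
        cols[name] = record.signal[i]
    pd.DataFrame(cols).to_csv(path, index=False)


def _read_csv(path) -> ECGRecord:
    df = pd.read_csv(path, float_precision="round_trip")
    if df.shape[1] < 2:
        raise ValueError(f"{path}: need a time column plus at least one lead")
    t = df.iloc[:, 0].to_numpy(dtype=float)
    if len(t) < 2:
        raise ValueError(f"{path}: fewer than 2 samples")
    dt = np.diff(t)
    if np.any(dt <= 0) or np.ptp(dt) > 1e-6:
        raise ValueError(f"{path}: time column must be uniformly increasing")
    fs = 1.0 / np.mean(dt)
    sig = df.iloc[:, 1:].to_numpy(dtype=float).T
    if np.isnan(sig).any():
        raise ValueError(f"{path}: inconsistent lead lengths (missing values)")
    return ECGRecord(fs, list(df.columns[1:]), sig, start_time=float(t[0]))


# -- minimal WFDB (MIT signal) reader: header + dat, formats 16 and 212 ------

def _read_wfdb(path: str) -> ECGRecord:
    hea = path if path.endswith(".hea") else path + ".hea"
    base_dir = os.path.dirname(os.path.abspath(hea))
    with open(hea) as fh:
        lines = [ln.strip() for ln in fh
                 if ln.strip() and not ln.startswith("#")]
    rec_line = lines[0].split()
    n_sig = int(rec_line[1])
    fs = float(rec_line[2].split("/")[0]) if len(rec_line) > 2 else 250.0
    n_samples = int(rec_line[3]) if len(rec_line) > 3 else 0

    sig_specs = []
    for ln in lines[1:1 + n_sig]:
        tok = ln.split()
        fname, fmt = tok[0], tok[1].split("x")[0].split(":")[0].split("+")[0]
        gain, baseline, adc_zero = 200.0, None, 0
        if len(tok) > 2:
            g = tok[2]
            if "(" in g:
                g, b = g.split("(")
                baseline = int(b.rstrip(")").split(")")[0])
            g = g.split("/")[0]
            gain = float(g) if float(g) != 0 else 200.0
        if len(tok) > 4:
            adc_zero = int(tok[4])
        if baseline is None:
            baseline = adc_zero
        name = tok[8] if len(tok) > 8 else f"sig{len(sig_specs)}"
        sig_specs.append((fname, int(fmt), gain, baseline, name))

    fmts = {s[1] for s in sig_specs}
    fnames = {s[0] for s in sig_specs}
    if len(fmts) > 1 or len(fnames) > 1:
        raise ValueError("only single-file, single-format WFDB records supported")
    fmt = fmts.pop()
    dat_path = os.path.join(base_dir, fnames.pop())
    raw = open(dat_path, "rb").read()

    if fmt == 16:  # 16-bit little-endian two's complement, interleaved
        data = np.frombuffer(raw, dtype="<i2")
        data = data[: (len(data) // n_sig) * n_sig].reshape(-1, n_sig).T
    elif fmt == 212:  # packed 12-bit pairs
        data = _unpack_212(raw)
        data = data[: (len(data) // n_sig) * n_sig].reshape(-1, n_sig).T
    else:
        raise ValueError(f"WFDB format {fmt} not supported (16 and 212 only)")
    if n_samples:
        data = data[:, :n_samples]

    sig = np.empty(data.shape, dtype=float)
    for i, (_, _, gain, baseline, _) in enumerate(sig_specs):
        sig[i] = (data[i].astype(float) - baseline) / gain
    names = [s[4] for s in sig_specs]
    return ECGRecord(fs, names, sig)


def _unpack_212(raw: bytes) -> np.ndarray:
    b = np.frombuffer(raw, dtype=np.uint8)
    n_trip = len(b) // 3
    b = b[: n_trip * 3].reshape(-1, 3).astype(np.int32)
    first = ((b[:, 1] & 0x0F) << 8) | b[:, 0]
    second = ((b[:, 1] & 0xF0) << 4) | b[:, 2]
    out = np.empty(2 * n_trip, dtype=np.int32)
    out[0::2], out[1::2] = first, second
    out[out > 2047] -= 4096  # sign-extend 12 bits
    return out


# -- beat-series CSV ----------------------------------------------------------

def write_beat_series_csv(series, path) -> None:
    """Write ``beat_index, t_s, rr_ms, qt_ms, tpe_ms, valid`` CSV."""
    df = pd.DataFrame({
        "beat_index": np.arange(len(series.t)),
        "t_s": series.t,
        "rr_ms": series.rr_ms,
        "qt_ms": series.qt_ms,
        "tpe_ms": series.tpe_ms,
        "valid": series.valid.astype(int),
    })
    df.to_csv(path, index=False)


def read_beat_series_csv(path):
    from .delineate import BeatSeries

    df = pd.read_csv(path, float_precision="round_trip")
    return BeatSeries(
        t=df["t_s"].to_numpy(float),
        rr_ms=df["rr_ms"].to_numpy(float),
        qt_ms=df["qt_ms"].to_numpy(float),
        tpe_ms=df["tpe_ms"].to_numpy(float),
        valid=df["valid"].to_numpy().astype(bool),
    )


# -- lead quality -------------------------------------------------------------

def rank_leads(record: ECGRecord, candidates=None) -> list[LeadQuality]:
    """Rank candidate leads by beat-template SNR, best first.

    SNR per lead is the power of the correlation-aligned median beat template
    over the power of the residual (signal minus the template subtracted at
    every beat), in dB.  A lead in which no beats can be detected is marked
    ``delineable=False`` and ranked last.
    """
    from .delineate import detect_beats

    if candidates is None:
        candidates = [n for n in DEFAULT_CANDIDATE_LEADS if n in record.lead_names]
        if not candidates:
            candidates = list(record.lead_names)
    if not candidates:
        raise ValueError("no candidate leads")
    missing = [c for c in candidates if c not in record.lead_names]
    if missing:
        raise KeyError(f"candidate leads not in record: {missing}")

    out = []
    for name in candidates:
        x = record.lead(name)
        try:
            peaks = detect_beats(record, name)
        except ValueError:
            peaks = np.array([])
        if len(peaks) < 3:
            out.append(LeadQuality(name, -np.inf, delineable=False))
            continue
        out.append(LeadQuality(name, _template_snr_db(x, peaks, record.sampling_rate)))
    out.sort(key=lambda q: (q.delineable, q.snr_db), reverse=True)
    return out


def _template_snr_db(x: np.ndarray, peaks_s: np.ndarray, fs: float) -> float:
    idx = np.round(peaks_s * fs).astype(int)
    half = int(round(0.30 * fs))
    wins = [x[i - half:i + half] for i in idx
            if i - half >= 0 and i + half <= len(x)]
    if len(wins) < 3:
        return -np.inf
    wins = np.array(wins)
    template = np.median(wins, axis=0)

    # align each window to the template by cross-correlation (+-25 ms)
    max_lag = max(1, int(round(0.025 * fs)))
    aligned = []
    for w in wins:
        lags = range(-max_lag, max_lag + 1)
        scores = [np.dot(np.roll(w, L), template) for L in lags]
        aligned.append(np.roll(w, list(lags)[int(np.argmax(scores))]))
    aligned = np.array(aligned)
    template = np.median(aligned, axis=0)

    resid = aligned - template
    p_sig = float(np.mean(template**2))
    p_res = float(np.mean(resid**2))
    if p_res <= 0:
        return np.inf
    return 10.0 * np.log10(p_sig / p_res)
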