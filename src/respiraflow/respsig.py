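"""Derived respiration channels and model-input windows.

Three respiration surrogates are extracted per 32-s window and resampled to
a common 4-Hz grid of 128 samples:

* RRint — the beat-to-beat interval series (respiratory sinus arrhythmia
  modulates beat timing);
* RPA — the R-peak amplitude series (breathing modulates QRS amplitude);
* ADR — an adaptive-filter estimate of the respiration-band component of
  the dominant-variance accelerometer axis.

Beat-domain series are cubic-spline interpolated onto the uniform grid and
mean-removed; each channel is z-normalised per window before being handed
to the model.  Ground-truth average/instantaneous rates are computed from
the reference respiration signal with the breath-counting detector.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from fractions import Fraction

import h5py
import numpy as np
from scipy import signal
from scipy.interpolate import CubicSpline

from .rrtools import advanced_count_rr
from .siggen import RawRecording

__all__ = ["SignalWindow", "detect_r_peaks", "extract_edr_rrint",
           "extract_edr_rpa", "extract_adr", "make_windows",
           "windows_to_h5", "windows_from_h5", "windows_to_arrays",
           "train_test_split", "CHANNEL_ORDER"]

CHANNEL_ORDER = ("rrint", "rpa", "adr")
OUT_FS = 4.0
WINDOW_S = 32.0
OUT_LEN = 128


@dataclass
class SignalWindow:
    """One 32-s model example: 3 derived channels x 128 samples at 4 Hz."""

    channels: np.ndarray              # (3, 128), z-normalised, CHANNEL_ORDER
    resp_ref: np.ndarray              # (128,), z-normalised reference
    rr_avg_gt: float                  # BrPM
    rr_inst_gt: np.ndarray            # BrPM per reference breath interval
    window_start_s: float = 0.0
    subject_id: str = "sim"
    noisy: bool = False               # motion bursts injected at simulation

    def __post_init__(self):
        self.channels = np.asarray(self.channels, dtype=np.float64)
        self.resp_ref = np.asarray(self.resp_ref, dtype=np.float64)
        self.rr_inst_gt = np.asarray(self.rr_inst_gt, dtype=np.float64)
        if self.channels.shape != (len(CHANNEL_ORDER), OUT_LEN):
            raise ValueError(f"channels must be {(len(CHANNEL_ORDER), OUT_LEN)}")
        if self.resp_ref.shape != (OUT_LEN,):
            raise ValueError(f"resp_ref must have {OUT_LEN} samples")
        if np.isfinite(self.rr_avg_gt) and self.rr_avg_gt < 0:
            raise ValueError("rr_avg_gt must be non-negative")


def detect_r_peaks(ecg, fs: float, annotated=None) -> np.ndarray:
    """QRS detection by band-passed derivative energy with an adaptive
    threshold and a 200-ms refractory period.

    When ``annotated`` peak indices are supplied they are returned
    unchanged (annotation passthrough).  A peak-free signal yields an empty
    array with a warning, never an exception.
    """
    if annotated is not None:
        return np.asarray(annotated, dtype=np.intp)
    x = np.asarray(ecg, dtype=np.float64)
    if len(x) < 2 * fs:
        raise ValueError("need at least 2 s of ECG")
    sos = signal.butter(2, [5.0, min(30.0, 0.45 * fs)], btype="band", fs=fs,
                        output="sos")
    bp = signal.sosfiltfilt(sos, x)
    energy = bp ** 2
    win = max(int(round(0.1 * fs)), 1)
    smooth = np.convolve(energy, np.ones(win) / win, mode="same")
    level = np.quantile(smooth, 0.99)
    if level <= 0:
        warnings.warn("no QRS energy found; returning empty peak list")
        return np.empty(0, dtype=np.intp)
    peaks, _ = signal.find_peaks(smooth, height=0.2 * level,
                                 distance=max(int(round(0.2 * fs)), 1))
    if peaks.size == 0:
        warnings.warn("no R peaks detected")
        return np.empty(0, dtype=np.intp)
    # refine to the raw-ECG maximum within +-50 ms
    half = int(round(0.05 * fs))
    refined = []
    for p in peaks:
        lo, hi = max(p - half, 0), min(p + half + 1, len(x))
        refined.append(lo + int(np.argmax(x[lo:hi])))
    refined = np.unique(np.asarray(refined, dtype=np.intp))
    return refined


def _beat_series_to_grid(times_s: np.ndarray, values: np.ndarray,
                         out_fs: float, out_len: int,
                         t0: float = 0.0) -> np.ndarray:
    """Cubic-spline a beat-domain series onto a uniform grid, mean-removed."""
    grid = t0 + np.arange(out_len) / out_fs
    cs = CubicSpline(times_s, values)
    y = cs(np.clip(grid, times_s[0], times_s[-1]))  # clamp extrapolation
    return y - y.mean()


def extract_edr_rrint(peaks, fs: float, out_fs: float = OUT_FS,
                      out_len: int = OUT_LEN) -> np.ndarray:
    """Respiration surrogate from successive R-R intervals."""
    peaks = np.asarray(peaks, dtype=np.float64)
    if len(peaks) < 3:
        raise ValueError("need at least 3 R peaks for an interval series")
    t = peaks[1:] / fs
    d = np.diff(peaks) / fs
    return _beat_series_to_grid(t, d, out_fs, out_len)


def extract_edr_rpa(peaks, amplitudes, fs: float, out_fs: float = OUT_FS,
                    out_len: int = OUT_LEN) -> np.ndarray:
    """Respiration surrogate from the R-peak amplitude series."""
    peaks = np.asarray(peaks, dtype=np.float64)
    amplitudes = np.asarray(amplitudes, dtype=np.float64)
    if len(amplitudes) != len(peaks):
        raise ValueError("amplitudes and peaks must have equal length")
    if len(peaks) < 3:
        raise ValueError("need at least 3 R peaks for an amplitude series")
    return _beat_series_to_grid(peaks / fs, amplitudes, out_fs, out_len)


def _resample_to(x: np.ndarray, fs_in: float, fs_out: float,
                 out_len: int) -> np.ndarray:
    frac = Fraction(fs_out / fs_in).limit_denominator(10000)
    y = signal.resample_poly(x, frac.numerator, frac.denominator)
    if len(y) < out_len:
        y = np.pad(y, (0, out_len - len(y)), mode="edge")
    return y[:out_len]


def extract_adr(accel_xyz, fs: float, out_fs: float = OUT_FS,
                out_len: int = OUT_LEN, *, taps_s: float = 1.0,
                mu: float = 0.01) -> np.ndarray:
    """Accelerometer-derived respiration via adaptive noise cancellation.

    The dominant-variance axis is decimated to an 8-Hz working rate (the
    respiration band is a comfortable fraction of that Nyquist range, so
    the band-pass stays numerically well conditioned), where a
    normalised-LMS filter (length ``taps_s`` seconds, step ``mu``) predicts
    the axis from its 0.1-1 Hz band-passed copy.  The coefficients adapted
    over the window are then applied as a fixed filter to the reference (a
    second, non-adaptive pass), so the output is a genuine filtering of the
    band-limited reference free of warm-up and coefficient-jitter
    artefacts.  The result is resampled to the output grid and
    mean-removed.  All-zero input returns zeros.
    """
    a = np.atleast_2d(np.asarray(accel_xyz, dtype=np.float64))
    n = a.shape[1]
    if n < 10 * fs:
        raise ValueError("need at least 10 s of accelerometer data")
    if not np.any(a):
        return np.zeros(out_len)
    axis = a[int(np.argmax(a.var(axis=1)))]
    axis = axis - axis.mean()
    work_fs = 8.0
    n_work = int(round(n * work_fs / fs))
    axis = _resample_to(axis, fs, work_fs, n_work)
    # brick-wall DFT band-pass: exact for fixed-length windowed processing
    spec = np.fft.rfft(axis)
    freqs = np.fft.rfftfreq(n_work, 1.0 / work_fs)
    spec[(freqs < 0.1) | (freqs > 1.0)] = 0.0
    ref = np.fft.irfft(spec, n=n_work)
    taps = max(int(round(taps_s * work_fs)), 1)
    w = np.zeros(taps)
    eps = 1e-12
    for i in range(taps, n_work):
        u = ref[i - taps:i]
        e = axis[i] - w @ u
        w += mu * e * u / (u @ u + eps)
    # replay: converged coefficients as a fixed FIR over the whole window
    padded = np.concatenate([ref[1:taps + 1][::-1], ref])
    y = signal.lfilter(w[::-1], 1.0, padded)[taps:]
    out = _resample_to(y, work_fs, out_fs, out_len)
    return out - out.mean()


def _znorm(x: np.ndarray, eps: float = 1e-9) -> np.ndarray:
    sd = x.std()
    return (x - x.mean()) / (sd + eps)


def make_windows(recording: RawRecording, window_s: float = WINDOW_S,
                 stride_s: float | None = None, out_fs: float = OUT_FS,
                 noisy: bool = False) -> list[SignalWindow]:
    """Cut a recording into half-open [start, start + window_s) windows and
    derive the three model channels for each.

    Windows in which a channel cannot be derived (for example too few
    detected beats) are skipped with a warning.  A recording shorter than
    one window yields an empty list with a warning.
    """
    stride_s = window_s if stride_s is None else stride_s
    out_len = int(round(window_s * out_fs))
    if recording.duration_s < window_s:
        warnings.warn("recording shorter than one window; no windows made")
        return []
    peaks_all = detect_r_peaks(recording.ecg, recording.ecg_fs,
                               annotated=recording.r_peaks)
    n_win = int((recording.duration_s - window_s) // stride_s) + 1
    out = []
    for k in range(n_win):
        t0 = k * stride_s
        t1 = t0 + window_s
        e0 = int(round(t0 * recording.ecg_fs))
        e1 = int(round(t1 * recording.ecg_fs))
        pk = peaks_all[(peaks_all >= e0) & (peaks_all < e1)] - e0
        a0 = int(round(t0 * recording.accel_fs))
        a1 = int(round(t1 * recording.accel_fs))
        r0 = int(round(t0 * recording.resp_fs))
        r1 = int(round(t1 * recording.resp_fs))
        try:
            rrint = extract_edr_rrint(pk, recording.ecg_fs, out_fs, out_len)
            amps = recording.ecg[e0:e1][pk]
            rpa = extract_edr_rpa(pk, amps, recording.ecg_fs, out_fs, out_len)
            adr = extract_adr(recording.accel[:, a0:a1], recording.accel_fs,
                              out_fs, out_len)
        except ValueError as exc:
            warnings.warn(f"window at {t0:.0f} s skipped: {exc}")
            continue
        ref = _resample_to(recording.resp_ref[r0:r1], recording.resp_fs,
                           out_fs, out_len)
        breaths = advanced_count_rr(ref, out_fs)
        channels = np.stack([_znorm(rrint), _znorm(rpa), _znorm(adr)])
        out.append(SignalWindow(
            channels=channels, resp_ref=_znorm(ref),
            rr_avg_gt=breaths.rr_avg, rr_inst_gt=breaths.rr_inst,
            window_start_s=t0, subject_id=recording.subject_id, noisy=noisy))
    return out


# ---------------------------------------------------------------------------
# persistence and training helpers
# ---------------------------------------------------------------------------

def windows_to_h5(windows: list[SignalWindow], path) -> None:
    """Store windows in an HDF5 container with named arrays; instantaneous
    rates are padded with NaN to a common width."""
    n = len(windows)
    max_b = max((len(w.rr_inst_gt) for w in windows), default=0)
    inst = np.full((n, max_b), np.nan)
    for i, w in enumerate(windows):
        inst[i, :len(w.rr_inst_gt)] = w.rr_inst_gt
    with h5py.File(path, "w") as f:
        f.create_dataset("channels", data=np.stack([w.channels for w in windows]))
        f.create_dataset("resp_ref", data=np.stack([w.resp_ref for w in windows]))
        f.create_dataset("rr_avg_gt", data=np.array([w.rr_avg_gt for w in windows]))
        f.create_dataset("rr_inst_gt", data=inst)
        f.create_dataset("window_start_s",
                         data=np.array([w.window_start_s for w in windows]))
        f.create_dataset("subject_id",
                         data=np.array([w.subject_id for w in windows],
                                       dtype=h5py.string_dtype()))
        f.create_dataset("noisy", data=np.array([w.noisy for w in windows]))


def windows_from_h5(path) -> list[SignalWindow]:
    with h5py.File(path, "r") as f:
        channels = f["channels"][...]
        resp_ref = f["resp_ref"][...]
        rr_avg = f["rr_avg_gt"][...]
        inst = f["rr_inst_gt"][...]
        starts = f["window_start_s"][...]
        subjects = [s.decode() for s in f["subject_id"][...]]
        noisy = f["noisy"][...]
    out = []
    for i in range(len(rr_avg)):
        row = inst[i]
        out.append(SignalWindow(
            channels=channels[i], resp_ref=resp_ref[i],
            rr_avg_gt=float(rr_avg[i]), rr_inst_gt=row[np.isfinite(row)],
            window_start_s=float(starts[i]), subject_id=subjects[i],
            noisy=bool(noisy[i])))
    return out


def windows_to_arrays(windows: list[SignalWindow]):
    """(X, y_resp, y_rr) training arrays."""
    X = np.stack([w.channels for w in windows])
    y_resp = np.stack([w.resp_ref for w in windows])
    y_rr = np.array([w.rr_avg_gt for w in windows])
    return X, y_resp, y_rr


def train_test_split(windows: list[SignalWindow], train_frac: float = 0.8,
                     mode: str = "window", seed: int = 0):
    """Seeded 80:20 (by default) split, window-wise or subject-wise."""
    if not 0 < train_frac < 1:
        raise ValueError("train_frac must be in (0, 1)")
    rng = np.random.default_rng(seed)
    if mode == "window":
        idx = rng.permutation(len(windows))
        cut = int(round(train_frac * len(windows)))
        train = [windows[i] for i in idx[:cut]]
        test = [windows[i] for i in idx[cut:]]
    elif mode == "subject":
        subjects = sorted({w.subject_id for w in windows})
        order = rng.permutation(len(subjects))
        cut = int(round(train_frac * len(subjects)))
        train_subj = {subjects[i] for i in order[:cut]}
        train = [w for w in windows if w.subject_id in train_subj]
        test = [w for w in windows if w.subject_id not in train_subj]
    else:
        raise ValueError("mode must be 'window' or 'subject'")
    return train, test
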