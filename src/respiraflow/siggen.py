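"""Seeded synthetic cardiorespiratory simulator.

Generates multi-rate recordings (ECG, triaxial accelerometer, reference
respiration) in which breathing leaves its three canonical fingerprints:

* respiratory sinus arrhythmia — the instantaneous beat interval is
  modulated sinusoidally at the breathing frequency (``rsa_depth``);
* R-peak amplitude modulation — each synthetic R-wave is scaled by
  ``1 + rpa_depth * sin(phase)``;
* chest motion — one accelerometer axis carries the breathing sinusoid at
  ``adr_gain`` g on top of white measurement noise.

R-waves are rendered as Gaussian bumps at the modulated beat times, which
is sufficient for peak-based respiration extraction; full P-QRS-T
morphology is deliberately out of scope.  Optional band-limited motion
bursts emulate transient movement artefacts and corrupt both accelerometer
and ECG; recordings carrying bursts are tagged so downstream uncertainty
tests can check that they are preferentially rejected.

Everything is driven by a single integer seed: identical parameters give
bit-identical recordings.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
from scipy import signal

__all__ = ["SimParams", "RawRecording", "SimDataset", "simulate_recording",
           "simulate_dataset", "write_recording", "read_recording"]

_R_WAVE_SIGMA_S = 0.012   # Gaussian R-wave width in seconds


@dataclass(frozen=True)
class SimParams:
    """Simulation parameters; defaults mirror a chest-worn exercise recorder
    (ECG and accelerometer at 256 Hz, reference respiration at 25.6 Hz)."""

    duration_s: float = 32.0
    resp_freq_hz: float | tuple = 0.25       # scalar or ((t0, f0), (t1, f1), ...)
    mean_hr_bpm: float = 80.0
    rsa_depth: float = 0.1                   # fractional beat-interval modulation
    rpa_depth: float = 0.2                   # fractional R-amplitude modulation
    adr_gain: float = 0.05                   # g
    motion_noise_sd: float = 0.01            # g, additive white accel noise
    ecg_noise_sd: float = 0.02
    burst_amp: float = 0.0                   # band-limited motion-burst amplitude
    burst_rate_hz: float = 0.02              # expected bursts per second
    ecg_fs_hz: float = 256.0
    accel_fs_hz: float = 256.0
    resp_fs_hz: float = 25.6
    seed: int = 0

    def __post_init__(self):
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")
        for name in ("mean_hr_bpm", "ecg_fs_hz", "accel_fs_hz", "resp_fs_hz"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 <= self.rsa_depth < 1:
            raise ValueError("rsa_depth must be in [0, 1)")
        if self.rpa_depth < 0 or self.adr_gain < 0:
            raise ValueError("modulation depths must be non-negative")
        for _, f in self._resp_segments():
            if not 4.0 <= f * 60.0 <= 60.0:
                raise ValueError(
                    f"respiratory frequency {f} Hz is outside 4-60 BrPM")

    def _resp_segments(self) -> tuple[tuple[float, float], ...]:
        f = self.resp_freq_hz
        if np.isscalar(f):
            return ((0.0, float(f)),)
        return tuple((float(t), float(v)) for t, v in f)

    def resp_phase(self, t: np.ndarray) -> np.ndarray:
        """Breathing phase 2*pi*integral(f dt), continuous across segments."""
        segs = self._resp_segments()
        t = np.asarray(t, dtype=np.float64)
        phase = np.zeros_like(t)
        acc = 0.0
        for i, (t0, f) in enumerate(segs):
            t1 = segs[i + 1][0] if i + 1 < len(segs) else np.inf
            m = (t >= t0) & (t < t1)
            phase[m] = acc + f * (t[m] - t0)
            if np.isfinite(t1):
                acc += f * (t1 - t0)
        return 2.0 * np.pi * phase


@dataclass
class RawRecording:
    """Multi-rate raw signals with optional R-peak annotations."""

    ecg: np.ndarray
    ecg_fs: float
    accel: np.ndarray                       # (3, n) in g
    accel_fs: float
    resp_ref: np.ndarray
    resp_fs: float
    r_peaks: np.ndarray | None = None       # sorted sample indices into ecg
    beat_times_s: np.ndarray | None = None  # simulator ground truth
    burst_spans_s: tuple = ()               # (start, stop) of motion bursts
    true_rr_brpm: float | None = None       # simulator ground truth (constant f)
    subject_id: str = "sim"

    def __post_init__(self):
        self.ecg = np.asarray(self.ecg, dtype=np.float64)
        self.accel = np.asarray(self.accel, dtype=np.float64)
        self.resp_ref = np.asarray(self.resp_ref, dtype=np.float64)
        if self.accel.ndim != 2 or self.accel.shape[0] != 3:
            raise ValueError("accel must have shape (3, n)")
        if self.r_peaks is not None:
            self.r_peaks = np.asarray(self.r_peaks, dtype=np.intp)
            if np.any(np.diff(self.r_peaks) <= 0):
                raise ValueError("r_peaks must be strictly increasing")
            if self.r_peaks.size and (self.r_peaks[0] < 0
                                      or self.r_peaks[-1] >= len(self.ecg)):
                raise ValueError("r_peaks outside the ECG record")

    @property
    def duration_s(self) -> float:
        return len(self.ecg) / self.ecg_fs


def _beat_times(p: SimParams) -> np.ndarray:
    times = []
    t = 0.0
    base = 60.0 / p.mean_hr_bpm
    while t < p.duration_s:
        times.append(t)
        mod = np.sin(p.resp_phase(np.array([t]))[0])
        t += base * (1.0 + p.rsa_depth * mod)
    return np.asarray(times)


def _motion_bursts(p: SimParams, rng: np.random.Generator,
                   n: int) -> tuple[np.ndarray, tuple]:
    """Band-limited (0.3-5 Hz) noise bursts of 1-3 s; returns series + spans.

    The band overlaps the respiration band, as real movement artefacts
    (steps, posture sway) do, so bursts genuinely contaminate the derived
    respiration channels."""
    out = np.zeros(n)
    spans = []
    if p.burst_amp <= 0:
        return out, ()
    n_bursts = rng.poisson(p.burst_rate_hz * p.duration_s)
    sos = signal.butter(2, [0.3, 5.0], btype="band", fs=p.accel_fs_hz,
                        output="sos")
    for _ in range(n_bursts):
        start = rng.uniform(0, max(p.duration_s - 1.0, 0.0))
        width = rng.uniform(1.0, 3.0)
        i0 = int(start * p.accel_fs_hz)
        i1 = min(int((start + width) * p.accel_fs_hz), n)
        if i1 <= i0:
            continue
        burst = signal.sosfilt(sos, rng.normal(0, 1.0, i1 - i0))
        win = np.hanning(i1 - i0)
        out[i0:i1] += p.burst_amp * burst * win
        spans.append((i0 / p.accel_fs_hz, i1 / p.accel_fs_hz))
    return out, tuple(spans)


def simulate_recording(params: SimParams) -> RawRecording:
    """Render one recording; identical ``params`` (including the seed) give
    bit-identical output."""
    p = params
    rng = np.random.default_rng(p.seed)
    n_ecg = int(round(p.duration_s * p.ecg_fs_hz))
    n_acc = int(round(p.duration_s * p.accel_fs_hz))
    n_resp = int(round(p.duration_s * p.resp_fs_hz))

    beats = _beat_times(p)
    t_ecg = np.arange(n_ecg) / p.ecg_fs_hz
    ecg = np.zeros(n_ecg)
    amps = 1.0 + p.rpa_depth * np.sin(p.resp_phase(beats))
    half = int(round(6 * _R_WAVE_SIGMA_S * p.ecg_fs_hz))
    for tb, amp in zip(beats, amps):
        c = int(round(tb * p.ecg_fs_hz))
        lo, hi = max(c - half, 0), min(c + half + 1, n_ecg)
        if hi <= lo:
            continue
        ecg[lo:hi] += amp * np.exp(
            -0.5 * ((t_ecg[lo:hi] - tb) / _R_WAVE_SIGMA_S) ** 2)
    if p.ecg_noise_sd > 0:
        ecg = ecg + rng.normal(0, p.ecg_noise_sd, n_ecg)

    t_acc = np.arange(n_acc) / p.accel_fs_hz
    accel = np.zeros((3, n_acc))
    accel[0] = p.adr_gain * np.sin(p.resp_phase(t_acc))
    if p.motion_noise_sd > 0:
        accel += rng.normal(0, p.motion_noise_sd, (3, n_acc))
    burst, spans = _motion_bursts(p, rng, n_acc)
    accel += burst[None, :]
    if p.burst_amp > 0 and spans:
        # movement also contaminates the ECG electrodes
        ecg = ecg + 0.5 * np.interp(t_ecg, t_acc, burst)

    t_resp = np.arange(n_resp) / p.resp_fs_hz
    resp_ref = np.sin(p.resp_phase(t_resp))

    r_peaks = np.unique(np.round(beats * p.ecg_fs_hz).astype(np.intp))
    r_peaks = r_peaks[r_peaks < n_ecg]
    f = p.resp_freq_hz
    true_rr = float(f) * 60.0 if np.isscalar(f) else None
    return RawRecording(ecg=ecg, ecg_fs=p.ecg_fs_hz, accel=accel,
                        accel_fs=p.accel_fs_hz, resp_ref=resp_ref,
                        resp_fs=p.resp_fs_hz, r_peaks=r_peaks,
                        beat_times_s=beats, burst_spans_s=spans,
                        true_rr_brpm=true_rr)


@dataclass
class SimDataset:
    """A batch of simulated recordings with per-recording ground truth."""

    recordings: list
    labels_brpm: np.ndarray           # ground-truth average RR per recording
    noisy: np.ndarray                 # True where motion bursts were injected


def simulate_dataset(n_windows: int, param_ranges: dict | None = None,
                     seed: int = 0, base: SimParams | None = None,
                     noisy_fraction: float = 0.0,
                     noisy_burst_amp: float = 0.5) -> SimDataset:
    """Draw ``n_windows`` independent recordings with uniformly sampled
    respiratory and heart rates.

    ``param_ranges`` accepts ``rr_brpm=(lo, hi)`` (default (10, 45)) and
    ``hr_bpm=(lo, hi)`` (default (60, 150)).  A ``noisy_fraction`` of the
    recordings receive motion bursts of amplitude ``noisy_burst_amp`` and
    are flagged in the returned dataset.
    """
    if n_windows < 1:
        raise ValueError("n_windows must be >= 1")
    ranges = {"rr_brpm": (10.0, 45.0), "hr_bpm": (60.0, 150.0)}
    ranges.update(param_ranges or {})
    for key, (lo, hi) in ranges.items():
        if hi < lo:
            raise ValueError(f"empty range for {key}: ({lo}, {hi})")
    base = base or SimParams()
    rng = np.random.default_rng(seed)
    rr = rng.uniform(*ranges["rr_brpm"], n_windows)
    hr = rng.uniform(*ranges["hr_bpm"], n_windows)
    seeds = rng.integers(0, 2 ** 31 - 1, n_windows)
    noisy = np.zeros(n_windows, dtype=bool)
    if noisy_fraction > 0:
        n_noisy = int(round(noisy_fraction * n_windows))
        noisy[rng.choice(n_windows, size=n_noisy, replace=False)] = True
    recs = []
    for i in range(n_windows):
        p = replace(base, resp_freq_hz=rr[i] / 60.0, mean_hr_bpm=hr[i],
                    seed=int(seeds[i]),
                    burst_amp=noisy_burst_amp if noisy[i] else base.burst_amp,
                    burst_rate_hz=0.1 if noisy[i] else base.burst_rate_hz)
        rec = simulate_recording(p)
        rec.subject_id = f"sim{i:04d}"
        recs.append(rec)
    return SimDataset(recordings=recs, labels_brpm=rr, noisy=noisy)


# ---------------------------------------------------------------------------
# delimited-text persistence
# ---------------------------------------------------------------------------

def write_recording(directory, stem: str, rec: RawRecording) -> None:
    """Write a recording as delimited text: one CSV per modality with a
    header row, plus a JSON sidecar with sampling rates and annotations."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    np.savetxt(d / f"{stem}.ecg.csv", rec.ecg[:, None], header="ecg",
               comments="", delimiter=",")
    np.savetxt(d / f"{stem}.accel.csv", rec.accel.T, header="ax,ay,az",
               comments="", delimiter=",")
    np.savetxt(d / f"{stem}.resp.csv", rec.resp_ref[:, None], header="resp",
               comments="", delimiter=",")
    meta = {"ecg_fs": rec.ecg_fs, "accel_fs": rec.accel_fs,
            "resp_fs": rec.resp_fs, "subject_id": rec.subject_id,
            "true_rr_brpm": rec.true_rr_brpm,
            "r_peaks": None if rec.r_peaks is None else rec.r_peaks.tolist()}
    (d / f"{stem}.json").write_text(json.dumps(meta))


def read_recording(directory, stem: str) -> RawRecording:
    d = Path(directory)
    meta = json.loads((d / f"{stem}.json").read_text())
    ecg = np.loadtxt(d / f"{stem}.ecg.csv", skiprows=1, delimiter=",")
    accel = np.loadtxt(d / f"{stem}.accel.csv", skiprows=1, delimiter=",").T
    resp = np.loadtxt(d / f"{stem}.resp.csv", skiprows=1, delimiter=",")
    peaks = meta.get("r_peaks")
    return RawRecording(
        ecg=ecg, ecg_fs=meta["ecg_fs"], accel=accel,
        accel_fs=meta["accel_fs"], resp_ref=resp, resp_fs=meta["resp_fs"],
        r_peaks=None if peaks is None else np.asarray(peaks, dtype=np.intp),
        true_rr_brpm=meta.get("true_rr_brpm"),
        subject_id=meta.get("subject_id", "sim"))
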