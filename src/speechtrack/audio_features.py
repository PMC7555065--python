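"""Auditory regressors: cochlear-style spectrogram, spectral envelope,
autocorrelation pitch, sound ON/OFF and per-fragment intensity.

The filterbank is a linear constant-Q bank of complex Gaussian filters
(128 log-spaced centers, 180-7200 Hz); per-bin magnitudes play the role of
rectified-and-smoothed band outputs, so the spectrogram is homogeneous of
degree one in the input amplitude.  All derived series live on a shared
100 Hz frame grid whose frame k is centered at (k + 0.5) * 10 ms.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._spectral import band_amplitudes
from .fragments import FRAME_RATE, Fragment

__all__ = [
    "Waveform",
    "Spectrogram",
    "FeatureStream",
    "cochlear_spectrogram",
    "spectral_envelope",
    "pitch_autocorr",
    "sound_onoff",
    "fragment_intensity",
    "extract_features",
]

N_BINS = 128
FMIN, FMAX = 180.0, 7200.0
SPEC_FRAME_STEP = 0.008  # 8 ms spectrogram frames


@dataclass
class Waveform:
    """Mono audio samples at a fixed sampling rate (16 kHz after standardization)."""

    samples: np.ndarray
    fs: int = 16000

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 1:
            raise ValueError("waveform must be mono (1-D)")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("waveform contains non-finite samples")
        if self.fs <= 2 * FMAX:
            raise ValueError(f"sampling rate {self.fs} too low for a {FMAX} Hz band")

    @property
    def duration(self) -> float:
        return len(self.samples) / self.fs


@dataclass
class Spectrogram:
    magnitudes: np.ndarray  # bins x frames, >= 0
    center_freqs: np.ndarray  # Hz, strictly increasing
    frame_step: float = SPEC_FRAME_STEP

    def __post_init__(self) -> None:
        if np.any(np.diff(self.center_freqs) <= 0):
            raise ValueError("center frequencies must be strictly increasing")

    @property
    def frame_times(self) -> np.ndarray:
        return (np.arange(self.magnitudes.shape[1]) + 0.5) * self.frame_step


@dataclass
class FeatureStream:
    """Envelope, pitch and ON/OFF regressors on a single 100 Hz time base."""

    envelope: np.ndarray
    pitch: np.ndarray
    onoff: np.ndarray
    frame_rate: float = FRAME_RATE
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = len(self.envelope)
        if not (len(self.pitch) == len(self.onoff) == n):
            raise ValueError("feature series must share one time base")
        if not np.isin(np.asarray(self.onoff), (0, 1)).all():
            raise ValueError("onoff must be binary")

    @property
    def frame_times(self) -> np.ndarray:
        return (np.arange(len(self.envelope)) + 0.5) / self.frame_rate

    def __len__(self) -> int:
        return len(self.envelope)


def bin_centers(n_bins: int = N_BINS, fmin: float = FMIN, fmax: float = FMAX) -> np.ndarray:
    return np.geomspace(fmin, fmax, n_bins)


def cochlear_spectrogram(wave: Waveform, n_bins: int = N_BINS) -> Spectrogram:
    """Constant-Q complex Gaussian filterbank magnitudes framed at 8 ms."""
    x = wave.samples
    frame_len = int(round(SPEC_FRAME_STEP * wave.fs))
    if len(x) < frame_len:
        raise ValueError("waveform shorter than one spectrogram frame")
    centers = bin_centers(n_bins)
    # geometric spacing ratio sets the (constant) Q of the bank
    ratio = centers[1] / centers[0]
    sigma_fs = centers * (ratio - 1.0)
    n_frames = len(x) // frame_len
    frame_times = (np.arange(n_frames) + 0.5) * SPEC_FRAME_STEP
    mags = band_amplitudes(x, wave.fs, centers, sigma_fs, frame_times)
    return Spectrogram(mags, centers)


def _resample_frames(values: np.ndarray, src_step: float, dst_rate: float = FRAME_RATE) -> np.ndarray:
    """Linear interpolation from src frame centers onto the 100 Hz centers."""
    src_times = (np.arange(len(values)) + 0.5) * src_step
    total = len(values) * src_step
    n_dst = int(round(total * dst_rate))
    dst_times = (np.arange(n_dst) + 0.5) / dst_rate
    return np.interp(dst_times, src_times, values)


def spectral_envelope(spec: Spectrogram) -> np.ndarray:
    """Bin-averaged magnitudes resampled onto the 100 Hz grid (non-negative)."""
    env = spec.magnitudes.mean(axis=0)
    return np.clip(_resample_frames(env, spec.frame_step), 0.0, None)


def pitch_autocorr(
    wave: Waveform,
    floor: float = 75.0,
    ceiling: float = 600.0,
    voicing_threshold: float = 0.45,
    frame_step: float = 0.01,
    octave_cost: float = 0.05,
) -> np.ndarray:
    """Frame-wise f0 from the window-corrected normalized autocorrelation.

    Frames are 3 floor-periods long, stepped every 10 ms; frames whose peak
    normalized autocorrelation inside [1/ceiling, 1/floor] falls below the
    voicing threshold are coded 0 (unvoiced).  Candidate lags are local
    maxima of the autocorrelation, scored with an octave cost that favors
    the shortest lag among near-equal peaks (subharmonic suppression).
    """
    if not floor < ceiling < wave.fs / 2:
        raise ValueError("need floor < ceiling < Nyquist")
    fs = wave.fs
    win = int(round(3.0 * fs / floor))
    if win < 8:
        raise ValueError("frame too short for the requested pitch floor")
    x = wave.samples
    hop = int(round(frame_step * fs))
    n_frames = int(round(len(x) / fs / frame_step))
    window = np.hanning(win)
    # Boersma-style correction: divide by the window autocorrelation
    wac = np.correlate(window, window, "full")[win - 1 :]
    wac /= wac[0]
    lag_lo = max(2, int(np.floor(fs / ceiling)))
    lag_hi = int(np.ceil(fs / floor))
    out = np.zeros(n_frames)
    nfft = int(2 ** np.ceil(np.log2(2 * win)))
    for k in range(n_frames):
        center = int(round((k + 0.5) * hop))  # frame center at (k+0.5)*step
        start = center - win // 2
        seg = np.zeros(win)
        lo, hi = max(0, start), min(len(x), start + win)
        if hi - lo < win // 2:
            continue
        seg[lo - start : hi - start] = x[lo:hi]
        seg = (seg - seg.mean()) * window
        spec = np.fft.rfft(seg, nfft)
        ac = np.fft.irfft(spec * np.conj(spec), nfft)[:win]
        if ac[0] <= 0:
            continue
        r = ac / ac[0]
        r = r / np.maximum(wac[:win], 1e-6)
        hi_l = min(lag_hi, win - 2)
        if hi_l <= lag_lo:
            continue
        seg_r = r[lag_lo : hi_l + 1]
        # candidate lags: local maxima (plus the global max as fallback)
        interior = (seg_r[1:-1] >= seg_r[:-2]) & (seg_r[1:-1] >= seg_r[2:])
        cand = np.nonzero(interior)[0] + 1
        if cand.size == 0:
            cand = np.array([int(np.argmax(seg_r))])
        taus = (lag_lo + cand) / fs
        scores = seg_r[cand] - octave_cost * np.log2(floor * taus)
        j = int(cand[np.argmax(scores)])
        peak = seg_r[j]
        if peak < voicing_threshold:
            continue
        lag = lag_lo + j
        # parabolic interpolation around the peak
        if 0 < j < len(seg_r) - 1:
            y0, y1, y2 = seg_r[j - 1], seg_r[j], seg_r[j + 1]
            denom = y0 - 2 * y1 + y2
            if abs(denom) > 1e-12:
                lag = lag + 0.5 * (y0 - y2) / denom
        out[k] = fs / lag
    return out


def sound_onoff(wave: Waveform, margin_db: float = 35.0, frame_step: float = 0.01) -> np.ndarray:
    """Binary series: frame intensity above I_max - margin_db."""
    fs = wave.fs
    hop = int(round(frame_step * fs))
    n_frames = len(wave.samples) // hop
    if n_frames < 1:
        raise ValueError("waveform shorter than one frame")
    frames = wave.samples[: n_frames * hop].reshape(n_frames, hop)
    rms = np.sqrt((frames**2).mean(axis=1))
    if not np.any(rms > 0):
        raise ValueError("all-zero input: maximal intensity undefined")
    db = 20.0 * np.log10(np.maximum(rms, 1e-12))
    imax = db.max()
    if np.isinf(margin_db):
        return np.ones(n_frames, dtype=np.int8)
    return (db > imax - margin_db).astype(np.int8)


def fragment_intensity(
    wave: Waveform, fragments, use_rms: bool = False
) -> np.ndarray:
    """Mean absolute sample amplitude (or RMS) per fragment."""
    out = []
    for frag in fragments:
        i0 = int(round(frag.onset * wave.fs))
        i1 = int(round(frag.offset * wave.fs))
        seg = wave.samples[i0:i1]
        if seg.size == 0:
            raise ValueError(f"empty fragment at onset {frag.onset}")
        out.append(np.sqrt((seg**2).mean()) if use_rms else np.abs(seg).mean())
    return np.asarray(out)


def extract_features(
    wave: Waveform,
    pitch_floor: float = 75.0,
    pitch_ceiling: float = 600.0,
    onoff_margin_db: float = 35.0,
) -> FeatureStream:
    """Full regressor set (envelope, pitch, ON/OFF) on the 100 Hz grid."""
    spec = cochlear_spectrogram(wave)
    env = spectral_envelope(spec)
    pitch = pitch_autocorr(wave, pitch_floor, pitch_ceiling)
    onoff = sound_onoff(wave, onoff_margin_db)
    n = min(len(env), len(pitch), len(onoff))
    return FeatureStream(env[:n], pitch[:n], onoff[:n])


def series_for_fragment(series: np.ndarray, frag: Fragment, frame_rate: float = FRAME_RATE) -> np.ndarray:
    """Slice a 100 Hz series to the frames whose centers fall in the fragment."""
    n = len(series)
    centers = (np.arange(n) + 0.5) / frame_rate
    m = (centers >= frag.onset) & (centers < frag.offset)
    return series[m]
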