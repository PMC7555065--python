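"""Raw multichannel recordings -> z-scored 100 Hz high-frequency-band amplitude.

Processing order: channel rejection, zero-phase line-noise notch (50 and
100 Hz), common average reference per grid over good channels, Gabor-wavelet
amplitude in 1 Hz bins over 65-125 Hz averaged into the HFB, frame-averaged
down to 100 Hz, then per-electrode z-scoring over the analysis fragments.

The Gabor atom's Gaussian amplitude envelope has FWHM = 4 wavelengths of the
bin frequency; in frequency this is a Gaussian of sigma_f = 1 / (2 pi
sigma_t).  Downsampling averages the (already smooth) amplitude within
consecutive 10 ms frames, so no extra anti-alias filter is needed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal

from ._spectral import band_amplitudes
from .fragments import FRAME_RATE, FragmentSet

__all__ = [
    "ChannelMeta",
    "RawRecording",
    "HFBMatrix",
    "reject_channels",
    "notch",
    "common_average_reference",
    "gabor_hfb",
    "zscore_over_fragments",
]

_FWHM_TO_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))


@dataclass
class ChannelMeta:
    id: str
    grid: str = "HD"
    good: bool = True
    label: str = ""  # anatomical label, e.g. "dPCC" / "STG"

    def to_dict(self) -> dict:
        return {"id": self.id, "grid": self.grid, "good": self.good, "label": self.label}

    @classmethod
    def from_dict(cls, d: dict) -> "ChannelMeta":
        return cls(d["id"], d.get("grid", "HD"), bool(d.get("good", True)), d.get("label", ""))


@dataclass
class RawRecording:
    """Channels x time signal with per-channel metadata."""

    samples: np.ndarray
    fs: float
    channel_meta: list[ChannelMeta]

    def __post_init__(self) -> None:
        self.samples = np.atleast_2d(np.asarray(self.samples, dtype=np.float64))
        if self.samples.shape[0] != len(self.channel_meta):
            raise ValueError("one metadata entry per channel required")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def duration(self) -> float:
        return self.samples.shape[1] / self.fs

    def good_mask(self) -> np.ndarray:
        return np.array([m.good for m in self.channel_meta], dtype=bool)

    def grids(self) -> dict[str, np.ndarray]:
        out: dict[str, list[int]] = {}
        for i, m in enumerate(self.channel_meta):
            out.setdefault(m.grid, []).append(i)
        return {g: np.array(ix) for g, ix in out.items()}

    def copy(self) -> "RawRecording":
        return RawRecording(self.samples.copy(), self.fs, [replace(m) for m in self.channel_meta])


@dataclass
class HFBMatrix:
    """Per-channel band amplitude on the 100 Hz frame grid."""

    values: np.ndarray  # channels x frames; NaN on bad channels
    channel_meta: list[ChannelMeta]
    frame_rate: float = FRAME_RATE
    zscored: bool = False
    edge_flags: np.ndarray = field(default=None)  # frames contaminated by padding

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=np.float64))
        if self.edge_flags is None:
            self.edge_flags = np.zeros(self.values.shape[1], dtype=bool)
        good = self.good_mask()
        if good.any() and not np.all(np.isfinite(self.values[good])):
            raise ValueError("non-finite HFB values on good channels")

    @property
    def n_frames(self) -> int:
        return self.values.shape[1]

    @property
    def frame_times(self) -> np.ndarray:
        return (np.arange(self.n_frames) + 0.5) / self.frame_rate

    def good_mask(self) -> np.ndarray:
        return np.array([m.good for m in self.channel_meta], dtype=bool)

    def frame_indices(self, onset: float, offset: float) -> np.ndarray:
        t = self.frame_times
        return np.nonzero((t >= onset) & (t < offset))[0]

    def fragment_frames(self, fragments: FragmentSet) -> np.ndarray:
        """Union of frame indices over all fragments (sorted, unique)."""
        idx = [self.frame_indices(f.onset, f.offset) for f in fragments]
        if not idx:
            return np.array([], dtype=int)
        return np.unique(np.concatenate(idx))


def reject_channels(rec: RawRecording, bad_ids: list[str]) -> RawRecording:
    """Flag channels as bad; they are kept in metadata but excluded from math."""
    out = rec.copy()
    known = {m.id for m in out.channel_meta}
    for bid in bad_ids:
        if bid not in known:
            raise KeyError(f"unknown channel id {bid!r}")
    for m in out.channel_meta:
        if m.id in bad_ids:
            m.good = False
    if not out.good_mask().any():
        raise ValueError("all channels rejected")
    return out


def notch(rec: RawRecording, freqs=(50.0, 100.0), bandwidth: float = 4.0) -> RawRecording:
    """Zero-phase IIR notch at each line frequency (forward-backward)."""
    out = rec.copy()
    good = out.good_mask()
    for f in freqs:
        if f >= rec.fs / 2:
            raise ValueError(f"notch frequency {f} Hz at or above Nyquist ({rec.fs / 2} Hz)")
        b, a = signal.iirnotch(f, f / bandwidth, fs=rec.fs)
        out.samples[good] = signal.filtfilt(b, a, out.samples[good], axis=1)
    return out


def common_average_reference(rec: RawRecording) -> RawRecording:
    """Subtract the instantaneous mean over good channels, per grid."""
    out = rec.copy()
    good = out.good_mask()
    for grid, idx in out.grids().items():
        gidx = idx[good[idx]]
        if len(gidx) < 2:
            raise ValueError(f"grid {grid!r} has fewer than 2 good channels")
        out.samples[gidx] -= out.samples[gidx].mean(axis=0, keepdims=True)
    return out


def gabor_hfb(
    rec: RawRecording,
    band: tuple[float, float] = (65.0, 125.0),
    bin_step: float = 1.0,
    fwhm_cycles: float = 4.0,
) -> HFBMatrix:
    """Mean Gabor-wavelet amplitude over 1 Hz bins in ``band``, at 100 Hz.

    Edges are handled by reflection padding; frames whose wavelet support
    touches the padding are flagged in ``edge_flags``.
    """
    lo, hi = band
    if not 0 < lo <= hi:
        raise ValueError("band must satisfy 0 < lo <= hi")
    if hi >= rec.fs / 2:
        raise ValueError(f"band edge {hi} Hz at or above Nyquist ({rec.fs / 2} Hz)")
    centers = np.arange(lo, hi + 0.5 * bin_step, bin_step, dtype=float)
    sigma_t = (fwhm_cycles / centers) / _FWHM_TO_SIGMA
    sigma_f = 1.0 / (2.0 * np.pi * sigma_t)
    pad = int(np.ceil(4.0 * sigma_t.max() * rec.fs))
    pad_t = pad / rec.fs
    n = rec.samples.shape[1]
    if pad >= n:
        raise ValueError("recording too short for the wavelet support")
    n_frames = int(n / rec.fs * FRAME_RATE)
    # average the amplitude over 5 sub-samples per 10 ms frame
    sub = 5
    sub_times = pad_t + (np.arange(n_frames * sub) + 0.5) / (FRAME_RATE * sub)
    values = np.full((rec.n_channels, n_frames), np.nan)
    good = rec.good_mask()
    for ch in np.nonzero(good)[0]:
        x = rec.samples[ch]
        xp = np.concatenate([x[pad:0:-1], x, x[-2 : -pad - 2 : -1]])
        amps = band_amplitudes(xp, rec.fs, centers, sigma_f, sub_times).mean(axis=0)
        values[ch] = amps.reshape(n_frames, sub).mean(axis=1)
    edge = np.zeros(n_frames, dtype=bool)
    t_rel = (np.arange(n_frames) + 0.5) / FRAME_RATE
    edge[(t_rel < pad_t) | (t_rel > n / rec.fs - pad_t)] = True
    return HFBMatrix(values, [replace(m) for m in rec.channel_meta], edge_flags=edge)


def zscore_over_fragments(hfb: HFBMatrix, fragments: FragmentSet) -> HFBMatrix:
    """Per-electrode z-score with moments taken over the fragment frames only.

    Frames outside the fragments are transformed with the same parameters.
    """
    idx = hfb.fragment_frames(fragments)
    if idx.size < 2:
        raise ValueError("fragments cover fewer than 2 frames")
    values = hfb.values.copy()
    good = hfb.good_mask()
    mu = np.nanmean(values[:, idx], axis=1, keepdims=True)
    sd = np.nanstd(values[:, idx], axis=1, keepdims=True)
    for ch in np.nonzero(good)[0]:
        if sd[ch, 0] < 1e-12:
            raise ValueError(f"zero-variance channel {hfb.channel_meta[ch].id!r}")
    values[good] = (values[good] - mu[good]) / sd[good]
    return HFBMatrix(
        values,
        [replace(m) for m in hfb.channel_meta],
        frame_rate=hfb.frame_rate,
        zscored=True,
        edge_flags=hfb.edge_flags.copy(),
    )
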