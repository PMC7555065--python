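"""Synthetic annotated audio and coupled multichannel neural recordings.

The generator lays out mutually non-overlapping 4-s fragment windows
(speech / nonspeech / noisy speech) on a 10 ms grid, renders a speech-like
source (harmonic complex with an f0 random walk, amplitude-modulated at
syllabic rates) plus a music/noise-like background, and synthesizes raw
neural channels whose 65-125 Hz amplitude follows the speech envelope at a
configurable gain and lag, on top of pink noise and line noise.

Everything is reproducible from ``SimConfig.seed``: each stage draws from an
independent child generator keyed off the seed, so the annotation is
bit-identical regardless of which downstream stages run.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
from scipy import signal

from . import io as stio
from .audio_features import FeatureStream, Waveform
from .fragments import FRAME_RATE, Annotation, Interval
from .preprocess import ChannelMeta, RawRecording

__all__ = [
    "SimConfig",
    "ChannelTruth",
    "GroundTruth",
    "CapacityError",
    "make_annotation",
    "synthesize_audio",
    "oracle_features",
    "synthesize_neural",
    "default_ground_truth",
    "make_fixture",
]

TRACKING_KINDS = ("envelope_tracking", "stg_like")
ALL_KINDS = TRACKING_KINDS + ("onoff_only", "unresponsive")


class CapacityError(ValueError):
    """Requested fragments do not fit into the total duration."""


def _q(t: float) -> float:
    """Quantize to the 10 ms frame grid."""
    return round(t * FRAME_RATE) / FRAME_RATE


@dataclass
class SimConfig:
    seed: int = 0
    total_duration: float | None = None  # seconds; None = auto-sized
    n_speech_fragments: int = 10
    n_nonspeech_fragments: int = 10
    n_noisy_fragments: int = 0
    fragment_duration: float = 4.0
    pause_range: tuple[float, float] = (0.15, 0.4)
    audio_fs: int = 16000
    neural_fs: float = 2000.0
    n_channels: int = 8
    snr_noisy_db: float = 0.0
    line_noise_hz: float = 50.0

    def __post_init__(self) -> None:
        if min(self.n_speech_fragments, self.n_nonspeech_fragments, self.n_noisy_fragments) < 0:
            raise ValueError("fragment counts must be non-negative")
        if self.fragment_duration <= 0:
            raise ValueError("fragment_duration must be positive")
        pmin, pmax = self.pause_range
        if not (0.12 <= pmin < pmax <= 0.5):
            raise ValueError("pause_range must satisfy 0.12 <= min < max <= 0.5")
        if self.audio_fs <= 2 * 7200:
            raise ValueError("audio_fs must exceed twice the 7200 Hz band edge")
        if self.total_duration is None:
            n = self.n_speech_fragments + self.n_nonspeech_fragments + self.n_noisy_fragments
            self.total_duration = _q(1.0 + n * (self.fragment_duration + 1.5) + 1.0)

    @property
    def n_fragments(self) -> int:
        return self.n_speech_fragments + self.n_nonspeech_fragments + self.n_noisy_fragments


def _rng(config: SimConfig, stage: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(config.seed), stage]))


@dataclass
class ChannelTruth:
    channel: str
    kind: str
    gain: float = 0.0
    lag_ms: float = 0.0
    noise_sd: float = 1.0

    def __post_init__(self) -> None:
        if self.kind not in ALL_KINDS:
            raise ValueError(f"unknown channel kind {self.kind!r}")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if self.kind in TRACKING_KINDS and self.gain > 0 and not -100.0 <= self.lag_ms <= 500.0:
            raise ValueError("tracking-channel lag must lie in [-100, 500] ms")


@dataclass
class GroundTruth:
    channels: list[ChannelTruth] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.channels)

    def __iter__(self):
        return iter(self.channels)

    def of_kind(self, *kinds: str) -> list[ChannelTruth]:
        return [c for c in self.channels if c.kind in kinds]

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps([asdict(c) for c in self.channels], indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        return cls([ChannelTruth(**d) for d in json.loads(Path(path).read_text())])


def default_ground_truth(
    config: SimConfig,
    gain: float = 3.0,
    noise_sd: float = 1.0,
    lags_ms: tuple[float, ...] = (0.0, 100.0, 300.0, 500.0),
) -> GroundTruth:
    """Deterministic channel roles: one STG-like reference, tracking channels
    cycling through the injected lags, one ON/OFF channel, rest unresponsive."""
    chans: list[ChannelTruth] = []
    for i in range(config.n_channels):
        cid = f"ch{i:02d}"
        if i == 0:
            chans.append(ChannelTruth(cid, "stg_like", gain=max(gain, 3.0), lag_ms=0.0, noise_sd=noise_sd))
        elif i < config.n_channels - 2:
            lag = lags_ms[(i - 1) % len(lags_ms)]
            chans.append(ChannelTruth(cid, "envelope_tracking", gain=gain, lag_ms=lag, noise_sd=noise_sd))
        elif i == config.n_channels - 2:
            chans.append(ChannelTruth(cid, "onoff_only", gain=gain, lag_ms=0.0, noise_sd=noise_sd))
        else:
            chans.append(ChannelTruth(cid, "unresponsive", gain=0.0, noise_sd=noise_sd))
    return GroundTruth(chans)


# ---------------------------------------------------------------------------
# annotation

def _fill_words(rng: np.random.Generator, t0: float, t1: float, pause_range) -> list[Interval]:
    """Fill [t0, t1) with phrases of contiguous words separated by short pauses.

    The first word starts at t0 and the last word ends exactly at t1, so a
    4-s window anchored at t0 is valid under the pause rule by construction.
    """
    pmin, pmax = pause_range
    words: list[Interval] = []
    cur = t0
    while cur < t1 - 1e-9:
        for _ in range(int(rng.integers(1, 4))):
            wl = _q(rng.uniform(0.25, 0.5))
            end = min(_q(cur + wl), t1)
            if end - cur >= 0.05:
                words.append(Interval(cur, end, "w"))
                cur = end
            if cur >= t1 - 1e-9:
                break
        if cur >= t1 - 1e-9:
            break
        pause = _q(rng.uniform(pmin, pmax))
        if cur + pause >= t1 - 0.25:
            last = words.pop()
            words.append(Interval(last.onset, t1, last.label))
            break
        cur = _q(cur + pause)
    return words


def make_annotation(config: SimConfig) -> Annotation:
    """Lay out fragment windows and their word/overlap/nonspeech/hand tiers."""
    rng = _rng(config, 0)
    conditions = (
        ["speech"] * config.n_speech_fragments
        + ["nonspeech"] * config.n_nonspeech_fragments
        + ["noisy"] * config.n_noisy_fragments
    )
    conditions = [conditions[i] for i in rng.permutation(len(conditions))]
    words: list[Interval] = []
    overlap: list[Interval] = []
    nonspeech: list[Interval] = []
    hand: list[Interval] = []
    t = 0.5
    for cond in conditions:
        t0 = _q(t)
        t1 = _q(t0 + config.fragment_duration)
        if t1 + 0.5 > config.total_duration:
            raise CapacityError(
                f"{len(conditions)} fragments of {config.fragment_duration}s do not fit "
                f"into {config.total_duration}s"
            )
        if cond in ("speech", "noisy"):
            words.extend(_fill_words(rng, t0, t1, config.pause_range))
            if cond == "noisy":
                overlap.append(Interval(t0, t1, "noise"))
        else:
            nonspeech.append(Interval(t0, t1, str(rng.choice(["music", "noise"]))))
        hand.append(Interval(t0, t1, str(int(rng.integers(0, 3)))))
        t = _q(t1 + rng.uniform(0.8, 1.5))
    return Annotation(words=words, overlap=overlap, nonspeech=nonspeech, hand=hand)


# ---------------------------------------------------------------------------
# modulation tracks shared by audio rendering and oracle features

def _bandpassed_noise(rng, n, fs, lo, hi, order=2) -> np.ndarray:
    x = rng.standard_normal(n)
    sos = signal.butter(order, [lo, hi], btype="band", fs=fs, output="sos")
    y = signal.sosfiltfilt(sos, x)
    sd = y.std()
    return y / sd if sd > 0 else y


def _modulation_tracks(annotation: Annotation, config: SimConfig) -> dict:
    """Deterministic 100 Hz control tracks for the speech-like source."""
    rng = _rng(config, 1)
    n = int(round(config.total_duration * FRAME_RATE))
    # f0 random walk reflected into [100, 300] Hz, lightly smoothed
    steps = rng.normal(0.0, 4.0, n)
    f0 = 180.0 + np.cumsum(steps)
    f0 = 100.0 + np.abs((f0 - 100.0) % 400.0 - 200.0)  # reflect into [100, 300]
    k = np.hanning(11)
    f0 = np.convolve(f0, k / k.sum(), mode="same")
    # syllabic amplitude modulation, 3-8 Hz, independent of f0
    am = 0.55 + 0.3 * _bandpassed_noise(rng, n, FRAME_RATE, 3.0, 8.0)
    am = np.clip(am, 0.05, None)
    # slow background modulation ("music")
    bg_am = 0.75 + 0.2 * _bandpassed_noise(rng, n, FRAME_RATE, 0.3, 2.0)
    bg_am = np.clip(bg_am, 0.1, None)
    centers = (np.arange(n) + 0.5) / FRAME_RATE
    gate = np.zeros(n)
    for w in annotation.words:
        gate[(centers >= w.onset) & (centers < w.offset)] = 1.0
    return {"f0": f0, "am": am, "bg_am": bg_am, "gate": gate, "centers": centers}


def oracle_features(annotation: Annotation, config: SimConfig) -> FeatureStream:
    """Ground-truth regressors implied by the synthesis model (100 Hz)."""
    tr = _modulation_tracks(annotation, config)
    envelope = tr["am"] * tr["gate"]
    pitch = tr["f0"] * tr["gate"]
    onoff = tr["gate"].astype(np.int8)
    return FeatureStream(envelope, pitch, onoff)


# ---------------------------------------------------------------------------
# audio

def _upsample(track: np.ndarray, centers: np.ndarray, t_audio: np.ndarray) -> np.ndarray:
    return np.interp(t_audio, centers, track)


def _window_slice(fs: int, iv: Interval, n: int) -> slice:
    return slice(int(round(iv.onset * fs)), min(n, int(round(iv.offset * fs))))


def synthesize_audio(annotation: Annotation, config: SimConfig) -> tuple[Waveform, Waveform]:
    """Render (mixed, isolated_speech) waveforms.

    The isolated track is nonzero only inside word intervals; the background
    (band-limited noise with slow AM) is nonzero only inside nonspeech and
    overlap windows, scaled per overlap window to ``snr_noisy_db`` against
    the speech inside that window.
    """
    tr = _modulation_tracks(annotation, config)
    rng = _rng(config, 2)
    fs = config.audio_fs
    n = int(round(config.total_duration * fs))
    t = np.arange(n) / fs
    f0 = _upsample(tr["f0"], tr["centers"], t)
    am = _upsample(tr["am"], tr["centers"], t)
    # hard word gate with 10 ms raised-cosine edges
    gate = np.zeros(n)
    for w in annotation.words:
        gate[_window_slice(fs, w, n)] = 1.0
    ramp = np.hanning(int(0.01 * fs))
    gate = signal.fftconvolve(gate, ramp / ramp.sum(), mode="same")
    phase = 2.0 * np.pi * np.cumsum(f0) / fs
    speech = np.zeros(n)
    for h in range(1, 9):
        speech += np.sin(h * phase) / h
    speech *= am * gate * 0.3
    # background: band-limited noise with slow AM
    bg_raw = _bandpassed_noise(rng, n, fs, 100.0, 4000.0, order=4)
    bg_raw *= _upsample(tr["bg_am"], tr["centers"], t)
    bg = np.zeros(n)
    word_rms = np.sqrt(np.mean(speech[gate > 0.5] ** 2)) if np.any(gate > 0.5) else 0.0
    for iv in annotation.nonspeech:
        sl = _window_slice(fs, iv, n)
        seg = bg_raw[sl]
        seg_rms = np.sqrt(np.mean(seg**2))
        target = word_rms if word_rms > 0 else 0.05
        if seg_rms > 0:
            bg[sl] = seg * (target / seg_rms)
    if np.isfinite(config.snr_noisy_db):
        snr_amp = 10.0 ** (-config.snr_noisy_db / 20.0)
        for iv in annotation.overlap:
            sl = _window_slice(fs, iv, n)
            seg = bg_raw[sl]
            seg_rms = np.sqrt(np.mean(seg**2))
            sp_rms = np.sqrt(np.mean(speech[sl] ** 2))
            if seg_rms > 0 and sp_rms > 0:
                bg[sl] = seg * (sp_rms * snr_amp / seg_rms)
    # soften background window edges
    if np.any(bg != 0):
        edge = np.hanning(int(0.01 * fs))
        on = signal.fftconvolve((bg != 0).astype(float), edge / edge.sum(), mode="same")
        bg *= np.clip(on, 0.0, 1.0)
    mixed = speech + bg
    peak = np.max(np.abs(mixed))
    scale = 0.95 / peak if peak > 0 else 1.0
    return Waveform(mixed * scale, fs), Waveform(speech * scale, fs)


# ---------------------------------------------------------------------------
# neural

def _pink_noise(rng: np.random.Generator, n: int) -> np.ndarray:
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n)
    spec[1:] /= np.sqrt(freqs[1:])
    spec[0] = 0.0
    x = np.fft.irfft(spec, n)
    return x / x.std()


def _standardize(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    return (x - x.mean()) / sd if sd > 0 else np.zeros_like(x)


def synthesize_neural(
    features: FeatureStream, truth: GroundTruth, config: SimConfig
) -> RawRecording:
    """Raw channels whose 65-125 Hz amplitude follows the driving feature.

    Tracking channels follow the (standardized) envelope delayed by their
    lag; ON/OFF channels follow the binary speech vector; unresponsive
    channels are noise only.  Pink noise and a line-noise sinusoid are added
    to every channel.
    """
    if len(truth) != config.n_channels:
        raise ValueError("ground truth must have one entry per channel")
    rng = _rng(config, 3)
    fs = config.neural_fs
    dur = len(features) / features.frame_rate
    n = int(round(dur * fs))
    t = np.arange(n) / fs
    frame_times = features.frame_times
    env_n = _standardize(np.asarray(features.envelope, dtype=float))
    onoff_n = _standardize(np.asarray(features.onoff, dtype=float))
    sos = signal.butter(4, [65.0, 125.0], btype="band", fs=fs, output="sos")
    samples = np.empty((config.n_channels, n))
    meta: list[ChannelMeta] = []
    for i, ct in enumerate(truth):
        if abs(ct.lag_ms) / 1000.0 >= dur:
            raise ValueError(f"lag {ct.lag_ms} ms not representable in a {dur}s recording")
        if ct.kind in TRACKING_KINDS:
            drive100 = env_n
        elif ct.kind == "onoff_only":
            drive100 = onoff_n
        else:
            drive100 = None
        carrier = signal.sosfiltfilt(sos, rng.standard_normal(n))
        carrier /= np.sqrt(np.mean(carrier**2))
        if drive100 is not None and ct.gain != 0.0:
            d = np.interp(t, frame_times + ct.lag_ms / 1000.0, drive100)
            amp = np.clip(1.0 + ct.gain * d, 0.05, None)
        else:
            amp = 1.0
        sig = carrier * amp
        sig += ct.noise_sd * _pink_noise(rng, n)
        sig += 2.0 * np.sin(2.0 * np.pi * config.line_noise_hz * t + rng.uniform(0, 2 * np.pi))
        samples[i] = sig
        label = "STG" if ct.kind == "stg_like" else ("dPCC" if ct.kind != "unresponsive" else "other")
        meta.append(ChannelMeta(ct.channel, grid="HD", good=True, label=label))
    return RawRecording(samples, fs, meta)


# ---------------------------------------------------------------------------
# fixture bundle

def make_fixture(
    config: SimConfig, outdir: str | Path, truth: GroundTruth | None = None
) -> dict[str, Path]:
    """Write the full bundle: WAV x2, TextGrid + TSV, neural container, JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ann = make_annotation(config)
    mixed, isolated = synthesize_audio(ann, config)
    feats = oracle_features(ann, config)
    if truth is None:
        truth = default_ground_truth(config)
    rec = synthesize_neural(feats, truth, config)
    paths = {
        "audio_mixed": outdir / "audio_mixed.wav",
        "audio_isolated": outdir / "audio_isolated.wav",
        "annotation_textgrid": outdir / "annotation.TextGrid",
        "annotation_tsv": outdir / "annotation.tsv",
        "neural": outdir / "neural.f32",
        "ground_truth": outdir / "ground_truth.json",
        "config": outdir / "config.json",
    }
    stio.write_wav(paths["audio_mixed"], mixed.samples, mixed.fs)
    stio.write_wav(paths["audio_isolated"], isolated.samples, isolated.fs)
    stio.write_textgrid(paths["annotation_textgrid"], ann, config.total_duration)
    stio.write_annotation_tsv(paths["annotation_tsv"], ann)
    stio.write_neural(paths["neural"], rec.samples, rec.fs, [m.to_dict() for m in rec.channel_meta])
    truth.to_json(paths["ground_truth"])
    paths["config"].write_text(json.dumps(asdict(config), indent=1))
    return paths
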