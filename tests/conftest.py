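"""Shared synthetic fixtures.

The heavy end-to-end bundle is built once per session and reused across the
tracking, regression and acceptance tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pytest

from speechtrack import audio_features as af
from speechtrack import fragments as fr
from speechtrack import preprocess as pp
from speechtrack import synthetic_data as sd


@dataclass
class Bundle:
    cfg: sd.SimConfig
    truth: sd.GroundTruth
    ann: fr.Annotation
    mixed: af.Waveform
    isolated: af.Waveform
    feats: af.FeatureStream  # extracted from the mixed track
    env_isolated: np.ndarray  # envelope extracted from the isolated track
    oracle: af.FeatureStream
    hfb: pp.HFBMatrix
    fragset: fr.FragmentSet  # speech + nonspeech
    noisy: fr.FragmentSet
    envelope: np.ndarray  # mixed-track envelope trimmed to the HFB length


TRUTH_LAGS = {"ch01": 0.0, "ch02": 100.0, "ch03": 300.0, "ch04": 500.0}


def build_bundle(seed: int = 7) -> Bundle:
    cfg = sd.SimConfig(
        seed=seed,
        n_speech_fragments=20,
        n_nonspeech_fragments=8,
        n_noisy_fragments=6,
        n_channels=8,
        snr_noisy_db=0.0,
    )
    chans = [
        sd.ChannelTruth("ch00", "stg_like", gain=4.0, lag_ms=0.0),
        sd.ChannelTruth("ch01", "envelope_tracking", gain=3.0, lag_ms=0.0),
        sd.ChannelTruth("ch02", "envelope_tracking", gain=3.0, lag_ms=100.0),
        sd.ChannelTruth("ch03", "envelope_tracking", gain=3.0, lag_ms=300.0),
        sd.ChannelTruth("ch04", "envelope_tracking", gain=3.0, lag_ms=500.0),
        sd.ChannelTruth("ch05", "onoff_only", gain=3.0),
        sd.ChannelTruth("ch06", "unresponsive"),
        sd.ChannelTruth("ch07", "unresponsive"),
    ]
    truth = sd.GroundTruth(chans)
    ann = sd.make_annotation(cfg)
    mixed, isolated = sd.synthesize_audio(ann, cfg)
    feats = af.extract_features(mixed)
    spec_iso = af.cochlear_spectrogram(isolated)
    env_iso = af.spectral_envelope(spec_iso)
    oracle = sd.oracle_features(ann, cfg)
    rec = sd.synthesize_neural(oracle, truth, cfg)
    rec = pp.notch(rec, freqs=(cfg.line_noise_hz, 2 * cfg.line_noise_hz))
    rec = pp.common_average_reference(rec)
    fragset = fr.extract_speech_fragments(ann).extend(fr.extract_nonspeech_fragments(ann))
    hfb = pp.zscore_over_fragments(pp.gabor_hfb(rec), fragset)
    noisy = fr.extract_noisy_fragments(ann)
    n = min(len(feats), hfb.n_frames)
    return Bundle(
        cfg=cfg,
        truth=truth,
        ann=ann,
        mixed=mixed,
        isolated=isolated,
        feats=feats,
        env_isolated=np.asarray(env_iso[:n]),
        oracle=oracle,
        hfb=hfb,
        fragset=fragset,
        noisy=noisy,
        envelope=np.asarray(feats.envelope[:n]),
    )


@pytest.fixture(scope="session")
def bundle() -> Bundle:
    return build_bundle()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
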