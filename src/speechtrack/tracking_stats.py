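"""Lag-resolved rank-correlation machinery and fragment-level contrasts.

Per electrode and fragment the Spearman correlation between an audio
feature and the HFB amplitude is maximized over a lag grid (10 ms steps,
positive lag = audio precedes the neural signal), Fisher-transformed, and
condition contrasts are tested with t tests Bonferroni-corrected over the
number of electrodes in play.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .audio_features import Waveform, fragment_intensity, series_for_fragment
from .fragments import FragmentSet
from .preprocess import HFBMatrix

__all__ = [
    "XCorrProfile",
    "ContrastResult",
    "spearman_rho",
    "lagged_xcorr_max",
    "fisher_z",
    "condition_contrast",
    "speech_preference",
    "envelope_tracking_contrast",
    "stg_reference_coupling",
    "noise_filter_contrast",
    "signed_r2",
    "intensity_contrast",
]


def _ranks(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, method="average")


def spearman_rho(x, y, log_pearson: bool = False) -> float:
    """Rank correlation: cov(rank x, rank y) / (sd(rank x) sd(rank y)).

    ``log_pearson`` switches to the alternative treatment (Pearson on
    log-transformed positive data) kept behind a flag.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D of equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for constant input")
    if log_pearson:
        rx, ry = np.log(x - x.min() + 1e-6), np.log(y - y.min() + 1e-6)
    else:
        rx, ry = _ranks(x), _ranks(y)
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    denom = np.sqrt((rx**2).sum() * (ry**2).sum())
    return float((rx * ry).sum() / denom)


def fisher_z(rho: float | np.ndarray):
    """Variance-stabilizing transform z = 0.5 ln((1+rho)/(1-rho))."""
    rho = np.asarray(rho, dtype=float)
    if np.any(np.abs(rho) >= 1.0):
        raise ValueError("|rho| must be < 1 for the Fisher transform")
    out = np.arctanh(rho)
    return float(out) if out.ndim == 0 else out


@dataclass
class XCorrProfile:
    lags_ms: np.ndarray
    rho_per_lag: np.ndarray  # NaN where the overlap was too short
    max_rho: float
    argmax_lag_ms: float


def lagged_xcorr_max(
    audio_feat: np.ndarray,
    neural: np.ndarray,
    lag_window_ms: tuple[float, float] = (-100.0, 500.0),
    step_ms: float = 10.0,
    min_overlap: int = 300,
) -> XCorrProfile:
    """Max Spearman correlation over a lag grid; ties go to the smallest |lag|.

    Positive lag k means the audio precedes the neural series:
    rho(k) = spearman(audio[0:T-k], neural[k:T]).
    """
    a = np.asarray(audio_feat, dtype=float)
    b = np.asarray(neural, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("series must be 1-D of equal length")
    T = len(a)
    lo, hi = lag_window_ms
    k_lo, k_hi = int(round(lo / step_ms)), int(round(hi / step_ms))
    if max(abs(k_lo), abs(k_hi)) >= T:
        raise ValueError("lag window longer than the fragment")
    eff_overlap = min(min_overlap, T)
    lags = np.arange(k_lo, k_hi + 1)
    rho = np.full(len(lags), np.nan)
    for i, k in enumerate(lags):
        if k >= 0:
            xa, xb = a[: T - k] if k else a, b[k:]
        else:
            xa, xb = a[-k:], b[: T + k]
        if len(xa) < max(3, eff_overlap):
            continue
        if np.ptp(xa) == 0 or np.ptp(xb) == 0:
            continue
        rho[i] = spearman_rho(xa, xb)
    if np.all(np.isnan(rho)):
        raise ValueError("no lag with sufficient overlap / non-constant data")
    best = None
    for i in np.argsort(np.abs(lags), kind="stable"):
        if np.isnan(rho[i]):
            continue
        if best is None or rho[i] > rho[best] + 1e-15:
            best = i
    return XCorrProfile(
        lags_ms=lags * step_ms,
        rho_per_lag=rho,
        max_rho=float(rho[best]),
        argmax_lag_ms=float(lags[best] * step_ms),
    )


@dataclass
class ContrastResult:
    """Per-electrode t contrast with Bonferroni correction over m electrodes."""

    electrodes: list[str]
    t: np.ndarray
    df: np.ndarray
    p_raw: np.ndarray
    p_bonferroni: np.ndarray
    significant: np.ndarray
    direction: np.ndarray
    alpha: float
    m: int
    extras: dict = field(default_factory=dict)

    def significant_ids(self) -> list[str]:
        return [e for e, s in zip(self.electrodes, self.significant) if s]


def _t_contrast(a: np.ndarray, b: np.ndarray, paired: bool) -> tuple[float, int, float]:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if paired:
        if len(a) != len(b):
            raise ValueError("paired contrast requires equal group sizes")
        if len(a) < 2:
            raise ValueError("need at least 2 pairs")
        d = a - b
        if d.std(ddof=1) == 0:
            if np.allclose(d, 0):
                return 0.0, len(a) - 1, 1.0
            raise ValueError("zero variance of paired differences")
        res = stats.ttest_rel(a, b)
        return float(res.statistic), len(a) - 1, float(res.pvalue)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least 2 observations per group")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        if a.mean() == b.mean():
            return 0.0, len(a) + len(b) - 2, 1.0
        raise ValueError("zero variance in both groups")
    res = stats.ttest_ind(a, b)  # pooled-variance Student t
    return float(res.statistic), len(a) + len(b) - 2, float(res.pvalue)


def condition_contrast(
    values_a: np.ndarray,
    values_b: np.ndarray,
    paired: bool = False,
    m_electrodes: int = 1,
    alpha: float = 0.05,
    electrode: str = "e0",
) -> ContrastResult:
    """Student t contrast for one electrode, Bonferroni over ``m_electrodes``."""
    t, df, p = _t_contrast(values_a, values_b, paired)
    p_b = min(1.0, p * m_electrodes)
    return ContrastResult(
        electrodes=[electrode],
        t=np.array([t]),
        df=np.array([df]),
        p_raw=np.array([p]),
        p_bonferroni=np.array([p_b]),
        significant=np.array([p_b < alpha]),
        direction=np.array([np.sign(t)]),
        alpha=alpha,
        m=m_electrodes,
    )


def _stack_contrast(
    electrodes: list[str],
    pairs: list[tuple[np.ndarray, np.ndarray]],
    paired: bool,
    alpha: float,
    m: int | None = None,
) -> ContrastResult:
    m = m if m is not None else len(electrodes)
    t = np.empty(len(pairs))
    df = np.empty(len(pairs), dtype=int)
    p = np.empty(len(pairs))
    for i, (a, b) in enumerate(pairs):
        t[i], df[i], p[i] = _t_contrast(a, b, paired)
    p_b = np.minimum(1.0, p * m)
    return ContrastResult(
        electrodes=electrodes,
        t=t,
        df=df,
        p_raw=p,
        p_bonferroni=p_b,
        significant=p_b < alpha,
        direction=np.sign(t),
        alpha=alpha,
        m=m,
    )


def fragment_mean_hfb(hfb: HFBMatrix, fragments: FragmentSet) -> np.ndarray:
    """Mean HFB per (fragment, electrode); shape (n_fragments, n_channels)."""
    out = np.empty((len(fragments), hfb.values.shape[0]))
    for i, frag in enumerate(fragments):
        idx = hfb.frame_indices(frag.onset, frag.offset)
        if idx.size == 0:
            raise ValueError(f"fragment at {frag.onset}s covers no frames")
        out[i] = hfb.values[:, idx].mean(axis=1)
    return out


def speech_preference(
    hfb: HFBMatrix, fragset: FragmentSet, alpha: float = 0.05
) -> tuple[ContrastResult, list[str]]:
    """Independent t per electrode on fragment-mean HFB, speech vs nonspeech.

    Returns the contrast over all good electrodes plus the mask of
    significant speech-preferring (positive-t) electrodes that downstream
    analyses are restricted to.
    """
    speech = fragset.by_condition("speech")
    nonspeech = fragset.by_condition("nonspeech")
    if len(speech) < 2 or len(nonspeech) < 2:
        raise ValueError("need at least 2 fragments per condition")
    means_s = fragment_mean_hfb(hfb, speech)
    means_n = fragment_mean_hfb(hfb, nonspeech)
    good = np.nonzero(hfb.good_mask())[0]
    electrodes = [hfb.channel_meta[i].id for i in good]
    pairs = [(means_s[:, i], means_n[:, i]) for i in good]
    res = _stack_contrast(electrodes, pairs, paired=False, alpha=alpha)
    mask = [e for e, s, t in zip(electrodes, res.significant, res.t) if s and t > 0]
    res.extras["mask"] = mask
    return res, mask


def _channel_index(hfb: HFBMatrix, electrode_id: str) -> int:
    for i, m in enumerate(hfb.channel_meta):
        if m.id == electrode_id:
            return i
    raise KeyError(f"unknown electrode {electrode_id!r}")


def _per_fragment_max_rho(
    feature: np.ndarray,
    hfb: HFBMatrix,
    channel: int,
    fragments: FragmentSet,
    lag_window_ms: tuple[float, float],
    min_overlap: int = 300,
) -> tuple[np.ndarray, np.ndarray]:
    """(max rho, argmax lag) per fragment for one electrode."""
    rhos = np.empty(len(fragments))
    lags = np.empty(len(fragments))
    for i, frag in enumerate(fragments):
        a = series_for_fragment(feature, frag)
        idx = hfb.frame_indices(frag.onset, frag.offset)
        b = hfb.values[channel, idx]
        n = min(len(a), len(b))
        if np.ptp(a[:n]) == 0 or np.ptp(b[:n]) == 0:
            # degenerate fragment (e.g. silent feature): no measurable rank
            # relation; recorded as zero correlation at zero lag
            rhos[i], lags[i] = 0.0, 0.0
            continue
        prof = lagged_xcorr_max(a[:n], b[:n], lag_window_ms, min_overlap=min_overlap)
        rhos[i] = prof.max_rho
        lags[i] = prof.argmax_lag_ms
    return rhos, lags


def envelope_tracking_contrast(
    hfb: HFBMatrix,
    envelope: np.ndarray,
    fragset: FragmentSet,
    mask: list[str],
    lag_window_ms: tuple[float, float] = (-100.0, 500.0),
    alpha: float = 0.01,
) -> ContrastResult:
    """Per masked electrode: fragmentwise max-lag rho -> Fisher z ->
    independent t, speech vs nonspeech, Bonferroni over the mask size."""
    if not mask:
        raise ValueError("electrode mask is empty")
    speech = fragset.by_condition("speech")
    nonspeech = fragset.by_condition("nonspeech")
    if len(speech) == 0:
        raise ValueError("no speech fragments")
    pairs = []
    best_lags_speech = {}
    best_lags_nonspeech = {}
    mean_profiles = {}
    for eid in mask:
        ch = _channel_index(hfb, eid)
        rho_s, lag_s = _per_fragment_max_rho(envelope, hfb, ch, speech, lag_window_ms)
        rho_n, lag_n = _per_fragment_max_rho(envelope, hfb, ch, nonspeech, lag_window_ms)
        pairs.append((fisher_z(np.clip(rho_s, -0.999999, 0.999999)),
                      fisher_z(np.clip(rho_n, -0.999999, 0.999999))))
        best_lags_speech[eid] = lag_s
        best_lags_nonspeech[eid] = lag_n
        mean_profiles[eid] = (np.nanmean(rho_s), np.nanmean(rho_n))
    res = _stack_contrast(mask, pairs, paired=False, alpha=alpha)
    res.extras["best_lags_speech"] = best_lags_speech
    res.extras["best_lags_nonspeech"] = best_lags_nonspeech
    res.extras["mean_rho"] = mean_profiles
    return res


def channel_lag_profile(
    hfb: HFBMatrix,
    envelope: np.ndarray,
    fragments: FragmentSet,
    electrode_id: str,
    lag_window_ms: tuple[float, float] = (-100.0, 500.0),
) -> XCorrProfile:
    """Fragment-averaged cross-correlation profile for one electrode."""
    ch = _channel_index(hfb, electrode_id)
    acc = None
    lags = None
    for frag in fragments:
        a = series_for_fragment(envelope, frag)
        idx = hfb.frame_indices(frag.onset, frag.offset)
        b = hfb.values[ch, idx]
        n = min(len(a), len(b))
        prof = lagged_xcorr_max(a[:n], b[:n], lag_window_ms)
        acc = prof.rho_per_lag if acc is None else acc + prof.rho_per_lag
        lags = prof.lags_ms
    mean_rho = acc / len(fragments)
    order = np.argsort(np.abs(lags), kind="stable")
    best = None
    for i in order:
        if np.isnan(mean_rho[i]):
            continue
        if best is None or mean_rho[i] > mean_rho[best] + 1e-15:
            best = i
    return XCorrProfile(lags, mean_rho, float(mean_rho[best]), float(lags[best]))


def stg_reference_coupling(
    hfb_all: HFBMatrix,
    envelope: np.ndarray,
    stg_candidate_ids: list[str],
    mask: list[str],
    fragset: FragmentSet,
    lag_window_ms: tuple[float, float] = (-200.0, 200.0),
    alpha: float = 0.01,
) -> tuple[str, ContrastResult, dict]:
    """Select the STG electrode best tracking the envelope, then contrast its
    coupling to each masked electrode between speech and nonspeech."""
    if not stg_candidate_ids:
        raise ValueError("no STG candidates")
    if not mask:
        raise ValueError("electrode mask is empty")
    speech = fragset.by_condition("speech")
    nonspeech = fragset.by_condition("nonspeech")
    best_stg, best_score = None, -np.inf
    for sid in stg_candidate_ids:
        ch = _channel_index(hfb_all, sid)
        rho_s, _ = _per_fragment_max_rho(envelope, hfb_all, ch, speech, (-100.0, 500.0))
        score = rho_s.mean()
        if score > best_score:
            best_stg, best_score = sid, score
    stg_ch = _channel_index(hfb_all, best_stg)
    pairs = []
    lag_distribution = {}
    used = [e for e in mask if e != best_stg]
    for eid in used:
        ch = _channel_index(hfb_all, eid)
        rho_s = np.empty(len(speech))
        lag_s = np.empty(len(speech))
        rho_n = np.empty(len(nonspeech))
        for i, frag in enumerate(speech):
            idx = hfb_all.frame_indices(frag.onset, frag.offset)
            prof = lagged_xcorr_max(hfb_all.values[stg_ch, idx], hfb_all.values[ch, idx], lag_window_ms)
            rho_s[i], lag_s[i] = prof.max_rho, prof.argmax_lag_ms
        for i, frag in enumerate(nonspeech):
            idx = hfb_all.frame_indices(frag.onset, frag.offset)
            prof = lagged_xcorr_max(hfb_all.values[stg_ch, idx], hfb_all.values[ch, idx], lag_window_ms)
            rho_n[i] = prof.max_rho
        pairs.append((fisher_z(np.clip(rho_s, -0.999999, 0.999999)),
                      fisher_z(np.clip(rho_n, -0.999999, 0.999999))))
        lag_distribution[eid] = lag_s
    res = _stack_contrast(used, pairs, paired=False, alpha=alpha)
    res.extras["best_stg"] = best_stg
    res.extras["best_stg_mean_rho"] = float(best_score)
    return best_stg, res, lag_distribution


def noise_filter_contrast(
    hfb: HFBMatrix,
    env_isolated: np.ndarray,
    env_mixed: np.ndarray,
    noisy_fragset: FragmentSet,
    mask: list[str],
    lag_window_ms: tuple[float, float] = (-100.0, 500.0),
    alpha: float = 0.05,
) -> ContrastResult:
    """Paired t per masked electrode: correlation to the isolated-speech
    envelope vs the mixed-track envelope over the noisy fragments."""
    noisy = noisy_fragset.by_condition("noisy")
    if len(noisy) < 2:
        raise ValueError("need at least 2 noisy fragments")
    if len(env_isolated) != len(env_mixed):
        raise ValueError("envelopes must share one time base")
    pairs = []
    for eid in mask:
        ch = _channel_index(hfb, eid)
        rho_iso, _ = _per_fragment_max_rho(env_isolated, hfb, ch, noisy, lag_window_ms)
        rho_mix, _ = _per_fragment_max_rho(env_mixed, hfb, ch, noisy, lag_window_ms)
        pairs.append((fisher_z(np.clip(rho_iso, -0.999999, 0.999999)),
                      fisher_z(np.clip(rho_mix, -0.999999, 0.999999))))
    return _stack_contrast(mask, pairs, paired=True, alpha=alpha)


def signed_r2(values: np.ndarray, labels: np.ndarray) -> float:
    """Squared point-biserial correlation signed by mean(move) - mean(rest).

    ``labels`` is boolean/0-1 with 1 = "move".
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels).astype(bool)
    if labels.all() or (~labels).all():
        raise ValueError("need at least 2 trials in each class")
    if labels.sum() < 2 or (~labels).sum() < 2:
        raise ValueError("need at least 2 trials in each class")
    ind = labels.astype(float)
    if np.ptp(values) == 0:
        return 0.0
    r = np.corrcoef(ind, values)[0, 1]
    sign = np.sign(values[labels].mean() - values[~labels].mean())
    return float(sign * r**2)


def intensity_contrast(
    audio: Waveform, fragset: FragmentSet, use_rms: bool = False
) -> tuple[float, float]:
    """Independent t on per-fragment intensity, speech vs nonspeech."""
    speech = fragset.by_condition("speech")
    nonspeech = fragset.by_condition("nonspeech")
    if len(speech) < 2 or len(nonspeech) < 2:
        raise ValueError("need at least 2 fragments per condition")
    int_s = fragment_intensity(audio, speech, use_rms=use_rms)
    int_n = fragment_intensity(audio, nonspeech, use_rms=use_rms)
    t, _, p = _t_contrast(int_s, int_n, paired=False)
    return t, p
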