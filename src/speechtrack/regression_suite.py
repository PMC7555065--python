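"""ON/OFF regression with a fragment-permutation null, partial rank
correlations, residual group comparisons and covariate / chi-square controls.

The permutation null shuffles the order of the per-fragment design blocks
before concatenation while the response stays fixed; significance compares
the observed F statistic against the empirical (1 - alpha) percentile.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .audio_features import series_for_fragment
from .fragments import FragmentSet
from .preprocess import HFBMatrix
from .tracking_stats import (
    ContrastResult,
    _channel_index,
    _per_fragment_max_rho,
    _t_contrast,
    fisher_z,
    spearman_rho,
    speech_preference,
)

log = logging.getLogger(__name__)

__all__ = [
    "OnOffFit",
    "PermutationNull",
    "GroupComparison",
    "ContingencyTable",
    "lag_align",
    "align_fragments",
    "onoff_ols",
    "permutation_f_test",
    "onoff_condition_contrast",
    "partial_spearman",
    "pitch_envelope_interaction",
    "auditory_ols_residuals",
    "rank_group_comparison",
    "covariate_control",
    "chi2_independence",
]

FRAME_MS = 10.0


@dataclass
class OnOffFit:
    beta: np.ndarray  # (intercept, slope, ...)
    t: np.ndarray  # per coefficient
    f: float
    df1: int
    df2: int
    residuals: np.ndarray
    r2: float


@dataclass
class PermutationNull:
    f_values: np.ndarray
    threshold: float
    alpha: float
    n_perm: int
    seed: int
    observed_f: float
    significant: bool


@dataclass
class GroupComparison:
    h: float
    p_kw: float
    dunn_z: dict
    dunn_p: dict  # Holm-corrected, keyed by (group_a, group_b)
    anova_f: dict  # factor1 / factor2 / interaction on global ranks
    anova_p: dict


@dataclass
class ContingencyTable:
    observed: np.ndarray
    chi2: float
    df: int
    p: float
    yates: bool


# ---------------------------------------------------------------------------
# lag alignment + OLS

def lag_align(series: np.ndarray, lag_ms: float, frame_ms: float = FRAME_MS) -> np.ndarray:
    """Advance a fragment's neural series by its lag: out[t] = in[t + lag].

    Negative lags are clamped to 0 (positive-shift-only convention, logged);
    the trailing frames beyond the fragment are dropped.
    """
    if lag_ms < 0:
        log.info("negative best-lag %.0f ms clamped to 0", lag_ms)
        lag_ms = 0.0
    k = int(round(lag_ms / frame_ms))
    if k >= len(series):
        raise ValueError(f"lag {lag_ms} ms >= fragment length")
    return np.asarray(series, dtype=float)[k:]


def align_fragments(
    hfb: HFBMatrix,
    fragset: FragmentSet,
    electrode_id: str,
    lags_ms: np.ndarray,
    design: np.ndarray,
) -> tuple[list[np.ndarray], list[np.ndarray]]:
    """Per-fragment (response, design) blocks after per-fragment lag shifts.

    ``design`` is a 100 Hz series over the whole recording; each block's
    design is truncated to the shifted response length.
    """
    ch = _channel_index(hfb, electrode_id)
    y_blocks, x_blocks = [], []
    for frag, lag in zip(fragset, lags_ms):
        idx = hfb.frame_indices(frag.onset, frag.offset)
        y = lag_align(hfb.values[ch, idx], lag)
        x = series_for_fragment(design, frag)[: len(y)]
        n = min(len(x), len(y))
        y_blocks.append(y[:n])
        x_blocks.append(x[:n])
    return y_blocks, x_blocks


def onoff_ols(y: np.ndarray, x: np.ndarray) -> OnOffFit:
    """OLS of the response on [1, x]; F tests the slope against intercept-only."""
    y = np.asarray(y, dtype=float)
    x = np.atleast_2d(np.asarray(x, dtype=float))
    if x.shape[0] > x.shape[1]:
        x = x.T
    if x.shape[1] != len(y):
        raise ValueError("design and response lengths differ")
    for j, col in enumerate(x):
        if np.ptp(col) == 0:
            raise ValueError(f"constant regressor (column {j})")
    n = len(y)
    X = np.column_stack([np.ones(n), *x])
    p = X.shape[1] - 1
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    yhat = X @ beta
    resid = y - yhat
    rss = float(resid @ resid)
    tss = float(((y - y.mean()) ** 2).sum())
    df2 = n - p - 1
    if rss <= 1e-12 * max(tss, 1.0):
        f = np.finfo(float).max / 1e6  # exact fit: large finite F
    else:
        f = ((tss - rss) / p) / (rss / df2)
    sigma2 = rss / df2 if df2 > 0 else np.nan
    xtx_inv = np.linalg.inv(X.T @ X)
    se = np.sqrt(np.maximum(np.diag(xtx_inv) * sigma2, 1e-300))
    t = beta / se
    r2 = 1.0 - rss / tss if tss > 0 else 0.0
    return OnOffFit(beta=beta, t=t, f=float(f), df1=p, df2=df2, residuals=resid, r2=r2)


def _f_single_regressor(y: np.ndarray, x: np.ndarray) -> float:
    """F of the slope for a single-column design (fast path, no lstsq)."""
    n = len(y)
    xc = x - x.mean()
    yc = y - y.mean()
    sxx = float(xc @ xc)
    syy = float(yc @ yc)
    if sxx == 0 or syy == 0:
        return 0.0
    r2 = float(xc @ yc) ** 2 / (sxx * syy)
    r2 = min(r2, 1.0 - 1e-15)
    return (n - 2) * r2 / (1.0 - r2)


def permutation_f_test(
    y_blocks: list[np.ndarray],
    x_blocks: list[np.ndarray],
    n_perm: int = 10_000,
    alpha: float = 0.001,
    seed: int = 0,
) -> PermutationNull:
    """Fragment-order permutation null for the ON/OFF regression F statistic.

    Each permutation shuffles the order of the design blocks prior to
    concatenation (responses fixed), refits, and records F; the threshold is
    the empirical (1 - alpha) percentile of the null.
    """
    if len(y_blocks) < 2:
        raise ValueError("need at least 2 fragments to permute")
    if n_perm < 1.0 / alpha:
        warnings.warn(
            f"n_perm={n_perm} < 1/alpha={1 / alpha:.0f}: threshold unreliable",
            stacklevel=2,
        )
    lens_y = [len(b) for b in y_blocks]
    lens_x = [len(b) for b in x_blocks]
    if lens_y != lens_x:
        raise ValueError("response and design blocks must have matching lengths")
    y = np.concatenate(y_blocks)
    observed = _f_single_regressor(y, np.concatenate(x_blocks))
    rng = np.random.default_rng(seed)
    n = len(y)
    nb = len(x_blocks)
    fvals = np.empty(n_perm)
    equal_lengths = len(set(lens_y)) == 1
    if equal_lengths:
        # vectorized: F depends on the permutation only through sum(x_perm * y),
        # since the multiset of x values (hence its mean/variance) is invariant.
        L = lens_y[0]
        xm = np.stack(x_blocks)  # nb x L
        ym = y.reshape(nb, L)
        m = xm @ ym.T  # m[i, p] = dot(x block i, y at position p)
        x_all = xm.ravel()
        sx, sxx = x_all.sum(), float(x_all @ x_all)
        sy, syy = y.sum(), float(y @ y)
        var_x = sxx - sx**2 / n
        var_y = syy - sy**2 / n
        perms = np.stack([rng.permutation(nb) for _ in range(n_perm)])
        sxy = m[perms, np.arange(nb)].sum(axis=1)
        cov = sxy - sx * sy / n
        if var_x <= 0 or var_y <= 0:
            fvals[:] = 0.0
        else:
            r2 = np.minimum(cov**2 / (var_x * var_y), 1.0 - 1e-15)
            fvals = (n - 2) * r2 / (1.0 - r2)
    else:
        for i in range(n_perm):
            order = rng.permutation(nb)
            xp = np.concatenate([x_blocks[j] for j in order])
            fvals[i] = _f_single_regressor(y, xp)
    threshold = float(np.percentile(fvals, 100.0 * (1.0 - alpha)))
    return PermutationNull(
        f_values=fvals,
        threshold=threshold,
        alpha=alpha,
        n_perm=n_perm,
        seed=seed,
        observed_f=float(observed),
        significant=bool(observed > threshold),
    )


def onoff_condition_contrast(
    betas_speech: np.ndarray, betas_nonspeech: np.ndarray
) -> tuple[float, float]:
    """Independent t over electrodes: speech vs nonspeech ON/OFF slopes."""
    if len(betas_speech) < 2 or len(betas_nonspeech) < 2:
        raise ValueError("need at least 2 electrodes per group")
    t, _, p = _t_contrast(np.asarray(betas_speech), np.asarray(betas_nonspeech), paired=False)
    return t, p


# ---------------------------------------------------------------------------
# partial rank correlations

def _rank_residualize(a: np.ndarray, c: np.ndarray) -> np.ndarray:
    X = np.column_stack([np.ones(len(c)), c])
    beta, *_ = np.linalg.lstsq(X, a, rcond=None)
    return a - X @ beta


def partial_spearman(y: np.ndarray, target: np.ndarray, control: np.ndarray) -> float:
    """Rank all three, residualize rank(y) and rank(target) on rank(control),
    return the Pearson correlation of the residuals."""
    y = np.asarray(y, dtype=float)
    target = np.asarray(target, dtype=float)
    control = np.asarray(control, dtype=float)
    if not len(y) == len(target) == len(control):
        raise ValueError("series must have equal length")
    for name, s in (("y", y), ("target", target), ("control", control)):
        if np.ptp(s) == 0:
            raise ValueError(f"constant series: {name}")
    if abs(spearman_rho(target, control)) > 0.999:
        raise ValueError("control is collinear with target")
    ry = stats.rankdata(y)
    rt = stats.rankdata(target)
    rc = stats.rankdata(control)
    ey = _rank_residualize(ry, rc)
    et = _rank_residualize(rt, rc)
    if np.ptp(ey) == 0 or np.ptp(et) == 0:
        return 0.0
    return float(np.corrcoef(ey, et)[0, 1])


def pitch_envelope_interaction(
    envelope: np.ndarray,
    pitch: np.ndarray,
    fragset: FragmentSet,
    envelope_isolated: np.ndarray | None = None,
    pitch_isolated: np.ndarray | None = None,
) -> dict:
    """Per-fragment Spearman(envelope, pitch) by condition, with t contrasts.

    Fragments where either series is constant (e.g. no voicing) are flagged
    and excluded.  When isolated-track series are given, noisy fragments are
    additionally compared isolated vs mixed with a paired t test.
    """

    def _per_fragment(env, pit, frags):
        rhos, excluded = [], []
        for i, frag in enumerate(frags):
            e = series_for_fragment(env, frag)
            p = series_for_fragment(pit, frag)
            n = min(len(e), len(p))
            if n < 3 or np.ptp(e[:n]) == 0 or np.ptp(p[:n]) == 0:
                excluded.append(i)
                continue
            rhos.append(spearman_rho(e[:n], p[:n]))
        return np.array(rhos), excluded

    out: dict = {}
    z_by_cond = {}
    for cond in ("speech", "nonspeech"):
        frags = fragset.by_condition(cond)
        rhos, excl = _per_fragment(envelope, pitch, frags)
        z = fisher_z(np.clip(rhos, -0.999999, 0.999999)) if len(rhos) else np.array([])
        z_by_cond[cond] = z
        entry = {"rho": rhos, "mean_rho": float(rhos.mean()) if len(rhos) else np.nan,
                 "excluded_fragments": excl}
        if len(z) >= 2 and np.ptp(z) > 0:
            res = stats.ttest_1samp(z, 0.0)
            entry["t_vs_zero"], entry["p_vs_zero"] = float(res.statistic), float(res.pvalue)
        out[cond] = entry
    if len(z_by_cond["speech"]) >= 2 and len(z_by_cond["nonspeech"]) >= 2:
        t, _, p = _t_contrast(z_by_cond["speech"], z_by_cond["nonspeech"], paired=False)
        out["speech_vs_nonspeech"] = {"t": t, "p": p}
    if envelope_isolated is not None and pitch_isolated is not None:
        noisy = fragset.by_condition("noisy")
        rho_mix, excl_m = _per_fragment(envelope, pitch, noisy)
        rho_iso, excl_i = _per_fragment(envelope_isolated, pitch_isolated, noisy)
        if len(rho_mix) == len(rho_iso) >= 2:
            t, _, p = _t_contrast(
                fisher_z(np.clip(rho_iso, -0.999999, 0.999999)),
                fisher_z(np.clip(rho_mix, -0.999999, 0.999999)),
                paired=True,
            )
            out["isolated_vs_mixed"] = {"t": t, "p": p,
                                        "mean_rho_isolated": float(rho_iso.mean()),
                                        "mean_rho_mixed": float(rho_mix.mean())}
    return out


# ---------------------------------------------------------------------------
# residual analysis

def auditory_ols_residuals(
    hfb: HFBMatrix,
    envelope: np.ndarray,
    onoff: np.ndarray,
    pitch: np.ndarray,
    fragset: FragmentSet,
    condition: str,
    electrode_ids: list[str] | None = None,
) -> dict:
    """Per-electrode OLS of concatenated condition frames on the three
    auditory regressors; returns residuals split back per fragment."""
    frags = fragset.by_condition(condition)
    if len(frags) == 0:
        raise ValueError(f"no fragments of condition {condition!r}")
    idx_blocks = [hfb.frame_indices(f.onset, f.offset) for f in frags]
    idx = np.concatenate(idx_blocks)
    cols = {"envelope": envelope[idx], "onoff": np.asarray(onoff, dtype=float)[idx],
            "pitch": pitch[idx]}
    names = list(cols)
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            if np.ptp(cols[a]) > 0 and np.ptp(cols[b]) > 0:
                r = np.corrcoef(cols[a], cols[b])[0, 1]
                if abs(r) > 0.9999:
                    raise ValueError(f"collinear design columns: {a}, {b}")
    X = np.column_stack([np.ones(len(idx))] + [cols[c] for c in names])
    if electrode_ids is None:
        electrode_ids = [m.id for m in hfb.channel_meta if m.good]
    out = {"electrodes": electrode_ids, "beta": {}, "residuals": {}, "r2": {},
           "fragment_slices": None, "columns": ["intercept"] + names}
    bounds = np.cumsum([0] + [len(b) for b in idx_blocks])
    out["fragment_slices"] = [slice(bounds[i], bounds[i + 1]) for i in range(len(frags))]
    for eid in electrode_ids:
        ch = _channel_index(hfb, eid)
        y = hfb.values[ch, idx]
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta
        tss = float(((y - y.mean()) ** 2).sum())
        out["beta"][eid] = beta
        out["residuals"][eid] = resid
        out["r2"][eid] = 1.0 - float(resid @ resid) / tss if tss > 0 else 0.0
    return out


def _kruskal_wallis(groups: list[np.ndarray]) -> tuple[float, float]:
    res = stats.kruskal(*groups)
    return float(res.statistic), float(res.pvalue)


def _dunn_tests(groups: dict[str, np.ndarray]) -> tuple[dict, dict]:
    """Pairwise Dunn z tests on joint ranks, Holm-corrected."""
    names = list(groups)
    all_vals = np.concatenate([groups[g] for g in names])
    n_total = len(all_vals)
    ranks = stats.rankdata(all_vals)
    mean_ranks = {}
    pos = 0
    for g in names:
        k = len(groups[g])
        mean_ranks[g] = ranks[pos : pos + k].mean()
        pos += k
    _, tie_counts = np.unique(all_vals, return_counts=True)
    tie_term = (tie_counts**3 - tie_counts).sum() / (12.0 * (n_total - 1))
    base_var = n_total * (n_total + 1) / 12.0 - tie_term
    z_out, p_raw, keys = {}, [], []
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            se = np.sqrt(base_var * (1.0 / len(groups[a]) + 1.0 / len(groups[b])))
            z = (mean_ranks[a] - mean_ranks[b]) / se if se > 0 else 0.0
            z_out[(a, b)] = float(z)
            p_raw.append(2.0 * stats.norm.sf(abs(z)))
            keys.append((a, b))
    # Holm step-down
    p_raw = np.asarray(p_raw)
    order = np.argsort(p_raw)
    m = len(p_raw)
    adj = np.empty(m)
    running = 0.0
    for rank_i, oi in enumerate(order):
        running = max(running, (m - rank_i) * p_raw[oi])
        adj[oi] = min(1.0, running)
    p_out = {k: float(adj[i]) for i, k in enumerate(keys)}
    return z_out, p_out


def _rank_two_way_anova(groups: dict[str, np.ndarray]) -> tuple[dict, dict]:
    """Two-way factorial ANOVA (condition x data-type + interaction) on the
    globally rank-transformed response."""
    import statsmodels.api as sm
    from statsmodels.formula.api import ols

    rows = []
    for key, vals in groups.items():
        cond, dtype = key.split("_", 1)
        for v in vals:
            rows.append({"cond": cond, "dtype": dtype, "value": v})
    df = pd.DataFrame(rows)
    df["rank"] = stats.rankdata(df["value"])
    model = ols("rank ~ C(cond) * C(dtype)", data=df).fit()
    table = sm.stats.anova_lm(model, typ=2)
    f_out = {
        "condition": float(table.loc["C(cond)", "F"]),
        "data_type": float(table.loc["C(dtype)", "F"]),
        "interaction": float(table.loc["C(cond):C(dtype)", "F"]),
    }
    p_out = {
        "condition": float(table.loc["C(cond)", "PR(>F)"]),
        "data_type": float(table.loc["C(dtype)", "PR(>F)"]),
        "interaction": float(table.loc["C(cond):C(dtype)", "PR(>F)"]),
    }
    return f_out, p_out


def rank_group_comparison(groups: dict[str, np.ndarray]) -> GroupComparison:
    """Kruskal-Wallis + Dunn post hocs + rank two-way ANOVA over the four
    {speech, nonspeech} x {full, resid} per-electrode mean-value groups."""
    for g, vals in groups.items():
        if len(vals) < 2:
            raise ValueError(f"group {g!r} has fewer than 2 values")
    arrays = [np.asarray(groups[g], dtype=float) for g in groups]
    if np.ptp(np.concatenate(arrays)) == 0:
        h, p_kw = 0.0, 1.0
    else:
        h, p_kw = _kruskal_wallis(arrays)
    dunn_z, dunn_p = _dunn_tests({g: np.asarray(v, dtype=float) for g, v in groups.items()})
    anova_f, anova_p = _rank_two_way_anova(groups)
    return GroupComparison(h=h, p_kw=p_kw, dunn_z=dunn_z, dunn_p=dunn_p,
                           anova_f=anova_f, anova_p=anova_p)


# ---------------------------------------------------------------------------
# covariate control

def covariate_control(
    hfb: HFBMatrix,
    fragset: FragmentSet,
    hand_labels: np.ndarray,
    envelope: np.ndarray,
    alpha: float = 0.05,
    lag_window_ms: tuple[float, float] = (-100.0, 500.0),
    rerun_tracking: bool = True,
) -> dict:
    """Regress the frame-expanded hand covariate out of every electrode,
    re-run the speech-preference and envelope-tracking analyses on the
    residuals, and compare original vs updated t maps with Wilcoxon tests."""
    frags = list(fragset)
    if len(hand_labels) != len(frags):
        raise ValueError("one hand label per fragment required")
    idx_blocks = [hfb.frame_indices(f.onset, f.offset) for f in frags]
    idx = np.concatenate(idx_blocks)
    hand = np.concatenate([
        np.full(len(ib), float(lab)) for ib, lab in zip(idx_blocks, hand_labels)
    ])
    resid_vals = hfb.values.copy()
    skipped = False
    if np.ptp(hand) == 0:
        log.warning("constant hand covariate: regression skipped, residual = centered HFB")
        skipped = True
        for ch in np.nonzero(hfb.good_mask())[0]:
            resid_vals[ch, idx] = hfb.values[ch, idx] - hfb.values[ch, idx].mean()
    else:
        X = np.column_stack([np.ones(len(idx)), hand])
        for ch in np.nonzero(hfb.good_mask())[0]:
            y = hfb.values[ch, idx]
            beta, *_ = np.linalg.lstsq(X, y, rcond=None)
            resid_vals[ch, idx] = y - X @ beta
    from dataclasses import replace as _replace

    resid_hfb = HFBMatrix(
        resid_vals, [_replace(m) for m in hfb.channel_meta],
        frame_rate=hfb.frame_rate, zscored=hfb.zscored, edge_flags=hfb.edge_flags.copy(),
    )
    pref_orig, mask = speech_preference(hfb, fragset, alpha=alpha)
    pref_new, _ = speech_preference(resid_hfb, fragset, alpha=alpha)
    out = {"hand_regression_skipped": skipped, "mask": mask,
           "preference_original": pref_orig, "preference_updated": pref_new}
    sig_idx = [i for i, s in enumerate(pref_orig.significant) if s]
    if len(sig_idx) >= 2:
        t_orig = pref_orig.t[sig_idx]
        t_new = pref_new.t[sig_idx]
        out["wilcoxon_preference"] = _wilcoxon_pair(t_orig, t_new)
    if mask and rerun_tracking:
        from .tracking_stats import envelope_tracking_contrast

        track_orig = envelope_tracking_contrast(hfb, envelope, fragset, mask, lag_window_ms)
        track_new = envelope_tracking_contrast(resid_hfb, envelope, fragset, mask, lag_window_ms)
        out["tracking_original"] = track_orig
        out["tracking_updated"] = track_new
        if len(mask) >= 2:
            out["wilcoxon_tracking"] = _wilcoxon_pair(track_orig.t, track_new.t)
    out["residual_hfb"] = resid_hfb
    return out


def _wilcoxon_pair(a: np.ndarray, b: np.ndarray) -> dict:
    d = np.asarray(a) - np.asarray(b)
    if np.allclose(d, 0):
        return {"statistic": np.nan, "p": 1.0, "note": "identical t maps"}
    method = "exact" if len(d) <= 25 else "auto"
    res = stats.wilcoxon(a, b, method=method)
    return {"statistic": float(res.statistic), "p": float(res.pvalue)}


# ---------------------------------------------------------------------------
# chi-square

def chi2_independence(observed: np.ndarray, yates: bool = False) -> ContingencyTable:
    """Pearson chi-square for independence; optional Yates correction (2x2)."""
    obs = np.asarray(observed, dtype=float)
    if obs.ndim != 2 or min(obs.shape) < 2:
        raise ValueError("need a table with at least 2 rows and 2 columns")
    if np.any(obs < 0) or not np.allclose(obs, np.round(obs)):
        raise ValueError("counts must be non-negative integers")
    row = obs.sum(axis=1, keepdims=True)
    col = obs.sum(axis=0, keepdims=True)
    total = obs.sum()
    if np.any(row == 0) or np.any(col == 0):
        raise ValueError("zero row or column margin")
    expected = row @ col / total
    if yates:
        if obs.shape != (2, 2):
            raise ValueError("Yates correction applies to 2x2 tables only")
        diff = np.maximum(np.abs(obs - expected) - 0.5, 0.0)
    else:
        diff = np.abs(obs - expected)
    chi2 = float((diff**2 / expected).sum())
    df = (obs.shape[0] - 1) * (obs.shape[1] - 1)
    p = float(stats.chi2.sf(chi2, df))
    return ContingencyTable(observed=obs.astype(int), chi2=chi2, df=df, p=p, yates=yates)
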