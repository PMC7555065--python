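"""Shared frequency-domain band-amplitude machinery.

A complex Gaussian band filter applied in the frequency domain yields the
analytic band signal; its modulus is the instantaneous band amplitude.  To
keep long recordings tractable, only the occupied slice of the spectrum is
inverse-transformed (alias-free for the complex band signal because the
filter support lies inside the slice), giving a decimated amplitude series
that is then interpolated onto the requested output times.
"""

from __future__ import annotations

import numpy as np
from scipy import fft as sp_fft

__all__ = ["band_amplitudes"]


def band_amplitudes(
    x: np.ndarray,
    fs: float,
    centers: np.ndarray,
    sigma_fs: np.ndarray,
    out_times: np.ndarray,
    min_rate: float = 500.0,
    n_sigma: float = 5.0,
) -> np.ndarray:
    """Instantaneous amplitude of Gaussian bands, sampled at ``out_times``.

    Parameters
    ----------
    x : real signal
    centers, sigma_fs : band center frequencies and Gaussian sigmas in Hz
    out_times : seconds; times (within the signal) to sample amplitudes at
    min_rate : minimum decimated rate of the internal amplitude series

    Returns an array of shape (len(centers), len(out_times)).
    """
    x = np.asarray(x, dtype=np.float64)
    n = len(x)
    nfft = sp_fft.next_fast_len(n)
    spec = sp_fft.fft(x, nfft)
    df = fs / nfft
    half = nfft // 2
    out = np.empty((len(centers), len(out_times)))
    w_min = int(np.ceil(min_rate / df))
    for i, (fc, sf) in enumerate(zip(centers, sigma_fs)):
        k0 = max(0, int(np.floor((fc - n_sigma * sf) / df)))
        k1 = min(half, int(np.ceil((fc + n_sigma * sf) / df)) + 1)
        if k1 - k0 < w_min:
            k1 = min(half, k0 + w_min)
            k0 = max(0, k1 - w_min)
        width = sp_fft.next_fast_len(k1 - k0)
        if k0 + width <= half:
            k1 = k0 + width
        else:
            k1 = min(half, k0 + width)
            k0 = max(0, k1 - width)
        w = k1 - k0
        f_slice = (k0 + np.arange(w)) * df
        h = 2.0 * np.exp(-((f_slice - fc) ** 2) / (2.0 * sf**2))
        y = sp_fft.ifft(spec[k0:k1] * h)
        amp = np.abs(y) * (w / nfft)
        t_dec = np.arange(w) * (nfft / w) / fs
        out[i] = np.interp(out_times, t_dec, amp)
    return out
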