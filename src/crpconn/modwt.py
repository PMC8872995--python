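"""Maximal Overlap Discrete Wavelet Transform (MODWT) with circular boundary
handling, and the associated additive multiresolution analysis (MRA).

Unlike the decimated DWT, the MODWT is translation-invariant, defined for any
series length N, and its MRA is exactly additive:

    x[t] = sum_j D_j[t] + S_J[t]

where D_j is the detail at level j (nominal passband (1/2^(j+1), 1/2^j) in
cycles per sample) and S_J the level-J smooth. Summing details over a range of
levels therefore implements a zero-phase band-pass filter, which is how the
pipeline isolates the 0.01-0.1 Hz BOLD band (levels 2-4 at TR = 2.57 s).

The pyramid algorithm uses the standard rescaled filters h~ = h/sqrt(2),
g~ = g/sqrt(2) and circular convolution:

    W_j[t] = sum_l h~[l] V_{j-1}[(t - 2^(j-1) l) mod N]
    V_j[t] = sum_l g~[l] V_{j-1}[(t - 2^(j-1) l) mod N]

Filter coefficients come from PyWavelets; the default is the 8-tap
least-asymmetric Daubechies wavelet ('sym8' in PyWavelets naming has 16 taps;
'sym4' is the 8-tap LA filter, see ``DEFAULT_WAVELET``).
"""

from __future__ import annotations

import numpy as np
import pywt

#: 8-tap least-asymmetric Daubechies (LA(8) in the Percival-Walden naming):
#: 4 vanishing moments, 8 coefficients = PyWavelets 'sym4'.
DEFAULT_WAVELET = "sym4"


def _modwt_filters(wavelet: str) -> tuple[np.ndarray, np.ndarray]:
    w = pywt.Wavelet(wavelet)
    g = np.asarray(w.dec_lo, dtype=float) / np.sqrt(2.0)
    h = np.asarray(w.dec_hi, dtype=float) / np.sqrt(2.0)
    return g, h


def _circ_filter_down(v: np.ndarray, filt: np.ndarray, step: int) -> np.ndarray:
    # out[t] = sum_l filt[l] * v[(t - step*l) mod N]; v may be (N,) or (N, K)
    out = np.zeros_like(v)
    for l, c in enumerate(filt):
        out += c * np.roll(v, step * l, axis=0)
    return out


def _circ_filter_up(v: np.ndarray, filt: np.ndarray, step: int) -> np.ndarray:
    # adjoint: out[t] = sum_l filt[l] * v[(t + step*l) mod N]
    out = np.zeros_like(v)
    for l, c in enumerate(filt):
        out += c * np.roll(v, -step * l, axis=0)
    return out


def _check_input(x: np.ndarray, level: int) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.ndim not in (1, 2):
        raise ValueError("input must be 1-D or (time x series) 2-D")
    n = x.shape[0]
    if level < 1:
        raise ValueError("level must be >= 1")
    if n < 2**level:
        raise ValueError(
            f"series of length {n} too short for MODWT level {level} "
            f"(need at least {2 ** level} samples)"
        )
    return x


def modwt(x, level: int, wavelet: str = DEFAULT_WAVELET):
    """MODWT of ``x`` to ``level`` levels.

    Returns ``(details, smooth)`` where ``details`` is a list of the wavelet
    coefficient arrays W_1..W_level (each the same shape as ``x``) and
    ``smooth`` is the scaling coefficient array V_level.
    """
    x = _check_input(x, level)
    g, h = _modwt_filters(wavelet)
    coeffs = []
    v = x
    for j in range(1, level + 1):
        step = 2 ** (j - 1)
        coeffs.append(_circ_filter_down(v, h, step))
        v = _circ_filter_down(v, g, step)
    return coeffs, v


def imodwt(details, smooth, wavelet: str = DEFAULT_WAVELET) -> np.ndarray:
    """Invert :func:`modwt`; exact to numerical precision."""
    g, h = _modwt_filters(wavelet)
    level = len(details)
    v = smooth
    for j in range(level, 0, -1):
        step = 2 ** (j - 1)
        v = _circ_filter_up(v, g, step) + _circ_filter_up(details[j - 1], h, step)
    return v


def modwt_mra(x, level: int, wavelet: str = DEFAULT_WAVELET):
    """Additive multiresolution analysis.

    Returns ``(details, smooth)`` where ``details[j-1]`` is the zero-phase
    detail component D_j and ``smooth`` the final smooth S_level, with
    ``sum(details) + smooth == x`` exactly (to round-off).
    """
    coeffs, v_final = modwt(x, level, wavelet)
    g, h = _modwt_filters(wavelet)
    details = []
    for j, w in enumerate(coeffs, start=1):
        d = _circ_filter_up(w, h, 2 ** (j - 1))
        for jj in range(j - 1, 0, -1):
            d = _circ_filter_up(d, g, 2 ** (jj - 1))
        details.append(d)
    s = v_final
    for jj in range(level, 0, -1):
        s = _circ_filter_up(s, g, 2 ** (jj - 1))
    return details, s


def scale_passband(level: int, tr: float) -> tuple[float, float]:
    """Nominal (low, high) frequency band in Hz of detail level ``level`` at
    sampling interval ``tr`` seconds."""
    fs = 1.0 / tr
    return fs / 2 ** (level + 1), fs / 2**level
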