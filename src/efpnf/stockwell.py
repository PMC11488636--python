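"""Stockwell (S-) transform.

The S-transform is a time-frequency representation with a Gaussian
analysis window whose width scales inversely with frequency
(sigma(f) = 1/f), combining STFT-like phase referencing with
wavelet-like multiresolution.  Two routes are provided:

* :func:`stockwell_fft` — the production O(N^2 log N) implementation via
  the FFT identity: row n is the inverse FFT of the spectrum shifted by
  n bins and tapered by a Gaussian ``exp(-2 pi^2 m^2 / n^2)``.
* :func:`stockwell_direct` — an O(N^2) per-row time-domain double sum
  against the analytically periodized Gaussian window, used as an
  independent oracle on small inputs.

Both use the circular (periodic) convention, so they agree to machine
precision.
"""

from __future__ import annotations

import numpy as np


def stockwell_fft(segment: np.ndarray, rows=None, return_complex: bool = False):
    """S-transform of a real segment via the FFT identity.

    Parameters
    ----------
    segment : 1-D array of N samples.
    rows : iterable of integer frequency-bin indices (1..N//2) to
        compute, or None for all bins 0..N//2.  Row 0 is the signal mean.
    return_complex : return the complex voices instead of magnitudes.

    Returns
    -------
    (S, row_indices) where S has shape (len(rows), N).
    """
    x = np.asarray(segment, dtype=float)
    n_samp = x.size
    if rows is None:
        rows = np.arange(n_samp // 2 + 1)
    rows = np.asarray(list(rows), dtype=int)
    if np.any(rows < 0) or np.any(rows > n_samp // 2):
        raise ValueError("row indices must lie in [0, N/2]")
    spec = np.fft.fft(x)
    m = np.fft.fftfreq(n_samp) * n_samp  # signed bin offsets
    out = np.empty((rows.size, n_samp), dtype=complex)
    for i, n in enumerate(rows):
        if n == 0:
            out[i] = np.mean(x)
            continue
        gauss = np.exp(-2.0 * np.pi**2 * m**2 / n**2)
        out[i] = np.fft.ifft(np.roll(spec, -n) * gauss)
    if return_complex:
        return out, rows
    return np.abs(out), rows


def stockwell_direct(segment: np.ndarray, rows, n_alias: int | None = None):
    """Independent time-domain S-transform (complex voices).

    Row n uses the analytic Gaussian window ``g(t) = f_n / sqrt(2 pi) *
    exp(-t^2 f_n^2 / 2)`` with ``f_n = n/N`` cycles/sample, periodized
    over ``2 n_alias + 1`` aliases to mirror the DFT's circular
    sampling, and evaluates the double sum

        S[n, j] = sum_k x[k] exp(-2 pi i n k / N) g_per[(j - k) mod N].
    """
    x = np.asarray(segment, dtype=float)
    n_samp = x.size
    rows = np.asarray(list(rows), dtype=int)
    out = np.empty((rows.size, n_samp), dtype=complex)
    l = np.arange(n_samp)
    for i, n in enumerate(rows):
        if n == 0:
            out[i] = np.mean(x)
            continue
        f = n / n_samp
        # The window SD is N/n samples; periodize far enough (>= 9 SDs)
        # that time-domain aliasing is below machine precision.
        p_max = n_alias if n_alias is not None else max(2, int(np.ceil(9.0 / n)))
        window = np.zeros(n_samp)
        for p in range(-p_max, p_max + 1):
            t = l + p * n_samp
            window += f / np.sqrt(2 * np.pi) * np.exp(-0.5 * (t * f) ** 2)
        demod = x * np.exp(-2j * np.pi * n * l / n_samp)
        wmat = window[(l[:, None] - l[None, :]) % n_samp]  # wmat[j, k] = g((j-k) mod N)
        out[i] = wmat @ demod
    return out, rows


class TFMatrix:
    """Magnitude time-frequency matrix (frequency bins x time points)."""

    def __init__(self, amplitudes: np.ndarray, freqs: np.ndarray, times: np.ndarray):
        amplitudes = np.asarray(amplitudes, dtype=float)
        freqs = np.asarray(freqs, dtype=float)
        times = np.asarray(times, dtype=float)
        if amplitudes.shape != (freqs.size, times.size):
            raise ValueError("amplitude shape inconsistent with axes")
        if np.any(amplitudes < 0):
            raise ValueError("amplitudes must be non-negative")
        if freqs.size > 1 and np.any(np.diff(freqs) <= 0):
            raise ValueError("freqs must be strictly increasing")
        self.amplitudes = amplitudes
        self.freqs = freqs
        self.times = times


def stockwell_transform(segment: np.ndarray, rate: float, expected_duration: float = 12.0
                        ) -> TFMatrix:
    """Magnitude S-transform of one analysis segment.

    The segment length must equal ``expected_duration * rate`` samples
    (the online pipeline uses 12-s windows at 250 Hz, i.e. 3000 samples).
    Frequency bins run 0..Nyquist on the DFT grid.
    """
    x = np.asarray(segment, dtype=float)
    n_expected = int(round(expected_duration * rate))
    if x.size != n_expected:
        raise ValueError(
            f"segment must contain {n_expected} samples "
            f"({expected_duration} s at {rate} Hz); got {x.size}")
    mags, rows = stockwell_fft(x)
    freqs = rows * rate / x.size
    times = np.arange(x.size) / rate
    return TFMatrix(mags, freqs, times)
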