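"""Canonical double-gamma hemodynamic response function.

The kernel follows the conventional parameterization used by standard
fMRI analysis packages: a gamma-shaped positive lobe peaking ~5 s after
stimulus onset minus a later, smaller gamma-shaped undershoot, with a
peak/undershoot amplitude ratio of 6 and a 32-s support.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

# Shape parameters of the two gamma densities (unit rate) and the
# undershoot ratio.  With these values the positive lobe peaks near 5 s.
_PEAK_SHAPE = 6.0
_UNDERSHOOT_SHAPE = 16.0
_RATIO = 6.0
DEFAULT_DURATION = 32.0


def double_gamma(t: np.ndarray) -> np.ndarray:
    """Evaluate the un-normalized double-gamma HRF at times ``t`` (s)."""
    t = np.asarray(t, dtype=float)
    h = stats.gamma.pdf(t, _PEAK_SHAPE) - stats.gamma.pdf(t, _UNDERSHOOT_SHAPE) / _RATIO
    h = np.where(t < 0, 0.0, h)
    return h


def _peak_value() -> float:
    # Dense fixed grid so that the normalization constant does not depend
    # on the sampling interval a caller requests.
    dense = np.arange(0.0, DEFAULT_DURATION, 1e-3)
    return float(double_gamma(dense).max())


_PEAK = _peak_value()


def canonical_hrf(tr: float, duration: float = DEFAULT_DURATION) -> np.ndarray:
    """Sample the canonical HRF at repetition time ``tr``.

    The kernel is peak-normalized to 1 using a tr-independent constant, so
    kernels sampled at different rates agree on their common grid.

    Parameters
    ----------
    tr : sampling interval in seconds (> 0).
    duration : kernel support in seconds (default 32 s).
    """
    if tr <= 0:
        raise ValueError(f"tr must be positive, got {tr}")
    if duration <= 0:
        raise ValueError(f"duration must be positive, got {duration}")
    t = np.arange(0.0, duration, tr)
    return double_gamma(t) / _PEAK
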