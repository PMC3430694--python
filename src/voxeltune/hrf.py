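"""Canonical double-gamma hemodynamic response function."""

from __future__ import annotations

import numpy as np
from scipy.stats import gamma

__all__ = ["canonical_hrf"]


def canonical_hrf(
    dt: float,
    peak_delay: float = 6.0,
    undershoot_delay: float = 16.0,
    ratio: float = 6.0,
    length: float = 32.0,
) -> np.ndarray:
    """Sample the canonical double-gamma HRF on a regular grid.

    The kernel is the difference of two gamma densities — a response peaking
    near ``peak_delay`` seconds and an undershoot peaking near
    ``undershoot_delay`` seconds at 1/``ratio`` amplitude — over ``length``
    seconds, normalised to unit peak.  Both gammas use unit dispersion
    (shape = delay, scale = 1), so h(0) = 0 and the mode of the positive lobe
    sits at ``peak_delay - 1`` seconds.

    Parameters
    ----------
    dt : float
        Sampling interval in seconds; must be > 0.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    t = np.arange(0.0, length + dt / 2, dt)
    h = gamma.pdf(t, a=peak_delay, scale=1.0) - gamma.pdf(
        t, a=undershoot_delay, scale=1.0
    ) / ratio
    peak = h.max()
    if peak <= 0:  # pragma: no cover - only for pathological parameters
        raise ValueError("HRF parameters yield a non-positive peak")
    return h / peak
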