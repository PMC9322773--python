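"""Synthetic stand-in reference EMD used as an independent test oracle.

This is a deliberately minimal, *independently coded* sifting
implementation used only to cross-check the package's decomposition.
It shares no code with ``multilstm.emd`` and makes different numerical
choices throughout: extrema via ``scipy.signal.argrelextrema``,
envelopes via ``scipy.interpolate.InterpolatedUnivariateSpline`` with
whole-signal even reflection (instead of extrema extension), and a
fixed sift count per mode (instead of SD / IMF-condition stopping).
It is a synthetic substitute for an external reference implementation
and is intentionally crude: agreement is asserted at the correlation
level, never sample-exactness.
"""

from __future__ import annotations

import numpy as np
from scipy.interpolate import InterpolatedUnivariateSpline
from scipy.signal import argrelextrema


def _envelope_mean(x: np.ndarray) -> np.ndarray | None:
    n = x.size
    pad = n // 2
    xe = np.concatenate([x[1:pad + 1][::-1], x, x[-pad - 1:-1][::-1]])
    mx = argrelextrema(xe, np.greater)[0]
    mn = argrelextrema(xe, np.less)[0]
    if mx.size < 2 or mn.size < 2:
        return None
    t = np.arange(n) + pad
    k_u = min(3, mx.size - 1)
    k_l = min(3, mn.size - 1)
    upper = InterpolatedUnivariateSpline(mx, xe[mx], k=k_u)(t)
    lower = InterpolatedUnivariateSpline(mn, xe[mn], k=k_l)(t)
    return (upper + lower) / 2.0


def reference_emd(x: np.ndarray, max_modes: int = 10, n_sift: int = 10) -> list[np.ndarray]:
    """Crude EMD: fixed-count sifting; returns modes, residual last."""
    x = np.asarray(x, dtype=float)
    modes: list[np.ndarray] = []
    r = x.copy()
    for _ in range(max_modes):
        h = r.copy()
        for _ in range(n_sift):
            m = _envelope_mean(h)
            if m is None:
                break
            h = h - m
        if _envelope_mean(r) is None or np.allclose(h, 0):
            break
        modes.append(h)
        r = r - h
        mx = argrelextrema(r, np.greater)[0]
        mn = argrelextrema(r, np.less)[0]
        if mx.size + mn.size < 2:
            break
    modes.append(r)
    return modes
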