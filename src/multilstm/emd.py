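"""Empirical mode decomposition (EMD) with the Cauchy SD stopping criterion.

EMD adaptively splits a nonstationary signal x(t) into intrinsic mode
functions (IMFs) plus a monotone-ish residual.  Each sifting pass fits
cubic-spline envelopes through the local maxima and minima, subtracts
their pointwise mean m(t) = (u(t) + v(t)) / 2, and repeats until the
candidate satisfies the IMF conditions:

1. the counts of interior extrema and zero crossings differ by at most 1;
2. the envelope mean is (numerically) zero everywhere.

Sifting also stops when the Cauchy criterion
``SD_k = sum |h_{k-1} - h_k|^2 / sum h_{k-1}^2`` falls below a threshold,
provided the countable condition 1 already holds, or when the iteration
cap is reached.  Extracted IMFs are subtracted from the running residual
(r_i = r_{i-1} - c_i) until the residual is monotone or a component cap
is hit, so the decomposition always reconstructs the input exactly:
x = sum c_i + r.

Instantaneous amplitude/frequency of each IMF come from the Hilbert
analytic signal.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.signal import hilbert
from scipy.stats import spearmanr

from .data_io import Signal

logger = logging.getLogger("multilstm")

__all__ = [
    "EMDConfig",
    "EnvelopePair",
    "SiftCandidate",
    "IMF",
    "Decomposition",
    "MonotoneResidual",
    "find_extrema",
    "count_zero_crossings",
    "build_envelopes",
    "sift_once",
    "sd_value",
    "is_imf",
    "extract_imf",
    "decompose",
    "reconstruct",
    "instantaneous_spectrum",
    "component_correlation",
    "orthogonality_index",
]


# Defaults: SD threshold 0.2 is Huang's conventional choice; the sift and
# component caps guard against over-sifting; envelope_tol relaxes the
# exact zero-envelope-mean IMF condition to a relative numeric bound.
@dataclass
class EMDConfig:
    sd_threshold: float = 0.2
    max_sift_iter: int = 50
    max_imfs: int | None = None  # None -> ceil(log2 N) + 1
    boundary_policy: str = "extrapolate"  # or "mirror", "clamp"
    envelope_tol: float = 0.5

    def resolved_max_imfs(self, n: int) -> int:
        if self.max_imfs is not None:
            return self.max_imfs
        return int(math.ceil(math.log2(max(n, 2)))) + 1

    def snapshot(self) -> dict:
        return {
            "sd_threshold": self.sd_threshold,
            "max_sift_iter": self.max_sift_iter,
            "max_imfs": self.max_imfs,
            "boundary_policy": self.boundary_policy,
            "envelope_tol": self.envelope_tol,
        }


class MonotoneResidual(Exception):
    """Raised when a signal has too few extrema to build envelopes."""


@dataclass
class EnvelopePair:
    u: np.ndarray  # upper envelope
    v: np.ndarray  # lower envelope

    @property
    def m(self) -> np.ndarray:
        return (self.u + self.v) / 2.0


@dataclass
class SiftCandidate:
    h: np.ndarray
    iteration: int
    sd_to_previous: float | None = None


@dataclass
class IMF:
    c: np.ndarray
    index: int
    n_extrema: int
    n_zero_crossings: int
    n_sift_iterations: int = 0
    f_inst: np.ndarray | None = None
    f_max: float | None = None
    resolution: float | None = None


@dataclass
class Decomposition:
    imfs: list[IMF]
    residual: np.ndarray
    config: dict = field(default_factory=dict)

    @property
    def n_imfs(self) -> int:
        return len(self.imfs)

    def components(self) -> list[np.ndarray]:
        """All component series, IMFs first then the residual."""
        return [imf.c for imf in self.imfs] + [self.residual]


def _as_array(signal) -> np.ndarray:
    if isinstance(signal, Signal):
        return np.asarray(signal.x, dtype=float)
    return np.asarray(signal, dtype=float).ravel()


def find_extrema(signal) -> tuple[list[int], list[int]]:
    """Interior strict local maxima and minima of a series.

    Plateau runs (consecutive equal samples flanked by strictly lower /
    higher neighbours) report a single index at their midpoint, ties
    broken toward the lower index.
    """
    x = _as_array(signal)
    n = x.size
    if n < 3:
        return [], []
    maxima: list[int] = []
    minima: list[int] = []
    i = 1
    while i < n - 1:
        if x[i] == x[i - 1]:
            i += 1
            continue
        # find end of plateau starting at i
        j = i
        while j + 1 < n and x[j + 1] == x[j]:
            j += 1
        if j >= n - 1:
            break
        left, right = x[i - 1], x[j + 1]
        mid = (i + j) // 2  # ties toward the lower index
        if x[i] > left and x[i] > right:
            maxima.append(mid)
        elif x[i] < left and x[i] < right:
            minima.append(mid)
        i = j + 1
    return maxima, minima


def count_zero_crossings(signal) -> int:
    """Sign changes between consecutive samples.

    An exact-zero sample counts once, and only when its nearest nonzero
    neighbours on each side have opposite signs.
    """
    x = _as_array(signal)
    signs = np.sign(x)
    nz = signs[signs != 0]
    if nz.size < 2:
        return 0
    return int(np.sum(nz[1:] * nz[:-1] < 0))


def _mirror_extension(
    x: np.ndarray, mx: np.ndarray, mn: np.ndarray, nbsym: int = 2
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Mirror extrema about the signal boundaries before spline fitting.

    The classic scheme: reflect the nearest ``nbsym`` extrema about the
    first/last extremum, unless the signal endpoint protrudes beyond the
    opposite envelope — then the endpoint itself is anchored as an
    extremum and the reflection is taken about the boundary instead.
    Returns extended (index, value) pairs for maxima and minima.
    """
    n = x.size
    end = n - 1

    # ---- left side
    if mx[0] < mn[0]:  # a maximum comes first
        if x[0] > x[mn[0]]:  # reflect about the first maximum
            lmax = mx[1:nbsym + 1][::-1]
            lmin = mn[0:nbsym][::-1]
            lsym = mx[0]
        else:  # endpoint sticks below: anchor it as a minimum
            lmax = mx[0:nbsym][::-1]
            lmin = np.append(mn[0:max(nbsym - 1, 0)][::-1], 0)
            lsym = 0
    else:
        if x[0] < x[mx[0]]:  # reflect about the first minimum
            lmax = mx[0:nbsym][::-1]
            lmin = mn[1:nbsym + 1][::-1]
            lsym = mn[0]
        else:  # endpoint sticks above: anchor it as a maximum
            lmax = np.append(mx[0:max(nbsym - 1, 0)][::-1], 0)
            lmin = mn[0:nbsym][::-1]
            lsym = 0
    tlmax = 2 * lsym - lmax
    tlmin = 2 * lsym - lmin
    if (tlmax.size and tlmax[0] > 0) or (tlmin.size and tlmin[0] > 0):
        # reflection about an interior extremum failed to extend; fall
        # back to reflecting about the boundary sample
        lmax = mx[0:nbsym][::-1]
        lmin = mn[0:nbsym][::-1]
        lsym = 0
        tlmax = 2 * lsym - lmax
        tlmin = 2 * lsym - lmin

    # ---- right side
    if mx[-1] > mn[-1]:  # a maximum comes last
        if x[-1] > x[mn[-1]]:  # reflect about the last maximum
            rmax = mx[-nbsym - 1:-1]
            rmin = mn[-nbsym:]
            rsym = mx[-1]
        else:
            rmax = mx[-nbsym:]
            rmin = np.append(mn[-(nbsym - 1):] if nbsym > 1 else np.array([], int), end)
            rsym = end
    else:
        if x[-1] < x[mx[-1]]:
            rmax = mx[-nbsym:]
            rmin = mn[-nbsym - 1:-1]
            rsym = mn[-1]
        else:
            rmax = np.append(mx[-(nbsym - 1):] if nbsym > 1 else np.array([], int), end)
            rmin = mn[-nbsym:]
            rsym = end
    trmax = 2 * rsym - rmax[::-1]
    trmin = 2 * rsym - rmin[::-1]
    if (trmax.size and trmax[-1] < end) or (trmin.size and trmin[-1] < end):
        rmax = mx[-nbsym:]
        rmin = mn[-nbsym:]
        rsym = end
        trmax = 2 * rsym - rmax[::-1]
        trmin = 2 * rsym - rmin[::-1]

    max_idx = np.concatenate([tlmax, mx, trmax]).astype(float)
    max_val = x[np.concatenate([lmax, mx, rmax[::-1]]).astype(int)]
    min_idx = np.concatenate([tlmin, mn, trmin]).astype(float)
    min_val = x[np.concatenate([lmin, mn, rmin[::-1]]).astype(int)]
    return max_idx, max_val, min_idx, min_val


def _dedup(ki: np.ndarray, kv: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    order = np.argsort(ki, kind="stable")
    ki, kv = ki[order], kv[order]
    keep = np.concatenate([[True], np.diff(ki) > 0])
    return ki[keep], kv[keep]


def _spline(ki: np.ndarray, kv: np.ndarray, n: int) -> np.ndarray:
    t = np.arange(n, dtype=float)
    if ki.size >= 4:
        return CubicSpline(ki, kv)(t)
    if ki.size == 3:
        return CubicSpline(ki, kv, bc_type="natural")(t)
    if ki.size == 2:
        return np.interp(t, ki, kv)
    raise MonotoneResidual("too few envelope knots")


def _extrapolate_extension(
    x: np.ndarray, idx: np.ndarray, n: int
) -> tuple[np.ndarray, np.ndarray]:
    """Extend one extrema sequence past the boundaries by its linear trend.

    Knot positions are mirrored about the endpoints; knot values follow
    the straight line through the two nearest extrema of the same kind,
    so a drifting signal keeps its local trend instead of having the
    trend folded back (which biases the envelope mean near the ends).
    Extrapolated values are clipped to the observed signal range, which
    prevents envelope blow-up when the reflection distance is large
    relative to the extrema spacing.
    """
    ki = idx.astype(float)
    kv = x[idx].astype(float)
    lo, hi = float(x.min()), float(x.max())
    if ki.size >= 2:
        li = -ki[:2][::-1]
        slope_l = (kv[1] - kv[0]) / (ki[1] - ki[0])
        lv = np.clip(kv[0] + slope_l * (li - ki[0]), lo, hi)
        ri = 2 * (n - 1) - ki[-2:][::-1]
        slope_r = (kv[-1] - kv[-2]) / (ki[-1] - ki[-2])
        rv = np.clip(kv[-1] + slope_r * (ri - ki[-1]), lo, hi)
    else:
        li = np.array([-ki[0]])
        lv = np.array([kv[0]])
        ri = np.array([2 * (n - 1) - ki[0]])
        rv = np.array([kv[0]])
    return np.concatenate([li, ki, ri]), np.concatenate([lv, kv, rv])


def _envelopes_from_extrema(
    x: np.ndarray, maxima: list[int], minima: list[int], policy: str
) -> tuple[np.ndarray, np.ndarray]:
    n = x.size
    mx = np.asarray(maxima, dtype=int)
    mn = np.asarray(minima, dtype=int)
    if policy == "extrapolate":
        uk_i, uk_v = _extrapolate_extension(x, mx, n)
        lk_i, lk_v = _extrapolate_extension(x, mn, n)
    elif policy == "mirror":
        uk_i, uk_v, lk_i, lk_v = _mirror_extension(x, mx, mn)
    elif policy == "clamp":
        # signal endpoints are treated as extrema of both envelopes
        uk_i = np.concatenate([[0], mx, [n - 1]]).astype(float)
        uk_v = np.concatenate([[x[0]], x[mx], [x[-1]]])
        lk_i = np.concatenate([[0], mn, [n - 1]]).astype(float)
        lk_v = np.concatenate([[x[0]], x[mn], [x[-1]]])
    else:
        raise ValueError(f"unknown boundary policy {policy!r}")
    u = _spline(*_dedup(uk_i, uk_v), n)
    v = _spline(*_dedup(lk_i, lk_v), n)
    return u, v


def build_envelopes(
    signal, maxima: list[int] | None = None, minima: list[int] | None = None,
    boundary_policy: str = "extrapolate",
) -> EnvelopePair:
    """Cubic-spline envelopes through the maxima and minima.

    Raises :class:`MonotoneResidual` when either kind of extremum is
    absent (a monotone or trend-only signal that cannot be sifted).
    """
    x = _as_array(signal)
    if maxima is None or minima is None:
        maxima, minima = find_extrema(x)
    if len(maxima) < 1 or len(minima) < 1:
        raise MonotoneResidual(
            f"need at least one maximum and one minimum, "
            f"got {len(maxima)} / {len(minima)}"
        )
    u, v = _envelopes_from_extrema(x, maxima, minima, boundary_policy)
    return EnvelopePair(u=u, v=v)


def sift_once(signal, boundary_policy: str = "extrapolate") -> SiftCandidate:
    """One sifting pass: h(t) = x(t) - m(t) with m the envelope mean."""
    x = _as_array(signal)
    env = build_envelopes(x, boundary_policy=boundary_policy)
    return SiftCandidate(h=x - env.m, iteration=1)


def sd_value(h_prev, h_curr) -> float:
    """Cauchy stopping statistic between successive sift iterates.

    ``SD = sum |h_prev - h_curr|^2 / sum h_prev^2``
    """
    a = _as_array(h_prev)
    b = _as_array(h_curr)
    if a.size != b.size:
        raise ValueError("sift iterates must have equal length")
    denom = float(np.sum(a * a))
    if denom == 0.0:
        raise ValueError("degenerate previous iterate (identically zero)")
    return float(np.sum((a - b) ** 2) / denom)


def is_imf(
    candidate, envelope_tol: float = 0.5, boundary_policy: str = "extrapolate"
) -> tuple[bool, dict]:
    """Test the two IMF conditions; returns (verdict, diagnostics).

    Condition 1: |#extrema - #zero crossings| <= 1.  Condition 2 (the
    zero envelope mean) is relaxed numerically to
    ``max |m(t)| <= envelope_tol * max |c(t)|``.  The zero series is an
    IMF by convention.
    """
    c = _as_array(candidate)
    maxima, minima = find_extrema(c)
    n_ext = len(maxima) + len(minima)
    n_zc = count_zero_crossings(c)
    diag = {"n_extrema": n_ext, "n_zero_crossings": n_zc, "max_abs_mean": 0.0}
    if np.all(c == 0):
        return True, diag
    cond1 = abs(n_ext - n_zc) <= 1
    try:
        env = build_envelopes(c, maxima, minima, boundary_policy)
    except MonotoneResidual:
        diag["max_abs_mean"] = float("inf")
        return False, diag
    max_m = float(np.max(np.abs(env.m)))
    diag["max_abs_mean"] = max_m
    cond2 = max_m <= envelope_tol * float(np.max(np.abs(c)))
    return cond1 and cond2, diag


def _count_condition(c: np.ndarray) -> bool:
    maxima, minima = find_extrema(c)
    return abs(len(maxima) + len(minima) - count_zero_crossings(c)) <= 1


def extract_imf(signal, config: EMDConfig | None = None) -> IMF:
    """Sift one IMF out of a signal.

    Stops when the candidate passes :func:`is_imf`, or when the Cauchy
    SD between successive iterates drops below ``sd_threshold`` while
    the extrema/zero-crossing count condition holds, or at the sift cap.
    Raises :class:`MonotoneResidual` when there is nothing to extract.
    """
    cfg = config or EMDConfig()
    h = _as_array(signal)
    # first sift; monotone input propagates MonotoneResidual
    h_new = sift_once(h, cfg.boundary_policy).h
    k = 1
    sd = None
    while k < cfg.max_sift_iter:
        ok, _ = is_imf(h_new, cfg.envelope_tol, cfg.boundary_policy)
        if ok:
            break
        try:
            nxt = sift_once(h_new, cfg.boundary_policy).h
        except MonotoneResidual:
            break
        sd = sd_value(h_new, nxt)
        h_new = nxt
        k += 1
        if sd < cfg.sd_threshold and is_imf(h_new, cfg.envelope_tol, cfg.boundary_policy)[0]:
            break
    maxima, minima = find_extrema(h_new)
    return IMF(
        c=h_new,
        index=0,
        n_extrema=len(maxima) + len(minima),
        n_zero_crossings=count_zero_crossings(h_new),
        n_sift_iterations=k,
    )


def _siftable(x: np.ndarray) -> bool:
    maxima, minima = find_extrema(x)
    return len(maxima) + len(minima) >= 2 and len(maxima) >= 1 and len(minima) >= 1


def decompose(signal, config: EMDConfig | None = None) -> Decomposition:
    """Full EMD: peel IMFs off the running residual until it is monotone.

    The returned decomposition reconstructs the input exactly
    (``sum IMFs + residual == x`` to floating-point accuracy) because
    each residual update is ``r_i = r_{i-1} - c_i``.
    """
    cfg = config or EMDConfig()
    x = _as_array(signal)
    if x.size < 4:
        raise ValueError(f"signal too short to decompose (N={x.size} < 4)")
    max_imfs = cfg.resolved_max_imfs(x.size)
    imfs: list[IMF] = []
    residual = x.copy()
    while len(imfs) < max_imfs and _siftable(residual):
        try:
            imf = extract_imf(residual, cfg)
        except MonotoneResidual:
            break
        if np.allclose(imf.c, 0.0):
            break
        imf.index = len(imfs) + 1
        imfs.append(imf)
        residual = residual - imf.c
    logger.debug("EMD extracted %d IMFs from N=%d signal", len(imfs), x.size)
    return Decomposition(imfs=imfs, residual=residual, config=cfg.snapshot())


def reconstruct(d: Decomposition) -> np.ndarray:
    """Elementwise sum of all IMFs plus the residual."""
    out = d.residual.copy()
    for imf in d.imfs:
        out = out + imf.c
    return out


def instantaneous_spectrum(
    imf, sample_rate: float = 1.0
) -> tuple[np.ndarray, np.ndarray, float, float]:
    """Hilbert instantaneous amplitude and frequency of one IMF.

    Returns ``(amplitude, frequency, f_max, resolution)`` where the
    amplitude is the analytic-signal modulus, the frequency the scaled
    derivative of the unwrapped phase, ``f_max`` the highest interior
    instantaneous frequency, and ``resolution = f_max / N``.
    """
    c = imf.c if isinstance(imf, IMF) else _as_array(imf)
    n = c.size
    if n < 8:
        raise ValueError("IMF too short for a meaningful Hilbert spectrum")
    analytic = hilbert(c)
    amplitude = np.abs(analytic)
    phase = np.unwrap(np.angle(analytic))
    freq = np.gradient(phase) * sample_rate / (2.0 * np.pi)
    # trim 10% from each end: the Hilbert transform rings at the borders
    lo, hi = n // 10, n - n // 10
    interior = freq[lo:hi] if hi > lo else freq
    f_max = float(np.max(interior))
    resolution = f_max / n
    return amplitude, freq, f_max, resolution


def component_correlation(d: Decomposition, original) -> np.ndarray:
    """Spearman rho of each component (IMFs then residual) vs the input.

    Constant components yield NaN (rank correlation undefined).
    """
    x = _as_array(original)
    rhos = []
    for comp in d.components():
        if comp.size != x.size:
            raise ValueError("component/original length mismatch")
        if np.all(comp == comp[0]) or np.all(x == x[0]):
            rhos.append(np.nan)
            continue
        rho, _ = spearmanr(comp, x)
        rhos.append(float(rho))
    return np.asarray(rhos)


def orthogonality_index(d: Decomposition, original) -> float:
    """Index of orthogonality: cross-component energy over signal energy.

    ``IO = sum_t sum_{i != j} c_i(t) c_j(t) / sum_t x(t)^2`` — small for
    a well-behaved (approximately orthogonal) decomposition.
    """
    x = _as_array(original)
    comps = d.components()
    total = np.zeros_like(x)
    sum_sq = np.zeros_like(x)
    for c in comps:
        total += c
        sum_sq += c * c
    cross = np.sum(total * total - sum_sq)
    denom = float(np.sum(x * x))
    if denom == 0:
        return 0.0
    return float(abs(cross) / denom)
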