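"""Empirical mode decomposition by envelope sifting.

Decomposes a 1-D signal into intrinsic mode functions (IMFs) ordered fast
to slow plus a residue, such that ``sum(imfs) + residue == signal`` to
machine precision (the decomposition is constructed by exact subtraction).
An IMF satisfies the usual two conditions within the sifting tolerance:
extrema and zero-crossing counts differ by at most one, and the mean of
the upper and lower envelopes is near zero everywhere.

Numerical choices (none of which are standardized across EMD variants):
natural cubic-spline envelopes through the extrema, mirror extension of
two extrema at each boundary, and a Rilling-style stop rule — sifting
ends when the envelope mean, normalized by the envelope amplitude, is
below ``theta`` at at least ``tolerance_fraction`` of samples (hard cap
``max_sifts`` iterations).  Decomposition stops at ``max_imfs`` or when
the residue has fewer than four extrema.

Sifting runs millions of times over a cohort, so the inner loop (extrema
detection, banded spline solve, envelope evaluation) is compiled with
numba; the public functions are thin wrappers over the same kernels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit


@njit(cache=False)
def _extrema_kernel(x):
    """Local maxima/minima indices; a plateau counts once, at its midpoint."""
    n = x.shape[0]
    maxi = np.empty(n // 2 + 1, dtype=np.int64)
    mini = np.empty(n // 2 + 1, dtype=np.int64)
    nmax = 0
    nmin = 0
    prev_sign = 0
    prev_idx = -1  # index into diff array of last nonzero slope
    for i in range(n - 1):
        d = x[i + 1] - x[i]
        if d == 0.0:
            continue
        s = 1 if d > 0 else -1
        if prev_sign != 0 and s != prev_sign:
            idx = (prev_idx + 1 + i) // 2
            if prev_sign > 0:
                maxi[nmax] = idx
                nmax += 1
            else:
                mini[nmin] = idx
                nmin += 1
        prev_sign = s
        prev_idx = i
    return maxi[:nmax], mini[:nmin]


@njit(cache=False)
def _mirror_kernel(idx, vals, n):
    """Extend knots by mirroring up to two extrema about each boundary."""
    m = idx.shape[0]
    k = 2 if m >= 2 else m
    t = np.empty(m + 2 * k, dtype=np.float64)
    v = np.empty(m + 2 * k, dtype=np.float64)
    for j in range(k):  # left mirror, ascending order
        t[j] = -float(idx[k - 1 - j])
        v[j] = vals[k - 1 - j]
    for j in range(m):
        t[k + j] = float(idx[j])
        v[k + j] = vals[j]
    for j in range(k):  # right mirror
        t[k + m + j] = float(2 * (n - 1) - idx[m - 1 - j])
        v[k + m + j] = vals[m - 1 - j]
    # drop duplicated knots (mirror of an endpoint extremum)
    keep_t = np.empty(m + 2 * k, dtype=np.float64)
    keep_v = np.empty(m + 2 * k, dtype=np.float64)
    cnt = 0
    for j in range(m + 2 * k):
        if cnt == 0 or t[j] > keep_t[cnt - 1]:
            keep_t[cnt] = t[j]
            keep_v[cnt] = v[j]
            cnt += 1
    return keep_t[:cnt], keep_v[:cnt]


@njit(cache=False)
def _natural_spline_eval(t, v, n):
    """Natural cubic spline through (t, v), evaluated at 0..n-1.

    Tridiagonal (Thomas) solve for the knot second derivatives with
    natural boundary conditions, then piecewise-cubic evaluation walking
    the sorted query points in one pass.
    """
    m = t.shape[0]
    out = np.empty(n, dtype=np.float64)
    if m == 1:
        for i in range(n):
            out[i] = v[0]
        return out
    if m < 4:  # too few knots for a cubic: linear interpolation
        for i in range(n):
            x = float(i)
            if x <= t[0]:
                j = 0
            elif x >= t[m - 1]:
                j = m - 2
            else:
                j = 0
                while t[j + 1] < x:
                    j += 1
            w = (x - t[j]) / (t[j + 1] - t[j])
            out[i] = v[j] * (1.0 - w) + v[j + 1] * w
        return out

    h = np.empty(m - 1)
    for j in range(m - 1):
        h[j] = t[j + 1] - t[j]
    # Thomas algorithm on the interior system; M[0] = M[m-1] = 0
    diag = np.empty(m)
    rhs = np.empty(m)
    diag[0] = 1.0
    rhs[0] = 0.0
    cprime = np.empty(m)
    cprime[0] = 0.0
    for j in range(1, m - 1):
        a = h[j - 1]
        b = 2.0 * (h[j - 1] + h[j])
        c = h[j]
        d = 6.0 * ((v[j + 1] - v[j]) / h[j] - (v[j] - v[j - 1]) / h[j - 1])
        wden = b - a * cprime[j - 1]
        cprime[j] = c / wden
        rhs[j] = (d - a * rhs[j - 1]) / wden
    M = np.empty(m)
    M[m - 1] = 0.0
    for j in range(m - 2, 0, -1):
        M[j] = rhs[j] - cprime[j] * M[j + 1]
    M[0] = 0.0

    j = 0
    for i in range(n):
        x = float(i)
        while j < m - 2 and t[j + 1] < x:
            j += 1
        hj = h[j]
        A = (t[j + 1] - x) / hj
        B = (x - t[j]) / hj
        out[i] = (
            A * v[j]
            + B * v[j + 1]
            + ((A**3 - A) * M[j] + (B**3 - B) * M[j + 1]) * hj * hj / 6.0
        )
    return out


@njit(cache=False)
def _envelope_kernel(x, idx):
    t, v = _mirror_kernel(idx, x[idx], x.shape[0])
    return _natural_spline_eval(t, v, x.shape[0])


@njit(cache=False)
def _sift_kernel(x, theta, tolerance_fraction, max_sifts):
    h = x.copy()
    n = h.shape[0]
    for it in range(1, max_sifts + 1):
        mx, mn = _extrema_kernel(h)
        if mx.shape[0] < 2 or mn.shape[0] < 2:
            return h, it - 1
        upper = _envelope_kernel(h, mx)
        lower = _envelope_kernel(h, mn)
        ok = 0
        for i in range(n):
            m = 0.5 * (upper[i] + lower[i])
            amp = 0.5 * (upper[i] - lower[i])
            if amp <= 0.0 or abs(m) < theta * amp:
                ok += 1
            h[i] -= m
        if ok >= tolerance_fraction * n:
            return h, it
    return h, max_sifts


def local_extrema(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Indices of local maxima and minima of a 1-D array."""
    return _extrema_kernel(np.ascontiguousarray(x, dtype=np.float64))


def zero_crossings(x: np.ndarray) -> int:
    s = np.sign(x)
    s = s[s != 0]
    return int(np.count_nonzero(s[:-1] != s[1:]))


def envelope(x: np.ndarray, idx: np.ndarray) -> np.ndarray:
    """Natural cubic-spline envelope through the extrema at ``idx``,
    with two extrema mirrored about each boundary."""
    return _envelope_kernel(
        np.ascontiguousarray(x, dtype=np.float64), np.ascontiguousarray(idx, dtype=np.int64)
    )


def sift(
    x: np.ndarray,
    theta: float = 0.05,
    tolerance_fraction: float = 0.95,
    max_sifts: int = 100,
) -> tuple[np.ndarray, int]:
    """Extract one IMF from ``x``; returns (imf, number of sifts used)."""
    return _sift_kernel(
        np.ascontiguousarray(x, dtype=np.float64), theta, tolerance_fraction, max_sifts
    )


@dataclass
class ImfSet:
    """Ordered IMFs (fastest first), residue and per-IMF sift counts."""

    imfs: list[np.ndarray]
    residue: np.ndarray
    sift_counts: list[int]

    def reconstruct(self) -> np.ndarray:
        out = self.residue.copy()
        for imf in self.imfs:
            out += imf
        return out


def _is_monotone(x: np.ndarray) -> bool:
    dx = np.diff(x)
    return bool(np.all(dx >= 0) or np.all(dx <= 0))


def emd(signal: np.ndarray, max_imfs: int = 8, **sift_kw) -> ImfSet:
    """Full decomposition of a 1-D signal into at most ``max_imfs`` IMFs.

    Signals with fewer than four extrema are returned as residue only.
    Raises on non-finite input.
    """
    x = np.asarray(signal, dtype=float)
    if x.ndim != 1:
        raise ValueError("emd expects a 1-D signal")
    if not np.all(np.isfinite(x)):
        raise ValueError("emd input contains non-finite values")
    if max_imfs < 1:
        raise ValueError("max_imfs must be >= 1")

    imfs: list[np.ndarray] = []
    counts: list[int] = []
    residue = x.copy()
    for _ in range(max_imfs):
        mx, mn = local_extrema(residue)
        if len(mx) + len(mn) < 4 or _is_monotone(residue):
            break
        imf, n_sifts = sift(residue, **sift_kw)
        if n_sifts == 0:  # sifting could not find envelopes
            break
        imfs.append(imf)
        counts.append(n_sifts)
        residue = residue - imf
    return ImfSet(imfs=imfs, residue=residue, sift_counts=counts)


def first_imf(signal: np.ndarray, **sift_kw) -> np.ndarray:
    """Fast path: only the first (highest-frequency) IMF.

    Equivalent to ``emd(signal, max_imfs=1).imfs[0]``; falls back to the
    signal itself when it carries too few extrema to sift (the feature
    downstream is then computed on the raw segment).
    """
    x = np.ascontiguousarray(signal, dtype=np.float64)
    mx, mn = _extrema_kernel(x)
    if mx.shape[0] + mn.shape[0] < 4:
        return x.copy()
    imf, n = sift(x, **sift_kw)
    return imf if n > 0 else x.copy()
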