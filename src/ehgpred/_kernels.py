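"""Compiled inner loops for the O(N^2) regularity measures.

These kernels are the performance-critical core of window characterization
(a 30-min recording yields 29 windows of 2400 samples; a cohort has 140
recordings). Pairs are enumerated in order of the templates' first
component, so pairs whose first-component distance already exceeds the
tolerance are pruned in bulk; the counts and memberships are identical to
the plain double loop. Reference pure-Python implementations used as
oracles live in the test suite, not here.
"""

from __future__ import annotations

import math

import numba as nb
import numpy as np

#: Exponent beyond which a fuzzy membership exp(-(d/r)^grad) is dropped;
#: exp(-34) ~ 1.7e-15, far below the 1e-10 oracle-agreement tolerance even
#: after summing over every template pair of a window.
_FUZZY_EXP_CUTOFF = 34.0


@nb.njit(cache=True, fastmath=True)
def sampen_counts(x: np.ndarray, m: int, r: float):  # pragma: no cover - numba
    """Template match counts (A, B) for sample entropy.

    Counts pairs (i < j) of length-m templates within Chebyshev distance r
    (B) and the same for length m+1 (A). Both counts run over the N - m
    templates whose (m+1)-sample extension exists, so self-similar signals
    such as a pure ramp give A == B exactly. Pairs are visited sorted by
    first component; |x_i - x_j| <= r is necessary for either match, so the
    inner loop breaks at the band edge without changing the counts.
    """
    n = x.shape[0]
    nt = n - m
    order = np.argsort(x[:nt])
    a_cnt = 0
    b_cnt = 0
    for a in range(nt - 1):
        i = order[a]
        xi = x[i]
        for b in range(a + 1, nt):
            j = order[b]
            d = x[j] - xi  # >= 0 in sorted order
            if d > r:
                break
            for k in range(1, m):
                dk = abs(x[i + k] - x[j + k])
                if dk > d:
                    d = dk
            if d <= r:
                b_cnt += 1
                dm = abs(x[i + m] - x[j + m])
                if dm > d:
                    d = dm
                if d <= r:
                    a_cnt += 1
    return a_cnt, b_cnt


_INV_LN2 = 1.4426950408889634
_LN2_HI = 0.6931471803691238
_LN2_LO = 1.9082149292705877e-10
# 1/k! for the degree-11 Taylor polynomial of exp on [-ln2/2, ln2/2];
# truncation error ~6e-15 relative, far below the oracle tolerance.
_C2 = 1.0 / 2
_C3 = 1.0 / 6
_C4 = 1.0 / 24
_C5 = 1.0 / 120
_C6 = 1.0 / 720
_C7 = 1.0 / 5040
_C8 = 1.0 / 40320
_C9 = 1.0 / 362880
_C10 = 1.0 / 3628800
_C11 = 1.0 / 39916800
# 2^-k for k in [0, 63]; the membership cutoff keeps k within this range
_POW2_NEG = 0.5 ** np.arange(64)


@nb.njit(inline="always", fastmath=True)
def _exp_neg(v: float) -> float:  # pragma: no cover - numba
    """exp(-v) for 0 <= v <= cutoff via range reduction and a degree-11 polynomial."""
    k = int(v * _INV_LN2 + 0.5)
    g = -((v - k * _LN2_HI) - k * _LN2_LO)
    p = 1.0 + g * (
        1.0
        + g
        * (
            _C2
            + g
            * (
                _C3
                + g
                * (
                    _C4
                    + g
                    * (
                        _C5
                        + g
                        * (
                            _C6
                            + g * (_C7 + g * (_C8 + g * (_C9 + g * (_C10 + g * _C11))))
                        )
                    )
                )
            )
        )
    )
    return p * _POW2_NEG[k]


@nb.njit(cache=True, fastmath=True)
def _fuzzy_sums_m2(
    b0, b1, c0, c1, c2, inv_r2: float, v_cut: float
):  # pragma: no cover - numba
    """Summed quadratic-gradient memberships for m = 2 in a single pass.

    ``b0, b1`` are the components of the centered length-2 templates,
    ``c0..c2`` of the centered length-3 templates. Returns (sum_m,
    sum_{m+1}); contributions with (d/r)^2 > v_cut are dropped.
    """
    nt = b0.shape[0]
    total_m = 0.0
    total_m1 = 0.0
    for i in range(nt - 1):
        a0 = b0[i]
        a1 = b1[i]
        e0 = c0[i]
        e1 = c1[i]
        e2 = c2[i]
        for j in range(i + 1, nt):
            d0 = abs(b0[j] - a0)
            d1 = abs(b1[j] - a1)
            d = d0 if d0 > d1 else d1
            v = d * d * inv_r2
            if v <= v_cut:
                total_m += _exp_neg(v)
            f0 = abs(c0[j] - e0)
            f1 = abs(c1[j] - e1)
            f2 = abs(c2[j] - e2)
            f = f0 if f0 > f1 else f1
            if f2 > f:
                f = f2
            v1 = f * f * inv_r2
            if v1 <= v_cut:
                total_m1 += _exp_neg(v1)
    return total_m, total_m1


@nb.njit(cache=True, fastmath=True)
def _banded_sq_distances(
    comp: np.ndarray, d_cut: float, inv_r: float, out: np.ndarray
):  # pragma: no cover - numba
    """Squared normalized Chebyshev distances (d/r)^2 of template pairs.

    ``comp`` has shape (width, n_templates): one row per template
    component. Only pairs with full Chebyshev distance <= d_cut are
    emitted (first-component banding prunes the rest); returns the number
    of values written to ``out``.
    """
    w = comp.shape[0]
    nt = comp.shape[1]
    order = np.argsort(comp[0])
    cnt = 0
    for a in range(nt - 1):
        i = order[a]
        ci0 = comp[0, i]
        for b in range(a + 1, nt):
            j = order[b]
            d = comp[0, j] - ci0
            if d > d_cut:
                break
            for k in range(1, w):
                dk = abs(comp[k, i] - comp[k, j])
                if dk > d:
                    d = dk
            if d <= d_cut:
                u = d * inv_r
                out[cnt] = u * u
                cnt += 1
    return cnt


def fuzzy_phis(x: np.ndarray, m: int, r: float, grad: float) -> tuple[float, float]:
    """Mean fuzzy memberships (phi_m, phi_{m+1}) with mean-centered templates.

    Membership is exp(-(d/r)^grad) on the Chebyshev distance d between
    centered templates; contributions with (d/r)^grad above the numerical
    cutoff are dropped. The exponential is evaluated vectorized over the
    collected pair distances.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    nt = n - m
    npairs = nt * (nt - 1) / 2.0

    def _centered_components(width: int) -> list[np.ndarray]:
        templ = np.lib.stride_tricks.sliding_window_view(x, width)[:nt]
        centered = templ - templ.mean(axis=1, keepdims=True)
        return [np.ascontiguousarray(centered[:, k]) for k in range(width)]

    if m == 2 and grad == 2.0:
        b0, b1 = _centered_components(2)
        c0, c1, c2 = _centered_components(3)
        s_m, s_m1 = _fuzzy_sums_m2(b0, b1, c0, c1, c2, 1.0 / r**2, _FUZZY_EXP_CUTOFF)
        return s_m / npairs, s_m1 / npairs

    d_cut = r * _FUZZY_EXP_CUTOFF ** (1.0 / grad)
    inv_r = 1.0 / r
    buf = np.empty(nt * (nt - 1) // 2)
    phis = []
    for width in (m, m + 1):
        centered = np.stack(_centered_components(width))
        cnt = _banded_sq_distances(centered, d_cut, inv_r, buf)
        usq = buf[:cnt]
        memberships = np.exp(-(np.sqrt(usq) ** grad))
        phis.append(float(memberships.sum()) / npairs)
    return phis[0], phis[1]


@nb.njit(cache=True)
def lz76_phrase_count(s: np.ndarray) -> int:  # pragma: no cover - numba
    """LZ76 phrase count via the Kaspar-Schuster scan over an int symbol array."""
    n = s.shape[0]
    if n == 0:
        return 0
    if n == 1:
        return 1
    c = 1
    i = 0
    k = 1
    l = 1
    k_max = 1
    while True:
        if s[i + k - 1] == s[l + k - 1]:
            k += 1
            if l + k > n:
                c += 1
                break
        else:
            if k > k_max:
                k_max = k
            i += 1
            if i == l:
                c += 1
                l += k_max
                if l + 1 > n:
                    break
                i = 0
                k = 1
                k_max = 1
            else:
                k = 1
    return c
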