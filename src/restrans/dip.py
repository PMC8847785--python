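"""Hartigan & Hartigan's dip statistic and bootstrap dip test.

The dip of an empirical CDF ``F_n`` is the smallest sup-norm distance from
``F_n`` to any unimodal CDF (convex up to a mode, concave after it). It is
the classic statistic for testing unimodality: a large dip means no
single-mode CDF can track the data. For ``n`` equally spaced distinct
points the dip attains its minimum ``1/(2n)``; its supremum is ``1/4``.

Computation follows the modal-interval refinement scheme: on the current
candidate modal interval, fit the greatest convex minorant (gcm) and least
concave majorant (lcm) of the ECDF; if the largest gap between the two
curves exceeds the deviation already incurred outside the interval, shrink
the interval to the gcm/lcm touch points bracketing that gap, charge the
convex/concave fitting error of the newly excluded flanks, and repeat.
On termination the dip is half the largest charged deviation. Working in
count units (ECDF x n) keeps the hull arithmetic exact for tied data.

The implementation is validated in the test suite against an independent
linear-programming oracle that fits unimodal CDFs within a sup-norm band
directly (mode placed at each distinct value in turn).

The bootstrap test calibrates the observed dip against uniform(0,1)
samples of the same size, the standard reference distribution for the dip.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Dict, Optional

import numpy as np

from .errors import InsufficientDataError, ParameterError


@dataclass
class DipResult:
    dip_statistic: float
    p_value: float
    n_observations: int
    n_bootstrap: int

    def to_dict(self) -> Dict:
        return asdict(self)


def _convex_minorant_pointers(x: np.ndarray) -> np.ndarray:
    """Predecessor pointers of the greatest convex minorant of (x_i, i).

    Pool-adjacent sweep; cross-multiplied slope comparisons avoid division
    and stay exact for tied x values.
    """
    n = x.size
    mn = np.zeros(n, dtype=np.int64)
    for j in range(1, n):
        mn[j] = j - 1
        while True:
            a = mn[j]
            if a == 0:
                break
            b = mn[a]
            if (x[j] - x[a]) * (a - b) < (x[a] - x[b]) * (j - a):
                break
            mn[j] = b
    return mn


def _concave_majorant_pointers(x: np.ndarray) -> np.ndarray:
    """Successor pointers of the least concave majorant of (x_i, i)."""
    n = x.size
    mj = np.zeros(n, dtype=np.int64)
    mj[n - 1] = n - 1
    for j in range(n - 2, -1, -1):
        mj[j] = j + 1
        while True:
            a = mj[j]
            if a == n - 1:
                break
            b = mj[a]
            if (x[j] - x[a]) * (a - b) < (x[a] - x[b]) * (j - a):
                break
            mj[j] = b
    return mj


def dip_statistic(values) -> float:
    """Hartigan & Hartigan dip of a sample (>= 4 finite observations)."""
    v = np.asarray(list(values), dtype=float)
    if v.size < 4:
        raise InsufficientDataError("dip statistic needs at least 4 observations")
    if not np.isfinite(v).all():
        raise InsufficientDataError(
            "dip statistic is undefined for non-finite values; exclude or cap them"
        )
    x = np.sort(v)
    n = x.size
    if x[0] == x[-1]:
        return 0.0

    mn = _convex_minorant_pointers(x)
    mj = _concave_majorant_pointers(x)
    low, high = 0, n - 1
    d_big = 1.0  # count units; yields the attainable minimum 1/(2n)

    while True:
        # hull vertex index lists on [low, high], ascending
        g = [high]
        while g[-1] > low:
            g.append(mn[g[-1]])
        gcm = np.array(g[::-1], dtype=np.int64)
        l = [low]
        while l[-1] < high:
            l.append(mj[l[-1]])
        lcm = np.array(l, dtype=np.int64)

        gx, gy = x[gcm], gcm.astype(float)          # gcm heights: index
        lx, ly = x[lcm], lcm.astype(float) + 1.0    # lcm heights: index + 1

        # largest gap between the curves, evaluated at both vertex sets
        gap_at_lcm = (lcm + 1.0) - np.interp(lx, gx, gy)
        gap_at_gcm = np.interp(gx, lx, ly) - gcm
        best_l = int(np.argmax(gap_at_lcm))
        best_g = int(np.argmax(gap_at_gcm))
        if gap_at_lcm[best_l] >= gap_at_gcm[best_g]:
            d = float(gap_at_lcm[best_l])
            iv = int(lcm[best_l])
            left = gcm[gx <= x[iv]]
            ix = int(left[-1]) if left.size else low
        else:
            d = float(gap_at_gcm[best_g])
            ix = int(gcm[best_g])
            right = lcm[lx >= x[ix]]
            iv = int(right[0]) if right.size else high

        if d <= d_big:
            break

        # deviation of the ECDF from the gcm over [low, ix] and from the
        # lcm over [iv, high]: the flanks committed outside the new modal
        # interval
        ml = np.arange(low, ix + 1)
        dl = float(((ml + 1.0) - np.interp(x[ml], gx, gy)).max())
        mu = np.arange(iv, high + 1)
        du = float((np.interp(x[mu], lx, ly) - mu).max())
        d_big = max(d_big, dl, du)
        if ix == low and iv == high:
            break
        low, high = ix, iv

    return d_big / (2.0 * n)


def dip_test(
    values,
    n_bootstrap: int = 2000,
    seed: Optional[int] = None,
) -> DipResult:
    """Bootstrap dip test of unimodality.

    The null reference is the uniform distribution: ``n_bootstrap`` uniform
    samples of the observed size are drawn and

        p = (1 + #{bootstrap dip >= observed dip}) / (1 + n_bootstrap),

    so the smallest attainable p is ``1/(n_bootstrap + 1)``.
    """
    if n_bootstrap < 1:
        raise ParameterError("n_bootstrap must be positive")
    if seed is None:
        raise ParameterError("seed is required for the bootstrap")
    v = np.asarray(list(values), dtype=float)
    observed = dip_statistic(v)
    n = v.size
    rng = np.random.default_rng(seed)
    count_ge = 0
    for _ in range(n_bootstrap):
        boot = dip_statistic(rng.random(n))
        if boot >= observed - 1e-12:
            count_ge += 1
    p = (1.0 + count_ge) / (1.0 + n_bootstrap)
    return DipResult(
        dip_statistic=float(observed),
        p_value=float(p),
        n_observations=int(n),
        n_bootstrap=int(n_bootstrap),
    )
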