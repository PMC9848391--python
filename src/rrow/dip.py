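"""Hartigan's dip statistic and a uniform-null Monte Carlo p-value.

The dip is the largest vertical distance between the empirical cdf and the
closest unimodal cdf, computed with the classic greatest-convex-minorant /
least-concave-majorant alternating algorithm.  No maintained implementation
is available in the pinned environment, so the statistic is implemented here
and pinned down by its analytic limits (1/(2n) floor for unimodal-compatible
samples, 1/4 ceiling approached by two equal point masses).
"""

from __future__ import annotations

import logging

import numpy as np

logger = logging.getLogger(__name__)


def dip_statistic(values: np.ndarray) -> float:
    """Hartigan's dip of a 1D sample."""
    x = np.sort(np.asarray(values, dtype=float))
    n = x.size
    if n < 1:
        raise ValueError("empty sample")
    if x[0] == x[-1]:
        logger.info("constant sample: dip degenerate at 0")
        return 0.0
    if n <= 3:
        return 1.0 / (2 * n)

    low, high = 0, n - 1
    dip = 1.0  # in ecdf-count units; final value is dip / (2n)
    mn = np.zeros(n, dtype=np.int64)
    mj = np.zeros(n, dtype=np.int64)
    gcm = np.zeros(n + 1, dtype=np.int64)
    lcm = np.zeros(n + 1, dtype=np.int64)

    for _ in range(n + 1):  # bounded; each pass shrinks [low, high]
        # convex minorant precursors on [low, high]
        mn[low] = low
        for j in range(low + 1, high + 1):
            mn[j] = j - 1
            while True:
                mnj = mn[j]
                mnmnj = mn[mnj]
                if mnj == low or (
                    (x[j] - x[mnj]) * (mnj - mnmnj)
                    < (x[mnj] - x[mnmnj]) * (j - mnj)
                ):
                    break
                mn[j] = mnmnj
        # concave majorant precursors
        mj[high] = high
        for k in range(high - 1, low - 1, -1):
            mj[k] = k + 1
            while True:
                mjk = mj[k]
                mjmjk = mj[mjk]
                if mjk == high or (
                    (x[k] - x[mjk]) * (mjk - mjmjk)
                    < (x[mjk] - x[mjmjk]) * (k - mjk)
                ):
                    break
                mj[k] = mjmjk

        # gcm change points, high -> low
        gcm[0] = high
        i = 0
        while gcm[i] > low:
            gcm[i + 1] = mn[gcm[i]]
            i += 1
        ig = l_gcm = i
        # lcm change points, low -> high
        lcm[0] = low
        i = 0
        while lcm[i] < high:
            lcm[i + 1] = mj[lcm[i]]
            i += 1
        ih = l_lcm = i

        ix = ig - 1
        iv = 1
        d = 0.0
        if l_gcm != 1 or l_lcm != 1:
            while True:
                gcm_ix = gcm[ix]
                lcm_iv = lcm[iv]
                if gcm_ix > lcm_iv:
                    gcm_i1 = gcm[ix + 1]
                    dx = (lcm_iv - gcm_i1 + 1) - (x[lcm_iv] - x[gcm_i1]) * (
                        gcm_ix - gcm_i1
                    ) / (x[gcm_ix] - x[gcm_i1])
                    iv += 1
                    if dx >= d:
                        d = dx
                        ig = ix + 1
                        ih = iv - 1
                else:
                    lcm_i1 = lcm[iv - 1]
                    dx = (x[gcm_ix] - x[lcm_i1]) * (lcm_iv - lcm_i1) / (
                        x[lcm_iv] - x[lcm_i1]
                    ) - (gcm_ix - lcm_i1 - 1)
                    ix -= 1
                    if dx > d:
                        d = dx
                        ig = ix + 1
                        ih = iv
                if ix < 0:
                    ix = 0
                if iv > l_lcm:
                    iv = l_lcm
                if gcm[ix] == lcm[iv]:
                    break
        else:
            d = 1.0
        if d < dip:
            break

        # dip restricted to the convex-minorant side
        dip_l = 0.0
        for j in range(ig, l_gcm):
            max_t = 1.0
            jb, je = gcm[j + 1], gcm[j]
            if je - jb > 1 and x[je] != x[jb]:
                c = (je - jb) / (x[je] - x[jb])
                for jj in range(jb, je + 1):
                    t = (jj - jb + 1) - (x[jj] - x[jb]) * c
                    if max_t < t:
                        max_t = t
            if dip_l < max_t:
                dip_l = max_t
        # and to the concave-majorant side
        dip_u = 0.0
        for j in range(ih, l_lcm):
            max_t = 1.0
            jb, je = lcm[j], lcm[j + 1]
            if je - jb > 1 and x[je] != x[jb]:
                c = (je - jb) / (x[je] - x[jb])
                for jj in range(jb, je + 1):
                    t = (x[jj] - x[jb]) * c - (jj - jb - 1)
                    if max_t < t:
                        max_t = t
            if dip_u < max_t:
                dip_u = max_t

        dip = max(dip, dip_l, dip_u)
        new_low, new_high = gcm[ig], lcm[ih]
        if new_low == low and new_high == high:
            break
        low, high = new_low, new_high

    return dip / (2.0 * n)


def dip_test(
    values: np.ndarray,
    *,
    n_boot: int = 200,
    rng: np.random.Generator | None = None,
) -> tuple[float, float]:
    """Dip statistic plus a Monte Carlo p-value under the uniform null.

    The p-value is the fraction of ``n_boot`` uniform samples of the same
    size whose dip is at least as large as the observed one.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 4:
        raise ValueError("need at least 4 values for the dip test")
    rng = rng or np.random.default_rng(0)
    d = dip_statistic(values)
    if d == 0.0:
        return 0.0, 1.0
    n = values.size
    null = np.array([dip_statistic(rng.uniform(size=n)) for _ in range(n_boot)])
    p = float((null >= d).sum() + 1) / (n_boot + 1)
    return d, p


def profile_dip(
    depths: np.ndarray,
    values: np.ndarray,
    *,
    pseudo_n: int = 500,
    n_boot: int = 200,
    rng: np.random.Generator | None = None,
) -> tuple[float, float]:
    """Dip test of a depth profile treated as a weighted sample over depth.

    Profile values (shifted to be nonnegative) act as weights: each depth is
    replicated in proportion to its weight to form a pseudo-sample of about
    ``pseudo_n`` points, which is then dip-tested against the uniform null at
    that pseudo-sample size.
    """
    depths = np.asarray(depths, dtype=float)
    values = np.asarray(values, dtype=float)
    ok = np.isfinite(values)
    depths, values = depths[ok], values[ok]
    if depths.size < 4:
        raise ValueError("need at least 4 defined profile points")
    w = values - values.min()
    if w.sum() == 0:
        logger.info("flat profile: dip degenerate at 0")
        return 0.0, 1.0
    counts = np.round(w / w.sum() * pseudo_n).astype(int)
    spacing = np.median(np.diff(np.sort(depths))) if depths.size > 1 else 1.0
    # spread replicates evenly across each depth bin so the pseudo-sample is
    # piecewise uniform rather than a stack of ties (ties would inflate the
    # dip relative to the continuous uniform null)
    parts = [
        d + spacing * (np.arange(c) + 0.5) / c - spacing / 2
        for d, c in zip(depths, counts)
        if c > 0
    ]
    sample = np.concatenate(parts)
    return dip_test(sample, n_boot=n_boot, rng=rng)
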