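"""Plug-in mutual information between binned firing rates and task variables.

Continuous variables (and firing rates) are discretized into 5 uniform-width
bins spanning their observed range; categorical variables pass through with
their natural categories.  MI values are shuffle-normalized by subtracting
the mean MI over circularly time-shifted spike trains, so normalized values
may be negative while raw plug-in MI is always >= 0.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .spikes import (
    DEFAULT_N_SHUFFLES,
    DEFAULT_SHIFT_RANGE,
    PETH,
    SpikeTrain,
    circular_shift,
)

logger = logging.getLogger(__name__)

DEFAULT_N_BINS = 5


def discretize(values: Sequence[float], n_bins: int = DEFAULT_N_BINS) -> np.ndarray:
    """Uniform-width binning of real values over their observed [min, max].

    The maximum value is assigned to the top bin (closed upper edge); a
    constant input collapses to a single occupied bin with a warning.
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0 or not np.all(np.isfinite(v)):
        raise ValueError("discretize requires at least one finite value")
    lo, hi = v.min(), v.max()
    if hi == lo:
        warnings.warn("constant input: all values fall in one bin (MI will be 0)")
        return np.zeros(v.size, dtype=int)
    width = (hi - lo) / n_bins
    return np.minimum((v - lo) // width, n_bins - 1).astype(int)


def mutual_information(b: Sequence[int], s: Sequence[int]) -> float:
    """Plug-in MI (bits) between two matched categorical sequences.

    ``MI = sum p(B,S) log2[p(B,S) / (p(B) p(S))]`` with ``0 log 0 = 0``,
    probabilities taken from empirical counts.
    """
    b = np.asarray(b)
    s = np.asarray(s)
    if b.size == 0 or b.size != s.size:
        raise ValueError("inputs must be nonempty and the same length")
    _, bi = np.unique(b, return_inverse=True)
    _, si = np.unique(s, return_inverse=True)
    nb, ns = bi.max() + 1, si.max() + 1
    joint = np.bincount(bi * ns + si, minlength=nb * ns).reshape(nb, ns).astype(float)
    return mi_from_joint(joint)


def mi_from_joint(joint: np.ndarray) -> float:
    """MI in bits from a joint count (or probability) table."""
    joint = np.asarray(joint, dtype=float)
    total = joint.sum()
    if total <= 0:
        raise ValueError("empty joint table")
    p = joint / total
    pb = p.sum(axis=1, keepdims=True)
    ps = p.sum(axis=0, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        term = p * np.log2(p / (pb * ps))
    return float(np.where(p > 0, term, 0.0).sum())


@dataclass
class MIResult:
    cell_id: int
    variable: str
    raw: np.ndarray          # per bin, or shape () for scalar MI
    null_mean: np.ndarray
    normalized: np.ndarray
    n_shuffles: int
    condition: str | None = None
    bin_centers: np.ndarray = field(default_factory=lambda: np.empty(0))


def _variable_codes(values: Sequence, categorical: bool, n_bins: int) -> np.ndarray:
    if categorical:
        _, codes = np.unique(np.asarray(values), return_inverse=True)
        return codes
    return discretize(values, n_bins)


def _timecourse_mi(per_visit: np.ndarray, codes: np.ndarray, n_bins: int) -> np.ndarray:
    """MI per time bin between across-visit rate vectors and the variable.

    Rates are discretized per time bin (each bin treated independently).
    Bins where any variable category has fewer than 2 defined visits are NaN.
    """
    n_time = per_visit.shape[1]
    out = np.full(n_time, np.nan)
    for j in range(n_time):
        col = per_visit[:, j]
        ok = np.isfinite(col)
        if ok.sum() < 2:
            continue
        cj = codes[ok]
        counts = np.bincount(cj)
        if (counts[counts > 0] < 2).any() or (counts > 0).sum() < 2:
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rates_binned = discretize(col[ok], n_bins)
        out[j] = mutual_information(cj, rates_binned)
    return out


def mi_timecourse(
    train: SpikeTrain,
    peth_fn,
    values: Sequence,
    *,
    variable: str = "variable",
    categorical: bool = True,
    n_bins: int = DEFAULT_N_BINS,
    n_shuffles: int = DEFAULT_N_SHUFFLES,
    shift_range: tuple[float, float] = DEFAULT_SHIFT_RANGE,
    rng: np.random.Generator | None = None,
) -> MIResult:
    """Shuffle-normalized MI between per-time-bin firing rates and a variable.

    ``peth_fn(train) -> PETH`` supplies the per-visit rate matrix (absolute
    100 ms bins for wait-zone analyses, 26 normalized bins for offer/reward
    zones); ``values`` gives the task variable per visit in the same order as
    the PETH's visit axis (rows dropped by the PETH are dropped here too).
    """
    rng = rng or np.random.default_rng(0)
    base: PETH = peth_fn(train)
    values = np.asarray(values)
    codes_all = _variable_codes(values, categorical, n_bins)
    codes = codes_all[base.kept_visits]
    raw = _timecourse_mi(base.per_visit, codes, n_bins)
    acc = np.zeros_like(raw)
    cnt = np.zeros_like(raw)
    for _ in range(n_shuffles):
        shifted = circular_shift(train, float(rng.uniform(*shift_range)))
        p = peth_fn(shifted)
        mi = _timecourse_mi(p.per_visit, codes_all[p.kept_visits], n_bins)
        ok = np.isfinite(mi)
        acc[ok] += mi[ok]
        cnt[ok] += 1
    with np.errstate(invalid="ignore", divide="ignore"):
        null_mean = np.where(cnt > 0, acc / cnt, np.nan)
    return MIResult(
        cell_id=train.cell_id,
        variable=variable,
        raw=raw,
        null_mean=null_mean,
        normalized=raw - null_mean,
        n_shuffles=n_shuffles,
        bin_centers=base.bin_centers,
    )


def _zone_rates(train: SpikeTrain, intervals: Sequence[tuple[float, float]]) -> np.ndarray:
    rates = np.empty(len(intervals))
    for i, (a, b) in enumerate(intervals):
        if b <= a:
            rates[i] = np.nan
            continue
        n = np.searchsorted(train.times, b) - np.searchsorted(train.times, a)
        rates[i] = n / (b - a)
    return rates


def mi_scalar(
    train: SpikeTrain,
    intervals: Sequence[tuple[float, float]],
    values: Sequence,
    *,
    variable: str = "variable",
    categorical: bool = False,
    n_bins: int = DEFAULT_N_BINS,
    n_shuffles: int = DEFAULT_N_SHUFFLES,
    shift_range: tuple[float, float] = DEFAULT_SHIFT_RANGE,
    rng: np.random.Generator | None = None,
    condition: str | None = None,
) -> MIResult:
    """Session-level shuffle-normalized MI between per-visit zone firing
    rates and one task variable."""
    rng = rng or np.random.default_rng(0)
    codes = _variable_codes(values, categorical, n_bins)

    def stat(tr: SpikeTrain) -> float:
        rates = _zone_rates(tr, intervals)
        ok = np.isfinite(rates)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rb = discretize(rates[ok], n_bins)
        return mutual_information(codes[ok], rb)

    raw = stat(train)
    null = np.mean(
        [stat(circular_shift(train, float(rng.uniform(*shift_range)))) for _ in range(n_shuffles)]
    )
    return MIResult(
        cell_id=train.cell_id,
        variable=variable,
        raw=np.asarray(raw),
        null_mean=np.asarray(null),
        normalized=np.asarray(raw - null),
        n_shuffles=n_shuffles,
        condition=condition,
    )


def mi_conditioned(
    train: SpikeTrain,
    intervals: Sequence[tuple[float, float]],
    values: Sequence[float],
    conditions: Sequence,
    *,
    variable: str = "offer_delay",
    n_bins: int = DEFAULT_N_BINS,
    n_shuffles: int = DEFAULT_N_SHUFFLES,
    shift_range: tuple[float, float] = DEFAULT_SHIFT_RANGE,
    rng: np.random.Generator | None = None,
) -> dict[str, MIResult]:
    """MI for a variable recomputed within each level of a conditioning
    variable (e.g. offer delay conditioned on offer-zone choice).

    Empty partitions are omitted; partitions where the variable collapses to
    a single category yield MI 0 by construction.
    """
    rng = rng or np.random.default_rng(0)
    values = np.asarray(values, dtype=float)
    conditions = np.asarray(conditions)
    intervals = list(intervals)
    out: dict[str, MIResult] = {}
    for level in np.unique(conditions):
        sel = np.flatnonzero(conditions == level)
        if sel.size < 2:
            logger.info("condition %r has <2 visits; omitted", level)
            continue
        out[str(level)] = mi_scalar(
            train,
            [intervals[i] for i in sel],
            values[sel],
            variable=variable,
            categorical=False,
            n_bins=n_bins,
            n_shuffles=n_shuffles,
            shift_range=shift_range,
            rng=rng,
            condition=str(level),
        )
    return out
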