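"""Pairwise transfer entropy and data-driven parcellation along the probe.

Spike trains are binned at 10 ms and binarized (0 / >=1 spike).  For a
directed pair the plug-in transfer entropy with order-1 histories is

    TE(X -> Y) = sum p(Y_t, Y_{t-1}, X_{t-1})
                 log2 [ p(Y_t | Y_{t-1}, X_{t-1}) / p(Y_t | Y_{t-1}) ]

normalized by subtracting the mean TE over circular time shifts of the input
cell only.  Normalized pair values are aggregated on a 100 um 2D grid of
(input depth, recipient depth); the mean of grid bins with both coordinates
within 200 um of each depth yields a dorso-ventral profile whose interior
local minima are the functional subregion boundaries.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .spikes import DEFAULT_N_SHUFFLES, DEFAULT_SHIFT_RANGE, SpikeTrain

logger = logging.getLogger(__name__)

DEFAULT_TE_BIN = 0.010
DEFAULT_MAP_RESOLUTION = 100.0
DEFAULT_DIAGONAL_WINDOW = 200.0
DEFAULT_MIN_PHASE_BINS = 3000


def bin_spikes(train: SpikeTrain, bin_width: float = DEFAULT_TE_BIN) -> np.ndarray:
    """Binarized spike counts: one symbol per ``bin_width`` bin (0 / >=1)."""
    n_bins = int(round(train.duration / bin_width))
    if train.times.size == 0:
        return np.zeros(n_bins, dtype=np.uint8)
    idx = np.minimum((train.times / bin_width).astype(np.int64), n_bins - 1)
    out = np.zeros(n_bins, dtype=np.uint8)
    out[idx] = 1
    return out


def _spike_bin_indices(train: SpikeTrain, bin_width: float, n_bins: int) -> np.ndarray:
    if train.times.size == 0:
        return np.empty(0, dtype=np.int64)
    return np.unique(np.minimum((train.times / bin_width).astype(np.int64), n_bins - 1))


def _te_from_counts(counts: np.ndarray) -> np.ndarray:
    """TE (bits) from joint count tables of shape (..., x0:2, y0:2, y1:2)."""
    c = np.asarray(counts, dtype=float)
    total = c.sum(axis=(-1, -2, -3))
    n_y0x0 = c.sum(axis=-1, keepdims=True)
    n_y0y1 = c.sum(axis=-3, keepdims=True)
    n_y0 = c.sum(axis=(-1, -3), keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = (c * n_y0) / (n_y0x0 * n_y0y1)
        term = c * np.log2(ratio)
    te = np.where(c > 0, term, 0.0).sum(axis=(-1, -2, -3)) / total
    return te


def transfer_entropy(x: Sequence[int], y: Sequence[int]) -> float:
    """Plug-in TE (bits) from binary input ``x`` to binary recipient ``y``."""
    x = np.asarray(x, dtype=np.int64)
    y = np.asarray(y, dtype=np.int64)
    if x.size != y.size:
        raise ValueError("sequences must have equal length")
    if x.size < 3:
        raise ValueError("need at least 3 time bins")
    code = 4 * x[:-1] + 2 * y[:-1] + y[1:]
    counts = np.bincount(code, minlength=8).reshape(2, 2, 2)
    return float(_te_from_counts(counts))


@dataclass
class TEPair:
    input_id: int
    recipient_id: int
    raw_te: float
    null_mean: float
    norm_te: float
    n_bins_used: int
    n_shuffles: int
    phase: str | None = None


@dataclass
class TEMatrixResult:
    """All-pairs TE for one ensemble; [input, recipient] indexed matrices."""

    cell_ids: np.ndarray
    raw: np.ndarray
    null_mean: np.ndarray
    norm: np.ndarray
    n_bins_used: int
    n_shuffles: int
    phase: str | None = None

    def pairs_frame(self) -> pd.DataFrame:
        n = len(self.cell_ids)
        inp, rec = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
        keep = inp != rec
        return pd.DataFrame(
            {
                "input_id": self.cell_ids[inp[keep]],
                "recipient_id": self.cell_ids[rec[keep]],
                "raw_te": self.raw[keep],
                "null_mean": self.null_mean[keep],
                "norm_te": self.norm[keep],
            }
        )


def _mask_valid_tau(mask: np.ndarray | None, n_bins: int) -> np.ndarray | None:
    """Positions tau where (tau, tau+1) are both inside the phase mask."""
    if mask is None:
        return None
    mask = np.asarray(mask, dtype=bool)
    if mask.size != n_bins:
        raise ValueError("mask length must equal the number of time bins")
    return mask[:-1] & mask[1:]


def te_matrix(
    trains: Sequence[SpikeTrain],
    *,
    bin_width: float = DEFAULT_TE_BIN,
    n_shuffles: int = DEFAULT_N_SHUFFLES,
    shift_range: tuple[float, float] = DEFAULT_SHIFT_RANGE,
    rng: np.random.Generator | None = None,
    mask: np.ndarray | None = None,
    phase: str | None = None,
) -> TEMatrixResult:
    """Shuffle-normalized TE between every ordered pair of cells.

    The null circularly shifts the *input* cell only, re-drawn per cell per
    shuffle; recipients are never shifted.  ``mask`` optionally restricts the
    estimate to time bins inside a task phase (shifts are applied on the full
    session circle before masking).
    """
    if n_shuffles < 1:
        raise ValueError("n_shuffles must be >= 1")
    rng = rng or np.random.default_rng(0)
    n_cells = len(trains)
    duration = trains[0].duration
    n_bins = int(round(duration / bin_width))
    valid_tau = _mask_valid_tau(mask, n_bins)
    tau_mask = None
    if valid_tau is not None:
        tau_mask = valid_tau
        n_used = int(tau_mask.sum())
    else:
        n_used = n_bins - 1
    if n_used < 2:
        raise ValueError("phase mask leaves too few usable time bins")

    spike_bins = [_spike_bin_indices(tr, bin_width, n_bins) for tr in trains]

    # recipient-side codes: base2[tau] = 2*y[tau] + y[tau+1]
    base2 = np.empty((n_cells, n_bins - 1), dtype=np.uint8)
    nb = np.empty((n_cells, 4), dtype=np.int64)
    for c in range(n_cells):
        y = np.zeros(n_bins, dtype=np.uint8)
        y[spike_bins[c]] = 1
        b = 2 * y[:-1].astype(np.uint8) + y[1:]
        base2[c] = b
        nb[c] = np.bincount(b[tau_mask] if tau_mask is not None else b, minlength=4)

    def input_taus(bins: np.ndarray) -> np.ndarray:
        taus = bins[bins <= n_bins - 2]
        if tau_mask is not None:
            taus = taus[tau_mask[taus]]
        return taus

    def pass_te(shifts: np.ndarray | None) -> np.ndarray:
        idx_parts, id_parts = [], []
        for c in range(n_cells):
            bins = spike_bins[c]
            if shifts is not None:
                bins = np.sort((bins + shifts[c]) % n_bins)
            taus = input_taus(bins)
            idx_parts.append(taus)
            id_parts.append(np.full(taus.size, c, dtype=np.int64))
        idx_all = np.concatenate(idx_parts)
        ids4 = np.concatenate(id_parts) * 4
        te = np.empty((n_cells, n_cells))
        for r in range(n_cells):
            codes = ids4 + base2[r][idx_all]
            c1 = np.bincount(codes, minlength=4 * n_cells).reshape(n_cells, 4)
            counts = np.empty((n_cells, 2, 2, 2), dtype=np.int64)
            # base2 = 2*y0 + y1
            counts[:, 1, 0, 0] = c1[:, 0]
            counts[:, 1, 0, 1] = c1[:, 1]
            counts[:, 1, 1, 0] = c1[:, 2]
            counts[:, 1, 1, 1] = c1[:, 3]
            counts[:, 0, 0, 0] = nb[r, 0] - c1[:, 0]
            counts[:, 0, 0, 1] = nb[r, 1] - c1[:, 1]
            counts[:, 0, 1, 0] = nb[r, 2] - c1[:, 2]
            counts[:, 0, 1, 1] = nb[r, 3] - c1[:, 3]
            te[:, r] = _te_from_counts(counts)
        return te

    raw = pass_te(None)
    lo = int(round(shift_range[0] / bin_width))
    hi = int(round(shift_range[1] / bin_width))
    null_acc = np.zeros_like(raw)
    for _ in range(n_shuffles):
        shifts = rng.integers(lo, hi + 1, size=n_cells)
        null_acc += pass_te(shifts)
    null_mean = null_acc / n_shuffles
    norm = raw - null_mean
    for arr in (raw, null_mean, norm):
        np.fill_diagonal(arr, np.nan)
    return TEMatrixResult(
        cell_ids=np.array([tr.cell_id for tr in trains]),
        raw=raw,
        null_mean=null_mean,
        norm=norm,
        n_bins_used=n_used,
        n_shuffles=n_shuffles,
        phase=phase,
    )


def te_normalized(
    x_train: SpikeTrain,
    y_train: SpikeTrain,
    *,
    bin_width: float = DEFAULT_TE_BIN,
    n_shuffles: int = DEFAULT_N_SHUFFLES,
    shift_range: tuple[float, float] = DEFAULT_SHIFT_RANGE,
    rng: np.random.Generator | None = None,
    mask: np.ndarray | None = None,
) -> TEPair:
    """Shuffle-normalized TE for one directed pair (X shifted, Y fixed)."""
    res = te_matrix(
        [x_train, y_train],
        bin_width=bin_width,
        n_shuffles=n_shuffles,
        shift_range=shift_range,
        rng=rng,
        mask=mask,
    )
    return TEPair(
        input_id=x_train.cell_id,
        recipient_id=y_train.cell_id,
        raw_te=float(res.raw[0, 1]),
        null_mean=float(res.null_mean[0, 1]),
        norm_te=float(res.norm[0, 1]),
        n_bins_used=res.n_bins_used,
        n_shuffles=n_shuffles,
    )


def intervals_to_mask(
    intervals: Sequence[tuple[float, float]],
    duration: float,
    bin_width: float = DEFAULT_TE_BIN,
) -> np.ndarray:
    """Boolean per-bin occupancy mask from a list of time intervals.

    A bin counts as inside the phase if its midpoint falls in an interval.
    """
    n_bins = int(round(duration / bin_width))
    mids = (np.arange(n_bins) + 0.5) * bin_width
    mask = np.zeros(n_bins, dtype=bool)
    for a, b in intervals:
        mask |= (mids >= a) & (mids < b)
    return mask


def te_by_phase(
    trains: Sequence[SpikeTrain],
    phase_intervals: dict[str, list[tuple[float, float]]],
    phase: str,
    *,
    bin_width: float = DEFAULT_TE_BIN,
    n_shuffles: int = DEFAULT_N_SHUFFLES,
    shift_range: tuple[float, float] = DEFAULT_SHIFT_RANGE,
    rng: np.random.Generator | None = None,
    min_bins: int = DEFAULT_MIN_PHASE_BINS,
) -> TEMatrixResult:
    """All-pairs normalized TE restricted to bins inside one task phase.

    Input-cell shifts are applied on the full session timeline before
    masking, preserving within-phase spike structure relative to the mask.
    """
    duration = trains[0].duration
    mask = intervals_to_mask(phase_intervals[phase], duration, bin_width)
    n_occupied = int(mask.sum())
    if n_occupied < min_bins:
        raise ValueError(
            f"phase {phase!r} occupies {n_occupied} bins < minimum {min_bins}"
        )
    return te_matrix(
        trains,
        bin_width=bin_width,
        n_shuffles=n_shuffles,
        shift_range=shift_range,
        rng=rng,
        mask=mask,
        phase=phase,
    )


# ---------------------------------------------------------------------------
# anatomical aggregation
# ---------------------------------------------------------------------------

@dataclass
class TEMap:
    """2D anatomical aggregation of pair TE at fixed depth resolution."""

    edges: np.ndarray        # shared bin edges along both axes, micrometers
    values: np.ndarray       # (n_bins, n_bins) mean norm TE, NaN where empty
    counts: np.ndarray       # pairs per bin
    resolution: float

    @property
    def centers(self) -> np.ndarray:
        return (self.edges[:-1] + self.edges[1:]) / 2


def te_spatial_map(
    pairs: pd.DataFrame,
    depths: dict[int, float] | pd.Series,
    *,
    resolution: float = DEFAULT_MAP_RESOLUTION,
    span: tuple[float, float] | None = None,
) -> TEMap:
    """Mean normalized TE on a (input depth x recipient depth) grid.

    The grid origin is anchored at the dorsal-most recorded depth.  Pairs
    with a depth outside an explicit ``span`` are dropped with a warning.
    """
    depths = pd.Series(depths)
    d_in = pairs["input_id"].map(depths).to_numpy(dtype=float)
    d_re = pairs["recipient_id"].map(depths).to_numpy(dtype=float)
    te = pairs["norm_te"].to_numpy(dtype=float)
    lo, hi = span if span is not None else (
        float(min(d_in.min(), d_re.min())),
        float(max(d_in.max(), d_re.max())),
    )
    keep = (d_in >= lo) & (d_in <= hi) & (d_re >= lo) & (d_re <= hi) & np.isfinite(te)
    n_drop = int((~keep).sum())
    if span is not None and n_drop:
        logger.warning("dropping %d pairs with depths outside the grid", n_drop)
    d_in, d_re, te = d_in[keep], d_re[keep], te[keep]
    n_bins = max(int(np.ceil((hi - lo) / resolution)), 1)
    edges = lo + resolution * np.arange(n_bins + 1)
    bi = np.minimum(((d_in - lo) // resolution).astype(int), n_bins - 1)
    bj = np.minimum(((d_re - lo) // resolution).astype(int), n_bins - 1)
    flat = bi * n_bins + bj
    counts = np.bincount(flat, minlength=n_bins * n_bins)
    sums = np.bincount(flat, weights=te, minlength=n_bins * n_bins)
    with np.errstate(invalid="ignore", divide="ignore"):
        values = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return TEMap(
        edges=edges,
        values=values.reshape(n_bins, n_bins),
        counts=counts.reshape(n_bins, n_bins),
        resolution=resolution,
    )


@dataclass
class DVProfile:
    depths: np.ndarray
    values: np.ndarray       # NaN where no occupied bin lies in the window


def diagonal_profile(temap: TEMap, window: float = DEFAULT_DIAGONAL_WINDOW) -> DVProfile:
    """Near-diagonal depth profile: at each grid depth, the mean of occupied
    2D bins whose input AND recipient centers are both within ``window``."""
    centers = temap.centers
    vals = np.full(centers.size, np.nan)
    occ = temap.counts > 0
    ci, cj = np.meshgrid(centers, centers, indexing="ij")
    for k, d in enumerate(centers):
        sel = occ & (np.abs(ci - d) <= window) & (np.abs(cj - d) <= window)
        if sel.any():
            vals[k] = float(temap.values[sel].mean())
    return DVProfile(depths=centers.copy(), values=vals)


@dataclass
class SubregionBounds:
    boundary_depths: np.ndarray
    labels: list[str] = field(default_factory=list)
    single_region: bool = False

    def __post_init__(self) -> None:
        self.boundary_depths = np.asarray(self.boundary_depths, dtype=float)
        if not self.labels:
            self.labels = [f"region_{k + 1}" for k in range(len(self.boundary_depths) + 1)]


def find_boundaries(
    profile: DVProfile,
    *,
    smooth: bool = False,
    min_separation: float = 200.0,
    prominence_frac: float = 0.1,
) -> SubregionBounds:
    """Interior local minima of the depth profile = subregion boundaries.

    Minima must have prominence of at least ``prominence_frac`` of the
    profile's range, and minima closer together than ``min_separation`` are
    pruned keeping the deeper (lower-valued) one.  ``smooth=True`` applies a
    width-3 moving average before minima detection.  A profile with no
    interior minima yields a flagged single-region result.
    """
    from scipy.signal import find_peaks

    ok = np.isfinite(profile.values)
    if ok.sum() < 5:
        raise ValueError("need at least 5 defined profile points")
    depths = profile.depths[ok]
    vals = profile.values[ok].astype(float)
    if smooth:
        pad = np.r_[vals[0], vals, vals[-1]]
        vals = (pad[:-2] + pad[1:-1] + pad[2:]) / 3.0

    span = float(vals.max() - vals.min())
    prominence = prominence_frac * span if span > 0 else None
    idx, _ = find_peaks(-vals, prominence=prominence)
    minima = []
    for i in idx:
        d = float(depths[i])
        # parabolic sub-bin refinement of the valley position, clamped to
        # half a grid step; removes the quantization offset of the 100 um grid
        denom = vals[i - 1] - 2 * vals[i] + vals[i + 1]
        if denom > 0:
            frac = 0.5 * (vals[i - 1] - vals[i + 1]) / denom
            frac = float(np.clip(frac, -0.5, 0.5))
            step = float(depths[min(i + 1, len(depths) - 1)] - depths[i]) or 1.0
            d += frac * step
        minima.append((float(vals[i]), d))

    kept: list[tuple[float, float]] = []
    for val, d in sorted(minima):
        if all(abs(d - d0) >= min_separation for _, d0 in kept):
            kept.append((val, d))
    bounds = np.array(sorted(d for _, d in kept))
    if bounds.size == 0:
        logger.warning("no interior minima: single-region result")
        return SubregionBounds(boundary_depths=np.empty(0), single_region=True)
    return SubregionBounds(boundary_depths=bounds)


def assign_subregions(
    depths: dict[int, float] | pd.Series, bounds: SubregionBounds
) -> pd.Series:
    """Label each cell by the boundary interval containing its depth.

    Cells exactly on a boundary join the dorsal (shallower) interval.
    """
    depths = pd.Series(depths, dtype=float)
    idx = np.searchsorted(bounds.boundary_depths, depths.to_numpy(), side="left")
    labels = [bounds.labels[i] for i in idx]
    return pd.Series(labels, index=depths.index, name="subregion")


@dataclass
class RegionTEStats:
    step_groups: dict[int, np.ndarray]
    step_means: dict[int, float]
    intra_vs_inter_z: float
    intra_vs_inter_p: float


def region_te_stats(pairs: pd.DataFrame, labels: pd.Series, region_order: list[str]) -> RegionTEStats:
    """Normalized-TE distributions grouped by subregion step distance.

    Step = |region index difference| of the two cells; step 0 is
    intra-regional.  Reports group means and the intra-vs-inter rank-sum
    comparison.  Empty step groups are omitted with a log note.
    """
    rank = {lab: i for i, lab in enumerate(region_order)}
    li = labels.reindex(pairs["input_id"]).map(rank).to_numpy()
    lr = labels.reindex(pairs["recipient_id"]).map(rank).to_numpy()
    te = pairs["norm_te"].to_numpy(dtype=float)
    ok = np.isfinite(te) & np.isfinite(li.astype(float)) & np.isfinite(lr.astype(float))
    step = np.abs(li[ok] - lr[ok]).astype(int)
    te = te[ok]
    groups: dict[int, np.ndarray] = {}
    means: dict[int, float] = {}
    for s in range(len(region_order)):
        sel = te[step == s]
        if sel.size == 0:
            logger.info("step group %d empty; omitted", s)
            continue
        groups[s] = sel
        means[s] = float(sel.mean())
    intra = te[step == 0]
    inter = te[step > 0]
    if intra.size and inter.size:
        z, p = sps.ranksums(intra, inter)
    else:
        z, p = float("nan"), float("nan")
        logger.info("intra or inter group empty; rank-sum undefined")
    return RegionTEStats(
        step_groups=groups,
        step_means=means,
        intra_vs_inter_z=float(z),
        intra_vs_inter_p=float(p),
    )
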