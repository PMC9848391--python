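"""Basic spiking properties, PETHs, and circular-shift shuffle normalization.

The shuffle engine here backs every downstream analysis: a statistic of a
spike train is normalized by subtracting its mean over circularly shifted
copies of the train (shifts uniform on 1-59 min of the session circle), which
preserves the train's internal structure while destroying its alignment to
events or partner cells.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .synthetic import TIME_RESOLUTION, SpikeTrain

logger = logging.getLogger(__name__)

DEFAULT_SHIFT_RANGE = (60.0, 3540.0)
DEFAULT_N_SHUFFLES = 30

#: normalized-time layout: 3 pre-context bins, 20 in-zone bins, 3 post bins
N_ZONE_BINS = 20
N_CONTEXT_BINS = 3
N_NORMALIZED_BINS = N_ZONE_BINS + 2 * N_CONTEXT_BINS


def circular_shift(train: SpikeTrain, shift: float) -> SpikeTrain:
    """Rotate spike times by ``shift`` seconds on the session circle."""
    times = np.sort(np.mod(train.times + shift, train.duration))
    return SpikeTrain(cell_id=train.cell_id, times=times, duration=train.duration)


def shuffle_normalize(
    statistic: Callable[[SpikeTrain], np.ndarray | float],
    train: SpikeTrain,
    *,
    n_shuffles: int = DEFAULT_N_SHUFFLES,
    shift_range: tuple[float, float] = DEFAULT_SHIFT_RANGE,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray | float, np.ndarray | float, np.ndarray | float]:
    """Return (normalized, raw, null_mean) for ``statistic`` on ``train``.

    ``normalized = statistic(train) - mean_k statistic(shifted_k(train))``
    with shifts drawn uniformly in ``shift_range``.
    """
    if n_shuffles < 1:
        raise ValueError("n_shuffles must be >= 1")
    rng = rng or np.random.default_rng(0)
    raw = statistic(train)
    acc = None
    for _ in range(n_shuffles):
        shift = float(rng.uniform(*shift_range))
        val = statistic(circular_shift(train, shift))
        acc = np.asarray(val, dtype=float) if acc is None else acc + np.asarray(val, dtype=float)
    null_mean = acc / n_shuffles
    raw_arr = np.asarray(raw, dtype=float)
    norm = raw_arr - null_mean
    if np.ndim(raw) == 0:
        return float(norm), float(raw_arr), float(null_mean)
    return norm, raw_arr, null_mean


# ---------------------------------------------------------------------------
# basic properties
# ---------------------------------------------------------------------------

@dataclass
class BasicProperties:
    cell_id: int
    mean_rate: float
    cv: float
    median_isi: float
    isi_sd: float
    burst_ratio: float
    spike_width: float
    n_spikes: int
    isi_defined: bool


def basic_properties(
    train: SpikeTrain,
    spike_width_us: float,
    *,
    cv_bin: float = 0.050,
    burst_short: float = 0.010,
    burst_long: float = 0.125,
) -> BasicProperties:
    """Rate, variability, and burstiness summaries of one spike train.

    CV is sd/mean of firing rates in 50 ms bins over the session; the burst
    ratio is #(ISI < 10 ms) / #(ISI > 125 ms).  With fewer than two spikes
    (or no long ISIs) the ISI-derived fields are NaN and flagged undefined
    rather than zero.
    """
    duration = train.duration
    n = len(train)
    mean_rate = n / duration
    n_bins = int(math.ceil(duration / cv_bin))
    counts = np.bincount(
        np.minimum((train.times / cv_bin).astype(int), n_bins - 1), minlength=n_bins
    )
    rates = counts / cv_bin
    cv = float(rates.std() / rates.mean()) if n > 0 else float("nan")

    if n >= 2:
        isi = np.diff(train.times)
        median_isi = float(np.median(isi))
        isi_sd = float(isi.std(ddof=1)) if isi.size > 1 else float("nan")
        n_short = int((isi < burst_short).sum())
        n_long = int((isi > burst_long).sum())
        if n_long == 0:
            burst_ratio = float("nan")
            isi_defined = False
            logger.info("cell %s: no long ISIs; burst ratio undefined", train.cell_id)
        else:
            burst_ratio = n_short / n_long
            isi_defined = True
    else:
        median_isi = isi_sd = burst_ratio = float("nan")
        isi_defined = False
    return BasicProperties(
        cell_id=train.cell_id,
        mean_rate=mean_rate,
        cv=cv,
        median_isi=median_isi,
        isi_sd=isi_sd,
        burst_ratio=burst_ratio,
        spike_width=spike_width_us,
        n_spikes=n,
        isi_defined=isi_defined,
    )


def classify_cell(
    mean_rate: float,
    spike_width_us: float,
    *,
    boundary: tuple[float, float] = (-0.02, 16.0),
) -> str:
    """Side-of-line split of rate x width space into principal vs interneuron.

    ``boundary = (slope, intercept)`` defines the line
    ``rate = slope * width + intercept``; cells strictly above it (high rate,
    narrow spikes for a negative slope) are interneurons.  A point exactly on
    the boundary is classified principal and logged.
    """
    slope, intercept = boundary
    line = slope * spike_width_us + intercept
    if mean_rate == line:
        logger.info("cell on classification boundary -> principal")
        return "principal"
    return "interneuron" if mean_rate > line else "principal"


# ---------------------------------------------------------------------------
# peri-event time histograms
# ---------------------------------------------------------------------------

@dataclass
class PETH:
    cell_id: int
    alignment: str
    bin_centers: np.ndarray        # seconds (absolute) or bin index (normalized)
    per_visit: np.ndarray          # (n_visits, n_bins) rates, NaN = undefined
    mean: np.ndarray               # unweighted mean across visits per bin
    normalized: bool = False
    n_shuffles: int = 0
    kept_visits: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))


def peth_absolute(
    train: SpikeTrain,
    event_times: Sequence[float],
    *,
    window: tuple[float, float] = (-2.0, 5.0),
    bin_width: float = 0.100,
    alignment: str = "event",
    valid_windows: Sequence[tuple[float, float]] | None = None,
) -> PETH:
    """Event-aligned firing rates in absolute-time bins.

    ``valid_windows``, if given, provides per-event intervals (relative to the
    event) outside which bins are NaN; used for wait-zone analyses where the
    in-zone duration differs across visits.
    """
    event_times = np.asarray(event_times, dtype=float)
    if event_times.size == 0:
        raise ValueError("need at least one alignment event")
    edges = np.arange(window[0], window[1] + bin_width / 2, bin_width)
    centers = (edges[:-1] + edges[1:]) / 2
    n_bins = centers.size
    per_visit = np.full((event_times.size, n_bins), np.nan)
    for i, t0 in enumerate(event_times):
        counts, _ = np.histogram(train.times - t0, bins=edges)
        rates = counts / bin_width
        if valid_windows is not None:
            lo, hi = valid_windows[i]
            mask = (centers >= lo) & (centers <= hi)
            rates = np.where(mask, rates, np.nan)
        per_visit[i] = rates
    with np.errstate(invalid="ignore"):
        mean = np.nanmean(per_visit, axis=0)
    return PETH(
        cell_id=train.cell_id,
        alignment=alignment,
        bin_centers=centers,
        per_visit=per_visit,
        mean=mean,
        kept_visits=np.arange(event_times.size),
    )


def peth_normalized(
    train: SpikeTrain,
    zone_intervals: Sequence[tuple[float, float]],
    *,
    pre_durations: Sequence[float] | None = None,
    post_durations: Sequence[float] | None = None,
    alignment: str = "zone",
) -> PETH:
    """Zone-duration-normalized firing profile: 20 in-zone bins of 5% of the
    zone time each, plus 3 pre and 3 post context bins of 10% of the
    preceding/following period.  Rates are counts over that visit's bin
    duration.  Zone visits shorter than 20 timestamp-resolution steps are
    dropped with a warning.
    """
    zone_intervals = list(zone_intervals)
    if not zone_intervals:
        raise ValueError("need at least one zone visit")
    n_visits = len(zone_intervals)
    pre_durations = list(pre_durations) if pre_durations is not None else [0.0] * n_visits
    post_durations = list(post_durations) if post_durations is not None else [0.0] * n_visits

    rows = []
    kept = []
    for i, (start, end) in enumerate(zone_intervals):
        zdur = end - start
        if zdur < N_ZONE_BINS * TIME_RESOLUTION:
            logger.warning("dropping zone visit of duration %.4f s", zdur)
            continue
        rates = np.full(N_NORMALIZED_BINS, np.nan)
        pre = pre_durations[i]
        if pre > 0:
            wb = pre / 10.0
            for b in range(N_CONTEXT_BINS):
                t1 = start - (N_CONTEXT_BINS - b) * wb
                rates[b] = _count_in(train.times, t1, t1 + wb) / wb
        wb = zdur / N_ZONE_BINS
        for b in range(N_ZONE_BINS):
            t1 = start + b * wb
            rates[N_CONTEXT_BINS + b] = _count_in(train.times, t1, t1 + wb) / wb
        post = post_durations[i]
        if post > 0:
            wb = post / 10.0
            for b in range(N_CONTEXT_BINS):
                t1 = end + b * wb
                rates[N_CONTEXT_BINS + N_ZONE_BINS + b] = _count_in(train.times, t1, t1 + wb) / wb
        rows.append(rates)
        kept.append(i)
    if not rows:
        raise ValueError("all zone visits too short for normalized binning")
    per_visit = np.vstack(rows)
    with np.errstate(invalid="ignore"):
        mean = np.nanmean(per_visit, axis=0)
    centers = np.arange(N_NORMALIZED_BINS) - N_CONTEXT_BINS  # pre bins at -3..-1
    return PETH(
        cell_id=train.cell_id,
        alignment=alignment,
        bin_centers=centers.astype(float),
        per_visit=per_visit,
        mean=mean,
        normalized=True,
        kept_visits=np.asarray(kept, dtype=int),
    )


def _count_in(times: np.ndarray, lo: float, hi: float) -> int:
    return int(np.searchsorted(times, hi) - np.searchsorted(times, lo))


def shuffle_normalized_peth(
    peth_fn: Callable[[SpikeTrain], PETH],
    train: SpikeTrain,
    *,
    n_shuffles: int = DEFAULT_N_SHUFFLES,
    shift_range: tuple[float, float] = DEFAULT_SHIFT_RANGE,
    rng: np.random.Generator | None = None,
) -> PETH:
    """PETH minus the mean PETH over circularly shifted spike trains."""
    norm, raw, null = shuffle_normalize(
        lambda tr: peth_fn(tr).mean,
        train,
        n_shuffles=n_shuffles,
        shift_range=shift_range,
        rng=rng,
    )
    base = peth_fn(train)
    return PETH(
        cell_id=base.cell_id,
        alignment=base.alignment,
        bin_centers=base.bin_centers,
        per_visit=base.per_visit,
        mean=np.asarray(norm),
        normalized=base.normalized,
        n_shuffles=n_shuffles,
        kept_visits=base.kept_visits,
    )
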