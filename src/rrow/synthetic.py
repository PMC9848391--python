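"""Generators for task sessions and spike ensembles with planted structure.

The session simulator produces an event log for a four-restaurant foraging
task: at each site the agent receives a delay offer (integer seconds, uniform
on ``delay_range``), accepts or skips it under a logistic rule around a
per-restaurant threshold, may quit during the wait, and lingers after earned
rewards.  The ensemble simulator layers inhomogeneous-Poisson spike trains on
top of a session, with per-cell multiplicative tuning gains and directed
pairwise coupling organized into depth blocks, so downstream analyses have a
known recovery target.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: event-log timestamp resolution, seconds
TIME_RESOLUTION = 1e-3

PHASES = ("OZ", "WZ", "RZ", "TZ")


def _quantize(t: float) -> float:
    return round(t / TIME_RESOLUTION) * TIME_RESOLUTION


@dataclass
class SessionConfig:
    """Parameters of one simulated foraging session."""

    n_restaurants: int = 4
    session_duration: float = 3600.0
    delay_range: tuple[int, int] = (1, 30)
    thresholds: tuple[float, ...] = (20.0, 15.0, 10.0, 5.0)
    accept_noise: float = 2.0        # logistic slope per second of value
    quit_hazard_scale: float = 0.10  # per-second hazard per second of negative value
    linger_lognorm: tuple[float, float] = (math.log(6.0), 0.5)
    reaction_lognorm: tuple[float, float] = (math.log(1.8), 0.35)
    travel_time: float = 4.0
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.delay_range
        if not (0 < lo <= hi):
            raise ValueError("delay_range must satisfy 0 < min <= max")
        if self.session_duration <= 0:
            raise ValueError("session_duration must be positive")
        if len(self.thresholds) != self.n_restaurants:
            raise ValueError("need one threshold per restaurant")
        for th in self.thresholds:
            if not (lo - 0.5 <= th <= hi + 0.5):
                raise ValueError(
                    f"threshold {th} outside delay range [{lo - 0.5}, {hi + 0.5}]"
                )


def _accept_probability(value: float, slope: float) -> float:
    if math.isinf(slope):
        return 1.0 if value >= 0 else 0.0
    return 1.0 / (1.0 + math.exp(-slope * value))


def simulate_session(config: SessionConfig) -> pd.DataFrame:
    """Simulate one session; return a chronologically ordered event log.

    Columns: ``time_s, event, restaurant, lap, offer_delay_s``.  Events per
    visit follow oz_enter -> oz_exit -> (wz_enter -> (reward -> rz_exit |
    wz_exit) | nothing) -> tz_enter.  ``attrs`` carries the config for
    downstream ground-truth access.
    """
    lo, hi = config.delay_range
    if config.travel_time + lo > config.session_duration:
        raise ValueError("session too short for a single visit")
    rng = np.random.default_rng(config.seed)
    rows: list[tuple[float, str, int, int, float]] = []

    t = _quantize(rng.uniform(0.5, 1.5))  # brief settling period before first visit
    visit_idx = 0
    while True:
        restaurant = visit_idx % config.n_restaurants
        lap = visit_idx // config.n_restaurants
        delay = int(rng.integers(lo, hi + 1))
        value = config.thresholds[restaurant] - delay
        accept = rng.uniform() < _accept_probability(value, config.accept_noise)
        mu_r, sd_r = config.reaction_lognorm
        reaction = float(rng.lognormal(mu_r, sd_r)) * (0.85 if accept else 1.0)
        reaction = max(reaction, 5 * TIME_RESOLUTION)

        visit: list[tuple[float, str, int, int, float]] = []
        t_oz = _quantize(t)
        t_exit = _quantize(t_oz + reaction)
        visit.append((t_oz, "oz_enter", restaurant, lap, float(delay)))
        visit.append((t_exit, "oz_exit", restaurant, lap, np.nan))
        if accept:
            t_wz = t_exit
            visit.append((t_wz, "wz_enter", restaurant, lap, np.nan))
            hazard = config.quit_hazard_scale * max(0.0, -value)
            t_quit = rng.exponential(1.0 / hazard) if hazard > 0 else math.inf
            if t_quit < delay:
                wait = min(max(_quantize(t_quit), TIME_RESOLUTION), delay - TIME_RESOLUTION)
                t_leave = _quantize(t_wz + wait)
                visit.append((t_leave, "wz_exit", restaurant, lap, np.nan))
            else:
                t_rw = _quantize(t_wz + delay)
                mu_l, sd_l = config.linger_lognorm
                linger = max(float(rng.lognormal(mu_l, sd_l)), 0.5)
                t_leave = _quantize(t_rw + linger)
                visit.append((t_rw, "reward", restaurant, lap, np.nan))
                visit.append((t_leave, "rz_exit", restaurant, lap, np.nan))
        else:
            t_leave = t_exit
        visit.append((t_leave, "tz_enter", restaurant, lap, np.nan))

        if t_leave > config.session_duration:
            break  # would run past session end: drop the incomplete visit
        rows.extend(visit)
        visit_idx += 1
        travel = float(rng.lognormal(math.log(config.travel_time), 0.15))
        t = t_leave + travel
        if t >= config.session_duration:
            break

    events = pd.DataFrame(
        rows, columns=["time_s", "event", "restaurant", "lap", "offer_delay_s"]
    )
    events = events.sort_values("time_s", kind="stable").reset_index(drop=True)
    events.attrs["session_duration"] = config.session_duration
    events.attrs["thresholds"] = tuple(config.thresholds)
    events.attrs["delay_range"] = tuple(config.delay_range)
    events.attrs["seed"] = config.seed
    return events


# ---------------------------------------------------------------------------
# spike ensembles
# ---------------------------------------------------------------------------

@dataclass
class SpikeTrain:
    """Sorted spike times of one cell over a session."""

    cell_id: int
    times: np.ndarray
    duration: float = 3600.0

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if self.times.size and (np.any(np.diff(self.times) < 0)):
            raise ValueError("spike times must be nondecreasing")
        if self.times.size and (self.times[0] < 0 or self.times[-1] > self.duration):
            raise ValueError("spike times outside session bounds")

    def __len__(self) -> int:
        return int(self.times.size)


@dataclass
class CellGains:
    """Multiplicative tuning of one cell's rate to task variables.

    ``phase`` multiplies rate per task phase; ``time_slope`` tilts rate
    linearly over the session (factor ``1 + slope * (t/T - 0.5)``); ``rank``
    multiplies by restaurant reward rank; ``choice`` applies during the
    offer-zone period of visits with the matching accept/skip outcome.
    """

    phase: dict[str, float] = field(default_factory=dict)
    time_slope: float = 0.0
    rank: dict[int, float] = field(default_factory=dict)
    choice: dict[str, float] = field(default_factory=dict)

    def phase_gain(self, phase: str) -> float:
        return self.phase.get(phase, 1.0)

    def rank_gain(self, rank: int) -> float:
        return self.rank.get(rank, 1.0)

    def choice_gain(self, choice: str) -> float:
        return self.choice.get(choice, 1.0)

    def max_gain(self) -> float:
        g = max([1.0, *self.phase.values()], default=1.0)
        g *= max([1.0, *self.rank.values()], default=1.0)
        g *= max([1.0, *self.choice.values()], default=1.0)
        g *= 1.0 + abs(self.time_slope) / 2.0
        return g


@dataclass
class EnsembleConfig:
    """Parameters of a simulated spike ensemble tied to a session."""

    n_cells: int = 40
    dv_span: tuple[float, float] = (0.0, 3000.0)
    block_bounds: tuple[float, ...] = (750.0, 1500.0, 2250.0)
    base_rate_range: tuple[float, float] = (2.0, 8.0)
    gains: list[CellGains] | None = None
    coupling: list[tuple[int, int, int, float]] = field(default_factory=list)
    spike_width_modes: tuple[tuple[float, float], tuple[float, float]] = (
        (250.0, 30.0),
        (550.0, 60.0),
    )
    narrow_fraction: float = 0.2
    te_bin: float = 0.010
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.dv_span
        bounds = tuple(self.block_bounds)
        if any(b2 <= b1 for b1, b2 in zip(bounds, bounds[1:])):
            raise ValueError("block_bounds must be strictly increasing")
        if bounds and (bounds[0] <= lo or bounds[-1] >= hi):
            raise ValueError("block_bounds must lie strictly inside dv_span")
        for inp, rec, lag, excess in self.coupling:
            if lag < 1:
                raise ValueError("coupling lag must be >= 1 bin")
            if not (0.0 <= excess <= 1.0):
                raise ValueError("coupling excess must be a probability")
        if self.base_rate_range[0] < 0:
            raise ValueError("rates must be nonnegative")


def block_of(depth: float, block_bounds: tuple[float, ...]) -> int:
    """Index of the depth block containing ``depth`` (bounds join the dorsal side)."""
    return int(np.searchsorted(np.asarray(block_bounds), depth, side="left"))


def make_block_coupling(
    depths: np.ndarray,
    block_bounds: tuple[float, ...],
    *,
    prob: float = 0.2,
    lag: int = 1,
    excess: float = 0.25,
    rng: np.random.Generator | None = None,
) -> list[tuple[int, int, int, float]]:
    """Random within-block directed couplings, the planted parcellation."""
    rng = rng or np.random.default_rng(0)
    blocks = [block_of(d, block_bounds) for d in depths]
    out = []
    n = len(depths)
    for i in range(n):
        for j in range(n):
            if i != j and blocks[i] == blocks[j] and rng.uniform() < prob:
                out.append((i, j, lag, excess))
    return out


def _session_segments(events: pd.DataFrame, duration: float) -> pd.DataFrame:
    """Piecewise-constant task context: start, end, phase, restaurant, choice."""
    from .behavior import parse_visits  # local import to avoid cycle at import time

    visits = parse_visits(events)
    segs: list[tuple[float, float, str, int, str]] = []
    cursor = 0.0
    for v in visits:
        if v.oz_enter > cursor:
            segs.append((cursor, v.oz_enter, "TZ", -1, ""))
        oz_choice = "skip" if v.outcome == "skip" else "accept"
        segs.append((v.oz_enter, v.oz_exit, "OZ", v.restaurant, oz_choice))
        cursor = v.oz_exit
        if v.outcome != "skip":
            segs.append((v.wz_enter, v.wz_exit, "WZ", v.restaurant, ""))
            cursor = v.wz_exit
        if v.outcome == "earn":
            segs.append((v.reward_time, v.rz_exit, "RZ", v.restaurant, ""))
            cursor = v.rz_exit
    if cursor < duration:
        segs.append((cursor, duration, "TZ", -1, ""))
    return pd.DataFrame(segs, columns=["start", "end", "phase", "restaurant", "choice"])


def _restaurant_ranks(events: pd.DataFrame) -> dict[int, int]:
    thresholds = events.attrs.get("thresholds")
    if thresholds is None:
        return {}
    order = np.argsort(-np.asarray(thresholds), kind="stable")
    return {int(r): rank + 1 for rank, r in enumerate(order)}


def simulate_ensemble(
    events: pd.DataFrame,
    config: EnsembleConfig,
    *,
    session_duration: float | None = None,
) -> tuple[list[SpikeTrain], pd.DataFrame]:
    """Simulate spike trains for ``config.n_cells`` cells during ``events``.

    Each cell is an inhomogeneous Poisson process (thinning of a homogeneous
    envelope) whose rate is base rate x phase gain x session-time trend x
    rank gain x choice gain.  Coupled pairs add excess recipient spikes at
    the configured lag (in ``te_bin`` steps) after input spikes.

    Returns the spike trains and a cell-metadata table with columns
    ``cell_id, probe_id, channel, dv_um, spike_width_us, base_rate_hz,
    true_block``.
    """
    duration = float(
        session_duration
        if session_duration is not None
        else events.attrs.get("session_duration", 3600.0)
    )
    rng = np.random.default_rng(config.seed)
    segments = _session_segments(events, duration)
    ranks = _restaurant_ranks(events)
    seg_start = segments["start"].to_numpy()
    n_cells = config.n_cells

    depths = rng.uniform(config.dv_span[0], config.dv_span[1], size=n_cells)
    base_rates = rng.uniform(*config.base_rate_range, size=n_cells)
    gains = config.gains or [CellGains() for _ in range(n_cells)]
    if len(gains) != n_cells:
        raise ValueError("need one CellGains per cell")

    # per-segment multiplier for each cell (time trend applied per spike below)
    narrow = rng.uniform(size=n_cells) < config.narrow_fraction
    widths = np.where(
        narrow,
        rng.normal(*config.spike_width_modes[0], size=n_cells),
        rng.normal(*config.spike_width_modes[1], size=n_cells),
    )

    base_spikes: list[np.ndarray] = []
    for c in range(n_cells):
        g = gains[c]
        seg_mult = np.ones(len(segments))
        for k, seg in enumerate(segments.itertuples(index=False)):
            m = g.phase_gain(seg.phase)
            if seg.restaurant >= 0 and ranks:
                m *= g.rank_gain(ranks[seg.restaurant])
            if seg.phase == "OZ" and seg.choice:
                m *= g.choice_gain(seg.choice)
            seg_mult[k] = m
        envelope = base_rates[c] * g.max_gain()
        if envelope <= 0:
            base_spikes.append(np.empty(0))
            continue
        n_cand = rng.poisson(envelope * duration)
        cand = np.sort(rng.uniform(0.0, duration, size=n_cand))
        seg_idx = np.clip(np.searchsorted(seg_start, cand, side="right") - 1, 0, None)
        rate = base_rates[c] * seg_mult[seg_idx]
        rate = rate * (1.0 + g.time_slope * (cand / duration - 0.5))
        neg = rate < 0
        if np.any(neg):
            logger.info("cell %d: clipping %d negative-rate points at 0", c, neg.sum())
            rate[neg] = 0.0
        keep = rng.uniform(size=n_cand) < rate / envelope
        base_spikes.append(cand[keep])

    extra: list[list[np.ndarray]] = [[] for _ in range(n_cells)]
    for inp, rec, lag, excess in config.coupling:
        src = base_spikes[inp]
        if src.size == 0:
            continue
        keep = rng.uniform(size=src.size) < excess
        added = src[keep] + lag * config.te_bin
        extra[rec].append(added[added <= duration])

    trains: list[SpikeTrain] = []
    for c in range(n_cells):
        times = np.sort(np.concatenate([base_spikes[c], *extra[c]])) if extra[c] else base_spikes[c]
        trains.append(SpikeTrain(cell_id=c, times=times, duration=duration))

    spacing = 20.0
    channels = np.clip(
        np.round((config.dv_span[1] - depths) / spacing).astype(int), 0, 63
    )
    cells = pd.DataFrame(
        {
            "cell_id": np.arange(n_cells),
            "probe_id": 0,
            "channel": channels,
            "dv_um": depths,
            "spike_width_us": widths,
            "base_rate_hz": base_rates,
            "true_block": [block_of(d, tuple(config.block_bounds)) for d in depths],
        }
    )
    cells.attrs["block_bounds"] = tuple(config.block_bounds)
    cells.attrs["dv_span"] = tuple(config.dv_span)
    return trains, cells
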