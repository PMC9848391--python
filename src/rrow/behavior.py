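"""Visit parsing and economic quantities: thresholds, value, ranks, timing.

A visit is skip / quit / earn depending on whether the wait zone was entered
and, if so, whether the full delay was waited out.  The per-restaurant
threshold is the least-squares fit of a Heaviside step to the earned
indicator as a function of offer delay; subjective value is the signed
distance of an offer from that threshold.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


class EventLogError(ValueError):
    """Structured parse error for a malformed event log."""

    def __init__(self, message: str, time_s: float | None = None):
        self.time_s = time_s
        if time_s is not None:
            message = f"{message} (at t={time_s:.3f} s)"
        super().__init__(message)


@dataclass
class Visit:
    restaurant: int
    lap: int
    offer_delay: float
    outcome: str  # skip | quit | earn
    oz_enter: float
    oz_exit: float
    wz_enter: float | None = None
    wz_exit: float | None = None
    reward_time: float | None = None
    rz_exit: float | None = None

    @property
    def reaction_time(self) -> float:
        return self.oz_exit - self.oz_enter

    @property
    def quit_time(self) -> float | None:
        if self.outcome != "quit":
            return None
        return self.wz_exit - self.wz_enter

    @property
    def linger_time(self) -> float | None:
        if self.outcome != "earn":
            return None
        return self.rz_exit - self.reward_time

    @property
    def earned(self) -> bool:
        return self.outcome == "earn"

    @property
    def leave_time(self) -> float:
        if self.outcome == "skip":
            return self.oz_exit
        if self.outcome == "quit":
            return self.wz_exit
        return self.rz_exit


def parse_visits(events: pd.DataFrame) -> list[Visit]:
    """Parse an ordered event log into one :class:`Visit` per offer-zone entry.

    Raises :class:`EventLogError` on out-of-order or dangling zone events,
    naming the offending timestamp.
    """
    times = events["time_s"].to_numpy()
    if np.any(np.diff(times) < 0):
        bad = int(np.argmax(np.diff(times) < 0)) + 1
        raise EventLogError("event log not chronologically ordered", times[bad])

    visits: list[Visit] = []
    oz_rows = events.index[events["event"] == "oz_enter"]
    for k, start in enumerate(oz_rows):
        stop = oz_rows[k + 1] if k + 1 < len(oz_rows) else len(events)
        chunk = events.iloc[start:stop]
        row0 = chunk.iloc[0]
        t_of = {}
        for ev in ("oz_exit", "wz_enter", "wz_exit", "reward", "rz_exit"):
            sel = chunk.loc[chunk["event"] == ev, "time_s"]
            t_of[ev] = float(sel.iloc[0]) if len(sel) else None
        oz_enter = float(row0["time_s"])
        oz_exit = t_of["oz_exit"]
        if oz_exit is None:
            oz_exit = t_of["wz_enter"]
        if oz_exit is None:
            sel = chunk.loc[chunk["event"] == "tz_enter", "time_s"]
            oz_exit = float(sel.iloc[0]) if len(sel) else None
        if oz_exit is None:
            raise EventLogError("offer-zone entry without any exit event", oz_enter)

        if t_of["wz_enter"] is None:
            outcome = "skip"
            if t_of["wz_exit"] is not None or t_of["reward"] is not None:
                raise EventLogError("wait-zone event without wz_enter", oz_enter)
            visit = Visit(
                restaurant=int(row0["restaurant"]),
                lap=int(row0["lap"]),
                offer_delay=float(row0["offer_delay_s"]),
                outcome=outcome,
                oz_enter=oz_enter,
                oz_exit=oz_exit,
            )
        elif t_of["reward"] is not None:
            if t_of["rz_exit"] is None:
                raise EventLogError("reward without rz_exit", t_of["reward"])
            visit = Visit(
                restaurant=int(row0["restaurant"]),
                lap=int(row0["lap"]),
                offer_delay=float(row0["offer_delay_s"]),
                outcome="earn",
                oz_enter=oz_enter,
                oz_exit=oz_exit,
                wz_enter=t_of["wz_enter"],
                wz_exit=t_of["reward"],
                reward_time=t_of["reward"],
                rz_exit=t_of["rz_exit"],
            )
        else:
            if t_of["wz_exit"] is None:
                raise EventLogError("wait-zone entry without exit or reward", t_of["wz_enter"])
            visit = Visit(
                restaurant=int(row0["restaurant"]),
                lap=int(row0["lap"]),
                offer_delay=float(row0["offer_delay_s"]),
                outcome="quit",
                oz_enter=oz_enter,
                oz_exit=oz_exit,
                wz_enter=t_of["wz_enter"],
                wz_exit=t_of["wz_exit"],
            )
        ts = [visit.oz_enter, visit.oz_exit, visit.wz_enter, visit.wz_exit,
              visit.reward_time, visit.rz_exit]
        ts = [t for t in ts if t is not None]
        if any(b < a for a, b in zip(ts, ts[1:])):
            raise EventLogError("timestamps not monotone within visit", visit.oz_enter)
        visits.append(visit)
    return visits


def visits_frame(visits: list[Visit]) -> pd.DataFrame:
    """Tabular view of parsed visits (one row per visit)."""
    return pd.DataFrame(
        {
            "restaurant": [v.restaurant for v in visits],
            "lap": [v.lap for v in visits],
            "offer_delay_s": [v.offer_delay for v in visits],
            "outcome": [v.outcome for v in visits],
            "oz_enter_s": [v.oz_enter for v in visits],
            "oz_exit_s": [v.oz_exit for v in visits],
            "wz_enter_s": [v.wz_enter for v in visits],
            "wz_exit_s": [v.wz_exit for v in visits],
            "reward_s": [v.reward_time for v in visits],
            "rz_exit_s": [v.rz_exit for v in visits],
            "reaction_time_s": [v.reaction_time for v in visits],
            "quit_time_s": [v.quit_time for v in visits],
            "linger_time_s": [v.linger_time for v in visits],
        }
    )


@dataclass
class ThresholdFit:
    restaurant: int
    threshold: float
    sse: float
    n_visits: int
    n_earned: int


def fit_threshold(
    delays: np.ndarray,
    earned: np.ndarray,
    *,
    delay_range: tuple[float, float] = (1.0, 30.0),
    restaurant: int = -1,
) -> ThresholdFit:
    """Least-squares Heaviside fit of the earned indicator vs offer delay.

    Candidates are the half-integer grid from ``delay_min - 0.5`` to
    ``delay_max + 0.5``; each candidate ``c`` predicts earn for delays
    ``<= c`` (H(c - delay) with H(0) = 1).  When an interval of candidates
    ties at minimal SSE the midpoint of the tied delay interval is reported.
    All-earn and all-skip sessions map to ``delay_max + 0.5`` and
    ``delay_min - 0.5``.
    """
    delays = np.asarray(delays, dtype=float)
    earned = np.asarray(earned, dtype=float)
    if delays.size == 0:
        raise ValueError("cannot fit a threshold with no visits")
    n_earned = int(earned.sum())
    lo, hi = delay_range
    if n_earned == delays.size:
        threshold = hi + 0.5
        sse = 0.0
    elif n_earned == 0:
        threshold = lo - 0.5
        sse = 0.0
    else:
        grid = np.arange(lo - 0.5, hi + 0.5 + 1e-9, 0.5)
        pred = (delays[None, :] <= grid[:, None]).astype(float)
        sse_all = ((earned[None, :] - pred) ** 2).sum(axis=1)
        best = sse_all.min()
        tied = grid[sse_all == best]
        # candidate c covers the delay interval [c, c + 0.5): report the
        # midpoint of the union of tied intervals
        threshold = float((tied.min() + tied.max() + 0.5) / 2.0)
        sse = float(best)
    return ThresholdFit(
        restaurant=restaurant,
        threshold=float(threshold),
        sse=float(sse),
        n_visits=int(delays.size),
        n_earned=n_earned,
    )


def fit_thresholds(
    visits: list[Visit], *, delay_range: tuple[float, float] = (1.0, 30.0)
) -> list[ThresholdFit]:
    """One Heaviside fit per restaurant present in ``visits``."""
    frame = visits_frame(visits)
    fits = []
    for r, grp in frame.groupby("restaurant"):
        fits.append(
            fit_threshold(
                grp["offer_delay_s"].to_numpy(),
                (grp["outcome"] == "earn").to_numpy(),
                delay_range=delay_range,
                restaurant=int(r),
            )
        )
    return fits


def subjective_value(threshold: float, delay: float) -> float:
    """Signed distance of an offer from threshold: ``threshold - delay``."""
    return threshold - delay


def rank_restaurants(fits: list[ThresholdFit]) -> dict[int, int]:
    """Rank restaurants 1..n by descending threshold.

    Exact threshold ties are broken by the greater number of earned rewards;
    a residual tie falls back to restaurant id order with a logged warning.
    """
    order = sorted(fits, key=lambda f: (-f.threshold, -f.n_earned, f.restaurant))
    for a, b in zip(order, order[1:]):
        if a.threshold == b.threshold and a.n_earned == b.n_earned:
            logger.warning(
                "restaurants %d and %d tie in threshold and earn count; "
                "falling back to id order", a.restaurant, b.restaurant,
            )
    return {f.restaurant: rank + 1 for rank, f in enumerate(order)}


def threshold_consistency(
    session_thresholds: np.ndarray,
) -> tuple[float, float, np.ndarray]:
    """Threshold stability summaries across sessions of one subject.

    ``session_thresholds`` is (n_sessions, n_restaurants).  Returns the mean
    per-restaurant variance across sessions, the mean per-session variance
    across restaurants, and the session-by-session Pearson correlation matrix
    of threshold vectors (NaN where a vector is constant).
    """
    th = np.asarray(session_thresholds, dtype=float)
    if th.ndim != 2 or th.shape[0] < 2:
        raise ValueError("need at least two sessions of thresholds")
    var_across_sessions = float(th.var(axis=0, ddof=1).mean())
    var_across_restaurants = float(th.var(axis=1, ddof=1).mean())
    n = th.shape[0]
    corr = np.full((n, n), np.nan)
    sd = th.std(axis=1)
    for i in range(n):
        for j in range(n):
            if sd[i] > 0 and sd[j] > 0:
                corr[i, j] = float(np.corrcoef(th[i], th[j])[0, 1])
    return var_across_sessions, var_across_restaurants, corr


def linger_percentile_range(
    visits: list[Visit], lo: float = 1.0, hi: float = 99.0
) -> tuple[float, float]:
    """Session linger-time range clipped to the [lo, hi] percentiles."""
    lingers = np.array([v.linger_time for v in visits if v.outcome == "earn"])
    if lingers.size == 0:
        raise ValueError("no earned visits: linger range undefined")
    return (float(np.percentile(lingers, lo)), float(np.percentile(lingers, hi)))


def phase_intervals(
    visits: list[Visit], session_duration: float
) -> dict[str, list[tuple[float, float]]]:
    """Task-phase occupancy intervals; gaps between visits count as TZ."""
    out: dict[str, list[tuple[float, float]]] = {p: [] for p in ("OZ", "WZ", "RZ", "TZ")}
    cursor = 0.0
    for v in visits:
        if v.oz_enter > cursor:
            out["TZ"].append((cursor, v.oz_enter))
        out["OZ"].append((v.oz_enter, v.oz_exit))
        cursor = v.oz_exit
        if v.outcome != "skip":
            out["WZ"].append((v.wz_enter, v.wz_exit))
            cursor = v.wz_exit
        if v.outcome == "earn":
            out["RZ"].append((v.reward_time, v.rz_exit))
            cursor = v.rz_exit
    if cursor < session_duration:
        out["TZ"].append((cursor, session_duration))
    return out
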