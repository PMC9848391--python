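"""Population-level quantifications: firing/behavior correlations, stepwise
regressions, net choice preferences, subsampling and session-block controls,
and windowed firing-rate correlations to offer delay and linger time.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .behavior import Visit
from .spikes import (
    DEFAULT_N_SHUFFLES,
    DEFAULT_SHIFT_RANGE,
    SpikeTrain,
    circular_shift,
    peth_normalized,
)

logger = logging.getLogger(__name__)

#: window definitions in seconds relative to wait-zone entry (Pre/Early) or
#: exit (Late/Post)
WZ_WINDOWS: dict[str, tuple[str, float, float]] = {
    "PreWZ": ("enter", -1.0, 0.0),
    "EarlyWZ": ("enter", 0.0, 3.0),
    "LateWZ": ("exit", -3.0, 0.0),
    "PostWZ": ("exit", 0.0, 1.0),
}

#: window definitions in normalized-bin indices (26-bin layout: 3 pre,
#: 20 in-zone, 3 post)
RZ_WINDOWS: dict[str, tuple[int, int]] = {
    "PreRZ": (0, 3),
    "EarlyRZ": (3, 13),
    "LateRZ": (13, 23),
    "PostRZ": (23, 26),
}


def zone_mean_rates(
    train: SpikeTrain, intervals: Sequence[tuple[float, float]]
) -> np.ndarray:
    """Mean firing rate in each (start, end) interval; NaN for empty ones."""
    out = np.empty(len(intervals))
    for i, (a, b) in enumerate(intervals):
        if b <= a:
            out[i] = np.nan
            continue
        n = np.searchsorted(train.times, b) - np.searchsorted(train.times, a)
        out[i] = n / (b - a)
    return out


@dataclass
class RateCorrelation:
    r: float
    p: float
    null_rs: np.ndarray
    defined: bool


def rate_behavior_correlation(
    train: SpikeTrain,
    intervals: Sequence[tuple[float, float]],
    values: Sequence[float],
    *,
    n_shuffles: int = DEFAULT_N_SHUFFLES,
    shift_range: tuple[float, float] = DEFAULT_SHIFT_RANGE,
    rng: np.random.Generator | None = None,
) -> RateCorrelation:
    """Pearson correlation between per-visit zone mean rate and a behavioral
    variable, with a circular-shift null distribution of the same r."""
    rng = rng or np.random.default_rng(0)
    values = np.asarray(values, dtype=float)
    if len(intervals) < 3:
        raise ValueError("need at least 3 visits")
    rates = zone_mean_rates(train, intervals)
    ok = np.isfinite(rates) & np.isfinite(values)
    if ok.sum() < 3 or np.std(rates[ok]) == 0 or np.std(values[ok]) == 0:
        logger.info("zero-variance rate or variable: correlation undefined")
        return RateCorrelation(float("nan"), float("nan"), np.empty(0), False)
    r, p = sps.pearsonr(rates[ok], values[ok])
    null = []
    for _ in range(n_shuffles):
        sh = circular_shift(train, float(rng.uniform(*shift_range)))
        sr = zone_mean_rates(sh, intervals)
        if np.std(sr[ok]) == 0:
            null.append(0.0)
        else:
            null.append(float(sps.pearsonr(sr[ok], values[ok])[0]))
    return RateCorrelation(float(r), float(p), np.asarray(null), True)


# ---------------------------------------------------------------------------
# stepwise regressions
# ---------------------------------------------------------------------------

@dataclass
class RegressionStep:
    variable: str
    coef: float
    intercept: float
    var_explained: float     # variance removed from the residual at this step
    residual_var: float      # residual variance after the step
    p: float
    degenerate: bool = False


@dataclass
class RegressionLadder:
    cell_id: int
    ordering_mode: str       # fixed | per-cell
    steps: list[RegressionStep]

    @property
    def order(self) -> list[str]:
        return [s.variable for s in self.steps]


def _fit_step(residual: np.ndarray, v: np.ndarray, name: str) -> tuple[RegressionStep, np.ndarray]:
    before = float(residual.var())
    if np.std(v) == 0:
        logger.info("variable %s degenerate (constant); coefficient 0", name)
        step = RegressionStep(name, 0.0, float(residual.mean()), 0.0, before, 1.0, True)
        return step, residual
    res = sps.linregress(v, residual)
    fitted = res.intercept + res.slope * v
    new_resid = residual - fitted
    after = float(new_resid.var())
    step = RegressionStep(
        variable=name,
        coef=float(res.slope),
        intercept=float(res.intercept),
        var_explained=before - after,
        residual_var=after,
        p=float(res.pvalue),
    )
    return step, new_resid


def stepwise_fixed(
    rates: np.ndarray,
    variables: dict[str, np.ndarray],
    order: Sequence[str],
    *,
    cell_id: int = -1,
) -> RegressionLadder:
    """Sequential univariate fits in a predetermined variable order; each
    variable is fit to the residual rates left by the preceding ones."""
    if set(order) != set(variables):
        raise ValueError("order must cover the variable set exactly")
    residual = np.asarray(rates, dtype=float).copy()
    steps = []
    for name in order:
        step, residual = _fit_step(residual, np.asarray(variables[name], float), name)
        steps.append(step)
    return RegressionLadder(cell_id=cell_id, ordering_mode="fixed", steps=steps)


def stepwise_percell(
    rates: np.ndarray,
    variables: dict[str, np.ndarray],
    *,
    cell_id: int = -1,
) -> RegressionLadder:
    """Stepwise fit entering, at each step, the remaining variable that
    explains the most residual variance (ties broken by config order)."""
    residual = np.asarray(rates, dtype=float).copy()
    remaining = list(variables)
    steps = []
    while remaining:
        best_name, best_gain = remaining[0], -1.0
        for name in remaining:
            v = np.asarray(variables[name], float)
            if np.std(v) == 0 or np.std(residual) == 0:
                gain = 0.0
            else:
                r = sps.pearsonr(v, residual)[0]
                gain = float(r * r * residual.var())
            if gain > best_gain:
                best_name, best_gain = name, gain
        step, residual = _fit_step(residual, np.asarray(variables[best_name], float), best_name)
        steps.append(step)
        remaining.remove(best_name)
    return RegressionLadder(cell_id=cell_id, ordering_mode="per-cell", steps=steps)


# ---------------------------------------------------------------------------
# net choice preference
# ---------------------------------------------------------------------------

@dataclass
class NetChoiceRate:
    net_rate: float          # mean rate (positive class) - mean rate (negative class)
    preference: str
    n_pos: int
    n_neg: int


def net_choice_rate(
    rates: Sequence[float],
    choices: Sequence[str],
    *,
    positive: str = "skip",
    negative: str = "accept",
) -> NetChoiceRate:
    """Net epoch firing rate between the two choice categories
    (e.g. skip - accept, or quit - earn)."""
    rates = np.asarray(rates, dtype=float)
    choices = np.asarray(choices)
    pos = rates[(choices == positive) & np.isfinite(rates)]
    neg = rates[(choices == negative) & np.isfinite(rates)]
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both choice categories must be present")
    net = float(pos.mean() - neg.mean())
    return NetChoiceRate(
        net_rate=net,
        preference=positive if net > 0 else negative,
        n_pos=int(pos.size),
        n_neg=int(neg.size),
    )


def proportion_test(n_preferring: int, n_cells: int) -> tuple[float, float]:
    """Chi-square test of a cell-preference proportion against 50%."""
    if n_cells < 1:
        raise ValueError("need at least one cell")
    chi2, p = sps.chisquare([n_preferring, n_cells - n_preferring])
    return float(chi2), float(p)


def signed_rank_timecourse(
    values: np.ndarray,
    *,
    alpha: float = 0.05,
    bonferroni: bool = True,
    alternative: str = "greater",
) -> tuple[np.ndarray, np.ndarray]:
    """Per-bin one-sample Wilcoxon signed-rank of (cells x bins) values
    against 0, Bonferroni-corrected across bins.

    Returns (significant flags, p-values); bins with fewer than 5 defined
    cells or all-zero values are NaN/False.
    """
    values = np.asarray(values, dtype=float)
    n_bins = values.shape[1]
    pvals = np.full(n_bins, np.nan)
    for j in range(n_bins):
        col = values[:, j]
        col = col[np.isfinite(col)]
        if col.size < 5 or np.all(col == 0):
            continue
        pvals[j] = float(sps.wilcoxon(col, alternative=alternative).pvalue)
    thresh = alpha / n_bins if bonferroni else alpha
    sig = np.where(np.isfinite(pvals), pvals < thresh, False).astype(bool)
    return sig, pvals


# ---------------------------------------------------------------------------
# subsampling and session blocks
# ---------------------------------------------------------------------------

def subsample_match(
    population: Sequence,
    analysis: Callable[[list], object],
    *,
    target_n: int = 72,
    n_iter: int = 500,
    replace: bool = False,
    rng: np.random.Generator | None = None,
) -> list:
    """Repeat ``analysis`` on random subsets of ``population``.

    ``target_n == len(population)`` short-circuits to the full population in
    its original order, so the identity case reproduces the unsubsampled
    result exactly.  Populations smaller than ``target_n`` require
    ``replace=True`` (flagged) or raise.
    """
    rng = rng or np.random.default_rng(0)
    pop = list(population)
    if target_n > len(pop) and not replace:
        raise ValueError(
            f"target_n={target_n} exceeds population of {len(pop)} without replacement"
        )
    if target_n > len(pop):
        logger.warning("sampling %d from %d with replacement", target_n, len(pop))
    out = []
    for _ in range(n_iter):
        if target_n == len(pop) and not replace:
            chosen = pop
        else:
            idx = rng.choice(len(pop), size=target_n, replace=replace)
            chosen = [pop[i] for i in idx]
        out.append(analysis(chosen))
    return out


def session_blocks(session_duration: float, n_blocks: int) -> list[tuple[float, float]]:
    """Contiguous equal-duration session blocks; only 3 or 5 are supported
    (20 min and 12 min blocks of the 1 h session respectively)."""
    if n_blocks not in (3, 5):
        raise ValueError("n_blocks must be 3 or 5")
    width = session_duration / n_blocks
    return [(k * width, (k + 1) * width) for k in range(n_blocks)]


def restrict_visits(visits: list[Visit], block: tuple[float, float]) -> list[Visit]:
    """Visits whose offer-zone entry falls inside the block."""
    a, b = block
    return [v for v in visits if a <= v.oz_enter < b]


def block_rates(
    train: SpikeTrain, blocks: Sequence[tuple[float, float]]
) -> np.ndarray:
    """Mean firing rate of one cell in each session block."""
    return zone_mean_rates(train, list(blocks))


# ---------------------------------------------------------------------------
# windowed firing-rate correlations
# ---------------------------------------------------------------------------

def _window_interval(visit: Visit, spec: tuple[str, float, float]) -> tuple[float, float]:
    anchor, lo, hi = spec
    t0 = visit.wz_enter if anchor == "enter" else visit.wz_exit
    return (t0 + lo, t0 + hi)


def delay_window_rates(
    trains: Sequence[SpikeTrain],
    visits: list[Visit],
    *,
    n_delay_bins: int = 6,
    delay_range: tuple[float, float] = (1.0, 30.0),
    windows: dict[str, tuple[str, float, float]] | None = None,
) -> pd.DataFrame:
    """Per delay-bin, per window mean firing rate for one subject.

    Accepted visits are grouped into ``n_delay_bins`` uniform offer-delay
    bins; rates are averaged over cells and visits within each bin.  Returns
    a long frame with columns ``window, delay_bin, bin_center, rate``.
    """
    windows = windows or WZ_WINDOWS
    accepted = [v for v in visits if v.outcome in ("quit", "earn")]
    if not accepted:
        raise ValueError("no accepted visits")
    lo, hi = delay_range
    width = (hi - lo) / n_delay_bins
    delays = np.array([v.offer_delay for v in accepted])
    bins = np.minimum(((delays - lo) // width).astype(int), n_delay_bins - 1)
    rows = []
    for name, spec in windows.items():
        intervals = [_window_interval(v, spec) for v in accepted]
        per_cell = np.vstack([zone_mean_rates(tr, intervals) for tr in trains])
        with np.errstate(invalid="ignore"):
            per_visit = np.nanmean(per_cell, axis=0)
        for b in range(n_delay_bins):
            sel = per_visit[bins == b]
            sel = sel[np.isfinite(sel)]
            if sel.size == 0:
                continue
            rows.append((name, b, lo + (b + 0.5) * width, float(sel.mean())))
    return pd.DataFrame(rows, columns=["window", "delay_bin", "bin_center", "rate"])


def linger_window_rates(
    trains: Sequence[SpikeTrain],
    visits: list[Visit],
    *,
    n_bins: int = 6,
    max_fraction: float = 0.30,
    windows: dict[str, tuple[int, int]] | None = None,
) -> pd.DataFrame:
    """Per linger-time-bin, per window mean normalized-PETH rate for one
    subject.

    Linger times are expressed as the fraction of the session's 1st-99th
    percentile range; visits up to ``max_fraction`` are kept and split into
    ``n_bins`` equal fraction bins.  Windows index the 26-bin normalized
    reward-zone layout.
    """
    windows = windows or RZ_WINDOWS
    earns = [v for v in visits if v.outcome == "earn"]
    if len(earns) < 2:
        raise ValueError("need at least 2 earned visits")
    lingers = np.array([v.linger_time for v in earns])
    lo = np.percentile(lingers, 1.0)
    hi = np.percentile(lingers, 99.0)
    if hi <= lo:
        raise ValueError("degenerate linger-time range")
    frac = (lingers - lo) / (hi - lo)
    keep = np.flatnonzero((frac >= 0) & (frac <= max_fraction))
    if keep.size == 0:
        raise ValueError("no visits within the linger fraction range")
    width = max_fraction / n_bins
    bins = np.minimum((frac[keep] // width).astype(int), n_bins - 1)

    rows = []
    for b in range(n_bins):
        sel = keep[bins == b]
        if sel.size == 0:
            continue
        zone = [(earns[i].reward_time, earns[i].rz_exit) for i in sel]
        pre = [earns[i].wz_exit - earns[i].wz_enter for i in sel]
        post = [10.0 for _ in sel]  # context after leaving; duration is nominal
        means = []
        for tr in trains:
            p = peth_normalized(tr, zone, pre_durations=pre, post_durations=post)
            means.append(p.mean)
        mean_peth = np.nanmean(np.vstack(means), axis=0)
        for name, (a, z) in windows.items():
            val = np.nanmean(mean_peth[a:z])
            rows.append((name, b, (b + 0.5) * width, float(val)))
    return pd.DataFrame(rows, columns=["window", "linger_bin", "bin_center", "rate"])


def windowed_rate_correlation(
    frames: Sequence[pd.DataFrame],
) -> dict[str, tuple[float, float, int]]:
    """Pearson correlation of window-mean rates vs behavioral bin centers,
    pooled across subjects (up to n_rats x n_bins points per window).

    Returns ``window -> (r, p, n_points)``; windows with fewer than 3
    defined points are reported as NaN.
    """
    pooled = pd.concat(frames, ignore_index=True)
    out: dict[str, tuple[float, float, int]] = {}
    for name, grp in pooled.groupby("window"):
        x = grp["bin_center"].to_numpy(dtype=float)
        y = grp["rate"].to_numpy(dtype=float)
        ok = np.isfinite(x) & np.isfinite(y)
        if ok.sum() < 3 or np.std(x[ok]) == 0 or np.std(y[ok]) == 0:
            out[name] = (float("nan"), float("nan"), int(ok.sum()))
            continue
        r, p = sps.pearsonr(x[ok], y[ok])
        out[name] = (float(r), float(p), int(ok.sum()))
    return out
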