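"""Standardized 3D localization of cells from probe geometry and turn logs.

Channel 0 is the ventral tip contact; deeper turning moves the whole probe
ventrally, so a cell's depth along the trajectory is the session's tip depth
minus the cell channel's distance from the tip.  Standardized coordinates
are obtained by linear interpolation between the trajectory's entry and tip
points.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)


@dataclass
class ProbeRecord:
    probe_id: int
    entry_point: tuple[float, float, float]  # standardized coordinates
    tip_point: tuple[float, float, float]
    turn_depths: tuple[float, ...]       # per-session cumulative tip depth, um
    trajectory_length_um: float = 3000.0  # real-space entry->tip length
    n_channels: int = 64
    channel_spacing: float = 20.0        # um
    shrinkage_factor: float | None = None  # histology-only; unused for synthetic data

    def __post_init__(self) -> None:
        if any(b < a for a, b in zip(self.turn_depths, self.turn_depths[1:])):
            raise ValueError("turn depths must be nondecreasing (probes only move ventrally)")
        if self.turn_depths and self.turn_depths[-1] > self.trajectory_length_um + 1e-9:
            raise ValueError("tip depth exceeds trajectory length")


@dataclass
class CellLocation:
    cell_id: int
    channel_index: int
    distance_from_tip: float
    depth_along_trajectory: float
    xyz: tuple[float, float, float]
    dv_um: float
    valid: bool = True


def peak_channel(amplitudes: np.ndarray) -> int:
    """Channel with the maximal waveform amplitude (putative cell body).

    Ties are resolved toward the deeper channel (higher index) with a log
    note; an all-zero profile is an error.
    """
    amp = np.asarray(amplitudes, dtype=float)
    if np.all(amp == 0):
        raise ValueError("all-zero amplitude profile")
    best = amp.max()
    ties = np.flatnonzero(amp == best)
    if ties.size > 1:
        logger.warning("amplitude tie across channels %s; taking deepest", ties.tolist())
    return int(ties[-1])


def locate_cell(
    cell_id: int,
    channel_index: int,
    probe: ProbeRecord,
    session: int,
) -> CellLocation:
    """Standardized location of a cell from its peak channel and the probe's
    turn log for ``session``."""
    if not (0 <= channel_index < probe.n_channels):
        raise ValueError(f"channel {channel_index} outside probe")
    if not (0 <= session < len(probe.turn_depths)):
        raise ValueError(f"no turn-log entry for session {session}")
    distance_from_tip = channel_index * probe.channel_spacing
    depth = probe.turn_depths[session] - distance_from_tip
    valid = depth >= 0
    if not valid:
        logger.warning("cell %d computed above the brain surface (depth %.1f um)", cell_id, depth)
    length = probe.trajectory_length_um
    frac = depth / length if length > 0 else 0.0
    e = np.asarray(probe.entry_point, dtype=float)
    t = np.asarray(probe.tip_point, dtype=float)
    xyz = e + frac * (t - e)
    return CellLocation(
        cell_id=cell_id,
        channel_index=channel_index,
        distance_from_tip=distance_from_tip,
        depth_along_trajectory=float(depth),
        xyz=tuple(float(v) for v in xyz),
        dv_um=float(depth),
        valid=bool(valid),
    )
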