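"""Session bundles on disk and seeded end-to-end orchestration.

A bundle directory holds ``config.json``, ``events.csv``, ``spikes.csv``,
``cells.csv``, an optional ``probes.json``, and a ``manifest.json`` with the
schema version and seeds.  All tables are plain UTF-8 CSV with a header row,
times in seconds, depths in micrometers.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .behavior import (
    fit_thresholds,
    parse_visits,
    phase_intervals,
    rank_restaurants,
    visits_frame,
)
from .information import mi_scalar
from .infoflow import (
    assign_subregions,
    diagonal_profile,
    find_boundaries,
    region_te_stats,
    te_matrix,
    te_spatial_map,
)
from .localization import ProbeRecord, locate_cell
from .spikes import SpikeTrain, basic_properties, classify_cell
from .synthetic import SessionConfig, simulate_ensemble, simulate_session

logger = logging.getLogger(__name__)

SCHEMA_VERSION = 1


class BundleError(ValueError):
    """Raised when a session bundle fails validation at load time."""


@dataclass
class SessionBundle:
    events: pd.DataFrame
    trains: list[SpikeTrain]
    cells: pd.DataFrame
    config: dict
    probes: list[ProbeRecord] | None = None

    @property
    def session_duration(self) -> float:
        return float(self.config["session_duration"])


def write_bundle(
    path: str | Path,
    events: pd.DataFrame,
    trains: list[SpikeTrain],
    cells: pd.DataFrame,
    config: dict,
    *,
    probes: list[ProbeRecord] | None = None,
) -> Path:
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    events.to_csv(path / "events.csv", index=False)
    spikes = pd.DataFrame(
        {
            "cell_id": np.concatenate(
                [np.full(len(tr), tr.cell_id, dtype=int) for tr in trains]
            )
            if trains
            else np.empty(0, dtype=int),
            "time_s": np.concatenate([tr.times for tr in trains])
            if trains
            else np.empty(0),
        }
    )
    spikes.to_csv(path / "spikes.csv", index=False)
    cols = ["cell_id", "probe_id", "channel", "dv_um", "spike_width_us"]
    cells[cols].to_csv(path / "cells.csv", index=False)
    with open(path / "config.json", "w") as fh:
        json.dump(config, fh, indent=2, sort_keys=True)
    if probes is not None:
        with open(path / "probes.json", "w") as fh:
            json.dump([dataclasses.asdict(p) for p in probes], fh, indent=2, sort_keys=True)
    manifest = {
        "schema_version": SCHEMA_VERSION,
        "package_version": __version__,
        "seed": config.get("seed"),
        "files": sorted(p.name for p in path.iterdir() if p.name != "manifest.json"),
    }
    with open(path / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return path


def read_bundle(path: str | Path, *, require_probes: bool = False) -> SessionBundle:
    """Load and validate a session bundle."""
    path = Path(path)
    mpath = path / "manifest.json"
    if not mpath.exists():
        raise BundleError(f"missing manifest.json in {path}")
    manifest = json.loads(mpath.read_text())
    if manifest.get("schema_version") != SCHEMA_VERSION:
        raise BundleError(
            f"schema version {manifest.get('schema_version')!r} != {SCHEMA_VERSION}"
        )
    config = json.loads((path / "config.json").read_text())
    duration = float(config["session_duration"])
    events = pd.read_csv(path / "events.csv")
    cells = pd.read_csv(path / "cells.csv")
    spikes = pd.read_csv(path / "spikes.csv")

    known = set(cells["cell_id"].tolist())
    orphan = ~spikes["cell_id"].isin(known)
    if orphan.any():
        row = int(np.flatnonzero(orphan.to_numpy())[0])
        raise BundleError(f"spikes.csv row {row}: unknown cell_id {spikes['cell_id'].iloc[row]}")
    bad = (spikes["time_s"] < 0) | (spikes["time_s"] > duration)
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise BundleError(f"spikes.csv row {row}: time {spikes['time_s'].iloc[row]} out of range")

    trains = []
    for cid, grp in spikes.groupby("cell_id", sort=True):
        t = grp["time_s"].to_numpy()
        if np.any(np.diff(t) < 0):
            raise BundleError(f"unsorted spike times for cell {cid}")
        trains.append(SpikeTrain(cell_id=int(cid), times=t, duration=duration))
    present = {tr.cell_id for tr in trains}
    for cid in sorted(known - present):
        trains.append(
            SpikeTrain(cell_id=int(cid), times=np.empty(0), duration=duration)
        )
    trains.sort(key=lambda tr: tr.cell_id)

    probes = None
    ppath = path / "probes.json"
    if ppath.exists():
        probes = [
            ProbeRecord(
                probe_id=int(rec["probe_id"]),
                entry_point=tuple(rec["entry_point"]),
                tip_point=tuple(rec["tip_point"]),
                turn_depths=tuple(rec["turn_depths"]),
                trajectory_length_um=float(rec.get("trajectory_length_um", 3000.0)),
                n_channels=int(rec.get("n_channels", 64)),
                channel_spacing=float(rec.get("channel_spacing", 20.0)),
                shrinkage_factor=rec.get("shrinkage_factor"),
            )
            for rec in json.loads(ppath.read_text())
        ]
    elif require_probes:
        raise BundleError("probes.json required for localization but missing")
    return SessionBundle(events=events, trains=trains, cells=cells, config=config, probes=probes)


def simulate_bundle(
    path: str | Path,
    session_config: SessionConfig,
    ensemble_config,
    *,
    probes: list[ProbeRecord] | None = None,
) -> Path:
    """Simulate a session + ensemble and write them as a bundle."""
    events = simulate_session(session_config)
    trains, cells = simulate_ensemble(events, ensemble_config)
    config = dataclasses.asdict(session_config)
    config["ensemble"] = dataclasses.asdict(ensemble_config)
    return write_bundle(path, events, trains, cells, config, probes=probes)


# ---------------------------------------------------------------------------
# pipeline orchestration
# ---------------------------------------------------------------------------

DEFAULT_SELECTION = ("behavior", "spikes", "mi", "infoflow")

MI_VARIABLES = ("oz_choice", "offer_delay", "session_time", "restaurant")


@dataclass
class RunConfig:
    selection: tuple[str, ...] = DEFAULT_SELECTION
    seed: int = 0
    n_shuffles: int = 30
    te_bin: float = 0.010
    map_resolution: float = 100.0
    diagonal_window: float = 200.0
    mi_variables: tuple[str, ...] = MI_VARIABLES
    phase: str | None = None  # restrict TE to one task phase (OZ/WZ/RZ/TZ)

    def params_hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _stage_rngs(seed: int) -> dict[str, np.random.Generator]:
    ss = np.random.SeedSequence(seed)
    names = ("mi", "infoflow")
    return {n: np.random.default_rng(s) for n, s in zip(names, ss.spawn(len(names)))}


def run_pipeline(
    bundle_path: str | Path,
    out_path: str | Path,
    config: RunConfig | None = None,
) -> Path:
    """Run the selected stages on a bundle and write a report directory.

    Stage failures retain partial outputs and are recorded in the run
    manifest.  Outputs are deterministic for a fixed bundle and seed.
    """
    config = config or RunConfig()
    bundle = read_bundle(bundle_path)
    out = Path(out_path)
    out.mkdir(parents=True, exist_ok=True)
    rngs = _stage_rngs(config.seed)
    summary: dict = {"seed": config.seed, "params_hash": config.params_hash(),
                     "bundle": Path(bundle_path).name}
    failures: dict[str, str] = {}

    visits = None
    if "behavior" in config.selection:
        try:
            visits = parse_visits(bundle.events)
            vf = visits_frame(visits)
            vf.to_csv(out / "visits.csv", index=False)
            fits = fit_thresholds(visits, delay_range=tuple(bundle.config["delay_range"]))
            pd.DataFrame(
                {
                    "restaurant": [f.restaurant for f in fits],
                    "threshold_s": [f.threshold for f in fits],
                    "sse": [f.sse for f in fits],
                    "n_visits": [f.n_visits for f in fits],
                    "n_earned": [f.n_earned for f in fits],
                }
            ).to_csv(out / "thresholds.csv", index=False)
            ranks = rank_restaurants(fits)
            summary["thresholds"] = {str(f.restaurant): f.threshold for f in fits}
            summary["reward_ranks"] = {str(r): k for r, k in sorted(ranks.items())}
        except Exception as exc:  # noqa: BLE001 - stage isolation by design
            failures["behavior"] = str(exc)

    if "spikes" in config.selection:
        try:
            widths = dict(zip(bundle.cells["cell_id"], bundle.cells["spike_width_us"]))
            rows = []
            for tr in bundle.trains:
                props = basic_properties(tr, widths.get(tr.cell_id, float("nan")))
                rows.append(
                    {
                        "cell_id": props.cell_id,
                        "mean_rate_hz": props.mean_rate,
                        "cv": props.cv,
                        "median_isi_s": props.median_isi,
                        "isi_sd_s": props.isi_sd,
                        "burst_ratio": props.burst_ratio,
                        "spike_width_us": props.spike_width,
                        "cell_class": classify_cell(props.mean_rate, props.spike_width),
                    }
                )
            pd.DataFrame(rows).to_csv(out / "properties.csv", index=False)
        except Exception as exc:  # noqa: BLE001
            failures["spikes"] = str(exc)

    if "mi" in config.selection and visits is not None:
        try:
            rng = rngs["mi"]
            fits = fit_thresholds(visits, delay_range=tuple(bundle.config["delay_range"]))
            ranks = rank_restaurants(fits)
            oz = [(v.oz_enter, v.oz_exit) for v in visits]
            var_values = {
                "oz_choice": (["skip" if v.outcome == "skip" else "accept" for v in visits], True),
                "offer_delay": ([v.offer_delay for v in visits], False),
                "session_time": ([v.oz_enter for v in visits], False),
                "restaurant": ([v.restaurant for v in visits], True),
                "reward_rank": ([ranks[v.restaurant] for v in visits], True),
            }
            rows = []
            for name in config.mi_variables:
                values, categorical = var_values[name]
                for tr in bundle.trains:
                    res = mi_scalar(
                        tr, oz, values,
                        variable=name, categorical=categorical,
                        n_shuffles=config.n_shuffles, rng=rng,
                    )
                    rows.append(
                        {
                            "cell_id": tr.cell_id,
                            "variable": name,
                            "condition": "",
                            "bin": "",
                            "raw_bits": float(res.raw),
                            "null_mean_bits": float(res.null_mean),
                            "normalized_bits": float(res.normalized),
                        }
                    )
            mi_frame = pd.DataFrame(rows)
            mi_frame.to_csv(out / "mi.csv", index=False)
            summary["mi_mean_normalized_bits"] = {
                name: float(grp["normalized_bits"].mean())
                for name, grp in mi_frame.groupby("variable")
            }
        except Exception as exc:  # noqa: BLE001
            failures["mi"] = str(exc)

    if "infoflow" in config.selection:
        try:
            rng = rngs["infoflow"]
            mask = None
            if config.phase is not None:
                from .infoflow import intervals_to_mask

                pv = visits if visits is not None else parse_visits(bundle.events)
                iv = phase_intervals(pv, bundle.session_duration)
                mask = intervals_to_mask(iv[config.phase], bundle.session_duration,
                                         config.te_bin)
            res = te_matrix(
                bundle.trains,
                bin_width=config.te_bin,
                n_shuffles=config.n_shuffles,
                rng=rng,
                mask=mask,
                phase=config.phase,
            )
            pairs = res.pairs_frame()
            pairs.to_csv(out / "te_pairs.csv", index=False)
            depths = pd.Series(
                bundle.cells["dv_um"].to_numpy(), index=bundle.cells["cell_id"]
            )
            temap = te_spatial_map(pairs, depths, resolution=config.map_resolution)
            map_frame = pd.DataFrame(
                {
                    "input_bin": np.repeat(np.arange(temap.values.shape[0]), temap.values.shape[1]),
                    "recipient_bin": np.tile(np.arange(temap.values.shape[1]), temap.values.shape[0]),
                    "mean_norm_te": temap.values.ravel(),
                    "count": temap.counts.ravel(),
                }
            )
            map_frame.to_csv(out / "te_map.csv", index=False)
            profile = diagonal_profile(temap, window=config.diagonal_window)
            pd.DataFrame({"dv_um": profile.depths, "mean_norm_te": profile.values}).to_csv(
                out / "profile.csv", index=False
            )
            bounds = find_boundaries(profile)
            labels = assign_subregions(depths, bounds)
            stats = region_te_stats(pairs, labels, bounds.labels)
            with open(out / "bounds.json", "w") as fh:
                json.dump(
                    {
                        "boundary_depths_um": bounds.boundary_depths.tolist(),
                        "labels": bounds.labels,
                        "single_region": bounds.single_region,
                    },
                    fh, indent=2, sort_keys=True,
                )
            summary["boundary_depths_um"] = bounds.boundary_depths.tolist()
            summary["region_labels"] = bounds.labels
            summary["region_cell_counts"] = {
                lab: int((labels == lab).sum()) for lab in bounds.labels
            }
            summary["te_step_means"] = {str(k): v for k, v in stats.step_means.items()}
            summary["te_intra_vs_inter_p"] = stats.intra_vs_inter_p
        except Exception as exc:  # noqa: BLE001
            failures["infoflow"] = str(exc)

    if "locate" in config.selection:
        try:
            bundle_p = read_bundle(bundle_path, require_probes=True)
            probe_by_id = {p.probe_id: p for p in bundle_p.probes}
            rows = []
            for rec in bundle_p.cells.itertuples(index=False):
                loc = locate_cell(
                    int(rec.cell_id), int(rec.channel), probe_by_id[int(rec.probe_id)], 0
                )
                rows.append(
                    {
                        "cell_id": loc.cell_id,
                        "channel": loc.channel_index,
                        "distance_from_tip_um": loc.distance_from_tip,
                        "dv_um": loc.dv_um,
                        "x": loc.xyz[0],
                        "y": loc.xyz[1],
                        "z": loc.xyz[2],
                        "valid": loc.valid,
                    }
                )
            pd.DataFrame(rows).to_csv(out / "locations.csv", index=False)
        except Exception as exc:  # noqa: BLE001
            failures["locate"] = str(exc)

    manifest = {
        "schema_version": SCHEMA_VERSION,
        "package_version": __version__,
        "seed": config.seed,
        "params_hash": config.params_hash(),
        "selection": list(config.selection),
        "failures": failures,
    }
    with open(out / "run_manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    return out
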