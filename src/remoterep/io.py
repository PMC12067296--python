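"""HDF5 session bundles.

One file per session with groups /position, /spikes/tetrodeNN, /units, /lfp,
/events (nosepokes and detections, written by the pipeline), /decode (optional
posterior cache) and /ground_truth (synthetic sidecar; analysis stages load
bundles with the guard enabled, which refuses to expose this group).
"""

from __future__ import annotations

import dataclasses
import json

import h5py
import numpy as np

from .synthetic import (
    GroundTruth,
    LFPTrace,
    MarkedSpikes,
    PlaceCellSet,
    PositionTrace,
    Session,
    SyntheticSessionConfig,
    EventSpec,
)
from .track import build_track

__all__ = ["save_session", "load_session", "validate_bundle", "SCHEMA_CHECKS"]

SCHEMA_CHECKS = (
    "readable",
    "required_groups",
    "position_timestamps_monotone",
    "spike_times_sorted",
    "marks_finite",
    "lfp_present",
    "phase_boundaries_valid",
    "decode_normalized",
)


def save_session(session: Session, path) -> None:
    cfg = dataclasses.asdict(session.config)
    cfg["injected_events"] = None  # realized events live in ground truth
    with h5py.File(path, "w") as f:
        f.attrs["config_json"] = json.dumps(cfg, sort_keys=True)
        f.attrs["target_arm"] = session.target_arm
        f.attrs["session_type"] = session.session_type
        f.attrs["exploration_end"] = session.exploration_end
        f.attrs["feedback_end"] = session.feedback_end

        g = f.create_group("geometry")
        g.attrs["arm_length"] = session.geometry.arm_length
        g.attrs["box_extent"] = session.geometry.box_extent
        g.attrs["bin_size"] = session.geometry.bin_size

        p = f.create_group("position")
        tr = session.trace
        for name in ("t", "xy", "head_direction", "linear", "segment",
                     "head_speed", "offtrack"):
            p.create_dataset(name, data=getattr(tr, name))

        sp = f.create_group("spikes")
        for tet in sorted(session.spikes.times):
            gt_ = sp.create_group(f"tetrode{tet:02d}")
            gt_.create_dataset("times", data=session.spikes.times[tet])
            gt_.create_dataset("marks", data=session.spikes.marks[tet])

        u = f.create_group("units")
        for k, st in enumerate(session.unit_spike_times):
            u.create_dataset(f"unit{k:03d}", data=st)

        lf = f.create_group("lfp")
        lf.attrs["t0"] = session.lfp.t0
        lf.attrs["fs"] = session.lfp.fs
        lf.create_dataset("samples", data=session.lfp.samples.astype(np.float32))

        f.create_group("events")

        if session._ground_truth is not None:
            gt = session._ground_truth
            gg = f.create_group("ground_truth")
            cells = gg.create_group("cells")
            cells.create_dataset("centers_lin", data=gt.cells.centers_lin)
            cells.create_dataset("centers_seg", data=gt.cells.centers_seg)
            cells.create_dataset("tetrode_of_cell", data=gt.cells.tetrode_of_cell)
            cells.create_dataset("mark_means", data=gt.cells.mark_means)
            cells.attrs["sigma"] = gt.cells.sigma
            cells.attrs["peak_rate"] = gt.cells.peak_rate
            cells.attrs["baseline_rate"] = gt.cells.baseline_rate
            ids = gg.create_group("spike_cell_ids")
            for tet, arr in gt.spike_cell_ids.items():
                ids.create_dataset(f"tetrode{tet:02d}", data=arr)
            ev = gg.create_group("events")
            ev.attrs["specs_json"] = json.dumps(
                [dataclasses.asdict(e) for e in gt.events], sort_keys=True
            )
            gg.create_dataset("ripple_intervals", data=gt.ripple_intervals)


def load_session(path, guard_ground_truth: bool = False) -> Session:
    """Load a session bundle; with ``guard_ground_truth`` the returned object
    refuses to expose the /ground_truth sidecar (used by analysis stages)."""
    with h5py.File(path, "r") as f:
        cfg = json.loads(f.attrs["config_json"])
        cfg["injected_events"] = None
        cfg["swr_times"] = tuple(cfg["swr_times"]) if cfg["swr_times"] else None
        cfg["poke_latency"] = tuple(cfg["poke_latency"])
        config = SyntheticSessionConfig(**cfg)
        geometry = build_track(
            f["geometry"].attrs["arm_length"],
            f["geometry"].attrs["box_extent"],
            f["geometry"].attrs["bin_size"],
        )
        p = f["position"]
        trace = PositionTrace(
            t=p["t"][:], xy=p["xy"][:], head_direction=p["head_direction"][:],
            linear=p["linear"][:], segment=p["segment"][:],
            head_speed=p["head_speed"][:], offtrack=p["offtrack"][:].astype(bool),
        )
        times, marks = {}, {}
        for name in f["spikes"]:
            tet = int(name.replace("tetrode", ""))
            times[tet] = f["spikes"][name]["times"][:]
            marks[tet] = f["spikes"][name]["marks"][:]
        units = [f["units"][k][:] for k in sorted(f["units"])]
        lfp = LFPTrace(
            t0=float(f["lfp"].attrs["t0"]),
            fs=float(f["lfp"].attrs["fs"]),
            samples=f["lfp"]["samples"][:].astype(float),
        )
        gt = None
        if "ground_truth" in f and not guard_ground_truth:
            gg = f["ground_truth"]
            cells = PlaceCellSet(
                centers_lin=gg["cells"]["centers_lin"][:],
                centers_seg=gg["cells"]["centers_seg"][:],
                sigma=float(gg["cells"].attrs["sigma"]),
                peak_rate=float(gg["cells"].attrs["peak_rate"]),
                baseline_rate=float(gg["cells"].attrs["baseline_rate"]),
                tetrode_of_cell=gg["cells"]["tetrode_of_cell"][:],
                mark_means=gg["cells"]["mark_means"][:],
            )
            ids = {
                int(name.replace("tetrode", "")): gg["spike_cell_ids"][name][:]
                for name in gg["spike_cell_ids"]
            }
            events = [
                EventSpec(**d)
                for d in json.loads(gg["events"].attrs["specs_json"])
            ]
            gt = GroundTruth(
                cells=cells,
                spike_cell_ids=ids,
                events=events,
                ripple_intervals=gg["ripple_intervals"][:],
            )
        return Session(
            config=config,
            geometry=geometry,
            trace=trace,
            spikes=MarkedSpikes(times=times, marks=marks),
            unit_spike_times=units,
            lfp=lfp,
            exploration_end=float(f.attrs["exploration_end"]),
            feedback_end=float(f.attrs["feedback_end"]),
            target_arm=str(f.attrs["target_arm"]),
            session_type=str(f.attrs["session_type"]),
            _ground_truth=gt,
            _guard=guard_ground_truth,
        )


def validate_bundle(path) -> dict:
    """Schema and sanity checks on a session bundle; pass/fail per check."""
    report = {name: False for name in SCHEMA_CHECKS}
    try:
        f = h5py.File(path, "r")
    except OSError as err:
        raise IOError(f"unreadable bundle {path}: {err}") from err
    with f:
        report["readable"] = True
        report["required_groups"] = all(
            g in f for g in ("position", "spikes", "units", "lfp", "events")
        )
        t = f["position"]["t"][:]
        report["position_timestamps_monotone"] = bool(np.all(np.diff(t) > 0))
        sorted_ok, finite_ok = True, True
        for name in f["spikes"]:
            st = f["spikes"][name]["times"][:]
            if np.any(np.diff(st) < 0):
                sorted_ok = False
            if not np.all(np.isfinite(f["spikes"][name]["marks"][:])):
                finite_ok = False
        report["spike_times_sorted"] = sorted_ok
        report["marks_finite"] = finite_ok
        report["lfp_present"] = "samples" in f.get("lfp", {})
        report["phase_boundaries_valid"] = bool(
            0 < f.attrs["exploration_end"] <= f.attrs["feedback_end"]
        )
        if "decode" in f:
            post = f["decode"]["posterior"][:]
            inf = f["decode"]["informative"][:].astype(bool)
            sums = post[inf].sum(axis=1)
            report["decode_normalized"] = bool(
                np.allclose(sums, 1.0, atol=1e-5)
            )
        else:
            report["decode_normalized"] = True
    return report
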