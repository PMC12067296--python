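"""End-to-end pipeline: synthesize -> decode -> detect -> classify ->
prevalence -> assemblies -> brain state, as a reproducible seeded run.

Each stage reads only upstream outputs. Sessions are re-loaded from their
HDF5 bundle with the ground-truth guard enabled before any analysis runs, so
a stage that tried to read the synthetic sidecar would raise. The target arm
is held for nine sessions (three simulated days) and then switched, mirroring
the experimental schedule. Two runs with the same config and seed produce
byte-identical summary JSON.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as bundle_io
from .assemblies import (
    activation_ratio,
    assembly_strength,
    bin_and_zscore,
    detect_assemblies,
    label_assemblies,
    place_maps_from_units,
)
from .brainstate import detect_swr, label_states, rayleigh_test, state_composition, theta_phase_at
from .classification import classify_detections
from .decoding import (
    decode_session,
    decoding_error,
    decoding_quality,
    fit_encoding_model,
    running_average_posterior,
)
from .detection import DetectionCriteria, NosepokeModel, audit_events, detect_events, head_direction_feedback
from .prevalence import detection_exclusion_windows, region_prevalence
from .synthetic import SyntheticSessionConfig, synthesize_session

__all__ = ["RunConfig", "run_pipeline", "analyze_session"]

log = logging.getLogger("remoterep")

SESSIONS_PER_TARGET = 9  # three simulated days, three sessions per day


@dataclasses.dataclass
class RunConfig:
    seed: int = 0
    n_sessions: int = 1
    output_dir: str = "run_output"
    session_overrides: dict = dataclasses.field(default_factory=dict)
    detection_overrides: dict = dataclasses.field(default_factory=dict)
    mark_bandwidth: float = 20.0
    position_bandwidth: float = 6.0
    amplitude_threshold: float = 100.0

    @classmethod
    def from_yaml(cls, path):
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


def _target_for_session(index: int) -> str:
    return "arm1" if (index // SESSIONS_PER_TARGET) % 2 == 0 else "arm2"


def analyze_session(session, run_config: RunConfig, rng) -> dict:
    """All analysis stages for one (guarded) session; returns the summary."""
    geometry = session.geometry
    target = session.target_arm
    criteria = DetectionCriteria(
        target_region=f"{target}_end", **run_config.detection_overrides
    )

    model = fit_encoding_model(
        session.spikes,
        session.trace,
        geometry,
        session.exploration_end,
        mark_bandwidth=run_config.mark_bandwidth,
        position_bandwidth=run_config.position_bandwidth,
        amplitude_threshold=run_config.amplitude_threshold,
    )
    decoded_expl = decode_session(
        session.spikes, model, geometry, 0.0, session.exploration_end
    )
    quality, included = decoding_quality(
        decoded_expl, session.trace, geometry, target, session.exploration_end
    )
    median_err = float(
        np.median(decoding_error(decoded_expl, session.trace, geometry))
    )

    decoded_fb = decode_session(
        session.spikes, model, geometry, session.exploration_end, session.feedback_end
    )
    averaged = running_average_posterior(decoded_fb)

    poke_model = NosepokeModel(
        rng, prob=session.config.poke_prob, latency=session.config.poke_latency
    )
    if session.session_type == "head_direction":
        events = head_direction_feedback(
            session.trace, target, criteria, geometry,
            session.exploration_end, poke_model=poke_model,
        )
    else:
        events = detect_events(
            averaged, session.trace, criteria, geometry,
            session.exploration_end, poke_model=poke_model,
        )
    if not audit_events(events, criteria):
        raise RuntimeError("event audit failed: emitted event violates criteria")
    rewards = sum(ev.rewarded for ev in events)

    remote_events = [ev for ev in events if ev.kind == "remote_rep"]
    classified = classify_detections(
        decoded_fb, remote_events, session.trace, geometry, target
    )
    cat_counts: dict = {}
    for ce in classified:
        cat_counts[ce.category] = cat_counts.get(ce.category, 0) + 1
    n_cls = max(1, len(classified))
    cat_fractions = {k: v / n_cls for k, v in sorted(cat_counts.items())}

    feedback_s = session.feedback_end - session.exploration_end
    prevalence_summary = {}
    if decoded_fb.informative.any():
        excl = detection_exclusion_windows(remote_events)
        try:
            prev_target = region_prevalence(
                decoded_fb, session.trace, geometry, f"{target}_end",
                session.exploration_end, session.feedback_end, exclude_windows=excl,
            )
            prev_base = region_prevalence(
                decoded_fb, session.trace, geometry, f"{target}_base",
                session.exploration_end, session.feedback_end, exclude_windows=excl,
            )
            prevalence_summary = {
                "target_end": prev_target.prevalence,
                "target_base": prev_base.prevalence,
            }
        except ValueError:
            prevalence_summary = {}

    # assemblies on the feedback phase
    assembly_summary = {}
    asm = None
    if feedback_s >= 10.0:
        z, kept, edges = bin_and_zscore(
            session.unit_spike_times, session.exploration_end, session.feedback_end
        )
        asm = detect_assemblies(z, edges, kept, random_state=int(rng.integers(2**31)))
        assembly_summary = {"n_significant": asm.n_significant}
    if asm is not None and asm.n_assemblies and remote_events:
        maps = place_maps_from_units(
            session.unit_spike_times, session.trace, geometry,
            session.exploration_end,
        )
        asm = label_assemblies(asm, maps, geometry, target)
        strengths = assembly_strength(asm.weights, z)
        ev_bins = np.clip(
            np.searchsorted(edges, [ev.time for ev in remote_events]) - 1,
            0, strengths.shape[1] - 1,
        )
        port_d = np.interp(
            (edges[:-1] + edges[1:]) / 2, session.trace.t,
            np.linalg.norm(
                session.trace.xy - geometry.center_port_xy[None, :], axis=1
            ),
        )
        eligible = np.flatnonzero(port_d < criteria.max_port_distance)
        target_idx = [i for i, lab in enumerate(asm.labels) if lab == "target"]
        if target_idx and len(ev_bins) >= 10:
            s = strengths[target_idx].mean(axis=0)
            ratio, mw = activation_ratio(s, ev_bins, eligible, 200, rng)
            assembly_summary.update(
                n_target=len(target_idx),
                activation_ratio=float(ratio),
                activation_p=float(mw.p),
            )

    # brain state
    swr = detect_swr(session.lfp)
    fb_edges = decoded_fb.t0 + np.arange(decoded_fb.n_t + 1) * decoded_fb.bin_s
    states = label_states(session.trace, swr, fb_edges)
    target_mass = decoded_fb.posterior[:, geometry.mask(f"{target}_end")].sum(axis=1)
    remote_bins = decoded_fb.informative & (target_mass > 0.40)
    comp: dict = {}
    ray = None
    if decoded_fb.n_t and remote_bins.sum() >= 20:
        rng_bins = rng.choice(decoded_fb.n_t, size=int(remote_bins.sum()), replace=False)
        comp_full = state_composition(
            {"remote": states[remote_bins], "random": states[rng_bins]}
        )
        comp = {
            "fractions": comp_full["fractions"],
            "chi2_p": comp_full["chi2_p"],
        }
        moving_remote = remote_bins & (states == "moving")
        if moving_remote.sum() >= 10:
            mid = fb_edges[:-1][moving_remote] + decoded_fb.bin_s / 2
            phases = theta_phase_at(mid, session.lfp)
            zs, pv = rayleigh_test(phases)
            ray = {"z": zs, "p": pv, "n": int(moving_remote.sum())}

    return {
        "session_type": session.session_type,
        "target_arm": target,
        "decoding": {
            "quality_fraction": quality,
            "included": bool(included),
            "median_movement_error_cm": median_err,
        },
        "detection": {
            "n_events": len(events),
            "n_rewarded": int(rewards),
            "audit_passed": True,
        },
        "classification": {"fractions": cat_fractions, "n": len(classified)},
        "prevalence": prevalence_summary,
        "assemblies": assembly_summary,
        "brain_state": {"n_swr": int(len(swr)), "composition": comp, "rayleigh": ray},
    }


def run_pipeline(config: RunConfig) -> dict:
    """Run all stages for every session in the config; returns the summary
    (also written as ``summary.json`` in the output directory)."""
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    fh = logging.FileHandler(outdir / "run.log", mode="w")
    fh.setFormatter(logging.Formatter("%(asctime)s %(name)s %(message)s"))
    log.addHandler(fh)
    log.setLevel(logging.INFO)
    try:
        summary = {
            "seed": config.seed,
            "config": dataclasses.asdict(config),
            "sessions": [],
        }
        seeds = np.random.SeedSequence(config.seed).spawn(config.n_sessions)
        rows = []
        for i in range(config.n_sessions):
            rng = np.random.default_rng(seeds[i])
            session_seed = int(rng.integers(2**31))
            overrides = dict(config.session_overrides)
            overrides.setdefault("target_arm", _target_for_session(i))
            scfg = SyntheticSessionConfig(seed=session_seed, **overrides)
            log.info("session %d: synthesizing (seed %d)", i, session_seed)
            session = synthesize_session(scfg)
            bundle_path = outdir / f"session{i:03d}.h5"
            bundle_io.save_session(session, bundle_path)
            # analysis consumes the bundle with the ground-truth guard on
            guarded = bundle_io.load_session(bundle_path, guard_ground_truth=True)
            try:
                result = analyze_session(guarded, config, rng)
            except Exception as err:
                manifest = {
                    "failed_session": i,
                    "stage_error": str(err),
                    "completed": [s["index"] for s in summary["sessions"]],
                }
                (outdir / "partial_manifest.json").write_text(
                    json.dumps(manifest, indent=2, sort_keys=True)
                )
                raise RuntimeError(f"session {i} failed: {err}") from err
            result["index"] = i
            summary["sessions"].append(result)
            rows.append(
                {
                    "index": i,
                    "session_type": result["session_type"],
                    "target_arm": result["target_arm"],
                    "n_events": result["detection"]["n_events"],
                    "n_rewarded": result["detection"]["n_rewarded"],
                    "prevalence_target_end": result["prevalence"].get("target_end"),
                    "prevalence_target_base": result["prevalence"].get("target_base"),
                }
            )
            log.info("session %d done: %s", i, json.dumps(result["detection"]))
        pd.DataFrame(rows).to_csv(outdir / "sessions.csv", index=False)
        (outdir / "summary.json").write_text(
            json.dumps(summary, indent=2, sort_keys=True, default=_json_default)
        )
        return summary
    finally:
        log.removeHandler(fh)
        fh.close()


def _json_default(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
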