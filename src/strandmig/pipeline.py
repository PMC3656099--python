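"""End-to-end orchestration: generate or read a trajectory, run the monitors,
build the landscape, detect the migration event, cluster states, and emit a
report bundle (JSON summary + CSVs + figures).

Re-running with an identical configuration and seeds reproduces the CSV and
JSON outputs byte for byte (figures excluded).
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import landscape as ls
from . import synthetic as syn
from .hbond import DEFAULT_HBP, HBPParams, hbp_matrix
from .metrics import base_pair_rmsd, contact_distance_series, ideal_pair_reference
from .registry import P1, build_default_registry
from .selection import kmeans_states
from .trajectory_io import Trajectory, read_trajectory, write_trajectory

__all__ = ["PipelineConfigError", "load_config", "validate_config",
           "run_pipeline", "STAGES"]

STAGES = ("input", "monitors", "landscape", "events", "clustering", "report")


class PipelineConfigError(ValueError):
    """Raised before any computation when a configuration is invalid."""


_DEFAULT_CONFIG: dict[str, Any] = {
    "synthetic": {"n_frames": 1000, "event_frame": 400, "noise_sigma": 0.1,
                  "seed": 7, "sam": True},
    "hbp": {},
    "criterion": {"mode": "hbond"},
    "landscape": {"n_bins": 50},
    "clustering": {"k": 5, "n_init": 10, "positions": [3, 4, 5, 6]},
    "output": {"directory": "strandmig_out", "figures": True},
}


def load_config(path: str | Path) -> dict:
    path = Path(path)
    if not path.exists():
        raise PipelineConfigError(f"config file not found: {path}")
    data = yaml.safe_load(path.read_text()) or {}
    return validate_config(data)


def validate_config(data: Mapping) -> dict:
    """Schema-check and default-fill a pipeline configuration."""
    if not isinstance(data, Mapping):
        raise PipelineConfigError("config must be a mapping")
    known = set(_DEFAULT_CONFIG) | {"trajectory"}
    unknown = set(data) - known
    if unknown:
        raise PipelineConfigError(f"unknown config sections: {sorted(unknown)}")
    has_syn = "synthetic" in data
    has_traj = "trajectory" in data
    if has_syn == has_traj:
        raise PipelineConfigError(
            "config must contain exactly one of 'synthetic' or 'trajectory'")
    cfg: dict[str, Any] = {}
    for key, defaults in _DEFAULT_CONFIG.items():
        if key == "synthetic":
            continue
        merged = dict(defaults)
        merged.update(data.get(key) or {})
        cfg[key] = merged
    if has_syn:
        merged = dict(_DEFAULT_CONFIG["synthetic"])
        merged.update(data["synthetic"] or {})
        cfg["synthetic"] = merged
    else:
        traj = dict(data["trajectory"] or {})
        if "path" not in traj:
            raise PipelineConfigError("trajectory section needs a 'path'")
        traj.setdefault("format", "pdb")
        cfg["trajectory"] = traj
    try:
        HBPParams(**{k: v for k, v in cfg["hbp"].items()})
        ls.EventCriterion(**cfg["criterion"])
    except (TypeError, ValueError) as exc:
        raise PipelineConfigError(str(exc)) from exc
    return cfg


def run_pipeline(config: Mapping | str | Path, out_dir: str | Path | None = None,
                 seed: int | None = None, dry_run: bool = False) -> dict:
    """Execute the full analysis pipeline described by ``config``.

    Returns the report dictionary (also written as ``report.json``).  With
    ``dry_run=True``, returns only the ordered stage list and writes nothing.
    """
    if isinstance(config, (str, Path)):
        cfg = load_config(config)
    else:
        cfg = validate_config(config)
    if dry_run:
        return {"stages": list(STAGES), "dry_run": True}

    out = Path(out_dir or cfg["output"]["directory"])
    (out / "monitors").mkdir(parents=True, exist_ok=True)
    if cfg["output"].get("figures", True):
        (out / "figures").mkdir(exist_ok=True)

    registry = build_default_registry()
    params = HBPParams(**cfg["hbp"])
    criterion = ls.EventCriterion(**cfg["criterion"])
    report: dict[str, Any] = {"stages": list(STAGES), "config": _plain(cfg)}

    # -- stage: input ---------------------------------------------------------
    if "synthetic" in cfg:
        s = cfg["synthetic"]
        use_seed = s["seed"] if seed is None else seed
        schedule = syn.default_schedule(s["n_frames"], s.get("event_frame"),
                                        sam_present=s.get("sam", True))
        traj, schedule = syn.generate_switch_trajectory(
            registry, schedule, s.get("noise_sigma", 0.1), use_seed)
        write_trajectory(traj, out / "trajectory.pdb")
        schedule.to_csv(out / "schedule.csv")
        if schedule.marker_scripts:
            schedule.markers_to_csv(out / "marker_scripts.csv")
        report["input"] = {"kind": "synthetic", "seed": use_seed,
                           "n_frames": traj.n_frames,
                           "noise_sigma": s.get("noise_sigma", 0.1),
                           "ligand_present": schedule.sam_present}
    else:
        t = cfg["trajectory"]
        traj = read_trajectory(t["path"], t.get("format", "pdb"))
        schedule = None
        report["input"] = {"kind": "file", "path": str(t["path"]),
                           "n_frames": traj.n_frames}

    interval = traj.recording_interval_ps

    # -- stage: monitors ------------------------------------------------------
    hbp_df = hbp_matrix(traj, registry, params)
    hbp_df.to_csv(out / "monitors" / "hbp.csv", index_label="frame")

    p1_positions = list(registry.positions(P1))
    rmsd_cols = {}
    for pos in p1_positions:
        ref = ideal_pair_reference(registry, pos)
        rmsd_cols[f"p1_pair{pos.ordinal}"] = np.array(
            [base_pair_rmsd(traj.frame(f), pos, ref)
             for f in range(traj.n_frames)])
    rmsd_df = pd.DataFrame(rmsd_cols)
    rmsd_df.insert(0, "frame", np.arange(traj.n_frames))
    rmsd_df.to_csv(out / "monitors" / "bp_rmsd.csv", index=False)

    contact_rows = {}
    if traj.has_atom(syn.MG_KEY):
        for key in [(8, "P"), (9, "O6"), (81, "P"), (82, "P"), (83, "P")]:
            if traj.has_atom(key):
                cs = contact_distance_series(traj, syn.MG_KEY, key)
                contact_rows[f"Mg-{key[0]}{key[1]}"] = cs.distances
    if traj.has_atom(syn.SD_KEY):
        for key in [(5, "O2"), (110, "O2")]:
            if traj.has_atom(key):
                cs = contact_distance_series(traj, syn.SD_KEY, key)
                contact_rows[f"S-{key[0]}O2"] = cs.distances
    if contact_rows:
        cdf = pd.DataFrame(contact_rows)
        cdf.insert(0, "frame", np.arange(traj.n_frames))
        cdf.to_csv(out / "monitors" / "contacts.csv", index=False)

    # -- stage: landscape -----------------------------------------------------
    reduced = ls.reduce_trajectory(traj, registry, params)
    reduced.to_csv(out / "monitors" / "reduced_coords.csv", index=False)
    grid = ls.population_grid(reduced, cfg["landscape"]["n_bins"])
    grid.to_csv(out / "landscape.csv")
    report["landscape"] = {"n_bins": cfg["landscape"]["n_bins"],
                           "total_frames": grid.n_frames,
                           "occupied_bins": int((grid.counts > 0).sum())}

    # -- stage: events --------------------------------------------------------
    record = ls.detect_full_p1(traj, registry, criterion)
    if record is None:
        report["event"] = None
    else:
        report["event"] = asdict(record)
        report["event"]["event_time_ns"] = record.event_frame * interval / 1000.0
        window = (record.event_frame, traj.n_frames)
        pos5 = registry.position(P1, 5)
        count, frac = ls.pair_occupancy(traj, pos5, window, criterion, registry)
        report["pair5_occupancy_after_event"] = {
            "count": count, "window_frames": window[1] - window[0],
            "fraction": frac}
    if schedule is not None and schedule.event_frame is not None:
        report["ground_truth_event_frame"] = int(schedule.event_frame)

    # -- stage: clustering ----------------------------------------------------
    ordinals = cfg["clustering"].get("positions", [3, 4, 5, 6])
    feats = np.stack([rmsd_cols[f"p1_pair{o}"] for o in ordinals], axis=1)
    k = cfg["clustering"]["k"]
    cl_seed = report["input"].get("seed", 0) if seed is None else seed
    try:
        assignment = kmeans_states(feats, k, seed=cl_seed,
                                   n_init=cfg["clustering"]["n_init"])
        assignment.to_csv(out / "monitors" / "states.csv")
        report["clustering"] = {"k": k, "seed": cl_seed,
                                "populations": assignment.populations,
                                "representatives": assignment.representatives}
    except ValueError as exc:  # e.g. noiseless input with < k distinct frames
        report["clustering"] = {"k": k, "skipped": str(exc)}

    # -- stage: report --------------------------------------------------------
    if cfg["output"].get("figures", True):
        _render_figures(out, reduced, grid, rmsd_df, interval)
    (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True,
                                                default=_plain) + "\n")
    return report


def _plain(obj):
    if isinstance(obj, Mapping):
        return {str(k): _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def _render_figures(out: Path, reduced: pd.DataFrame, grid: "ls.PopulationGrid",
                    rmsd_df: pd.DataFrame, interval: float) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    mesh = ax.pcolormesh(grid.x_edges, grid.y_edges, grid.log_population().T,
                         cmap="viridis")
    ax.plot(reduced["f_p1"], reduced["f_at"], color="orange", lw=0.4, alpha=0.6)
    ax.set_xlabel("P1 helix H-bond fraction")
    ax.set_ylabel("AT helix H-bond fraction")
    fig.colorbar(mesh, ax=ax, label="log population")
    fig.tight_layout()
    fig.savefig(out / "figures" / "landscape.png", dpi=150)
    plt.close(fig)

    pair_cols = [c for c in rmsd_df.columns if c != "frame"]
    fig, ax = plt.subplots(figsize=(6, 3))
    mat = rmsd_df[pair_cols].to_numpy().T
    im = ax.imshow(mat, aspect="auto", origin="lower", cmap="jet_r",
                   extent=(0, len(rmsd_df) * interval / 1000.0, 0.5,
                           len(pair_cols) + 0.5))
    ax.set_xlabel("time (ns)")
    ax.set_ylabel("P1 base pair")
    fig.colorbar(im, ax=ax, label="RMSD (A)")
    fig.tight_layout()
    fig.savefig(out / "figures" / "bp_rmsd.png", dpi=150)
    plt.close(fig)
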