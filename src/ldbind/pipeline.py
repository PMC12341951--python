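"""End-to-end pipeline: generate -> analyze -> report.

A YAML/JSON config describes one or more scenarios plus per-stage options;
``run_pipeline`` executes the requested stages (simulate, contacts, depth,
defects, helix) and writes plain TSV/JSON outputs, a summary JSON of
headline numbers, and a run manifest.  Deterministic stages reproduce
byte-identical summaries on rerun with the same config.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .contacts import contact_profile, contacts_per_frame_table
from .defects import classify_surface, defect_size_constant, defect_table
from .depth import depth_map
from .model import membrane_geometry
from .synthetic import ScenarioConfig, generate_trajectory

logger = logging.getLogger(__name__)

STAGES = ("simulate", "contacts", "depth", "defects", "helix")

_SCHEMA = {
    "seed": int,
    "out_dir": str,
    "stages": list,
    "scenarios": list,
    "contacts": dict,
    "depth": dict,
    "defects": dict,
    "helix": dict,
    "write_trajectories": bool,
}
_STAGE_KEYS = {
    "contacts": {"threshold", "cutoff"},
    "depth": {"bin_width", "z_max", "use_calpha"},
    "defects": {"cell_size", "atom_radius", "a_min", "leaflet"},
    "helix": {"sequence", "start", "end", "seq_offset", "mutations", "tolerance"},
}


class ConfigError(ValueError):
    """The pipeline config violates the declared schema."""


def validate_config(config: dict) -> dict:
    """Validate the config mapping; unknown keys raise naming the key."""
    if not isinstance(config, dict):
        raise ConfigError("config must be a mapping")
    for key in config:
        if key not in _SCHEMA:
            raise ConfigError(f"unknown config key: {key!r}")
    for stage, allowed in _STAGE_KEYS.items():
        for key in config.get(stage, {}) or {}:
            if key not in allowed:
                raise ConfigError(f"unknown key {key!r} in section {stage!r}")
    stages = config.get("stages", list(STAGES))
    for s in stages:
        if s not in STAGES:
            raise ConfigError(f"unknown stage: {s!r}")
    if "scenarios" in config:
        for i, sc in enumerate(config["scenarios"]):
            if not isinstance(sc, dict):
                raise ConfigError(f"scenario {i} must be a mapping")
            extra = dict(sc)
            extra.pop("name", None)
            ScenarioConfig.from_dict(extra)  # raises on unknown keys
    return config


def load_config(path: str | Path) -> dict:
    path = Path(path)
    data = yaml.safe_load(path.read_text())
    return validate_config(data or {})


@dataclass
class RunManifest:
    """Provenance record of one pipeline run."""

    config_hash: str
    seed: int
    version: str
    stages: list[str]
    outputs: dict[str, list[str]] = field(default_factory=dict)
    started: float = 0.0
    finished: float = 0.0

    def to_json(self) -> dict:
        return {
            "config_hash": self.config_hash, "seed": self.seed,
            "version": self.version, "stages": self.stages,
            "outputs": self.outputs, "started": self.started,
            "finished": self.finished,
        }


def _config_hash(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()


def _scenario_configs(config: dict, seed: int) -> list[tuple[str, ScenarioConfig]]:
    out = []
    for i, sc in enumerate(config.get("scenarios", [{}])):
        sc = dict(sc)
        name = sc.pop("name", f"scenario{i}")
        sc.setdefault("seed", seed + i)
        out.append((name, ScenarioConfig.from_dict(sc)))
    return out


def run_pipeline(
    config: dict | str | Path,
    out_dir: str | Path,
    seed: int | None = None,
) -> Path:
    """Run all requested stages; returns the report directory.

    A stage failure aborts with the stage named; outputs written before the
    failure are preserved.
    """
    if not isinstance(config, dict):
        config = load_config(config)
    else:
        config = validate_config(config)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0) if seed is None else seed)
    stages = list(config.get("stages", STAGES))
    manifest = RunManifest(_config_hash(config), seed, __version__, stages,
                           started=time.time())

    summary: dict = {"seed": seed, "version": __version__, "scenarios": []}
    c_opts = config.get("contacts", {}) or {}
    d_opts = config.get("depth", {}) or {}
    f_opts = dict(config.get("defects", {}) or {})
    leaflet = f_opts.pop("leaflet", "upper")
    a_min = f_opts.pop("a_min", 5.0)
    f_opts.setdefault("atom_radius", 4.0)

    for name, scfg in _scenario_configs(config, seed):
        sdir = out_dir / name
        sdir.mkdir(exist_ok=True)
        outputs: list[str] = []
        entry: dict = {"name": name, "config": scfg.to_dict()}
        try:
            traj = generate_trajectory(scfg)
            geometry = membrane_geometry(traj)
            if config.get("write_trajectories", False):
                from .io import write_topology_json, write_trajectory_xyz

                write_trajectory_xyz(sdir / "trajectory.xyz", traj)
                write_topology_json(sdir / "topology.json", traj.topology)
                outputs += ["trajectory.xyz", "topology.json"]
        except Exception as exc:
            raise RuntimeError(f"stage 'simulate' failed for {name!r}: {exc}") from exc

        if "contacts" in stages:
            try:
                prof = contact_profile(traj, **c_opts)
                contacts_per_frame_table(prof).to_csv(
                    sdir / "contacts_per_frame.tsv", sep="\t", index=False)
                prof.to_frame().to_csv(sdir / "contact_profile.tsv", sep="\t",
                                       index=False)
                outputs += ["contacts_per_frame.tsv", "contact_profile.tsv"]
                entry["bound_residues"] = prof.bound_residues().tolist()
                entry["first_binding_frame"] = prof.first_binding_frame
                entry["max_avg_bound_residue"] = (
                    int(prof.residue_ids[int(np.argmax(prof.avg_bound))])
                    if prof.avg_bound.max() > 0 else None)
                entry["total_cumulative_contact"] = float(prof.cumulative[-1])
            except Exception as exc:
                raise RuntimeError(f"stage 'contacts' failed for {name!r}: {exc}") from exc

        if "depth" in stages:
            try:
                dmap = depth_map(traj, geometry, **d_opts)
                dmap.to_frame().to_csv(sdir / "depth_relative.tsv", sep="\t")
                outputs.append("depth_relative.tsv")
                modal = dict(zip(dmap.residue_ids.tolist(),
                                 dmap.modal_depth().tolist()))
                entry["modal_depth_binding"] = {
                    str(r): modal[r] for r in sorted(scfg.binding_residues)
                    if r in modal}
                head_depth = float(np.mean(geometry.head_plane_upper
                                           - geometry.center_z))
                entry["head_plane_depth"] = head_depth
            except Exception as exc:
                raise RuntimeError(f"stage 'depth' failed for {name!r}: {exc}") from exc

        if "defects" in stages:
            try:
                maps = [classify_surface(traj.topology, fr, leaflet, geometry,
                                         **f_opts) for fr in traj.frames]
                defect_table(maps).to_csv(sdir / "defects.tsv", sep="\t",
                                          index=False)
                outputs.append("defects.tsv")
                areas = np.concatenate([m.areas() for m in maps]) \
                    if maps else np.array([])
                entry["defect_area_fraction"] = float(
                    np.mean([m.defect_fraction for m in maps]))
                try:
                    lam = defect_size_constant(areas, a_min=a_min)
                except ValueError:
                    lam = None
                entry["defect_size_constant"] = lam
                (sdir / "defects_summary.json").write_text(json.dumps({
                    "total_area_fraction": entry["defect_area_fraction"],
                    "size_constant": lam}, indent=2))
                outputs.append("defects_summary.json")
            except Exception as exc:
                raise RuntimeError(f"stage 'defects' failed for {name!r}: {exc}") from exc

        entry["outputs"] = outputs
        manifest.outputs[name] = outputs
        summary["scenarios"].append(entry)

    if "helix" in stages and config.get("helix"):
        from .helix import annotate_helix

        h = dict(config["helix"])
        try:
            sequence = h.pop("sequence")
            start, end = h.pop("start"), h.pop("end")
            mutations = h.pop("mutations", None)
            ann = annotate_helix(sequence, start, end, **h)
            panel = {"wild_type": {"ww_sum": round(ann.ww_sum, 6),
                                   "moment": ann.moment_magnitude,
                                   "moment_direction": ann.moment_direction}}
            if mutations:
                mut = annotate_helix(sequence, start, end, mutations=mutations, **h)
                panel["mutant"] = {"mutations": [str(m) for m in mutations],
                                   "ww_sum": round(mut.ww_sum, 6),
                                   "moment": mut.moment_magnitude,
                                   "moment_direction": mut.moment_direction}
            ann.to_frame().to_csv(out_dir / "helix_report.tsv", sep="\t")
            summary["helix"] = panel
        except (KeyError, ValueError) as exc:
            raise RuntimeError(f"stage 'helix' failed: {exc}") from exc

    manifest.finished = time.time()
    (out_dir / "summary.json").write_text(json.dumps(summary, indent=2,
                                                     sort_keys=True))
    (out_dir / "manifest.json").write_text(json.dumps(manifest.to_json(),
                                                      indent=2))
    return out_dir


def compare_scenarios(
    summaries: list[dict], grouping_keys: list[str] | None = None
) -> pd.DataFrame:
    """Long-format comparison table of headline metrics across scenarios.

    ``summaries`` are scenario entries from pipeline summary JSONs.  Metric
    sets must match across entries; an empty grouping-key list pools all
    scenarios into a single row of metric means.
    """
    if len(summaries) < 2:
        raise ValueError("need at least 2 scenario summaries to compare")
    metric_keys = None
    rows = []
    numeric = ("first_binding_frame", "total_cumulative_contact",
               "defect_area_fraction", "defect_size_constant",
               "head_plane_depth")
    for entry in summaries:
        metrics = {k: entry.get(k) for k in numeric if k in entry}
        keys = frozenset(metrics)
        if metric_keys is None:
            metric_keys = keys
        elif keys != metric_keys:
            raise ValueError("scenario summaries carry mismatched metric sets")
        row = {"name": entry.get("name")}
        cfg = entry.get("config", {})
        for k in ("membrane_kind", "composition", "orientation_index", "protein"):
            row[k] = cfg.get(k)
        row.update(metrics)
        rows.append(row)
    df = pd.DataFrame(rows)
    value_cols = sorted(metric_keys or [])
    long = df.melt(id_vars=[c for c in df.columns if c not in value_cols],
                   value_vars=value_cols, var_name="metric", value_name="value")
    if grouping_keys:
        for k in grouping_keys:
            if k not in long.columns:
                raise ValueError(f"unknown grouping key {k!r}")
        return (long.groupby(grouping_keys + ["metric"], dropna=False)["value"]
                .mean().reset_index())
    return (long.groupby("metric", dropna=False)["value"].mean()
            .reset_index())
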