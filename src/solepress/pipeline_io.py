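"""Recording container format and the end-to-end analysis driver.

A recording container is a directory:

    meta.json           sample_rate_hz, body_mass_kg, side, task_label,
                        grid dims, cell_area_cm2, seed, provenance
    frames.txt | .npy   T rows x (n_rows * n_cols) values, row-major
    gyro.txt            optional yaw-rate trace (deg/s)
    ground_truth.json   optional generative ground truth

The text dialect round-trips bit-exactly (values printed with repr
precision); the binary dialect (.npy) is for bulk storage.  Both are read
transparently.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .foot_model import (
    FootOutline,
    PressureRecording,
    SensorGrid,
    build_standard_outline,
)
from .synthetic import (
    GroundTruth,
    SyntheticTaskConfig,
    gen_jump,
    gen_standing,
    gen_walking,
)
from .preprocessing import PreprocessConfig, preprocess_recording
from .contact_metrics import (
    ActivationRule,
    compute_frame_metrics,
    exclude_low_force,
    force_area_relationship,
)
from .complexity import (
    component_correlation_clusters,
    cluster_emergence_order,
    components_for_threshold,
)
from .task_stats import compare_groups

__all__ = [
    "ContainerError",
    "write_recording",
    "read_recording",
    "run_full_analysis",
]

logger = logging.getLogger(__name__)

META_KEYS = (
    "sample_rate_hz", "body_mass_kg", "side", "task_label",
    "n_rows", "n_cols", "cell_area_cm2",
)


class ContainerError(ValueError):
    """Container violates its invariants; ``errors`` lists every one."""

    def __init__(self, errors: list[str]):
        self.errors = errors
        super().__init__("; ".join(errors))


def _truth_to_json(truth: GroundTruth) -> dict:
    d: dict = {
        "step_windows": [list(w) for w in truth.step_windows],
        "turn_windows": [list(w) for w in truth.turn_windows],
        "turn_angles_deg": truth.turn_angles_deg,
        "stomp_frame": truth.stomp_frame,
    }
    if truth.cop_trace is not None:
        d["cop_trace"] = np.asarray(truth.cop_trace).tolist()
    if truth.planted_components is not None:
        d["planted_components"] = np.asarray(truth.planted_components).tolist()
    if truth.planted_activations is not None:
        d["planted_activations"] = np.asarray(truth.planted_activations).tolist()
    return d


def _truth_from_json(d: dict) -> GroundTruth:
    def arr(key):
        return np.asarray(d[key], dtype=float) if key in d else None

    return GroundTruth(
        cop_trace=arr("cop_trace"),
        step_windows=[tuple(w) for w in d.get("step_windows", [])],
        planted_components=arr("planted_components"),
        planted_activations=arr("planted_activations"),
        turn_windows=[tuple(w) for w in d.get("turn_windows", [])],
        turn_angles_deg=list(d.get("turn_angles_deg", [])),
        stomp_frame=d.get("stomp_frame"),
    )


def write_recording(
    path: str | Path,
    recording: PressureRecording,
    gyro_trace: np.ndarray | None = None,
    ground_truth: GroundTruth | None = None,
    fmt: str = "text",
    seed: int | None = None,
) -> Path:
    """Write a recording container; returns the directory path."""
    if fmt not in ("text", "binary"):
        raise ValueError("fmt must be 'text' or 'binary'")
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    meta = {
        "sample_rate_hz": recording.sample_rate_hz,
        "body_mass_kg": recording.body_mass_kg,
        "side": recording.side,
        "task_label": recording.task_label,
        "n_rows": recording.grid.n_rows,
        "n_cols": recording.grid.n_cols,
        "cell_area_cm2": recording.grid.cell_area_cm2,
        "n_frames": recording.n_frames,
        "seed": seed,
        "provenance": f"solepress {__version__}",
        "frames_format": fmt,
    }
    (path / "meta.json").write_text(json.dumps(meta, indent=1))
    flat = recording.flattened()
    if fmt == "text":
        with open(path / "frames.txt", "w") as fh:
            for row in flat:
                fh.write(" ".join(repr(float(v)) for v in row))
                fh.write("\n")
    else:
        np.save(path / "frames.npy", recording.frames)
    if gyro_trace is not None:
        np.savetxt(path / "gyro.txt", np.asarray(gyro_trace, dtype=float))
    if ground_truth is not None:
        (path / "ground_truth.json").write_text(
            json.dumps(_truth_to_json(ground_truth))
        )
    return path


def read_recording(
    path: str | Path,
) -> tuple[PressureRecording, np.ndarray | None, GroundTruth | None]:
    """Load and validate a recording container.

    Raises :class:`ContainerError` listing every violated invariant.
    """
    path = Path(path)
    errors: list[str] = []
    meta_path = path / "meta.json"
    if not meta_path.exists():
        raise ContainerError([f"missing meta.json in {path}"])
    meta = json.loads(meta_path.read_text())
    for key in META_KEYS:
        if key not in meta:
            errors.append(f"missing meta key {key!r}")
    if errors:
        raise ContainerError(errors)

    n_rows, n_cols = int(meta["n_rows"]), int(meta["n_cols"])
    txt, npy = path / "frames.txt", path / "frames.npy"
    if txt.exists():
        rows = []
        for t, line in enumerate(txt.read_text().splitlines()):
            vals = line.split()
            if len(vals) != n_rows * n_cols:
                errors.append(
                    f"frame {t}: expected {n_rows * n_cols} values, "
                    f"got {len(vals)}"
                )
                continue
            rows.append([float(v) for v in vals])
        frames = np.asarray(rows, dtype=float).reshape(-1, n_rows, n_cols)
    elif npy.exists():
        frames = np.load(npy)
        if frames.shape[1:] != (n_rows, n_cols):
            errors.append(
                f"frames shape {frames.shape[1:]} does not match meta grid "
                f"({n_rows}, {n_cols})"
            )
    else:
        errors.append("missing frames file (frames.txt or frames.npy)")
        raise ContainerError(errors)

    if "n_frames" in meta and not errors and frames.shape[0] != meta["n_frames"]:
        errors.append(
            f"meta declares {meta['n_frames']} frames, file has {frames.shape[0]}"
        )
    if not errors and np.any(frames < 0):
        errors.append("negative pressures in frames")
    if errors:
        raise ContainerError(errors)

    grid = SensorGrid(n_rows, n_cols, float(meta["cell_area_cm2"]))
    rec = PressureRecording(
        frames=frames, grid=grid,
        sample_rate_hz=float(meta["sample_rate_hz"]),
        body_mass_kg=float(meta["body_mass_kg"]),
        side=meta["side"], task_label=meta["task_label"],
    )
    gyro = None
    if (path / "gyro.txt").exists():
        gyro = np.loadtxt(path / "gyro.txt")
    truth = None
    if (path / "ground_truth.json").exists():
        truth = _truth_from_json(json.loads((path / "ground_truth.json").read_text()))
    return rec, gyro, truth


def simulate_task(
    config: SyntheticTaskConfig, outline: FootOutline | None = None
) -> tuple[list[PressureRecording], GroundTruth]:
    """Dispatch to the right generator; always returns a recording list."""
    if config.task_kind in ("standing", "wobble"):
        recs, truth = gen_standing(config, outline)
        return [recs["left"], recs["right"]], truth
    if config.task_kind in ("walking", "gravel"):
        rec, truth = gen_walking(config, outline)
        return [rec], truth
    if config.task_kind == "jump":
        rec, truth = gen_jump(config, outline)
        return [rec], truth
    raise ValueError(f"cannot simulate task_kind {config.task_kind!r}")


def _config_hash(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def run_full_analysis(
    config: dict,
    out_dir: str | Path,
    seed: int = 0,
) -> dict:
    """Run preprocess -> metrics -> complexity -> stats on synthetic tasks.

    ``config`` lists tasks, e.g.::

        {"tasks": [{"name": "standing", "task_kind": "standing",
                    "duration_s": 30}, ...],
         "threshold": 0.9, "k_max": 20, "n_restarts": 2,
         "frame_stride": 4}

    Every random stage derives its seed from the single top-level seed.
    Reports (CSV/JSON) are written under ``out_dir``.
    """
    tasks = config.get("tasks", [])
    if not tasks:
        raise ValueError("config lists zero tasks")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    outline = build_standard_outline()
    pre_cfg = PreprocessConfig()
    rule = ActivationRule()
    threshold = config.get("threshold", 0.90)
    k_max = config.get("k_max", 30)
    n_restarts = config.get("n_restarts", 10)
    frame_stride = config.get("frame_stride", 1)

    header = {
        "config_hash": _config_hash(config),
        "solepress_version": __version__,
        "seed": seed,
    }
    summary: dict = {**header, "tasks": {}}
    task_components: dict[str, np.ndarray] = {}
    area_groups: dict[str, np.ndarray] = {}
    force_groups: dict[str, np.ndarray] = {}

    for t_idx, spec in enumerate(tasks):
        name = spec.get("name", spec["task_kind"])
        task_seed = seed * 1009 + t_idx
        cfg = SyntheticTaskConfig(
            task_kind=spec["task_kind"],
            duration_s=spec.get("duration_s", 30.0),
            body_mass_kg=spec.get("body_mass_kg", 70.0),
            seed=task_seed,
            duty_factor=spec.get("duty_factor", 0.6),
            noise_sigma=spec.get("noise_sigma", 0.5),
            hotspot_rate=spec.get("hotspot_rate", 4.0),
        )
        try:
            recs, truth = simulate_task(cfg, outline)
        except Exception as exc:
            raise RuntimeError(
                f"stage 'simulate' failed for task {name!r}: {exc}"
            ) from exc

        task_report: dict = {"seed": task_seed, "recordings": len(recs)}
        metric_tables = []
        pooled_frames = []
        for rec in recs:
            try:
                pre = preprocess_recording(rec, pre_cfg, strict_trim=False)
            except Exception as exc:
                raise RuntimeError(
                    f"stage 'preprocess' failed for task {name!r}: {exc}"
                ) from exc
            proc = pre["recording"]
            metrics = compute_frame_metrics(proc, outline, rule)
            metrics.insert(0, "side", rec.side)
            metric_tables.append(metrics)
            pooled_frames.append(proc.flattened()[::frame_stride])

        metrics_all = pd.concat(metric_tables, ignore_index=True)
        metrics_all.to_csv(out_dir / f"metrics_{name}.csv", index=False)
        retained = exclude_low_force(metrics_all)
        task_report["n_frames"] = int(len(metrics_all))
        task_report["n_retained"] = int(len(retained))
        task_report["mean_force_pct_bm"] = float(retained["force_pct_bm"].mean())
        task_report["mean_contact_area_pct"] = float(
            retained["contact_area_pct"].mean()
        )
        rel = force_area_relationship(retained)
        task_report["force_area_spearman"] = rel["spearman_rho"]

        # per-second chunk means are the observation unit for group tests
        chunk = int(recs[0].sample_rate_hz)
        grouped = retained.groupby(retained.index // chunk)
        area_groups[name] = grouped["contact_area_pct"].mean().to_numpy()
        force_groups[name] = grouped["force_pct_bm"].mean().to_numpy()

        X = np.vstack(pooled_frames)
        X = X[X.sum(axis=1) > 0]
        try:
            comp = components_for_threshold(
                X, threshold=threshold, k_max=k_max, seed=task_seed,
                n_restarts=n_restarts, keep_models=True,
            )
        except Exception as exc:
            raise RuntimeError(
                f"stage 'complexity' failed for task {name!r}: {exc}"
            ) from exc
        task_report["k_star"] = comp.k_star
        task_report["ve_by_k"] = {str(k): v for k, v in comp.ve_by_k.items()}
        if comp.k_star is not None:
            model = comp.models[comp.k_star]
            task_components[name] = model.spatial
            np.savetxt(
                out_dir / f"components_{name}.txt", model.spatial, fmt="%.6e"
            )
        summary["tasks"][name] = task_report
        logger.info("task %s: %s", name, task_report)

    if len(task_components) >= 2:
        try:
            clusters = component_correlation_clusters(task_components)
            emergence = cluster_emergence_order(task_components)
        except Exception as exc:
            raise RuntimeError(f"stage 'clustering' failed: {exc}") from exc
        np.savetxt(out_dir / "cluster_corr_sorted.txt",
                   clusters.sorted_corr(), fmt="%.6f")
        summary["clusters"] = {
            "n_clusters": clusters.n_clusters,
            "emergence": [
                {k: v for k, v in d.items() if k != "centroid"}
                for d in emergence
            ],
        }

    if len(area_groups) >= 2 and all(len(v) >= 2 for v in area_groups.values()):
        try:
            cmp_area = compare_groups(area_groups)
            cmp_force = compare_groups(force_groups)
        except Exception as exc:
            raise RuntimeError(f"stage 'stats' failed: {exc}") from exc
        cmp_area.pairwise.to_csv(out_dir / "pairwise_contact_area.csv", index=False)
        cmp_force.pairwise.to_csv(out_dir / "pairwise_force.csv", index=False)
        summary["stats"] = {
            "contact_area": {"H": cmp_area.h_statistic, "p": cmp_area.p_value},
            "force": {"H": cmp_force.h_statistic, "p": cmp_force.p_value},
        }

    (out_dir / "summary.json").write_text(json.dumps(summary, indent=1))
    return summary
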