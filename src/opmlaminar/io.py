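"""Configuration, file formats, and run provenance.

Formats: PLY for surface meshes, TSV for sensor layouts and decision
tables, YAML for sweep configurations, JSON for the run manifest, NPZ for
trial datasets and lead fields.  All writes are atomic
(temp-file-then-rename) and deterministic.
"""

from __future__ import annotations

import dataclasses
import json
import os
import tempfile
from pathlib import Path

import numpy as np
import pandas as pd
import trimesh
import yaml

from .experiments import SweepConfig
from .forward import LeadField
from .geometry import SensorArray, SurfaceMesh
from .simulate import TrialDataset

__all__ = [
    "load_config",
    "dump_config",
    "write_outputs",
    "save_mesh_ply",
    "load_mesh_ply",
    "save_sensor_layout",
    "load_sensor_layout",
    "save_dataset",
    "load_dataset",
    "save_leadfield",
    "load_leadfield",
]

_CONFIG_FIELDS = {f.name: f for f in dataclasses.fields(SweepConfig)}


def load_config(path) -> SweepConfig:
    """Load and validate a sweep configuration from YAML.

    Unknown keys are rejected by name; all omitted keys take the documented
    defaults (200 trials at 200 Hz, 5 mm patches, 35 mm spacing ...).
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError("config must be a YAML mapping")
    unknown = sorted(set(raw) - set(_CONFIG_FIELDS))
    if unknown:
        raise ValueError(f"unknown config key(s): {', '.join(unknown)}")
    if "patch_fwhm_pairs" in raw:
        raw["patch_fwhm_pairs"] = [tuple(p) for p in raw["patch_fwhm_pairs"]]
    config = SweepConfig(**raw)
    config.validate()
    return config


def dump_config(config: SweepConfig, path) -> None:
    payload = dataclasses.asdict(config)
    payload["patch_fwhm_pairs"] = [list(p) for p in payload["patch_fwhm_pairs"]]
    _atomic_write_text(path, yaml.safe_dump(payload, sort_keys=True))


def _atomic_write_text(path, text: str) -> None:
    path = Path(path)
    fd, tmp = tempfile.mkstemp(dir=path.parent, suffix=".tmp")
    try:
        with os.fdopen(fd, "w") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def _config_hash(config: SweepConfig) -> str:
    return config.content_hash()


def build_manifest(config: SweepConfig, notes: dict | None = None) -> dict:
    import scipy

    from . import __version__

    return dict(
        config_hash=_config_hash(config),
        master_seed=config.master_seed,
        versions=dict(
            opmlaminar=__version__,
            numpy=np.__version__,
            scipy=scipy.__version__,
            pandas=pd.__version__,
        ),
        geometry_substitution=(
            "synthetic nested icosphere cortical layers; "
            "Sarvas conducting-sphere forward kernel"
        ),
        notes=notes or {},
    )


def write_outputs(
    table: pd.DataFrame,
    summaries: pd.DataFrame,
    manifest: dict,
    out_dir,
) -> dict:
    """Write the decision table, summaries, and JSON manifest atomically."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "table": out_dir / "decisions.tsv",
        "summary": out_dir / "summary.tsv",
        "manifest": out_dir / "manifest.json",
    }
    _atomic_write_text(paths["table"], table.to_csv(sep="\t", index=False))
    _atomic_write_text(paths["summary"], summaries.to_csv(sep="\t", index=False))
    _atomic_write_text(paths["manifest"], json.dumps(manifest, indent=2, sort_keys=True))
    return paths


# ---------------------------------------------------------------------------
# meshes and sensor layouts


def save_mesh_ply(mesh: SurfaceMesh, path, ascii: bool = True) -> None:
    tm = trimesh.Trimesh(vertices=mesh.vertices, faces=mesh.faces, process=False)
    data = tm.export(file_type="ply", encoding="ascii" if ascii else "binary")
    mode = "wb" if isinstance(data, bytes) else "w"
    with open(path, mode) as fh:
        fh.write(data)


def load_mesh_ply(path) -> SurfaceMesh:
    tm = trimesh.load_mesh(path, process=False)
    normals = np.asarray(tm.vertex_normals, dtype=float).copy()
    normals /= np.linalg.norm(normals, axis=1, keepdims=True)
    return SurfaceMesh(np.asarray(tm.vertices, float), np.asarray(tm.faces, int), normals)


_LAYOUT_COLUMNS = [
    "sensor_id", "x", "y", "z",
    "ax1x", "ax1y", "ax1z", "ax2x", "ax2y", "ax2z", "ax3x", "ax3y", "ax3z",
    "n_axes", "offset_mm",
]


def save_sensor_layout(array: SensorArray, path) -> None:
    rows = []
    for i in range(array.n_sensors):
        axes = np.zeros((3, 3))
        axes[: array.n_axes] = array.channel_axes[i]
        rows.append(
            [f"s{i:03d}", *array.positions[i], *axes.reshape(-1), array.n_axes, array.offset_mm]
        )
    df = pd.DataFrame(rows, columns=_LAYOUT_COLUMNS)
    _atomic_write_text(path, df.to_csv(sep="\t", index=False))


def load_sensor_layout(path, fiducials: dict | None = None) -> SensorArray:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in _LAYOUT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"sensor layout missing column(s): {', '.join(missing)}")
    n_axes = int(df["n_axes"].iloc[0])
    positions = df[["x", "y", "z"]].to_numpy(float)
    axes = df[[f"ax{k}{c}" for k in (1, 2, 3) for c in "xyz"]].to_numpy(float)
    axes = axes.reshape(-1, 3, 3)[:, :n_axes, :]
    if fiducials is None:
        # nominal fiducials on the bounding sphere (layouts do not carry them)
        r = np.linalg.norm(positions, axis=1).mean()
        fiducials = {
            "nasion": np.array([0.0, r, 0.0]),
            "lpa": np.array([-r, 0.0, 0.0]),
            "rpa": np.array([r, 0.0, 0.0]),
        }
    return SensorArray(
        positions=positions,
        radial_axes=axes[:, 0, :].copy(),
        channel_axes=axes,
        offset_mm=float(df["offset_mm"].iloc[0]),
        fiducials=fiducials,
    )


# ---------------------------------------------------------------------------
# datasets and lead fields


def save_dataset(dataset: TrialDataset, path) -> None:
    np.savez_compressed(
        path,
        data=dataset.data,
        fs=dataset.fs,
        times=dataset.times,
        channel_ids=np.array(dataset.channel_ids),
        ground_truth=json.dumps(dataset.ground_truth),
        noise_record=json.dumps(dataset.noise_record),
    )


def load_dataset(path) -> TrialDataset:
    with np.load(path, allow_pickle=False) as z:
        noise = json.loads(str(z["noise_record"]))
        return TrialDataset(
            data=z["data"],
            fs=float(z["fs"]),
            times=z["times"],
            channel_ids=[str(c) for c in z["channel_ids"]],
            ground_truth=json.loads(str(z["ground_truth"])),
            noise_record=noise,
        )


def save_leadfield(lf: LeadField, path) -> None:
    np.savez_compressed(
        path,
        gain=lf.gain,
        channel_ids=np.array(lf.channel_ids),
        source_positions=lf.source_positions,
        source_orientations=lf.source_orientations,
        surface_label=lf.surface_label,
        metadata=json.dumps(lf.metadata),
    )


def load_leadfield(path) -> LeadField:
    with np.load(path, allow_pickle=False) as z:
        return LeadField(
            gain=z["gain"],
            channel_ids=[str(c) for c in z["channel_ids"]],
            source_positions=z["source_positions"],
            source_orientations=z["source_orientations"],
            surface_label=str(z["surface_label"]),
            metadata=json.loads(str(z["metadata"])),
        )
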