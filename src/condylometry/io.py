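"""File I/O: meshes (STL/PLY/OBJ via trimesh), landmark JSON, CSV tables,
YAML specs, and run manifests."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import trimesh
import yaml

from .errors import ConfigError, LandmarkError

MESH_SUFFIXES = (".stl", ".ply", ".obj")


def load_mesh(path) -> trimesh.Trimesh:
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"mesh file not found: {path}")
    mesh = trimesh.load(str(path), force="mesh")
    if not isinstance(mesh, trimesh.Trimesh) or len(mesh.faces) == 0:
        raise ConfigError(f"could not read a triangle mesh from {path}")
    return mesh


def save_mesh(mesh: trimesh.Trimesh, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    mesh.export(str(path))
    return path


def load_landmarks(path) -> dict:
    """Landmark JSON: ``{name: [x, y, z]}`` in mm."""
    path = Path(path)
    if not path.exists():
        raise LandmarkError(f"landmark file not found: {path}")
    try:
        with open(path) as fh:
            raw = json.load(fh)
    except json.JSONDecodeError as exc:
        raise LandmarkError(f"malformed landmark file {path}: {exc}") from exc
    if not isinstance(raw, dict):
        raise LandmarkError(f"malformed landmark file {path}: expected an "
                            "object of name -> [x, y, z]")
    out = {}
    for name, coords in raw.items():
        arr = np.asarray(coords, dtype=float)
        if arr.shape != (3,) or not np.all(np.isfinite(arr)):
            raise LandmarkError(
                f"malformed landmark {name!r} in {path}: need 3 finite "
                "coordinates")
        out[str(name)] = arr
    return out


def save_landmarks(landmarks: dict, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump({k: [float(x) for x in np.asarray(v)]
                   for k, v in landmarks.items()}, fh, indent=1)
    return path


def load_table(path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"table not found: {path}")
    return pd.read_csv(path)


def save_table(df: pd.DataFrame, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format="%.10g")
    return path


def load_yaml(path) -> dict:
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"file not found: {path}")
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return data or {}


def save_yaml(obj: dict, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        yaml.safe_dump(obj, fh, sort_keys=True)
    return path


def sha256_of_file(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def sha256_of_text(text: str) -> str:
    return hashlib.sha256(text.encode()).hexdigest()
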