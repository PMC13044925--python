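"""Volume I/O (MRC/CCP4 via gemmi), angle sidecars and YAML configs.

Axis convention: in-memory volumes are ``(z, y, x)`` ndarrays; on disk the
map grid is stored in the MRC fast-to-slow order ``(x, y, z)``, so arrays
are transposed on the way in and out.  Float32 voxel values round-trip
bitwise.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import platform
from pathlib import Path

import gemmi
import numpy as np
import yaml

__all__ = [
    "read_mrc",
    "write_mrc",
    "read_angles",
    "write_angles",
    "load_config",
    "provenance_record",
]


def read_mrc(path) -> tuple[np.ndarray, dict]:
    """Read a volume; returns ``(data (z,y,x), header info)``."""
    path = Path(path)
    try:
        m = gemmi.read_ccp4_map(str(path))
    except Exception as e:  # noqa: BLE001 - re-raise with file context
        raise ValueError(f"cannot read MRC map {path}: {e}") from e
    grid = np.array(m.grid, copy=True)  # (x, y, z)
    cell = m.grid.unit_cell
    nx, ny, nz = m.grid.shape
    header = {
        "voxel_size": (cell.a / nx if nx else 1.0,
                       cell.b / ny if ny else 1.0,
                       cell.c / nz if nz else 1.0),
        "shape": (nz, ny, nx),
        "path": str(path),
    }
    return np.ascontiguousarray(grid.transpose(2, 1, 0)), header


def write_mrc(volume: np.ndarray, path, voxel_size: float | tuple = 1.0) -> None:
    """Write a float32 volume as an MRC/CCP4 map."""
    v = np.asarray(volume)
    if v.ndim != 3:
        raise ValueError(f"expected a 3D volume, got shape {v.shape}")
    v = np.ascontiguousarray(v.astype(np.float32).transpose(2, 1, 0))  # (x,y,z)
    vs = (voxel_size,) * 3 if np.isscalar(voxel_size) else tuple(voxel_size)
    m = gemmi.Ccp4Map()
    m.grid = gemmi.FloatGrid(v)
    nx, ny, nz = m.grid.shape
    m.grid.unit_cell = gemmi.UnitCell(vs[2] * nx, vs[1] * ny, vs[0] * nz, 90, 90, 90)
    m.grid.spacegroup = gemmi.SpaceGroup("P1")
    m.update_ccp4_header()
    m.write_ccp4_map(str(path))


def read_tilt_stack(path) -> tuple[np.ndarray, dict]:
    """Read a projection stack; section count = number of projections."""
    data, header = read_mrc(path)
    return data, header  # (n_sections, ny, nx)


def write_angles(angles, path) -> None:
    Path(path).write_text("".join(f"{float(a):.4f}\n" for a in angles))


def read_angles(path) -> np.ndarray:
    lines = [ln.strip() for ln in Path(path).read_text().splitlines() if ln.strip()]
    return np.array([float(x) for x in lines])


def load_config(path, allowed_keys: set[str]) -> dict:
    """Strict YAML config: unknown keys are an error."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError(f"config {path} must be a mapping")
    unknown = set(cfg) - allowed_keys
    if unknown:
        raise ValueError(
            f"unknown config keys in {path}: {sorted(unknown)}; "
            f"allowed: {sorted(allowed_keys)}"
        )
    return cfg


def provenance_record(seed: int, config: dict) -> dict:
    """Machine-readable record of a run: config hash, seed, versions."""
    def _clean(o):
        if dataclasses.is_dataclass(o) and not isinstance(o, type):
            return _clean(dataclasses.asdict(o))
        if isinstance(o, dict):
            return {k: _clean(v) for k, v in o.items()}
        if isinstance(o, (list, tuple)):
            return [_clean(v) for v in o]
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.integer, np.floating)):
            return o.item()
        return o

    clean = _clean(config)
    blob = json.dumps(clean, sort_keys=True, default=str).encode()
    import equitomo

    return {
        "seed": int(seed),
        "config": clean,
        "config_sha256": hashlib.sha256(blob).hexdigest(),
        "versions": {
            "equitomo": equitomo.__version__,
            "numpy": np.__version__,
            "gemmi": gemmi.__version__,
            "python": platform.python_version(),
        },
    }
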