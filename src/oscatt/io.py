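"""Artifact writers: CSV grids, phase tables, label maps, and the run
manifest (resolved config plus content hashes of every output)."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, is_dataclass
from pathlib import Path

import numpy as np
from PIL import Image

__all__ = [
    "write_grid_csv",
    "write_phases_csv",
    "write_label_map",
    "write_manifest",
    "save_image",
]


def _jsonable(obj):
    if is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(asdict(obj))
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj


def write_grid_csv(path: Path | str, grid: np.ndarray, fmt: str = "%.8g") -> Path:
    """An (M, N) map as a plain CSV grid (no header)."""
    path = Path(path)
    np.savetxt(path, np.asarray(grid), delimiter=",", fmt=fmt)
    return path


def write_phases_csv(path: Path | str, times: np.ndarray, phases: np.ndarray,
                     shape: tuple[int, int]) -> Path:
    """Phase traces in long format: time,row,col,psi."""
    path = Path(path)
    m, n = shape
    rows, cols = np.divmod(np.arange(m * n), n)
    with open(path, "w") as fh:
        fh.write("time,row,col,psi\n")
        for ti, t in enumerate(times):
            for p in range(m * n):
                fh.write(f"{t:.4f},{rows[p]},{cols[p]},{phases[ti, p]:.6f}\n")
    return path


def write_label_map(path_png: Path | str, labels: np.ndarray) -> Path:
    """Label grid as a PNG with one gray level per label."""
    labels = np.asarray(labels)
    n = max(int(labels.max()), 1)
    gray = (labels * (255 // n)).astype(np.uint8)
    Image.fromarray(gray, mode="L").save(path_png)
    return Path(path_png)


def save_image(path: Path | str, image: np.ndarray) -> Path:
    Image.fromarray(np.asarray(image)).save(path)
    return Path(path)


def write_manifest(path: Path | str, config, outputs: list[Path]) -> Path:
    """JSON manifest: resolved config and sha256 content hash per output."""
    path = Path(path)
    hashes = {}
    for p in outputs:
        p = Path(p)
        hashes[p.name] = hashlib.sha256(p.read_bytes()).hexdigest()
    path.write_text(json.dumps({"config": _jsonable(config), "outputs": hashes}, indent=2))
    return path
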