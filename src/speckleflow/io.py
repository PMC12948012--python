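"""Stack I/O, run manifests and the bundle container.

Single stacks travel as multi-page float32 TIFF with a JSON sidecar
(trajectory, optics, role, units); training bundles use HDF5 (many small
arrays plus metadata).  Every CLI run writes exactly one manifest with a
config hash that is stable under key reordering.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

from speckleflow import __version__
from speckleflow.forward import PatternStack, ScanTrajectory

__all__ = [
    "read_stack",
    "write_stack",
    "write_maps",
    "read_maps",
    "RunManifest",
    "config_hash",
]


def write_stack(stack: PatternStack, path: str | Path) -> None:
    """Multi-page float32 TIFF plus JSON sidecar; lossless for float32."""
    path = Path(path)
    tifffile.imwrite(path, np.asarray(stack.frames, dtype=np.float32), photometric="minisblack")
    sidecar = {
        "role": stack.role,
        "trajectory": stack.trajectory.to_dict(),
        "meta": stack.meta,
        "units": {"offsets": "um", "intensity": "normalized"},
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=2))


def read_stack(path: str | Path) -> PatternStack:
    """Read a multi-page TIFF stack; integer pages are promoted to float32
    with the scale recorded in the metadata."""
    path = Path(path)
    with tifffile.TiffFile(path) as tif:
        shapes = [p.shape for p in tif.pages]
        for i, s in enumerate(shapes):
            if s != shapes[0]:
                raise ValueError(
                    f"ragged TIFF: page {i + 1} has shape {s}, expected {shapes[0]}"
                )
        frames = tif.asarray()
    if frames.ndim == 2:
        frames = frames[None]
    meta: dict = {}
    if np.issubdtype(frames.dtype, np.integer):
        meta["promoted_from"] = str(frames.dtype)
        meta["integer_scale"] = 1.0
        frames = frames.astype(np.float32)
    sidecar_path = path.with_suffix(path.suffix + ".json")
    if sidecar_path.exists():
        sidecar = json.loads(sidecar_path.read_text())
        trajectory = ScanTrajectory.from_dict(sidecar["trajectory"])
        role = sidecar.get("role", "reference")
        meta.update(sidecar.get("meta", {}))
    else:
        trajectory = ScanTrajectory(np.zeros((len(frames), 2)))
        role = "reference"
    return PatternStack(frames=frames, trajectory=trajectory, role=role, meta=meta)


def write_maps(maps: dict[str, np.ndarray], path: str | Path) -> None:
    """Named 2D maps as a multi-page float32 TIFF with page names in a sidecar."""
    path = Path(path)
    names = list(maps)
    tifffile.imwrite(path, np.stack([maps[n] for n in names]).astype(np.float32), photometric="minisblack")
    path.with_suffix(path.suffix + ".json").write_text(json.dumps({"pages": names}))


def read_maps(path: str | Path) -> dict[str, np.ndarray]:
    path = Path(path)
    pages = tifffile.imread(path)
    if pages.ndim == 2:
        pages = pages[None]
    names = json.loads(path.with_suffix(path.suffix + ".json").read_text())["pages"]
    return {n: pages[i] for i, n in enumerate(names)}


def config_hash(config: dict) -> str:
    """Hash of a JSON-serializable config, stable under key reordering."""
    canon = json.dumps(config, sort_keys=True, separators=(",", ":"), default=str)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


@dataclass
class RunManifest:
    command: str
    config: dict
    seed: int | None = None
    inputs: list[str] = field(default_factory=list)
    outputs: list[str] = field(default_factory=list)
    version: str = __version__
    timestamp: float = field(default_factory=time.time)

    def to_dict(self) -> dict:
        return {
            "tool_version": self.version,
            "command": self.command,
            "config": self.config,
            "config_hash": config_hash(self.config),
            "seed": self.seed,
            "inputs": self.inputs,
            "outputs": self.outputs,
            "timestamp": self.timestamp,
        }

    def write(self, out_dir: str | Path) -> Path:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        path = out_dir / f"manifest_{self.command}.json"
        path.write_text(json.dumps(self.to_dict(), indent=2))
        return path
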