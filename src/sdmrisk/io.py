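"""Raster, point and report I/O plus provenance manifests.

Raster stacks are written as one single-band TIFF per layer (float32,
NaN nodata) beside a JSON manifest holding the planar-km geometry
(origin, cell size), the layer -> file map and registry metadata. Integer
maps (binary, change codes) round-trip bitwise; suitability layers within
float32 resolution.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .grid import EnvStack, RasterGrid
from .occurrences import OccurrenceSet

MANIFEST_NAME = "stack_manifest.json"


def write_grid(grid: RasterGrid, path: Path) -> None:
    vals = np.asarray(grid.values, dtype=np.float32).copy()
    vals[~grid.mask] = np.nan
    tifffile.imwrite(str(path), vals)


def read_grid(path: Path, cell_km: float = 1.0,
              origin: tuple[float, float] = (0.0, 0.0)) -> RasterGrid:
    vals = tifffile.imread(str(path)).astype(float)
    return RasterGrid(vals, cell_km, origin)


def write_stack(stack: EnvStack, directory: Path) -> Path:
    """Write a stack as per-layer TIFFs plus a JSON manifest; returns manifest path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest = {
        "cell_km": stack.cell_km,
        "origin": list(stack.origin),
        "shape": list(stack.shape),
        "layers": {},
        "registry": stack.registry,
    }
    for name in stack.names:
        fname = f"layer_{name}.tif"
        write_grid(stack[name], directory / fname)
        manifest["layers"][name] = fname
    path = directory / MANIFEST_NAME
    # layer order is meaningful; keep insertion order
    path.write_text(json.dumps(manifest, indent=2))
    return path


def read_stack(manifest_path: Path) -> EnvStack:
    manifest_path = Path(manifest_path)
    manifest = json.loads(manifest_path.read_text())
    directory = manifest_path.parent
    layers = {}
    for name, fname in manifest["layers"].items():
        fpath = directory / fname
        if not fpath.exists():
            raise FileNotFoundError(f"stack manifest references missing layer "
                                    f"{name!r} ({fname})")
        layers[name] = tifffile.imread(str(fpath)).astype(float)
    shapes = {a.shape for a in layers.values()}
    if len(shapes) > 1:
        bad = {n: layers[n].shape for n in layers}
        raise ValueError(f"layer grids disagree in shape: {bad}")
    return EnvStack(layers, manifest["cell_km"], tuple(manifest["origin"]),
                    registry=manifest.get("registry", {}))


def write_occurrences(occ: OccurrenceSet, path: Path) -> None:
    occ.to_frame().to_csv(path, index=False)


def read_occurrences(path: Path) -> OccurrenceSet:
    """Read a species,x,y[,source] CSV, reporting bad rows by line number."""
    df = pd.read_csv(path, dtype=str)
    required = {"species", "x", "y"}
    if not required <= set(df.columns):
        raise ValueError(f"occurrence CSV needs columns {sorted(required)}")
    xs, ys = [], []
    for i, row in df.iterrows():
        try:
            xs.append(float(row["x"]))
            ys.append(float(row["y"]))
        except (TypeError, ValueError) as exc:
            # +2: header line plus 1-based numbering
            raise ValueError(
                f"{path}: non-numeric coordinate on row {i + 2}") from exc
    src = list(df["source"]) if "source" in df.columns else []
    return OccurrenceSet(str(df["species"].iloc[0]) if len(df) else "unknown",
                         np.column_stack([xs, ys]) if xs else np.empty((0, 2)),
                         src)


def sha256_of(path: Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def write_manifest(outdir: Path, config: dict, extra: dict | None = None) -> Path:
    """Provenance manifest: config hash, seeds and a hash of every artifact."""
    outdir = Path(outdir)
    files = {
        str(p.relative_to(outdir)): sha256_of(p)
        for p in sorted(outdir.rglob("*"))
        if p.is_file() and p.name != "provenance.json"
    }
    payload = {
        "config": config,
        "config_sha256": hashlib.sha256(
            json.dumps(config, sort_keys=True).encode()).hexdigest(),
        "files": files,
    }
    if extra:
        payload.update(extra)
    path = outdir / "provenance.json"
    path.write_text(json.dumps(payload, indent=2, sort_keys=True))
    return path
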