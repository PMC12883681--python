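"""NIfTI/TSV/YAML readers and writers, atlas label lookup, run provenance.

All volumes are NIfTI-1 (optionally gzipped) via nibabel; tables are TSV;
configuration and provenance sidecars are YAML.  Voxel indices are 0-based
internally and all reported peak coordinates are world mm via the affine.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .grid import AFFINE_ATOL, GridMismatchError, VolumeGrid

__all__ = [
    "AtlasVolume",
    "read_volume",
    "write_volume",
    "read_mask",
    "read_atlas",
    "write_atlas",
    "lookup_labels",
    "write_provenance",
]

#: atlas regions covering less than this fraction of a cluster are not reported
LABEL_REPORTING_FLOOR = 0.05


@dataclass
class AtlasVolume:
    """Integer-label region volume plus a label -> region-name table."""

    labels: np.ndarray = field(repr=False)
    names: dict[int, str] = field(default_factory=dict)
    grid: VolumeGrid = None

    def __post_init__(self) -> None:
        lab = np.asarray(self.labels)
        if not np.issubdtype(lab.dtype, np.integer):
            rounded = np.round(lab)
            if not np.array_equal(rounded, lab):
                raise ValueError("atlas labels must be integers")
            lab = rounded.astype(np.int32)
        if lab.min() < 0:
            raise ValueError("atlas labels must be non-negative (0 = background)")
        present = set(np.unique(lab).tolist()) - {0}
        missing = present - set(self.names)
        if missing:
            raise ValueError(f"labels missing from the name table: {sorted(missing)}")
        self.labels = lab


def _grid_from_img(img) -> VolumeGrid:
    return VolumeGrid(tuple(int(s) for s in img.shape[:3]), np.asarray(img.affine, dtype=float))


def read_volume(
    path, expect_ndim: int | None = None, reference_grid: VolumeGrid | None = None
):
    """Read a NIfTI volume; returns (data, grid).

    ``expect_ndim`` (3 or 4) enforces dimensionality with a typed error;
    ``reference_grid`` enforces grid identity within 1e-6 on the affine
    (inputs must be pre-aligned — registration is out of scope).
    """
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    if expect_ndim is not None and data.ndim != expect_ndim:
        raise ValueError(f"{path}: expected a {expect_ndim}D volume, got {data.ndim}D")
    grid = _grid_from_img(img)
    if reference_grid is not None:
        if grid.shape != reference_grid.shape or not np.allclose(
            grid.affine, reference_grid.affine, atol=AFFINE_ATOL, rtol=0.0
        ):
            raise GridMismatchError(f"grid mismatch: {path} is not on the reference grid")
    return data, grid


def write_volume(path, data: np.ndarray, grid: VolumeGrid, dtype=None) -> None:
    data = np.asarray(data)
    if dtype is not None:
        data = data.astype(dtype)
    img = nib.Nifti1Image(data, grid.affine)
    nib.save(img, str(path))


def read_mask(path, reference_grid: VolumeGrid | None = None):
    """Read a binary 3D mask; non-binary values are a counted, typed error."""
    data, grid = read_volume(path, expect_ndim=3, reference_grid=reference_grid)
    bad = ~np.isin(data, (0, 1))
    if bad.any():
        raise ValueError(f"{path}: mask contains {int(bad.sum())} non-binary values")
    return data.astype(np.uint8), grid


def read_atlas(volume_path, names_path, reference_grid: VolumeGrid | None = None) -> AtlasVolume:
    """Atlas = integer label NIfTI + two-column TSV (label, name)."""
    data, grid = read_volume(volume_path, expect_ndim=3, reference_grid=reference_grid)
    table = pd.read_csv(names_path, sep="\t")
    names = dict(zip(table["label"].astype(int), table["name"].astype(str)))
    return AtlasVolume(labels=data, names=names, grid=grid)


def write_atlas(atlas: AtlasVolume, volume_path, names_path) -> None:
    write_volume(volume_path, atlas.labels, atlas.grid, dtype=np.int16)
    pd.DataFrame(
        {"label": list(atlas.names), "name": list(atlas.names.values())}
    ).to_csv(names_path, sep="\t", index=False)


def lookup_labels(
    cluster_voxels: np.ndarray, atlas: AtlasVolume, floor: float = LABEL_REPORTING_FLOOR
) -> list[tuple[str, float]]:
    """Atlas regions overlapping a cluster, as (name, fraction), sorted descending.

    ``cluster_voxels`` is a boolean volume on the atlas grid.  Regions
    covering less than ``floor`` of the cluster (default 5%) are omitted;
    background (label 0) is never reported.
    """
    cluster_voxels = np.asarray(cluster_voxels, dtype=bool)
    if cluster_voxels.shape != atlas.labels.shape:
        raise GridMismatchError("cluster volume does not match the atlas grid")
    n = int(cluster_voxels.sum())
    if n == 0:
        raise ValueError("empty cluster")
    inside = atlas.labels[cluster_voxels]
    counts = np.bincount(inside)
    out = []
    for label in np.nonzero(counts)[0]:
        if label == 0:
            continue
        frac = counts[label] / n
        if frac >= floor:
            out.append((atlas.names[int(label)], float(frac)))
    out.sort(key=lambda item: item[1], reverse=True)
    return out


def write_provenance(path, config: dict, seed: int | None = None) -> None:
    """YAML sidecar with the full configuration, its hash and library versions."""
    import scipy

    payload = {
        "config": config,
        "seed": seed,
        "config_sha256": hashlib.sha256(
            yaml.safe_dump(config, sort_keys=True).encode()
        ).hexdigest(),
        "versions": {
            "numpy": np.__version__,
            "scipy": scipy.__version__,
            "nibabel": nib.__version__,
            "pandas": pd.__version__,
        },
    }
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))
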