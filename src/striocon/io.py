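"""File I/O: NIfTI volumes, TSV tables, YAML configuration, provenance.

NIfTI is handled through nibabel; the voxel->world affine is stored in the
sform. Label volumes get an optional sidecar ``<stem>_legend.tsv`` with
``label`` / ``name`` columns. Connectivity tables are TSV with columns
``i j k`` followed by one column per target group.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .core import (
    AnalysisParams,
    ConnectivityTable,
    GridError,
    LabelVolume,
    ProbabilityVolume,
    VolumeGrid,
)

__all__ = [
    "read_label_volume",
    "write_label_volume",
    "read_probability_volume",
    "write_probability_volume",
    "read_connectivity_table",
    "write_connectivity_table",
    "load_params",
    "save_params",
    "write_provenance",
]


def _grid_from_img(img: nib.Nifti1Image, space: str, hemisphere: str) -> VolumeGrid:
    affine = np.asarray(img.affine, dtype=float)
    if abs(np.linalg.det(affine[:3, :3])) < 1e-12:
        raise GridError("NIfTI affine is not invertible")
    return VolumeGrid(
        shape=tuple(int(s) for s in img.shape[:3]),
        affine=affine,
        space=space,
        hemisphere=hemisphere,
    )


def _legend_path(path: Path) -> Path:
    stem = path.name
    for suffix in (".nii.gz", ".nii"):
        if stem.endswith(suffix):
            stem = stem[: -len(suffix)]
            break
    return path.with_name(stem + "_legend.tsv")


def read_label_volume(
    path, space: str = "phantom", hemisphere: str = "right"
) -> LabelVolume:
    """Read an integer-valued NIfTI label volume (legend sidecar if present)."""
    path = Path(path)
    img = nib.load(path)
    data = np.asanyarray(img.dataobj)
    as_int = np.rint(data).astype(np.int32)
    if not np.allclose(data, as_int, atol=1e-6):
        raise ValueError(f"{path} does not contain integer-valued data")
    legend: dict[int, str] = {}
    sidecar = _legend_path(path)
    if sidecar.exists():
        tab = pd.read_csv(sidecar, sep="\t")
        legend = dict(zip(tab["label"].astype(int), tab["name"].astype(str)))
    return LabelVolume(_grid_from_img(img, space, hemisphere), as_int, legend)


def write_label_volume(vol: LabelVolume, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    nib.Nifti1Image(vol.labels.astype(np.int32), vol.grid.affine).to_filename(path)
    if vol.legend:
        tab = pd.DataFrame(
            sorted(vol.legend.items()), columns=["label", "name"]
        )
        tab.to_csv(_legend_path(path), sep="\t", index=False)
    return path


def read_probability_volume(
    path, space: str = "phantom", hemisphere: str = "right", is_probability: bool = True
) -> ProbabilityVolume:
    path = Path(path)
    img = nib.load(path)
    data = np.asanyarray(img.dataobj).astype(float)
    return ProbabilityVolume(
        _grid_from_img(img, space, hemisphere), data, is_probability=is_probability
    )


def write_probability_volume(vol: ProbabilityVolume, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    nib.Nifti1Image(vol.values.astype(np.float64), vol.grid.affine).to_filename(path)
    return path


def read_connectivity_table(path, grid: VolumeGrid) -> ConnectivityTable:
    """Read a seed-voxel x target-group TSV against a known grid.

    Raises a validation error on negative counts or out-of-grid voxel
    indices; an empty body yields a valid zero-seed table.
    """
    path = Path(path)
    tab = pd.read_csv(path, sep="\t")
    required = ["i", "j", "k"]
    missing = [c for c in required if c not in tab.columns]
    if missing:
        raise ValueError(f"{path}: missing voxel index columns {missing}")
    groups = [c for c in tab.columns if c not in required + ["streamlines_per_seed"]]
    seeds = tab[required].to_numpy(dtype=np.intp).reshape(-1, 3)
    counts = tab[groups].to_numpy(dtype=float).reshape(len(seeds), len(groups))
    if counts.size and counts.min() < 0:
        raise ValueError(f"{path}: negative streamline count")
    if len(seeds) and not grid.contains(seeds).all():
        raise ValueError(f"{path}: seed voxel index outside grid {grid.shape}")
    sps = (
        int(tab["streamlines_per_seed"].iloc[0])
        if "streamlines_per_seed" in tab.columns and len(tab)
        else 0
    )
    return ConnectivityTable(
        grid=grid,
        seed_voxels=seeds,
        target_groups=tuple(groups),
        counts=counts,
        streamlines_per_seed=sps,
    )


def write_connectivity_table(conn: ConnectivityTable, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tab = pd.DataFrame(conn.seed_voxels, columns=["i", "j", "k"])
    for g_idx, g in enumerate(conn.target_groups):
        tab[g] = conn.counts[:, g_idx]
    tab["streamlines_per_seed"] = conn.streamlines_per_seed
    tab.to_csv(path, sep="\t", index=False)
    return path


def load_params(path) -> AnalysisParams:
    """Load analysis parameters from YAML; absent keys keep their defaults."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    known = {f.name for f in dataclasses.fields(AnalysisParams)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown parameter keys: {sorted(unknown)}")
    return AnalysisParams(**raw)


def save_params(params: AnalysisParams, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    payload = dataclasses.asdict(params)
    payload["core_fractions"] = list(params.core_fractions)
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=True)
    return path


def write_provenance(out_dir, *, params: AnalysisParams, seed: int, extra=None) -> Path:
    """Machine-readable run record: parameters, RNG seed, versions."""
    import nibabel
    import scipy

    from . import __version__

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    payload = {
        "params": json.loads(json.dumps(dataclasses.asdict(params), default=list)),
        "rng_seed": int(seed),
        "versions": {
            "striocon": __version__,
            "numpy": np.__version__,
            "scipy": scipy.__version__,
            "pandas": pd.__version__,
            "nibabel": nibabel.__version__,
        },
    }
    if extra:
        payload.update(extra)
    path = out_dir / "provenance.json"
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
    return path
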