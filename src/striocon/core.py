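"""Core spatial containers shared by every stage of the pipeline.

All phantom volumes live on a single grid (one space, no registration), so a
volume is an array plus a :class:`VolumeGrid` describing voxel geometry.
World coordinates follow the MNI axis convention: +x right, +y anterior,
+z superior.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "VolumeGrid",
    "LabelVolume",
    "ProbabilityVolume",
    "ConnectivityTable",
    "CompartmentMaskPair",
    "BaitGrouping",
    "AnalysisParams",
]


class GridError(ValueError):
    """Raised when grid geometry is invalid or two grids disagree."""


@dataclass(frozen=True)
class VolumeGrid:
    """Voxel lattice with an affine voxel->world (mm) transform.

    Parameters
    ----------
    shape
        Voxel counts along (i, j, k); every entry must be >= 1.
    affine
        4x4 invertible transform mapping voxel indices to world mm.
    space
        ``"phantom"`` or ``"standard"``.
    hemisphere
        ``"left"``, ``"right"`` or ``"bilateral"``.
    """

    shape: tuple[int, int, int]
    affine: np.ndarray
    space: str = "phantom"
    hemisphere: str = "right"

    def __post_init__(self) -> None:
        shape = tuple(int(s) for s in self.shape)
        object.__setattr__(self, "shape", shape)
        if len(shape) != 3 or any(s < 1 for s in shape):
            raise GridError(f"shape must be three entries >= 1, got {shape}")
        aff = np.asarray(self.affine, dtype=float)
        if aff.shape != (4, 4):
            raise GridError("affine must be 4x4")
        if abs(np.linalg.det(aff[:3, :3])) < 1e-12:
            raise GridError("affine is not invertible")
        object.__setattr__(self, "affine", aff)
        if self.space not in ("phantom", "standard"):
            raise GridError(f"unknown space tag {self.space!r}")
        if self.hemisphere not in ("left", "right", "bilateral"):
            raise GridError(f"unknown hemisphere tag {self.hemisphere!r}")

    @property
    def voxel_size(self) -> tuple[float, float, float]:
        return tuple(float(v) for v in np.sqrt((self.affine[:3, :3] ** 2).sum(axis=0)))

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.shape))

    def voxel_to_world(self, ijk: np.ndarray) -> np.ndarray:
        """World-mm coordinates of voxel centers, shape (..., 3)."""
        ijk = np.asarray(ijk, dtype=float)
        return ijk @ self.affine[:3, :3].T + self.affine[:3, 3]

    def contains(self, ijk: np.ndarray) -> np.ndarray:
        ijk = np.atleast_2d(np.asarray(ijk))
        ok = np.ones(len(ijk), dtype=bool)
        for ax in range(3):
            ok &= (ijk[:, ax] >= 0) & (ijk[:, ax] < self.shape[ax])
        return ok

    def same_geometry(self, other: "VolumeGrid", atol: float = 1e-6) -> bool:
        return self.shape == other.shape and np.allclose(
            self.affine, other.affine, atol=atol
        )

    def require_same(self, other: "VolumeGrid") -> None:
        if not self.same_geometry(other):
            raise GridError("grids differ in shape or affine")


def _check_grid_array(grid: VolumeGrid, data: np.ndarray) -> np.ndarray:
    data = np.asarray(data)
    if data.shape != grid.shape:
        raise GridError(
            f"data shape {data.shape} does not match grid shape {grid.shape}"
        )
    return data


@dataclass(frozen=True)
class LabelVolume:
    """Integer label field on a grid; label 0 is background."""

    grid: VolumeGrid
    labels: np.ndarray
    legend: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        labels = _check_grid_array(self.grid, self.labels)
        if not np.issubdtype(labels.dtype, np.integer):
            as_int = labels.astype(np.int32)
            if not np.array_equal(as_int, labels):
                raise ValueError("label data is not integer valued")
            labels = as_int
        object.__setattr__(self, "labels", labels)
        present = set(np.unique(labels).tolist()) - {0}
        legend = dict(self.legend)
        for lab in sorted(present):
            legend.setdefault(int(lab), f"region_{int(lab)}")
        object.__setattr__(self, "legend", legend)

    def voxels_of(self, label: int) -> np.ndarray:
        """(n, 3) voxel indices carrying ``label``, in lexicographic order."""
        return np.argwhere(self.labels == label)

    def mask_of(self, label: int) -> np.ndarray:
        return self.labels == label


@dataclass(frozen=True)
class ProbabilityVolume:
    """Per-voxel non-negative values; NaN marks voxels outside the domain.

    With ``is_probability=True`` finite values must lie in [0, 1].
    """

    grid: VolumeGrid
    values: np.ndarray
    is_probability: bool = True

    def __post_init__(self) -> None:
        values = _check_grid_array(self.grid, self.values).astype(float)
        finite = values[np.isfinite(values)]
        if finite.size and finite.min() < -1e-12:
            raise ValueError("probability/amplitude values must be >= 0")
        if self.is_probability and finite.size and finite.max() > 1 + 1e-9:
            raise ValueError("probability values must be <= 1")
        object.__setattr__(self, "values", values)

    @property
    def defined_mask(self) -> np.ndarray:
        return np.isfinite(self.values)

    def with_values(self, values: np.ndarray, **kw) -> "ProbabilityVolume":
        return replace(self, values=values, **kw)


def _voxel_array(voxels) -> np.ndarray:
    arr = np.asarray(list(voxels) if not isinstance(voxels, np.ndarray) else voxels)
    arr = arr.reshape(-1, 3).astype(np.intp)
    return arr


def sort_voxels(voxels: np.ndarray) -> np.ndarray:
    """Lexicographic (i, j, k) ordering — the canonical deterministic order."""
    arr = _voxel_array(voxels)
    order = np.lexsort((arr[:, 2], arr[:, 1], arr[:, 0]))
    return arr[order]


def voxel_set(voxels: np.ndarray) -> set[tuple[int, int, int]]:
    return {tuple(int(x) for x in v) for v in _voxel_array(voxels)}


@dataclass(frozen=True)
class ConnectivityTable:
    """Seed-voxel x target-group streamline counts (classification targets).

    Counts are real-valued because distance correction rescales them; each
    seed's total may fall short of ``streamlines_per_seed`` (streamlines can
    reach no target).
    """

    grid: VolumeGrid
    seed_voxels: np.ndarray          # (n, 3) int
    target_groups: tuple[str, ...]
    counts: np.ndarray               # (n, g) float
    streamlines_per_seed: int

    def __post_init__(self) -> None:
        seeds = _voxel_array(self.seed_voxels)
        counts = np.asarray(self.counts, dtype=float).reshape(
            len(seeds), len(self.target_groups)
        )
        if counts.size and counts.min() < 0:
            raise ValueError("streamline counts must be non-negative")
        if len(seeds) and not self.grid.contains(seeds).all():
            raise ValueError("seed voxel index outside grid")
        object.__setattr__(self, "seed_voxels", seeds)
        object.__setattr__(self, "counts", counts)
        object.__setattr__(self, "target_groups", tuple(self.target_groups))

    @property
    def n_seeds(self) -> int:
        return len(self.seed_voxels)

    def group_counts(self, groups: Sequence[str]) -> np.ndarray:
        """Pooled counts over a set of target groups, one value per seed."""
        idx = [self.target_groups.index(g) for g in groups]
        return self.counts[:, idx].sum(axis=1)

    def drop_groups(self, groups: Sequence[str]) -> "ConnectivityTable":
        keep = [i for i, g in enumerate(self.target_groups) if g not in set(groups)]
        return ConnectivityTable(
            grid=self.grid,
            seed_voxels=self.seed_voxels,
            target_groups=tuple(self.target_groups[i] for i in keep),
            counts=self.counts[:, keep],
            streamlines_per_seed=self.streamlines_per_seed,
        )


@dataclass(frozen=True)
class BaitGrouping:
    """Bait regions grouped by the compartment they favor.

    Defaults follow the tract-tracing literature the parcellation leans on:
    4 striosome-favoring and 5 matrix-favoring regions (the rostral insula is
    excluded so insular connectivity can later be quantified without
    circularity).
    """

    striosome_group: tuple[str, ...] = (
        "mediodorsal_thalamus",
        "posterior_orbitofrontal",
        "basolateral_amygdala",
        "basal_operculum",
    )
    matrix_group: tuple[str, ...] = (
        "supplementary_motor",
        "primary_motor",
        "primary_sensory",
        "globus_pallidus_interna",
        "vlc_vplo_thalamus",
    )
    left_out: str | None = None

    def __post_init__(self) -> None:
        s, m = set(self.striosome_group), set(self.matrix_group)
        if not s or not m:
            raise ValueError("bait groups must be non-empty")
        if s & m:
            raise ValueError(f"bait groups overlap: {sorted(s & m)}")
        if self.left_out is not None and self.left_out in (s | m):
            raise ValueError("left_out region must be absent from both groups")
        object.__setattr__(self, "striosome_group", tuple(self.striosome_group))
        object.__setattr__(self, "matrix_group", tuple(self.matrix_group))

    @property
    def all_regions(self) -> tuple[str, ...]:
        return self.striosome_group + self.matrix_group

    def leave_out(self, region: str) -> "BaitGrouping":
        """Remove one bait region from its group (the N-1 configuration)."""
        if region in self.striosome_group:
            group = tuple(r for r in self.striosome_group if r != region)
            if not group:
                raise ValueError("cannot leave out the sole striosome-group region")
            return BaitGrouping(group, self.matrix_group, left_out=region)
        if region in self.matrix_group:
            group = tuple(r for r in self.matrix_group if r != region)
            if not group:
                raise ValueError("cannot leave out the sole matrix-group region")
            return BaitGrouping(self.striosome_group, group, left_out=region)
        raise ValueError(f"region {region!r} is in neither bait group")


@dataclass(frozen=True)
class CompartmentMaskPair:
    """Equal-volume sets of the most-biased striosome-like / matrix-like voxels."""

    grid: VolumeGrid
    striosome_like: np.ndarray   # (n, 3) int, lexicographically sorted
    matrix_like: np.ndarray
    source: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        s = sort_voxels(self.striosome_like)
        m = sort_voxels(self.matrix_like)
        if voxel_set(s) & voxel_set(m):
            raise ValueError("striosome-like and matrix-like masks overlap")
        object.__setattr__(self, "striosome_like", s)
        object.__setattr__(self, "matrix_like", m)

    @property
    def n_striosome(self) -> int:
        return len(self.striosome_like)

    @property
    def n_matrix(self) -> int:
        return len(self.matrix_like)

    def voxels(self, compartment: str) -> np.ndarray:
        if compartment == "striosome":
            return self.striosome_like
        if compartment == "matrix":
            return self.matrix_like
        raise KeyError(compartment)

    def as_label_volume(self) -> LabelVolume:
        """Binary-ish label volume: striosome-like = 1, matrix-like = 2."""
        lab = np.zeros(self.grid.shape, dtype=np.int16)
        if len(self.striosome_like):
            lab[tuple(self.striosome_like.T)] = 1
        if len(self.matrix_like):
            lab[tuple(self.matrix_like.T)] = 2
        return LabelVolume(self.grid, lab, {1: "striosome_like", 2: "matrix_like"})


@dataclass(frozen=True)
class AnalysisParams:
    """Tunable thresholds of the analysis, with the study's operating values.

    mask_fraction
        Fraction of classified striatal voxels entering each equal-volume
        mask (the "uppermost 13%" / 1.5 SD rule).
    high_bias_threshold
        Connection probability defining "highly biased" voxels.
    suprathreshold
        Normalized probability above which an insular voxel counts toward a
        compartment.
    edge_trim_sum
        Insular voxels whose striosome+matrix probability sum falls below
        this are trimmed as partial-volume edge artifacts.
    min_suprathreshold_voxels
        Minimum suprathreshold voxels per compartment for a hemisphere to
        enter group statistics.
    jitter_max
        Maximum per-plane displacement (voxels) for the neighborhood control.
    rostro_caudal_split_y
        World-mm coronal plane splitting rostral from caudal insular
        striosome clusters.
    core_fractions
        Voxel-count fractions retained when isolating bundle cores.
    n_permutations
        Sign-flip permutations for voxelwise FWE testing.
    bonferroni_family_sizes
        Named test families and their sizes.
    trending_multiplier
        Results below ``trending_multiplier x family alpha`` are "trending".
    """

    mask_fraction: float = 0.13
    high_bias_threshold: float = 0.87
    suprathreshold: float = 0.55
    edge_trim_sum: float = 0.5
    min_suprathreshold_voxels: int = 19
    jitter_max: int = 3
    rostro_caudal_split_y: float = 1.0
    core_fractions: tuple[float, ...] = (0.25, 0.50, 0.75)
    n_permutations: int = 5000
    bonferroni_family_sizes: Mapping[str, int] = field(
        default_factory=lambda: {
            "subregion_ancova": 19,
            "hemisphere_streamlines": 3,
            "leftout_regions": 2,
            "randomise": 2,
            "cog_rms": 2,
            "cog_planes": 6,
        }
    )
    trending_multiplier: float = 10.0

    def __post_init__(self) -> None:
        if not 0 < self.mask_fraction < 0.5:
            raise ValueError("mask_fraction must lie in (0, 0.5)")
        if not 0.5 < self.high_bias_threshold <= 1:
            raise ValueError("high_bias_threshold must lie in (0.5, 1]")
        if not 0.5 <= self.suprathreshold <= 1:
            raise ValueError("suprathreshold must lie in [0.5, 1]")
        if self.min_suprathreshold_voxels < 1:
            raise ValueError("min_suprathreshold_voxels must be >= 1")
        object.__setattr__(
            self, "bonferroni_family_sizes", dict(self.bonferroni_family_sizes)
        )
        object.__setattr__(self, "core_fractions", tuple(self.core_fractions))

    def family_alpha(self, family: str, alpha: float = 0.05) -> float:
        return alpha / self.bonferroni_family_sizes[family]
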