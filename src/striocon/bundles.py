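"""Extra-insular streamline bundle analysis.

Bidirectional (AB-BA) averaging of path-density maps, normalization to
maximum amplitude, voxel-count thresholded bundle cores, Dice overlap, and
per-insular-voxel streamline count statistics; the voxelwise bundle contrast
delegates FWE inference to :mod:`striocon.inference`.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .core import ProbabilityVolume, sort_voxels
from .inference import voxelwise_permutation_test

__all__ = [
    "BundleMap",
    "abba_average",
    "core_threshold",
    "dice",
    "streamline_density_stats",
    "voxelwise_bundle_contrast",
]


@dataclass(frozen=True)
class BundleMap:
    """Streamline visit-count map for one compartment-bound bundle."""

    density: ProbabilityVolume
    compartment: str
    hemisphere: str
    total_streamlines: float
    seed_volume_voxels: int

    def normalized(self) -> "BundleMap":
        """Rescale the density relative to its maximum amplitude."""
        vals = self.density.values
        peak = np.nanmax(vals) if np.isfinite(vals).any() else 0.0
        if peak <= 0:
            return self
        return replace(
            self,
            density=self.density.with_values(vals / peak, is_probability=True),
        )


def abba_average(map_ab: BundleMap, map_ba: BundleMap) -> BundleMap:
    """Voxelwise mean of the seed->target and target->seed runs."""
    if map_ab.compartment != map_ba.compartment or map_ab.hemisphere != map_ba.hemisphere:
        raise ValueError("AB and BA maps must share compartment and hemisphere")
    map_ab.density.grid.require_same(map_ba.density.grid)
    mean = 0.5 * (map_ab.density.values + map_ba.density.values)
    return BundleMap(
        density=map_ab.density.with_values(mean),
        compartment=map_ab.compartment,
        hemisphere=map_ab.hemisphere,
        total_streamlines=0.5 * (map_ab.total_streamlines + map_ba.total_streamlines),
        seed_volume_voxels=map_ab.seed_volume_voxels,
    )


def core_threshold(bundle: BundleMap, keep_fraction: float) -> np.ndarray:
    """Bundle core: the uppermost ``keep_fraction`` of nonzero voxels.

    Selection is by voxel count among nonzero voxels (not an amplitude
    cutoff): exactly ``round(keep_fraction * N_nonzero)`` highest-amplitude
    voxels, ties broken by lexicographic voxel index.  An empty map yields
    an empty mask.
    """
    if not 0 < keep_fraction <= 1:
        raise ValueError("keep_fraction must lie in (0, 1]")
    vals = np.nan_to_num(bundle.density.values, nan=0.0)
    voxels = np.argwhere(vals > 0)
    mask = np.zeros(bundle.density.grid.shape, dtype=bool)
    if not len(voxels):
        return mask
    k = int(round(keep_fraction * len(voxels)))
    if k == 0:
        return mask
    amp = vals[tuple(voxels.T)]
    order = np.lexsort((voxels[:, 2], voxels[:, 1], voxels[:, 0], -amp))
    chosen = voxels[order[:k]]
    mask[tuple(chosen.T)] = True
    return mask


def dice(mask_a: np.ndarray, mask_b: np.ndarray) -> float:
    """Dice similarity coefficient ``2|A n B| / (|A| + |B|)``; 0 if both empty."""
    mask_a = np.asarray(mask_a, dtype=bool)
    mask_b = np.asarray(mask_b, dtype=bool)
    if mask_a.shape != mask_b.shape:
        raise ValueError("masks live on different grids")
    a, b = int(mask_a.sum()), int(mask_b.sum())
    if a + b == 0:
        return 0.0
    return 2.0 * int((mask_a & mask_b).sum()) / (a + b)


def streamline_density_stats(
    striosome_count: float,
    matrix_count: float,
    insular_seed_volume: int,
) -> dict:
    """Seed-volume-normalized counts, matrix percentage, and fold ratio.

    The matrix percentage is ``matrix / (striosome + matrix)``; the fold
    ratio is striosome count over matrix count.
    """
    if insular_seed_volume <= 0:
        raise ValueError("insular seed volume must be positive")
    total = striosome_count + matrix_count
    if total <= 0:
        raise ValueError("zero total streamlines: ratio undefined")
    return {
        "striosome_per_insular_voxel": striosome_count / insular_seed_volume,
        "matrix_per_insular_voxel": matrix_count / insular_seed_volume,
        "matrix_percent": 100.0 * matrix_count / total,
        "fold_ratio_striosome_over_matrix": (
            striosome_count / matrix_count if matrix_count > 0 else np.inf
        ),
    }


def voxelwise_bundle_contrast(
    maps_strio: list[BundleMap],
    maps_matrix: list[BundleMap],
    n_permutations: int = 5000,
    alpha: float = 0.025,
    variance_smoothing_mm: float = 0.0,
    rng_seed: int = 0,
    analysis_mask: np.ndarray | None = None,
):
    """Paired voxelwise striosome-vs-matrix bundle contrast with FWE control.

    Takes one striosome-bound and one matrix-bound map per subject, forms
    per-subject difference volumes, and runs the sign-flip max-statistic
    permutation test per direction at ``alpha`` each.  Reports the fraction
    of analyzed voxels significant in each direction and the mean densities
    within each significant cluster.
    """
    if len(maps_strio) != len(maps_matrix):
        raise ValueError("unpaired bundle map lists")
    if len(maps_strio) < 8:
        raise ValueError("need at least 8 subjects for voxelwise contrast")
    grid = maps_strio[0].density.grid
    for m in maps_strio + maps_matrix:
        grid.require_same(m.density.grid)
    diffs = np.stack(
        [
            np.nan_to_num(s.density.values) - np.nan_to_num(m.density.values)
            for s, m in zip(maps_strio, maps_matrix)
        ]
    )
    result = voxelwise_permutation_test(
        diffs,
        grid=grid,
        n_permutations=n_permutations,
        alpha=alpha,
        variance_smoothing_mm=variance_smoothing_mm,
        rng_seed=rng_seed,
        analysis_mask=analysis_mask,
    )
    sig_s, sig_m = result.significant_mask_per_direction
    n_analyzed = (
        int(analysis_mask.sum()) if analysis_mask is not None else grid.n_voxels
    )
    mean_s = np.stack([np.nan_to_num(m.density.values) for m in maps_strio]).mean(axis=0)
    mean_m = np.stack([np.nan_to_num(m.density.values) for m in maps_matrix]).mean(axis=0)
    summary = {
        "fraction_significant_striosome": sig_s.sum() / n_analyzed,
        "fraction_significant_matrix": sig_m.sum() / n_analyzed,
        "fraction_significant_total": (sig_s.sum() + sig_m.sum()) / n_analyzed,
        "strio_density_in_strio_clusters": float(mean_s[sig_s].mean()) if sig_s.any() else 0.0,
        "matrix_density_in_strio_clusters": float(mean_m[sig_s].mean()) if sig_s.any() else 0.0,
        "strio_density_in_matrix_clusters": float(mean_s[sig_m].mean()) if sig_m.any() else 0.0,
        "matrix_density_in_matrix_clusters": float(mean_m[sig_m].mean()) if sig_m.any() else 0.0,
    }
    return result, summary
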