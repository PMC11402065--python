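"""Per-subregion quantification of insulo-striate compartment bias.

From the classification-targets probability pair on the insula: voxelwise
normalization with edge trimming, suprathreshold counting per insular
subregion, the volume-percent bias statistic, hemisphere-level QC, and
center-of-gravity geometry with the rostro-caudal split of the
striosome-favoring distribution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import LabelVolume, ProbabilityVolume

__all__ = [
    "normalize_probability_pair",
    "subregion_bias",
    "volume_percent",
    "hemisphere_qc",
    "cog_analysis",
    "CogResult",
    "mirror_x_world",
]


def normalize_probability_pair(
    p_strio: ProbabilityVolume,
    p_matrix: ProbabilityVolume,
    edge_trim_sum: float = 0.5,
) -> tuple[ProbabilityVolume, ProbabilityVolume, np.ndarray]:
    """Voxelwise renormalization with partial-volume edge trimming.

    Voxels whose summed probability (striosome + matrix) falls below
    ``edge_trim_sum`` are trimmed; retained voxels are rescaled so the pair
    sums to exactly 1.  Returns the normalized pair and the retained-voxel
    boolean mask; trimmed voxels carry NaN and are excluded from every
    downstream count.
    """
    p_strio.grid.require_same(p_matrix.grid)
    s = p_strio.values
    m = p_matrix.values
    total = s + m
    retained = np.isfinite(total) & (total >= edge_trim_sum)
    if not retained.any():
        raise ValueError("edge trimming removed every voxel")
    out_s = np.full(s.shape, np.nan)
    out_m = np.full(m.shape, np.nan)
    out_s[retained] = s[retained] / total[retained]
    out_m[retained] = m[retained] / total[retained]
    return (
        p_strio.with_values(out_s),
        p_matrix.with_values(out_m),
        retained,
    )


def volume_percent(n_favoring: int, n_other: int) -> float:
    """The bias statistic: ``100 * n_favoring / (n_favoring + n_other)``."""
    if n_favoring + n_other == 0:
        raise ValueError("volume percent undefined with zero suprathreshold voxels")
    return 100.0 * n_favoring / (n_favoring + n_other)


def subregion_bias(
    norm_strio: ProbabilityVolume,
    norm_matrix: ProbabilityVolume,
    insula_labels: LabelVolume,
    suprathreshold: float = 0.55,
    subject: str = "s0",
    hemisphere: str | None = None,
) -> pd.DataFrame:
    """Suprathreshold counts and volume-percent bias per insular subregion.

    For each subregion: ``n_strio`` / ``n_matrix`` count retained voxels
    whose normalized probability reaches ``suprathreshold`` for that
    compartment; ``volume_percent_matrix`` follows the volume-percent
    formula and is NaN (flagged) when both counts are zero.  The graded
    companion ``mean_p_matrix`` (mean normalized matrix probability over the
    subregion's retained voxels) is always defined and is the statistic the
    control comparisons use when suprathreshold counts binarize or vanish.
    """
    norm_strio.grid.require_same(insula_labels.grid)
    hemi = hemisphere or insula_labels.grid.hemisphere
    rows = []
    for lab in sorted(insula_labels.legend):
        in_sub = insula_labels.mask_of(lab)
        s_vals = norm_strio.values[in_sub]
        m_vals = norm_matrix.values[in_sub]
        n_s = int(np.nansum(s_vals >= suprathreshold))
        n_m = int(np.nansum(m_vals >= suprathreshold))
        vp = 100.0 * n_m / (n_s + n_m) if (n_s + n_m) > 0 else np.nan
        mean_m = float(np.nanmean(m_vals)) if np.isfinite(m_vals).any() else np.nan
        rows.append(
            {
                "subject": subject,
                "hemisphere": hemi,
                "subregion": int(lab),
                "n_strio": n_s,
                "n_matrix": n_m,
                "volume_percent_matrix": vp,
                "mean_p_matrix": 100.0 * mean_m,
                "qc_pass": True,   # provisional; hemisphere_qc may revoke
            }
        )
    return pd.DataFrame(rows)


def hemisphere_qc(
    records: pd.DataFrame, min_suprathreshold_voxels: int = 19
) -> pd.DataFrame:
    """Hemisphere-level minimum-sample criterion.

    A (subject, hemisphere) fails when its total suprathreshold count over
    all subregions falls below the minimum for either compartment; failing
    hemispheres have ``qc_pass`` set False so group statistics can exclude
    them.
    """
    out = records.copy()
    totals = records.groupby(["subject", "hemisphere"])[["n_strio", "n_matrix"]].sum()
    ok = (totals["n_strio"] >= min_suprathreshold_voxels) & (
        totals["n_matrix"] >= min_suprathreshold_voxels
    )
    key = list(zip(out["subject"], out["hemisphere"]))
    out["qc_pass"] = [bool(ok.loc[k]) for k in key]
    return out


@dataclass(frozen=True)
class CogResult:
    """Probability-weighted center of gravity for one cluster."""

    cluster: str          # matrix_whole | strio_rostral | strio_caudal
    cog: tuple[float, float, float]    # world mm
    delta_vs_matrix: tuple[float, float, float] | None
    rms_distance_vs_matrix: float | None


def mirror_x_world(world: np.ndarray) -> np.ndarray:
    """Mirror world coordinates about the mid-sagittal plane (x -> -x)."""
    out = np.asarray(world, dtype=float).copy()
    out[..., 0] *= -1
    return out


def _weighted_cog(world: np.ndarray, weights: np.ndarray) -> np.ndarray:
    return (world * weights[:, None]).sum(axis=0) / weights.sum()


def cog_analysis(
    norm_strio: ProbabilityVolume,
    norm_matrix: ProbabilityVolume,
    split_y: float = 1.0,
    mirror_left_x: bool = True,
) -> dict[str, CogResult]:
    """COG geometry of the compartment-favoring probability distributions.

    The matrix COG spans the whole insula; the striosome-favoring
    distribution is split at the coronal plane ``y = split_y`` (world mm,
    voxel centers exactly on the plane go caudal) into rostral and caudal
    clusters, each compared to the matrix COG by per-plane deltas and RMS
    distance.  Left-hemisphere coordinates are mirrored about the midline so
    hemispheres can be pooled.
    """
    norm_strio.grid.require_same(norm_matrix.grid)
    grid = norm_strio.grid

    def cluster(vol: ProbabilityVolume, region: str) -> tuple[np.ndarray, np.ndarray]:
        vals = vol.values
        mask = np.isfinite(vals) & (vals > 0)
        voxels = np.argwhere(mask)
        world = grid.voxel_to_world(voxels)
        if grid.hemisphere == "left" and mirror_left_x:
            world = mirror_x_world(world)
        w = vals[mask]
        if region == "rostral":
            sel = world[:, 1] > split_y
        elif region == "caudal":
            sel = world[:, 1] <= split_y
        else:
            sel = np.ones(len(world), dtype=bool)
        return world[sel], w[sel]

    world_m, w_m = cluster(norm_matrix, "whole")
    if w_m.sum() <= 0:
        raise ValueError("matrix-favoring distribution has no mass")
    cog_m = _weighted_cog(world_m, w_m)
    results = {
        "matrix_whole": CogResult(
            "matrix_whole", tuple(cog_m), None, None
        )
    }
    for name, region in (("strio_rostral", "rostral"), ("strio_caudal", "caudal")):
        world_s, w_s = cluster(norm_strio, region)
        if w_s.sum() <= 0:
            results[name] = CogResult(name, (np.nan,) * 3, None, None)
            continue
        cog_s = _weighted_cog(world_s, w_s)
        delta = cog_s - cog_m
        results[name] = CogResult(
            name,
            tuple(cog_s),
            tuple(delta),
            float(np.sqrt((delta**2).sum())),
        )
    return results
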