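"""Connectivity-based striatal parcellation.

Scores each striatal seed voxel by the fraction of its bait-bound streamlines
that reached striosome-favoring regions, then takes the uppermost
``mask_fraction`` of classified voxels from each of the two complementary
probability distributions to form equal-volume, disjoint masks of the
most-biased striosome-like and matrix-like voxels.  Includes the N-1 variant
(one bait region left out) and the nucleus-proportional quota variant.
"""

from __future__ import annotations

import hashlib

import numpy as np

from .core import (
    BaitGrouping,
    CompartmentMaskPair,
    ConnectivityTable,
    LabelVolume,
    ProbabilityVolume,
)

__all__ = [
    "ctt_bias_score",
    "select_equal_volume_masks",
    "n1_parcellation",
    "proportional_masks",
]


def ctt_bias_score(
    conn: ConnectivityTable, baits: BaitGrouping
) -> tuple[ProbabilityVolume, ProbabilityVolume]:
    """Per-voxel compartment connection probabilities.

    ``p_strio(v) = S(v) / (S(v) + M(v))`` where S and M pool streamline
    counts over the striosome-favoring and matrix-favoring bait groups;
    ``p_matrix = 1 - p_strio``.  Voxels with ``S + M = 0`` are unclassified
    and carry NaN (they are excluded from distributions downstream, never
    treated as 0.5).
    """
    missing = [g for g in baits.all_regions if g not in conn.target_groups]
    if missing:
        raise ValueError(f"connectivity table lacks bait target groups {missing}")
    s = conn.group_counts(baits.striosome_group)
    m = conn.group_counts(baits.matrix_group)
    total = s + m
    classified = total > 0
    if conn.n_seeds == 0 or not classified.any():
        raise ValueError("all seed voxels are unclassified (zero pooled counts)")
    p = np.full(conn.n_seeds, np.nan)
    p[classified] = s[classified] / total[classified]

    vol_s = np.full(conn.grid.shape, np.nan)
    vol_s[tuple(conn.seed_voxels.T)] = p
    vol_m = np.full(conn.grid.shape, np.nan)
    vol_m[tuple(conn.seed_voxels.T)] = 1.0 - p
    return (
        ProbabilityVolume(conn.grid, vol_s),
        ProbabilityVolume(conn.grid, vol_m),
    )


def _top_voxels(
    values: np.ndarray, voxels: np.ndarray, k: int, exclude: set | None = None
) -> np.ndarray:
    """Highest-valued ``k`` voxels; ties broken by lexicographic voxel index."""
    order = np.lexsort((voxels[:, 2], voxels[:, 1], voxels[:, 0], -values))
    picked = []
    for idx in order:
        key = tuple(int(x) for x in voxels[idx])
        if exclude and key in exclude:
            continue
        picked.append(voxels[idx])
        if len(picked) == k:
            break
    return np.asarray(picked, dtype=np.intp).reshape(-1, 3)


def _distribution_hash(values: np.ndarray) -> str:
    return hashlib.sha256(np.ascontiguousarray(values).tobytes()).hexdigest()[:16]


def select_equal_volume_masks(
    p_strio: ProbabilityVolume,
    p_matrix: ProbabilityVolume,
    fraction: float = 0.13,
) -> CompartmentMaskPair:
    """Equal-volume masks of the most-biased voxels from each distribution.

    Each mask holds exactly ``round(fraction * N_classified)`` voxels.  The
    striosome-like mask is filled first; matrix-like selection skips any
    voxel already claimed, which keeps the pair disjoint even under massed
    ties at 0.5 (possible only because complementary scores cannot place a
    voxel in both upper tails when ``fraction < 0.5``).
    """
    if not 0 < fraction < 0.5:
        raise ValueError("fraction must lie in (0, 0.5): disjointness is not "
                         "guaranteed for complementary scores otherwise")
    p_strio.grid.require_same(p_matrix.grid)
    defined = p_strio.defined_mask & p_matrix.defined_mask
    voxels = np.argwhere(defined)
    n_classified = len(voxels)
    if n_classified < int(np.ceil(1 / fraction)):
        raise ValueError(
            f"only {n_classified} classified voxels; need >= {int(np.ceil(1/fraction))}"
        )
    k = int(round(fraction * n_classified))
    vals_s = p_strio.values[defined]
    vals_m = p_matrix.values[defined]
    strio = _top_voxels(vals_s, voxels, k)
    taken = {tuple(int(x) for x in v) for v in strio}
    matrix = _top_voxels(vals_m, voxels, k, exclude=taken)
    return CompartmentMaskPair(
        grid=p_strio.grid,
        striosome_like=strio,
        matrix_like=matrix,
        source={
            "method": "fraction",
            "fraction": fraction,
            "n_classified": n_classified,
            "n_per_mask": k,
            "distribution_hash": _distribution_hash(vals_s),
        },
    )


def n1_parcellation(
    conn: ConnectivityTable,
    baits: BaitGrouping,
    leave_out: str,
    fraction: float = 0.13,
) -> CompartmentMaskPair:
    """Parcellation with one bait region's counts excluded (N-1 analysis)."""
    reduced = baits.leave_out(leave_out)
    conn_reduced = (
        conn.drop_groups([leave_out]) if leave_out in conn.target_groups else conn
    )
    p_s, p_m = ctt_bias_score(conn_reduced, reduced)
    masks = select_equal_volume_masks(p_s, p_m, fraction)
    masks.source["left_out"] = leave_out
    return masks


def proportional_masks(
    p_strio: ProbabilityVolume,
    p_matrix: ProbabilityVolume,
    nucleus_labels: LabelVolume,
    quotas: dict[str, int],
) -> CompartmentMaskPair:
    """Nucleus-proportional mask selection (per-nucleus voxel quotas).

    Instead of taking the most-biased voxels from anywhere in the striatum,
    each nucleus contributes a fixed quota of its own most-biased voxels
    (e.g. 80 from the caudate, 100 from the putamen), so caudate/putamen
    volume differences cannot drive compartment contrasts.  Striosome-like
    and matrix-like masks stay equal in volume per nucleus.
    """
    p_strio.grid.require_same(p_matrix.grid)
    p_strio.grid.require_same(nucleus_labels.grid)
    name_to_label = {v: k for k, v in nucleus_labels.legend.items()}
    defined = p_strio.defined_mask & p_matrix.defined_mask

    taken: set = set()
    parts = {"striosome": [], "matrix": []}
    for comp, pvol in (("striosome", p_strio), ("matrix", p_matrix)):
        for nucleus, quota in sorted(quotas.items()):
            if quota == 0:
                continue
            if nucleus not in name_to_label:
                raise ValueError(f"nucleus {nucleus!r} not in label legend")
            in_nuc = defined & nucleus_labels.mask_of(name_to_label[nucleus])
            voxels = np.argwhere(in_nuc)
            if len(voxels) - sum(
                1 for v in map(tuple, voxels) if v in taken
            ) < quota:
                raise ValueError(
                    f"nucleus {nucleus!r} holds fewer than {quota} available "
                    f"classified voxels for the {comp} mask"
                )
            vals = pvol.values[in_nuc]
            sel = _top_voxels(vals, voxels, quota, exclude=taken)
            taken.update(tuple(int(x) for x in v) for v in sel)
            parts[comp].append(sel)

    strio = np.concatenate(parts["striosome"]) if parts["striosome"] else np.empty((0, 3), int)
    matrix = np.concatenate(parts["matrix"]) if parts["matrix"] else np.empty((0, 3), int)
    return CompartmentMaskPair(
        grid=p_strio.grid,
        striosome_like=strio,
        matrix_like=matrix,
        source={
            "method": "quota",
            "quotas": dict(sorted(quotas.items())),
            "distribution_hash": _distribution_hash(p_strio.values[defined]),
        },
    )
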