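"""Synthetic connectome phantom.

Generates a single-hemisphere striatum (caudate + putamen) whose voxels carry
ground-truth compartment labels — a dispersed, connected striosome labyrinth
occupying ~15% of striatal volume with medio-lateral, rostro-caudal and
dorso-ventral gradients — plus a 19-subregion insular sheet with known
per-subregion compartment biases, bait-region labels, and simulators for the
two tractography abstractions the analysis consumes:

* classification-targets streamline counts from striatal seed voxels to bait
  regions (multinomial, with tunable fidelity and lapse rate), and
* insulo-striate streamline counts / straight-segment path-density maps from
  insular seed voxels to compartment target masks.

Everything is seeded; identical parameters and seed give identical output.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from skimage.draw import line_nd

from .core import (
    BaitGrouping,
    CompartmentMaskPair,
    ConnectivityTable,
    LabelVolume,
    ProbabilityVolume,
    VolumeGrid,
)

__all__ = [
    "PhantomTruth",
    "default_grid",
    "make_striatum",
    "make_insula",
    "make_baits",
    "make_phantom",
    "simulate_ctt",
    "simulate_insulo_striate",
    "simulate_region_ctt",
    "DEFAULT_SUBREGION_BIAS",
    "DEFAULT_SUBREGION_ORDER",
]

STRIOSOME = 1
MATRIX = 2
CAUDATE = 1
PUTAMEN = 2

# True probability that a streamline seeded in each insular subregion targets
# striosome-like tissue.  Values are anchored to the observed per-subregion
# matrix volume-percents (strio bias = 1 - matrix%/100); the three subregions
# without a significant bias sit at 0.5.  Seven subregions lean striosome
# (> 0.55), nine lean matrix (< 0.45), three are neutral.
DEFAULT_SUBREGION_BIAS: dict[int, float] = {
    1: 0.341, 2: 0.331, 3: 0.386, 4: 0.350, 5: 0.290, 6: 0.500, 7: 0.664,
    8: 0.500, 9: 0.400, 10: 0.233, 11: 0.412, 12: 0.781, 13: 0.907,
    14: 0.596, 15: 0.316, 16: 0.711, 17: 0.927, 18: 0.500, 19: 0.789,
}

# Subregion ids laid out from the rostroventral to the caudodorsal end of the
# insular sheet: striosome-leaning subregions sit rostroventrally,
# matrix-leaning ones caudodorsally, neutral ones in between.
DEFAULT_SUBREGION_ORDER: tuple[int, ...] = (
    17, 13, 19, 12, 16, 7, 14, 6, 8, 18, 11, 9, 3, 4, 1, 2, 15, 5, 10,
)


def default_grid(hemisphere: str = "right") -> VolumeGrid:
    """1.5 mm isotropic right-hemisphere grid, 30 x 40 x 30 voxels.

    The affine places the insular matrix-cluster center near the y = 1 mm
    coronal plane and the midline at x = 0 (medial edge of the grid).
    """
    affine = np.array(
        [
            [1.5, 0.0, 0.0, 0.0],
            [0.0, 1.5, 0.0, -29.0],
            [0.0, 0.0, 1.5, -19.5],
            [0.0, 0.0, 0.0, 1.0],
        ]
    )
    return VolumeGrid(shape=(30, 40, 30), affine=affine, hemisphere=hemisphere)


@dataclass(frozen=True)
class PhantomTruth:
    """Ground truth of one phantom hemisphere, for parameter-recovery tests."""

    compartment_labels: LabelVolume      # striosome=1, matrix=2 inside striatum
    nucleus_labels: LabelVolume          # caudate=1, putamen=2
    insula_labels: LabelVolume           # subregions 1..K
    bait_labels: LabelVolume
    subregion_true_bias: dict[int, float]
    striosome_fraction: float = 0.15
    gradient_strengths: tuple[float, float, float] = (1.0, 1.0, 1.0)
    fidelity: float = 0.8
    rng_seed: int = 0
    # per-voxel true bias within each subregion (mean-preserving spread
    # around subregion_true_bias, mimicking the within-region gradation of
    # real probability maps); None means every voxel carries its
    # subregion's value exactly
    insula_voxel_bias: ProbabilityVolume | None = None

    @property
    def grid(self) -> VolumeGrid:
        return self.compartment_labels.grid

    def striatal_voxels(self) -> np.ndarray:
        return np.argwhere(self.nucleus_labels.labels > 0)

    def compartment_of(self, voxels: np.ndarray) -> np.ndarray:
        voxels = np.asarray(voxels).reshape(-1, 3)
        return self.compartment_labels.labels[tuple(voxels.T)]

    def insular_voxels(self) -> np.ndarray:
        return np.argwhere(self.insula_labels.labels > 0)

    def save_truth(self, path) -> Path:
        payload = {
            "subregion_true_bias": {
                str(k): v for k, v in sorted(self.subregion_true_bias.items())
            },
            "striosome_fraction": self.striosome_fraction,
            "gradient_strengths": list(self.gradient_strengths),
            "fidelity": self.fidelity,
            "rng_seed": self.rng_seed,
        }
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)
        return path


def _ellipsoid_mask(shape, center, semi_axes) -> np.ndarray:
    grids = np.indices(shape, dtype=float)
    dist = sum(
        ((grids[a] - center[a]) / semi_axes[a]) ** 2 for a in range(3)
    )
    return dist <= 1.0


def _standardized_world(grid: VolumeGrid, voxels: np.ndarray) -> np.ndarray:
    world = grid.voxel_to_world(voxels)
    mu = world.mean(axis=0)
    sd = world.std(axis=0)
    sd[sd == 0] = 1.0
    return (world - mu) / sd


def _striosome_intensity(
    grid: VolumeGrid, voxels: np.ndarray, gradients: tuple[float, float, float]
) -> np.ndarray:
    """Unnormalized striosome propensity: higher medially, rostrally, ventrally."""
    z = _standardized_world(grid, voxels)
    g_ml, g_rc, g_dv = gradients
    medial = -z[:, 0] if grid.hemisphere != "left" else z[:, 0]
    # ventral enrichment is the strongest gradient in tissue, medial the
    # weakest; the axis weights mirror that ordering
    logw = 0.5 * g_ml * medial + 0.8 * g_rc * z[:, 1] + 1.0 * g_dv * (-z[:, 2])
    return np.exp(logw)


def make_striatum(
    grid: VolumeGrid | None = None,
    striosome_fraction: float = 0.15,
    gradient_strengths: tuple[float, float, float] = (1.0, 1.0, 1.0),
    rng_seed: int = 0,
) -> tuple[LabelVolume, LabelVolume]:
    """Build nucleus labels and grow the striosome labyrinth inside them.

    The striosome is laid down as random-walk branches whose seeds and steps
    are weighted by a spatial intensity that increases medially, rostrally
    and ventrally (scaled by ``gradient_strengths``); the walk stops exactly
    when ``round(striosome_fraction * N)`` voxels are marked, so the
    realized fraction is exact to rounding.

    Returns
    -------
    (nucleus_labels, compartment_labels)
        caudate=1 / putamen=2, and striosome=1 / matrix=2 within striatum.
    """
    if grid is None:
        grid = default_grid()
    if striosome_fraction > 0.5:
        raise ValueError("striosome_fraction > 0.5 is infeasible for the minority compartment")
    rng = np.random.default_rng(rng_seed)

    caudate = _ellipsoid_mask(grid.shape, (7.0, 24.0, 18.0), (4.2, 9.5, 6.2))
    putamen = _ellipsoid_mask(grid.shape, (17.0, 18.0, 12.0), (5.2, 10.5, 7.2))
    putamen &= ~caudate
    nucleus = np.zeros(grid.shape, dtype=np.int16)
    nucleus[caudate] = CAUDATE
    nucleus[putamen] = PUTAMEN
    for name, mask in (("caudate", caudate), ("putamen", putamen)):
        if mask.sum() < 500:
            raise ValueError(f"grid too small: {name} holds {int(mask.sum())} < 500 voxels")

    voxels = np.argwhere(nucleus > 0)
    n_total = len(voxels)
    target = int(round(striosome_fraction * n_total))
    # intensity standardized within each nucleus: the gradients describe
    # where striosome sits inside a nucleus, so the dorsomedial caudate /
    # ventrolateral putamen geometry must not leak into them
    weight = np.empty(n_total)
    nuc_of_vox = nucleus[tuple(voxels.T)]
    for n in (CAUDATE, PUTAMEN):
        sel = nuc_of_vox == n
        weight[sel] = _striosome_intensity(grid, voxels[sel], gradient_strengths)

    index_of = {tuple(v): i for i, v in enumerate(map(tuple, voxels))}
    nuc_of = nucleus[tuple(voxels.T)]
    marked = np.zeros(n_total, dtype=bool)
    n_marked = 0
    steps = np.array(
        [[1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0], [0, 0, 1], [0, 0, -1]]
    )

    def weighted_choice(candidates: np.ndarray) -> int:
        w = weight[candidates]
        return int(rng.choice(candidates, p=w / w.sum()))

    # one obligatory starting branch per nucleus keeps both compartments
    # represented in both nuclei
    starts = [weighted_choice(np.flatnonzero(nuc_of == n)) for n in (CAUDATE, PUTAMEN)]
    branch_origins: list[int] = []
    for s in starts:
        marked[s] = True
        n_marked += 1
        branch_origins.append(s)

    while n_marked < target:
        # new branch: sprout from an existing striosome voxel (keeps the
        # labyrinth locally connected) or start a fresh island — many
        # independent intensity-weighted islands keep the structure
        # dispersed while the gradient sets where branches accumulate
        if branch_origins and rng.random() < 0.65:
            cur = weighted_choice(np.asarray(branch_origins))
        else:
            unmarked = np.flatnonzero(~marked)
            cur = weighted_choice(unmarked)
            if not marked[cur]:
                marked[cur] = True
                n_marked += 1
                branch_origins.append(cur)
                if n_marked >= target:
                    break
        walk_len = 2 + int(rng.geometric(1 / 3.0))
        pos = voxels[cur].copy()
        for _ in range(walk_len):
            if n_marked >= target:
                break
            nbrs = pos + steps
            cand = [index_of.get(tuple(nb)) for nb in nbrs]
            cand = [c for c in cand if c is not None]
            if not cand:
                break
            cand = np.asarray(cand)
            w = weight[cand]
            nxt = int(rng.choice(cand, p=w / w.sum()))
            pos = voxels[nxt].copy()
            if not marked[nxt]:
                marked[nxt] = True
                n_marked += 1
                branch_origins.append(nxt)

    compartment = np.zeros(grid.shape, dtype=np.int16)
    compartment[tuple(voxels.T)] = MATRIX
    compartment[tuple(voxels[marked].T)] = STRIOSOME
    nuc_vol = LabelVolume(grid, nucleus, {CAUDATE: "caudate", PUTAMEN: "putamen"})
    comp_vol = LabelVolume(grid, compartment, {STRIOSOME: "striosome", MATRIX: "matrix"})
    return nuc_vol, comp_vol


def _ramp_profile(n: int) -> dict[int, float]:
    """Fallback bias profile for n != 19: linear rostroventral->caudodorsal ramp."""
    vals = np.linspace(0.8, 0.2, n)
    return {i + 1: float(v) for i, v in enumerate(vals)}


def make_insula(
    grid: VolumeGrid | None = None,
    n_subregions: int = 19,
    true_bias_profile: dict[int, float] | None = None,
) -> tuple[LabelVolume, dict[int, float]]:
    """Build the insular sheet and its per-subregion ground-truth biases.

    The sheet is a three-voxel-thick lateral ellipse; voxels are banded into
    ``n_subregions`` contiguous subregions along the rostroventral ->
    caudodorsal axis.  With 19 subregions the default bias profile and id
    layout follow :data:`DEFAULT_SUBREGION_BIAS` / :data:`DEFAULT_SUBREGION_ORDER`.
    """
    if grid is None:
        grid = default_grid()
    if n_subregions < 2:
        raise ValueError("need at least 2 insular subregions")
    sheet = np.zeros(grid.shape, dtype=bool)
    for x in (24, 25, 26):
        if x < grid.shape[0]:
            jj, kk = np.indices(grid.shape[1:], dtype=float)
            sheet[x] = ((jj - 20.0) / 14.0) ** 2 + ((kk - 13.0) / 9.0) ** 2 <= 1.0
    voxels = np.argwhere(sheet)
    if n_subregions > len(voxels):
        raise ValueError(
            f"{n_subregions} subregions exceed the {len(voxels)}-voxel sheet"
        )
    z = _standardized_world(grid, voxels)
    axis = -z[:, 1] + z[:, 2]       # low = rostroventral, high = caudodorsal
    order = np.argsort(axis, kind="stable")
    bands = np.array_split(order, n_subregions)

    if true_bias_profile is not None:
        bias = {int(k): float(v) for k, v in true_bias_profile.items()}
        if set(bias) != set(range(1, n_subregions + 1)):
            raise ValueError("bias profile must cover subregions 1..n exactly")
        if min(bias.values()) < 0 or max(bias.values()) > 1:
            raise ValueError("biases must lie in [0, 1]")
        id_order = sorted(bias, key=lambda k: -bias[k])  # strio-leaning rostroventral
    elif n_subregions == 19:
        bias = dict(DEFAULT_SUBREGION_BIAS)
        id_order = list(DEFAULT_SUBREGION_ORDER)
    else:
        bias = _ramp_profile(n_subregions)
        id_order = list(range(1, n_subregions + 1))

    labels = np.zeros(grid.shape, dtype=np.int16)
    for band, sub_id in zip(bands, id_order):
        labels[tuple(voxels[band].T)] = sub_id
    legend = {i: f"insular_subregion_{i}" for i in sorted(bias)}
    return LabelVolume(grid, labels, legend), bias


_BAIT_CENTERS = {
    # striosome-favoring
    "mediodorsal_thalamus": (4.0, 14.0, 14.0),
    "posterior_orbitofrontal": (10.0, 35.0, 8.0),
    "basolateral_amygdala": (14.0, 8.0, 4.0),
    "basal_operculum": (22.0, 30.0, 6.0),
    # matrix-favoring
    "supplementary_motor": (6.0, 30.0, 26.0),
    "primary_motor": (14.0, 24.0, 27.0),
    "primary_sensory": (20.0, 14.0, 26.0),
    "globus_pallidus_interna": (11.5, 12.0, 9.0),
    "vlc_vplo_thalamus": (5.0, 8.0, 16.0),
}


def make_baits(grid: VolumeGrid | None = None) -> LabelVolume:
    """Nine spherical bait regions (4 striosome-favoring, 5 matrix-favoring)."""
    if grid is None:
        grid = default_grid()
    labels = np.zeros(grid.shape, dtype=np.int16)
    legend = {}
    for lab, (name, center) in enumerate(_BAIT_CENTERS.items(), start=1):
        sphere = _ellipsoid_mask(grid.shape, center, (2.2, 2.2, 2.2))
        labels[sphere & (labels == 0)] = lab
        legend[lab] = name
    return LabelVolume(grid, labels, legend)


def _voxel_bias_map(
    grid: VolumeGrid,
    insula_labels: LabelVolume,
    subregion_bias: dict[int, float],
    sd: float,
    rng: np.random.Generator,
) -> ProbabilityVolume:
    """Per-voxel true biases: subregion mean plus centered, bound-respecting
    deviations — the subregion's empirical mean equals its nominal bias
    exactly, while individual voxels spread the way real probability maps
    do within a region."""
    vals = np.full(grid.shape, np.nan)
    for lab in sorted(subregion_bias):
        b = subregion_bias[lab]
        vox = insula_labels.voxels_of(lab)
        dev = rng.normal(0.0, sd, len(vox))
        dev -= dev.mean()
        scale = 1.0
        if dev.max() > 0:
            scale = min(scale, (0.98 - b) / dev.max())
        if dev.min() < 0:
            scale = min(scale, (b - 0.02) / (-dev.min()))
        vals[tuple(vox.T)] = b + max(scale, 0.0) * dev
    return ProbabilityVolume(grid, vals)


def make_phantom(
    grid: VolumeGrid | None = None,
    striosome_fraction: float = 0.15,
    gradient_strengths: tuple[float, float, float] = (1.0, 1.0, 1.0),
    n_subregions: int = 19,
    true_bias_profile: dict[int, float] | None = None,
    fidelity: float = 0.8,
    within_subregion_sd: float = 0.10,
    rng_seed: int = 0,
) -> PhantomTruth:
    """Assemble the complete phantom hemisphere."""
    if not 0.5 <= fidelity <= 1.0:
        raise ValueError("fidelity must lie in [0.5, 1]")
    if grid is None:
        grid = default_grid()
    nucleus, compartment = make_striatum(
        grid, striosome_fraction, gradient_strengths, rng_seed
    )
    insula, bias = make_insula(grid, n_subregions, true_bias_profile)
    baits = make_baits(grid)
    voxel_bias = None
    if within_subregion_sd > 0:
        voxel_bias = _voxel_bias_map(
            grid, insula, bias, within_subregion_sd,
            np.random.default_rng([rng_seed, 101]),
        )
    return PhantomTruth(
        compartment_labels=compartment,
        nucleus_labels=nucleus,
        insula_labels=insula,
        bait_labels=baits,
        subregion_true_bias=bias,
        striosome_fraction=striosome_fraction,
        gradient_strengths=tuple(gradient_strengths),
        fidelity=fidelity,
        rng_seed=rng_seed,
        insula_voxel_bias=voxel_bias,
    )


def simulate_ctt(
    truth: PhantomTruth,
    baits: BaitGrouping | None = None,
    streamlines_per_seed: int = 5000,
    fidelity: float | None = None,
    fidelity_gradient: float = 0.0,
    lapse: float = 0.0,
    region_weights: dict[str, float] | None = None,
    rng_seed: int = 0,
    distance_correction: bool = False,
) -> ConnectivityTable:
    """Classification-targets counts from every striatal voxel to bait regions.

    For a seed voxel of true compartment c, streamline targets are drawn
    multinomially: probability ``fidelity`` to the concordant bait group and
    ``1 - fidelity`` to the discordant group, split across each group's
    regions proportionally to ``region_weights`` (equal by default); a
    ``lapse`` fraction reaches no target.

    ``fidelity_gradient`` spreads per-voxel fidelity spatially while keeping
    each compartment's mean fidelity exact: voxels deeper in their
    compartment's home territory (rostro-ventro-medial for striosome,
    caudo-dorso-lateral for matrix) carry purer compartment character, as
    partial-volume mixing would produce in tissue; the spread is scaled down
    so per-voxel fidelity never leaves [0.5, 1] (it vanishes at
    ``fidelity`` = 1 or 0.5).  ``distance_correction`` rescales counts by
    seed-to-bait-centroid path length in mm, mimicking the tractography-tool
    correction that yields non-integer counts.
    """
    if streamlines_per_seed <= 0:
        raise ValueError("streamlines_per_seed must be positive")
    if baits is None:
        baits = BaitGrouping()
    fid = truth.fidelity if fidelity is None else fidelity
    if not 0.5 <= fid <= 1.0:
        raise ValueError("fidelity must lie in [0.5, 1]")
    if not 0.0 <= lapse < 1.0:
        raise ValueError("lapse must lie in [0, 1)")
    rng = np.random.default_rng(rng_seed)

    regions = baits.all_regions
    weights = np.array([(region_weights or {}).get(r, 1.0) for r in regions], float)
    is_strio_col = np.array([r in baits.striosome_group for r in regions])
    w_s = weights * is_strio_col
    w_m = weights * ~is_strio_col

    seeds = np.argwhere(truth.nucleus_labels.labels > 0)
    comp = truth.compartment_of(seeds)

    fid_vox = np.full(len(seeds), fid)
    if fidelity_gradient > 0:
        intensity = np.log(
            _striosome_intensity(truth.grid, seeds, truth.gradient_strengths)
        )
        sd = intensity.std()
        intensity = (intensity - intensity.mean()) / (sd if sd > 0 else 1.0)
        for c, sign in ((STRIOSOME, 1.0), (MATRIX, -1.0)):
            idx = comp == c
            if not idx.any():
                continue
            dev = sign * intensity[idx]
            dev -= dev.mean()
            scale = fidelity_gradient
            if dev.max() > 0:
                scale = min(scale, (1.0 - fid) / dev.max())
            if dev.min() < 0:
                scale = min(scale, (fid - 0.5) / (-dev.min()))
            fid_vox[idx] = fid + max(scale, 0.0) * dev

    # probability a streamline from each voxel reaches striosome-favoring bait
    p_strio_vox = np.where(comp == STRIOSOME, fid_vox, 1.0 - fid_vox)
    p3 = np.column_stack(
        [
            (1 - lapse) * p_strio_vox,
            (1 - lapse) * (1.0 - p_strio_vox),
            np.full(len(seeds), lapse),
        ]
    )
    group_draw = rng.multinomial(streamlines_per_seed, p3)
    split_s = rng.multinomial(group_draw[:, 0], w_s[is_strio_col] / w_s.sum())
    split_m = rng.multinomial(group_draw[:, 1], w_m[~is_strio_col] / w_m.sum())
    counts = np.zeros((len(seeds), len(regions)), dtype=float)
    counts[:, is_strio_col] = split_s
    counts[:, ~is_strio_col] = split_m

    if distance_correction:
        centers = {
            truth.bait_labels.legend[lab]: truth.grid.voxel_to_world(
                truth.bait_labels.voxels_of(lab).mean(axis=0)
            )
            for lab in truth.bait_labels.legend
        }
        seed_world = truth.grid.voxel_to_world(seeds)
        for g_idx, r in enumerate(regions):
            d = np.linalg.norm(seed_world - centers[r], axis=1)
            counts[:, g_idx] *= d

    return ConnectivityTable(
        grid=truth.grid,
        seed_voxels=seeds,
        target_groups=regions,
        counts=counts,
        streamlines_per_seed=streamlines_per_seed,
    )


def _accumulate_segments(density, starts, ends, weights) -> None:
    for s, e, w in zip(starts, ends, weights):
        if w <= 0:
            continue
        line = line_nd(tuple(s), tuple(e), endpoint=True)
        density[line] += w


def simulate_insulo_striate(
    truth: PhantomTruth,
    masks: CompartmentMaskPair,
    streamlines_per_seed: int = 5000,
    rng_seed: int = 0,
    targeting: str = "mask",
    with_paths: bool = False,
    direction: str = "insula_to_striatum",
):
    """Insulo-striate streamline simulation against compartment target masks.

    Each insular voxel of subregion ``s`` sends streamlines toward
    striosome-like targets with probability ``subregion_true_bias[s]`` and
    matrix-like targets with the complement.

    targeting
        ``"mask"``: a streamline's group is decided by mask identity and the
        target voxel is uniform within that mask (the idealized round-5
        emulation).  ``"tissue"``: each target voxel is weighted by the
        affinity of its *ground-truth* compartment, so impure masks (jittered
        or proportional controls) capture streamlines according to the tissue
        they actually contain.
    with_paths
        Also rasterize straight seed->target segments into two path-density
        volumes (striosome-bound, matrix-bound visit counts).
    direction
        ``"insula_to_striatum"`` (seeds are insular voxels) or
        ``"striatum_to_insula"`` (seeds are mask voxels, targets insular
        voxels weighted by subregion bias) — the reverse leg of AB-BA
        averaged bundle mapping.

    Returns ``conn`` or ``(conn, (density_strio, density_matrix))``.
    """
    if masks.n_striosome == 0 or masks.n_matrix == 0:
        raise ValueError("compartment target masks must be non-empty")
    if streamlines_per_seed <= 0:
        raise ValueError("streamlines_per_seed must be positive")
    if targeting not in ("mask", "tissue"):
        raise ValueError(f"unknown targeting mode {targeting!r}")
    rng = np.random.default_rng(rng_seed)
    grid = truth.grid

    s_vox, m_vox = masks.striosome_like, masks.matrix_like
    bias = truth.subregion_true_bias

    if direction == "striatum_to_insula":
        return _simulate_reverse(
            truth, masks, streamlines_per_seed, rng, with_paths
        )
    if direction != "insula_to_striatum":
        raise ValueError(f"unknown direction {direction!r}")

    insula = truth.insula_labels
    seeds = np.argwhere(insula.labels > 0)
    sub_of = insula.labels[tuple(seeds.T)]
    if truth.insula_voxel_bias is not None:
        b_seed = truth.insula_voxel_bias.values[tuple(seeds.T)]
    else:
        b_seed = np.array([bias[int(s)] for s in sub_of])

    if targeting == "tissue":
        s_truth = truth.compartment_of(s_vox) == STRIOSOME
        m_truth = truth.compartment_of(m_vox) == STRIOSOME
        nS_s, nS_m = int(s_truth.sum()), int((~s_truth).sum())
        nM_s, nM_m = int(m_truth.sum()), int((~m_truth).sum())

    # per-seed probability that a streamline joins the striosome-bound group
    if targeting == "mask":
        p_group_s = b_seed
    else:
        # group weight = summed per-voxel affinity of the true tissue inside
        # each mask; impure masks capture streamlines accordingly
        wS = b_seed * nS_s + (1 - b_seed) * nS_m
        wM = b_seed * nM_s + (1 - b_seed) * nM_m
        total = wS + wM
        p_group_s = np.where(total > 0, wS / np.where(total > 0, total, 1.0), 0.0)

    n_s_all = rng.binomial(streamlines_per_seed, p_group_s)
    counts = np.column_stack(
        [n_s_all, streamlines_per_seed - n_s_all]
    ).astype(float)
    dens_s = np.zeros(grid.shape) if with_paths else None
    dens_m = np.zeros(grid.shape) if with_paths else None

    if with_paths:
        for i, (seed, b) in enumerate(zip(seeds, b_seed)):
            if targeting == "mask":
                p_within_s = p_within_m = None  # uniform
            else:
                aff_s = np.where(s_truth, b, 1.0 - b)
                aff_m = np.where(m_truth, b, 1.0 - b)
                p_within_s = aff_s / aff_s.sum() if aff_s.sum() > 0 else None
                p_within_m = aff_m / aff_m.sum() if aff_m.sum() > 0 else None
            for n_hit, vox, pw, dens in (
                (int(counts[i, 0]), s_vox, p_within_s, dens_s),
                (int(counts[i, 1]), m_vox, p_within_m, dens_m),
            ):
                if n_hit == 0:
                    continue
                if pw is None:
                    per_target = rng.multinomial(n_hit, np.full(len(vox), 1 / len(vox)))
                else:
                    per_target = rng.multinomial(n_hit, pw)
                hit = np.flatnonzero(per_target)
                _accumulate_segments(
                    dens, np.repeat(seed[None, :], len(hit), axis=0),
                    vox[hit], per_target[hit],
                )

    conn = ConnectivityTable(
        grid=grid,
        seed_voxels=seeds,
        target_groups=("striosome_like", "matrix_like"),
        counts=counts,
        streamlines_per_seed=streamlines_per_seed,
    )
    if with_paths:
        return conn, (
            ProbabilityVolume(grid, dens_s, is_probability=False),
            ProbabilityVolume(grid, dens_m, is_probability=False),
        )
    return conn


def simulate_region_ctt(
    truth: PhantomTruth,
    region: str,
    masks: CompartmentMaskPair,
    strio_affinity: float,
    streamlines_per_seed: int = 50000,
    rng_seed: int = 0,
    targeting: str = "tissue",
) -> ConnectivityTable:
    """Classification-targets counts from one bait region to compartment masks.

    Emulates the left-out-region round: every voxel of ``region`` seeds
    streamlines whose per-target affinity is ``strio_affinity`` for
    striosome tissue and its complement for matrix (``targeting="tissue"``),
    or mask-identity-driven (``targeting="mask"``).  Target groups are
    ``striosome_like`` / ``matrix_like``.
    """
    if not 0 <= strio_affinity <= 1:
        raise ValueError("strio_affinity must lie in [0, 1]")
    label = {v: k for k, v in truth.bait_labels.legend.items()}.get(region)
    if label is None:
        raise ValueError(f"unknown bait region {region!r}")
    seeds = truth.bait_labels.voxels_of(label)
    rng = np.random.default_rng(rng_seed)
    b = strio_affinity
    if targeting == "mask":
        p_s = b
    elif targeting == "tissue":
        s_truth = truth.compartment_of(masks.striosome_like) == STRIOSOME
        m_truth = truth.compartment_of(masks.matrix_like) == STRIOSOME
        wS = b * s_truth.sum() + (1 - b) * (~s_truth).sum()
        wM = b * m_truth.sum() + (1 - b) * (~m_truth).sum()
        p_s = wS / (wS + wM) if (wS + wM) > 0 else 0.0
    else:
        raise ValueError(f"unknown targeting mode {targeting!r}")
    n_s = rng.binomial(streamlines_per_seed, p_s, size=len(seeds))
    counts = np.column_stack([n_s, streamlines_per_seed - n_s]).astype(float)
    return ConnectivityTable(
        grid=truth.grid,
        seed_voxels=seeds,
        target_groups=("striosome_like", "matrix_like"),
        counts=counts,
        streamlines_per_seed=streamlines_per_seed,
    )


def _simulate_reverse(truth, masks, streamlines_per_seed, rng, with_paths):
    """Striatal-mask seeds targeting insular voxels (the BA leg of AB-BA)."""
    grid = truth.grid
    insula = truth.insula_labels
    ins_vox = np.argwhere(insula.labels > 0)
    sub_of = insula.labels[tuple(ins_vox.T)]
    if truth.insula_voxel_bias is not None:
        b_ins = truth.insula_voxel_bias.values[tuple(ins_vox.T)]
    else:
        b_ins = np.array([truth.subregion_true_bias[int(s)] for s in sub_of])

    counts_rows = []
    seeds_rows = []
    dens = {"striosome": np.zeros(grid.shape), "matrix": np.zeros(grid.shape)}
    for comp, vox, w_ins in (
        ("striosome", masks.striosome_like, b_ins),
        ("matrix", masks.matrix_like, 1.0 - b_ins),
    ):
        p = w_ins / w_ins.sum() if w_ins.sum() > 0 else np.full(len(ins_vox), 1 / len(ins_vox))
        for seed in vox:
            per_target = rng.multinomial(streamlines_per_seed, p)
            seeds_rows.append(seed)
            counts_rows.append(
                (per_target.sum() if comp == "striosome" else 0,
                 per_target.sum() if comp == "matrix" else 0)
            )
            if with_paths:
                hit = np.flatnonzero(per_target)
                _accumulate_segments(
                    dens[comp], np.repeat(seed[None, :], len(hit), axis=0),
                    ins_vox[hit], per_target[hit],
                )
    conn = ConnectivityTable(
        grid=grid,
        seed_voxels=np.asarray(seeds_rows),
        target_groups=("striosome_like", "matrix_like"),
        counts=np.asarray(counts_rows, dtype=float),
        streamlines_per_seed=streamlines_per_seed,
    )
    if with_paths:
        return conn, (
            ProbabilityVolume(grid, dens["striosome"], is_probability=False),
            ProbabilityVolume(grid, dens["matrix"], is_probability=False),
        )
    return conn
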