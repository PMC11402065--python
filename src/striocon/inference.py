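"""Statistical testing: per-subregion ANCOVA with Bonferroni families,
paired-t families, and voxelwise sign-flip permutation testing with
familywise error control.

The voxelwise engine uses the max-statistic null distribution for FWE
control (a deliberate substitution for threshold-free cluster enhancement:
the max statistic has the same exchangeability-based FWE guarantee with far
less machinery).  Two-sided questions are run as two one-directional
max-stat tests, each at half the familywise alpha.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.ndimage as ndi
import scipy.stats as st
import statsmodels.formula.api as smf
from statsmodels.stats.anova import anova_lm

from .core import ProbabilityVolume, VolumeGrid

__all__ = [
    "AncovaResult",
    "PermutationResult",
    "subregion_ancova",
    "paired_t_family",
    "voxelwise_permutation_test",
    "verdict_for",
]


def verdict_for(p: float, family_alpha: float, trending_multiplier: float = 10.0) -> str:
    """significant if p < family alpha; trending if within 10x of it."""
    if p < family_alpha:
        return "significant"
    if p < trending_multiplier * family_alpha:
        return "trending"
    return "ns"


@dataclass(frozen=True)
class AncovaResult:
    subregion: int
    factor: str
    F: float
    df: tuple[int, int]
    p: float
    verdict: str


ANCOVA_FORMULA = (
    "count ~ C(compartment) + C(hemisphere) + C(handedness) + C(sex) "
    "+ C(race) + age + C(sex):C(hemisphere):C(compartment)"
)

_ANCOVA_TERMS = {
    "C(compartment)": "compartment",
    "C(hemisphere)": "hemisphere",
    "C(handedness)": "handedness",
    "C(sex)": "sex",
    "C(race)": "race",
    "age": "age",
    "C(sex):C(hemisphere):C(compartment)": "sex_x_hemisphere_x_compartment",
}


def subregion_ancova(
    records: pd.DataFrame,
    covariates: pd.DataFrame,
    family_size: int = 19,
    alpha: float = 0.05,
    trending_multiplier: float = 10.0,
    formula: str = ANCOVA_FORMULA,
) -> list[AncovaResult]:
    """One ANCOVA per insular subregion on compartment-biased voxel counts.

    ``records`` must hold columns ``subject, hemisphere, subregion,
    compartment, count`` (one row per subject x hemisphere x compartment,
    count = suprathreshold voxels); ``covariates`` holds one row per subject
    with ``subject, handedness, sex, race, age``.  The family alpha is
    ``alpha / family_size`` and results within ``trending_multiplier`` of it
    are labeled trending.
    """
    needed = {"subject", "hemisphere", "subregion", "compartment", "count"}
    if missing := needed - set(records.columns):
        raise ValueError(f"records table lacks columns {sorted(missing)}")
    cov_needed = {"subject", "handedness", "sex", "race", "age"}
    if missing := cov_needed - set(covariates.columns):
        raise ValueError(f"covariate table lacks columns {sorted(missing)}")
    if covariates[sorted(cov_needed)].isna().any().any():
        raise ValueError("missing covariate values are rejected, not imputed")
    data = records.merge(covariates, on="subject", how="left", validate="m:1")
    if data[["handedness", "sex", "race", "age"]].isna().any().any():
        raise ValueError("some subjects in records lack covariate rows")
    fam_alpha = alpha / family_size
    results: list[AncovaResult] = []
    for subregion, chunk in data.groupby("subregion"):
        model = smf.ols(formula, data=chunk).fit()
        if np.linalg.matrix_rank(model.model.exog) < model.model.exog.shape[1]:
            raise ValueError(
                f"subregion {subregion}: rank-deficient design "
                f"(aliased factors among {sorted(_ANCOVA_TERMS.values())})"
            )
        table = anova_lm(model, typ=2)
        for term, label in _ANCOVA_TERMS.items():
            if term not in table.index:
                continue
            p = float(table.loc[term, "PR(>F)"])
            results.append(
                AncovaResult(
                    subregion=int(subregion),
                    factor=label,
                    F=float(table.loc[term, "F"]),
                    df=(int(table.loc[term, "df"]), int(model.df_resid)),
                    p=p,
                    verdict=verdict_for(p, fam_alpha, trending_multiplier),
                )
            )
    return results


def ancova_results_table(results: list[AncovaResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "subregion": [r.subregion for r in results],
            "factor": [r.factor for r in results],
            "F": [r.F for r in results],
            "df_num": [r.df[0] for r in results],
            "df_den": [r.df[1] for r in results],
            "p": [r.p for r in results],
            "verdict": [r.verdict for r in results],
        }
    )


def paired_t_family(
    values_a,
    values_b,
    family_size: int = 1,
    alpha: float = 0.05,
    trending_multiplier: float = 10.0,
) -> dict:
    """Two-tailed paired t-test with a Bonferroni family verdict."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired vectors differ in length")
    if len(a) < 3:
        raise ValueError("need at least 3 pairs")
    d = a - b
    if np.allclose(d.std(ddof=1), 0):
        t, p = (0.0, 1.0) if np.allclose(d, 0) else (np.inf * np.sign(d.mean()), 0.0)
        degenerate = True
    else:
        t, p = st.ttest_rel(a, b)
        degenerate = False
    fam_alpha = alpha / family_size
    return {
        "t": float(t),
        "p": float(p),
        "df": len(a) - 1,
        "family_alpha": fam_alpha,
        "verdict": verdict_for(float(p), fam_alpha, trending_multiplier),
        "degenerate": degenerate,
    }


@dataclass(frozen=True)
class PermutationResult:
    """Outcome of the voxelwise sign-flip max-statistic test."""

    statistic_map: ProbabilityVolume
    fwe_p_map: ProbabilityVolume
    fwe_p_per_direction: tuple[np.ndarray, np.ndarray]
    significant_mask_per_direction: tuple[np.ndarray, np.ndarray]
    n_permutations: int
    alpha: float
    exhaustive: bool


def _t_from_signs(
    signs: np.ndarray,
    data: np.ndarray,
    sumsq: np.ndarray,
    smooth_sigma_vox,
    shape,
    analysis_flat: np.ndarray | None,
) -> np.ndarray:
    """One-sample t per voxel for each sign-flip row; rows of ``signs`` are
    permutations.  Variance is computed from the flipped data (sum of squares
    is flip-invariant) and optionally Gaussian-smoothed over the volume."""
    n = data.shape[0]
    means = signs @ data / n
    var = (sumsq - n * means**2) / (n - 1)
    var = np.maximum(var, 0.0)
    if smooth_sigma_vox is not None:
        smoothed = np.empty_like(var)
        for r in range(var.shape[0]):
            vol = np.zeros(int(np.prod(shape)))
            if analysis_flat is not None:
                vol[analysis_flat] = var[r]
                sm = ndi.gaussian_filter(vol.reshape(shape), smooth_sigma_vox)
                smoothed[r] = sm.reshape(-1)[analysis_flat]
            else:
                sm = ndi.gaussian_filter(var[r].reshape(shape), smooth_sigma_vox)
                smoothed[r] = sm.reshape(-1)
        var = np.maximum(smoothed, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = means / np.sqrt(var / n)
    t[~np.isfinite(t)] = 0.0
    return t


def voxelwise_permutation_test(
    diff_maps: np.ndarray,
    grid: VolumeGrid,
    n_permutations: int = 5000,
    alpha: float = 0.025,
    variance_smoothing_mm: float = 0.0,
    rng_seed: int = 0,
    analysis_mask: np.ndarray | None = None,
) -> PermutationResult:
    """Sign-flip permutation test on paired difference volumes with FWE control.

    ``diff_maps`` has shape (n_subjects, *grid.shape).  A one-sample t is
    computed per voxel; the null distribution of the maximum statistic over
    voxels calibrates FWE-corrected p-values.  Each direction (positive =
    first condition larger, negative = second larger) is tested one-sidedly
    at ``alpha``.  When ``n_permutations >= 2^n_subjects`` the sign flips
    are enumerated exhaustively and the p-values are exact.
    """
    diff_maps = np.asarray(diff_maps, dtype=float)
    n_subj = diff_maps.shape[0]
    if n_subj < 2:
        raise ValueError("need at least 2 subjects")
    if diff_maps.shape[1:] != grid.shape:
        raise ValueError("difference maps do not match the grid")
    flat = diff_maps.reshape(n_subj, -1)
    analysis_flat = None
    if analysis_mask is not None:
        analysis_flat = np.flatnonzero(np.asarray(analysis_mask, bool).reshape(-1))
        flat = flat[:, analysis_flat]
    sumsq = (flat**2).sum(axis=0)

    sigma = None
    if variance_smoothing_mm > 0:
        sigma = tuple(variance_smoothing_mm / v for v in grid.voxel_size)

    exhaustive = n_permutations >= 2**n_subj
    if exhaustive:
        signs = np.array(list(itertools.product((1.0, -1.0), repeat=n_subj)))
        n_perm = len(signs)
    else:
        rng = np.random.default_rng(rng_seed)
        signs = rng.choice((1.0, -1.0), size=(n_permutations, n_subj))
        n_perm = n_permutations

    t_obs = _t_from_signs(
        np.ones((1, n_subj)), flat, sumsq, sigma, grid.shape, analysis_flat
    )[0]
    t_perm = _t_from_signs(signs, flat, sumsq, sigma, grid.shape, analysis_flat)
    max_pos = t_perm.max(axis=1)
    max_neg = (-t_perm).max(axis=1)

    if exhaustive:
        # the identity flip is one of the enumerated permutations
        fwe_pos = (max_pos[None, :] >= t_obs[:, None] - 1e-12).mean(axis=1)
        fwe_neg = (max_neg[None, :] >= -t_obs[:, None] - 1e-12).mean(axis=1)
    else:
        fwe_pos = (1.0 + (max_pos[None, :] >= t_obs[:, None] - 1e-12).sum(axis=1)) / (
            n_perm + 1
        )
        fwe_neg = (1.0 + (max_neg[None, :] >= -t_obs[:, None] - 1e-12).sum(axis=1)) / (
            n_perm + 1
        )

    def unflatten(v, fill=np.nan):
        if analysis_flat is None:
            return v.reshape(grid.shape)
        out = np.full(grid.n_voxels, fill)
        out[analysis_flat] = v
        return out.reshape(grid.shape)

    sig_pos = unflatten((fwe_pos <= alpha).astype(float), 0.0).astype(bool)
    sig_neg = unflatten((fwe_neg <= alpha).astype(float), 0.0).astype(bool)
    fwe_min = np.minimum(fwe_pos, fwe_neg)
    return PermutationResult(
        statistic_map=ProbabilityVolume(
            grid, np.abs(unflatten(t_obs)), is_probability=False
        ),
        fwe_p_map=ProbabilityVolume(grid, unflatten(fwe_min), is_probability=True),
        fwe_p_per_direction=(unflatten(fwe_pos), unflatten(fwe_neg)),
        significant_mask_per_direction=(sig_pos, sig_neg),
        n_permutations=n_perm,
        alpha=alpha,
        exhaustive=exhaustive,
    )
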