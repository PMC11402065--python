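"""ANCOVA, paired-t families, and the sign-flip permutation engine."""

import itertools

import numpy as np
import pandas as pd
import pytest
import scipy.stats as st

from striocon import inference
from striocon.core import VolumeGrid


def _covariates(subjects, rng):
    # race drawn independently of sex so no factor aliases another
    return pd.DataFrame(
        {
            "subject": subjects,
            "sex": [("F", "M")[i % 2] for i in range(len(subjects))],
            "handedness": ["right"] * (len(subjects) - 1) + ["left"],
            "race": rng.choice(["white", "black", "asian", "other"], len(subjects)),
            "age": rng.integers(20, 66, len(subjects)),
        }
    )


def _records(rng, subjects, n_subregions=3, compartment_shift=0.0, sigma=5.0,
             base=50.0):
    rows = []
    for subject in subjects:
        for hemi in ("left", "right"):
            for sub in range(1, n_subregions + 1):
                for comp in ("striosome", "matrix"):
                    mu = base + (compartment_shift if comp == "striosome" else 0.0)
                    rows.append(
                        {
                            "subject": subject,
                            "hemisphere": hemi,
                            "subregion": sub,
                            "compartment": comp,
                            "count": rng.normal(mu, sigma),
                        }
                    )
    return pd.DataFrame(rows)


class TestSubregionAncova:
    def test_compartment_reduction_reproduces_the_paired_t_identity(self):
        # single-factor model with subject blocking: the compartment F must
        # equal the squared paired t statistic
        rng = np.random.default_rng(0)
        subjects = [f"s{i}" for i in range(12)]
        recs = _records(rng, subjects, n_subregions=1, compartment_shift=3.0)
        recs = recs[recs["hemisphere"] == "right"]
        cov = _covariates(subjects, rng)
        results = inference.subregion_ancova(
            recs, cov, family_size=1,
            formula="count ~ C(subject) + C(compartment)",
        )
        f_comp = next(r for r in results if r.factor == "compartment")
        a = recs[recs["compartment"] == "striosome"].sort_values("subject")["count"]
        b = recs[recs["compartment"] == "matrix"].sort_values("subject")["count"]
        t = st.ttest_rel(a.to_numpy(), b.to_numpy()).statistic
        assert f_comp.F == pytest.approx(t**2, abs=1e-9)

    def test_planted_effect_reaches_the_bonferroni_threshold(self):
        rng = np.random.default_rng(1)
        subjects = [f"s{i}" for i in range(50)]  # 100 hemispheres
        cov = _covariates(subjects, rng)
        hits = 0
        for rep in range(30):
            recs = _records(rng, subjects, n_subregions=1, compartment_shift=7.5)
            results = inference.subregion_ancova(recs, cov, family_size=19)
            comp = next(r for r in results if r.factor == "compartment")
            hits += comp.verdict == "significant"
        assert hits >= 28  # d = 1.5 at n = 100 hemispheres is near-certain

    def test_verdict_bands(self):
        fam_alpha = 0.05 / 19
        assert inference.verdict_for(fam_alpha / 2, fam_alpha) == "significant"
        assert inference.verdict_for(fam_alpha * 5, fam_alpha) == "trending"
        assert inference.verdict_for(fam_alpha * 20, fam_alpha) == "ns"

    def test_missing_covariates_are_rejected(self):
        rng = np.random.default_rng(2)
        subjects = ["s0", "s1", "s2"]
        recs = _records(rng, subjects, n_subregions=1)
        cov = _covariates(subjects, rng)
        cov.loc[1, "age"] = np.nan
        with pytest.raises(ValueError, match="missing covariate"):
            inference.subregion_ancova(recs, cov)
        cov2 = _covariates(["s0", "s1"], rng)   # s2 absent entirely
        with pytest.raises(ValueError, match="lack covariate rows"):
            inference.subregion_ancova(recs, cov2)


class TestPairedTFamily:
    def test_identical_vectors_are_degenerate_null(self):
        out = inference.paired_t_family([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert out["t"] == 0.0 and out["p"] == 1.0 and out["degenerate"]

    def test_constant_shift_is_overwhelming(self):
        a = np.arange(10, dtype=float)
        out = inference.paired_t_family(a + 2.0, a)
        assert out["p"] < 1e-6

    def test_family_of_three_uses_0167(self):
        rng = np.random.default_rng(3)
        a = rng.normal(0, 1, 20)
        out = inference.paired_t_family(a + 1.0, a, family_size=3)
        assert out["family_alpha"] == pytest.approx(0.05 / 3)

    def test_length_mismatch_and_minimum_n(self):
        with pytest.raises(ValueError):
            inference.paired_t_family([1.0, 2.0], [1.0, 2.0, 3.0])
        with pytest.raises(ValueError):
            inference.paired_t_family([1.0, 2.0], [1.0, 2.0])


def _enumeration_oracle(diffs):
    """Independent exhaustive max-statistic FWE p-values for tiny inputs."""
    n, v = diffs.shape

    def tstats(x):
        m = x.mean(axis=0)
        s = x.std(axis=0, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = m / (s / np.sqrt(n))
        return np.nan_to_num(t)

    t_obs = tstats(diffs)
    max_stats = []
    for signs in itertools.product((1, -1), repeat=n):
        flipped = diffs * np.asarray(signs)[:, None]
        max_stats.append(tstats(flipped).max())
    max_stats = np.asarray(max_stats)
    return np.array([(max_stats >= t - 1e-12).mean() for t in t_obs])


class TestVoxelwisePermutation:
    def test_all_zero_differences_are_never_significant(self):
        grid = VolumeGrid(shape=(4, 4, 4), affine=np.eye(4))
        diffs = np.zeros((8, 4, 4, 4))
        result = inference.voxelwise_permutation_test(diffs, grid, 200, rng_seed=0)
        sig_pos, sig_neg = result.significant_mask_per_direction
        assert sig_pos.sum() == 0 and sig_neg.sum() == 0

    def test_exhaustive_p_matches_the_enumeration_oracle(self):
        rng = np.random.default_rng(4)
        grid = VolumeGrid(shape=(3, 2, 1), affine=np.eye(4))
        n = 7
        diffs = rng.normal(0.4, 1.0, (n, 3, 2, 1))
        result = inference.voxelwise_permutation_test(
            diffs, grid, n_permutations=5000, rng_seed=1
        )
        assert result.exhaustive and result.n_permutations == 2**n
        oracle = _enumeration_oracle(diffs.reshape(n, -1))
        fwe_pos = result.fwe_p_per_direction[0].reshape(-1)
        assert np.allclose(fwe_pos, oracle, atol=1e-12)

    def test_fwe_p_values_respect_their_floor(self):
        rng = np.random.default_rng(5)
        grid = VolumeGrid(shape=(3, 3, 3), affine=np.eye(4))
        diffs = rng.normal(2.0, 1.0, (6, 3, 3, 3))
        result = inference.voxelwise_permutation_test(diffs, grid, 40, rng_seed=2)
        fwe = result.fwe_p_map.values
        assert np.nanmin(fwe) >= 1.0 / (result.n_permutations + 1) - 1e-12
        assert np.nanmax(fwe) <= 1.0

    def test_planted_corridor_power_and_specificity(self):
        rng = np.random.default_rng(6)
        grid = VolumeGrid(shape=(8, 8, 8), affine=np.eye(4))
        corridor = np.zeros(grid.shape, dtype=bool)
        corridor[3:5] = True
        hits, false_alarms = [], []
        for seed in range(5):
            diffs = rng.normal(0, 1, (16, 8, 8, 8))
            diffs[:, corridor] += 2.0
            result = inference.voxelwise_permutation_test(
                diffs, grid, 500, alpha=0.025, rng_seed=seed
            )
            sig_pos, _ = result.significant_mask_per_direction
            hits.append(sig_pos[corridor].mean())
            false_alarms.append(sig_pos[~corridor].mean())
        assert np.mean(hits) >= 0.9
        assert np.mean(false_alarms) < 0.025

    def test_variance_smoothing_changes_the_statistic_but_not_validity(self):
        rng = np.random.default_rng(7)
        grid = VolumeGrid(shape=(6, 6, 6), affine=np.diag([2.0, 2.0, 2.0, 1.0]))
        diffs = rng.normal(0, 1, (10, 6, 6, 6))
        plain = inference.voxelwise_permutation_test(diffs, grid, 300, rng_seed=3)
        smoothed = inference.voxelwise_permutation_test(
            diffs, grid, 300, variance_smoothing_mm=2.0, rng_seed=3
        )
        assert not np.allclose(
            plain.statistic_map.values, smoothed.statistic_map.values
        )
        sig_pos, sig_neg = smoothed.significant_mask_per_direction
        assert sig_pos.sum() + sig_neg.sum() <= 2  # null data stays null

    def test_analysis_mask_restricts_the_search(self):
        rng = np.random.default_rng(8)
        grid = VolumeGrid(shape=(5, 5, 5), affine=np.eye(4))
        diffs = rng.normal(1.0, 1.0, (10, 5, 5, 5))
        mask = np.zeros(grid.shape, dtype=bool)
        mask[:2] = True
        result = inference.voxelwise_permutation_test(
            diffs, grid, 200, rng_seed=4, analysis_mask=mask
        )
        assert np.isnan(result.fwe_p_map.values[~mask]).all()

    def test_too_few_subjects_rejected(self):
        grid = VolumeGrid(shape=(2, 2, 2), affine=np.eye(4))
        with pytest.raises(ValueError):
            inference.voxelwise_permutation_test(np.zeros((1, 2, 2, 2)), grid, 10)
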