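"""Bias scoring and equal-volume mask selection, with an exhaustive oracle."""

import numpy as np
import pytest

from striocon import parcellate, pipeline
from striocon.core import BaitGrouping, ConnectivityTable, LabelVolume, ProbabilityVolume
from striocon.phantom import STRIOSOME


def _tiny_conn(small_grid, counts, groups=("s1", "m1")):
    counts = np.asarray(counts, dtype=float)
    seeds = [(i, 0, 0) for i in range(len(counts))]
    return ConnectivityTable(small_grid, seeds, groups, counts, 1000)


def _tiny_baits():
    return BaitGrouping(("s1",), ("m1",))


class TestBiasScore:
    def test_formula(self, small_grid):
        conn = _tiny_conn(small_grid, [[300, 100], [50, 50], [0, 0]])
        p_s, p_m = parcellate.ctt_bias_score(conn, _tiny_baits())
        vals_s = p_s.values[[0, 1, 2], 0, 0]
        assert vals_s[0] == pytest.approx(0.75)
        assert vals_s[1] == pytest.approx(0.5)
        assert np.isnan(vals_s[2])  # unclassified, never 0.5
        assert p_m.values[0, 0, 0] == pytest.approx(0.25)

    def test_complementarity_at_classified_voxels(self, parcellation):
        _, p_s, p_m, _ = parcellation
        both = p_s.defined_mask & p_m.defined_mask
        assert np.allclose(p_s.values[both] + p_m.values[both], 1.0, atol=1e-12)

    def test_all_unclassified_is_an_error(self, small_grid):
        conn = _tiny_conn(small_grid, [[0, 0], [0, 0]])
        with pytest.raises(ValueError, match="unclassified"):
            parcellate.ctt_bias_score(conn, _tiny_baits())

    def test_missing_bait_group_is_an_error(self, small_grid):
        conn = _tiny_conn(small_grid, [[1, 1]], groups=("s1", "other"))
        with pytest.raises(ValueError, match="lacks bait"):
            parcellate.ctt_bias_score(conn, _tiny_baits())


def _volumes_from_scores(grid, scores):
    vals_s = np.full(grid.shape, np.nan)
    flat = vals_s.reshape(-1)
    flat[: len(scores)] = scores
    vals_s = flat.reshape(grid.shape)
    return (
        ProbabilityVolume(grid, vals_s),
        ProbabilityVolume(grid, 1.0 - vals_s),
    )


class TestEqualVolumeMasks:
    def test_mask_size_is_the_rounded_fraction(self, small_grid):
        rng = np.random.default_rng(0)
        grid = small_grid
        n = 100
        p_s, p_m = _volumes_from_scores(grid, rng.random(n))
        masks = parcellate.select_equal_volume_masks(p_s, p_m, 0.13)
        assert masks.n_striosome == masks.n_matrix == 13

    def test_all_ties_still_equal_and_disjoint_and_deterministic(self, small_grid):
        p_s, p_m = _volumes_from_scores(small_grid, np.full(60, 0.5))
        m1 = parcellate.select_equal_volume_masks(p_s, p_m, 0.2)
        m2 = parcellate.select_equal_volume_masks(p_s, p_m, 0.2)
        assert m1.n_striosome == m1.n_matrix == round(0.2 * 60)
        assert np.array_equal(m1.striosome_like, m2.striosome_like)
        assert np.array_equal(m1.matrix_like, m2.matrix_like)

    def test_fraction_half_or_more_rejected(self, small_grid):
        p_s, p_m = _volumes_from_scores(small_grid, np.random.default_rng(1).random(50))
        with pytest.raises(ValueError):
            parcellate.select_equal_volume_masks(p_s, p_m, 0.5)

    def test_row_order_invariance(self, small_grid, baits):
        rng = np.random.default_rng(2)
        counts = rng.integers(0, 50, size=(40, 9)).astype(float)
        seeds = [(i % 6, (i // 6) % 6, i // 36) for i in range(40)]
        conn = ConnectivityTable(small_grid, seeds, baits.all_regions, counts, 1000)
        perm = rng.permutation(40)
        shuffled = ConnectivityTable(
            small_grid, np.asarray(seeds)[perm], baits.all_regions, counts[perm], 1000
        )
        for c in (conn, shuffled):
            p_s, p_m = parcellate.ctt_bias_score(c, baits)
            masks = parcellate.select_equal_volume_masks(p_s, p_m, 0.2)
            if c is conn:
                first = masks
        assert np.array_equal(first.striosome_like, masks.striosome_like)
        assert np.array_equal(first.matrix_like, masks.matrix_like)

    def test_matches_exhaustive_sort_and_take_oracle(self, small_grid):
        # independent oracle: sort (score desc, voxel asc) over all
        # classified voxels and take the head
        rng = np.random.default_rng(3)
        for trial in range(5):
            n = int(rng.integers(50, 200))
            scores = np.round(rng.random(n), 2)  # duplicates force tie-breaks
            p_s, p_m = _volumes_from_scores(small_grid, scores)
            fraction = 0.17
            masks = parcellate.select_equal_volume_masks(p_s, p_m, fraction)
            voxels = np.argwhere(np.isfinite(p_s.values))
            vals = p_s.values[tuple(voxels.T)]
            k = round(fraction * n)
            oracle = sorted(
                zip(vals, map(tuple, voxels)), key=lambda t: (-t[0], t[1])
            )[:k]
            assert {v for _, v in oracle} == {tuple(v) for v in masks.striosome_like}
            remaining = [
                (1 - val, vox)
                for val, vox in zip(vals, map(tuple, voxels))
                if vox not in {v for _, v in oracle}
            ]
            oracle_m = sorted(remaining, key=lambda t: (-t[0], t[1]))[:k]
            assert {v for _, v in oracle_m} == {tuple(v) for v in masks.matrix_like}

    def test_recovery_on_the_phantom(self, default_truth, parcellation):
        _, _, _, masks = parcellation
        purity = pipeline.mask_purity(masks, default_truth)
        assert purity["striosome"] >= 0.9
        assert purity["matrix"] >= 0.9


class TestN1Parcellation:
    def test_null_contribution_leaves_masks_unchanged(self, small_grid):
        baits = BaitGrouping(("s1", "s2"), ("m1",))
        counts = np.random.default_rng(4).integers(1, 50, size=(30, 3)).astype(float)
        counts[:, 1] = 0.0  # s2 never reached
        seeds = [(i % 6, i // 6, 0) for i in range(30)]
        conn = ConnectivityTable(small_grid, seeds, ("s1", "s2", "m1"), counts, 1000)
        full = parcellate.select_equal_volume_masks(
            *parcellate.ctt_bias_score(conn, baits), 0.2
        )
        n1 = parcellate.n1_parcellation(conn, baits, "s2", 0.2)
        assert np.array_equal(full.striosome_like, n1.striosome_like)
        assert np.array_equal(full.matrix_like, n1.matrix_like)
        assert n1.source["left_out"] == "s2"

    def test_sole_group_member_cannot_be_left_out(self, small_grid):
        baits = BaitGrouping(("s1",), ("m1", "m2"))
        conn = _tiny_conn(small_grid, [[5, 5]], groups=("s1", "m1"))
        with pytest.raises(ValueError, match="sole"):
            parcellate.n1_parcellation(conn, baits, "s1", 0.2)

    def test_phantom_purity_survives_leaving_one_region_out(
        self, default_truth, baits, parcellation
    ):
        conn, _, _, full_masks = parcellation
        full_purity = pipeline.mask_purity(full_masks, default_truth)
        n1 = parcellate.n1_parcellation(conn, baits, "basolateral_amygdala", 0.13)
        n1_purity = pipeline.mask_purity(n1, default_truth)
        for comp in ("striosome", "matrix"):
            assert n1_purity[comp] >= full_purity[comp] - 0.10


class TestProportionalMasks:
    def test_quota_counts_per_nucleus(self, default_truth, parcellation):
        _, p_s, p_m, _ = parcellation
        masks = parcellate.proportional_masks(
            p_s, p_m, default_truth.nucleus_labels, {"caudate": 80, "putamen": 100}
        )
        assert masks.n_striosome == masks.n_matrix == 180
        nuc = default_truth.nucleus_labels.labels
        in_caudate = nuc[tuple(masks.striosome_like.T)] == 1
        assert in_caudate.sum() == 80

    def test_zero_quota_contributes_nothing(self, default_truth, parcellation):
        _, p_s, p_m, _ = parcellation
        masks = parcellate.proportional_masks(
            p_s, p_m, default_truth.nucleus_labels, {"caudate": 0, "putamen": 50}
        )
        nuc = default_truth.nucleus_labels.labels
        assert (nuc[tuple(masks.striosome_like.T)] == 2).all()

    def test_insufficient_quota_names_the_nucleus(self, default_truth, parcellation):
        _, p_s, p_m, _ = parcellation
        with pytest.raises(ValueError, match="caudate"):
            parcellate.proportional_masks(
                p_s, p_m, default_truth.nucleus_labels, {"caudate": 10**6}
            )

    def test_quota_rebalances_a_caudate_dominant_score_field(self, default_truth):
        # constructed field: caudate striosome scores uniformly exceed the
        # putamen's, so fraction-based selection concentrates in the caudate
        # while quota selection cannot
        nuc = default_truth.nucleus_labels
        vals = np.full(nuc.grid.shape, np.nan)
        rng = np.random.default_rng(5)
        vals[nuc.labels == 1] = 0.8 + 0.1 * rng.random((nuc.labels == 1).sum())
        vals[nuc.labels == 2] = 0.3 + 0.1 * rng.random((nuc.labels == 2).sum())
        p_s = ProbabilityVolume(nuc.grid, vals)
        p_m = ProbabilityVolume(nuc.grid, 1.0 - vals)
        frac_masks = parcellate.select_equal_volume_masks(p_s, p_m, 0.05)
        in_caudate = nuc.labels[tuple(frac_masks.striosome_like.T)] == 1
        assert in_caudate.all()
        quota_masks = parcellate.proportional_masks(
            p_s, p_m, nuc, {"caudate": 60, "putamen": 74}
        )
        in_caudate_q = nuc.labels[tuple(quota_masks.striosome_like.T)] == 1
        assert in_caudate_q.sum() == 60
        assert not np.array_equal(
            frac_masks.striosome_like, quota_masks.striosome_like
        )
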