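"""Phantom generator: ground-truth construction and simulators."""

import numpy as np
import pytest
import scipy.ndimage as ndi

from striocon import phantom
from striocon.core import BaitGrouping, CompartmentMaskPair
from striocon.phantom import MATRIX, STRIOSOME


def _offset_delta(nuc, comp):
    """Striosome-minus-matrix mean offset from each voxel's nucleus centroid."""
    grid = nuc.grid
    cents = {
        n: grid.voxel_to_world(np.argwhere(nuc.labels == n)).mean(axis=0)
        for n in (1, 2)
    }
    mean_off = {}
    for c in (STRIOSOME, MATRIX):
        offs = [
            grid.voxel_to_world(np.argwhere((comp.labels == c) & (nuc.labels == n)))
            - cents[n]
            for n in (1, 2)
        ]
        mean_off[c] = np.concatenate(offs).mean(axis=0)
    return mean_off[STRIOSOME] - mean_off[MATRIX]


class TestMakeStriatum:
    def test_fraction_is_met_by_construction(self, default_truth):
        comp = default_truth.compartment_labels.labels
        frac = (comp == STRIOSOME).sum() / (comp > 0).sum()
        assert 0.13 <= frac <= 0.17

    def test_both_nuclei_contain_both_compartments(self, default_truth):
        nuc = default_truth.nucleus_labels.labels
        comp = default_truth.compartment_labels.labels
        for n in (1, 2):
            assert (comp[nuc == n] == STRIOSOME).any()
            assert (comp[nuc == n] == MATRIX).any()

    def test_infeasible_fraction_rejected(self):
        with pytest.raises(ValueError):
            phantom.make_striatum(striosome_fraction=0.6)

    def test_gradients_put_striosome_medial_rostral_ventral(self):
        # Monte-Carlo over seeds: relative to its nucleus centroid, the
        # striosome must sit medial (dx < 0 in the right hemisphere),
        # rostral (dy > 0) and ventral (dz < 0) in at least 19 of 20 draws
        wins = np.zeros(3)
        for seed in range(20):
            nuc, comp = phantom.make_striatum(rng_seed=seed)
            d = _offset_delta(nuc, comp)
            wins += [d[0] < 0, d[1] > 0, d[2] < 0]
        assert (wins >= 19).all()

    def test_zero_gradients_remove_the_location_bias(self):
        deltas = []
        for seed in range(20):
            nuc, comp = phantom.make_striatum(
                gradient_strengths=(0, 0, 0), rng_seed=seed
            )
            deltas.append(_offset_delta(nuc, comp))
        mean_delta_mm = np.abs(np.mean(deltas, axis=0))
        assert (mean_delta_mm < 1.5).all()  # < 1 voxel of 1.5 mm


class TestMakeInsula:
    def test_default_profile_matches_the_observed_split(self):
        _, bias = phantom.make_insula()
        vals = np.array(list(bias.values()))
        assert (vals > 0.55).sum() == 7       # striosome-leaning
        assert (vals < 0.45).sum() == 9       # matrix-leaning
        assert ((vals >= 0.45) & (vals <= 0.55)).sum() == 3

    def test_uniform_profile_is_neutral(self):
        profile = {i: 0.5 for i in range(1, 20)}
        _, bias = phantom.make_insula(true_bias_profile=profile)
        assert all(v == 0.5 for v in bias.values())

    def test_two_subregions_partition_the_sheet_contiguously(self):
        labels, bias = phantom.make_insula(
            n_subregions=2, true_bias_profile={1: 0.7, 2: 0.3}
        )
        present = set(np.unique(labels.labels)) - {0}
        assert present == {1, 2}
        for lab in present:
            n_comp = ndi.label(labels.labels == lab)[1]
            assert n_comp == 1

    def test_too_many_subregions_rejected(self):
        with pytest.raises(ValueError, match="sheet"):
            phantom.make_insula(n_subregions=100000)

    def test_voxel_bias_spread_preserves_subregion_means(self, default_truth):
        vb = default_truth.insula_voxel_bias
        for lab, b in default_truth.subregion_true_bias.items():
            vox = default_truth.insula_labels.voxels_of(lab)
            vals = vb.values[tuple(vox.T)]
            assert vals.mean() == pytest.approx(b, abs=1e-9)
            assert vals.min() >= 0.0 and vals.max() <= 1.0


class TestSimulateCtt:
    def test_perfect_fidelity_forces_zero_discordant_counts(self, default_truth, baits):
        conn = phantom.simulate_ctt(
            default_truth, baits, 500, fidelity=1.0, rng_seed=0
        )
        comp = default_truth.compartment_of(conn.seed_voxels)
        strio_counts = conn.group_counts(baits.striosome_group)
        matrix_counts = conn.group_counts(baits.matrix_group)
        assert (matrix_counts[comp == STRIOSOME] == 0).all()
        assert (strio_counts[comp == MATRIX] == 0).all()

    def test_mean_concordant_fraction_tracks_fidelity(self, default_truth, baits):
        conn = phantom.simulate_ctt(default_truth, baits, 5000, fidelity=0.8, rng_seed=1)
        comp = default_truth.compartment_of(conn.seed_voxels)
        s = conn.group_counts(baits.striosome_group)
        m = conn.group_counts(baits.matrix_group)
        concordant = np.where(comp == STRIOSOME, s, m) / (s + m)
        assert concordant.mean() == pytest.approx(0.8, abs=0.01)

    def test_half_fidelity_centers_bias_on_half(self, default_truth, baits):
        conn = phantom.simulate_ctt(default_truth, baits, 5000, fidelity=0.5, rng_seed=2)
        s = conn.group_counts(baits.striosome_group)
        m = conn.group_counts(baits.matrix_group)
        assert (s / (s + m)).mean() == pytest.approx(0.5, abs=0.01)

    def test_totals_exact_without_lapse_and_reduced_with(self, default_truth, baits):
        conn = phantom.simulate_ctt(default_truth, baits, 1000, rng_seed=3)
        assert (conn.counts.sum(axis=1) == 1000).all()
        lapsed = phantom.simulate_ctt(
            default_truth, baits, 1000, lapse=0.2, rng_seed=3
        )
        assert lapsed.counts.sum(axis=1).mean() == pytest.approx(800, rel=0.01)

    def test_fidelity_gradient_preserves_means_and_bounds(self, default_truth, baits):
        conn = phantom.simulate_ctt(
            default_truth, baits, 5000, fidelity=0.8, fidelity_gradient=0.1, rng_seed=4
        )
        comp = default_truth.compartment_of(conn.seed_voxels)
        s = conn.group_counts(baits.striosome_group)
        m = conn.group_counts(baits.matrix_group)
        concordant = np.where(comp == STRIOSOME, s, m) / (s + m)
        assert concordant.mean() == pytest.approx(0.8, abs=0.01)
        # gradient must vanish at fidelity 1 so discordant counts stay zero
        perfect = phantom.simulate_ctt(
            default_truth, baits, 500, fidelity=1.0, fidelity_gradient=0.1, rng_seed=5
        )
        comp_p = default_truth.compartment_of(perfect.seed_voxels)
        assert (perfect.group_counts(baits.matrix_group)[comp_p == STRIOSOME] == 0).all()

    def test_distance_correction_rescales_counts(self, default_truth, baits):
        raw = phantom.simulate_ctt(default_truth, baits, 100, rng_seed=6)
        corrected = phantom.simulate_ctt(
            default_truth, baits, 100, rng_seed=6, distance_correction=True
        )
        assert not np.allclose(raw.counts, corrected.counts)
        assert (corrected.counts >= 0).all()

    def test_parameter_errors(self, default_truth, baits):
        with pytest.raises(ValueError):
            phantom.simulate_ctt(default_truth, baits, 0)
        with pytest.raises(ValueError):
            phantom.simulate_ctt(default_truth, baits, 10, fidelity=0.3)


class TestSimulateInsuloStriate:
    def test_total_bias_forces_zero_matrix_counts(self, parcellation):
        _, _, _, masks = parcellation
        profile = {i: 1.0 for i in range(1, 20)}
        truth = phantom.make_phantom(
            true_bias_profile=profile, within_subregion_sd=0.0, rng_seed=7
        )
        conn = phantom.simulate_insulo_striate(truth, masks, 100, rng_seed=0)
        assert (conn.group_counts(["matrix_like"]) == 0).all()

    def test_single_segment_path_density_support(self, default_truth):
        masks = CompartmentMaskPair(
            default_truth.grid, [(10, 20, 10)], [(20, 10, 20)]
        )
        profile_truth = phantom.make_phantom(
            true_bias_profile={i: 1.0 for i in range(1, 20)},
            within_subregion_sd=0.0,
            rng_seed=8,
        )
        conn, (dens_s, dens_m) = phantom.simulate_insulo_striate(
            profile_truth, masks, 10, rng_seed=1, with_paths=True
        )
        from skimage.draw import line_nd

        expected = np.zeros(default_truth.grid.shape, dtype=bool)
        for seed in conn.seed_voxels:
            line = line_nd(tuple(seed), (10, 20, 10), endpoint=True)
            expected[line] = True
        assert (dens_m.values == 0).all()
        assert set(map(tuple, np.argwhere(dens_s.values > 0))) <= set(
            map(tuple, np.argwhere(expected))
        )

    def test_subregion_empirical_fraction_matches_truth(self, default_truth, parcellation):
        _, _, _, masks = parcellation
        conn = phantom.simulate_insulo_striate(default_truth, masks, 5000, rng_seed=2)
        labels = default_truth.insula_labels.labels[tuple(conn.seed_voxels.T)]
        s = conn.group_counts(["striosome_like"])
        m = conn.group_counts(["matrix_like"])
        for lab, b in default_truth.subregion_true_bias.items():
            sel = labels == lab
            frac = s[sel].sum() / (s[sel] + m[sel]).sum()
            assert frac == pytest.approx(b, abs=0.02)

    def test_tissue_targeting_tracks_mask_composition(self, default_truth, parcellation):
        # with perfectly pure equal-size masks the tissue mode reduces to
        # the mask mode in expectation
        _, _, _, masks = parcellation
        conn = phantom.simulate_insulo_striate(
            default_truth, masks, 5000, rng_seed=3, targeting="tissue"
        )
        labels = default_truth.insula_labels.labels[tuple(conn.seed_voxels.T)]
        s = conn.group_counts(["striosome_like"])
        m = conn.group_counts(["matrix_like"])
        lab = 13  # strongly striosome-leaning subregion
        sel = labels == lab
        frac = s[sel].sum() / (s[sel] + m[sel]).sum()
        assert frac == pytest.approx(
            default_truth.subregion_true_bias[lab], abs=0.05
        )

    def test_empty_mask_rejected(self, default_truth):
        empty = CompartmentMaskPair(
            default_truth.grid, np.empty((0, 3), int), [(1, 1, 1)]
        )
        with pytest.raises(ValueError, match="non-empty"):
            phantom.simulate_insulo_striate(default_truth, empty, 10)


def test_seeded_determinism_everywhere(baits):
    t1 = phantom.make_phantom(rng_seed=42)
    t2 = phantom.make_phantom(rng_seed=42)
    assert np.array_equal(
        t1.compartment_labels.labels, t2.compartment_labels.labels
    )
    assert np.array_equal(
        t1.insula_voxel_bias.values[np.isfinite(t1.insula_voxel_bias.values)],
        t2.insula_voxel_bias.values[np.isfinite(t2.insula_voxel_bias.values)],
    )
    c1 = phantom.simulate_ctt(t1, baits, 200, rng_seed=9)
    c2 = phantom.simulate_ctt(t2, baits, 200, rng_seed=9)
    assert np.array_equal(c1.counts, c2.counts)
    c3 = phantom.simulate_ctt(t1, baits, 200, rng_seed=10)
    assert not np.array_equal(c1.counts, c3.counts)


def test_region_ctt_strio_affinity_direction(default_truth, parcellation):
    _, _, _, masks = parcellation
    conn = phantom.simulate_region_ctt(
        default_truth, "primary_motor", masks, strio_affinity=0.05,
        streamlines_per_seed=5000, rng_seed=0,
    )
    s = conn.group_counts(["striosome_like"])
    m = conn.group_counts(["matrix_like"])
    assert (m > s).all()
    with pytest.raises(ValueError, match="unknown bait region"):
        phantom.simulate_region_ctt(default_truth, "nope", masks, 0.5)
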