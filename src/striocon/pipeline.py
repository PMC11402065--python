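"""End-to-end orchestration of the analysis rounds on phantom data.

Mirrors the seven tractography rounds: (1) parcellation, (2) N-1
parcellation, (3) left-out-region bias, (4) bundle mapping with AB-BA
averaging and Dice of thresholded cores, (5) per-subregion bias with QC and
COG geometry, (6) nucleus-proportional masks, (7) the jittered-neighborhood
control — plus the statistical testing plan on the resulting tables.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from . import bundles, controls, inference, io, parcellate, phantom, subregion, validate
from .core import AnalysisParams, BaitGrouping, CompartmentMaskPair

__all__ = [
    "make_covariates",
    "parcellation_round",
    "bias_records_for_subject",
    "records_to_ancova_long",
    "mask_purity",
    "run_full_study",
]


def make_covariates(subjects: list[str], rng_seed: int = 0) -> pd.DataFrame:
    """Plausible demographic covariates: balanced sex, 90% right-handed,
    mixed self-identified race, ages spread over the adult span."""
    rng = np.random.default_rng(rng_seed)
    n = len(subjects)
    races = rng.choice(
        ["asian", "black", "white", "other"], size=n, p=[0.13, 0.28, 0.51, 0.08]
    )
    return pd.DataFrame(
        {
            "subject": subjects,
            "sex": [("F", "M")[i % 2] for i in range(n)],
            "handedness": np.where(rng.random(n) < 0.9, "right", "left"),
            "race": races,
            "age": np.linspace(20, 65, n).round(0),
        }
    )


def parcellation_round(
    truth: phantom.PhantomTruth,
    params: AnalysisParams | None = None,
    baits: BaitGrouping | None = None,
    streamlines_per_seed: int = 5000,
    fidelity: float | None = None,
    rng_seed: int = 0,
):
    """Round 1: classification-targets scoring and equal-volume mask selection."""
    params = params or AnalysisParams()
    baits = baits or BaitGrouping()
    conn = phantom.simulate_ctt(
        truth, baits, streamlines_per_seed, fidelity=fidelity, rng_seed=rng_seed
    )
    p_s, p_m = parcellate.ctt_bias_score(conn, baits)
    masks = parcellate.select_equal_volume_masks(p_s, p_m, params.mask_fraction)
    return conn, p_s, p_m, masks


def mask_purity(masks: CompartmentMaskPair, truth: phantom.PhantomTruth) -> dict:
    """Fraction of each mask whose ground-truth compartment is concordant."""
    comp_s = truth.compartment_of(masks.striosome_like)
    comp_m = truth.compartment_of(masks.matrix_like)
    return {
        "striosome": float((comp_s == phantom.STRIOSOME).mean()),
        "matrix": float((comp_m == phantom.MATRIX).mean()),
    }


def bias_records_for_subject(
    truth: phantom.PhantomTruth,
    masks: CompartmentMaskPair,
    params: AnalysisParams | None = None,
    streamlines_per_seed: int = 5000,
    rng_seed: int = 0,
    subject: str = "s0",
    hemisphere: str = "right",
    targeting: str = "mask",
) -> pd.DataFrame:
    """Round-5 style quantification for one subject-hemisphere.

    Simulates insular classification-targets counts against the masks,
    normalizes the per-voxel probability pair with edge trimming, and
    returns the per-subregion bias records.
    """
    params = params or AnalysisParams()
    conn = phantom.simulate_insulo_striate(
        truth, masks, streamlines_per_seed, rng_seed=rng_seed, targeting=targeting
    )
    s = conn.group_counts(["striosome_like"])
    m = conn.group_counts(["matrix_like"])
    total = s + m
    p = np.where(total > 0, s / np.where(total > 0, total, 1.0), np.nan)
    vol_s = np.full(truth.grid.shape, np.nan)
    vol_m = np.full(truth.grid.shape, np.nan)
    vol_s[tuple(conn.seed_voxels.T)] = p
    vol_m[tuple(conn.seed_voxels.T)] = 1.0 - p
    from .core import ProbabilityVolume

    ps = ProbabilityVolume(truth.grid, vol_s)
    pm = ProbabilityVolume(truth.grid, vol_m)
    ns, nm, _ = subregion.normalize_probability_pair(ps, pm, params.edge_trim_sum)
    recs = subregion.subregion_bias(
        ns, nm, truth.insula_labels, params.suprathreshold, subject, hemisphere
    )
    return recs, (ns, nm)


def records_to_ancova_long(records: pd.DataFrame) -> pd.DataFrame:
    """Reshape QC-passing bias records into the ANCOVA layout: one row per
    subject x hemisphere x subregion x compartment with the suprathreshold
    voxel count as response."""
    keep = records[records["qc_pass"]]
    long = keep.melt(
        id_vars=["subject", "hemisphere", "subregion"],
        value_vars=["n_strio", "n_matrix"],
        var_name="compartment",
        value_name="count",
    )
    long["compartment"] = long["compartment"].map(
        {"n_strio": "striosome", "n_matrix": "matrix"}
    )
    return long


def run_full_study(
    out_dir=None,
    rng_seed: int = 0,
    params: AnalysisParams | None = None,
    n_subjects: int = 8,
    streamlines_parcellation: int = 5000,
    streamlines_subregion: int = 5000,
    bundle_streamlines: int = 150,
    fidelity: float = 0.9,
    quotas: dict[str, int] | None = None,
) -> dict:
    """Run every stage on one phantom and return a summary dictionary.

    Problem sizes default to desk scale (a single ~2,500-voxel striatal
    hemisphere, 8 simulated subjects); all randomness derives from
    ``rng_seed``.  When ``out_dir`` is given, tables, volumes and a
    provenance record are written there.
    """
    params = params or AnalysisParams()
    quotas = quotas or {"caudate": 80, "putamen": 100}
    base = np.random.SeedSequence(rng_seed).generate_state(1)[0] % (2**31 - 1)
    truth = phantom.make_phantom(fidelity=fidelity, rng_seed=int(base))
    baits = BaitGrouping()
    summary: dict = {"rng_seed": rng_seed}

    # round 1: parcellation
    conn, p_s, p_m, masks = parcellation_round(
        truth, params, baits, streamlines_parcellation, rng_seed=int(base) + 1
    )
    purity = mask_purity(masks, truth)
    summary["mask_purity_striosome"] = purity["striosome"]
    summary["mask_purity_matrix"] = purity["matrix"]

    # validation: abundance and voxel location
    pct_s, pct_m = validate.abundance_fraction(p_s, p_m, params.high_bias_threshold)
    summary["abundance_striosome_percent"] = pct_s
    summary["abundance_matrix_percent"] = pct_m
    records_loc = validate.location_records(masks, truth.nucleus_labels)
    anova = validate.location_anova(records_loc)
    summary["location_anova"] = anova["anova"]

    # rounds 2-3: N-1 parcellation and left-out-region bias
    n1 = parcellate.n1_parcellation(conn, baits, "primary_motor", params.mask_fraction)
    motor_conn = phantom.simulate_region_ctt(
        truth, "primary_motor", n1, strio_affinity=0.05,
        streamlines_per_seed=streamlines_subregion, rng_seed=int(base) + 2,
    )
    _, pct_motor_matrix = validate.leftout_region_bias(
        motor_conn, params.high_bias_threshold
    )
    summary["motor_matrix_biased_percent"] = pct_motor_matrix

    # round 4: bundle mapping
    conn_ab, (dens_s_ab, dens_m_ab) = phantom.simulate_insulo_striate(
        truth, masks, bundle_streamlines, rng_seed=int(base) + 3, with_paths=True
    )
    conn_ba, (dens_s_ba, dens_m_ba) = phantom.simulate_insulo_striate(
        truth, masks, bundle_streamlines, rng_seed=int(base) + 4,
        with_paths=True, direction="striatum_to_insula",
    )
    n_insula = len(truth.insular_voxels())
    bmaps = {}
    for comp, ab, ba, col in (
        ("striosome", dens_s_ab, dens_s_ba, "striosome_like"),
        ("matrix", dens_m_ab, dens_m_ba, "matrix_like"),
    ):
        m_ab = bundles.BundleMap(ab, comp, truth.grid.hemisphere,
                                 float(conn_ab.group_counts([col]).sum()), n_insula)
        m_ba = bundles.BundleMap(ba, comp, truth.grid.hemisphere,
                                 float(conn_ba.group_counts([col]).sum()), n_insula)
        bmaps[comp] = bundles.abba_average(m_ab, m_ba).normalized()
    dice_by_fraction = {
        f: bundles.dice(
            bundles.core_threshold(bmaps["striosome"], f),
            bundles.core_threshold(bmaps["matrix"], f),
        )
        for f in params.core_fractions
    }
    summary["core_dice"] = dice_by_fraction
    summary["density_stats"] = bundles.streamline_density_stats(
        bmaps["striosome"].total_streamlines,
        bmaps["matrix"].total_streamlines,
        n_insula,
    )

    # round 5: subregion bias across subjects and hemispheres
    subjects = [f"s{i:02d}" for i in range(n_subjects)]
    all_records = []
    norm_pairs = {}
    for si, subj in enumerate(subjects):
        for hi, hemi in enumerate(("left", "right")):
            recs, norm = bias_records_for_subject(
                truth, masks, params, streamlines_subregion,
                rng_seed=int(base) + 10 + 2 * si + hi,
                subject=subj, hemisphere=hemi,
            )
            all_records.append(recs)
            if subj == subjects[0] and hemi == "right":
                norm_pairs["round5"] = norm
    records5 = subregion.hemisphere_qc(
        pd.concat(all_records, ignore_index=True), params.min_suprathreshold_voxels
    )
    summary["subregion_records"] = records5
    cogs = subregion.cog_analysis(*norm_pairs["round5"], params.rostro_caudal_split_y)
    summary["cog"] = cogs

    # significance testing on round-5 records
    covariates = make_covariates(subjects, rng_seed=int(base) + 5)
    long5 = records_to_ancova_long(records5)
    ancova = inference.subregion_ancova(
        long5, covariates,
        family_size=params.bonferroni_family_sizes["subregion_ancova"],
        trending_multiplier=params.trending_multiplier,
    )
    summary["ancova"] = inference.ancova_results_table(ancova)

    # rounds 6-7: controls, quantified in tissue-targeting mode so mask
    # composition (not mask identity) drives the counts
    records5_tissue = []
    for si, subj in enumerate(subjects):
        for hi, hemi in enumerate(("left", "right")):
            recs, _ = bias_records_for_subject(
                truth, masks, params, streamlines_subregion,
                rng_seed=int(base) + 100 + 2 * si + hi,
                subject=subj, hemisphere=hemi, targeting="tissue",
            )
            records5_tissue.append(recs)
    records5_tissue = subregion.hemisphere_qc(
        pd.concat(records5_tissue, ignore_index=True),
        params.min_suprathreshold_voxels,
    )

    prop_masks = parcellate.proportional_masks(
        p_s, p_m, truth.nucleus_labels, quotas
    )
    records6 = []
    for si, subj in enumerate(subjects):
        for hi, hemi in enumerate(("left", "right")):
            recs, _ = bias_records_for_subject(
                truth, prop_masks, params, streamlines_subregion,
                rng_seed=int(base) + 200 + 2 * si + hi,
                subject=subj, hemisphere=hemi, targeting="tissue",
            )
            records6.append(recs)
    records6 = subregion.hemisphere_qc(
        pd.concat(records6, ignore_index=True), params.min_suprathreshold_voxels
    )
    summary["proportional"] = controls.proportional_comparison(
        records5_tissue, records6
    )

    shifted, jit_report = controls.jitter_masks(
        masks, truth.nucleus_labels, params.jitter_max, rng_seed=int(base) + 6
    )
    records7 = []
    for si, subj in enumerate(subjects):
        for hi, hemi in enumerate(("left", "right")):
            recs, _ = bias_records_for_subject(
                truth, shifted, params, streamlines_subregion,
                rng_seed=int(base) + 300 + 2 * si + hi,
                subject=subj, hemisphere=hemi, targeting="tissue",
            )
            records7.append(recs)
    records7 = subregion.hemisphere_qc(
        pd.concat(records7, ignore_index=True), params.min_suprathreshold_voxels
    )
    summary["jitter_report"] = jit_report
    summary["neighborhood"] = controls.neighborhood_comparison(
        records5_tissue, records7,
        family_size=params.bonferroni_family_sizes["subregion_ancova"],
    )

    if out_dir is not None:
        _write_outputs(Path(out_dir), params, rng_seed, truth, conn, p_s, p_m,
                       masks, summary)
    return summary


def _write_outputs(out_dir, params, rng_seed, truth, conn, p_s, p_m, masks, summary):
    out_dir.mkdir(parents=True, exist_ok=True)
    io.write_provenance(out_dir, params=params, seed=rng_seed)
    io.write_label_volume(truth.compartment_labels, out_dir / "compartments.nii.gz")
    io.write_label_volume(truth.nucleus_labels, out_dir / "nuclei.nii.gz")
    io.write_label_volume(truth.insula_labels, out_dir / "insula.nii.gz")
    io.write_connectivity_table(conn, out_dir / "parcellation_ctt.tsv")
    io.write_probability_volume(p_s, out_dir / "p_striosome.nii.gz")
    io.write_probability_volume(p_m, out_dir / "p_matrix.nii.gz")
    io.write_label_volume(masks.as_label_volume(), out_dir / "compartment_masks.nii.gz")
    summary["subregion_records"].to_csv(
        out_dir / "subregion_bias.tsv", sep="\t", index=False
    )
    summary["ancova"].to_csv(out_dir / "ancova.tsv", sep="\t", index=False)
    summary["location_anova"].to_csv(
        out_dir / "location_anova.tsv", sep="\t", index=False
    )
    summary["neighborhood"].to_csv(
        out_dir / "neighborhood_comparison.tsv", sep="\t", index=False
    )
    summary["proportional"]["per_subregion"].to_csv(
        out_dir / "proportional_comparison.tsv", sep="\t", index=False
    )
    lines = [
        "stage\tquantity\tvalue",
        f"parcellation\tmask_purity_striosome\t{summary['mask_purity_striosome']:.4f}",
        f"parcellation\tmask_purity_matrix\t{summary['mask_purity_matrix']:.4f}",
        f"validation\tabundance_striosome_percent\t{summary['abundance_striosome_percent']:.2f}",
        f"validation\tmotor_matrix_biased_percent\t{summary['motor_matrix_biased_percent']:.2f}",
    ]
    for f, d in summary["core_dice"].items():
        lines.append(f"bundles\tdice_core_{int(round(100 * f))}\t{d:.4f}")
    lines.append(
        "bundles\tfold_ratio\t"
        f"{summary['density_stats']['fold_ratio_striosome_over_matrix']:.3f}"
    )
    lines.append(
        "controls\tproportional_rank_correlation\t"
        f"{summary['proportional']['rank_correlation']:.4f}"
    )
    (out_dir / "report.tsv").write_text("\n".join(lines) + "\n")
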