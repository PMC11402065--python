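"""Anatomic validation of the parcellation.

Three checks mirror what is known from striatal histology: the relative
abundance of highly biased voxels (~15% striosome / ~85% matrix), the
intra-striate location of compartment-like voxels relative to their nucleus
centroid (two-factor ANOVA: compartment x nucleus, subject as nuisance), and
the compartment bias of connectivity with a bait region that was left out of
the parcellation (N-1 round).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import scipy.stats as st
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.anova import anova_lm

from .core import (
    CompartmentMaskPair,
    ConnectivityTable,
    LabelVolume,
    ProbabilityVolume,
)

__all__ = [
    "abundance_fraction",
    "location_records",
    "location_anova",
    "leftout_region_bias",
]


def abundance_fraction(
    p_strio: ProbabilityVolume,
    p_matrix: ProbabilityVolume,
    threshold: float = 0.87,
) -> tuple[float, float]:
    """Percent of highly biased volume that is striosome-like vs matrix-like.

    A voxel is highly biased when its connection probability to either
    compartment reaches ``threshold``; the two percentages sum to 100.
    """
    if not 0.5 < threshold <= 1:
        raise ValueError("threshold must lie in (0.5, 1]")
    p_strio.grid.require_same(p_matrix.grid)
    n_s = int(np.nansum(p_strio.values >= threshold))
    n_m = int(np.nansum(p_matrix.values >= threshold))
    if n_s + n_m == 0:
        raise ValueError("no suprathreshold voxels in either distribution")
    pct_s = 100.0 * n_s / (n_s + n_m)
    return pct_s, 100.0 - pct_s


def location_records(
    masks: CompartmentMaskPair,
    nucleus_labels: LabelVolume,
    subject: str = "s0",
    hemisphere: str | None = None,
) -> pd.DataFrame:
    """One row per mask voxel: world-mm offset from its nucleus centroid.

    The centroid is the unweighted mean voxel-center position of the whole
    nucleus mask, not of the parcellated voxels only.
    """
    masks.grid.require_same(nucleus_labels.grid)
    hemi = hemisphere or masks.grid.hemisphere
    centroids = {
        lab: nucleus_labels.grid.voxel_to_world(
            nucleus_labels.voxels_of(lab)
        ).mean(axis=0)
        for lab in nucleus_labels.legend
    }
    rows = []
    for comp in ("striosome", "matrix"):
        voxels = masks.voxels(comp)
        if not len(voxels):
            continue
        labs = nucleus_labels.labels[tuple(voxels.T)]
        if (labs == 0).any():
            bad = voxels[labs == 0][0]
            raise ValueError(f"mask voxel {tuple(bad)} lies outside both nuclei")
        world = masks.grid.voxel_to_world(voxels)
        for lab in np.unique(labs):
            sel = labs == lab
            offs = world[sel] - centroids[int(lab)]
            sub = pd.DataFrame(offs, columns=["dx", "dy", "dz"])
            sub["subject"] = subject
            sub["hemisphere"] = hemi
            sub["compartment"] = comp
            sub["nucleus"] = nucleus_labels.legend[int(lab)]
            rows.append(sub)
    out = pd.concat(rows, ignore_index=True)
    return out[["subject", "hemisphere", "compartment", "nucleus", "dx", "dy", "dz"]]


def _simple_main_effects(model, data: pd.DataFrame, axis: str, alpha: float):
    """Effect of each factor at fixed levels of the other, tested against the
    full-model error with Kirk's conservative simultaneous test procedure:
    F'_crit = (ab - 1) / df_effect * F_alpha(ab - 1, df_error)."""
    mse = model.mse_resid
    df_err = int(model.df_resid)
    cells = data.groupby(["compartment", "nucleus"], observed=True)[axis]
    n_cells = cells.ngroups
    rows = []
    for fixed, varied in (("compartment", "nucleus"), ("nucleus", "compartment")):
        for level, chunk in data.groupby(fixed, observed=True):
            groups = [g[axis].to_numpy() for _, g in chunk.groupby(varied, observed=True)]
            if len(groups) < 2:
                continue
            grand = np.concatenate(groups).mean()
            ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
            df_eff = len(groups) - 1
            f = (ss_between / df_eff) / mse
            f_crit = (n_cells - 1) / df_eff * st.f.ppf(1 - alpha, n_cells - 1, df_err)
            rows.append(
                {
                    "axis": axis,
                    "effect_of": varied,
                    "at": f"{fixed}={level}",
                    "F": f,
                    "df": (df_eff, df_err),
                    "F_crit_stp": f_crit,
                    "significant": f > f_crit,
                }
            )
    return pd.DataFrame(rows)


def location_anova(records: pd.DataFrame, alpha: float = 0.05) -> dict:
    """Two-factor ANOVA per axis: compartment, nucleus, their interaction.

    Subject identity enters as a fixed nuisance factor.  When the
    interaction is significant, simple main effects are tested with the
    conservative simultaneous test procedure.

    Returns ``{"anova": DataFrame, "simple_main_effects": DataFrame}``.
    """
    for factor in ("compartment", "nucleus"):
        if records[factor].nunique() < 2:
            raise ValueError(f"factor {factor!r} has fewer than 2 levels")
    anova_rows = []
    sme_frames = []
    multi_subject = records["subject"].nunique() > 1
    for axis in ("dx", "dy", "dz"):
        terms = "C(compartment) * C(nucleus)"
        if multi_subject:
            terms = "C(subject) + " + terms
        model = smf.ols(f"{axis} ~ {terms}", data=records).fit()
        table = anova_lm(model, typ=2)
        for term, label in (
            ("C(compartment)", "compartment"),
            ("C(nucleus)", "nucleus"),
            ("C(compartment):C(nucleus)", "interaction"),
        ):
            anova_rows.append(
                {
                    "axis": axis,
                    "factor": label,
                    "F": float(table.loc[term, "F"]),
                    "df_num": int(table.loc[term, "df"]),
                    "df_den": int(model.df_resid),
                    "p": float(table.loc[term, "PR(>F)"]),
                }
            )
        p_int = anova_rows[-1]["p"]
        if p_int < alpha:
            sme_frames.append(_simple_main_effects(model, records, axis, alpha))
    sme = (
        pd.concat(sme_frames, ignore_index=True)
        if sme_frames
        else pd.DataFrame(
            columns=["axis", "effect_of", "at", "F", "df", "F_crit_stp", "significant"]
        )
    )
    return {"anova": pd.DataFrame(anova_rows), "simple_main_effects": sme}


def leftout_region_bias(
    region_conn: ConnectivityTable,
    threshold: float = 0.87,
) -> tuple[float, float]:
    """Compartment preference of a left-out region's biased seed voxels.

    ``region_conn`` holds, for each seed voxel of the left-out region,
    streamline counts to the two N-1 compartment masks (target groups
    ``striosome_like`` / ``matrix_like``).  A voxel is "biased" when its
    connection probability to either mask reaches ``threshold``; returns the
    percentage of biased voxels favoring (striosome, matrix).
    """
    for g in ("striosome_like", "matrix_like"):
        if g not in region_conn.target_groups:
            raise ValueError(f"region table lacks target group {g!r}")
    s = region_conn.group_counts(["striosome_like"])
    m = region_conn.group_counts(["matrix_like"])
    total = s + m
    classified = total > 0
    p_s = np.where(classified, s / np.where(classified, total, 1.0), np.nan)
    biased_s = classified & (p_s >= threshold)
    biased_m = classified & ((1 - p_s) >= threshold)
    n_biased = int(biased_s.sum() + biased_m.sum())
    if n_biased == 0:
        raise ValueError("no biased seed voxels at this threshold")
    pct_s = 100.0 * biased_s.sum() / n_biased
    return float(pct_s), float(100.0 - pct_s)
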