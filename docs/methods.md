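# Methods

## The analysis chain

The pipeline mirrors a multi-round tractography design:

1. **Parcellation.** Classification-targets streamline counts from every
   striatal voxel to 4 striosome-favoring bait regions (mediodorsal
   thalamus, posterior orbitofrontal cortex, basolateral amygdala, basal
   operculum) and 5 matrix-favoring regions (supplementary motor, primary
   motor, primary sensory, internal globus pallidus, VLc/VPLo thalamus) are
   pooled per group; the voxel's striosome connection probability is
   `S/(S+M)`. Voxels with `S+M = 0` are *unclassified* and excluded — a
   ratio of zeros is undefined, and treating it as 0.5 would fabricate
   neutrality. Equal-volume masks take the uppermost 13% of classified
   voxels from each of the two complementary distributions
   (`round(0.13·N)` voxels each), ties broken by descending score then
   lexicographic voxel index; the striosome-like mask is filled first and
   matrix-like selection skips claimed voxels, which keeps the pair
   disjoint even under massed ties at 0.5. (The 13% figure is the
   operational rule; note that the upper tail beyond 1.5 SD of a normal
   distribution is ≈6.7%, not 13% — the fraction parameter, not the SD
   phrase, governs behavior here.)
2. **Validation.** Relative abundance of highly biased voxels (probability
   ≥ 0.87); per-voxel offsets from the centroid of the voxel's own nucleus
   (caudate or putamen), tested with a two-factor ANOVA
   (compartment × nucleus, subject as a fixed nuisance factor, type-II sums
   of squares); and connectivity bias of a region left out of the
   parcellation (N-1 round), scored against the N-1 masks with the same
   0.87 threshold. Simple main effects use Kirk's conservative simultaneous
   test procedure: `F'_crit = (ab−1)/df_effect · F_α(ab−1, df_error)`.
3. **Bundle mapping.** Streamline path densities are simulated in both
   directions (insula → masks, masks → insula), averaged voxelwise (AB-BA),
   normalized to their maximum amplitude, and thresholded to the uppermost
   25/50/75% of nonzero voxels **by voxel count** (not an amplitude
   cutoff); overlap is the Dice coefficient `2|A∩B|/(|A|+|B|)`, defined 0
   when both masks are empty.
4. **Subregion bias.** The insular probability pair is renormalized per
   voxel to sum to 1; edge voxels whose raw sum falls below 0.5 are trimmed
   as partial-volume artifacts. Per subregion, voxels with normalized
   probability ≥ 0.55 count toward a compartment; the volume percent is
   `100·N_matrix/(N_strio+N_matrix)`, undefined (missing, never 50%) when
   both counts are zero. A hemisphere needs ≥ 19 suprathreshold voxels for
   *both* compartments to enter group statistics — the marginal-voxel
   arithmetic shows why: at (1 matrix, 9 striosome) a single added matrix
   voxel moves the percent by 8.2 points. Center-of-gravity geometry splits
   the striosome-favoring distribution at the coronal plane y = 1 mm
   (voxel centers exactly on the plane go caudal); COGs are
   probability-weighted means of voxel centers, and left-hemisphere x is
   mirrored about the midline before pooling.
5. **Inference.** Per-subregion ANCOVA on suprathreshold voxel counts
   (rows = subject × hemisphere × compartment; factors compartment,
   hemisphere, handedness, sex, self-identified race, age, plus the
   sex × hemisphere × compartment interaction), Bonferroni family
   α = 0.05/19, results within 10× of the threshold labeled "trending".
   Voxelwise inference uses one-sample t statistics on paired difference
   volumes with sign-flip permutations and the **max-statistic** null for
   familywise error control; two-sided questions run as two one-directional
   tests at α/2 each. When the permutation budget reaches 2^n subjects the
   flips are enumerated exhaustively and p-values are exact. Max-statistic
   FWE replaces threshold-free cluster enhancement deliberately: it has the
   same exchangeability-based familywise guarantee with far less machinery,
   and cluster-enhancement spatial priors are not what the phantom tests.
   Variance smoothing (Gaussian, given in mm) is available and off by
   default in phantom work.
6. **Controls.** The nucleus-proportional control reselects masks with
   fixed per-nucleus quotas (80 caudate + 100 putamen voxels per
   compartment). The neighborhood control shifts every mask voxel by
   uniform integer offsets in [−3, 3]³, redrawing while the destination
   lies in either original mask, outside the striatum, or on an
   already-placed shifted voxel (both latter rules are flags; collisions
   between shifted voxels trigger redraw so the shifted mask stays a set).
   A draw budget of 10,000 per voxel guards termination; with
   `jitter_max = 0` every draw collides with the original mask and the
   control is infeasible by construction.

## The phantom: what it emulates, what it does not

One 30×40×30 grid at 1.5 mm isotropic holds everything (single space, no
registration; world axes +x right, +y anterior, +z superior; right
hemisphere by default, the midline at x = 0). Two ellipsoidal nuclei
(caudate ≈ 1,030 voxels, putamen ≈ 1,660) contain a striosome labyrinth
grown by intensity-weighted random-walk branches until exactly
`round(0.15·N)` voxels are marked. The intensity increases medially,
rostrally and ventrally with axis weights 0.5/0.8/1.0 (ventral strongest,
medial weakest — the ordering seen in tissue), standardized within each
nucleus so that nucleus placement (dorsomedial caudate, ventrolateral
putamen) does not leak into the compartment gradients. The result is
enrichment, not confinement: ~13% of striosome voxels still sit in the
dorsal half of their nucleus, and mean per-nucleus offsets come out near
(−2, +5, −5) mm.

The insula is a three-voxel-thick lateral sheet of ~1,170 voxels banded
into 19 contiguous subregions along a rostroventral→caudodorsal axis. Each
subregion carries a ground-truth probability that its streamlines target
striosome; the default profile is anchored to the observed per-subregion
biases (7 striosome-leaning > 0.55, 9 matrix-leaning < 0.45, 3 neutral),
laid out so striosome-leaning subregions sit rostroventrally. On top of the
subregion means, per-voxel true biases spread with sd 0.10 (centered within
each subregion, scaled to stay in [0.02, 0.98], so the subregion mean is
preserved exactly). This within-subregion gradation matters: with a single
value per subregion, every suprathreshold statistic binarizes to 0/100 at
desk scale, which no real probability map does.

Streamline counts are multinomial draws: each striatal voxel sends
`fidelity` of its streamlines to the concordant bait group (split equally
across that group's regions by default; weights are configurable because
real pooling conventions vary), the rest to the discordant group, an
optional lapse fraction to no target. An optional *fidelity gradient*
spreads per-voxel fidelity spatially (mean-preserving per compartment,
scaled to stay within [0.5, 1]) so the most-biased voxels of each
compartment concentrate in its home territory; it is off by default — with
13% + 13% of the striatum in the masks, spatially clustered masks leave
jitter with no legal destinations — and switched on explicitly for the
segregated-bundle construction. Distance correction (counts rescaled by
seed-to-bait path length) is available and off by default: it is a
tractography-tool behavior the analysis consumes, not defines.

Insulo-striate simulation has two targeting modes. In **mask** mode a
streamline's group follows mask identity — the idealized round-5 setting.
In **tissue** mode each target voxel is weighted by the affinity of its
ground-truth compartment (`b` for striosome tissue, `1−b` for matrix), so
impure masks capture streamlines according to the tissue they actually
contain; the controls use this mode, since a jittered mask's scientific
content *is* its tissue composition. Path densities rasterize straight
seed→target segments (one line per drawn target, weighted by its
multinomial count); curvature, step length and diffusion physics are not
modeled — bundle-level statistics need spatial extent, not fiber physics.

What passing tests therefore do **not** show about real data: robustness to
registration error beyond the edge-trim rule, to crossing-fiber ambiguity,
to distance- and depth-dependent tractography biases, or to anatomically
curved trajectories. The phantom verifies the *analysis* — scoring,
selection, thresholds, QC, statistics, controls — not the tractography.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `mask_fraction` | 0.13 | fraction of classified voxels per equal-volume mask |
| `high_bias_threshold` | 0.87 | connection probability defining "highly biased" |
| `suprathreshold` | 0.55 | normalized probability counting a voxel for a compartment |
| `edge_trim_sum` | 0.5 | minimum raw probability sum for an insular voxel to survive |
| `min_suprathreshold_voxels` | 19 | per-compartment hemisphere QC floor |
| `jitter_max` | 3 | maximum per-plane shift (voxels) in the neighborhood control |
| `rostro_caudal_split_y` | 1 mm | coronal plane splitting striosome COG clusters |
| `core_fractions` | 0.25/0.50/0.75 | voxel-count fractions for bundle cores |
| `n_permutations` | 5000 | sign-flip permutations for voxelwise FWE |
| `trending_multiplier` | 10 | "trending" band above the family alpha |
| phantom `striosome_fraction` | 0.15 | true striosome share of striatal volume |
| phantom `fidelity` | 0.8 | concordant-bait targeting probability |
| `streamlines_per_seed` | 5000 (50,000 for insular quantification) | sampling depth |

## Numerical choices and degenerate inputs

Ties in every top-k selection break by descending value then lexicographic
voxel index, making masks invariant to input row order. Unclassified and
trimmed voxels propagate as NaN and are excluded from denominators.
Permutation FWE p-values have floor `1/(n_perm+1)` (exact `1/2^n` when
exhaustive). Paired t-tests with zero-variance differences are flagged
degenerate (t = 0, p = 1 for identical vectors; p = 0 for a constant
nonzero shift). The ANCOVA raises on rank-deficient designs rather than
silently dropping aliased factors, and missing covariates are rejected, not
imputed. Dice of two empty masks is defined as 0 and logged.

## Problem sizes

The test suite and the acceptance script run the study at desk scale: one
~2,690-voxel striatal hemisphere, 349-voxel masks, ~1,170 insular voxels,
5,000 streamlines per seed voxel for parcellation and 50,000 where insular
quantification needs the depth, 8–16 simulated subjects for group
statistics, 10 phantom seeds for recovery and control checks, and
100 × 500-permutation replicates on an 8×8×8 grid for null calibration.
These sizes were chosen so each property is measured with comfortable
Monte-Carlo margin while the whole suite completes in about a minute.

## Known limitations

- The comparison metric for the two control rounds defaults to the graded
  mean matrix probability rather than the suprathreshold volume percent:
  against near-neutral jittered masks the phantom yields no suprathreshold
  voxels at all, so the thresholded statistic is undefined there (it
  remains available via `metric="volume_percent_matrix"`).
- The phantom's masks occupy 26% of its striatum (13% per compartment of
  ~2,690 voxels), a larger share than a full-resolution striatum would
  give; this makes the jitter control's boundary pressure relatively
  stronger, visible as a net ventral→dorsal drift of ~0.9 mm (still below
  the 1 mm neighborhood criterion, and comparable to what the method shows
  on real data).
- Hemispheres are simulated independently and pooled at the record level
  after x-mirroring; no true left/right anatomical asymmetry is modeled,
  so hemisphere effects in the ANCOVA are null by construction.
- The three-way sex × hemisphere × compartment ANCOVA term is entered
  without its two-way companions; with treatment coding this term spans
  4 numerator degrees of freedom, and the reported df follow that coding.
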