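# Methods

This note documents the models, algorithms and design choices behind
`aaquant`: what the synthetic phantoms emulate, how diameters are measured,
how the statistics are specified, and where the known limitations are.

## Airway tree model and labeling

An airway tree is a rooted collection of centreline branches (polylines in
world mm). Branches are maximal inter-branch-point segments, so every
internal node has at least two children; this is validated on construction,
which makes airway generation (bifurcation count from the trachea) identical
to breadth-first depth. Trifurcations advance the generation by one like any
other branching node.

Segmental generations renumber each segmental bronchus to 1:
`seg_gen = generation − generation(segmental bronchus) + 1`. The `+1` offset
is a convention choice — a plain subtraction would start at 0 — exposed as
the module constant `SEG_GEN_OFFSET`. Which branches are segmental bronchi
is carried as explicit per-branch flags in the tree file rather than derived
from geometry; the generator sets the flags itself, and real segmented trees
must supply them. Peripheral airways are `seg_gen >= 4`.

## Synthetic phantoms

The generator's job is to produce two cohorts whose *structure* matches the
comparisons the analysis layer makes, with every quantity knowable exactly.

**Disease model (per branch at segmental generation g, central airways use
g = 1):**

    A_out_A(g) = base_AoutA + slope_AoutA · (g − 1)
    A_WT_A(g)  = 2 · wall_fraction · base_AoutA + slope_AWTA · (g − 1)
    outer = artery · A_out_A,   inner = artery · (A_out_A − A_WT_A)

with a subject-level normal shift on `base_AoutA` (sd 0.05, giving the mixed
model true between-subject variance to recover) and multiplicative lognormal
branch jitter (σ = 0.1) on both ratios, keeping everything positive on the
ratio scale the analysis uses. Defaults: controls `base_AoutA = 1.0`, zero
slopes, wall fraction 0.15; CF-like `base_AoutA = 1.05`, slopes 0.03 and
0.02 per generation, wall fraction 0.17. The slopes put the CF−control
A_out_A difference at roughly 0.08 at segmental generation 2 rising to
~0.2 at generation 6 — a realistic paediatric-bronchiectasis effect size,
chosen once and not tuned against any test.

**Arteries** taper geometrically with airway generation
(`12 mm · decay^generation`): decay 0.75 in controls and 0.78 in the CF-like
cohort. The slower CF taper encodes that bronchiectatic airway–artery pairs
remain absolutely larger towards the periphery, so they stay above the CT
resolution floor for two to three generations longer — the mechanism that
produces the excess of visible peripheral AA-pairs in CF. Trees grow to
segmental generation 8 (CF) vs 6 (control) per lobe, full binary splitting
to generation 2 and main-daughter-plus-terminating-twig bifurcations beyond,
which bounds branch count (~650 vs ~450 per tree) while keeping every
internal node a true branching point.

**Lung volume.** Expiration multiplies inner and outer airway diameters by
`volume_scale_expiration = 0.8`; arteries are unchanged. In ground truth
this makes A_in_A, A_out_A and A_WT_A strictly larger on inspiration for
every branch, and leaves A_WT (wall/outer) volume-invariant; in measured
data it additionally removes small airways from visibility, reproducing the
inspiration–expiration count gap. Paired volume states of a subject reuse
the same per-subject random stream, so they differ *only* by the scaling.

**Rasterization.** Branches are drawn as tubes at nominal plateaus: lumen
−1000 HU, wall −50 HU, artery +50 HU, parenchyma −850 HU (fixed constants,
not fitted to any scanner), plus additive Gaussian noise (default sd 25 HU)
on a 0.5 mm isotropic grid. Partial volume at tube surfaces is handled by
2×2×2 supersampled coverage averaging in the one-voxel surface shell. Each
branch's artery runs parallel at centre distance
`outer radius + 1.5 · artery radius` — i.e. a parenchyma gap of half an
artery radius, adjacent but never fused — along the binormal of the
bifurcation plane, the direction facing away from sibling branches.
Geometry uses branch lengths ≈ 3–4× local calibre so neighbouring tubes
clear each other at the mid-branch measurement plane; residual crowding in
dense subtrees shows up as honest `excluded_noise` rows, much like motion
or noise exclusions in clinical reading.

What the phantoms deliberately do **not** emulate: lung texture, cardiac and
breathing motion, reconstruction kernels, dose. Passing tests therefore
demonstrate correctness of geometry, edge localisation, resolution-limited
visibility and statistics — not robustness to real-scanner artefacts.

## Cross-section measurement

One measurement per branch, mid-branch by default (the position is a
config knob, and repeated measurements at jittered positions provide the
replicates for ICC analysis). The patch is resampled by trilinear
interpolation on a plane perpendicular to the centreline tangent (tangent
from centred differences on a 5-point moving-average-smoothed centreline),
in-plane grid at half the voxel pitch, side ≥ 3× the expected outer
diameter and wide enough to include the artery.

64 rays are cast from the centre. Along each (lightly smoothed) ray profile:

* the **wall** is the *first local maximum* with lumen contrast at least
  3× the patch noise sd — first, not global, because the brighter paired
  artery lies further out;
* the **inner edge** is the half-maximum crossing between the lumen plateau
  and the wall peak; the **outer edge** the half-maximum crossing between
  the wall peak and the parenchyma background (patch median);
* the patch noise sd comes from the median absolute horizontal first
  difference (robust to edges).

Rays whose edge radius sits far from the ring median (>35% or 0.3 mm) are
trimmed — a touching neighbour drags single rays out. Ellipses are fitted
to both edge-point sets and diameters reported as the equivalent-area
diameter `2·sqrt(ab)`, mirroring area-based manual ellipse annotation.

Exclusion rules, in order: fewer than 60% valid rays → `excluded_no_lumen`
(or `excluded_noise` when the patch noise estimate exceeds 150 HU — a
noise-dominated patch yields few or erratic edges); ellipse RMS residual
above 15% of the fitted radius → `excluded_noise`; fitted lumen below 2
voxels → `excluded_no_lumen` (a sub-resolution lumen is not "clearly
visible"). The artery is the brightest connected component above the
background/peak midpoint whose centroid lies within 3× the expected outer
radius but outside the airway's own footprint, with plausible area; no
candidate → `excluded_no_artery`; among several, the nearest centroid wins
and the tie is logged.

**Known bias.** Half-maximum edge placement overestimates the outer
diameter of walls thinner than about one voxel (the wall peak is depressed
by partial volume, pushing the outer crossing outward). On the 0.5 mm
recovery grid this caps accuracy at the 2–3 mm calibres (errors up to
~0.6 mm) while 5–10 mm tubes recover to ~0.1–0.2 mm; the median absolute
error over the 2–10 mm grid is ~0.16 mm and the orientation (parallax)
discrepancy ~0.03 mm. This is a property of the FWHM convention itself, not
of the implementation.

## Statistics

* **Mixed models.** `response ~ disease_status + volume_state` (+ optional
  covariates/two-way interactions) with a subject random intercept and a
  lobe variance component *within* subject. True crossed subject×lobe
  effects are not available in the backend; nesting lobe in subject captures
  per-subject lobe heterogeneity and is the standard practical substitute.
  REML for reported fits; ML refits for likelihood-ratio comparisons
  (statistic 2Δllf against chi-square on the fixed-parameter difference).
  Variance components estimated at ~0 flag the fit as singular rather than
  failing. Optimisation uses Powell with a conjugate-gradient fallback —
  the quasi-Newton path in the backend can silently return a degenerate
  optimum on these profiles.
* **ROC.** AUC by the rank (Mann–Whitney, midrank ties) formulation —
  verified exhaustively against the trapezoidal empirical-ROC oracle —
  threshold by Youden's index over midpoints of adjacent unique values,
  ties resolved toward the higher (more specific) cut; 95% CI by
  nonparametric bootstrap over *subjects*, since branch rows within a
  subject are correlated.
* **ICC.** Between-target variance over total variance from a
  variance-components model; with subject and generation columns present
  the nesting branch-within-generation-within-subject is respected and all
  between-target strata count toward agreement. Bands: <0.4 below-moderate,
  0.4–0.6 moderate, 0.6–0.8 good, ≥0.8 very good. Zero within-target
  variance short-circuits to ICC 1 (the boundary case the mixed model
  cannot represent).
* **Nonparametrics.** Wilcoxon signed-rank for paired
  inspiration/expiration counts per subject, Mann–Whitney for cohort
  contrasts, simple regression for counts vs age/height. P-values are
  reported raw; no multiple-testing correction is applied, and the report
  says so.

## Problem sizes and determinism

Simulation studies in the test-suite and reproduction script run at desk
scale, chosen as the package's own defaults: 2 subjects per cohort for
rasterized imaging runs (8 volumes, ~450–650 branches each), the full
11 + 12 subjects for ground-truth-table analyses, 100 seeds for fixed-effect
recovery, 200 simulations for LRT type-I calibration, 200 targets for ICC
recovery. Every random quantity flows from an explicit seed through numpy
`SeedSequence` spawning; measurement itself is deterministic, so identical
config + seed reproduces every output byte for byte.

## Limitations

* Trees are inputs (synthetic or externally segmented); the package does
  not segment airways or extract centrelines from raw CT.
* The FWHM/ellipse automation approximates manual area-based annotation;
  no claim of equivalence to any commercial tool is made.
* Phantom intensity is piecewise-constant plus white noise; bias from
  texture, kernels and motion is out of scope.
* Cohort-level numbers from real patient studies (counts, AUCs, cut-offs)
  depend on cohort composition and scanner protocol; the synthetic defaults
  reproduce their *directions and structure*, not their magnitudes.
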