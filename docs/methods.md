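# Methods

This note documents the models, parameters and design choices behind
`tibstrain`: what each stage computes, what the synthetic data do and do not
emulate, and where the genuinely open choices were made.

## Overview

The pipeline links tibia-fibula geometric variation to finite-element
estimates of periosteal effective strain under mass-scaled running loads:

1. **Synthetic cohort** — parametric tibia-fibula meshes deformed by planted
   analytic shape modes, with per-subject body mass and height.
2. **Shape models** — generalized Procrustes alignment + PCA of corresponded
   surface point sets, in three variants (tibia surface, tibia + fibula
   surfaces, cortical + endosteal surfaces), followed by a cross-model
   collinearity screen of PC scores.
3. **FE solve** — linear orthotropic elasticity on 10-node tetrahedra with
   plateau fixation, a malleolar anterior-posterior constraint, tibio-fibular
   ligament springs and penalty ties, loaded by concentrated nodal forces
   (ankle joint contact force + 16 muscles) at 3, 4 and 5 m/s.
4. **Strain field** — von Mises-equivalent ("effective") strain on the
   periosteal surface of the tibial shaft (15–75% of tibia length), with
   elements near muscle attachments masked (10 mm soleus, 5 mm others).
5. **Statistics** — element-wise simple regression of strain on each retained
   PC score, thresholded by the permutation maximum-|t| method at
   family-wise alpha = 0.05.

## Synthetic geometry

The template is deliberately non-anatomical: a two-region
(cortical shell + trabecular core) circular-section tibia whose outer radius
and cortical thickness vary along the axis (condylar flare proximally,
malleolar flare distally), plus a slender single-region fibula offset 28 mm
laterally and 12 mm posteriorly. Cross-sections are triangulated (centre fan
plus a cortical ring), extruded into wedges, and split into tetrahedra with
the minimum-global-index diagonal rule, which makes the mesh conforming by
construction and its node/element counts closed-form in the section counts
(tibia: `9·A·C` tetrahedra for `A` axial and `C` circumferential sections).
Edge midnodes give 10-node elements. The first and last tibia element layers
are labelled cortical so the cortical set is a closed shell around the
trabecular core. Coordinates: x = medial-lateral (+lateral), y =
anterior-posterior (+anterior), z = axial (+proximal); mm / N / MPa
throughout, so ligament stiffnesses in N/mm need no conversion.

Because every subject is an analytic deformation of one template, cohorts are
corresponded node-for-node — no registration step exists, and the shape-model
stage sees perfect correspondence. This is the main idealization: real
cohorts require segmentation and non-rigid registration, whose errors are
absent here. Passing tests therefore validate the *pipeline machinery*, not
robustness to correspondence error.

### Planted shape modes

Six analytic displacement fields with the identity at score 0, all smooth
and inversion-free out to |score| = 3 SD (verified by Jacobian checks):

| mode | action | SD (natural units) |
|---|---|---|
| `length` | axial scaling; extent multiplies by exactly 1 + s | 0.03 (fraction) |
| `overall_width` | in-plane scaling about the tibial axis, both bones | 0.04 (fraction) |
| `upper_thickness_condyle` | radial widening weighted toward the upper half plus a Gaussian condylar bump | 0.05 (fraction) |
| `cortical_thickness` | endosteal interface moves inward by s·g(z) mm (midshaft Gaussian window); outer surface unchanged | 0.4 mm |
| `ap_curvature` | anterior bow u_y = s·sin(pi·z/L); max chord offset is exactly s | 2.0 mm |
| `fibula_offset` | posterior translation of the fibula | 1.5 mm |

SDs approximate adult variability on the template scale (a few percent in
size/width, sub-millimetre endosteal variation, millimetre-scale bow). The
`cortical_thickness` mode is invisible to the two outer-surface model
variants and only appears in the cortical + trabecular variant — mirroring
why an endosteal shape model is needed at all.

Covariates are drawn as body mass ~ N(70.22, 11.36²) kg and height ~
N(176.06, 11.61²) cm, coupled to the `length` mode through a latent size
factor so that height and mass jointly explain roughly two-thirds of the
variance in overall bone size. Scores are clipped at ±3 SD (the template's
validity envelope); clipping affects ≈0.3% of draws.

### Load table

`data/running_loads.csv` is a versioned, synthetic per-kg load table (one
ankle joint contact force and 16 muscle entries per speed). It reproduces
structure and ordering, not measured values: ankle JCF ≈ 8.2 / 10.6 / 13.0
bodyweights at 3 / 4 / 5 m/s (strictly increasing), soleus the largest muscle
force, plantarflexors pulling distally. Directions are fixed across speeds.
Forces are scaled by each subject's body mass (exact degree-1 homogeneity,
which the linear solver propagates to strains).

## Shape models

Generalized Procrustes alignment removes translations and rotations
(scaling is **off** by default: size is itself a shape characteristic of
interest, and size-related strain questions require it in the model). The
mean is initialized from the raw average so a converged set is a fixed point
of re-alignment; iteration stops when the mean moves < 1e-10. PCA of the
aligned, flattened coordinates yields at most n−1 modes; variance
percentages are relative to total shape variance and non-increasing.

The collinearity screen works on |Pearson r| (PC sign is arbitrary, so a
signed rule would depend on an arbitrary reflection) with cutoff 0.6.
Correlated pairs are processed in descending |r|; within a pair the loser
is determined by: (1) a tibia-only component loses to a tibia-fibula one,
(2) otherwise lower explained variance loses, (3) otherwise the higher PC
index loses. Descending-|r| processing is deterministic and removes the
strongest redundancy first; the retained set is pairwise |r| ≤ cutoff and
re-screening removes nothing. A zero-variance score column is an error
naming the column. Default candidate counts are 6 / 7 / 4 components for
the tibia / tibia-fibula / cortical-trabecular variants (17 candidates),
configurable.

## Finite elements

Ten-node tetrahedra with 4-point Gauss quadrature (exact for the stiffness
of straight-sided elements). Orthotropic constants follow constant
anisotropy tied to the axial modulus E3: E1 = 0.574·E3, E2 = 0.577·E3,
G12 = 0.195·E3, G23 = 0.265·E3, G31 = 0.216·E3, nu12 = 0.427, nu23 = 0.234,
nu31 = 0.405, with E3 = 18.6 GPa for cortical bone (and the entire fibula)
and 10.4 GPa for the trabecular region — generic densities by design, so
shape is the only varying factor. Minor Poisson ratios follow from
compliance symmetry; the compliance matrix is checked positive definite.

Constraints: solid elements carry no rotational DOFs, so "fixed in
translation and rotation" is implemented as translational fixation of all
plateau nodes (fixing the node set also removes rigid rotation). The surface
node nearest the medial malleolus is fixed in y (anterior-posterior);
nearest-node selections break ties by lowest node index. The four
tibio-fibular ligaments are axial springs (133 / 166 / 78 / 101 N/mm for
proximal anterior / proximal posterior / distal anterior / distal posterior)
acting along the undeformed pair axis. Tied contact at the tibio-fibular
joints is approximated by stiff isotropic node-pair penalties
(default 1e5 N/mm, configurable; the linear static solve precludes true
contact). Loads are concentrated nodal forces — deliberately not smoothed;
the local singular strains they create are handled by the masking stage, not
by the solver.

The constrained system is solved by sparse LU with one step of iterative
refinement (relative residual < 1e-8 enforced). Element strain is the
volume-weighted quadrature average; a surface element inherits the strain of
the tetrahedron owning its face (per-element granularity, no extrapolation).

**Effective strain** is the von Mises-equivalent strain
`sqrt(2/3 * e_dev : e_dev)`: non-negative, zero exactly for purely
volumetric strain, and degree-1 homogeneous. The underlying solver output it
emulates is not defined in closed form by its originating tool; the
deviatoric definition is a documented choice and the function is pluggable
(an effective Lagrange strain could be substituted without touching the
pipeline).

Verification: uniaxial patch test exact to ~1e-14 relative; a single
element's energy matches closed-form barycentric-monomial integration of a
quadratic displacement field to 1e-9; a slender cantilever (L/d = 20,
2×2×40 elements) matches Euler-Bernoulli tip deflection to 0.4%.

## Strain-field extraction

The shaft window is the closed interval [0.15, 0.75] of tibia length,
measured **from the distal tip upward**, selecting surface elements by
**centroid** inclusion; both conventions are config-exposed since either
reading is self-consistent. Masking distance is 3-D Euclidean
centroid-to-insertion-node (the simplest defensible reading of "within
1 cm"), 10 mm for soleus and 5 mm for the other 15 muscles. At very coarse
mesh resolution surface-element centroids can all lie farther than the mask
radius from any insertion node, in which case masking removes nothing — the
radii are kept fixed rather than rescaled with the mesh. The fibula surface
is excluded from the field.

## Field statistics

Per element, simple linear regression of effective strain on one PC score
(each PC in its own model; no correction across the ~10 models, a
faithful-reproduction choice). t = slope / SE with df = n − 2; positive t
means strain rises with the score. A perfect fit reports a signed infinity
sentinel; a constant strain column reports t = 0 with a flag.

The family-wise threshold is the ceil((1−alpha)·n_perm)-th order statistic
of the max-over-elements |t| under permutations of the predictor, identity
permutation always included; the full group is enumerated automatically when
n! ≤ n_perm. Two-tailed max-|t| is used because both signs of association
are reported. Default n_perm = 10 000 (2 000 in the pipeline config; 1 000
in the calibration harnesses), seed recorded in the output — the permutation
count is a package default, not an inherited value.

Calibration and power (all recomputed by `scripts/acceptance.py` and the
acceptance tests; sizes chosen to exercise the analysis at desk scale):

* 1 000 null datasets (10 subjects × 50 elements): empirical FWER inside the
  99% binomial band around 0.05, with and without strong spatial field
  correlation (the max statistic adapts to smoothness).
* planted 1-SD-per-SD patch effect, 30 subjects × 150 elements, 400 repeats:
  patch sensitivity ≈ 0.83 (> 0.8), false positives outside the patch at the
  FWER level, recovered sign always positive.
* zero-effect analysis-scale cohorts: significant maps in ≈5% of repeats.

## Pipeline and reproducibility

`PipelineConfig` (pydantic-validated) holds every tunable with defaults equal
to the fixed study parameters (15–75% window, 10/5 mm radii, r > 0.6,
alpha = 0.05, ligament stiffnesses, moduli). A run writes CSV tables, optional
VTK fields and a JSON manifest (resolved config, package version, per-stage
seeds, SHA-256 of every table); the same config + seed reproduces identical
hashes. The demo scale (12 subjects, 12×10 sections, 3 speeds, 1 000–2 000
permutations) completes in well under a minute on one CPU; section counts
and cohort size scale the cost roughly linearly.

## Known limitations

* Anatomical realism is out of scope: no real bone surfaces, no density
  mapping, no registration. Results demonstrate method correctness, not
  biological effect sizes.
* Tied contact is a linear penalty; contact nonlinearity and load-path
  changes at the joints are not modelled.
* Concentrated nodal loads make strain near insertions mesh-dependent;
  only the masked shaft field is meaningful.
* The load table is synthetic; absolute strain magnitudes (~1 000–1 600
  microstrain across 3–5 m/s for a 70 kg subject) are plausible for running
  but not calibrated to measurements.
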