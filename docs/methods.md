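# Methods

`enstract` implements ensemble tractography: instead of committing to one
tracking parameter set, it generates candidate streamline connectomes under a
sweep of parameters, pools them, and lets a linear fascicle-evaluation model
with non-negative weights decide which streamlines the diffusion data
actually support. This note records the models, the numerical choices, and
what the bundled synthetic phantom does and does not demonstrate.

## The pipeline

1. **Tracking.** A minimal local tracker consumes a discrete per-voxel
   orientation field and produces one single-parameter connectome (SPC) per
   parameter set. Defaults mirror common practice: step size 0.2 mm, length
   bounds 10–200 mm (full scale), amplitude stopping criterion 0.1, uniform
   seeding over the mask, bidirectional growth from the seed.
2. **Pooling.** SPC candidates are concatenated with provenance labels
   (`combine`); no deduplication — redundancy is resolved by the fit. An
   optional preselection (`preselect`) pools only the top-weighted
   streamlines of individually fitted SPCs, bounding the pooled problem size.
3. **Fascicle evaluation.** A sparse design matrix maps streamline weights to
   demeaned diffusion signal; non-negative least squares yields per-streamline
   weights; streamlines with strictly positive weight form the optimized
   connectome.
4. **Evaluation.** Cross-validated per-voxel error ratios, white-matter
   coverage, streamline density, curvature distributions, and
   pathway-restricted fits for tract-level comparison.

## Curvature bound

The minimum radius of curvature R and the per-step angle threshold are
equivalent through the chord relation `theta = 2·arcsin(step/(2R))`: two
successive steps are equal chords on the circle of radius R. At the 0.2 mm
step the sweep radii 0.25/0.5/1/2/4 mm correspond to
47.2/23.1/11.5/5.7/2.9 degrees. The bound is enforced exactly, per step,
including at the seed junction of the two growth directions (the seed-side
half is constrained by the first step of the other half).

## Probabilistic step: trial directions on a pseudo-FOD

The tracker stores a *discrete* orientation set per voxel, not a continuous
fiber orientation distribution. The probabilistic step draws `n_trials`
(default 60) candidate directions uniformly within the angle cone around the
incoming heading and picks one with probability proportional to a pseudo-FOD
amplitude: each discrete orientation contributes an axially symmetric von
Mises–Fisher lobe of peak height equal to its amplitude,
`A(u) = Σ_k a_k · exp(κ(|u·t_k| − 1))`. Propagation stops when no candidate
reaches the amplitude criterion (0.1).

An earlier design — sampling a vMF perturbation *around* an admissible
orientation and rejecting draws outside the cone — is structurally unsound
for tight cones: once the heading drifts more than the threshold away from
the voxel's single orientation, nothing is admissible and the streamline
dies, which starves the strict end of the sweep even on straight bundles.
The trial-direction scheme is how established probabilistic trackers behave:
the heading wanders within the allowed cone, attracted to the FOD ridge, so
per-step dispersion genuinely scales with the curvature bound.

The kernel concentration κ (default 20, lobe sd ≈ 13°) sets the angular
dispersion of the pseudo-FOD. The default is deliberately broad — comparable
to CSD FOD lobe widths at moderate SNR — so that lenient curvature bounds
actually produce high-curvature streamlines and the sweep spans a range of
curvature distributions rather than collapsing onto the lobe width.

## Fascicle-evaluation model

Per fit-mask voxel the across-direction mean of the diffusion-weighted
signal is removed, and each streamline's contribution is a single-stick
Gaussian attenuation per within-voxel segment,
`s0 · exp(−b·λ·(g·t)²)` scaled by segment length (mm), summed over segments,
then demeaned across directions. Segments are split at voxel boundaries and
assigned to the voxel containing their midpoint; the same voxelization rule
is used for coverage and density so "covered" always means the same thing.
`s0` is the voxel's measured mean b0 (configurable to 1 for unit tests);
λ defaults to 1.7e-3 mm²/s (axial) with 3.0e-3 mm²/s for the phantom's
isotropic compartment — conventional white-matter/free-water values at
b = 2000 s/mm², configurable because no single value is canonical.

The non-negative solve is projected gradient with Barzilai–Borwein step
lengths, started at w = 0, safeguarded by a halving backtracking line search
so the recorded objective trajectory is non-increasing; it stops when the
relative objective decrease falls below 1e-6 (default) or at 500 iterations.
Weights at or below 1e-12 are flushed to zero; "supported" means strictly
positive weight. On small instances the solver matches exhaustive
active-set non-negative least squares to ~1e-11 in objective. Duplicate or
near-duplicate streamlines make individual weights non-identifiable; only
summed weights and predictions are meaningful in that case.

## Accuracy metrics

With two acquisition repeats, per voxel over N directions:
`M_rmse` (prediction vs held-out repeat), `D_rmse` (repeat 1 vs repeat 2),
and `R_rmse = M_rmse / D_rmse`. The fit uses repeat 1; scoring uses
repeat 2. R_rmse = 1 means the model is as accurate as test-retest
reliability; the ideal-predictor floor under equal-variance additive noise
is 1/√2 ≈ 0.707. RMSEs are computed on demeaned signals by default
(consistent with the fitted quantity); a `demeaned=False` mode scores raw
signals. Voxels with `D_rmse = 0` are excluded from the ratio (count
reported), not clamped. The headline summary is the median across voxels.
Without a second repeat, a single-repeat fallback scores against the fitting
data and is flagged as non-cross-validated.

## Curvature statistics

Each streamline is interpolated by a cubic spline parameterized by
cumulative chord length; per-node extrinsic curvature is
`|r′ × r″| / |r′|³`, the mean is taken over nodes, and the mean radius is
its inverse (infinite for straight lines, accumulated in an overflow
bucket). Boundary conditions are not-a-knot: natural boundary conditions
clamp endpoint second derivatives to zero and bias the mean curvature of
constant-curvature test curves by 2.5–5.6%, while not-a-knot reproduces
circle and helix radii to 0.2%.

## The synthetic phantom

The phantom emulates the structure of a two-repeat single-shell protocol:
1.5 mm isotropic voxels (20×14×3 grid), 96 golden-spiral gradient directions
at b = 2000 s/mm², two repeats sharing the noiseless signal and differing
only in the additive Gaussian noise realization (sd 0.5 against a b0 of
100; b0 is averaged over ten b=0 volumes, noise sd/√10). The forward model
is stick-and-ball. Rician bias, spatial noise correlation, distortion, and
realistic anatomy are deliberately absent.

Ground truth mixes the fascicle classes the curvature sweep is meant to
distinguish:

* a long bundle along x: 22 mm straight core ending in a 2.5 mm-radius hook
  (major association pathways mix straight and curved sections; a perfectly
  straight pathway would be modeled completely by the strictest sweep member
  alone, leaving an ensemble nothing to add);
* a crossing bundle along y (crossing-fiber voxels, fractions 0.5/0.5);
* a U-shaped bundle of 3 mm radius with short straight legs, signal
  fraction 0.5 — traversable only under lenient curvature bounds.

Because a curved fascicle spans a range of tangents inside a coarse voxel,
the orientation field clusters each bundle's within-voxel tangents into
~10°-wide entries with the bundle's signal fraction split by length share.
With a single averaged orientation per voxel, tangent jumps of 30–50° at
voxel boundaries would defeat every curvature bound.

Ground-truth streamlines are resampled at the 0.2 mm tracking step so
curvature analytics are comparable between truth and tracked sets.

### Desk-scale parameters

The bundled sweep (`curvature_sweep`) tracks 400 streamlines per parameter
set with length bounds 6–60 mm — the phantom's U-pathway is ~14 mm and its
long pathway ~26 mm, so these bounds bracket the phantom's fascicles the way
10–200 mm brackets real ones. The noise level keeps cross-validated error
dominated by model structure rather than noise at this grid size. All
stochastic stages are seeded; pipeline regression tests fix both the phantom
seed and the sweep seed.

### What passing tests show — and do not

On the phantom, the optimized ensemble connectome supports more streamlines,
covers at least the coverage of every single-parameter connectome, achieves
a lower median R_rmse, spans multiple provenance labels, and wins or ties
the pathway-restricted comparisons in which the best single parameter flips
between the U-pathway (lenient bound best; strict bounds produce no tract at
all) and the long pathway (strict bound best). These are seeded regression
properties of a small, noise-controlled phantom: they demonstrate the
mechanics and the direction of the effect, not effect sizes on real brains,
where FOD estimation error, anatomy, and acquisition artifacts all enter.
The pathway-restricted ensemble margin is small (a few percent) and can tie
or narrowly reverse under reseeding, consistent with "similar or better"
behavior rather than a theorem.

## Known limitations

* Nearest-voxel orientation lookup (no trilinear FOD interpolation).
* Gaussian, not Rician, noise; single shell only.
* The tracker is a minimal reference implementation — no anatomical
  constraints, no FOD estimation from signal (the orientation field is
  supplied or synthesized directly).
* Outlier removal operationalizes "position outlier" as mean node-to-core
  distance after resampling to 100 nodes, applied once (not iterated),
  length criterion first.
* Preselection requires equal per-SPC candidate counts to keep the pool
  balanced; unequal counts trigger a warning.
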