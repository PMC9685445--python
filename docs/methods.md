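# Methods

This note records the models, conventions, and numerical choices behind
each pipeline stage, what the synthetic-data generators do and do not
emulate, and the known limitations.

## Stimulus grid and calcium processing

The stimulus protocol is fixed by the experiment the pipeline models:
5 temporal frequencies (0.5, 1, 2, 4, 8 Hz) × 5 spatial frequencies
(0.0625, 0.125, 0.25, 0.5, 1.0 cpd) × 4 motion directions (90°, 180°,
270°, 360°), 5 trials per condition, 6 s of movement preceded by 3 s of
rest. `StimulusGrid` carries these as defaults; 100 distinct conditions.

ΔF/F uses F0 = mean fluorescence over the full pre-stimulus rest window —
the only segment guaranteed stimulus-free. Max ΔF/F is taken over the
movement window only. The responsiveness rule ("above 10%, repeated at
least twice") is read per condition: the same condition must exceed the
threshold in ≥ 2 of its trials. The alternative reading (two exceedances
anywhere) is available via `across_conditions=True`; the per-condition
reading is the default because trials are the experiment's unit of
repetition.

Motion correction uses integer-pixel circular cross-correlation against a
template built from the average of the first third of the stack, iterated
(template recomputed from the registered stack) up to 5 passes or until
shifts stabilize. Absolute shifts are identifiable only relative to the
template: if the template frames themselves drift, all recovered shifts
share that constant offset. Recovery tests therefore plant motion after a
stable reference period, the situation in which absolute ground truth is
well defined. Sub-pixel refinement is out of scope. Frames whose
normalized correlation peak falls below 0.2 are flagged unreliable.

## Orientation and spatiotemporal tuning

OSI is computed from orientation means (180°/360° = horizontal, 90°/270°
= vertical) of the direction-wise grand means of trial-averaged maxima;
360° is the same stimulus as 0°. OSI is defined as 0 when both
orientation means vanish, and raises on negative inputs (the index's
range is only meaningful for non-negative responses).

The spatiotemporal model is a 2D Gaussian in log₂(sf), log₂(tf) whose
temporal center drifts linearly in log₂(sf) with slope ξ. All logarithms
are base 2 (tuning widths in octaves). Fitting minimizes squared error
over the 25 grid points with `scipy.optimize.least_squares` (trf,
bounded), parameterized in (A, log₂sf₀, log₂tf₀, σ_sf, σ_tf, ξ).

Bounds: sf₀ ∈ [0.03125, 2] cpd and tf₀ ∈ [0.25, 16] Hz (one octave beyond
the grid), σ ∈ [0.3, 4] octaves, ξ ∈ [−2, 2]. The amplitude bound is
deliberately loose (10⁶ × observed grid peak): when the tuning center
lies off-grid with narrow widths, the observed peak can understate A by
orders of magnitude, and a tight multiplicative bound would exclude the
true optimum.

Initialization matters more than iteration here. The first start is an
algebraic estimate: within one SF column the log of the model is exactly
quadratic in log₂ tf, so a parabola through three points around the
column maximum yields the column's preferred TF, temporal width, and
vertex amplitude; the vertex amplitudes are again exactly quadratic in
log₂ sf (giving A, sf₀, σ_sf) and the vertex positions linear (giving ξ,
tf₀). On noiseless model matrices this start is exact up to floating
point, and one polish converges immediately. Column weights are clamped
to a 10³ dynamic range to keep the cross-column fits conditioned.
Additional starts place (sf₀, tf₀) at the grid argmax with ξ ∈ {−1, 0, 1},
plus narrow-width starts one octave past the grid edge; when no start
reaches an essentially perfect fit, up to 50 further random starts inside
the bounds are tried. Best-SSR wins.

R² is the coefficient of determination 1 − SS_res/SS_tot over the 25 grid
points, stored raw (it can be negative for structureless data); the
squared-Pearson alternative can be derived from the stored fit but the
determination coefficient is primary. An all-equal matrix raises
(SS_tot = 0).

## Cross-modality matching

Points are row vectors (x, y) in pixels, origin at the image upper-left,
y downward. The landmark affine is solved in closed form on centered
coordinates: T* = mean(P₂) − mean(P₁) (with T* re-expressed so the
centroid maps exactly under p·R + T), R* = pinv(P₁ − mean(P₁))·(P₂ −
mean(P₂)); the norm minimized is the Frobenius norm over all landmarks.
With fewer than three landmarks the affine is skipped and a pure
translation (difference of means) is used, mirroring the fallback used
in practice; collinear landmarks raise a rank-deficiency error.

The rigid pre-rotation maps the cortical-surface normal to +z by the
minimal rotation about normal × z; the antiparallel case rotates 180°
about the x-axis by convention.

Automatic cell assignment (the manual step of the original workflow) is
mutual-nearest-neighbour matching within a `max_dist` pixel gate, with
conflicts resolved greedily by ascending distance and each structural
cell used at most once. No distance gate is anatomically canonical; the
default (5 px) is a config choice. Optional per-cell fiber descriptors
(orientation histograms) gate candidate pairs by cosine similarity; they
are off by default and make no claim of equivalence to visual fiber
matching. Matching rate = matched / responsive; tracing rate = traced /
matched; sample rate = traced / labeled in vivo.

## Projection quantification

SWC type 2 (axon) edges only — dendrites never contribute to projection
profiles; the edge joining the first axon node to the soma root counts as
axon. Each edge is split into pieces of at most `step_um` (default 1 µm)
and each piece's length accrues to the region at its midpoint, looked up
by floor((p − origin)/voxel) with half-open voxel ownership;
out-of-volume midpoints accrue to "outside". This midpoint rule converges
to exact geometric clipping as the step shrinks, with error bounded by
one step per region-boundary crossing — which is what the oracle tests
assert. The ≥ 1.0 mm target rule is inclusive at exactly 1.0 mm, and
fiber-tract regions are treated like any other label. Hemisphere
attribution (ipsi/contra) is delegated to the region table; synthetic
volumes have no anatomical midline. Profiles are computed in the
volume's own coordinate space; atlas registration is out of scope.

## Signal quality

Axonal SNR is sampled at nodes whose straight-line distance to the soma
is an integer multiple of 40 µm, within a tolerance (default: half the
median inter-node spacing; exact multiples essentially never occur on
real reconstructions). Per (branch, multiple) the closest node wins;
ties break toward the lower node id. "Six neighbourhood pixels" is read
as the 6 face-adjacent voxels in 3D for shaft points and the 8 in-plane
neighbours of the terminal voxel's plane for endings; both conventions
are parameters. Background is a spherical voxel shell (default radii
3–6 voxels) around the sampling point, excluding the signal set and a
1-voxel sleeve around it; SNR = (signal mean − background mean) /
background SD, computed per point rather than per image tile. Median of
an even count is the mean of the middle pair.

SBR on a 23-pixel fiber cross-profile is (max − mean of the 4 lowest) /
(mean of the 4 lowest); it is invariant to pure rescaling but not to
additive offsets, which the tests assert as a property. The pipeline does
not place the 23-pixel ROI automatically — fiber detection is out of
scope.

## Clustering and association statistics

Features (R², OSI) enter k-means unstandardized — both already live in
[0, 1] — with a flag to standardize. k is scanned over 2..6 with 50
seeded initializations per k; the Calinski–Harabasz index
(B/(k−1))/(W/(n−k)) selects k, ties toward the smaller k. Zero
within-dispersion with positive between-dispersion yields +inf; all-equal
data raises.

Spearman correlations use average ranks; p-values come from the
two-sided t-approximation, replaced by exact permutation enumeration for
n ≤ 8 (full enumeration beyond that is impractical and the association
contract requires n ≥ 5). An association is significant only under the
dual rule p < 0.05 **and** |r| > 0.6. Per-region correlations restrict to
"projecting" neurons — those meeting the 1.0 mm target rule in that
region. Mann–Whitney uses the exact distribution for small untied
samples and the tie-corrected normal approximation otherwise;
Kruskal–Wallis is tie-corrected with a chi-square p; Dunn's post-hoc
z-tests on mean ranks apply no multiplicity adjustment by default
(Bonferroni/Holm by flag).

## Synthetic data: what it emulates, and what it does not

The generators exist to give every stage an analytic oracle, not to be
realistic:

* **Tuning tensors** draw per-trial maxima directly from the model plus
  i.i.d. Gaussian noise (rectified at zero), with a shared per-direction
  gain scaling the non-preferred orientation by (1 − OSI)/(1 + OSI) so
  the noiseless tensor's OSI equals its target exactly. No time courses,
  no calcium dynamics, no spike-to-fluorescence model.
* **Frame stacks** are sums of Gaussian "cells" under circular integer
  shifts — no optics, PSF, bleaching, or non-rigid motion.
* **Label volumes** are axis-aligned half-open boxes so clipped segment
  lengths have closed forms; real atlas regions are not box-shaped.
* **SWC neurons** are resampled waypoint polylines rooted at a soma;
  morphology statistics (branching angles, tortuosity) are not modelled.
* **Cohorts** draw (R², OSI) around class centroids (within-class SD
  0.05, i.e. at least 10× below the minimum centroid spacing of 0.5, so
  the three classes are well separated) and plant a Spearman correlation
  between one index and one region's length through a Gaussian copula:
  the Pearson parameter is 2·sin(π·ρ_s/6), so the population Spearman
  equals the requested value and ±1 are exact. Lengths are strictly
  monotone transforms of the copula variate, centred well above the
  1.0 mm rule.

Consequently, passing tests demonstrate correctness of the computations
and recoverability of planted structure under these idealized conditions;
they say nothing about segmentation quality, reconstruction accuracy, or
biological effect sizes on real data.

## Problem sizes and determinism

The end-to-end synthetic study runs 16 neurons in a 600×600×300 µm
box-world atlas (10 µm voxels, six regions), axon lengths of a few mm per
neuron, SWC node spacing 10 µm and length-quantification step 2 µm —
small enough to iterate quickly while every stage still exercises its
full contract. Property measurements use 1000 random affine transforms,
100 tuning draws (noiseless and at 10% relative noise), 50 box-world
reconstructions, 200 cohort replicates at n = 38 (clustering) and n = 17
(association), and 100 seeded frame stacks.

All randomness flows from explicit seeds through
`numpy.random.default_rng`; the pipeline expands one master seed per
stage via `SeedSequence.spawn`. Stage outputs are pure functions of
(config, seed): re-running with the same config yields byte-identical
CSVs, which the manifest's SHA-256 checksums make checkable.

## Known limitations

* Cell matching is geometric; the fiber-morphology criterion used by a
  human matcher is only crudely approximated by optional descriptors.
* The spatiotemporal fit can be near-unidentifiable when the true center
  lies off-grid with sub-grid-spacing widths; the algebraic initializer
  resolves this for noiseless data, but on noisy data parameters in that
  corner of the space carry little information from a 5×5 grid.
* Projection lengths are computed in native volume space; no atlas
  registration, so cross-animal comparisons are out of scope.
* Dunn's test without multiplicity adjustment (the default) is liberal
  when many pairs are compared.
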