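# Methods

This note records the models, numerical choices and limitations behind
`scarconcord`, in the spirit of a statistical software methods appendix.
Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Scar segmentation (FWHM)

Scar is the set of LV-wall voxels whose intensity strictly exceeds
`fwhm_frac` (default 0.5) times the maximum intensity over the wall mask.
Choices:

- **Strict ">" at the boundary.** A voxel at exactly half-maximum is
  normal. With continuous intensities the boundary set has measure zero;
  the convention only matters for constructed integer examples and is
  pinned by tests.
- **No pre-filtering.** The maximum is taken over raw wall intensities.
  An optional `clip_percentile` replaces the maximum with a wall-intensity
  percentile to guard hyper-intense outliers; it is off by default.
- **Known failure mode.** Half-maximum thresholding presumes enhancement
  is present. On a scar-free wall the maximum is just the noise ceiling
  and most of the wall exceeds half of it, so the method over-calls scar.
  This is inherent to the rule, reproduced faithfully, and covered by a
  test; users analysing possibly scar-free data should inspect the
  segmented volume fraction.

Voxel convention: 0-based indices, voxel centre = affine × index (NIfTI).

## Rigid registration

`fit_rigid_landmarks` is the closed-form Kabsch/orthogonal-Procrustes
solution: SVD of the centred cross-covariance with the standard
determinant sign correction, so the result is always a proper rotation.
Collinear sources leave the rotation under-determined and are rejected at
`LandmarkSet` construction.

`icp_refine` alternates nearest-vertex correspondence (KD-tree) with a
fresh Kabsch fit of the original points to their current correspondences,
stopping when the mean correspondence distance changes by less than `tol`
(default 1e-4 mm) or at `max_iter` (default 100; reported via a
`converged` flag, not an exception). The per-iteration RMS correspondence
distance — the quantity the least-squares step minimizes, hence provably
non-increasing — is recorded in `history_rms_mm`.

**ICP is off by default in the pipeline.** The scar point cloud is
transmural: it fills the wall thickness, while the mesh is only the
endocardial surface. Point-to-vertex ICP of a thick cloud against a
surface systematically pulls the transform inward by roughly half the
wall thickness (measured ~5–7 mm translation error on the phantom versus
~1 mm for the landmark fit alone), because a rigid translation along the
patch normal halves the mean cloud-to-surface distance. ICP genuinely
refines an alignment when the cloud lies on or near the surface — the
regime its recovery tests exercise — so the refinement remains available
via `AnalysisOptions(use_icp=True)` / the CLI flag, but the landmark fit
alone is the default estimate.

`map_points_to_nodes` labels a vertex scar if at least one point's nearest
vertex is it; ties on equidistant vertices resolve to the lowest index
(determinism). Points farther than `max_dist_mm` (default 5 mm) from every
vertex — e.g. epicardial-side voxels of a transmural scar under a thick
wall — are discarded and counted.

## Electroanatomic maps

Samples assign to their nearest vertex; multiple samples on one vertex
average (order-independent). Those vertices are Dirichlet constraints; the
remaining vertices solve the combinatorial (uniform-weight) graph Laplace
system, i.e. each unknown equals the mean of its neighbours. Uniform
weights are the minimal reading of "linear interpolation between mapping
points" on a shell; cotangent weighting was considered and not adopted
since all downstream statistics are binary per-vertex labels and the
choice only moves values near the measured/interpolated boundary. The
system is solved with a sparse direct factorisation; `method="jacobi"`
iterates the literal mean-of-neighbours relaxation to the same fixed
point and serves as an internal cross-check. Properties guaranteed and
tested: known values unchanged, solution within the known-value range
(discrete maximum principle), linearity in the boundary data, idempotence
(Laplace residual < 1e-8).

Thresholding: abnormal is strictly *below* the voltage threshold
(default 1.5 mV); slow conduction is strictly *above* the S-QRS threshold
(default 40 ms, very-slow flag at ≥ 80 ms). A site delay of exactly 40 ms
is therefore normal. Published summaries of the same data occasionally
write the slow rule as "≥ 40 ms"; the boundary convention only matters if
a site sits exactly on the threshold, and both thresholds are parameters.
Non-capturing pace sites are counted separately and excluded from
captured-site proportions and S-QRS diagnostics by default;
`impute_no_capture_as_slow` treats them as maximally slow instead.

## Concordance

"Total" Dice is the micro-averaged two-class Dice, algebraically the
fraction of vertices on which the two binary maps agree. This is the only
reading under which a scar Dice far below the normal Dice can coexist
with a total between them on a majority-normal surface; the macro average
(mean of the class coefficients) is available via `average="macro"`. A
class empty in both maps scores 1, empty in exactly one scores 0, so a
scar-free truth with a scar-free test scores perfect concordance. The
default comparison uses all vertices of the interpolated voltage map (the
platform's colour maps are surface-complete); `measured_only` restricts
to vertices that received an electrogram.

## Diagnostics

The LGE-derived nodal scar map is the gold standard. Voltage diagnostics
are per-electrogram: each sample is classified by its own voltage and its
truth is the LGE label of its nearest vertex. Confusion counts are
real-valued so that expected tables can be reconstructed from class sizes
and (sensitivity, specificity); `diagnostic_summary ∘ reconstruct_confusion`
returns the input rates identically. Undefined rates (zero denominators)
are `None`, never 0. ROC curves sweep all distinct score values, group
ties at one operating point and integrate by the trapezoidal rule, which
makes the AUC equal to the tie-aware Mann–Whitney pairwise probability
(asserted to 1e-12 against an O(n²) oracle). `orientation` declares the
disease direction: low for voltage, high for S-QRS.

## The phantom

The generator emulates the study regime rather than ventricular anatomy:

- **Geometry.** The LV wall is an ellipsoidal half-shell (endocardial
  semi-axes 20×20×32 mm, wall thickness 8 mm) truncated at a basal plane,
  on a 64³ grid of 1.2 mm isotropic voxels. The analytic membership test
  makes every geometric output checkable by brute force. Scar is a
  transmural sector: an azimuthal window (default 60°) intersected with
  the apical fraction of the shell depth (default 0.8), giving a scar
  volume of ~5 mL.
- **Mesh.** The endocardial surface is triangulated with latitude rings
  whose vertex counts are proportional to ring circumference (96 at the
  basal rim, 48 rings), stitched by a two-pointer merge — vertex spacing
  stays ~1.3 mm from apex to base. A plain UV parameterisation was
  rejected: its polar crowding puts many apical vertices inside a single
  voxel, leaving scar vertices with no nearest scar voxel and corrupting
  the voxel-to-node transfer. Matching vertex spacing to voxel size is
  the fidelity condition for nearest-vertex transfer.
- **Intensities.** Blood pool N(70, 5), normal wall N(30, 3), scar wall
  N(90, 9) in arbitrary signal units: scar at 3× wall intensity with 10%
  noise, comfortably above the half-maximum cut.
- **Electrics.** Bipolar voltage is log-normal per class — strictly
  positive and right-skewed like measured bipolar amplitudes — with
  median 3.8 mV (normal) and 0.8 mV (scar), log-SD 0.5. These medians
  place the 1.5 mV rule near its literature operating point and, with a
  0.1 mV scanner noise floor, give per-class SNR means (~43 normal, ~11
  scar) in the reported range for in-scanner electrogram recording. S-QRS
  delays are Gaussian truncated at zero, N(25, 8) ms normal and
  N(60, 10) ms scar; scar pace sites fail to capture with probability
  0.15. Activation time is a linear apex-to-base ramp (0.6 ms/mm) plus a
  15 ms scar delay and 4 ms noise — a smooth plausible field, carried as
  a secondary output with no downstream statistics.
- **Sampling.** 445 electrograms and 113 pace sites per study, sampled at
  mesh vertices with ≤ 1 mm jitter. Scar vertices are oversampled 3:1
  (`scar_sample_weight`), emulating mapping focused on the imaged scar
  and yielding roughly a third of samples in scar.
- **Frames.** Image and mapping frames differ by a rigid transform
  (default ~8° combined rotation, (4, −3, 2) mm translation — the scale
  of reported image-integration registration errors). The mesh and all
  electrical samples live in the mapping frame; the image and masks in
  the image frame. Landmark sources spread over ~1.5× the LV radius
  (multi-chamber blood-pool landmarks); destinations add 0.5 mm Gaussian
  noise. The wide baseline is what keeps the recovered rotation under
  ~1°.
- **Determinism.** One integer seed; each operation draws from a child
  stream with a fixed spawn key, so outputs are reproducible whether the
  phantom is built whole or operations are called in isolation.

What the phantom does *not* model — and hence what passing tests do not
establish about real data: ventricular anatomy and trabeculation, MRI
physics (partial volume, surface-coil shading, motion), electrophysiological
wave propagation and far-field electrogram genesis, catheter contact
variability, and non-rigid deformation between imaging and mapping. The
phantom validates the *analysis chain*, not the biology.

## Problem sizes

Default test and acceptance runs use the study-scale phantom
(64³ voxels, ~3000 vertices, 445 electrograms; < 1 s per pipeline run).
Unit tests use a 40³ down-scaled shell. The end-to-end operating-point
check draws 10,000 electrograms so that the comparison against the
closed-form log-normal tail probabilities is dominated by the systematic
voxel-to-node transfer error (~2–4 percentage points, concentrated in the
one-vertex band around the scar border) rather than binomial sampling
noise.

## Known limitations

- Point-to-vertex (not point-to-triangle) correspondences throughout,
  matching the nodal outputs; sub-edge geometry is invisible.
- The Dice sweep reuses one interpolated voltage map per run; threshold
  effects on interpolation (re-measuring at different densities) are out
  of scope.
- No confidence intervals on AUC or Dice (none are computed upstream
  either); the acceptance script reports point estimates per seed.
- FWHM over-calls scar when no enhancement is present (see above).
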