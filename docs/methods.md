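# Methods

Models, conventions, parameter defaults and numerical choices behind
`lnmech`.  Units follow the bench conventions stated in each module: forces
in µN, geometry in mm, microscopy lengths in µm (fibrils in nm), times in s,
moduli in Pa.  µN/mm² equals Pa exactly, so stress-like formulas need no
numeric conversion; the two conversions that do change magnitude (1/mm →
1/m in the effective resistance, µm → m in the passive tension) are explicit
in `mechanics`.

## 1. Plate-compression viscoelasticity (`mechanics`)

**Model.**  Force relaxation at constant strain follows a generalized Kelvin
body: an equilibrium spring in parallel with two Maxwell branches,

    F(t) = F_eq + A1 exp(-t/τ1) + A2 exp(-t/τ2),  τ1 < τ2 (canonical order).

**Fitting.**  Double exponentials are ill-conditioned, so
`fit_relaxation` restarts a bounded trust-region least-squares fit from 8
(τ1, τ2) pairs log-spaced over [1, 1000] s and keeps the lowest-residual
solution.  All parameters are constrained non-negative.  Only samples at
`t ≥ strain_onset_t` enter, with the decay clock zeroed at onset.  A flat
trace short-circuits to the exact degenerate solution (zero amplitudes,
zero residual).  When the fitted slow timescale exceeds half the recording
span, the slow branch is extrapolation, not measurement: the fit is flagged
`viscosity_undetermined` (flagged rather than discarded, so callers can
apply their own exclusion policy).

**Derived quantities.**  With contact stress `s = F_eq/(πR3²)` and strain
`ε = 1 − h_eq/h0`:

* effective resistance `σ = s / ((1/R1 + 1/R2)·1000)` N/m (radii in mm);
* Young's modulus `E = s/ε`;
* branch stiffnesses `kᵢ = (Aᵢ/πR3²)/ε` — each decay amplitude is treated
  as a stress amplitude over the same contact and normalized by the same
  applied strain as the equilibrium branch — and viscosities `µᵢ = kᵢτᵢ`,
  so the fitted timescales satisfy `τᵢ = µᵢ/kᵢ` identically.  µ2 (the
  minutes-scale branch) is the value quoted as "the viscosity";
* node volume `V = 4/3 π R1 (h0/2)²` from the side view, approximating the
  node as a spheroid with polar radius h0/2.

## 2. Capsule mechanics (`mechanics`)

Micropipette aspiration: Laplace's law `E = ΔP/(h/d)²` with the study
defaults ΔP = 750 Pa and d = 15 µm.  The inversion is exactly closed under
the generator (`gen_aspiration` computes `h = d·sqrt(ΔP/E)`), so noiseless
round trips are bit-exact.  Passive capsule tension is `E × thickness`
(µm → m), in N/m.

## 3. Network pore packing (`network_gaps`)

**Procedure.**  Gaps (non-network pixels) are packed with maximal inscribed
circles/spheres, largest diameter first.  The reference definition is:
recompute the Euclidean distance transform (EDT, image border treated as
blocked) after every placement and place the current diameter at the first
raster-order pixel whose EDT admits it.  The implementation runs one EDT per
diameter pass and validates each candidate against the pixels claimed
earlier in the same pass; because blocked space only grows, this is exactly
equivalent to the per-placement recompute (the test suite checks equality
against a brute-force implementation on random 2D and 3D masks).

**Conventions.**

* Ball membership and conflicts use exact integer arithmetic
  (`4·|offset|² ≤ d²`), so pixels at exactly the radius are classified
  deterministically with no float ties.
* Each element claims the still-unclaimed gap pixels within d/2 of its
  center; area fractions are claimed-pixel counts over total gap pixels and
  sum to 1.
* Diameter-1 elements claim every remaining gap pixel in raster order.
* The weighted distribution multiplies each bin's area fraction by its
  diameter (µm), emphasizing large pores; `mean_fitted_diameter` is the
  mean over the weighted distribution, with the plain area-weighted mean
  also reported.
* Anisotropic 3D stacks are resampled to isotropic voxels by
  nearest-neighbour zoom along z before packing.
* Stack averaging aligns per-slice distributions on the union diameter grid,
  averages area fractions per bin and recomputes the derived quantities.

## 4. Clonal clustering and the Cluster Factor (`clonal_clusters`)

**Pipeline.**  (1) ICP rigid registration of the red channel onto the green
(nearest-neighbour correspondences + Kabsch, reflection-corrected; clouds
whose second singular value is degenerate raise `RankDeficiencyError`).
(2) Mutual-nearest spot pairs closer than the 6 µm cell radius merge into
"yellow" double-labeled cells at the pair midpoint.  (3) Cells outside the
node or within the 100 µm edge margin are excluded.  (4) Per-lineage DBSCAN
where cells are 12 µm spheres and neighbours are within a 20 µm
surface-to-surface gap (center distance ≤ 32 µm), minimum 3 cells.  Yellow
cells join no cluster (their lineage is ambiguous) but stay in the
denominator of the clustered fraction.  (5) The null re-places the observed
per-lineage counts uniformly at random in the placement region (node
interior eroded by the margin, minus vessel volumes), re-clusters
identically, and averages the clustered fraction over 10 replicates.
(6) `CF = observed fraction / simulated fraction`; degenerate nulls warn and
return inf (observed clustering, none simulated) or NaN (neither).

**Region geometry.**  Analytic phantoms (ellipsoidal node, cylindrical
vessels) are voxelized once at 10 µm; interior and vessel-surface distances
come from EDTs of the voxel masks, and null placements sample region voxels
uniformly with intra-voxel jitter.

**Phantom density choice.**  The default synthetic node has semi-axes
(420, 260, 260) µm with a 100 µm margin (eroded interior ≈ 3.4 × 10⁷ µm³).
This was set analytically so that 300 uniformly placed cells produce an
expected clustered fraction of roughly 0.1–0.15 — enough clusters per CSR
replicate that the null CF concentrates near 1 instead of degenerating into
ratios of near-zero Poisson counts.  In a much larger phantom the CSR
statistic is undefined about half the time (zero clusters in both observed
and null draws), which tests nothing.

**Clonal generator sparsity.**  `gen_madm_cells` defaults to 10 labeled
precursors × 10 offspring with 8 µm dispersion.  Sparse labeling is the
point of the mosaic method: at this density the null clustered fraction is
~0.01 and clustered data sit two orders of magnitude above chance, while at
double the density chance clustering among unrelated lineages already
erodes the contrast.

## 5. Fibril alignment (`fibril_alignment`)

**Centerline.**  A natural cubic spline through 4 support points, fitted by
minimizing

    λ_data · mean² point-to-spline distance
  + λ_curv · ∫ κ² ds
  + λ_len  · (arc length − mean fibril length)²
  + λ_space· var(inter-support arc spacing)

with defaults (1, 10⁻³, 10⁻², 10⁻²).  The optimizer works in a centred,
unit-RMS-scaled frame, so the weights are dimensionless and the fit is
covariant under rigid motion and uniform scaling.  Starts come from the
principal axis of the pooled cloud (plus one seeded jitter) and are refined
by Powell search on a subsampled cloud with a coarse spline sampling; the
reported cost terms are recomputed densely at the optimum.  A result whose
cost exceeds the principal-axis initialization is flagged unconverged with a
warning.  `support_points` overrides the fit for manual centerlines.

**Angles.**  At each fibril vertex the central-difference tangent is
compared with the spline tangent at the nearest centerline point
(dense sampling + bounded refinement):
`A = acos(|v_f·v_c|/(|v_f||v_c|)) ∈ [0°, 90°]`.  Per-fibril alignment is the
mean over vertices; the bundle summary is the distribution of per-fibril
means.  Optional moving-average smoothing (odd window, truncated at the
ends) suppresses tracing jitter before angle extraction.

## 6. Ablation recoil (`recoil`)

**Kymograph pathway.**  Per post-cut frame, the edge is the maximum of the
absolute spatial gradient of the lightly smoothed profile, refined to
sub-pixel by a parabolic fit; frames whose best gradient is below 6 robust
(MAD) noise standard deviations raise `EdgeNotFoundError` rather than
returning a fabricated edge.  Recoil velocity is the least-squares slope of
the edge track over the first 5 post-cut frames, with an optional
caller-measured pre-cut drift slope subtracted.

**Field pathway (PIV).**  Frames are difference-of-Gaussians bandpassed
(σ = 1, 8 px), tiled into 32 px windows at 50% overlap, and each window's
displacement is the sub-pixel peak of the cyclic FFT normalized
cross-correlation.  Because window contents are not periodic, the raw
cyclic correlation at lag l is attenuated by the overlap fraction 1 − |l|/m,
biasing peaks toward zero; the correlator divides by that factor and
restricts the search to |l| ≤ m/4 (quarter-window rule) so the correction
cannot amplify spurious large-lag peaks.  On pure translations this leaves
a residual bias of ~0.02 px for shifts up to m/5.  Windows with near-zero
variance or a peak below 0.3 are invalid.  `perpendicular_recoil` averages
`v·n̂` over valid in-ROI vectors with the cut normal oriented toward the ROI
centroid, so motion away from the cut is positive.

## 7. Morphometry (`morphometry`)

Exclusive compartment volumes subtract overlaps in a fixed order:
lymphatics are removed from both T-zone and follicles, then the T-zone from
the follicles; fractions are of the exclusive sum and always total 1.
Nuclear/cytoplasmic ratio requires disjoint nonempty masks; ratio > 1 flags
nuclear enrichment.  Capsule thickness averages at least 3 per-node
measurements.  Control normalization divides by the mean control intensity.

## 8. Synthetic data (`synthetic_data`)

Every generator takes a single integer seed; sub-streams are spawned per
component (`SeedSequence.spawn`), so changing one parameter does not
reshuffle unrelated draws.  Defaults are the study conditions (relaxation:
F_eq 40 µN, A1 30 µN/τ1 5 s, A2 20 µN/τ2 300 s, 1% noise, 1200 s at 1 Hz;
geometry h0 2 mm → h_eq 1.5 mm, R1 = R2 = 1 mm, R3 = 0.5 mm).

What the generators emulate: the measured signal structure each analysis
inverts — double-exponential force decays with sensor noise, lattice-like
network masks with optional jitter, Gaussian-dispersed clonal families in a
voxelized node, straight fibrils drawn from a cone around a spline
centerline, a textured band retracting at constant speed, exact Laplace
tongues.  What they do not emulate: optics (no PSF, no photon statistics),
segmentation artifacts, anatomically realistic node shapes or vessel trees,
curved or growing fibrils, non-constant recoil (no viscoelastic slowdown
within the fitted window).  They are correctness instruments, not
microscopy simulators.

Problem sizes throughout (voxel grids of ~10⁵–10⁶ cells, hundreds of cells
or fibrils, hundreds of Monte-Carlo replicates) are the package's own
choice: large enough for the statistics to be meaningful, small enough that
the full validation suite runs in minutes on one CPU.

## Limitations

* The Kelvin inversion assumes the relaxation is fully captured by two
  branches; tissues with a broader spectrum will alias into the two fitted
  timescales.
* The packing statistic is resolution-dependent by construction (diameters
  live on the pixel grid); compare distributions only at matched pixel
  sizes (enforced in `average_over_stack`).
* The CF null conditions on the observed per-lineage counts and the node
  geometry, not on biological constraints (e.g. niches), so CF > 1 means
  "clustered beyond uniform chance", nothing more.
* PIV assumes locally uniform displacement per window; shear inside a
  window biases toward the dominant motion.
* ICP needs a reasonable initial overlap; it recovers small inter-channel
  offsets (µm-scale shifts, degree-scale rotations), not gross
  misalignments.
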