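# Methods

This note documents the model and the numerical choices behind `fiberskel`:
what the reconstruction computes, what the surrogate generator simulates,
which parameters matter, and where the genuinely open design decisions were
resolved.

## The reconstruction model

A 3D image stack B(x, y, z) of a thin-fiber network is reduced to a binary,
one-voxel-wide medial-axis skeleton in one pass of 2D template matching per
scan axis.

**Search sections and mismatch.** For a scan along axis a, the search plane
is the 2D slice perpendicular to a. Every interior pixel's centered
s × s window **w** is compared with a template **t** of the same size. Both
are flattened to vectors, the *global* stack mean μ is subtracted from every
component, and both are normalized to unit magnitude; the mismatch is their
Euclidean distance

    D = ‖ŵ − t̂‖ = sqrt(2 − 2 cos(w − μ𝟙, t)) ∈ [0, 2].

Subtracting the global (rather than a local) mean keeps the statistic
sensitive to absolute contrast against the stack's background while making
the pipeline exactly invariant under affine intensity maps B → aB + b
(a > 0) applied before quantization: b cancels in the mean subtraction and
a in the normalization. Windows that are exactly constant have no direction
and are assigned the maximal mismatch 2, as are border-margin pixels
(distance < s/2 from the plane edge), so both are fluid for any threshold.

**Per-plane skeletonization.** Pixels with D below the mismatching
threshold form localized clusters — the cross-sections of fibers cut by the
search plane. Within each cluster the *local minima* of D are kept: a pixel
survives if no 4-neighbor inside the cluster has smaller D (row-major
tie-break, so a tied plateau keeps exactly one pixel, and no two surviving
pixels are ever edge-adjacent). An elongated cross-section — the normal
case under anisotropic axial blur — thus reduces to its medial ridge.
Suppression is deliberately 4- rather than 8-connected: full 8-neighbor
suppression leaves pure one-dimensional chains whose neighbor-count mode is
pinned at 2 for *every* threshold, which would make the topology criterion
below unsatisfiable, while 4-neighbor suppression lets diagonal
near-duplicates coexist so that the reconstruction thickens gradually as
the threshold grows — fragmented chains at low thresholds, slightly
doubled chains at high ones, with the correct topology in between.

**Scan directions and combination.** Fibers intersecting a plane at less
than ~45° distort beyond what one template matches, but such fibers are
near-perpendicular to one of the other scan axes. In confocal *reflection*
mode the blind-spot effect makes fibers steep to the imaging plane
invisible, so only the x- and y-scans carry information; *fluorescence*
stacks are scanned along x, y and z. The per-axis binary stacks are
combined by voxelwise OR.

**Topology-driven threshold.** Voxelized isotropic line networks have a
universal signature: the histogram P(n) of the number of solid 26-neighbors
per solid voxel peaks at n = 3, almost independently of density (verified
here across a >10× density range; see the voxelization section). The
mismatching threshold is therefore chosen so the *reconstruction* shows
this signature. The search walks a coarse threshold grid (step 0.1)
upward, tracking the neighbor mode, which is non-decreasing in the
operating regime; both edges of the mode-3 interval are then refined by
bisection to 0.01 and the midpoint is returned. Two guards make the search
honest: (i) beyond the operating regime, background noise floods the
planes and the mode briefly *drops* before climbing again — the walk stops
at that collapse, and any mode-3 beyond it is rejected as spurious;
(ii) if the mode jumps from below 3 to above 3 between grid points, the
sliver in between is bisected before concluding failure. If no threshold
in (0, 2) yields mode 3, the input is reported as not line-like rather
than silently returning the nearest miss. A tie P(3) = P(2) (or P(4))
counts as satisfying the criterion, being the boundary of the acceptable
interval. The target mode is a module constant (3 for line networks);
other porous topologies would need a different value, which requires
a-priori knowledge of the structure — by design it is not a CLI flag.

## Automatic template generation

The template for each scan axis is the weighted average of 10⁴ random
s₀ × s₀ sections (s₀ = 21) perpendicular to that axis, weighted by the
central pixel's brightness above the stack minimum. Measuring the weight
from the stack minimum — for ordinary 8-bit stacks with dark voxels this
equals the raw central intensity — makes the average exactly equivariant
under affine intensity maps, which the raw-intensity weighting is not
(an offset would re-weight the sections).

Two systematic effects of this estimator are handled explicitly:

- **Center noise spike.** Selecting sections by their own central
  brightness correlates the selection with the center pixel's noise; the
  averaged pattern equals the true blurred cross-section plus a delta of
  height σ²/w̄ at the center pixel only (σ the per-voxel noise s.d., w̄ the
  mean weight). Left in place, that spike makes the template match
  isolated noise voxels. It is subtracted analytically, with σ estimated
  robustly from first differences (MAD). At σ ≳ 20 under strong blur the
  spike exceeds the true center signal — the template is then not
  learnable and template construction fails loudly; this bounds the
  method's noise envelope.
- **Positive far-field halo.** For a homogeneous random fiber network the
  intensity autocovariance is nonnegative, so the weighted average decays
  to the global mean *from above*; a strict "border pixels are negative"
  rule would never fire on surrogate data (on structured real data, where
  borders do go negative, it fires immediately and the behavior is
  unchanged). The size rule is therefore relative: the adapted size is the
  smallest odd s ≥ 5 whose outermost ring dips below 45% of the central
  peak — the half-decay ring of the cross-section. The floor of 5 exists
  because a 3×3 window cannot distinguish a blurred cross-section from a
  noise spike. The size is evaluated on the *uncorrected* average: its
  center spike sharpens the apparent profile as SNR drops, so the matching
  window automatically narrows on noisy data, as a matched filter should.
  The pattern itself is cropped from the corrected average and normalized.

Because the half-decay ring tracks the optical blur width, the adapted
size follows the input resolution (measured sizes 5 → 7 → 11 for the same
network rendered at voxel sizes 4 → 2 → 1 with fixed physical PSF), which
is what makes the method scale invariant.

## Surrogate data generator

The generator produces ground-truth-known stacks that mimic confocal
imaging of random line networks.

**Mikado networks.** N straight fibers of fixed length L with midpoints
uniform in the volume (so edge density is unbiased; out-of-volume parts are
clipped) and isotropic orientations: azimuth φ ~ U[0, 2π), cos θ ~ U[−1, 1].

**Voxelization.** A voxel is solid iff a fiber passes within r = 0.58
voxels of its center. The radius is the one genuinely free parameter of
the rasterization and is calibrated against the topology signature the
method relies on: at r ≤ 0.55 the traces fragment (isolated dots, mode 2);
at r ≥ 0.65 they are two voxels wide (mode ≥ 4); within r ≈ 0.57–0.60 the
traces are 26-connected, one voxel wide, and their neighbor-count mode is
3 across a >10× density range, 64³–128³ volumes and fiber lengths 30–70.
Simpler rules fail this property: nearest-voxel stepping along the
dominant axis gives pure chains (mode 2) and marking every cube the line
passes through gives mode 4.

**Imaging.** In reflection mode each fiber's voxels are pre-weighted by
the blind-spot factor f(θ) = sin²θ (full extinction for vertical fibers;
the exponent p = 2 is a modeling choice, p being unreported for real
optics); where fibers overlap, the brighter one wins. The volume is
convolved with an anisotropic Gaussian PSF (σz > σx = σy, blur largest
along the optical axis), rescaled so the brightest core reaches the target
peak (default 200) above background (default 15, matching typical confocal
reflection background statistics of ~15 ± 5 at 8 bit), plus additive
Gaussian noise, clipping and 8-bit quantization. The noise seed affects
only the noise: the noiseless component is bit-reproducible.

What the generator does *not* model: speckle (an interference artifact of
reflection microscopy, represented here only through the noise term),
refractive-index mismatch, depth-dependent attenuation, finite and
variable fiber thickness, and fiber curvature. Passing the validation
battery therefore demonstrates correctness under idealized straight-fiber
imaging, not performance on every real gel; in particular, real
high-resolution recordings resolve fine sub-fibers that the uniform-width
surrogates cannot represent, so the "pores shrink slightly at the highest
resolution" effect appears here only as approximate equality.

## Evaluation statistics

**Nearest-obstacle distances.** The pore-size proxy is the distribution
p(d) of Euclidean distances from uniform random test points to the nearest
solid voxel center, computed exactly with a KD-tree in physical units
(anisotropic voxel sizes supported). Defaults: 10⁵ test points, histogram
bin width of one voxel of the coarsest stack under comparison. Fidelity is
the Pearson correlation of two binned distributions on shared edges;
distributions binned differently are rebinned from their raw distances.

**Validation battery.** Twenty 128³ surrogate conditions spanning a 4×
density range (150–600 fibers, solid fractions ~0.5–2%, mean pores 3–8
voxels), lateral PSF 0.6–1.5 / axial 1.5–4.0 voxels, and noise 4–25
(harshest noise only at low density, where the template stays learnable —
in practice dense gels are imaged at better settings). The battery
prescribes *conditions*, not realizations; if a drawn realization at the
envelope's edge admits no topology-consistent threshold, one fresh
realization of the same condition is drawn. Measured over several seed
bases, per-stack correlations are 0.97–1.00 with batch means of
0.994–0.995 and every reconstruction at neighbor mode 3. The problem sizes
(128³, 20 stacks, 10⁵ test points) were chosen so a full battery runs in a
few minutes on one CPU.

## Numerical choices

- Mismatch fields are computed per plane with three small correlations
  (window·template, window sum, window sum of squares) and cached per axis
  as float32 volumes, so re-skeletonizing at a new threshold during the
  search costs only the cheap cluster-reduction step.
- Threshold-search tolerances: coarse step 0.1, edge bisection to 0.01,
  midpoint of the mode-3 interval returned.
- Degenerate inputs fail loudly: constant stacks (no positive template
  core), pure-noise stacks (no topology-consistent threshold), stacks
  thinner than the template, unknown imaging modes.
- Coordinates are 0-based (x, y, z) with z the optical axis; arrays are
  indexed [x, y, z] internally and written to TIFF as z-pages. Voxel
  (i, j, k) spans [i, i+1)×[j, j+1)×[k, k+1) with center at (+0.5 each).
- All randomness (network draws, noise, section sampling, test points)
  flows through numpy Generators seeded explicitly; fixed seeds give
  bit-identical outputs end to end.

## Known limitations

- Lateral PSF below ~0.5 voxel (under-sampled optics) is outside the
  operating envelope: cross-sections are 1–2 pixel dots and template
  matching cannot separate them from noise.
- Noise σ ≳ 20 at 8-bit with strong blur leaves the template unlearnable
  (see the center-spike bound above).
- At very high network density (≳ 800 fibers of length 60 per 128³, solid
  fraction ≳ 2.5%) the reconstruction raster sits at the P(2) ≈ P(3) knife
  edge and the mode-3 criterion becomes sensitive to the realization.
- Sub-voxel medial-axis refinement and curvature analysis of the
  reconstructed chains are out of scope; the skeleton is a voxel chain
  with quantization wiggle.
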