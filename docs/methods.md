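# Methods

`tubetomo` reimplements, on fully synthetic data, the computational chain
used to characterize the membranous tail tube that bacteriophage PRD1
assembles for genome delivery: phantom simulation with a single-axis
missing wedge, constrained-correlation subtomogram alignment and
wedge-compensated averaging, PCA/multireference classification, FSC
resolution estimation, rotational-symmetry analysis of 2D tube
cross-sections, and geometric parameterization of tubes, apertures and
vesicles. This note records the models, the defaults and why they hold,
and what the synthetic data do and do not establish.

## Phantom model

A particle is a sum of smooth density components on a cubic grid (axes
x, y, z; center voxel `N//2`; default voxel 0.88 nm, the pixel size of the
source tomograms):

- **Capsid**: an icosahedral shell. The surface is the support function of
  the 20 face planes (exact near faces, where the shell lives); the shell
  is `|s| < t/2` with thickness t = 5 nm. The circumradius default of
  33.3 nm is chosen so that the vertex-to-vertex (edge) distance is
  ~35 nm, the spacing seen between adjacent vertices; the circumradius
  itself is not a directly printed number. Vertex order follows the
  standard golden-ratio construction, documented in
  `icosahedron_vertices`, so vertex indices are stable.
- **De-capped vertex**: density is removed along a smooth cylindrical bore
  of diameter 15 nm along the vertex axis. A bore (rather than an angular
  cone) makes the hole's chord diameter on the shell equal to the request
  regardless of local shell radius, so generator and measurement agree by
  construction rather than by calibration.
- **Tail tube**: a hollow cylinder with inner diameter 2r1 = 4.5 nm and
  outer diameter 2r2 = 14 nm (the printed dimensions), default length
  51.4 nm, attached at the vertex surface (so the protruding length equals
  the requested length) and tilted by the deflection angle in the x-z plane.
  `n_strands` > 0 adds Gaussian rods on the mid-wall circle (optionally
  twisted) to emulate an ordered multi-strand wall; 0 gives the
  featureless cylinder used for negative controls and class references.
  An optional crowning ring is an annulus of diameter 18 nm, radial
  thickness 2 nm and height 3 nm, placed 2 nm below the tube tip.
- **Vesicle**: icosahedral (intact procapsid membrane, circumradius
  23 nm), spherical, or "map-pin" (collapsed late-ejection morphology: a
  15 nm-radius head plus a thin neck toward the tube vertex). Membrane
  thickness 5 nm. The head radius is a modeling choice made once so that
  the icosahedral-to-map-pin transition reduces enclosed volume clearly
  more than membrane area, the direction reported for the real particles;
  exact percentages are shape-model-dependent and are not asserted.

All surfaces are rendered as soft indicators `0.5*erfc(s/(σ√2))` of their
signed distance with σ = 1 voxel. This anti-aliasing places half-maximum
density crossings on the geometric surface, which is what makes
half-maximum radius fitting consistent at 5-voxel wall scales, and avoids
staircase artifacts that would dominate cross-correlation scores.

Tube populations draw lengths from a normal(51.4, 9.4²) nm truncated to
positive (physical positivity; the source text is silent on the tail
shape) and orientations uniform over SO(3) or cone-restricted.

**2D cross-sections** are 80×80 images at 0.28 nm/px (the 2D analysis used
2.8 Å pixels, not the tomogram pixel size): an annulus between the tube
radii, modulated by `1 + c·cos(kφ)` for k-fold symmetry (contrast c = 0.6,
random phase), plus white noise. Symmetry order 1 is rejected — it is not
a rotational symmetry of a closed tube wall. The default mixture
reproduces the reported population: 18% 3-fold, 28% 2-fold, 19% higher
(spread over orders 4–7), 35% spurious (plain annuli whose angular signal
is noise only), with noise sd 0.35 relative to unit wall amplitude.

## Tilt-series simulation and the missing wedge

The beam runs along z and the tilt axis is y (one convention everywhere).
Projection rotates the volume about y (trilinear, about the center voxel)
and sums along z. The default geometry is ±64° in 1.5° steps, the
acquisition range of the source data; the wedge mask marks Fourier voxels
whose in-plane direction solves `fx·sinθ + fz·cosθ = 0` for some sampled
θ. The mask is explicitly symmetrized (Friedel), is 1 at zero frequency,
and for ±64° excludes (180−128)/180 ≈ 28.9% of the in-plane angular range.

WBP applies a ramp filter apodized with a raised cosine from 0.9 Nyquist
(suppresses ringing on small grids), back-projects, masks to the inscribed
cylinder, and finally restricts the result in Fourier space to the sampled
region of its own tilt geometry: trilinear back-projection leaks ~9%
broadband amplitude off the central-section planes, and the acquisition
geometry says those voxels must be empty. SIRT is the plain simultaneous
update (default 30 iterations, no positivity). No CTF is simulated
anywhere, matching the uncorrected source data; band-limiting phantoms to
~5 nm via `lowpass` stands in for the first-zero limit where needed.

`simulate_subtomogram` offers two degradation routes — full
project→noise→WBP, or direct Fourier wedge masking plus real-space noise —
which agree at cc > 0.9 on smooth phantoms; the Fourier route is the fast
default for tests. Noise is white Gaussian at variance = signal
variance / SNR, always seeded.

## Alignment and averaging

Euler angles are intrinsic Z-Y-Z triplets in degrees mapping the reference
frame onto the particle frame (the original software's internal convention
is unknown; this one is fixed and documented). The constrained cc of two
volumes is computed over the intersection of their (rotated) wedge masks
with the DC term removed — correlation only where both particles carry
signal, so mutually missing wedges cannot fake agreement.

The orientation search reproduces the coarse-to-fine protocol: a cone of
directions (default aperture 60°, full 360° azimuth) sampled at 15°, then
three local re-scans that halve the sampling (final 1.875°). Cone grids
are Fibonacci-sphere points clipped to the cone — deterministic and
near-uniform — thinned greedily to the target spacing and oversampled 1.5×
so the worst-case gap stays below the nominal sampling; recovery of a
known rotation is tested to within the final sampling. Translations come
from the correlation theorem under the particle's wedge, restricted to
per-axis shift limits (the stated "along the tube long axis" restriction
generalizes to per-axis limits).

Averaging maps each particle back through the inverse of its alignment,
sums in Fourier space, and divides voxelwise by the summed rotated wedge
masks floored at 0.1 × n_particles (bounds noise amplification in
never-sampled voxels). Iterative refinement alternates align/average
(default 4 iterations) and finally drops particles with cc below
0.5 × mean cc — the multiplicative reading of the published selection
rule, the only reading that scales with dataset SNR. Subboxing maps a
reference-frame offset through each particle's alignment and re-extracts
a smaller cube, inheriting the wedge with the rotation recorded.

## Classification

The "constrained covariance" is implemented as the Gram matrix of pairwise
constrained ccs of aligned particles (the computable reading of the
phrase; whether the original PCA acted on this matrix or on masked voxel
features is not stated). Particles are embedded on the top eigenvectors
scaled by √eigenvalue. The outlier rule runs 2-means on the embedding but
accepts the split as real structure only when the between-group mean cc is
below 0.7× the within-group mean — otherwise the set is homogeneous and
fully retained. A bare "keep the larger cluster" would split a homogeneous
set roughly in half, which is not pruning but data loss.

Multireference classification starts from four featureless cylindrical
shells spanning ±1 voxel in wall radius and ±20% in length, aligns every
particle to every reference, assigns arg-max cc (ties to the lowest
index), and re-averages per class; emptied classes are re-seeded from the
worst-fitting particles. The negative control required of this machinery
is that averaging featureless-cylinder subtomograms (random orientations,
±64° wedge, SNR 0.5) must not imprint an angular pattern: the maximal
cross-section harmonic energy of the average stays below 3× the
noise-free cylinder's.

## Resolution

FSC is the per-shell normalized complex correlation (real part) between
two volumes; resolution is the first downward 0.5 crossing, linearly
interpolated, in nm. If the curve never crosses, the Nyquist distance
(2 × voxel) is returned with a flag. Half-sets share the final alignment
and split only at averaging (even/odd particle index), mirroring the
described procedure; a gold-standard split is out of scope. Real-space
masks inflate FSC, so the pipeline logs the mask in use. Filters are
radial raised-cosine rolloffs two Fourier shells wide; the zero-frequency
term is untouched, preserving the mean.

## 2D symmetry analysis

The rotational power spectrum resamples an image to polar coordinates
(128 angular samples) about its center, takes the angular Fourier
transform, and integrates `r·|A_n(r)|²` over the radial window (r-weighted
so annuli count by area; default window 8–30 px covers the tube wall).
Energies of harmonics 1–9 are normalized to sum 100; n = 0 is excluded
(a pure radial profile carries no symmetry information) but retained as
`angular_fraction`, the raw angular share of total energy, which is what
distinguishes a plain annulus (angular_fraction ≈ 0) from a modulated one.
Images are normalized and low-pass filtered to 1.5 nm before analysis.

Spectra are grouped on a 5×5 batch SOM (Gaussian neighborhood shrinking
from σ=2.0 to 0.4 over 30 epochs, seeded, with per-node mean and variance
reported). The kernel-density SOM variant of the original workflow is
replaced by this standard batch SOM: the map is only used to group spectra
before harmonic labeling, which the dominance rule automates — a node is
labeled with harmonic h when P_h is maximal and ≥ 1.5× the runner-up,
mapping h=2 → 2-fold, h=3 → 3-fold, h∈4..9 → higher, otherwise spurious.
The numeric dominance ratio operationalizes what was originally a visual
call. Population fractions are percentages of images per label. Because
every member of a node inherits the node's label, minority members of
mixed nodes are counted with the majority; on the default mixture this
biases the recovered 2-/3-fold fractions slightly upward (weakly
modulated or spurious images absorbed into symmetric nodes), a failure
mode shared with any group-then-label workflow.

## Geometry measurements

- **Radii**: mean density in 1-voxel cylindrical annuli about the tube
  axis, averaged over a z-range; r1/r2 are the half-maximum crossings of
  the wall peak (linear interpolation). Half-maximum crossing rather than
  a Gaussian fit matches the ~5-voxel wall scale.
- **Length**: Otsu-thresholded density beyond a clearance radius (outside
  all capsid density), principal axis by intensity-weighted second moment,
  length = maximal axis coordinate minus the capsid surface radius
  (lengths are measured from the capsid surface; whether the originals
  were measured from the surface or the gate is not stated).
- **Exit angle**: angle between the fitted tube axis and the vertex radial
  axis, folded to [0°, 90°] (axes are unsigned). The spherical clearance
  cut clips the tube base obliquely, which biases the estimate by ~1°
  at 20° deflection — within the ±2° tolerance used throughout.
- **Aperture**: for directions in a cap around the vertex, the maximal
  density along the radius forms a shell-presence map; the aperture is the
  angular extent around the vertex where presence stays below half the
  surrounding shell level, converted to a chord at the local shell-peak
  radius. An intact vertex reports 0.
- **Ring**: per-slice radial profiles (slices with < 25% of the global
  maximum are skipped as smoothing tails); ring slices are those whose
  outermost significant peak exceeds the body median by ≥ 2 voxels;
  diameter = 2× that peak radius.
- **Vesicle metrics**: volume by voxel counting; area by marching-cubes
  triangulation of the 0.5 isosurface after 1-voxel Gaussian smoothing of
  the binary mask (raw binary marching cubes overestimates area by ~8%;
  smoothing brings a digitized sphere within 1%).

All measurements are checked to be invariant under global rotation at
stated tolerances.

## Problem sizes and numerical choices

Default boxes are 96³ for single-particle measurements and 160–280³ for
whole-capsid phantoms (populations share one cached static capsid render
and differ only in their tubes). Alignment tests use 36–40³ boxes with
reduced schedules; the full-scale schedule (60° cone, 15° sampling, three
halvings) is exercised on the known-rotation recovery test. The symmetry
chain runs at full scale (1,758 images) in seconds. Degenerate inputs
(all-zero particles, empty masks, monotone profiles, emptied classes,
curves that never cross the threshold) raise or flag rather than return
silently wrong numbers; tie-breaks (class assignment, arg-max shifts) go
to the lowest index.

## What the synthetic data do not show

Phantoms are noise-free geometry plus white noise: no CTF, no dose or
beam-induced motion, no fiducial alignment error, no structural
flexibility, no crowded background, and the 2D "spurious" class is a
plain annulus rather than the full zoo of oblique sections and overlaps
in micrographs. Passing recovery tests therefore demonstrates the
correctness and self-consistency of the measurement chain — that each
operator recovers what the generator planted, through the wedge and the
full pipeline — not that the pipeline would achieve the same accuracy on
real cryo-ET data. Real-data headline numbers (5.8/6.4/5.7 nm
resolutions, class sizes, inter-class ccs, in-vivo tube dimensions) are
functions of the original data and are out of scope.
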