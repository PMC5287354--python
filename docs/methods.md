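# Methods

This note documents the models, conventions, default parameters and design
choices behind the package, and what its synthetic experiments do and do
not demonstrate about real data.

## Conventions

* Volumes are arrays indexed `data[ix, iy, iz]`; a voxel's index triple is
  its Cartesian coordinate in voxel units. MRC files written through gemmi
  put x on the fast axis, interoperable with the usual `(z, y, x)` readers.
* Euler angles are intrinsic ZYZ `(phi, theta, psi)` in degrees,
  `R = Rz(phi) Ry(theta) Rz(psi)`; a pose rotates the reference about the
  box centre `(n−1)/2`, then translates. Particle centres and shifts are
  stored in Å in the unbinned tomogram frame, so they are invariant under
  rebinning; only their voxel representation changes.
* The tilt axis is the image y-axis at zero in-plane rotation; the beam at
  tilt t is the z-axis rotated by t about the tilt axis. A frequency k is
  observed if the tilt solving `k·beam(t) = 0` falls inside the tilt range;
  at ±60° this leaves the classic missing wedge around the beam axis.

## Phantoms

**Microtubule.** A sum of isotropic Gaussian monomer blobs on an n-start
helical lattice: protofilament p sits at azimuth `2πp/n`, staggered
axially by `p·(start·spacing/n)`; defaults n = 13, spacing = 40 Å,
start = 3 (the textbook in vivo 13_3 lattice; the paper-scale seam is
deliberately not modelled — symmetrisation is exact n-fold). The axial
centring offset is rounded to a whole number of repeats so lattices of
different lengths share one axial phase.

Two calibrated geometric choices:

* `monomer_sigma` = 14 Å (FWHM ≈ 33 Å). Compact monomers keep ~20% density
  modulation at the 40 Å repeat and a clear ~48 Å protofilament
  separation — the striations visible in real tomographic slices of
  microtubules. A much smoother lattice (σ ≳ 20 Å) suppresses the repeat
  below 1% (`exp(−2π²σ²/T²)`) and with it any possibility of register
  alignment.
* The monomer-centre radius is solved (from the ring–Gaussian convolution
  profile `exp(−(r−a)²/2σ²)·√(a/r)`) so that the outer half-maximum of the
  rotationally averaged radial profile falls exactly at
  `outer_diameter/2` = 125 Å; "outer diameter" therefore means the same
  thing the measurement reports.

**Capsid.** A Gaussian radial shell (default σ = 30 Å) of the given radius
with optional marker blobs just outside the 12 five-fold vertices
(amplitude 10× the shell), standing in for penton-like surface features.
Vertices follow the 532 convention with 2-fold axes on the coordinate
axes; the 60-operator icosahedral rotation group is generated by closure
from a vertex 5-fold and the z 2-fold.

## Imaging model

Projection is a parallel-beam line integral computed by rigidly resampling
the scene onto a beam-aligned grid (trilinear) and summing along the beam;
mass is conserved to interpolation error. The default scheme is ±60° in 3°
steps — conventional values, since exact acquisition schedules live in
supplementary material not reproduced here. Noise is white Gaussian with
variance `var(signal)/snr` taken over the whole image stack; detector MTF,
dose-dependent damage and fiducial-based alignment errors are not
modelled (the simulator emits perfectly aligned tilt series). The CTF is
the standard two-term model with underfocus positive and no astigmatism or
envelope; the first lobe is negative, so the uncorrected forward model
inverts low-frequency contrast relative to the object, and phase flipping
(multiplication by sign CTF) makes the transfer `|CTF|`. Per-strip
flipping applies the tilt-induced defocus gradient
`Δz(d) = Δz₀ + d·tan(t)` in bands perpendicular to the tilt axis,
reassembled without feathering.

Reconstruction is weighted back-projection: Ram-Lak `|f|` filtering along
the in-plane direction perpendicular to the tilt axis, then smearing along
rays; the global scale is arbitrary.

## Alignment

`align_subvolume` searches rotations exhaustively on a grid around the
starting pose and reads the translation from the peak of the constrained
cross-correlation — normalised over the Fourier components outside the
missing wedge and (by default in the workflows) inside a 25 Å low-pass
band. Band-limiting the correlation is standard practice: at snr 0.3 the
full band is dominated by noise while the discriminating lattice features
(the 40 Å layer line, the 48 Å protofilament spacing) sit well below
1/25 Å⁻¹. Translation normalisation is exact (a shift only changes
phases), one inverse FFT scores all shifts, and the integer peak is
refined per axis by parabolic interpolation; the shift window is a per-axis
bound and poses at its edge are flagged. A cosine-edged spherical mask
suppresses wrap-around. Rotated-reference FFTs are cached across particles
that share a reference and wedge.

`refine_iteratively` runs the schedule of shrinking
`(ang_range, ang_step, shift_limit)` entries independently per half-set,
starting (by default) from the unaligned average of each half's picked
particles — a data-derived reference with no external-bias risk. Two
choices matter for helical specimens:

* **Reference symmetrisation.** Each half reference is symmetrised with
  the 13_3 screw operators every iteration. This is not cosmetic: it makes
  every correlation maximum in the (spin, axial-shift) landscape land *on*
  the helical lattice, so early, noisy register locks are harmless (any
  lattice-equivalent pose maps the data onto the same canonical density).
  Without it, register locking at snr 0.3 stalls near 50%.
* **Search shape.** The first two passes search only the spin angle
  (±14°, half the 27.7° lattice period — every register has a reachable
  equivalent) with shifts up to 28 Å, covering the accompanying helical
  rise (up to ±20 Å along the axis); the filament axis itself is already
  known from the trace to within the picking accuracy, and the final pass
  refines all three angles. A full three-angle wide search is slower and,
  at this snr, less reliable.

Independent half-set refinement determines each half's structure only up
to a global spin/axial-shift gauge. Before the combined average is
accumulated, half B's reference is registered onto half A's by a
screw-axis search and the correction composed onto half B's poses — the
halves never see each other's data during refinement; only the final
combined product uses the cross-half registration. (A full third
refinement on the combined data would serve the same purpose at twice the
cost.)

Averaging accumulates mean-subtracted, inverse-transformed sub-volumes in
Fourier space, each masked by its rotated wedge, and divides by the summed
wedge occupancy. Datasets whose particles carry diverse lattice spins fill
the equatorial region that a single orientation leaves empty — this is why
the scene generator randomises spins per filament.

`align_reference_to_particle` (the capsid path) low-passes both volumes to
the stated resolution (cosine edge ending exactly at the cutoff), scores a
quasi-exhaustive ZYZ grid over the whole rotation group, locally refines
the best distinct candidates with shrinking ranges, and reports two poses
when the runner-up is within 1% — which for a symmetric particle is the
expected outcome (symmetry copies tie).

## Validation

FSC uses shells one Fourier voxel wide on a cubic box, no smoothing.
Resolution is the *first* downward threshold crossing (0.5 and 0.143),
linearly interpolated; an uncrossed curve reports Nyquist with a flag,
because noisy curves re-cross and a tight mask can manufacture crossings
in noise — the null-statistics tests reproduce that masked null FSC is
biased upward relative to unmasked. Four mask regimes are provided: none,
reference-thresholded with a cosine soft edge, and hard/soft cylinders of
approximately the filament diameter.

The lattice diagnostics: the rotational power spectrum samples the wall
band (70–135 Å radius) on rings, FFTs over angle and averages power over
radius (area-weighted) and the central half of the box; the layer-line
profile integrates `|F|²` over in-plane frequency per axial frequency,
with a parabolic sub-shell peak refinement when a repeat distance is
reported. Back-plotting paints the average at every pose into an empty
volume; the default voxelwise-maximum mode avoids double-counting where
overlapping filament boxes meet.

## The reference experiments and their scale

`run_microtubule_benchmark` (seeded end to end): 208×208×56 voxels at
8 Å (a ~1.7 µm² field, about a sixth of a production tomogram's linear
extent), five filaments of 1280 Å with directions spread over 180°,
random spins and registers, snr 0.3, ±60°/3° tilts; ~165 picks of 48³ at
40 Å intervals, three refinement iterations in gold-standard halves,
CCC ≥ 0.2 and 4 nm duplicate filtering (register moves along the filament
axis make some picks collide; the lower-scoring one is dropped, typically
leaving ~80–110). The protofilament count is measured on the
*unsymmetrised* combined average, so the 13 is not imposed by the
operators; the layer-line repeat is measured on the helically symmetrised
final model, whose operator comb also suppresses box-scale axial
envelopes that dominate the profile of a small-N average. Across seeds the
run yields order 13 and a repeat of 39.1–39.6 Å in one to two minutes on
one CPU.

`run_ctf_comparison`: a single-filament scene imaged at 5.2 µm underfocus
(first CTF zero ≈ 0.031 Å⁻¹, in-band at 8 Å voxels), reconstructed with
and without phase flipping; sub-volumes are averaged at ground-truth poses
so the comparison isolates the CTF treatment, and both branches share one
noise realisation. The FSC to an ideal reference (the noiseless lattice,
Gaussian-blurred to Nyquist and matched in sampling and box) is negative
in the first negative CTF lobe without flipping, non-negative with it, and
the flipped curve dominates beyond the first zero.

## What the synthetic experiments do not show

The generator omits crowded cytoplasm, membranes and neighbouring
macromolecules, detector physics, dose fractionation damage, tilt-series
misalignment, filament curvature and the microtubule seam. Passing tests
therefore demonstrate the correctness and internal consistency of the
algorithms under a faithful geometric and statistical model of wedge,
CTF and noise — not that the pipeline's parameter defaults transfer
unchanged to any particular microscope's data.

## Numerical choices

Trilinear interpolation for all resampling (rotations about the box
centre); float32 volumes with float64 accumulators; FFT caches keyed by
quantised Euler triples; duplicate removal is greedy in descending CCC
with ties broken by lower particle id; degenerate inputs (zero-range
searches, empty particle sets, never-crossing FSC curves, gimbal-locked
Euler poles) are handled explicitly and tested.
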