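# Methods

This note documents the models, estimators, and numerical choices behind
sarcotom, and what the synthetic data do and do not establish about real
tomograms.

## Coordinate and orientation conventions

Lengths are nanometres throughout; coordinates are right-handed (x, y, z).
Generated sarcomeres run along +x; density maps are indexed (z, y, x) with
cubic voxels and the voxel center at its coordinate, and are written as MRC
mode 2 with the voxel size (Å) in the header.

Euler angles use the zxz convention with the rotation matrix
`R = Rz(psi) @ Rx(theta) @ Rz(phi)` acting on column vectors.  `R @ ez` is
independent of phi, so (theta, psi) are fixed by the local filament tangent
(theta = polar angle from +z, psi = azimuth) and phi is the free in-plane
rotation about the filament axis.  In the gimbal case (tangent parallel to
z) psi is set to 0.  Since the in-plane rotation cannot be read from a
tomogram, initial poses draw phi i.i.d. uniformly from a 30° grid,
independently per subvolume; this breaks the in-plane degeneracy during
averaging (the unaligned average of such poses is a featureless cylinder).

## Synthetic study conditions

The generator's defaults are the conditions of the study the analyses
target: hexagonal thick-filament lattice constant 45.1 nm; trigonal thin
filaments at 45.1/√3 = 26.0 nm; sarcomere length 1800 nm (examples at 1650
and 1960 nm); Z-disk width 120 nm (100–140 nm range); I-band 270 nm
(240–300); bare zone 140 nm; thin-filament length sd 50 nm; actin rise
2.76 nm, twist −167.0°, 13-subunit repeat 35.88 nm (printed 35.9).

**Jitter semantics.**  Interfilament spacings are reported as mean ± sd of
measured distances (45.1 ± 3.8 nm), so `LatticeSpec.jitter_sd` is
calibrated to the spacing spread it induces: each filament receives a rigid
lateral offset with per-component sd `jitter_sd/√2`, making the sd of
nearest-neighbor spacings equal `jitter_sd`.  Jitter is rigid per filament
(not per point), preserving the "equidistant and nearly parallel" premise
of the near-neighbor analysis.

**Interstitial thin filaments.**  Two placement models are provided.
`build_lattice` places a Poisson number of extras uniformly per unit cell,
rejected within 10 nm of any existing axis (steric exclusion implied by the
8.4/17.4 nm filament diameters; bounded retries, then an error).  The
spatial statistics of real interstitial filaments beyond their 15.5 nm
nearest-neighbor mean are not known, so for calibrated tests
`build_calibrated_lattice` plants the nearest-neighbor law exactly: thin
filaments come in isolated four-filament clusters (two trigonal bases one
trigonal spacing apart — keeping the 26 nm shell in the histogram — each
with a companion at a distance drawn from N(15.5, 1.4)).  Companion
*directions* are rejection-sampled to keep 22 nm clear of every other thin
filament, but the drawn distance is never resampled, so the planted
distance law is exact by construction; the steric thick-filament exclusion
is waived for companions for the same reason.  Uniform placement cannot
plant a controlled nearest-neighbor distribution (companions stray near
other thins and drag the true mean far below the target), which is why the
cluster design exists.

**Sarcomere construction.**  Thin filaments anchor their barbed ends at the
Z-disk faces (half a Z-disk width from the Z-disk center) and extend toward
the M-line with Gaussian lengths truncated at the planted maximum extent
(sarcomere/2 + overlap/2 from the Z-disk center); the longest filament per
half-sarcomere is set to the cap exactly, so the planted overlap is
realized exactly and is recoverable by direct geometry.  Thick filaments
span the A-band centered on the M-line.  Construction errors are raised
when the planted overlap is unreachable by the thin-length distribution or
the thick filaments would invade the Z-disk.

**Density model.**  Thin filaments render as soft-sphere subunit densities
on the single-start actin helix plus two continuous tropomyosin tubes
following the long-pitch twist (wrap(2·twist)/2 = +13°/subunit) at
tpm_radius, 180° apart, rotated by `tpm_azimuth`.  Each subunit is two
Gaussian lobes (main lobe at radius 2.2 nm, σ 1.2 nm; secondary lobe at
2.9 nm, azimuth +45°, axial offset +0.69 nm, σ 0.8 nm).  The secondary
lobe breaks the perpendicular two-fold symmetry that a plain helix of
spheres would have — a bare uniform helix maps onto itself under a 180°
flip, so polarity would be undetectable; the off-phase lobe plays the role
of the asymmetric actin subunit shape.  The lobe and tropomyosin radii are
separated (2.2/2.9 vs 4.8 nm) so the cylindrical shell used for the
tropomyosin azimuth measurement is tropomyosin-dominated; with overlapping
radii the measured azimuthal shift is biased toward zero by the
polarity-carrying actin density.  Noise is additive Gaussian scaled so that
signal variance / noise variance equals `snr`; the optional missing wedge
(off by default) zeroes frequencies within the half-angle of the beam (z)
frequency axis, tilt axis y.  Rendering is linear in the poses and
deterministic given the imaging seed.

## Packing estimators

Every other filament contributes its single closest point per reference
point (no k-nearest scheme); θ is the unsigned acute angle between tangents
because tangent sign is meaningless before polarity is known.  Default
bins: 0.5 nm × 1°, configurable (the choice is not critical; it is not
specified by the analyses this package follows).

The spacing estimator keeps the "two-thirds of the peak maximum" rule but
evaluates it robustly.  Straight synthetic filaments contribute ~100
identical distances per filament pair, so the raw marginal is lumpy at the
pair level; locating and bounding the shell by raw threshold crossings made
the estimate unstable (sd 0.33 nm across seeds at the 45.1/3.8 conditions).
Therefore: (1) the shell is located on a 7-bin moving average, requiring a
peak prominence of 20% of the maximum so pair lumps on a shell tail cannot
pose as a shell, and taking the smallest-d qualifying peak so dense second
shells cannot capture the estimate; (2) the two-thirds cut is evaluated on
a robust Gaussian profile of the shell — trimmed moments (±2.5 σ, de-biased
by the truncation factor 0.9546) of the raw distances in the shell's
support region — giving the window mean ± 0.9005 σ, the two-thirds-of-peak
points of a Gaussian; (3) mean and sd are computed over the raw distances
in that window (sd 0.11 nm across seeds).  On a jitter-free lattice all
distances coincide and the estimator returns the lattice constant exactly
with zero sd.  The reported sd is the spread of thresholded distances (not
a per-tomogram sd, which the source analyses leave unspecified).

Local frames skip reference points without a parallel neighbor in the
distance range; exact neighbor-distance ties (ideal lattices) are broken by
neighbor id, which is deterministic but not rotation-equivariant —
equivariance holds whenever distances are distinct.

## Alignment, averaging, polarity

Scoring is masked normalized cross-correlation under a soft cylindrical
mask (radius 0.4 box, 2-voxel cosine edge); the scoring function of the
established subtomogram-averaging packages is internal to them, and masked
NCC is the standard, documented choice.  Each subvolume is resampled once
into the reference frame through the inverse of its current pose; candidate
delta rotations are shared across subvolumes, so rotated references are
computed once per round, and translations are searched on the integer-voxel
grid by FFT cross-correlation with exact per-shift masked normalization,
followed by parabolic sub-voxel refinement.  Shifts are constrained to
±1.38 nm (half a subunit) along the filament axis — so alignment cannot
slide onto the neighboring subunit — and ±2 voxels transverse.  A matched
delta rotation Q of the reference corresponds to the particle rotation
`R_base @ Q.T`; getting this composition right is what makes scores and
averages consistent (scores then rise monotonically on noise-free input).
Angular grids default to 10° global in-plane and ±10° at 2° local; they are
configurable and deliberately coarse at desk scale.  Iterative averaging
stops with an error if the mean score drops three rounds in a row.

Deduplication keeps one pose per actin subunit: greedy by descending score
within each filament, dropping poses strictly closer than 2.76 nm to a kept
one; the kept set is maximal.

FSC uses unit-width spherical frequency shells; the resolution is the
linearly interpolated first 0.143 downward crossing, Nyquist (two voxels)
when the curve never drops below threshold.

**Polarity test design.**  Per filament, score samples against the two
references are compared with a two-sided pooled-variance unpaired Student's
t-test (Welch variant behind a flag); p < α calls the higher-scoring
reference.  The default `design="split"` scores even-indexed subvolumes
against reference A and odd-indexed against B, so the two samples are
statistically independent and the test is calibrated: on polarity-free
noise the confident-call fraction equals α (measured 0.038 on 500 noise
filaments at α = 0.05).  Scoring *every* subvolume against both references
(`design="both"`) makes the samples share the subvolume noise and the
unpaired test grossly conservative (0 of 500 false calls in the same
simulation); it is kept for comparison and is exactly symmetric under
reference swap, whereas the split design is symmetric only in
distribution.  Filaments with fewer than two subvolumes per sample are
unassigned with p = 1.

## Sarcomere metrics

The myofibril axis defaults to the first principal axis of all local
tangents (second-moment eigenvector, insensitive to tangent sign).
Half-sarcomere arrays are formed by 1D clustering of barbed-end positions
(gap threshold 300 nm) within each polarity class.  A left-pointing array
followed by a right-pointing one is a Z-disk, positioned at the midpoint of
the facing barbed-end clusters; boundary arrays without a partner across
the outermost Z-disks yield one-sided estimates (offset by half the Z-disk
gap, i.e. within half a Z-disk width).  The reverse succession is an
M-line, at the midpoint of the pointed-end overlap interval (the gap
midpoint when the overlap is zero).  The overlap is the maximum pointed-end
interpenetration over opposite-polarity pairs bridging the M-line, clipped
at zero — the per-M-line reduction is not specified by the analyses this
package follows, so the maximum is reported along with the bridging-pair
count; the planted-geometry filament tips are the measurement endpoints.
Overlap fractions use the flanking Z-disk distance and are reported at full
precision (percentages round to integers in displays only).

Helical parameters: rise is the mean axial spacing of consecutive-subunit
poses projected on the filament direction; twist is the signed circular
mean of consecutive in-plane angle differences wrapped to (−180°, 180°].
The repeat is n × rise with n the smallest subunit count (≤ 28) whose
accumulated twist returns within 15° of a full turn; for twist −167.0° that
is the canonical 13-subunit crossover (residual 11°), and a strict argmin
would instead pick n = 28 (residual 4°), which does not correspond to the
crossover repeat the field quotes.  Zero twist gives n = 1, repeat = rise.

The tropomyosin azimuthal shift cross-correlates (azimuth × z)-resolved
intensity profiles on a cylindrical shell at the tropomyosin radius
(4.8 ± 0.8 nm), circularly over azimuth with parabolic sub-bin refinement;
z must stay resolved because averaging over z washes out the helically
twisting strands.  The two-strand 180° ambiguity is resolved by folding the
shift to (−90°, 90°] — the smaller absolute shift.

## Problem sizes and what the tests show

The test and reproduction pipelines run at desk scale: lattices of ~200
thick filaments (14 × 14) for the 45.1 nm recovery and 24 × 24 unit cells
(~256 thin filaments) for the 15.5 nm calibration; 1 nm voxels with 20–24
voxel boxes, 10–30° in-plane grids and two or three alignment rounds; 500
filaments × 20 subvolumes for the type-I simulation.  These sizes make each
pipeline run in seconds to a few tens of seconds while leaving the
estimators' statistical error well inside the tolerances checked.

The synthetic data are straight, rigid filaments with isotropic Gaussian
noise, no contrast transfer function, no dose or tilt effects, and (by
default) no missing wedge; subunits are two-lobe Gaussians, not actin.
Passing tests therefore establish the correctness and calibration of the
estimators and pipelines — planted quantities are recovered at the planted
values, null inputs produce null outputs at the stated rates — not the
attainable accuracy on real tomograms, where filament curvature, crowding,
the missing wedge, and model mismatch all degrade alignment and packing
statistics.  Quantities that depend on the real data (assignment rates,
map resolutions, filament diameters) are out of scope by design.
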