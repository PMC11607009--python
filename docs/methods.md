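# Methods

This note documents the models, conventions and numerical choices behind
fidkit, and what the synthetic phantom does and does not emulate.

## Device model

The device is modelled purely combinatorially: an ordered tuple of wheels
(blue, green, red, yellow — the order is normative for configuration
tuples, CSV columns and CLI output), a stop count per wheel, the angular
step between stops, one arm radius per wheel, and three signed offsets of
the column markers along the mechanical axis. Validity requires
`positions_per_wheel × angular_step = 360°` exactly and strictly positive,
pairwise distinct arm radii — distinctness is what makes wheel identity
recoverable from an unlabelled point cloud. The distinctness check is
deliberately deferred from the constructor to `validate()` and to
classification, so a malformed device can be constructed in order to test
the ambiguity error path.

The mechanical drawings of the arms are not public, so the default radii
(60/75/90/105 mm), column offsets (0/10/20 mm), wheel stack heights
(−10/−18/−26/−34 mm) and home azimuths (20°/110°/225°/315°) are this
package's own synthetic device: radii sized for a large adult head, home
azimuths chosen with no two arms opposite each other (so deleting a column
marker cannot leave an accidentally collinear triple). Configuration
enumeration is the plain Cartesian product in lexicographic order, first
wheel slowest — 10⁴ settings for the default device.

## Axis fit and rotation convention

The rotation axis is fitted to the three column-marker centroids as the
total-least-squares 3D line: pivot = centroid, direction = dominant right
singular vector of the centred points. The PCA sign ambiguity is resolved
by requiring the largest-magnitude component of the direction to be
positive; this rule is normative because the rotation sense is defined
relative to the direction vector. The fit residual is the RMS
perpendicular distance, computed from the explicit perpendicular component
(no cancellation for exactly collinear input).

Rotations about the axis use the Rodrigues axis-angle form; positive
angles follow the right-hand rule about the direction vector, i.e. the
motion appears clockwise when sighting along it. The canonical case is
locked by a unit test: +z axis, +90° maps (1, 0, 0) → (0, 1, 0). A fully
expanded scalar form of the same affine map (direction `(i,j,k)`, pivot
`(p,q,r)`) is retained as an independent code path and asserted equal to
the Rodrigues path, guarding against transcription slips in the long
formula. Candidate stop `k` is the home point rotated by `(k−1)·36°`; stop
1 is the home point bit-exactly. A home point within 1 µm of the axis is
rejected (degenerate orbit).

## Registration and the error chain

The rigid fit is the closed-form SVD (Kabsch/Arun) solution with the
determinant correction that forbids reflections; inputs with a rank-
deficient (collinear) configuration raise rather than silently reflecting.
FRE is the RMS residual over fiducials after alignment (RMS, not mean
distance — all error quantities in the package are RMS, in mm).

FLE is estimated from repeated FREs by `FLE² = N/(N−2)·μ`, the exact
inversion of `⟨FRE²⟩ = (1 − 2/N)·FLE²` for isotropic, independent,
zero-mean localization noise. μ is taken as the mean of squared
*per-repeat RMS FREs* (the alternative reading — mean over per-fiducial
residuals — is numerically identical in expectation; the per-repeat
convention matches how repeated registrations are actually logged).

Expected TRE uses the standard first-order analytic model

    TRE²(r) = FLE²/N · (1 + ⅓ Σₖ dₖ²/fₖ²)

with principal axes and spreads taken from the eigendecomposition of the
fiducial scatter matrix; `fₖ²` is the mean squared fiducial distance to
axis `k` (sum of the other two eigenvalues). A configuration is rejected
as degenerate when the smallest `fₖ` is below 10⁻⁶ of the largest. The
model's assumptions — small, isotropic, independent FLE — are exactly the
phantom's noise model, which is why the shipped Monte-Carlo estimator
(isotropic perturbation → rigid fit → target displacement, vectorized over
trials with batched 3×3 SVDs) agrees with it to well under a percent at
realistic geometry; the Monte-Carlo path is first-class so users can
cross-check any configuration where they doubt the first-order model.

## Configuration search

The search is exhaustive and fully vectorized: all `10⁴` fiducial stacks
are formed by fancy indexing, their scatter eigendecompositions batched,
and the analytic TRE evaluated for every target at once (well under a
second on one core). Multiple targets are reduced by worst-case `max` by
default (`mean` available) — the conservative choice when one setting must
serve several targets. Near-collinear configurations are skipped with a
count rather than aborting (the physical device cannot produce them, but
synthetic geometries can). Ties are broken deterministically: smallest
TRE, then smallest centroid-to-target distance, then lexicographically
smallest index tuple; the result is therefore independent of evaluation
order.

## Localization and classification

Detection thresholds the volume (Otsu by default, overridable), labels
26-connected components, and filters by size (component volume within
0.5–2× the nominal 4 mm sphere volume) and by sphericity (component volume
over the volume of the bounding sphere of the maximum Feret diameter,
floor 0.35). Centroids are intensity-weighted with weights `I − threshold`,
which is symmetric for a shaded sphere and gives sub-voxel accuracy; on
noiseless rendered volumes the observed error is ~0.02 mm at 0.5 mm
voxels, far inside the half-voxel contract. The threshold and shape
parameters are declared defaults, not inferred from any reference system.

Classification scans all 3-subsets for the minimal collinearity residual
(RMS perpendicular distance; tolerance 0.3 mm ≈ half a voxel of a typical
cranial CT), fits a provisional axis, and assigns wheels to the remaining
points by minimum-cost bipartite matching on `|distance-to-axis − arm
radius|` — matching, not greedy assignment, so the result is independent
of input order (the input is also canonically sorted, making the whole
routine permutation-invariant). A matched cost above 5 mm fails
classification; if swapping any two wheel assignments changes the total
cost by less than 0.5 mm the radii do not discriminate the wheels and an
ambiguity error is raised. Leftover points become target candidates.

Physical coordinates are LPS mm throughout (DICOM patient convention);
NIfTI input is converted from RAS by SimpleITK on read.

## Synthetic phantom

The phantom emulates a cranial CT of the device: 4 mm marker spheres and
2 mm screw-head targets rendered with partial-volume shading (linear
intensity ramp one voxel wide) at the printed protocol spacing
0.488 × 0.488 × 0.6 mm by default, plus optional Gaussian intensity noise.
Tracking sessions apply a uniformly random rigid patient pose and add
isotropic Gaussian localization noise, default 0.4 mm RMS total
(per-axis σ = FLE/√3) — a realistic electromagnetic-tracker noise scale —
independently per fiducial and per repeat; probe noise on targets defaults
to 0. Every draw derives from a seed; identical seeds give bitwise
identical sessions.

What the phantom does *not* emulate: CT physics (beam hardening, metal
artefacts, reconstruction kernels), anatomical background intensity,
tracker field distortion, or anisotropic/heteroscedastic localization
noise. Passing tests therefore demonstrate correctness of the geometry,
search and error calculus under the isotropic model — not robustness to
real-scanner artefacts. The twelve-target demonstration scene spreads
targets over near-axis deep and peripheral superficial sites so that the
achievable centroid-to-target distance varies several-fold; its error
numbers are synthetic and demonstrate the workflow and the
accuracy-vs-distance trend only.

## Problem sizes and tolerances

Default analysis sizes, chosen to make sampling error a small fraction of
each tolerance: 200 point sets for noiseless rigid-fit recovery (10⁻⁹
contract); 10⁴ session repeats for the FRE/FLE law (estimator SE ≈ 0.6%,
checked at 5%); 5 × 10⁴ Monte-Carlo trials per configuration for TRE
validation (RMS SE ≈ 0.3%, checked at 3%); 500 repeats per target for the
twelve-target trend. The rendered test volume uses a compact device
(radii 20–38 mm, 192 × 192 × 128 voxels at 0.5 mm) so that volume tests
run in seconds; the full-size device at CT spacing is exercised once as a
smoke test.

## Known limitations

* The analytic TRE model is first-order in FLE; at FLE comparable to the
  fiducial spread it underestimates. The Monte-Carlo path is the fallback.
* FLE estimation from FREs inherits the isotropy/independence assumption;
  correlated tracker error (field distortion) will bias it.
* Wheel classification relies on distinct arm radii; devices with radii
  closer than the ambiguity margin (0.5 mm) cannot be auto-labelled.
* Marker detection assumes bright spheres on a darker background and will
  not segment markers touching comparably bright structures.
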