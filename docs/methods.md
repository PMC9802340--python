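# Methods

This note records the models, numerical choices, and limitations behind
`biofilm_mech`, in the order the pipeline runs.

## Synthetic data generator

The raw microscopy this kind of analysis is normally applied to (bright-field
colony time lapses; fluorescence time lapses of tracer beads in the gel) is
not publicly deposited, so the generator renders both channels from a
prescribed forward model and hands the model itself back as ground truth.
Nothing is re-estimated: recovery tests compare analysis output against the
functions used to draw the pixels.

**Colony channel.**  The front is r(θ, t) = R(t) + A·cos(kθ) with
R(t) = R₀ + ∫v dt.  The roughness is a fixed low-order Fourier mode rather
than a stochastic perturbation so that the true radius is well defined per
frame.  Pixels ramp linearly from interior to exterior intensity across one
pixel of signed distance to the front, so the mid-level isocontour of the
rendered image lies exactly on r(θ); Gaussian grayscale noise is added per
frame from the scenario seed.  Frames are 16-bit, the common microscopy
container.  Defaults: 512×512 px at 2 µm/px (a 4x-objective scale; the
acquisition optics are not part of the model and the value is a documented
choice, roughly a 1 mm field of view), 10-min frame interval, initial radius
300 µm, front speed 5 µm/min = 0.30 mm/h (the saturation scale of expansion
on stiff polyacrylamide), roughness 5 µm at wavenumber 8, noise 800 counts
(≈4% of the 2×10⁴-count contrast).

**Bead channel.**  Beads of diameter 4.8 µm (the tracer size used in such
gels) at density 0.015 µm⁻² are placed uniformly at seeded rest positions
and advected by the displacement model: frame t renders each bead at
x₀ + u(x₀, t).  Spots are Gaussians whose σ combines the optical PSF with
the bead footprint (σ ≈ d/4), integrated analytically over each pixel
(separable erf differences — the exact limit of supersampled rendering), so
subpixel positions are exactly meaningful; this is what makes subpixel PIV
testable.  Default pixel size is 1.6 µm/px (typical of a 4x objective with a
6.5 µm camera pixel), giving ≈3 px particle images — the size class at which
correlation peaks are sharp enough for accurate subpixel interpolation.
Default density gives ≈39 beads per 32-px window (a validator enforces ≥10).
Beads are pure tracers: they move with the surface, never appear or
disappear, and are clipped (but flagged in the ground truth) if displaced
out of frame.  A `periodic` option renders on a torus for shift-invariance
oracles.

**Displacement model.**  u(x, t) is a sum of
* contractile creep toward a center c, u = −t·A·(x−c)/L·exp(½ − r²/2L²),
  zero at the center, peak magnitude t·A at r = L, accumulating linearly in
  time (the slow inward bead drift seen under growing colonies);
* transient Gaussian hot spots (default direction: radially outward from
  the contractile center), active for a frame window, emulating the ~20 µm
  localized pulses near expanding edges;
* an optional edge-locked radial annulus u_r = B·exp(−(r−R_t)²/2w²) whose
  divergence is a ring travelling with the prescribed front radii R_t — the
  synthetic source for divergence-wave analysis.  A constructor calibrates
  B so the analytic peak of |∂u_r/∂r + u_r/r| equals a prescribed value
  (0.015 in the acceptance suite, the unitless scale such waves show over a
  short displacement window);
* rigid stage drift, t·d per frame.

Frame 0 is the rest configuration (u ≡ 0) by definition; displacements are
relative to it, matching the accumulated-PIV convention.  The model is
deterministic and superposable, and both properties are tested.

What the generator does *not* emulate: bead defocus and z-motion (the
tracers are treated as staying in focus; axial displacement is out of
scope), colony biology (the front law is prescribed, not emergent),
intensity drift/photobleaching, and gel viscoelasticity.  Passing tests
therefore demonstrate correctness of the measurement chain under the stated
image-formation model, not robustness to every artifact of real microscopy.

## Front tracking

Manual supervision of boundary detection is replaced by a deterministic
chain: Gaussian denoise (σ = 1 px) → Otsu threshold → polarity selection
(`interior="auto"` picks the phase whose largest connected component
touches the image border least — the inoculum is central; `"dark"`/
`"bright"` override it) → largest component, morphological closing
(radius 2), hole filling → subpixel contour at the threshold level
(marching squares on the intensity image, not on the binary mask, which is
what achieves < 1 px accuracy) → contour selection by proximity to the mask
edge, or to the previous frame's boundary when one is supplied (the
"prior-snap" stand-in for supervised tracking).  A frame with no contrast
or no component above 64 px raises a "no colony detected" error rather than
returning a guess.

Circle fits seed a Kåsa algebraic solution (exact on noiseless data, stable
on short arcs) and refine it by Levenberg–Marquardt on the orthogonal radial
misfit; the reported residual is the RMS radial misfit.  Collinear input is
rejected via the smallest singular value of the centred cloud.

Radial velocity between consecutive arcs casts n rays (default 50) from the
*earlier* arc's center across the angular range both arcs cover, measures
the earlier-circle→later-circle distance along each ray, and averages;
rays that miss the later arc's circle or angular span are excluded, and an
all-excluded pair is an error.  Anchoring rays at the earlier center is a
documented convention choice (any fixed anchor agrees to first order when
consecutive arc centers nearly coincide).  Velocities are computed on a
20-min increment grid, stamped at the interval midpoint (unbiased for
linear growth), in 4 equal angular sectors; the colony summary is the
across-window mean ± SEM.  Windows that fail detection or fitting are
dropped with a warning; fewer than 2 surviving windows is an error.

## PIV

Each 32-px interrogation window (50% overlap) is matched against a search
region extending ws/2 px beyond it using `skimage`'s normalized
cross-correlation.  Vector validation: windows with standard deviation
below 10⁻³ of the frame contrast are featureless; a normalized peak below
0.5 means no credible match (genuine matches score ≳0.9 under the default
noise, spurious peaks on random bead fields ≈0.2–0.35 — this also catches
content that left the field of view); and the peak-to-second-peak ratio
must exceed 1.5.  Masked vectors are NaN, never fabricated.

Subpixel estimation uses a second interrogation pass: the current-frame
window is re-extracted offset by the integer displacement (cropped to the
common support at frame edges, iterated up to 3 times until the integer
correction converges), and the matched windows are correlated with
zero-padded full correlation normalized by the per-lag overlap count.  For
content-matched windows this correlation is exactly symmetric about its
peak, so the three-point Gaussian interpolation (log-parabola, with a
plain-parabola fallback for non-positive samples) is unbiased — integer
shifts are recovered to machine precision, and rendered subpixel
displacements to ≈0.04 px RMS.  A single-pass scheme was measurably worse
(0.1–0.5 px errors from the asymmetric sample correlation of random bead
patterns), which is why the offset pass exists.

Accumulated mode correlates frame t directly against frame 0 — it is a
direct measurement, never a sum of instantaneous fields.  Frames whose
median vector quality drops below 1.2 are flagged as decorrelated.

Drift correction subtracts the single mean vector of the valid vectors
inside a user-specified stress-free rectangle (the minimal deterministic
reading of subtracting the stress-free region's field); the subtracted
vector is recorded in the field metadata.  At least 4 valid vectors are
required.  Note the region must genuinely be beyond the colony's
displacement field: if a long-range contractile tail reaches it, that tail
is (correctly) treated as drift and removed.

Divergence is ∂u_x/∂x + ∂u_y/∂y by central differences on interior nodes
and one-sided differences at edges; edge nodes and nodes adjacent to masked
vectors are flagged as boundary nodes.  Masked vectors are filled by linear
(then nearest) interpolation before differencing.  The wave profile
azimuthally averages divergence in radial bins (default width: one grid
spacing) of signed distance to the colony edge |x − c| − R and reports the
per-frame peak bin; bins with fewer than 4 nodes are ignored for peaking.
At 5 µm grid spacing a 15 µm-wide annulus of peak 0.015 is recovered to
4–7% (second-order finite-difference attenuation plus binning).

## Traction reconstruction

The gel is a linear elastic half-space: thickness (0.8–1 mm) exceeds the
µm-scale displacements and the grid spacing by orders of magnitude, so a
spectral Green-tensor formulation replaces volumetric finite elements; the
forward operator then doubles as the independent oracle for inverse tests.
Tractions are tangential (the standard working assumption of this
measurement); ν defaults to 0.5 (incompressible hydrogel, config-exposed),
E = 2G′(1+ν) where needed.  G′′ is carried as metadata only.

Forward and inverse both act per wavevector.  The default convolution is
unpadded (periodic — the standard Fourier traction cytometry convention),
which makes forward/inverse exact inverses on the grid; `pad_factor > 1`
zero-pads for isolated-patch simulation (used by the 1/r far-field decay
test).  The k = 0 mode is excluded: a net in-plane force has no bounded
half-space solution, so tractions are force-balanced and displacement
fields are treated as mean-free (drift correction already enforces this).
Round-trip statements therefore apply to force-balanced tractions.

Tikhonov weight λ is specified relative to the squared operator norm
(Gershgorin bound over wavevectors), making values comparable across grids
and moduli.  `reg="auto"` minimizes the generalized cross-validation score
GCV(λ) = ‖residual‖² / (Σᵢ λ/(sᵢ² + λ))², computed in closed form from the
per-wavevector eigenvalues sᵢ of the Green tensor, over 33 log-spaced
values in [10⁻⁸, 1].  GCV was chosen over the L-curve corner after the
corner proved unstable on these gradual trade-off curves (selected weights
wandered over four decades between noise realizations); the L-curve
selector is retained as `reg="lcurve"`, with near-stationary points of the
curve excluded from the curvature search.  At the acceptance noise level
(0.1 px displacement noise) GCV recovers a Gaussian patch amplitude within
7–11% across seeds.

An optional finite-thickness damping factor 1 − (1 + 2kh)e^(−2kh)
(h = gel thickness) interpolates between the rigid-base limit (no response
at wavelengths ≫ h) and the half-space (kh ≫ 1); it is off by default and
is an approximation, not an exact bonded-layer solution.

Stress summaries report quartiles, whiskers (`"minmax"` by default;
`"tukey"` 1.5·IQR clipped to the data range as the alternative — box-plot
whisker conventions differ between publications, so it is config-exposed),
mean, and count of |τ| over the analysis region per timepoint.  Strain is
the identity ε = τ/G′, exposed for any τ (scalar, array, or field) since
which statistic of the stress map to convert is a caller's choice.

## Pipeline

A `PipelineConfig` (YAML) fully determines a run: synth (optional) → track
→ piv → tfm → figures.  Every tunable that affects a number in an output
file lives in the config, which is serialized next to the outputs; the
manifest records SHA-256 checksums of all numeric outputs (CSV/TIFF/HDF5/
JSON/YAML).  HDF5 sidecars are written with `track_times=False` and TIFFs
without timestamps, so identically configured runs are byte-identical —
verified by test.  Figures (PNG) are rendered from the CSVs and deliberately
excluded from checksumming: raster encoding is not part of the numeric
contract.  Validation errors (missing inputs, TFM without a modulus) abort
before any computation, and stage failures abort with the stage name.

## Problem sizes

The test and acceptance suites run on 512² colony frames (5 frames), 256²
bead frames (2–4 frames), 64² traction grids, and 102² divergence grids —
sizes at which every stage's error is dominated by the method, not the
discretization, while a full suite completes in well under a minute of
compute per module.

## Known limitations

* Boundary detection assumes a single dominant colony with two intensity
  phases; merging colonies, internal structure steeper than the closing
  radius, or fronts touching the frame edge degrade it.
* PIV assumes displacements ≤ half a window and locally uniform motion per
  window; strong in-window gradients (hot spots much smaller than the
  window) are low-pass filtered.
* The elastic model is isotropic, homogeneous, and purely elastic —
  viscoelastic substrates (agar-like) are out of scope, as are normal
  tractions and axial displacements.
* The divergence wave analysis assumes a roughly circular front (signed
  distance is computed from the fitted arc).
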