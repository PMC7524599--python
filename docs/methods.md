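# Methods

This note records the model assumptions, parameter choices and numerical
decisions behind `swmpam`, in the spirit of a model-description appendix.
Nothing here states an empirical result that the test-suite or
`scripts/acceptance.py` does not itself compute.

## Conventions

Volumes are indexed `(fast, slow, time)`; lateral images are
`(row = slow, col = fast)`; all coordinates are 0-based. Depth is mapped
from the time axis by one-way propagation, `z_k = k * c / f_s` with sound
speed `c` (default 1540 m/s, soft tissue — the hardware description leaves
it unstated) and sampling rate `f_s` (default 50 MHz). The canonical
on-disk amplitude type is float32; TIFF pages are time slices.

## Forward model

The simulator composes, in order: source noise `N1`, the optical
point-spread kernel `K_laser`, the location mapping `M_map`, sensor noise
`N2`, and a per-A-line constant baseline offset.

**Scan map.** The functional form of the MEMS velocity nonlinearity is not
published; we use a smooth slowdown concentrated at the B-scan turning
points, `v(s) = 1 - a * b(s)` with `b` a pair of Gaussian bumps (width 12 %
of the sweep). The electrothermal profile is asymmetric (bump weights
0.6/1.0 — the end of the sweep is worse), the electrostatic profile mild
and symmetric (0.35/0.35, width 10 %). `a` is the `nonlinearity` parameter
in [0, 1); the location map is the cumulative trapezoidal integral of `v`,
rescaled to fix the endpoints, hence strictly monotone and invertible for
every `a < 1`. `nonlinearity = 0` gives the exact identity.

**Point-spread kernel.** Separable. Lateral: Gaussian with FWHM equal to
the Airy-disk diameter expressed in pixels per axis (12.5 um -> 3.1 px
fast, 2.1 px slow at 4/6 um steps), normalized to unit sum. Axial: by
default the derivative of a Gaussian (sigma = 1 sample) — a point absorber
launches a bipolar, N-shaped pressure transient, and the back-projection
formula differentiates the measured pressure, so a unipolar axial profile
would put a null at the true source depth. The bipolar kernel sums to zero
by antisymmetry and is normalized to unit L1; the unit-sum ("energy
preserving") convention applies to the lateral blur. Unipolar (`gaussian`)
and identity (`delta`) axial profiles are available for controlled tests.

**Noise.** `N1`, `N2` are white Gaussian; baseline offsets are drawn per
A-line from `N(mean, std)` (the hardware exhibits per-A-line offsets but no
distribution is published). Benchmark defaults: `sigma1 = 0.02`,
`sigma2 = 0.01`, baseline `N(0.05, 0.02)` on unit-amplitude phantoms —
a few percent of peak, i.e. a clean but not noiseless acquisition. All
randomness flows through one integer seed.

**Phantoms.** The grid chart places lines at `pitch` spacing starting half
a pitch from the border; every crossing's sub-pixel centre is recorded as
ground truth. The vessel phantom grows smooth lateral random walks with
slowly drifting depth confined to the middle of the time axis (clear of
the leading baseline window), tube radius 1-2 px, amplitude 0.6-1.0;
nonzero fraction stays below 10 %.

## Layer 1 — baseline and denoising

The baseline offset of an A-line is the mean over an inclusive sample
window `[n_st, n_nd]`; we divide by the sample count (not the index
difference), which makes the correction exactly cancel constant offsets
and renders it idempotent. The window defaults to the first 10 % of
samples (the pre-signal region; its location is a configuration choice).

The adaptive Wiener filter is the classic Lee estimator
`out = mu + max(var - nu, 0) / max(var, nu) * (in - mu)` on 3x3 windows.
The noise power `nu` defaults to the **median** of the slice's local
variances rather than the textbook mean: the median of a mostly-flat slice
is zero, so noise-free piecewise-constant images pass through unchanged
(the contract the pipeline relies on), while on noisy data median and mean
agree to a few percent. `local_psnr_map` keeps the mean-of-variances
convention. Windows whose variance is exactly zero pass the centre pixel
through untouched, which also absorbs float residue of the box filters.

## Layer 2 — segmentation, corners, registration

**Intensity model.** A two-component equal-variance 1-D Gaussian mixture is
fitted by EM, deterministically initialized at the 25th/75th intensity
percentiles; the threshold is the equal-posterior crossing.

**MRF labelling.** The per-pixel objective switches between a data term
`|L_p - I_p|` and an 8-neighbourhood smoothness term
`mean_nb |L_p - I_nb|` (border neighbourhoods truncated with renormalized
weights). The observed image is rescaled so the mixture threshold maps to
1/2, which makes the pure-data-term limit coincide exactly with plain
thresholding. With the switch chosen per pixel the objective decouples
across pixels; the annealed Metropolis sweeps (T0 = 0.1 x initial energy
per pixel, decay 0.9, 20 sweeps, seeded) are retained as the optimization
procedure, and a final zero-temperature sweep lands on the exact minimizer,
so the final energy never exceeds the initial one. Energy ties are broken
toward the smoothness branch: that is the step that deletes isolated
impulse pixels and is why the labelling beats plain thresholding under
salt-and-pepper noise. A global-switch reading of the objective is possible
but would reduce to a conventional coupled MRF; the per-pixel reading keeps
the thresholding limit exact.

**Corners.** Harris-Stephens (`k = 0.04`, structure-tensor sigma 1.5 px —
standard values) on the binary mask. A crossing of two finite-width lines
produces a ring of response maxima around the true junction, so maxima
within 5 px are merged into their response-weighted centroid and recentred
on the thresholded response moments. Each candidate is then refined by an
iterated intensity centroid on the grayscale chart with a triangular taper
centred on the fractional estimate (window radius 5 px < half the pitch):
for a symmetric blurred cross this iteration contracts geometrically to
the true junction, making localization robust to mask defects and to the
optical blur. Adaptive non-maximal suppression (radius = distance to the
nearest strictly stronger point) spreads the detections; a point is finally
verified only if both the fast-axis and slow-axis Sobel edge maps
(binarized at 25 % of max) fire within 2 px.

**Matching and fitting.** Mutual nearest neighbours under a Euclidean
cutoff (default: half the median nearest-neighbour spacing of the
reference corners). Transform families: projective (>= 4 pairs),
polynomial degree 2/3 (>= 6/10), and MATLAB-style local weighted mean
(>= 12; degree-2 fits over each control point's 12 neighbours, blended
with the cubic weight `1 - 3r^2 + 2r^3`; an approximating, not
interpolating, scheme). `auto` picks polynomial-3 when 10+ pairs exist —
the scan distortion is smooth but not projective — else projective. Both
mapping directions are fitted; warping uses inverse-mapping resampling
(bilinear default, zero outside the domain, with sub-millipixel snapping
at the borders so a near-identity fit does not drop edge pixels). A
fold-over check (numerical Jacobian positive over the control-point
domain) rejects degenerate fits.

**Acceptance loop.** Registration is accepted when the NMI between the
warped chart and the reference reaches `epsilon = 0.48`, evaluated on
two-level histograms (the binary-histogram convention; a flag selects
grayscale). If the automatic fit falls short, manually supplied pairs
(CSV, not interactive) are folded in for one refit; persistent failure
raises an error carrying the diagnostics.

## Layer 3 — delay-and-sum deconvolution

For each voxel the wavefront set contains the lateral neighbours within
the region's top disk whose A-line has a sample at the same source-sensor
distance as the voxel (fractional index solved in closed form from the
geometry and refined on the sample grid by linear interpolation). The
contribution of each member is `|dp/dd| cos(theta) / d`, with the
derivative taken along the A-line by finite differences against the
(non-uniform) distance grid; amplitudes are summed non-coherently, and the
directional coefficient of the single-source formula is absorbed into the
weights.

The deconvolution region is a cylinder: top face = enlarged Airy disk
(enlargement 1.5, a thermal-spread margin; radius in fast-axis pixels) and
height 1.05 mm, centred axially on the voxel and truncated at borders.
The weight of each lateral offset is the mean amplitude of that offset's
A-line over the region's axial window; weights are normalized to sum to
one per voxel, and the delay-and-sum multiplies the weighted sum by the
region's mean amplitude (the magnitude the normalization removed). This
keeps the output proportional to signal strength squared, which is what
"enhance an already strong source, weaken a weak one in the same region"
means operationally; with purely normalized weights the operator would
instead plateau around bright sources. Weights are recomputed per centre
by default (a global chart-derived matrix is representable but the local
average is better determined). The operator is linear for frozen weights,
and the vectorized implementation is verified against an explicit
triple-loop reference at 1e-10 on small volumes.

The default sensor sits at 8.80 mm from the scan-area centre, 45 degrees
off the depth axis in the fast/depth plane, so `cos(theta)` (angle to the
fast axis) is bounded away from zero over the whole volume; sensor
position is fully configurable.

**Guided filter.** Standard local linear model (`q = a I + b`, box means
over truncated windows computed with integral images), window 3x3, `eps =
1e-3` on [0,1]-normalized guides; the guide of each slice is the
pre-deconvolution amplitude slice. In the limit guide = input, eps -> 0
it returns its input; with a constant guide it is a box filter.

## Pipeline, serialization, benchmark

`apply_swm` runs baseline correction, Wiener denoising, the registration
warp, delay-and-sum and guided filtering in exactly that order and is
bit-deterministic. The SWM is serialized as a single `.npz` holding a JSON
payload (layer settings, transform coefficients, region, geometry,
provenance: config hash, chart id, timestamp); save/load/apply round trips
bit-identically. The interpolation step between layers is precisely the
bilinear resampling inside the warp — no additional resampling is invented,
though isotropic voxel resampling can be added downstream.

The synthetic benchmark (`run_demo`, also behind `swmpam swm demo`) uses a
200 x 200 x 48 volume: a 200 x 200 layer size with 4/6 um steps
(0.8 x 1.2 mm — the layer size is fixed at 200 square and takes precedence
over the nominal 1.20 x 0.80 mm area, which at these steps would be
non-square), electrothermal nonlinearity 0.3, grid pitch 20 px, Airy
12.5 um, the noise defaults above, 48 time samples (~1.5 mm depth; keeps
the full pipeline under ~10 s on one CPU). Registration accuracy is
reported as the mean deviation between the fitted inverse map and the true
one over the interior (a 10 % margin per side — displacement is linear in
the interior and concentrated at the sweep ends). MAP-image NMI against
ground truth uses 256-bin histograms (the image-comparison convention; the
2-bin convention is reserved for the epsilon check, where a mid-range
threshold on a contrast-compressed deconvolution output would be
uninformative), and PSNR is computed between peak-normalized amplitude
volumes.

## What the synthetic data does and does not show

The generator reproduces the *structure* of the degradation — nonlinear
but time-invariant scan maps, separable blur, white noise, constant
baseline offsets, bipolar transients — so passing tests demonstrate that
the three layers invert exactly those effects and compose correctly. It
does not emulate thermal drift (time-varying distortion), the sensor's
electrical impulse response (deliberately replaced by denoising),
speckle/structured noise, depth-dependent PSF changes, or acoustic
propagation (no wave solver: the forward model is the layered composition,
not a PDE). Results on real acquisitions therefore depend on how well a
chart calibration taken under matched conditions represents the
acquisition of interest.

## Known limitations

* The per-pixel-switch MRF cannot fill holes (a label agreeing with its own
  observation always has zero cost); impulse robustness comes from the
  tie-break plus the centroid refinement downstream.
* Polynomial-3 under-fits the distortion within ~1.5 pitch of the B-scan
  turning points; the local-weighted-mean family tracks it closer there at
  the cost of noisier extrapolation outside the control hull.
* The delay-and-sum output scales like amplitude squared; quantitative
  amplitude comparisons should be made before the deconvolution layer or
  after explicit renormalization.
* Registration quality is bounded by chart corner coverage; with sparse or
  badly degraded charts, manual pairs (CSV) are required, mirroring manual
  point selection in practice.
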