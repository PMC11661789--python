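# Methods

## Scope and model

`thonring` estimates the contrast transfer function (CTF) of TEM micrographs
from their power spectra and extends the classical thin-flat-specimen model
with two sample parameters: a tilt plane and a slab thickness.  The
underlying assumptions are those of Thon-ring fitting generally: the
specimen is amorphous enough that its spectrum is smooth apart from the CTF
modulation, the defocus variation across a tilted specimen is planar, and
the thickness modulation is the incoherent average of sin^2(chi) through a
homogeneous slab, which closes to CTF_t = 1/2 (1 - sinc(pi lambda g^2 t)
cos 2chi) with the unnormalized sinc.  Higher-order aberrations, chromatic
envelopes and detector MTF are not modeled; phase-plate data is supported
only insofar as a constant phase shift is carried through chi.

Conventions: defoci, thickness and resolutions in Angstrom; positive defocus
is underfocus; angles in degrees at the API surface; the astigmatism
parameters are canonicalized to defocus_1 >= defocus_2 with the angle in
(-90, 90], which removes the swap/rotate-90 degeneracy.  The tilt axis phi
is counterclockwise from +x in [0, 360); the d > 0 side of the axis (d the
signed perpendicular distance) is further from focus.  This sign convention
is arbitrary but fixed, and is what disambiguates phi from phi + 180.

## Spectrum preparation

Power spectra are tile averages (50% overlap, no taper — overlap halves the
variance at negligible cost and amorphous spectra do not need a window) of
|FFT|^2, reported as amplitudes (sqrt of power).  The smooth background is a
box convolution of half-width box_size/16, subtracted once before fitting
and never applied to the model; the exact width is a config knob since any
box much wider than a ring period works.  1D profiles are binned at 0.5
Fourier pixel.  The equiphase average (EPA) bins each spectrum pixel by the
frequency at which a non-astigmatic CTF at the mean defocus reaches the same
phase chi, inverting the quadratic in g^2 exactly (the Cs branch takes the
root on the rising flank of chi).  For thickness fitting the EPA profile is
mapped to oscillate about 0.5 via a smoothed local min/max envelope, with
the envelope width floored at 10% of its median so the node region (where
the oscillation genuinely vanishes) maps to ~0.5 instead of amplified noise.

## Fitting and scores

All scores are Pearson-type normalized cross-correlations (NCC).  The
baseline fit is an exhaustive 1D defocus scan (default 5000–50000 Å in
100 Å steps; exact ties resolve to the lowest defocus) followed by local
maximization of the 2D-spectrum NCC over (Df1, Df2, alpha).  Local
maximization uses Nelder-Mead simplex with parameter-scaled initial steps
and a best-so-far guard, so the returned score never falls below its
initialization; any local maximizer satisfying that contract would do, and
gradients of the NCC through the interpolated spectra are not worth the
complexity.

The goodness-of-fit curve is a sliding-window NCC whose window spans a fixed
number of model oscillations measured in chi (sin^2 chi has period pi), 3
oscillations by default, widened 1.5x when the thickness model is active so
the node region does not truncate the fit.  The fit resolution is the first
frequency where the curve drops below 0.5 and stays below for 2 consecutive
samples; a single-bin dip is ignored.  Window count, threshold and
persistence are exposed; the defaults are package choices since no canonical
values exist for them.

## Tilt estimation

The micrograph is Fourier-cropped so its Nyquist matches the high-resolution
fit limit, square-cropped, and an initial defocus is fitted to a heavily
binned 128-px spectrum (non-astigmatic scan, then astigmatic refinement).
Local 128-px tile spectra (background-subtracted radial profiles over the
fit band) are then scored against non-astigmatic models at each tile's
predicted local defocus; the coarse scan covers phi in 10-degree and theta
in 5-degree steps up to 70 degrees (generous enough for ±51-degree series
on a 20-degree pre-tilted lamella), followed by simplex refinement of
(theta, phi, Df_avg).

The tilt-corrected spectrum averages power spectra of user-size tiles
(default 512 px) after radially rescaling each by m = sqrt(Df_local/Df_avg)
with bilinear interpolation.  The square root follows from equating ring
positions of sin^2(pi lambda g^2 Df): a ring of the local defocus at g lands
at g sqrt(Df_local/Df_avg) of the average-defocus pattern.  The small
Cs-induced error of a pure radial rescale is accepted.  At theta = 0 the
correction is exactly the plain tile average.

## Thickness estimation

Order of operations when both options are on: tilt first, thickness on the
tilt-corrected spectrum.  The initial thickness reads the thin-model
goodness-of-fit resolution as the first node (t = 1/(lambda g^2)); if the
fit never decayed inside the band there is no node to read and a mid-range
150 nm seeds the search instead.  The brute-force stage scans t in
50–400 nm and defocus within ±200 nm of the prior fit, both in 10-nm steps,
scoring the 0.5-scaled EPA profile (scaled once, not per candidate) against
CTF_t over the thickness band (default 10–3 Å).  The optional 2D refinement
frees (t, Df1, Df2, alpha) — the astigmatism angle, not the amplitude
contrast, which is a fixed microscope constant — against the 2D spectrum.

## Tilt-series geometry

Rotations are built from (theta, phi) as a rotation about the in-plane axis
at angle phi.  The pre-tilt solve uses R0_i = Rtom_i^T R_i; only plane
normals matter, so the stage-axis search back-rotates each image's normal
and minimizes the RMS spread about the mean normal over a 1-degree coarse
grid, a 0.1-degree fine grid, and a final parabolic vertex — a smooth
1-parameter objective that does not warrant joint nonlinear optimization.
Outliers beyond 2.0x the RMSD of the normal deviations are excluded once
(no threshold is canonical; 2 RMSD is a conventional default).  Images with
estimated tilt under 5 degrees are flagged axis-unreliable: near-untilted
planes constrain the axis direction arbitrarily badly.  The pre-tilt angles
come from the mean normal via theta0 = ±acos(z0) (sign of x0) and
phi0 = atan(-x0/y0) in [0, 180].

## Beer-Lambert cross-validation

t = -kappa ln(I/I0); the sign is chosen so thickness is positive for
attenuated intensities, and the line fitted is -ln(I/I0) = t/kappa.  The
robust fit is scikit-learn's RANSAC (seeded, MAD-based residual threshold,
1000 trials) followed by ordinary least squares on the consensus set, which
makes the no-noise case coincide exactly with OLS.  Fits with under 50%
consensus are rejected as meaningless.

## CTF correction

Phase flipping multiplies Fourier coefficients by sign(-sin chi) with the
DC gain forced to +1 (preserving the mean) and sign(0) taken as +1 (making
the operation an exact involution).  The Wiener-like filter is
H = C/(C^2 + N) with N(g) = (1/strength - 1 + 1e-3) exp(falloff g/g_nyq) —
a monotone two-knob noise family chosen to satisfy the required limits:
bounded gain at the CTF zeros, heavier amplitude damping as strength
decreases, increasing high-frequency damping with falloff.  Defaults are
falloff 1.3, strength 0.7.  This family is the package's own construction;
other monotone noise models would serve equally.

## Synthetic data

Every generator forward-models exactly what its consumer estimates.
Micrographs are white Gaussian noise filtered in Fourier space by |CTF|
(thin) or sqrt(CTF_t) (thick — so the resulting power spectrum follows
CTF_t), normalized to unit RMS, plus additive white noise of relative RMS
0.5 — a shot-noise-dominated but ring-preserving level typical of ~30 e/Å^2
exposures once tile-averaged.  Tilted specimens use piecewise-constant
defocus over 64-px blocks, much smaller than the 128-px analysis tiles, so
each tile sees a near-constant local defocus.  The generator reproduces the
spectral statistics Thon-ring fitting relies on but none of the structure of
real images (particles, membranes, crystalline ice, drift envelopes), so
passing recovery tests demonstrate correctness of the estimators under the
model's own assumptions, not robustness to structured backgrounds.

Study conditions used by the test suite and the acceptance script: 1024-px
micrographs at 1.0 Å/px for defocus (5000–40000 Å, ≤10% astigmatism) and
thickness (100–300 nm) recovery; 2048-px at 2.0 Å/px (a ~4100 Å field of
view, typical of counting-mode detectors) for tilt recovery at 10/20/40
degrees, since the tilt signal is the defocus gradient across the physical
field; at 4 µm defocus the fit band stops at 8 Å, standard practice where
ring spacing approaches the spectrum sampling.  A 35-image series from -51
to 51 degrees in 3-degree steps exercises the geometry fit; 500 points with
10% gross outliers and a 5-nm residual exercise the Beer-Lambert fit.
These sizes keep the full suite under a minute per component on one CPU.

## Known limitations

No envelope/MTF modeling (fit resolution on real data will be limited by
envelopes the model ignores); tilt estimation assumes a single plane (bent
lamellae violate this); thickness assumes a homogeneous slab (carbon or
platinum layers bias the node); no pooling of defocus across tilt-series
images; astigmatism is unrestrained; the MRC writer emits mode 2 only.
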