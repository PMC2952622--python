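# Methods

This note documents the models behind `cret`, their assumptions, the
parameters that matter, and the choices made where the design was open.

## Cerenkov emission model

A charged particle of speed `beta = v/c` in a dielectric of refractive
index `n` radiates when `beta * n > 1`. The spectral photon yield per
path length is the Frank–Tamm density

    d2N/(dx dlambda) = 2 pi alpha / lambda^2 * (1 - 1/(beta^2 n^2)),

returned in photons cm⁻¹ nm⁻¹. The kinetic-energy threshold for an
electron, `T = m_e c^2 (1/sqrt(1 - 1/n^2) - 1)`, is 264 keV in water
(n = 1.33). The refractive index defaults to a wavelength-independent
1.33 for water/PBS/soft tissue; a callable `n(lambda)` can be supplied
for dispersive media, in which case the threshold is evaluated at the
smallest index on the working grid (conservative: all path segments below
local threshold contribute zero rather than erroring).

**Beta spectra.** Each beta branch carries an endpoint energy `Q`. Initial
kinetic energies follow the allowed shape
`p * E_tot * (Q - E)^2 * F(Z, E)`, normalized numerically on a 4001-point
grid (unit integral to 1e-6). `F` is the nonrelativistic Fermi function
`2 pi eta / (1 - exp(-2 pi eta))` with `eta = +Z alpha / beta` for
electrons and `-Z alpha / beta` for positrons (low-energy suppression);
`Z` is the daughter atomic number and `coulomb=False` gives the bare
shape. The endpoints shipped (0.635, 0.655, 0.578 MeV) sit well inside
the validity range of all approximations used.

**Slowing-down integration.** Particles lose energy in the
continuous-slowing-down approximation with the Katz–Penfold range–energy
relation `R(E) = 0.412 E^(1.265 - 0.0954 ln E)` g/cm² (electrons in
low-Z media, valid to ~2.5 MeV), divided by the medium density. The
expected per-decay spectrum is a Monte-Carlo average: energies are drawn
by inverse-CDF sampling (seeded, reproducible), and each particle above
threshold accumulates `integral_T_thr^E0 (d2N/dx dlambda)(beta(E)) dR/dE dE`,
precomputed as a cumulative table on a 512-point energy grid and
interpolated at the sampled energies. Branch spectra are weighted by
branch fraction and summed; gamma branches contribute nothing.
Bremsstrahlung and gamma-induced radioluminescence are deliberately out
of model. With the default 20 000 samples the total-yield Monte-Carlo
error is ≪ 1%.

The shipped nuclide table (F-18: 1.83 h, β⁺ 97%, 0.635 MeV; Cu-64:
12.7 h, β⁺ 19% 0.655 MeV + β⁻ 39% 0.578 MeV; Tc-99m: 6.0 h, γ 89%,
0.140 MeV) gives roughly 2.2 (F-18) and 1.0 (Cu-64) Cerenkov photons per
decay over 300–900 nm, and exactly zero for Tc-99m. Absolute spectral
scale is treated as arbitrary throughout: all quantification is
ratio-based, so detector calibration constants cancel.

## Acceptor coupling

Energy transfer to the fluorophore is modeled as purely radiative
(absorption and re-emission); whether a resonance component also operates
is an open experimental question, and radiative transfer is the only
parameter-free choice. The observed spectrum is

    observed(l) = donor(l) * T(l) + phi * A_total * em(l),
    T(l) = 10^(-eps(l) * c * L),
    A_total = integral donor(l) * (1 - T(l)) dl,

with `em` a unit-integral emission profile. Re-emitted light is not
re-absorbed (single pass): the ~250 nm Stokes shift puts the emission
band where the acceptor extinction is negligible. Photon number is
conserved up to the quantum yield.

**Qtracker705 stand-in.** No published extinction curve exists for the
commercial nanoparticle, so the packaged model is parametric:
`eps(l) = eps450 * (450/l)^3` below a 780 nm cutoff and zero above, with
`eps450 = 2.5e6 M^-1 cm^-1` chosen so that 400 nM over 1 cm gives unit
absorbance at 450 nm — a substantial donor trough at cuvette
concentrations, matching the qualitative behavior the method exploits.
Emission is Gaussian at 705 nm with 70 nm FWHM (typical quantum-dot
linewidth), quantum yield 0.7 by default; all four parameters are
constructor arguments. Consequently, simulated CRET magnitudes are
comparable only within this model, never to measured values obtained
with the real nanoparticle and real filter transmissions.

## Image formation

Filters are ideal boxes — open, blue [grid-min, 510), green [500, 570),
red [590, grid-max] nm — because real transmission curves for the
instrument are unpublished. Band integration clips the box to the
spectrum grid with edge interpolation, so blue + [510, 590) gap + red
tile the open filter exactly. Scenes are non-overlapping coordinate-mask
regions, each with a spectrum and a tissue depth; rendering paints the
band flux uniformly over each mask, convolves with a Gaussian PSF
(default sigma 2 px), adds a flat per-pixel background flux, and
Poisson-samples counts over the exposure.

The background flux (default 0.2 photons/s/px, identical across filters)
models the camera dark/readout floor. It is load-bearing for the
gamma-null control: a literally zero scene has zero flux in both spectral
windows and the CRET ratio (a quotient) would be undefined; with the
floor, acceptor and control ratios are both ≈ 1 and CRET ≈ 0, which is
the behavior the null experiment shows.

Hot pixels — isolated outliers from 511 keV annihilation photons striking
the CCD — are injected as a Poisson-count number of pixels (Chebyshev
separation ≥ 2) set to 10–100× the image's 99.5th percentile, with
ground-truth coordinates recorded.

**Tissue attenuation.** `mu(l) = a exp(-(l - 400)/lambda_d) + b` mm⁻¹
with defaults a = 1.0, lambda_d = 120 nm, b = 0.02 — strongly absorbing
in the UV/blue, nearly transparent in the far red, non-increasing in
wavelength. The coefficients are generic soft-tissue-like values (no
measured coefficients exist for the phantom system) and are freely
overridable.

## Quantification

With acceptor window X (red) and donor window Y (blue),

    CRET = X/Y (with fluorophore) - X/Y (Cerenkov alone).

Replicates are aggregated as the difference of the two arms' mean ratios
(the definition is written in terms of aggregate light); the mean of
index-paired per-replicate differences is also emitted. The SEM of the
difference is the root sum of squares of the arm SEMs; a single-replicate
arm contributes no variance term, and with one replicate in both arms the
uncertainty is reported as unavailable rather than zero.

**Hot-pixel repair.** A pixel is flagged when it exceeds its 3×3
neighborhood median (center excluded) by more than k = 6 times the
neighborhood's robust scale, and is replaced by the mean of its
non-flagged neighbors — detection and replacement both read the original
values in a single pass, which makes the operation idempotent. The
robust scale is 1.4826 × MAD floored at (a) 1e-3 × |median| and (b) the
shot-noise scale `sqrt(rate/exposure) + 1/exposure` with the rate taken
as max(median, neighborhood mean). The floors matter: in dim
photon-counting backgrounds the quantized count values drive both the
MAD and the median to exactly zero, and an unfloored MAD rule flags
thousands of ordinary one-count fluctuations. With the floors, the
detector recovers injected hot pixels on the fixture plates exactly, with
zero false positives.

**Ratio and calculated CRET images.** Red images are divided by blue
images pixelwise with an explicit positive floor on the denominator
(default 1e-9 × its maximum); sub-floor pixels are carried as an invalid
mask (NaN) through subsequent operations rather than silently becoming
infinities. The calculated CRET image subtracts the mean valid ratio over
a control ROI (the fluorophore-free phantom) from every valid pixel, so
the control ROI mean is zero by construction. Note the image-domain
readout (mean of pixel ratios) and the flux-domain CRET (ratio of summed
fluxes) are different aggregations — mean-of-ratios vs ratio-of-means —
and agree only approximately; both are computed and reported.

**Statistics.** The t test is classic pooled-variance Student, two-tailed
(Welch by flag); zero pooled variance with equal means returns p = 1 by
contract, with unequal means t = ±inf, p = 0. Trend fits are ordinary
least squares. No multiple-testing correction is applied: the analyses
are single pairwise comparisons.

## Synthetic scenarios

`PlateScenario` lays conditions (concentration × activity cross product)
into columns of a 96-well grid on a 256×384 canvas (binning-8 scale,
circular wells of radius 11 px), triplicate rows by default. The two
canonical plates are the acceptor ladder (0/10/25/50/100/200 nM at
5.6 MBq F-18 per well, 10 s exposure) and the activity titration
(0/0.037/0.37/3.7/37 MBq at 0 and 40 nM, 30 s exposure) — the 0 nM
column doubles as the "Cerenkov alone" control at every dose. Expected
decays during an exposure are activity × exposure (decay within ≤ 60 s
exposures is negligible and ignored); a collection efficiency (default
1e-3) absorbs solid angle and quantum efficiency. Cross-well light spill
arises only from the PSF; no separate spill term is modeled.

`MouseScenario` renders a 256×256 phantom: an elliptical body silhouette
carrying the blood-pool fraction (default 0.70) of the in-field activity
at skin depth (0.5 mm), organ foci (brain/heart/bladder, 0.15 combined)
at 3 mm showing the far-red Cerenkov tail, and two elliptical flank
pseudotumors sharing the remainder. The acceptor flank sees donor light
attenuated over the tumor depth on the way in (excitation), couples it,
and the composite is attenuated again on the way out; the PBS flank is
raw Cerenkov attenuated over twice the depth. Because physical overlap
of the blood pool with the flanks is intrinsic to the scene, the
generator sums per-layer noise-free expected images and applies Poisson
noise once (the renderer's non-overlap contract applies within layers).
In-field activity decays as physical half-life × single-exponential
renal clearance (default half-time 15 min), so later timepoints are
strictly dimmer; the embedded acceptor content is static (the phantoms
are avascular). This geometry is what produces the two headline in-vivo
behaviors: higher acceptor concentration → higher CRET, and any tumor
depth > 0 → strictly lower CRET than the same phantom at depth 0 (blue
excitation and red emission are both lost to tissue while the
superficial blue-rich background persists in the ROI denominators).

Every generated acquisition ships with a noise-free render (quantized to
the float32 precision of the on-disk TIFFs so pipeline output matches
manifest ground truth bit-for-bit), per-well/per-ROI noise-free fluxes,
noise-free CRET ratios, hot-pixel coordinates, and the full scenario
(seeds included) in `manifest.json`.

**What the generator does not emulate:** real filter transmission curves,
camera gain/ADC and flat-field structure, refractive-index dispersion,
depth-resolved photon migration (a single Beer–Lambert slab per region),
pharmacokinetic realism of tracer uptake, or the true nanoparticle
photophysics. Passing tests therefore demonstrate correctness of the
quantification pipeline and the qualitative physics (thresholds, spectral
shape, monotonic trends, null controls), not agreement with any measured
CRET magnitude.

## Numerical choices

- Wavelength grid 300–900 nm at 1 nm; energy grids 512 (yield table) and
  4001 (beta pdf) points; quadrature is trapezoidal throughout.
- All stochastic operations take explicit integer seeds; scenario seeds
  fan out into named substreams (CRC-32 of a stage label mixed into a
  `SeedSequence`), so adding a stage never perturbs another stage's draws.
- Emission-profile unit integral enforced to 1e-6; beta-pdf
  normalization to 1e-6; band-partition additivity holds to 1e-9.
- Degenerate inputs fail loudly: empty ROIs, overlapping scene masks,
  out-of-bounds masks, non-increasing wavelength grids, zero donor-window
  flux, refractive index ≤ 1, negative times/depths.

## Known limitations

- CRET magnitudes depend on the parametric acceptor and box filters;
  only orderings, trends, and null results transfer to real instruments.
- The activity-independence of noise-free plate CRET (ratios cancel
  activity except through the background floor) is a property of the
  ideal model; real systems add dose-dependent detector effects.
- The Fermi function is the nonrelativistic form; adequate for the
  shipped endpoints, increasingly approximate above ~1 MeV.
- The mouse phantom is a flat 2-D scene with per-region effective depths,
  not a light-transport simulation.
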