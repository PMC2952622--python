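# cret

Simulation and quantification of **Cerenkov radiation energy transfer
(CRET)** imaging: optical detection of PET isotopes by coupling their
blue-weighted Cerenkov emission to red-shifted quantum-dot acceptors.

Beta particles from radionuclide decay (e.g. [18F]FDG, 64Cu) that exceed
the Cerenkov threshold in water — 264 keV for an electron at n = 1.33 —
emit a continuous spectrum with intensity ∝ 1/λ². Those UV/blue photons
are strongly absorbed in tissue, but a high-Stokes-shift acceptor such
as a 705 nm quantum dot can absorb them and re-emit in the far red,
where tissue is nearly transparent. The transfer is quantified, in
analogy to BRET/FRET ratios, by the **CRET ratio**

    CRET = (X / Y)_with fluorophore  −  (X / Y)_Cerenkov alone

where X is the photon flux in an acceptor window centered on the
fluorophore emission (>590 nm) and Y the flux in a donor window of the
Cerenkov emission (<510 nm).

The package provides, as a library plus a thin `cret` CLI:

- **physics** — Frank–Tamm spectral density, Cerenkov thresholds,
  allowed-shape beta spectra with Fermi correction, seeded sampling, and
  CSDA slowing-down integration to expected Cerenkov photons per decay
  (F-18, Cu-64, Tc-99m shipped); radioactive decay correction.
- **coupling** — Beer–Lambert radiative transfer to a parametric
  Qtracker705-like acceptor (photon-conserving, single-pass).
- **imaging** — four-filter (open/blue/green/red) CCD image synthesis:
  box filters, Gaussian PSF, Poisson noise, wavelength-dependent tissue
  attenuation, annihilation hot pixels; TIFF + JSON acquisition I/O.
- **quantify** — hot-pixel repair (median + floored-MAD rule), ROI
  fluxes, CRET ratios with SEM, red/blue ratio images, calculated CRET
  images, Student t test, OLS trend fits.
- **synthetic_data** — complete in-silico experiments with ground-truth
  manifests: acceptor concentration ladders, activity titrations, a
  gamma-only null plate, and a two-pseudotumor mouse phantom with
  blood-pool clearance.

## Worked example

`examples/03_plate_quantification.py` simulates the acceptor
concentration ladder (0–200 nM at 5.6 MBq F-18 per well, triplicates,
Poisson noise, hot pixels), repairs hot pixels, and quantifies CRET per
concentration against the 0 nM control wells:

```
hot pixels repaired: 12 (red), 11 (blue)

conc (nM)   CRET ratio        noise-free truth
       10   0.059 +/- 0.003   0.061
       25   0.155 +/- 0.002   0.157
       50   0.333 +/- 0.001   0.330
      100   0.729 +/- 0.004   0.732
      200   1.797 +/- 0.009   1.787

linear fit of CRET vs concentration: y = 0.0092 x + -0.093, R^2 = 0.991
```

Each noisy estimate (mean ± SEM over triplicate wells) sits within a few
SEM of the manifest's noise-free truth, and CRET rises monotonically —
quasi-linearly — with acceptor concentration. The other examples cover
per-decay Cerenkov spectra (`01`), the cuvette concentration series with
its donor trough and 705 nm acceptor peak (`02`), and the in-vivo
phantom with its depth-dependent CRET loss (`04`):

```
depth 0.0 mm -> CRET 1.812
depth 2.0 mm -> CRET 0.331
depth 4.0 mm -> CRET 0.060
```

The same pipeline is scriptable from the shell:

```sh
cret simulate-plate --out plate/
cret quantify --acquisition plate/ --rois plate/rois.json \
     --sample-roi r0c5 --sample-roi r1c5 --sample-roi r2c5 \
     --control-roi r0c0 --control-roi r1c0 --control-roi r2c0 \
     --out results/
cret report results/cret_result.json --out report.json
```

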