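"""Synthetic 96-well plate: simulate, quantify, and fit the CRET trend.

Generates the acceptor concentration ladder (0-200 nM at 5.6 MBq F-18 per
well, triplicate wells, Poisson noise, hot pixels), repairs hot pixels,
sums ROI fluxes behind the red (>590 nm) and blue (<510 nm) filters, and
reports the CRET ratio per concentration with its SEM.
"""

import tempfile
from pathlib import Path

import numpy as np

import cret.io as cio
from cret.imaging import read_acquisition
from cret.quantify import (
    BandFluxPair,
    correct_hot_pixels,
    cret_ratio_replicates,
    linear_fit,
    roi_flux,
)
from cret.synthetic_data import PlateScenario, generate_plate

workdir = Path(tempfile.mkdtemp())
scenario = PlateScenario(seed=42)
path, manifest = generate_plate(scenario, workdir / "plate")

images = read_acquisition(path)
rois = cio.load_rois(path / "rois.json", images["red"].pixels.shape)
red, hot_red = correct_hot_pixels(images["red"])
blue, hot_blue = correct_hot_pixels(images["blue"])
print(f"hot pixels repaired: {hot_red.shape[0]} (red), "
      f"{hot_blue.shape[0]} (blue)\n")


def pairs(conc):
    return [BandFluxPair(roi_flux(red, rois[w["well_id"]]),
                         roi_flux(blue, rois[w["well_id"]]))
            for w in manifest["wells"] if w["concentration_nm"] == conc]


controls = pairs(0.0)
print("conc (nM)   CRET ratio        noise-free truth")
concs, crets = [], []
for record in sorted(manifest["cret_noise_free"],
                     key=lambda r: r["concentration_nm"]):
    conc = record["concentration_nm"]
    result = cret_ratio_replicates(pairs(conc), controls)
    print(f"{conc:9.0f}   {result.cret_ratio:.3f} +/- {result.uncertainty:.3f}"
          f"   {record['cret_ratio']:.3f}")
    concs.append(conc)
    crets.append(result.cret_ratio)

slope, intercept, r2 = linear_fit(concs, crets)
print(f"\nlinear fit of CRET vs concentration: "
      f"y = {slope:.4f} x + {intercept:.3f}, R^2 = {r2:.3f}")
print("CRET grows monotonically with acceptor concentration; each noisy "
      "estimate sits within\na few SEM of the manifest's noise-free truth.")
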