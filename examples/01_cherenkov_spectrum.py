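"""Cerenkov emission from PET isotopes in water.

Computes the emission threshold for electrons in water and the expected
Cerenkov photon yield per decay for F-18, Cu-64 and Tc-99m, sampling each
beta branch and integrating the Frank-Tamm density along the slowing-down
track.
"""

from cret.physics import (
    cherenkov_photons_per_decay,
    cherenkov_threshold_energy,
    get_nuclide,
    water,
)

medium = water()
threshold_kev = 1000.0 * cherenkov_threshold_energy(medium)
print(f"Cerenkov threshold for an electron in water (n = 1.33): "
      f"{threshold_kev:.1f} keV")
print("  -> only beta particles above this kinetic energy radiate.\n")

for name in ("F-18", "Cu-64", "Tc-99m"):
    nuclide = get_nuclide(name)
    spectrum = cherenkov_photons_per_decay(nuclide, medium,
                                           n_samples=50_000, seed=1)
    total = spectrum.total()
    blue = spectrum.interp(400.0)
    red = spectrum.interp(800.0)
    branches = ", ".join(f"{b.mode} {b.fraction:.0%} {b.energy_mev} MeV"
                         for b in nuclide.branches)
    print(f"{name} ({branches})")
    print(f"  photons per decay, 300-900 nm: {total:.3f}")
    if total > 0:
        print(f"  density at 400 nm vs 800 nm: {blue:.2e} / {red:.2e} "
              f"(ratio {blue / red:.1f}; the 1/lambda^2 blue weighting)")
    else:
        print("  no Cerenkov light: gamma-only decay, no charged particle "
              "above threshold")
    print()
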