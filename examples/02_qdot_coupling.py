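"""Radiative coupling of Cerenkov light to a 705 nm quantum dot.

Reproduces the cuvette-style concentration series: a fixed Cu-64 Cerenkov
donor spectrum observed through increasing concentrations of a
Qtracker705-like acceptor.  The donor band (400-550 nm) is progressively
absorbed while the 705 nm acceptor peak grows.
"""

import numpy as np
from scipy.integrate import trapezoid

from cret.coupling import CouplingGeometry, couple_spectrum, default_qtracker705
from cret.physics import cherenkov_photons_per_decay, get_nuclide, water

donor = cherenkov_photons_per_decay(get_nuclide("Cu-64"), water(),
                                    n_samples=50_000, seed=1)
donor = donor.scaled(70e6)  # 70 MBq worth of decays per second
qdot = default_qtracker705()


def band(spectrum, lo, hi):
    lam = spectrum.wavelengths_nm
    sel = (lam >= lo) & (lam <= hi)
    return trapezoid(spectrum.density[sel], lam[sel])


print("conc (nM)   donor 400-550   acceptor 650-750   peak@705 density")
for conc in (0.0, 49.0, 222.0, 400.0):
    observed = couple_spectrum(donor, qdot, CouplingGeometry.from_nm(conc))
    print(f"{conc:9.0f}   {band(observed, 400, 550):13.3e}   "
          f"{band(observed, 650, 750):16.3e}   "
          f"{observed.interp(705.0):16.3e}")

print("\nThe donor band falls and the acceptor band rises monotonically "
      "with concentration:\nabsorbed blue Cerenkov photons reappear, "
      "quantum-yield-scaled, in the 705 nm emission peak.")
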