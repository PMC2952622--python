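"""In-vivo pseudotumor phantom: ratio images and depth dependence.

Simulates a mouse carrying an acceptor-loaded and a PBS-loaded Matrigel
pseudotumor after a systemic F-18 injection, quantifies the tumor CRET
ratio at 5 and 30 minutes from red/blue ratio images, and shows how
tissue attenuation at depth erodes the CRET contrast.
"""

import tempfile
from pathlib import Path

import cret.io as cio
from cret.imaging import read_acquisition
from cret.quantify import calculated_cret_image, ratio_image, roi_ratio_mean
from cret.synthetic_data import MouseScenario, generate_mouse

workdir = Path(tempfile.mkdtemp())
scenario = MouseScenario(pseudotumor_concentrations_nm=(500.0, 0.0), seed=7)
path, manifest = generate_mouse(scenario, workdir / "mouse")

for tp in manifest["timepoints"]:
    t = tp["timepoint_min"]
    tdir = path / f"t{int(round(t)):03d}min"
    clean = read_acquisition(tdir / "noise_free")
    rois = cio.load_rois(tdir / "rois.json", clean["red"].pixels.shape)
    ratio = ratio_image(clean["red"], clean["blue"])
    calc = calculated_cret_image(ratio, rois["pbs_tumor"])
    print(f"t = {t:.0f} min: in-field activity {tp['activity_mbq']:.2f} MBq")
    print(f"  flux-domain CRET (acceptor ROI ratio - control ROI ratio): "
          f"{tp['cret_ratio']:.3f}")
    print(f"  image-domain CRET (mean of calculated CRET image over "
          f"acceptor ROI): {roi_ratio_mean(calc, rois['qdot_tumor']):.3f}")

print("\ndepth sweep at 500 nM (noise-free):")
for depth in (0.0, 1.0, 2.0, 4.0):
    s = MouseScenario(tumor_depth_mm=depth, poisson_noise=False,
                      hot_pixel_rate=0.0, timepoints_min=[5.0], seed=7)
    _, m = generate_mouse(s, workdir / f"depth_{depth}")
    print(f"  depth {depth:.1f} mm -> CRET {m['timepoints'][0]['cret_ratio']:.3f}")

print("\nDeeper phantoms lose blue excitation and red emission to tissue "
      "absorption while the\nsuperficial blood-pool background persists, so "
      "the CRET contrast falls with depth.")
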