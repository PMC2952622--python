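"""Synthetic CRET experiments with exact ground truth.

Two scenario families mirror the experimental designs the quantification
pipeline was built for:

* 96-well plate acquisitions: a fluorophore concentration ladder at fixed
  activity (0-200 nM Qtracker705-like acceptor with 5.6 MBq of F-18 per
  well) and an activity titration at fixed concentration (0-37 MBq at
  40 nM), imaged through the four-filter set with Poisson noise and
  annihilation hot pixels.
* A two-pseudotumor mouse phantom: acceptor-loaded and PBS-loaded Matrigel
  flanks over a blood-pool Cerenkov background that clears exponentially,
  with wavelength-dependent tissue attenuation and superficial organ foci
  (brain/heart/bladder) carrying the far-red Cerenkov tail.

Every generated acquisition directory is accompanied by a noise-free
render and a JSON manifest holding each intermediate quantity (per-well
band fluxes, red/blue ratios, noise-free CRET ratios, hot-pixel ground
truth), so the quantification pipeline can be validated end to end
without any external data.
"""

from __future__ import annotations

import json
from itertools import product
from pathlib import Path

import numpy as np
from pydantic import BaseModel, ConfigDict, Field

from . import coupling, imaging, physics, quantify

__all__ = [
    "PlateScenario",
    "MouseScenario",
    "generate_plate",
    "generate_mouse",
    "canonical_fixture_suite",
]

MANIFEST_SCHEMA_VERSION = 1


class PlateScenario(BaseModel):
    """Configuration for a synthetic 96-well plate acquisition.

    Conditions are the cross product of ``fluorophore_concentration_nm``
    and ``activity_per_well_mbq``; each condition occupies one plate
    column (wrapping across row blocks), replicates occupy rows.
    """

    model_config = ConfigDict(extra="forbid")

    name: str = "plate"
    nuclide: str = "F-18"
    activity_per_well_mbq: list[float] = Field(default=[5.6])
    fluorophore_concentration_nm: list[float] = Field(
        default=[0.0, 10.0, 25.0, 50.0, 100.0, 200.0])
    replicates: int = 3
    exposure_s: float = 10.0
    pathlength_cm: float = 0.5
    collection_efficiency: float = 1e-3
    quantum_yield: float = 0.7
    psf_sigma: float = 2.0
    background_flux: float = 0.2
    poisson_noise: bool = True
    hot_pixel_rate: float = 10.0
    n_samples: int = 20000
    canvas: tuple[int, int] = (256, 384)
    well_radius_px: float = 11.0
    seed: int = 0

    def model_post_init(self, __context) -> None:
        if any(a < 0 for a in self.activity_per_well_mbq):
            raise ValueError("activities must be non-negative")
        if any(c < 0 for c in self.fluorophore_concentration_nm):
            raise ValueError("concentrations must be non-negative")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")


class MouseScenario(BaseModel):
    """Configuration for the two-pseudotumor mouse phantom."""

    model_config = ConfigDict(extra="forbid")

    name: str = "mouse"
    nuclide: str = "F-18"
    pseudotumor_concentrations_nm: tuple[float, float] = (500.0, 0.0)
    injected_activity_mbq: float = 17.6
    tumor_depth_mm: float = 2.0
    skin_depth_mm: float = 0.5
    organ_depth_mm: float = 3.0
    background_fraction: float = 0.70
    organ_fractions: dict[str, float] = Field(
        default={"brain": 0.04, "heart": 0.04, "bladder": 0.07})
    timepoints_min: list[float] = Field(default=[5.0, 30.0])
    clearance_half_time_min: float = 15.0
    exposure_s: float = 60.0
    pathlength_cm: float = 0.3
    collection_efficiency: float = 1e-3
    quantum_yield: float = 0.7
    psf_sigma: float = 2.0
    background_flux: float = 0.2
    poisson_noise: bool = True
    hot_pixel_rate: float = 5.0
    tissue_a_mm: float = 1.0
    tissue_decay_nm: float = 120.0
    tissue_floor_mm: float = 0.02
    n_samples: int = 20000
    canvas: tuple[int, int] = (256, 256)
    seed: int = 0

    def model_post_init(self, __context) -> None:
        if any(c < 0 for c in self.pseudotumor_concentrations_nm):
            raise ValueError("concentrations must be non-negative")
        if self.injected_activity_mbq <= 0:
            raise ValueError("injected activity must be positive")
        if list(self.timepoints_min) != sorted(self.timepoints_min):
            raise ValueError("timepoints must be increasing")
        total = self.background_fraction + sum(self.organ_fractions.values())
        if not 0.0 < total < 1.0:
            raise ValueError("background + organ fractions must lie in (0, 1)")

    @property
    def flank_fraction(self) -> float:
        return (1.0 - self.background_fraction
                - sum(self.organ_fractions.values())) / 2.0


# ---------------------------------------------------------------------------
# shared helpers


def _donor_per_second(nuclide_name: str, activity_mbq: float,
                      collection_efficiency: float, n_samples: int,
                      seed: int) -> physics.EmissionSpectrum:
    """Detected Cerenkov spectrum (photons/s/nm) for an activity in water."""
    nuclide = physics.get_nuclide(nuclide_name)
    per_decay = physics.cherenkov_photons_per_decay(
        nuclide, physics.water(), n_samples=n_samples, seed=seed)
    return per_decay.scaled(activity_mbq * 1e6 * collection_efficiency)


def _json_dump(path: Path, payload: dict) -> None:
    path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def _noise_free_fluxes(images: dict[str, imaging.FilteredImage],
                       roi: quantify.Roi) -> dict[str, float]:
    return {key: quantify.roi_flux(img, roi) for key, img in images.items()}


# ---------------------------------------------------------------------------
# plate generation


def _plate_layout(scenario: PlateScenario):
    """Assign (concentration, activity, replicate) -> well center coordinates."""
    conditions = list(product(scenario.fluorophore_concentration_nm,
                              scenario.activity_per_well_mbq))
    n_cols, n_rows = 12, 8
    rows_needed = ((len(conditions) - 1) // n_cols + 1) * scenario.replicates
    if rows_needed > n_rows:
        raise ValueError("layout does not accommodate conditions x replicates")
    cell_r = scenario.canvas[0] / n_rows
    cell_c = scenario.canvas[1] / n_cols
    wells = []
    for idx, (conc, act) in enumerate(conditions):
        col = idx % n_cols
        block = idx // n_cols
        for rep in range(scenario.replicates):
            row = block * scenario.replicates + rep
            center = (cell_r * (row + 0.5), cell_c * (col + 0.5))
            wells.append({
                "well_id": f"r{row}c{col}",
                "row": row, "col": col,
                "center": center,
                "concentration_nm": conc,
                "activity_mbq": act,
                "replicate": rep,
            })
    return wells


def generate_plate(scenario: PlateScenario,
                   output_dir: str | Path) -> tuple[Path, dict]:
    """Render a plate acquisition (4 filters), write it with ground truth.

    The output directory contains the (optionally noisy, hot-pixel
    corrupted) acquisition, a ``noise_free/`` acquisition rendered from
    the same scene without noise, ``rois.json`` with one circular ROI per
    well, and ``manifest.json`` with per-well noise-free fluxes and
    noise-free CRET ratios per condition (controls are the 0 nM wells at
    the same activity).
    """
    out = Path(output_dir)
    fluor = coupling.default_qtracker705(quantum_yield=scenario.quantum_yield)
    bands = imaging.filter_set()
    tissue = imaging.no_tissue()
    meta = imaging.AcquisitionMeta(exposure_s=scenario.exposure_s,
                                   binning=8)
    wells = _plate_layout(scenario)

    donor_cache: dict[float, physics.EmissionSpectrum] = {}
    spectra_cache: dict[tuple[float, float], physics.EmissionSpectrum] = {}
    physics_seed = physics._substream_int(scenario.seed, "physics")
    for well in wells:
        act, conc = well["activity_mbq"], well["concentration_nm"]
        if act not in donor_cache:
            donor_cache[act] = _donor_per_second(
                scenario.nuclide, act, scenario.collection_efficiency,
                scenario.n_samples, physics_seed)
        if (conc, act) not in spectra_cache:
            geom = coupling.CouplingGeometry.from_nm(
                conc, pathlength_cm=scenario.pathlength_cm)
            spectra_cache[(conc, act)] = coupling.couple_spectrum(
                donor_cache[act], fluor, geom)

    regions = []
    for well in wells:
        mask = imaging.circle_mask(well["center"], scenario.well_radius_px,
                                   scenario.canvas)
        well["mask"] = mask
        regions.append(imaging.SceneRegion(
            mask=mask,
            spectrum=spectra_cache[(well["concentration_nm"],
                                    well["activity_mbq"])],
            depth_mm=0.0))

    clean_images, noisy_images = {}, {}
    hot_truth: dict[str, list] = {}
    for key, band in bands.items():
        expected = imaging.expected_image(
            regions, band, tissue, scenario.psf_sigma, scenario.canvas,
            scenario.background_flux)
        # quantize to the float32 precision of the on-disk TIFFs so manifest
        # ground truth matches what the pipeline reads back, bit for bit
        expected = expected.astype(np.float32).astype(np.float64)
        clean_images[key] = imaging.FilteredImage(expected, band, meta)
        if scenario.poisson_noise:
            img = imaging.render_image(
                regions, band, tissue, meta, scenario.psf_sigma,
                physics._substream_int(scenario.seed, f"noise:{key}"),
                shape=scenario.canvas,
                background_flux=scenario.background_flux, noise=True)
        else:
            img = imaging.FilteredImage(expected.copy(), band, meta)
        img, coords = imaging.inject_hot_pixels(
            img, scenario.hot_pixel_rate,
            seed=physics._substream_int(scenario.seed, f"hot:{key}"))
        noisy_images[key] = img
        hot_truth[key] = coords.tolist()

    # ground-truth quantification on the noise-free render
    for well in wells:
        roi = quantify.Roi(well["well_id"], well["mask"])
        well["fluxes_noise_free"] = _noise_free_fluxes(clean_images, roi)

    controls_by_activity: dict[float, list[dict]] = {}
    for well in wells:
        if well["concentration_nm"] == 0.0:
            controls_by_activity.setdefault(well["activity_mbq"], []).append(well)

    cret_records = []
    for conc, act in sorted({(w["concentration_nm"], w["activity_mbq"])
                             for w in wells}):
        controls = controls_by_activity.get(act, [])
        if conc == 0.0 or not controls:
            continue
        sample_pairs = [
            quantify.BandFluxPair(w["fluxes_noise_free"]["red"],
                                  w["fluxes_noise_free"]["blue"])
            for w in wells
            if w["concentration_nm"] == conc and w["activity_mbq"] == act
        ]
        control_pairs = [
            quantify.BandFluxPair(w["fluxes_noise_free"]["red"],
                                  w["fluxes_noise_free"]["blue"])
            for w in controls
        ]
        result = quantify.cret_ratio_replicates(sample_pairs, control_pairs)
        cret_records.append({
            "concentration_nm": conc,
            "activity_mbq": act,
            "sample_ratio": result.sample_ratio,
            "control_ratio": result.control_ratio,
            "cret_ratio": result.cret_ratio,
        })

    extra = {"scenario": json.loads(scenario.model_dump_json()),
             "seed": scenario.seed, "kind": "plate"}
    imaging.write_acquisition(out, noisy_images, extra_meta=extra)
    imaging.write_acquisition(out / "noise_free", clean_images, extra_meta=extra)

    rois = {w["well_id"]: {"circle": [w["center"][0], w["center"][1],
                                      scenario.well_radius_px]}
            for w in wells}
    _json_dump(out / "rois.json", rois)

    manifest = {
        "schema_version": MANIFEST_SCHEMA_VERSION,
        "kind": "plate",
        "scenario": json.loads(scenario.model_dump_json()),
        "wells": [{k: v for k, v in w.items() if k not in ("mask", "center")}
                  | {"center": list(w["center"])} for w in wells],
        "cret_noise_free": cret_records,
        "hot_pixels": hot_truth,
        "spectral_band_flux": {
            f"c{conc:g}_a{act:g}": {
                key: imaging.integrate_band(spec, band)
                for key, band in bands.items()}
            for (conc, act), spec in sorted(spectra_cache.items())
        },
    }
    _json_dump(out / "manifest.json", manifest)
    return out, manifest


# ---------------------------------------------------------------------------
# mouse generation


def _mouse_geometry(scenario: MouseScenario):
    shape = scenario.canvas
    cy = shape[1] / 2.0
    body = imaging.ellipse_mask((shape[0] * 0.52, cy),
                                (shape[0] * 0.42, shape[1] * 0.22), shape)
    flank_q = imaging.ellipse_mask((shape[0] * 0.64, cy - shape[1] * 0.17),
                                   (16.0, 11.0), shape)
    flank_p = imaging.ellipse_mask((shape[0] * 0.64, cy + shape[1] * 0.17),
                                   (16.0, 11.0), shape)
    organs = {
        "brain": imaging.circle_mask((shape[0] * 0.18, cy), 7.0, shape),
        "heart": imaging.circle_mask((shape[0] * 0.38, cy), 8.0, shape),
        "bladder": imaging.circle_mask((shape[0] * 0.80, cy), 7.0, shape),
    }
    return body, flank_q, flank_p, organs


def _mouse_activity(scenario: MouseScenario, t_min: float) -> float:
    """In-field blood-pool activity: physical decay times renal clearance."""
    half_life_min = physics.get_nuclide(scenario.nuclide).half_life_h * 60.0
    return (scenario.injected_activity_mbq
            * 2.0 ** (-t_min / half_life_min)
            * 2.0 ** (-t_min / scenario.clearance_half_time_min))


def generate_mouse(scenario: MouseScenario,
                   output_dir: str | Path) -> tuple[Path, dict]:
    """Render the pseudotumor phantom at each timepoint with ground truth.

    The acceptor-loaded flank sees donor light attenuated over the tumor
    depth on the way in (excitation), couples it, and is attenuated again
    on the way out; the PBS flank is raw Cerenkov attenuated over twice
    the depth.  The blood-pool background (and organ foci) is blue-rich
    Cerenkov at shallow depth, so it anchors the donor window of ROI
    ratios.  Expected images from the overlapping layers are summed before
    a single Poisson step.
    """
    out = Path(output_dir)
    fluor = coupling.default_qtracker705(quantum_yield=scenario.quantum_yield)
    bands = imaging.filter_set()
    tissue = imaging.default_tissue(scenario.tissue_a_mm,
                                    scenario.tissue_decay_nm,
                                    scenario.tissue_floor_mm)
    body, flank_q, flank_p, organs = _mouse_geometry(scenario)
    conc_q, conc_p = scenario.pseudotumor_concentrations_nm
    physics_seed = physics._substream_int(scenario.seed, "physics")
    per_decay = physics.cherenkov_photons_per_decay(
        physics.get_nuclide(scenario.nuclide), physics.water(),
        n_samples=scenario.n_samples, seed=physics_seed)

    def flank_spectrum(conc_nm: float,
                       donor: physics.EmissionSpectrum) -> physics.EmissionSpectrum:
        arriving = imaging.attenuate(donor, tissue, scenario.tumor_depth_mm)
        geom = coupling.CouplingGeometry.from_nm(
            conc_nm, pathlength_cm=scenario.pathlength_cm)
        return coupling.couple_spectrum(arriving, fluor, geom)

    rois = {
        "qdot_tumor": {"ellipse": [scenario.canvas[0] * 0.64,
                                   scenario.canvas[1] / 2.0 - scenario.canvas[1] * 0.17,
                                   16.0, 11.0]},
        "pbs_tumor": {"ellipse": [scenario.canvas[0] * 0.64,
                                  scenario.canvas[1] / 2.0 + scenario.canvas[1] * 0.17,
                                  16.0, 11.0]},
    }
    roi_q = quantify.Roi("qdot_tumor", flank_q)
    roi_p = quantify.Roi("pbs_tumor", flank_p)

    timepoint_records = []
    for t_min in scenario.timepoints_min:
        tdir = out / f"t{int(round(t_min)):03d}min"
        activity = _mouse_activity(scenario, t_min)
        total = per_decay.scaled(
            activity * 1e6 * scenario.collection_efficiency)
        donor_flank = total.scaled(scenario.flank_fraction)
        background_layer = [imaging.SceneRegion(
            body, total.scaled(scenario.background_fraction),
            depth_mm=scenario.skin_depth_mm)]
        focal_layer = [
            imaging.SceneRegion(flank_q, flank_spectrum(conc_q, donor_flank),
                                depth_mm=scenario.tumor_depth_mm),
            imaging.SceneRegion(flank_p, flank_spectrum(conc_p, donor_flank),
                                depth_mm=scenario.tumor_depth_mm),
        ] + [
            imaging.SceneRegion(organs[name], total.scaled(frac),
                                depth_mm=scenario.organ_depth_mm)
            for name, frac in scenario.organ_fractions.items()
        ]

        meta = imaging.AcquisitionMeta(exposure_s=scenario.exposure_s,
                                       binning=8, timestamp_h=t_min / 60.0)
        clean_images, noisy_images = {}, {}
        hot_truth: dict[str, list] = {}
        for key, band in bands.items():
            expected = sum(
                imaging.expected_image(layer, band, tissue,
                                       scenario.psf_sigma, scenario.canvas)
                for layer in (background_layer, focal_layer)
            ) + scenario.background_flux
            expected = expected.astype(np.float32).astype(np.float64)
            clean_images[key] = imaging.FilteredImage(expected, band, meta)
            if scenario.poisson_noise:
                rng = np.random.default_rng(physics._substream_int(
                    scenario.seed, f"{t_min}:noise:{key}"))
                pixels = rng.poisson(expected * meta.exposure_s) / meta.exposure_s
            else:
                pixels = expected.copy()
            img = imaging.FilteredImage(pixels, band, meta)
            img, coords = imaging.inject_hot_pixels(
                img, scenario.hot_pixel_rate,
                seed=physics._substream_int(scenario.seed,
                                            f"{t_min}:hot:{key}"))
            noisy_images[key] = img
            hot_truth[key] = coords.tolist()

        extra = {"scenario": json.loads(scenario.model_dump_json()),
                 "seed": scenario.seed, "kind": "mouse",
                 "timepoint_min": t_min}
        imaging.write_acquisition(tdir, noisy_images, extra_meta=extra)
        imaging.write_acquisition(tdir / "noise_free", clean_images,
                                  extra_meta=extra)
        _json_dump(tdir / "rois.json", rois)

        flux_q = _noise_free_fluxes(clean_images, roi_q)
        flux_p = _noise_free_fluxes(clean_images, roi_p)
        result = quantify.cret_ratio(
            quantify.BandFluxPair(flux_q["red"], flux_q["blue"]),
            quantify.BandFluxPair(flux_p["red"], flux_p["blue"]))
        timepoint_records.append({
            "timepoint_min": t_min,
            "activity_mbq": activity,
            "fluxes_noise_free": {"qdot_tumor": flux_q, "pbs_tumor": flux_p},
            "total_open_flux_noise_free": float(
                clean_images["open"].pixels.sum()),
            "sample_ratio": result.sample_ratio,
            "control_ratio": result.control_ratio,
            "cret_ratio": result.cret_ratio,
            "hot_pixels": hot_truth,
        })

    manifest = {
        "schema_version": MANIFEST_SCHEMA_VERSION,
        "kind": "mouse",
        "scenario": json.loads(scenario.model_dump_json()),
        "timepoints": timepoint_records,
    }
    out.mkdir(parents=True, exist_ok=True)
    _json_dump(out / "manifest.json", manifest)
    return out, manifest


# ---------------------------------------------------------------------------
# canonical fixture bundle


def canonical_fixture_suite(output_dir: str | Path, seed: int = 0) -> dict:
    """Write the canonical fixture bundle used by the test suite.

    Contents: the concentration-ladder plate, the activity-titration
    plate, a gamma-only (Tc-99m) null plate, both mouse cohorts (200 and
    500 nM acceptor), and a clean/corrupted image pair for hot-pixel
    repair, all with seeds derived from ``seed``.  Re-running overwrites
    with identical content.
    """
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    sub = physics._substream_int
    bundle: dict[str, dict] = {}

    scenarios = {
        "concentration_plate": PlateScenario(
            name="concentration_plate", seed=sub(seed, "conc_ladder")),
        "titration_plate": PlateScenario(
            name="titration_plate",
            fluorophore_concentration_nm=[0.0, 40.0],
            activity_per_well_mbq=[0.0, 0.037, 0.37, 3.7, 37.0],
            exposure_s=30.0, seed=sub(seed, "act_titration")),
        "tc99m_plate": PlateScenario(
            name="tc99m_plate", nuclide="Tc-99m",
            fluorophore_concentration_nm=[0.0, 400.0],
            activity_per_well_mbq=[5.6],
            hot_pixel_rate=0.0, seed=sub(seed, "tc99m")),
    }
    for key, scenario in scenarios.items():
        path, manifest = generate_plate(scenario, out / key)
        bundle[key] = {"path": str(path), "manifest": manifest}

    for key, conc in (("mouse_200nM", 200.0), ("mouse_500nM", 500.0)):
        scenario = MouseScenario(
            name=key, pseudotumor_concentrations_nm=(conc, 0.0),
            seed=sub(seed, key))
        path, manifest = generate_mouse(scenario, out / key)
        bundle[key] = {"path": str(path), "manifest": manifest}

    clean, corrupted, coords = hot_pixel_pair(seed=sub(seed, "hotpix"))
    hp_dir = out / "hot_pixel_pair"
    imaging.write_acquisition(hp_dir, {"clean": clean, "corrupted": corrupted})
    _json_dump(hp_dir / "injected.json", {"coordinates": coords.tolist()})
    bundle["hot_pixel_pair"] = {"path": str(hp_dir),
                                "n_injected": int(coords.shape[0])}

    _json_dump(out / "bundle.json",
               {k: {kk: vv for kk, vv in v.items() if kk != "manifest"}
                for k, v in bundle.items()})
    return bundle


def hot_pixel_pair(seed: int = 0, n_expected: float = 20.0
                   ) -> tuple[imaging.FilteredImage, imaging.FilteredImage,
                              np.ndarray]:
    """A clean noise-free well image and its hot-pixel corrupted twin."""
    scenario = PlateScenario(
        name="hotpix", fluorophore_concentration_nm=[0.0, 100.0],
        activity_per_well_mbq=[5.6], replicates=2, poisson_noise=False,
        hot_pixel_rate=0.0, canvas=(128, 192), seed=seed)
    fluor = coupling.default_qtracker705(quantum_yield=scenario.quantum_yield)
    donor = _donor_per_second(scenario.nuclide, 5.6,
                              scenario.collection_efficiency,
                              scenario.n_samples,
                              physics._substream_int(seed, "physics"))
    geom = coupling.CouplingGeometry.from_nm(100.0, scenario.pathlength_cm)
    spectrum = coupling.couple_spectrum(donor, fluor, geom)
    regions = [
        imaging.SceneRegion(
            imaging.circle_mask((64.0, 48.0 + 64.0 * i), 11.0, scenario.canvas),
            spectrum if i else donor)
        for i in range(3)
    ]
    band = imaging.filter_set()["blue"]
    meta = imaging.AcquisitionMeta(exposure_s=10.0)
    clean = imaging.render_image(
        regions, band, imaging.no_tissue(), meta, scenario.psf_sigma,
        seed=0, shape=scenario.canvas,
        background_flux=scenario.background_flux, noise=False)
    corrupted, coords = imaging.inject_hot_pixels(
        clean, rate=n_expected, seed=physics._substream_int(seed, "inject"))
    return clean, corrupted, coords
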