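"""Filtered CCD image synthesis: emission filters, optics, noise, tissue.

Scenes are lists of spatial regions, each carrying an emission spectrum and
a tissue depth.  Rendering integrates every region's spectrum over the
selected filter band (after wavelength-dependent tissue attenuation),
paints the band flux uniformly over the region mask, applies a Gaussian
point-spread blur, and Poisson-samples photon counts over the exposure.
Hot pixels -- isolated outliers caused by 511 keV annihilation photons
striking the CCD -- are injected as a separate, seeded nuisance process.

The filter set mirrors a four-filter acquisition: open, <510 nm (blue,
donor window), 500-570 nm (green), >590 nm (red, acceptor window), modeled
as ideal boxes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import tifffile
from scipy.integrate import trapezoid
from scipy.ndimage import gaussian_filter

from .physics import EmissionSpectrum

__all__ = [
    "FilterBand",
    "filter_set",
    "FILTER_ORDER",
    "AcquisitionMeta",
    "FilteredImage",
    "SceneRegion",
    "TissueModel",
    "default_tissue",
    "no_tissue",
    "integrate_band",
    "attenuate",
    "render_image",
    "expected_image",
    "inject_hot_pixels",
    "circle_mask",
    "ellipse_mask",
    "write_acquisition",
    "read_acquisition",
]

FILTER_ORDER = ("open", "blue", "green", "red")


@dataclass(frozen=True)
class FilterBand:
    """Ideal box emission filter passing [lo, hi) nm."""

    name: str
    lo_nm: float
    hi_nm: float

    def __post_init__(self) -> None:
        if self.hi_nm <= self.lo_nm:
            raise ValueError("filter band must have hi > lo")

    def transmission(self, wavelength_nm):
        lam = np.asarray(wavelength_nm, dtype=float)
        out = ((lam >= self.lo_nm) & (lam < self.hi_nm)).astype(float)
        return float(out) if out.ndim == 0 else out


def filter_set(grid_min_nm: float = 300.0,
               grid_max_nm: float = 900.0) -> dict[str, FilterBand]:
    """The four-filter acquisition set with box edges at 510/500/570/590 nm."""
    return {
        "open": FilterBand("open", grid_min_nm, grid_max_nm),
        "blue": FilterBand("blue_lt510", grid_min_nm, 510.0),
        "green": FilterBand("green_500_570", 500.0, 570.0),
        "red": FilterBand("red_gt590", 590.0, grid_max_nm),
    }


@dataclass(frozen=True)
class AcquisitionMeta:
    exposure_s: float
    binning: int = 8
    field_of_view: str = "FOV15"
    f_stop: str = "1/f"
    timestamp_h: float = 0.0

    def __post_init__(self) -> None:
        if self.exposure_s <= 0.0:
            raise ValueError("exposure must be positive")
        if self.binning < 1:
            raise ValueError("binning must be >= 1")


@dataclass
class FilteredImage:
    """2-D photon-flux array (photons/s per pixel) behind one filter."""

    pixels: np.ndarray
    filter: FilterBand
    meta: AcquisitionMeta

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2:
            raise ValueError("pixels must be a 2-D array")
        if np.any(self.pixels < 0.0):
            raise ValueError("pixel fluxes must be non-negative")


@dataclass(frozen=True)
class SceneRegion:
    """Spatial region emitting one spectrum, at a given tissue depth (mm)."""

    mask: np.ndarray  # (N, 2) int array of (row, col) coordinates
    spectrum: EmissionSpectrum
    depth_mm: float = 0.0

    def __post_init__(self) -> None:
        mask = np.asarray(self.mask, dtype=int)
        if mask.ndim != 2 or mask.shape[1] != 2 or mask.shape[0] == 0:
            raise ValueError("mask must be a non-empty (N, 2) coordinate array")
        if self.depth_mm < 0.0:
            raise ValueError("depth must be non-negative")
        object.__setattr__(self, "mask", mask)


@dataclass(frozen=True)
class TissueModel:
    """Wavelength-dependent optical attenuation mu(lambda) in mm^-1."""

    attenuation_mm: Callable[[np.ndarray], np.ndarray]

    def mu(self, wavelength_nm):
        out = np.asarray(self.attenuation_mm(np.asarray(wavelength_nm, float)),
                         dtype=float)
        if np.any(out < 0.0):
            raise ValueError("attenuation must be non-negative")
        return float(out) if out.ndim == 0 else out


def default_tissue(a_mm: float = 1.0, decay_nm: float = 120.0,
                   floor_mm: float = 0.02) -> TissueModel:
    """Generic soft-tissue model: mu(l) = a*exp(-(l-400)/decay) + floor.

    Strongly absorbing in the UV/blue (hemoglobin, cytochromes, water) and
    nearly transparent in the far red; non-increasing in wavelength.
    """
    def mu(lam):
        return a_mm * np.exp(-(np.asarray(lam, float) - 400.0) / decay_nm) + floor_mm

    return TissueModel(attenuation_mm=mu)


def no_tissue() -> TissueModel:
    return TissueModel(attenuation_mm=lambda lam: np.zeros_like(np.asarray(lam, float)))


# ---------------------------------------------------------------------------
# spectral operations


def integrate_band(spectrum: EmissionSpectrum, band: FilterBand) -> float:
    """Photon flux through a box filter: integral of density over [lo, hi].

    The band is clipped to the spectrum grid (zero density outside), with
    linear interpolation at the band edges so that adjacent bands tile the
    open filter exactly.
    """
    lam = spectrum.wavelengths_nm
    lo = max(band.lo_nm, lam[0])
    hi = min(band.hi_nm, lam[-1])
    if hi <= lo:
        return 0.0
    inside = (lam > lo) & (lam < hi)
    xs = np.concatenate(([lo], lam[inside], [hi]))
    ys = np.concatenate(([spectrum.interp(lo)], spectrum.density[inside],
                         [spectrum.interp(hi)]))
    return float(trapezoid(ys, xs))


def attenuate(spectrum: EmissionSpectrum, tissue: TissueModel,
              depth_mm: float) -> EmissionSpectrum:
    """Beer--Lambert tissue attenuation: density * exp(-mu(lambda) * depth)."""
    if depth_mm < 0.0:
        raise ValueError("depth must be non-negative")
    if depth_mm == 0.0:
        return spectrum
    factor = np.exp(-tissue.mu(spectrum.wavelengths_nm) * depth_mm)
    return EmissionSpectrum(spectrum.wavelengths_nm, spectrum.density * factor)


# ---------------------------------------------------------------------------
# image synthesis


def _check_bounds_and_overlap(regions: Sequence[SceneRegion],
                              shape: tuple[int, int]) -> None:
    seen: set[tuple[int, int]] = set()
    for region in regions:
        rr, cc = region.mask[:, 0], region.mask[:, 1]
        if (rr.min() < 0 or cc.min() < 0
                or rr.max() >= shape[0] or cc.max() >= shape[1]):
            raise ValueError("region mask outside image bounds")
        coords = set(map(tuple, region.mask.tolist()))
        if seen & coords:
            raise ValueError("region masks overlap")
        seen |= coords


def expected_image(regions: Sequence[SceneRegion], band: FilterBand,
                   tissue: TissueModel, psf_sigma: float = 2.0,
                   shape: tuple[int, int] = (256, 384),
                   background_flux: float = 0.0) -> np.ndarray:
    """Noise-free expected flux image (photons/s per pixel)."""
    _check_bounds_and_overlap(regions, shape)
    img = np.zeros(shape, dtype=np.float64)
    for region in regions:
        flux = integrate_band(attenuate(region.spectrum, tissue, region.depth_mm),
                              band)
        if flux > 0.0:
            img[region.mask[:, 0], region.mask[:, 1]] += flux / region.mask.shape[0]
    if psf_sigma > 0.0:
        img = gaussian_filter(img, sigma=psf_sigma, mode="constant")
    return img + background_flux


def render_image(regions: Sequence[SceneRegion], band: FilterBand,
                 tissue: TissueModel, meta: AcquisitionMeta,
                 psf_sigma: float = 2.0, seed: int = 0, *,
                 shape: tuple[int, int] = (256, 384),
                 background_flux: float = 0.0,
                 noise: bool = True) -> FilteredImage:
    """Synthesize one filtered acquisition from a scene description.

    Poisson noise is applied to expected counts (flux x exposure) and the
    result converted back to flux; with ``noise=False`` the expected flux
    image is returned directly.  Deterministic given ``seed``.
    """
    expected = expected_image(regions, band, tissue, psf_sigma, shape,
                              background_flux)
    if noise:
        rng = np.random.default_rng(seed)
        counts = rng.poisson(expected * meta.exposure_s)
        pixels = counts / meta.exposure_s
    else:
        pixels = expected
    return FilteredImage(pixels=pixels, filter=band, meta=meta)


def inject_hot_pixels(image: FilteredImage, rate: float,
                      amplitude_range: tuple[float, float] = (10.0, 100.0),
                      seed: int = 0) -> tuple[FilteredImage, np.ndarray]:
    """Corrupt an image with isolated annihilation-photon hot pixels.

    A Poisson(rate) number of isolated pixels (Chebyshev separation >= 2)
    is set to amplitude x the image's robust maximum (99.5th percentile).
    Returns the corrupted copy plus the (N, 2) array of injected
    coordinates; the input image is never modified.
    """
    if rate < 0.0:
        raise ValueError("rate must be non-negative")
    if rate == 0.0:
        return image, np.empty((0, 2), dtype=int)
    rng = np.random.default_rng(seed)
    n_hot = int(rng.poisson(rate))
    pixels = image.pixels.copy()
    robust_max = float(np.percentile(pixels, 99.5))
    if robust_max <= 0.0:
        robust_max = 1.0
    coords: list[tuple[int, int]] = []
    attempts = 0
    while len(coords) < n_hot and attempts < 100 * max(n_hot, 1):
        attempts += 1
        r = int(rng.integers(0, pixels.shape[0]))
        c = int(rng.integers(0, pixels.shape[1]))
        if all(max(abs(r - r0), abs(c - c0)) >= 2 for r0, c0 in coords):
            coords.append((r, c))
    for r, c in coords:
        amplitude = rng.uniform(*amplitude_range)
        pixels[r, c] = amplitude * robust_max
    corrupted = FilteredImage(pixels=pixels, filter=image.filter, meta=image.meta)
    return corrupted, np.asarray(coords, dtype=int).reshape(-1, 2)


# ---------------------------------------------------------------------------
# mask helpers


def circle_mask(center: tuple[float, float], radius: float,
                shape: tuple[int, int]) -> np.ndarray:
    rr, cc = np.mgrid[0:shape[0], 0:shape[1]]
    inside = (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius**2
    return np.argwhere(inside)


def ellipse_mask(center: tuple[float, float], semi_axes: tuple[float, float],
                 shape: tuple[int, int]) -> np.ndarray:
    rr, cc = np.mgrid[0:shape[0], 0:shape[1]]
    a, b = semi_axes
    inside = ((rr - center[0]) / a) ** 2 + ((cc - center[1]) / b) ** 2 <= 1.0
    return np.argwhere(inside)


# ---------------------------------------------------------------------------
# acquisition directory I/O: open.tif / blue.tif / green.tif / red.tif + meta.json


def write_acquisition(directory: str | Path, images: dict[str, FilteredImage],
                      extra_meta: dict | None = None) -> Path:
    """Write a 4-filter acquisition as 32-bit float TIFFs plus meta.json."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    meta: dict = {"filters": {}}
    for key, image in images.items():
        tifffile.imwrite(directory / f"{key}.tif",
                         image.pixels.astype(np.float32))
        meta["filters"][key] = {
            "name": image.filter.name,
            "lo_nm": image.filter.lo_nm,
            "hi_nm": image.filter.hi_nm,
        }
        meta["acquisition"] = {
            "exposure_s": image.meta.exposure_s,
            "binning": image.meta.binning,
            "field_of_view": image.meta.field_of_view,
            "f_stop": image.meta.f_stop,
            "timestamp_h": image.meta.timestamp_h,
        }
    if extra_meta:
        meta.update(extra_meta)
    (directory / "meta.json").write_text(
        json.dumps(meta, indent=2, sort_keys=True) + "\n")
    return directory


def read_acquisition(directory: str | Path) -> dict[str, FilteredImage]:
    """Read an acquisition directory written by :func:`write_acquisition`."""
    directory = Path(directory)
    meta_path = directory / "meta.json"
    if not meta_path.exists():
        raise FileNotFoundError(f"missing meta.json in {directory}")
    meta = json.loads(meta_path.read_text())
    acq = meta.get("acquisition", {})
    acq_meta = AcquisitionMeta(
        exposure_s=acq.get("exposure_s", 1.0),
        binning=acq.get("binning", 8),
        field_of_view=acq.get("field_of_view", "FOV15"),
        f_stop=acq.get("f_stop", "1/f"),
        timestamp_h=acq.get("timestamp_h", 0.0),
    )
    images = {}
    for key, band_info in meta["filters"].items():
        path = directory / f"{key}.tif"
        if not path.exists():
            raise FileNotFoundError(
                f"acquisition {directory} is missing the {key!r} filter image")
        band = FilterBand(band_info["name"], band_info["lo_nm"],
                          band_info["hi_nm"])
        images[key] = FilteredImage(pixels=tifffile.imread(path),
                                    filter=band, meta=acq_meta)
    return images
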