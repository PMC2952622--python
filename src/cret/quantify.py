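"""Quantification of CRET from filtered photon-flux images.

The headline statistic is the CRET ratio: with an acceptor window X
(red, >590 nm, centered on the fluorophore emission) and a donor window Y
(blue, <510 nm, the bulk of the Cerenkov emission),

    CRET = (X/Y) with fluorophore  -  (X/Y) with Cerenkov radiation alone.

The control term subtracts the contribution of the raw Cerenkov tail to
the acceptor window, so a fluorophore-free scene scores zero by
construction.  Supporting operations: hot-pixel repair (neighborhood
median + MAD outlier rule, replacement by the mean of clean neighbors),
ROI photon flux, red/blue ratio images, "calculated CRET" images
(control-ROI mean subtracted from every pixel), replicate statistics with
SEM, Student's t test and ordinary least squares for dose/concentration
trends.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy import stats

from .imaging import FilteredImage

__all__ = [
    "Roi",
    "BandFluxPair",
    "CretResult",
    "RatioImage",
    "correct_hot_pixels",
    "roi_flux",
    "cret_ratio",
    "cret_ratio_replicates",
    "ratio_image",
    "calculated_cret_image",
    "two_sample_t",
    "linear_fit",
]


@dataclass(frozen=True)
class Roi:
    """Named region of interest as an explicit (N, 2) coordinate mask."""

    label: str
    mask: np.ndarray

    def __post_init__(self) -> None:
        mask = np.asarray(self.mask, dtype=int)
        if mask.ndim != 2 or mask.shape[1] != 2 or mask.shape[0] == 0:
            raise ValueError("ROI mask must be a non-empty (N, 2) array")
        object.__setattr__(self, "mask", mask)


@dataclass(frozen=True)
class BandFluxPair:
    """Acceptor-window (X) and donor-window (Y) photon fluxes for one sample."""

    x_flux: float
    y_flux: float

    def __post_init__(self) -> None:
        if self.x_flux < 0.0 or self.y_flux < 0.0:
            raise ValueError("band fluxes must be non-negative")

    @property
    def ratio(self) -> float:
        if self.y_flux <= 0.0:
            raise ZeroDivisionError("donor-window flux must be positive")
        return self.x_flux / self.y_flux


@dataclass(frozen=True)
class CretResult:
    """CRET ratio with its components and (when available) uncertainty.

    ``cret_ratio == sample_ratio - control_ratio`` always holds; the SEM of
    the difference is propagated as the root sum of squares of the two
    arms' SEMs.  ``mean_of_differences`` is the secondary per-pair
    aggregation (mean over sample ratios each differenced against the mean
    control ratio equals the primary; the field stores the mean of
    replicate-wise differences when arms are paired by index).
    """

    sample_ratio: float
    control_ratio: float
    cret_ratio: float
    uncertainty: float | None
    n: int
    n_control: int = 1
    mean_of_differences: float | None = None


@dataclass
class RatioImage:
    """Pixelwise ratio of two filtered images with a validity mask."""

    pixels: np.ndarray
    valid: np.ndarray
    numerator_filter: str
    denominator_filter: str


# ---------------------------------------------------------------------------
# hot-pixel correction


def _neighborhoods(pixels: np.ndarray, window: int) -> np.ndarray:
    """(H, W, window*window-1) array of each pixel's neighbors (reflect-padded)."""
    half = window // 2
    padded = np.pad(pixels, half, mode="reflect")
    view = np.lib.stride_tricks.sliding_window_view(padded, (window, window))
    flat = view.reshape(*pixels.shape, window * window)
    center = (window * window) // 2
    return np.delete(flat, center, axis=-1)


def correct_hot_pixels(image: FilteredImage, detection_k: float = 6.0,
                       window: int = 3, scale_floor_rel: float = 1e-3,
                       shot_noise_floor: bool = True
                       ) -> tuple[FilteredImage, np.ndarray]:
    """Flag and repair isolated outlier pixels.

    A pixel is flagged when it exceeds the median of its window
    neighborhood (center excluded) by more than ``detection_k`` times the
    neighborhood's robust scale.  The scale is MAD-based (1.4826 * MAD)
    but floored at (a) ``scale_floor_rel`` times the neighborhood median
    and (b) the Poisson shot-noise scale sqrt(rate / exposure) + one
    count, with the rate taken from the neighborhood mean -- without the
    floors, the heavily quantized count values of dim neighborhoods make
    both the MAD and the median collapse to zero and ordinary counting
    fluctuations get flagged.  Flagged pixels
    are replaced by the mean of their non-flagged neighbors; detection
    and replacement both read the original values (single pass).  Returns
    the corrected image and the (N, 2) array of corrected coordinates.
    """
    if window < 3 or window % 2 == 0:
        raise ValueError("window must be an odd integer >= 3")
    pixels = image.pixels
    if min(pixels.shape) < window:
        raise ValueError("image smaller than the correction window")
    neigh = _neighborhoods(pixels, window)
    med = np.median(neigh, axis=-1)
    mad = np.median(np.abs(neigh - med[..., None]), axis=-1)
    robust_sigma = np.maximum(1.4826 * mad, scale_floor_rel * np.abs(med))
    if shot_noise_floor:
        exposure = image.meta.exposure_s
        rate = np.maximum(med, neigh.mean(axis=-1))
        shot = np.sqrt(np.maximum(rate, 0.0) / exposure) + 1.0 / exposure
        robust_sigma = np.maximum(robust_sigma, shot)
    flagged = pixels - med > detection_k * robust_sigma
    coords = np.argwhere(flagged)
    if coords.size == 0:
        return replace(image, pixels=pixels.copy()), coords

    corrected = pixels.copy()
    half = window // 2
    pixels_padded = np.pad(pixels, half, mode="reflect")
    flagged_padded = np.pad(flagged, half, mode="reflect")
    for r, c in coords:
        rows = slice(r, r + window)
        cols = slice(c, c + window)
        neigh_vals = pixels_padded[rows, cols].ravel()
        neigh_flags = flagged_padded[rows, cols].ravel()
        center = (window * window) // 2
        keep = np.ones(window * window, dtype=bool)
        keep[center] = False
        keep &= ~neigh_flags
        if keep.any():
            corrected[r, c] = neigh_vals[keep].mean()
        else:
            corrected[r, c] = med[r, c]
    return replace(image, pixels=corrected), coords


# ---------------------------------------------------------------------------
# fluxes and ratios


def roi_flux(image: FilteredImage, roi: Roi) -> float:
    """Total photon flux (photons/s) summed over the ROI mask."""
    rr, cc = roi.mask[:, 0], roi.mask[:, 1]
    shape = image.pixels.shape
    if rr.min() < 0 or cc.min() < 0 or rr.max() >= shape[0] or cc.max() >= shape[1]:
        raise ValueError(f"ROI {roi.label!r} extends outside the image")
    return float(image.pixels[rr, cc].sum())


def cret_ratio(sample: BandFluxPair, control: BandFluxPair) -> CretResult:
    """Single-measurement CRET ratio: sample X/Y minus control X/Y."""
    s = sample.ratio
    c = control.ratio
    return CretResult(sample_ratio=s, control_ratio=c, cret_ratio=s - c,
                      uncertainty=None, n=1, n_control=1)


def _mean_sem(values: np.ndarray) -> tuple[float, float | None]:
    mean = float(values.mean())
    if values.size < 2:
        return mean, None
    return mean, float(values.std(ddof=1) / math.sqrt(values.size))


def cret_ratio_replicates(samples: Sequence[BandFluxPair],
                          controls: Sequence[BandFluxPair]) -> CretResult:
    """CRET from replicate wells/animals, with SEM propagation.

    Primary aggregation: difference of the two arms' mean ratios (the
    ratio definition is written in terms of aggregate light).  The SEM of
    the difference is sqrt(SEM_sample**2 + SEM_control**2); an arm with a
    single replicate contributes no variance term, and with one replicate
    in both arms the uncertainty is reported as None.  The mean of
    index-paired per-replicate differences is also recorded.
    """
    if not samples or not controls:
        raise ValueError("both replicate lists must be non-empty")
    s_ratios = np.array([p.ratio for p in samples])
    c_ratios = np.array([p.ratio for p in controls])
    s_mean, s_sem = _mean_sem(s_ratios)
    c_mean, c_sem = _mean_sem(c_ratios)
    if s_sem is None and c_sem is None:
        uncertainty = None
    else:
        uncertainty = math.sqrt((s_sem or 0.0) ** 2 + (c_sem or 0.0) ** 2)
    n_pairs = min(s_ratios.size, c_ratios.size)
    mean_diff = float((s_ratios[:n_pairs] - c_ratios[:n_pairs]).mean())
    return CretResult(sample_ratio=s_mean, control_ratio=c_mean,
                      cret_ratio=s_mean - c_mean, uncertainty=uncertainty,
                      n=int(s_ratios.size), n_control=int(c_ratios.size),
                      mean_of_differences=mean_diff)


def ratio_image(numerator: FilteredImage, denominator: FilteredImage,
                floor: float | None = None) -> RatioImage:
    """Pixelwise numerator/denominator with an explicit validity mask.

    Pixels whose denominator falls below ``floor`` (default 1e-9 x the
    denominator maximum) are marked invalid and carry NaN.
    """
    if numerator.pixels.shape != denominator.pixels.shape:
        raise ValueError("ratio images require identically shaped inputs")
    if floor is None:
        floor = 1e-9 * float(denominator.pixels.max())
    if floor <= 0.0:
        floor = np.finfo(float).tiny
    valid = denominator.pixels >= floor
    pixels = np.full(numerator.pixels.shape, np.nan)
    pixels[valid] = numerator.pixels[valid] / denominator.pixels[valid]
    return RatioImage(pixels=pixels, valid=valid,
                      numerator_filter=numerator.filter.name,
                      denominator_filter=denominator.filter.name)


def calculated_cret_image(ratio: RatioImage, control_roi: Roi) -> RatioImage:
    """Subtract the control-ROI mean ratio from every valid pixel.

    The control ROI (e.g. over the fluorophore-free pseudotumor) supplies
    the "Cerenkov alone" term of the CRET definition pixelwise; its own
    mean becomes zero by construction.
    """
    rr, cc = control_roi.mask[:, 0], control_roi.mask[:, 1]
    shape = ratio.pixels.shape
    if rr.min() < 0 or cc.min() < 0 or rr.max() >= shape[0] or cc.max() >= shape[1]:
        raise ValueError("control ROI extends outside the ratio image")
    roi_valid = ratio.valid[rr, cc]
    if not roi_valid.any():
        raise ValueError("control ROI contains no valid pixels")
    control_mean = float(ratio.pixels[rr, cc][roi_valid].mean())
    pixels = ratio.pixels - control_mean
    pixels[~ratio.valid] = np.nan
    return RatioImage(pixels=pixels, valid=ratio.valid.copy(),
                      numerator_filter=ratio.numerator_filter,
                      denominator_filter=ratio.denominator_filter)


def roi_ratio_mean(ratio: RatioImage, roi: Roi) -> float:
    """Mean of valid ratio pixels over an ROI (the in-vivo ratio readout)."""
    rr, cc = roi.mask[:, 0], roi.mask[:, 1]
    vals = ratio.pixels[rr, cc]
    ok = ratio.valid[rr, cc]
    if not ok.any():
        raise ValueError(f"ROI {roi.label!r} contains no valid ratio pixels")
    return float(vals[ok].mean())


# ---------------------------------------------------------------------------
# statistics


def two_sample_t(sample_a: Sequence[float], sample_b: Sequence[float],
                 welch: bool = False) -> tuple[float, float]:
    """Unpaired two-tailed Student t test (pooled variance by default).

    Zero pooled variance with equal means returns (0, 1) by contract;
    zero pooled variance with unequal means returns (+/-inf, 0).
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs at least 2 observations")
    if a.std(ddof=1) == 0.0 and b.std(ddof=1) == 0.0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        return math.copysign(math.inf, a.mean() - b.mean()), 0.0
    t, p = stats.ttest_ind(a, b, equal_var=not welch)
    return float(t), float(p)


def linear_fit(x: Sequence[float], y: Sequence[float]
               ) -> tuple[float, float, float]:
    """Ordinary least squares: returns (slope, intercept, r_squared)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or x.size != y.size:
        raise ValueError("need matching x/y with at least 2 points")
    if np.all(x == x[0]):
        raise ValueError("x values are degenerate (all equal)")
    result = stats.linregress(x, y)
    return float(result.slope), float(result.intercept), float(result.rvalue**2)
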