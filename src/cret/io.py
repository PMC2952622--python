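"""Configuration, ROI files, and the file-level quantification pipeline.

Ties the module chain (hot-pixel repair -> ROI flux -> CRET ratio ->
ratio image -> calculated CRET image) to acquisition directories on disk,
with full provenance (input hashes, parameters, seeds) carried into every
result record.

ROI files are JSON mapping labels to either an explicit list of
``[row, col]`` pairs or a shape spec:
``{"rect": [r0, c0, r1, c1]}`` (half-open), ``{"circle": [r, c, radius]}``
or ``{"ellipse": [r, c, semi_r, semi_c]}``.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile
from pydantic import BaseModel, ConfigDict

from . import imaging, quantify

__all__ = [
    "QuantifyConfig",
    "load_rois",
    "quantify_acquisition",
    "report_results",
]


class QuantifyConfig(BaseModel):
    """Validated parameter set for the quantification command."""

    model_config = ConfigDict(extra="forbid")

    acquisition: str
    roi_file: str
    sample_rois: list[str]
    control_rois: list[str]
    output_dir: str
    hot_pixel_correction: bool = True
    detection_k: float = 6.0
    window: int = 3
    ratio_floor: float | None = None
    acceptor_filter: str = "red"
    donor_filter: str = "blue"


def _mask_from_spec(spec, shape: tuple[int, int]) -> np.ndarray:
    if isinstance(spec, list):
        return np.asarray(spec, dtype=int)
    if isinstance(spec, dict):
        if "rect" in spec:
            r0, c0, r1, c1 = spec["rect"]
            rr, cc = np.mgrid[int(r0):int(r1), int(c0):int(c1)]
            return np.column_stack([rr.ravel(), cc.ravel()])
        if "circle" in spec:
            r, c, radius = spec["circle"]
            return imaging.circle_mask((r, c), radius, shape)
        if "ellipse" in spec:
            r, c, a, b = spec["ellipse"]
            return imaging.ellipse_mask((r, c), (a, b), shape)
    raise ValueError(f"unrecognized ROI spec: {spec!r}")


def load_rois(path: str | Path, shape: tuple[int, int]) -> dict[str, quantify.Roi]:
    specs = json.loads(Path(path).read_text())
    return {label: quantify.Roi(label, _mask_from_spec(spec, shape))
            for label, spec in specs.items()}


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def quantify_acquisition(config: QuantifyConfig) -> dict:
    """Run the full quantification chain on one acquisition directory.

    Writes ``roi_fluxes.csv``, ``cret_result.json`` and (when red and blue
    images are present) ``cret_image.tif`` into the output directory, and
    returns the result record.
    """
    acq_dir = Path(config.acquisition)
    images = imaging.read_acquisition(acq_dir)
    for key in (config.acceptor_filter, config.donor_filter):
        if key not in images:
            raise FileNotFoundError(
                f"acquisition {acq_dir} is missing the {key!r} filter image")
    shape = next(iter(images.values())).pixels.shape
    rois = load_rois(config.roi_file, shape)
    for label in config.sample_rois + config.control_rois:
        if label not in rois:
            raise KeyError(f"ROI {label!r} not present in {config.roi_file}")

    corrected_coords: dict[str, list] = {}
    if config.hot_pixel_correction:
        for key, image in images.items():
            images[key], coords = quantify.correct_hot_pixels(
                image, config.detection_k, config.window)
            corrected_coords[key] = coords.tolist()

    flux_rows = []
    roi_fluxes: dict[str, dict[str, float]] = {}
    for label, roi in rois.items():
        roi_fluxes[label] = {}
        for key, image in images.items():
            flux = quantify.roi_flux(image, roi)
            roi_fluxes[label][key] = flux
            flux_rows.append({"roi": label, "filter": key,
                              "flux_photons_per_s": flux})

    def pairs(labels: Sequence[str]) -> list[quantify.BandFluxPair]:
        return [quantify.BandFluxPair(
            roi_fluxes[lab][config.acceptor_filter],
            roi_fluxes[lab][config.donor_filter]) for lab in labels]

    sample_pairs = pairs(config.sample_rois)
    control_pairs = pairs(config.control_rois)
    result = quantify.cret_ratio_replicates(sample_pairs, control_pairs)

    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(flux_rows).to_csv(out / "roi_fluxes.csv", index=False)

    acq_meta = json.loads((acq_dir / "meta.json").read_text())
    record = {
        "acquisition": str(acq_dir),
        "input_hashes": {p.name: _sha256(p)
                         for p in sorted(acq_dir.glob("*.tif"))},
        "parameters": json.loads(config.model_dump_json()),
        "seed": acq_meta.get("seed"),
        "scenario": acq_meta.get("scenario"),
        "hot_pixels_corrected": corrected_coords,
        "roi_fluxes": roi_fluxes,
        "sample_ratios": [p.ratio for p in sample_pairs],
        "control_ratios": [p.ratio for p in control_pairs],
        "cret": {
            "sample_ratio": result.sample_ratio,
            "control_ratio": result.control_ratio,
            "cret_ratio": result.cret_ratio,
            "uncertainty_sem": result.uncertainty,
            "n": result.n,
            "n_control": result.n_control,
            "mean_of_differences": result.mean_of_differences,
            "sem_propagation": "root-sum-square of arm SEMs",
        },
    }
    (out / "cret_result.json").write_text(
        json.dumps(record, indent=2, sort_keys=True) + "\n")

    if config.acceptor_filter in images and config.donor_filter in images:
        ratio = quantify.ratio_image(images[config.acceptor_filter],
                                     images[config.donor_filter],
                                     config.ratio_floor)
        cret_img = quantify.calculated_cret_image(
            ratio, rois[config.control_rois[0]])
        tifffile.imwrite(out / "cret_image.tif",
                         cret_img.pixels.astype(np.float32))
    return record


def report_results(result_files: Sequence[str | Path],
                   trend_key: str = "concentration_nm") -> dict:
    """Summarize a set of quantification results.

    Collects CRET ratios, runs a Spearman monotonicity check of CRET
    against ``trend_key`` (read from each record's scenario metadata when
    present), and a pooled Student t test of sample vs control red/blue
    ratios across all records.
    """
    from scipy import stats

    records = [json.loads(Path(p).read_text()) for p in result_files]
    crets, trends = [], []
    sample_ratios, control_ratios = [], []
    for rec in records:
        crets.append(rec["cret"]["cret_ratio"])
        sample_ratios.extend(rec["sample_ratios"])
        control_ratios.extend(rec["control_ratios"])
        scenario = rec.get("scenario") or {}
        trend = rec.get(trend_key, scenario.get(trend_key))
        trends.append(trend)

    summary: dict = {
        "n_results": len(records),
        "cret_ratios": crets,
        "results": [str(p) for p in result_files],
    }
    if len(records) >= 3 and all(t is not None for t in trends):
        rho, p = stats.spearmanr(trends, crets)
        summary["monotonicity"] = {"trend_key": trend_key,
                                   "spearman_rho": float(rho),
                                   "p_value": float(p)}
    if len(sample_ratios) >= 2 and len(control_ratios) >= 2:
        t, p = quantify.two_sample_t(sample_ratios, control_ratios)
        summary["t_test_sample_vs_control"] = {"t": t, "p": p}
    return summary
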