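"""imzML reading/writing, artifact serialization, and the staged workflow.

Coordinates are 0-based (x, y) with origin top-left internally; imzML's
1-based convention is converted at the boundary.  CSV artifacts embed a hash
of the resolved run configuration on their first comment line so that
downstream stages can warn when mixing artifacts from different runs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .annotate import (
    AnnotationResult,
    annotate_fast,
    annotate_thorough,
)
from .chem import TheoreticalSpectrum, read_ion_library
from .deconv import DeconvolutionConfig, IonImage, deconvolve_dataset
from .segment import (
    SegmentationConfig,
    kmeans_threshold_segment,
    spatial_dgmm_segment,
)
from .spectra import MSIDataset, Spectrum, centroid_dataset, normalize_tic, restrict_mz

logger = logging.getLogger("otmsi")

__all__ = [
    "RunConfig",
    "read_imzml",
    "write_imzml",
    "write_ion_images_imzml",
    "write_proportions_csv",
    "read_proportions_csv",
    "run_workflow",
]


@dataclass
class RunConfig:
    """Resolved parameters of one workflow run (all stages)."""

    input_path: str | None = None
    output_dir: str = "otmsi_out"
    library_path: str | None = None
    mass_range: tuple[float, float] | None = (700.0, 900.0)
    normalize: bool = True
    centroid_height_fraction: float = 0.5
    centroid_max_width: float = 0.2
    centroid_noise_floor: float = 1e-6
    annotation_strategy: str = "thorough"  # or "fast"
    strict_kappa_mixture: float = 0.005
    strict_kappa_components: float = 0.01
    annotation_threshold: float = 1e-9
    kappa_mixture: float = 0.012
    kappa_components: float = 0.016
    min_pixels: int = 1
    image_scale: str = "tic"
    k: int = 2
    r: int = 3
    beta: float = 6.0
    seed: int = 0
    stop_after: str | None = None  # preprocess | annotate | deconvolve

    def resolved(self) -> dict:
        return asdict(self)

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.resolved(), sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


def read_imzml(path, mode: str | None = None) -> MSIDataset:
    """Read an imzML/ibd pair (continuous or processed, profile or centroid).

    ``mode`` overrides mode detection from the file metadata.
    """
    from pyimzml.ImzMLParser import ImzMLParser

    parser = ImzMLParser(str(path))
    if mode is None:
        # imzML declares the spectrum representation in its file description
        meta = getattr(parser, "metadata", None)
        mode = "profile"
        try:
            params = meta.file_description.param_by_name
            if "centroid spectrum" in params:
                mode = "centroid"
        except AttributeError:
            pass
    coords = parser.coordinates
    xs = [c[0] for c in coords]
    ys = [c[1] for c in coords]
    x0, y0 = min(xs), min(ys)
    pixels = []
    for i, (x, y, *_z) in enumerate(coords):
        mz, intensity = parser.getspectrum(i)
        mz = np.asarray(mz)
        intensity = np.asarray(intensity)
        if mz.size == 1 and mz[0] == 0.0 and intensity[0] == 0.0:
            # sentinel written by write_imzml for empty pixels
            mz, intensity = mz[:0], intensity[:0]
        pixels.append((x - x0, y - y0, Spectrum(mz, intensity, mode)))
    width = max(xs) - x0 + 1
    height = max(ys) - y0 + 1
    return MSIDataset(pixels, width, height, mode)


def write_imzml(ds: MSIDataset, path, layout: str = "continuous") -> None:
    """Write a dataset as an imzML/ibd pair.

    The continuous layout requires a shared m/z axis across pixels and errors
    otherwise; the processed layout stores per-pixel axes (zero-length arrays
    for empty pixels).
    """
    from pyimzml.ImzMLWriter import ImzMLWriter

    if layout not in ("continuous", "processed"):
        raise ValueError("layout must be 'continuous' or 'processed'")
    if layout == "continuous" and ds.pixels:
        grid = ds.pixels[0][2].mz
        for _, _, s in ds.pixels[1:]:
            if len(s) != grid.size or not np.allclose(s.mz, grid):
                raise ValueError("continuous layout requires a shared m/z axis")
    spec_type = "profile" if ds.mode == "profile" else "centroid"
    with ImzMLWriter(str(path), mode=layout, spec_type=spec_type) as writer:
        for x, y, s in ds.pixels:
            if len(s) == 0:
                # the imzML writer cannot store zero-length arrays; empty
                # pixels use a single zero-intensity sentinel point at m/z 0,
                # stripped again by read_imzml
                writer.addSpectrum(np.zeros(1), np.zeros(1), (x + 1, y + 1, 1))
            else:
                writer.addSpectrum(s.mz, s.intensity, (x + 1, y + 1, 1))


def write_ion_images_imzml(images: dict[str, IonImage], monos: dict[str, float], path) -> None:
    """Write deconvolved ion images as a centroid-mode processed imzML with
    one stick per ion at its monoisotopic m/z, readable by downstream tools."""
    from pyimzml.ImzMLWriter import ImzMLWriter

    labels = [lab for lab in images if lab in monos]
    mz = np.array([monos[lab] for lab in labels])
    order = np.argsort(mz)
    mz = mz[order]
    labels = [labels[i] for i in order]
    height, width = next(iter(images.values())).values.shape
    with ImzMLWriter(str(path), mode="processed", spec_type="centroid") as writer:
        for y in range(height):
            for x in range(width):
                intensity = np.array([images[lab].values[y, x] for lab in labels])
                writer.addSpectrum(mz, intensity, (x + 1, y + 1, 1))


def write_proportions_csv(
    images: dict[str, IonImage], path, config_hash: str = ""
) -> None:
    """Write the per-pixel proportion/signal table (x, y, one column per ion).

    Verifies at write time that per-pixel proportions plus the unexplained
    fraction sum to 1 where the table is on the proportion scale.
    """
    labels = [lab for lab in images if lab != "unexplained"]
    first = next(iter(images.values()))
    height, width = first.values.shape
    rows = {"x": [], "y": []}
    for lab in labels + (["unexplained"] if "unexplained" in images else []):
        rows[lab] = []
    for y in range(height):
        for x in range(width):
            if not first.mask[y, x]:
                continue
            rows["x"].append(x)
            rows["y"].append(y)
            for lab in labels:
                rows[lab].append(images[lab].values[y, x])
            if "unexplained" in images:
                rows["unexplained"].append(images["unexplained"].values[y, x])
    table = pd.DataFrame(rows)
    if "unexplained" in images:
        totals = table[labels + ["unexplained"]].sum(axis=1)
        # proportion-scale tables must sum to one; signal-scale tables sum to
        # the pixel TIC, so only a normalized table is checked
        if np.allclose(totals.max(), 1.0, atol=0.1) and not np.allclose(
            totals, 1.0, atol=1e-6
        ):
            warnings.warn("proportion rows do not sum to 1 within 1e-6")
    with open(path, "w") as fh:
        fh.write(f"# config_hash={config_hash}\n")
        table.to_csv(fh, index=False)


def read_proportions_csv(path, expected_hash: str | None = None) -> pd.DataFrame:
    with open(path) as fh:
        header = fh.readline()
        if expected_hash is not None and expected_hash not in header:
            warnings.warn(
                "proportion table was produced by a different configuration"
            )
        return pd.read_csv(fh)


def _write_annotation_csv(result: AnnotationResult, path, config_hash: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# config_hash={config_hash}\n")
        result.table.to_csv(fh, index=False)


def run_workflow(
    cfg: RunConfig,
    ds: MSIDataset | None = None,
    library: list[TheoreticalSpectrum] | None = None,
) -> dict:
    """Run the staged workflow: preprocess -> envelopes -> annotate ->
    deconvolve -> segment, writing Out1 (annotations), Out2 (ion images) and
    Out3 (segmentations) under ``cfg.output_dir``.

    ``ds``/``library`` may be passed in memory; otherwise they are read from
    ``cfg.input_path`` / ``cfg.library_path``.  Returns a dict of in-memory
    artifacts.  ``cfg.stop_after`` ends the run after the named stage.
    """
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = cfg.config_hash()
    (out / "config.json").write_text(
        json.dumps({"hash": chash, **cfg.resolved()}, indent=2, default=str)
    )
    artifacts: dict = {"config_hash": chash}

    if ds is None:
        if cfg.input_path is None:
            raise ValueError("no input dataset")
        ds = read_imzml(cfg.input_path)
    if library is None:
        if cfg.library_path is None:
            raise ValueError("no candidate-ion library")
        library = read_ion_library(cfg.library_path)

    # S1: preprocess
    stage = "preprocess"
    try:
        if ds.mode == "profile":
            if cfg.normalize:
                ds = ds.map_spectra(normalize_tic)
            if cfg.mass_range is not None:
                lo, hi = cfg.mass_range
                ds = ds.map_spectra(lambda s: restrict_mz(s, lo, hi))
            cds = centroid_dataset(
                ds,
                cfg.centroid_height_fraction,
                cfg.centroid_max_width,
                cfg.centroid_noise_floor,
            )
        else:
            cds = ds
            if cfg.mass_range is not None:
                lo, hi = cfg.mass_range
                cds = cds.map_spectra(lambda s: restrict_mz(s, lo, hi))
        logger.info("S1 preprocess: %d pixels, mode=%s", len(cds), cds.mode)
        artifacts["preprocessed"] = cds
    except Exception as exc:  # pragma: no cover - stage attribution
        raise RuntimeError(f"workflow failed at stage {stage}: {exc}") from exc
    if cfg.stop_after == "preprocess":
        return artifacts

    # S2 envelopes are the library itself (already TheoreticalSpectrum);
    # S3: annotate
    stage = "annotate"
    strict = DeconvolutionConfig(cfg.strict_kappa_mixture, cfg.strict_kappa_components)
    if cfg.annotation_strategy == "fast":
        ann = annotate_fast(cds, library, strict)
    elif cfg.annotation_strategy == "thorough":
        ann = annotate_thorough(
            cds, library, strict, threshold=cfg.annotation_threshold, seed=cfg.seed
        )
    else:
        raise RuntimeError(f"workflow failed at stage {stage}: unknown strategy")
    _write_annotation_csv(ann, out / "out1_annotations.csv", chash)
    logger.info(
        "S3 annotate (%s): %d/%d ions detected",
        cfg.annotation_strategy,
        len(ann.detected_labels),
        len(library),
    )
    artifacts["annotation"] = ann
    if cfg.stop_after == "annotate":
        return artifacts

    # S4: deconvolve with quantification kappas, then the spatial filter
    detected = [c for c in library if c.label in set(ann.detected_labels)]
    quant = DeconvolutionConfig(cfg.kappa_mixture, cfg.kappa_components)
    images = deconvolve_dataset(cds, detected, quant, scale=cfg.image_scale)
    kept = [
        lab
        for lab in (c.label for c in detected)
        if int(np.count_nonzero(images[lab].values > 0)) >= cfg.min_pixels
    ]
    images = {
        lab: img
        for lab, img in images.items()
        if lab in kept or lab == "unexplained"
    }
    write_proportions_csv(images, out / "out2_ion_images.csv", chash)
    logger.info("S4 deconvolve: %d ions kept after min_pixels=%d", len(kept), cfg.min_pixels)
    artifacts["images"] = images
    if cfg.stop_after == "deconvolve":
        return artifacts

    # S5: segment each kept ion image
    seg_cfg = SegmentationConfig(k=cfg.k, r=cfg.r, beta=cfg.beta)
    segmentations = {}
    rows = []
    for lab in kept:
        naive = kmeans_threshold_segment(images[lab], k=cfg.k, seed=cfg.seed)
        aware = spatial_dgmm_segment(images[lab], seg_cfg, seed=cfg.seed)
        segmentations[lab] = {"naive": naive, "aware": aware}
        h, w = aware.labels.shape
        for y in range(h):
            for x in range(w):
                rows.append(
                    {
                        "ion": lab,
                        "x": x,
                        "y": y,
                        "label": int(aware.labels[y, x]),
                        "posterior_high": float(aware.posteriors[y, x, -1]),
                    }
                )
    with open(out / "out3_segmentation.csv", "w") as fh:
        fh.write(f"# config_hash={chash}\n")
        pd.DataFrame(rows).to_csv(fh, index=False)
    logger.info("S5 segment: %d ions segmented (k=%d, r=%d, beta=%g)", len(kept), cfg.k, cfg.r, cfg.beta)
    artifacts["segmentations"] = segmentations
    return artifacts
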