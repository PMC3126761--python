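"""Batch orchestration: run the full metrology over image sets and report.

`run_porometry` processes a list of micrographs through preprocessing,
segmentation and radius measurement, and pools the per-image samples into
one distribution (pooling concatenates radius samples, so images are
weighted by their sample counts — the frequency definition is
per-measurement, not per-image). `run_interface` does the same with a
cell mask per image and produces a pooled depth profile. Both are
deterministic given the configuration, and every emitted file embeds the
config hash and package version.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import __version__
from .config import PipelineConfig
from .errors import InvalidParameterError, PoremetryError
from .interface_profile import DepthProfile, interface_distance_map, profile_by_depth
from .porometry import (BinnedDistribution, RadiusSampleSet, bin_values,
                        distance_transform, extract_skeleton, measure_radii)
from .preprocess import CalibratedImage, preprocess, read_image
from .segment import exclude_region, segment

logger = logging.getLogger(__name__)


def _run_single(img: CalibratedImage, cfg: PipelineConfig, phase: str = "pore",
                exclude: np.ndarray | None = None) -> RadiusSampleSet:
    pre = preprocess(
        img, background_scale_px=cfg.background_scale_px, tv_weight=cfg.tv_weight,
        tv_max_iter=cfg.tv_max_iter, tv_tol=cfg.tv_tol,
        shock_sigma_px=cfg.shock_sigma_px, shock_rho_px=cfg.shock_rho_px,
        shock_n_iter=cfg.shock_n_iter, shock_dt=cfg.shock_dt)
    pm = segment(pre, method=cfg.threshold_method, threshold=cfg.threshold,
                 polarity=cfg.polarity, min_lumen_area_nm2=cfg.min_lumen_area_nm2)
    if exclude is not None:
        pm = exclude_region(pm, exclude)
    dmap = distance_transform(pm, phase)
    skeleton = extract_skeleton(dmap, pm)
    return measure_radii(dmap, skeleton)


def measure_image(img: CalibratedImage, cfg: PipelineConfig, phase: str = "pore",
                  exclude: np.ndarray | None = None) -> RadiusSampleSet:
    """Full chain on one in-memory image: preprocess, segment, measure.

    ``exclude`` (e.g. a cell-body mask) is removed from the matrix before
    measurement, so radii are measured to the remaining alginate only.
    """
    return _run_single(img, cfg, phase, exclude)


@dataclass(frozen=True)
class PorometryReport:
    per_image: dict[str, BinnedDistribution]
    pooled: BinnedDistribution
    pooled_samples_nm: np.ndarray
    n_failed: int
    config_hash: str


def run_porometry(images, cfg: PipelineConfig, phase: str = "pore",
                  out_dir=None) -> PorometryReport:
    """Measure a batch of micrograph files and pool their distributions."""
    images = list(images)
    if not images:
        raise InvalidParameterError("need at least one image")
    per_image: dict[str, BinnedDistribution] = {}
    pooled: list[np.ndarray] = []
    n_failed = 0
    for path in images:
        try:
            img = read_image(path, cfg.pixel_pitch_nm)
            samples = _run_single(img, cfg, phase)
            per_image[str(path)] = bin_values(samples.radii_nm, cfg.bin_scheme)
            pooled.append(samples.radii_nm)
        except (PoremetryError, OSError) as exc:
            n_failed += 1
            logger.error("skipping %s: %s", path, exc)
    if not pooled:
        raise PoremetryError("all input images failed to process")
    all_nm = np.concatenate(pooled)
    report = PorometryReport(per_image=per_image,
                             pooled=bin_values(all_nm, cfg.bin_scheme),
                             pooled_samples_nm=all_nm, n_failed=n_failed,
                             config_hash=cfg.config_hash())
    if out_dir is not None:
        _write_porometry(report, cfg, out_dir)
    return report


@dataclass(frozen=True)
class InterfaceReport:
    per_image: dict[str, DepthProfile]
    pooled: DepthProfile
    n_failed: int
    config_hash: str


def run_interface(images, cell_masks, cfg: PipelineConfig,
                  out_dir=None) -> InterfaceReport:
    """Depth-profile a batch of (micrograph, cell mask) pairs and pool them."""
    images, cell_masks = list(images), list(cell_masks)
    if not images or len(images) != len(cell_masks):
        raise InvalidParameterError("need equally many images and cell masks")
    per_image: dict[str, DepthProfile] = {}
    pooled_radii, pooled_depth = [], []
    n_failed = 0
    for img_path, mask_path in zip(images, cell_masks):
        try:
            img = read_image(img_path, cfg.pixel_pitch_nm)
            cell = np.asarray(read_image(mask_path, cfg.pixel_pitch_nm).pixels) > 0
            if cell.shape != img.shape:
                raise InvalidParameterError(
                    f"mask {mask_path} and image {img_path} dimensions differ")
            samples = _run_single(img, cfg, exclude=cell)
            idmap = interface_distance_map(cell, cfg.pixel_pitch_nm)
            inside_cell = cell[tuple(samples.coords.T)]
            samples = RadiusSampleSet(
                phase=samples.phase, radii_px=samples.radii_px[~inside_cell],
                coords=samples.coords[~inside_cell],
                pixel_pitch_nm=samples.pixel_pitch_nm)
            per_image[str(img_path)] = profile_by_depth(
                samples, idmap, cfg.depth_edges_nm, cfg.bin_scheme,
                cfg.n_min_per_depth)
            depth = idmap.values[tuple(samples.coords.T)] * cfg.pixel_pitch_nm
            pooled_radii.append(samples.radii_nm)
            pooled_depth.append(depth)
        except (PoremetryError, OSError) as exc:
            n_failed += 1
            logger.error("skipping pair (%s, %s): %s", img_path, mask_path, exc)
    if not pooled_radii:
        raise PoremetryError("all image/mask pairs failed to process")
    pooled = pool_depth_profiles(np.concatenate(pooled_radii),
                                 np.concatenate(pooled_depth), cfg)
    report = InterfaceReport(per_image=per_image, pooled=pooled,
                             n_failed=n_failed, config_hash=cfg.config_hash())
    if out_dir is not None:
        _write_interface(report, cfg, out_dir)
    return report


def pool_depth_profiles(radii_nm: np.ndarray, depth_nm: np.ndarray,
                        cfg: PipelineConfig) -> DepthProfile:
    """Build a DepthProfile from already-paired (radius, depth) samples."""
    from .porometry import DistanceMap

    n = radii_nm.size
    fake = DistanceMap(values=depth_nm.reshape(1, -1) / cfg.pixel_pitch_nm,
                       pixel_pitch_nm=cfg.pixel_pitch_nm, phase="interface")
    samples = RadiusSampleSet(
        phase="pore", radii_px=radii_nm / cfg.pixel_pitch_nm,
        coords=np.column_stack([np.zeros(n, int), np.arange(n)]),
        pixel_pitch_nm=cfg.pixel_pitch_nm)
    return profile_by_depth(samples, fake, cfg.depth_edges_nm, cfg.bin_scheme,
                            cfg.n_min_per_depth)


# ---------------------------------------------------------------------------
# Serialization of reports


def _dist_record(d: BinnedDistribution) -> dict:
    return {"bin_edges_nm": list(d.bin_edges_nm), "labels": d.labels,
            "percent": [round(float(p), 4) for p in d.percent],
            "n_samples": d.n_samples}


def _meta(cfg: PipelineConfig) -> dict:
    return {"poremetry_version": __version__, "config_hash": cfg.config_hash(),
            "config": cfg.to_dict()}


def _write_porometry(report: PorometryReport, cfg: PipelineConfig, out_dir) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    payload = _meta(cfg)
    payload["pooled"] = _dist_record(report.pooled)
    payload["per_image"] = {k: _dist_record(v) for k, v in report.per_image.items()}
    payload["n_failed"] = report.n_failed
    (out / "porometry.json").write_text(json.dumps(payload, indent=1, default=list))
    with open(out / "porometry_pooled.csv", "w") as fh:
        fh.write(f"# poremetry {__version__} config {cfg.config_hash()}\n")
        fh.write("bin,percent,n_samples\n")
        for lab, pct in zip(report.pooled.labels, report.pooled.percent):
            fh.write(f"{lab},{pct:.4f},{report.pooled.n_samples}\n")
    with open(out / "porometry_samples.csv", "w") as fh:
        fh.write(f"# poremetry {__version__} config {cfg.config_hash()}\n")
        fh.write("radius_nm\n")
        for r in report.pooled_samples_nm:
            fh.write(f"{r:.4f}\n")
    try:
        _plot_distribution(report.pooled, out / "porometry_pooled.png")
    except Exception as exc:  # plotting must never fail a batch
        logger.warning("could not render chart: %s", exc)


def _write_interface(report: InterfaceReport, cfg: PipelineConfig, out_dir) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    payload = _meta(cfg)
    payload["pooled"] = _profile_record(report.pooled)
    payload["per_image"] = {k: _profile_record(v) for k, v in report.per_image.items()}
    payload["n_failed"] = report.n_failed
    (out / "interface.json").write_text(json.dumps(payload, indent=1, default=list))
    with open(out / "interface_pooled.csv", "w") as fh:
        fh.write(f"# poremetry {__version__} config {cfg.config_hash()}\n")
        fh.write("depth_bin_nm,rpr_bin,percent,n\n")
        prof = report.pooled
        for i, d in enumerate(prof.per_depth):
            lo, hi = prof.depth_edges_nm[i], prof.depth_edges_nm[i + 1]
            if d is None:
                continue
            for lab, pct in zip(d.labels, d.percent):
                fh.write(f"{lo:g}-{hi:g},{lab},{pct:.4f},{d.n_samples}\n")


def _profile_record(p: DepthProfile) -> dict:
    return {"depth_edges_nm": list(p.depth_edges_nm),
            "n_per_depth": [int(n) for n in p.n_per_depth],
            "low_confidence": [bool(b) for b in p.low_confidence],
            "per_depth": [None if d is None else _dist_record(d)
                          for d in p.per_depth]}


def _plot_distribution(dist: BinnedDistribution, path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 3.5))
    ax.bar(range(len(dist.percent)), dist.percent, color="#4878a8")
    ax.set_xticks(range(len(dist.percent)))
    ax.set_xticklabels(dist.labels, rotation=30, ha="right", fontsize=8)
    ax.set_ylabel("frequency (%)")
    ax.set_xlabel("radius class (nm)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
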