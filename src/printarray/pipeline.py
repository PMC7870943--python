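"""End-to-end orchestration: simulate -> segment -> geometry -> SI -> metrics.

A run is described by a single YAML-serialisable config; every stage
writes its outputs (TIFF masks, CSV tables, JSON summaries) into the
run directory together with a provenance manifest (config hash, seed,
library versions), so a run can be reproduced bit-for-bit for the
deterministic stages.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from . import __version__
from .ecolmetrics import AbundanceRecord, frequency
from .printgeom import (
    SQUARE_RADIUS_CONSTANT, PrintGeometry, estimate_side_length,
    isolate_print, neighbour_distances, register_print,
)
from .segment2d import Segment2DParams, extract_colony_features, segment_microcolonies_2d
from .segregation import PAPER_SPANS_PX, assign_pixel_genotypes, compare_to_reference, si_profile
from .synthgen import (
    GrowthParams, Micrograph, NoiseParams, make_printing_map, render_scene,
)

logger = logging.getLogger("printarray")

__all__ = ["RunConfig", "run_pipeline", "save_micrograph", "load_micrograph"]


def save_micrograph(img: Micrograph, path: str | Path) -> None:
    """Write a two-channel micrograph as a (2, y, x) float32 TIFF."""
    data = np.stack(img.channels).astype(np.float32)
    tifffile.imwrite(path, data, metadata={"pixel_size_um": img.pixel_size})


def load_micrograph(path: str | Path, pixel_size: float | None = None) -> Micrograph:
    """Read a two-channel TIFF; pixel size from metadata unless overridden."""
    with tifffile.TiffFile(path) as tf:
        data = tf.asarray()
        meta = tf.shaped_metadata or ()
        if pixel_size is None:
            for m in meta:
                if "pixel_size_um" in m:
                    pixel_size = float(m["pixel_size_um"])
                    break
    if pixel_size is None:
        raise ValueError(f"{path}: no pixel size in metadata; pass pixel_size")
    if data.ndim != 3 or data.shape[0] < 2:
        raise ValueError(f"{path}: expected a (2, y, x) two-channel image")
    return Micrograph(channels=(data[0], data[1]), pixel_size=pixel_size)


@dataclass
class RunConfig:
    """Parameters of one pipeline run (all stages)."""

    seed: int = 0
    out_dir: str = "run"
    # simulate stage
    n_x: int = 7
    n_y: int = 8
    pattern: str = "segregated-halves"
    mix_fraction: float = 0.5
    strip_widths: list | None = None
    rotation_deg: float = 0.0
    n_debris: int = 0
    pixel_size_um: float = 1.515
    growth: dict = field(default_factory=dict)
    noise: dict = field(default_factory=dict)
    # optional pre-existing image instead of simulation
    input_image: str | None = None
    # segmentation stage
    segment2d: dict = field(default_factory=dict)
    # geometry stage
    margin_factor: float = 1.15
    n_angles: int = 360
    # SI stage
    spans_px: list = field(default_factory=lambda: list(PAPER_SPANS_PX))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls(**(yaml.safe_load(Path(path).read_text()) or {}))

    def to_yaml_str(self) -> str:
        return yaml.safe_dump(asdict(self), sort_keys=True)


def run_pipeline(config: RunConfig) -> Path:
    """Execute every stage and return the run directory.

    Stages: simulate (or load), 2D segmentation + features, print
    geometry (isolation, registration, neighbour distances), SI profile
    with reference comparison, and frequency from genotype areas.
    Failures abort with the failing stage named; outputs already
    written are retained.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "setup"
    manifest = {
        "seed": config.seed,
        "config_sha256": hashlib.sha256(
            config.to_yaml_str().encode()
        ).hexdigest(),
        "versions": {
            "printarray": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "stages": [],
    }
    try:
        # -- simulate / load ------------------------------------------------
        stage = "simulate"
        pmap = make_printing_map(
            config.n_x, config.n_y, config.pattern,
            mix_fraction=config.mix_fraction,
            strip_widths=config.strip_widths,
        )
        if config.input_image:
            img = load_micrograph(config.input_image,
                                  pixel_size=config.pixel_size_um)
            scene = None
        else:
            scene = render_scene(
                pmap,
                GrowthParams(**config.growth),
                NoiseParams(**config.noise),
                rotation=config.rotation_deg,
                n_debris=config.n_debris,
                seed=config.seed,
                pixel_size=config.pixel_size_um,
            )
            img = scene.image
            save_micrograph(img, out / "scene.tiff")
            scene.colonies.to_csv(out / "ground_truth.csv", index=False)
            pmap.to_json(out / "printing_map.json")
        logger.info("simulate: %d x %d %s print rendered", config.n_x,
                    config.n_y, config.pattern)
        manifest["stages"].append("simulate")

        # -- 2D segmentation ------------------------------------------------
        stage = "segment2d"
        mask = segment_microcolonies_2d(img, Segment2DParams(**config.segment2d))
        table = extract_colony_features(mask, img)
        tifffile.imwrite(out / "labels.tiff", mask.labels.astype(np.uint16))
        table.to_csv(out / "colonies.csv", index=False)
        logger.info("segment2d: %d microcolonies", len(table))
        manifest["stages"].append("segment2d")

        # -- print geometry -------------------------------------------------
        stage = "geometry"
        kept, centre = isolate_print(table, config.margin_factor)
        theta, registered, extent = register_print(kept, centre,
                                                   config.n_angles)
        L = estimate_side_length(kept, centre)
        geom = PrintGeometry(
            centre=centre,
            mean_radius=L * SQUARE_RADIUS_CONSTANT,
            side_length=L,
            rotation_deg=theta,
            registered_extent=extent,
        )
        graph = neighbour_distances(kept)
        (out / "geometry.json").write_text(json.dumps(geom.to_dict(), indent=1))
        pd.DataFrame({
            "i": graph.edges[:, 0], "j": graph.edges[:, 1],
            "distance_um": graph.distances,
        }).to_csv(out / "neighbour_edges.csv", index=False)
        registered.to_csv(out / "colonies_registered.csv", index=False)
        logger.info("geometry: theta=%.2f deg, %d colonies kept", theta,
                    len(kept))
        manifest["stages"].append("geometry")

        # -- segregation index ----------------------------------------------
        stage = "si"
        gmask = assign_pixel_genotypes(img)
        profile = si_profile(gmask, spans_px=config.spans_px)
        profile.to_frame().to_csv(out / "si_profile.csv", index=False)
        paired, max_dev = compare_to_reference(
            profile, pmap, pixel_size=img.pixel_size, seed=config.seed
        )
        paired.to_csv(out / "si_vs_reference.csv", index=False)
        logger.info("si: SI(max span)=%.3f, max |dSI| vs reference=%.3f",
                    profile.si[-1], max_dev)
        manifest["stages"].append("si")

        # -- outcome metrics ------------------------------------------------
        stage = "metrics"
        areas = gmask.genotype_areas()
        result = frequency(
            AbundanceRecord("A", areas["A"], "area_um2"),
            AbundanceRecord("B", areas["B"], "area_um2"),
        )
        report = {
            "frequencies": result.frequencies,
            "areas_um2": areas,
            "si_profile": {
                "span_um": profile.spans_um.tolist(),
                "si": profile.si.tolist(),
            },
            "max_si_deviation_vs_reference": max_dev,
            "rotation_deg": theta,
        }
        (out / "report.json").write_text(json.dumps(report, indent=1))
        logger.info("metrics: f_A=%.3f", result.frequencies["A"])
        manifest["stages"].append("metrics")
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    finally:
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
        (out / "config.yaml").write_text(config.to_yaml_str())
    return out
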