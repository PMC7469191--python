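"""One-call orchestration of the full image → FE-model flow.

``run_pipeline`` chains: image loading → region detection → distance /
sizing / fixed-point construction → mesh generation → section
assignment → discontinuity excision → optional corrugation → .inp
export, and writes a JSON report plus the effective configuration next
to the outputs so every run is reproducible.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import corrugation, distance_field, export_inp, mesher, region_detect
from .errors import FrameMismatchError, WingforgeError
from .image_io import PixelImage, check_same_frame, load_image

log = logging.getLogger("wingforge")

__all__ = ["RunConfig", "PipelineResult", "run_pipeline", "load_config"]


@dataclass
class RunConfig:
    """Every user-settable parameter of the pipeline.

    Paths may be None when the corresponding in-memory object is passed
    to :func:`run_pipeline` directly (as the test-suite does).
    """

    image: str | None = None
    subdomain_seeds: list[tuple[int, int]] = field(default_factory=list)
    hole_seeds: list[tuple[int, int]] = field(default_factory=list)
    threshold: float = 0.5
    # meshing
    h0: float = 8.0
    sizing: str = "uniform"
    grading: float = 0.3
    spacing: float | None = None  # fixed-point thinning; default = h0
    max_iter: int = 2000
    rng_seed: int = 0
    # corrugation
    height_image: str | None = None
    iterations: int = 100
    amplitude: float | None = None
    constrain: bool = True
    constraint_mask: str | None = None
    # export
    materials: list[list] = field(default_factory=list)
    scale: float = 1.0
    output: str = "model.inp"
    report: str | None = None

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, default=str)


def load_config(path) -> RunConfig:
    """Read a RunConfig from a TOML or JSON file."""
    text = Path(path).read_text()
    if str(path).endswith(".json"):
        data = json.loads(text)
    else:
        import tomllib

        data = tomllib.loads(text)
    return RunConfig(**data)


@dataclass
class PipelineResult:
    mesh: mesher.TriMesh
    region: region_detect.RegionMap
    deck_text: str
    report: dict


def _stage(name: str):
    log.info("stage: %s", name)
    return time.perf_counter()


def run_pipeline(
    config: RunConfig,
    image: PixelImage | None = None,
    height_image: PixelImage | None = None,
) -> PipelineResult:
    """Execute the full flow; any stage error is re-raised with the
    stage name and a remediation hint attached."""
    stage = "load"
    try:
        t0 = _stage(stage)
        if image is None:
            image = load_image(config.image, mode="binary", threshold=config.threshold)
        if height_image is None and config.height_image:
            height_image = load_image(config.height_image, mode="continuous")
        if height_image is not None and not check_same_frame(image, height_image):
            raise FrameMismatchError(
                f"height image frame {height_image.shape} differs from "
                f"primary image frame {image.shape}"
            )

        stage = "detect_regions"
        _stage(stage)
        seeds = region_detect.SeedSpec(
            subdomain_seeds=tuple(map(tuple, config.subdomain_seeds)),
            hole_seeds=tuple(map(tuple, config.hole_seeds)),
        )
        region = region_detect.detect_regions(image, seeds)

        stage = "distance_field"
        _stage(stage)
        dfield = distance_field.build_signed_distance(region)
        sizing = distance_field.build_sizing(
            region, mode=config.sizing, h0=config.h0,
            grading=config.grading, dfield=dfield,
        )
        dfield = dfield.with_sizing(sizing)
        spacing = config.spacing if config.spacing is not None else config.h0
        interface_pts = distance_field.select_fixed_points(region, spacing=spacing)
        boundary_pts = distance_field.select_boundary_fixed_points(
            region, spacing=spacing, avoid=interface_pts
        )
        pfix = distance_field.combine_fixed_points(
            interface_pts, boundary_pts, spacing
        )

        stage = "generate_mesh"
        _stage(stage)
        params = mesher.MeshParams(
            h0=config.h0, max_iter=config.max_iter, rng_seed=config.rng_seed
        )
        mesh = mesher.generate_mesh(dfield, pfix, params)

        stage = "assign_sections"
        _stage(stage)
        mesh = mesher.assign_sections(mesh, region)
        n_before = mesh.n_triangles
        mesh = mesher.remove_hole_elements(mesh, region)
        removed = n_before - mesh.n_triangles

        if height_image is not None:
            stage = "corrugation"
            _stage(stage)
            mask = None
            if config.constraint_mask:
                mask = load_image(config.constraint_mask, mode="binary").values == 0
            hmap = corrugation.smooth_heightmap(
                height_image,
                iterations=config.iterations,
                constrain=config.constrain,
                constraint_mask=mask,
                amplitude=config.amplitude,
            )
            mesh = corrugation.apply_heights(mesh, hmap)

        stage = "export"
        _stage(stage)
        mats = [export_inp.MaterialSpec(m[0], *map(float, m[1:])) for m in config.materials]
        out = Path(config.output)
        out.parent.mkdir(parents=True, exist_ok=True)
        deck_text = export_inp.write_inp(mesh, materials=mats, path=out, scale=config.scale)

        q = mesher.triangle_quality(mesh)
        sections, counts = np.unique(mesh.section_of, return_counts=True)
        report = {
            "n_nodes": mesh.n_nodes,
            "n_elements": mesh.n_triangles,
            "n_subdomains": region.n_subdomains,
            "n_holes": region.n_holes,
            "elements_per_section": {int(s): int(c) for s, c in zip(sections, counts)},
            "removed_hole_elements": int(removed),
            "quality_min": float(q.min()),
            "quality_median": float(np.median(q)),
            "converged": bool(mesh.converged),
            "iterations": int(mesh.n_iterations),
            "corrugated": height_image is not None,
            "elapsed_s": round(time.perf_counter() - t0, 3),
        }
        report_path = Path(config.report) if config.report else out.with_suffix(".report.json")
        report_path.write_text(json.dumps(report, indent=2) + "\n")
        out.with_suffix(".config.json").write_text(config.to_json() + "\n")
        return PipelineResult(mesh=mesh, region=region, deck_text=deck_text, report=report)
    except WingforgeError as exc:
        raise WingforgeError(
            f"pipeline stage '{stage}' failed: {exc} "
            "(check seeds, border closure, and frame sizes)"
        ) from exc
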