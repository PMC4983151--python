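"""End-to-end orchestration of the analysis stages.

Stages: load inputs -> assign endpoints -> triangle count fields ->
hemisphere coverage -> CC segmentation -> streamline segment passage ->
17-network involvement -> vulnerability profiles (17 then 7 networks) ->
run manifest.  All outputs are deterministic functions of the inputs.
"""

from __future__ import annotations

import csv
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Optional, Sequence, Tuple

import numpy as np

from . import __version__
from . import io_formats as io
from .callosotomy import DEFAULT_K, segment_cc, streamline_segments
from .errors import ValidationError
from .networks import (
    callosotomy_profile,
    default_mapping_path,
    downsample_17_to_7,
    network_involvement,
    spearman_reproducibility,
)
from .surface_mapping import (
    assign_endpoints,
    hemisphere_coverage,
    triangle_counts,
)

log = logging.getLogger("transcallosal")

DEFAULT_EXTENTS = (0.2, 0.4, 0.6, 0.8, 1.0)


@dataclass
class PipelineConfig:
    """Inputs, knobs and output location of one full analysis run."""

    surface_left: Path
    surface_right: Path
    tractogram: Path
    mask: Path
    labels_left: Path
    labels_right: Path
    out_dir: Path
    mapping: Optional[Path] = None
    k: int = DEFAULT_K
    extents: Sequence[float] = DEFAULT_EXTENTS
    rule: str = "median"
    area_weighted: bool = False
    max_distance_mm: Optional[float] = None
    seed: int = 0

    def __post_init__(self):
        for name in ("surface_left", "surface_right", "tractogram",
                     "mask", "labels_left", "labels_right", "out_dir"):
            setattr(self, name, Path(getattr(self, name)))
        if self.mapping is not None:
            self.mapping = Path(self.mapping)
        for j in (round(e * self.k) for e in self.extents):
            if not 0 <= j <= self.k:
                raise ValidationError(
                    f"extents {list(self.extents)} inconsistent with k={self.k}"
                )


def load_pipeline_config(path, **overrides) -> PipelineConfig:
    """Read a flat key-value TOML config; keyword overrides win."""
    import tomllib

    with open(path, "rb") as fh:
        data = tomllib.load(fh)
    data.update({k: v for k, v in overrides.items() if v is not None})
    return PipelineConfig(**data)


def _load_inputs(config: PipelineConfig):
    surfaces = (
        io.read_surface(config.surface_left, "left"),
        io.read_surface(config.surface_right, "right"),
    )
    tractogram = io.read_tractogram(config.tractogram)
    mask = io.read_mask(config.mask)
    labels = (
        io.read_labels(config.labels_left),
        io.read_labels(config.labels_right),
    )
    return surfaces, tractogram, mask, labels


def run_full_analysis(config: PipelineConfig) -> Dict[str, Path]:
    """Run every stage and write the output bundle; returns output paths."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: Dict[str, Path] = {}

    surfaces, tractogram, mask, labels = _load_inputs(config)
    log.info(
        "stage=load streamlines=%d triangles=%d+%d mask_voxels=%d",
        tractogram.n_streamlines, surfaces[0].n_triangles,
        surfaces[1].n_triangles, mask.n_voxels,
    )

    assignment = assign_endpoints(
        tractogram, surfaces, max_distance_mm=config.max_distance_mm
    )
    log.info(
        "stage=assign endpoints=%d assigned=%d",
        assignment.n_endpoints, assignment.n_assigned,
    )
    paths["assignment"] = out / "endpoint_assignment.csv"
    with open(paths["assignment"], "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["streamline", "end", "vertex", "distance_mm"])
        for s, e, v, d in zip(assignment.streamline_index, assignment.end,
                              assignment.vertex, assignment.distance):
            writer.writerow([s, "first" if e == 0 else "last", v, f"{d:.6f}"])

    fields = tuple(triangle_counts(assignment, surf) for surf in surfaces)
    for surf, fld in zip(surfaces, fields):
        key = f"field_{surf.hemisphere}"
        paths[key] = out / f"triangle_field_{surf.hemisphere}.csv"
        with open(paths[key], "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["triangle", "n", "log1p"])
            for i, n in enumerate(fld.n):
                writer.writerow([i, int(n), f"{np.log1p(n):.6f}"])

    paths["coverage"] = out / "coverage.csv"
    with open(paths["coverage"], "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["hemisphere", "coverage"])
        for surf, fld in zip(surfaces, fields):
            cov = hemisphere_coverage(
                fld, surf, area_weighted=config.area_weighted, rule=config.rule
            )
            writer.writerow([surf.hemisphere, f"{cov:.6f}"])
    log.info("stage=coverage done")

    segmentation = segment_cc(mask, config.k)
    io.write_label_volume(
        segmentation.segment_of_voxel, mask, out / "cc_segments.nii.gz"
    )
    paths["cc_segments"] = out / "cc_segments.nii.gz"
    segments = streamline_segments(tractogram, segmentation, mask)
    log.info(
        "stage=segment k=%d non_callosal=%d",
        config.k, segments.n_non_callosal,
    )
    paths["segments"] = out / "streamline_segments.csv"
    with open(paths["segments"], "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["streamline", "segments", "anterior_most"])
        for i, (segs, ant) in enumerate(
            zip(segments.segment_sets, segments.anterior_most)
        ):
            writer.writerow([i, " ".join(map(str, sorted(segs))), int(ant)])

    involvement = network_involvement(fields, labels, rule=config.rule)
    paths["involvement"] = out / "network_involvement.csv"
    with open(paths["involvement"], "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["network", "involvement"])
        for net, val in involvement.items():
            writer.writerow([net, f"{val:.6f}"])
    log.info("stage=involvement networks=%d", len(involvement))

    profile17 = callosotomy_profile(
        assignment, segments, labels, surfaces, config.extents,
        rule=config.rule,
    )
    paths["profile_17"] = out / "profile_17.csv"
    io.write_profile(profile17, paths["profile_17"])

    mapping_path = config.mapping or default_mapping_path()
    mapping = io.read_mapping(mapping_path)
    if set(mapping.network17.tolist()) <= set(
        int(n) for n in profile17.networks
    ):
        profile7 = downsample_17_to_7(profile17, mapping)
        paths["profile_7"] = out / "profile_7.csv"
        io.write_profile(profile7, paths["profile_7"])
    else:
        log.info("stage=downsample skipped (profile does not cover mapping)")
    log.info("stage=profile extents=%s", list(config.extents))

    manifest = {
        "package_version": __version__,
        "python": sys.version.split()[0],
        "numpy": np.__version__,
        "seed": config.seed,
        "parameters": {
            "k": config.k,
            "extents": list(config.extents),
            "rule": config.rule,
            "area_weighted": config.area_weighted,
            "max_distance_mm": config.max_distance_mm,
        },
        "inputs": {
            "surface_left": str(config.surface_left),
            "surface_right": str(config.surface_right),
            "tractogram": str(config.tractogram),
            "mask": str(config.mask),
            "labels_left": str(config.labels_left),
            "labels_right": str(config.labels_right),
            "mapping": str(mapping_path),
        },
        "counts": {
            "streamlines": tractogram.n_streamlines,
            "endpoints_assigned": assignment.n_assigned,
            "non_callosal_excluded": segments.n_non_callosal,
        },
    }
    paths["manifest"] = out / "manifest.json"
    paths["manifest"].write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return paths


def triangle_count_vector(assignment, surfaces) -> np.ndarray:
    """Concatenated per-triangle median counts (left then right)."""
    return np.concatenate(
        [triangle_counts(assignment, surf).n for surf in surfaces]
    )


def run_reproducibility(bundle_a, bundle_b):
    """Spearman correlation of per-triangle counts from two sessions.

    Both bundles must share one surface/label geometry (equal triangle
    counts); each bundle's tractogram is mapped onto its own surfaces and
    the two concatenated per-triangle count vectors are correlated.
    """
    from .synthetic import load_bundle

    counts = []
    n_triangles = None
    for bundle in (bundle_a, bundle_b):
        surfaces, _mask, _labels, tractogram, _gt = load_bundle(bundle)
        total = surfaces[0].n_triangles + surfaces[1].n_triangles
        if n_triangles is None:
            n_triangles = total
        elif total != n_triangles:
            raise ValidationError(
                "bundles have mismatched triangle counts "
                f"({n_triangles} vs {total})"
            )
        assignment = assign_endpoints(tractogram, surfaces)
        counts.append(triangle_count_vector(assignment, surfaces))
    return spearman_reproducibility(counts[0], counts[1])
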