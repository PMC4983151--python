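"""Synthetic input bundles with planted ground truth, plus a toy tracker.

The generator builds two deformed-sphere hemisphere meshes flanking a
midline corpus-callosum slab, a contiguous longitude-band network
parcellation, and a tractogram in which every streamline runs from a
left-surface vertex through one CC position to a right-surface vertex.
Termination vertices are drawn with para-sagittal concentration
(density proportional to ``exp(-d_midline^2 / 2 sigma^2)``, with the
left-hemisphere spread scaled by the asymmetry ratio), and each
streamline's CC passage position follows its network's anterior-posterior
distribution.  Every downstream quantity - hemisphere coverage, network
involvement, disruption curves - is recorded as ground truth from the
realised per-streamline draws.

``track_streamlines`` is a deliberately small deterministic tracker
implementing fixed-step bidirectional Euler integration with anisotropy,
turning-angle and length termination rules; it exists to make those
rules testable, not to model diffusion reconstruction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
from scipy.spatial import ConvexHull

from .callosotomy import segment_cc
from .errors import (
    ConfigurationError,
    DegenerateInputError,
    ParameterError,
    ValidationError,
)
from .io_formats import LabelTable, VolumeMask
from .networks import network_involvement
from .surface_mapping import (
    CorticalSurface,
    Tractogram,
    TriangleCountField,
    triangle_median_counts,
)

__all__ = [
    "SyntheticConfig",
    "GroundTruth",
    "OrientationField",
    "SyntheticDataset",
    "generate_dataset",
    "otsu_threshold",
    "track_streamlines",
    "write_bundle",
    "load_bundle",
]

#: resection extents at which disruption curves are planted (k = 5 fifths)
GROUND_TRUTH_EXTENTS = (0.2, 0.4, 0.6, 0.8, 1.0)
_GT_K = 5


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of one synthetic dataset realisation.

    ``network_ap_gradient`` holds each network's mean CC passage position
    along the principal (anterior-posterior) axis, 0 = anterior; defaults
    to an even spread from 0.1 (network 1) to 0.9 (network n).
    """

    seed: int
    n_streamlines: int = 20_000
    mesh_triangles_per_hemisphere: int = 8_000
    parasagittal_sigma: float = 10.0
    asymmetry: float = 1.2
    n_networks: int = 17
    network_ap_gradient: Optional[Sequence[float]] = None
    network_ap_sigma: float = 0.05
    cc_extent: Tuple[float, float, float] = (10.0, 40.0, 10.0)
    voxel_size: float = 1.0
    hemisphere_radius: float = 25.0
    hemisphere_offset: float = 35.0

    def __post_init__(self):
        if self.n_streamlines < 1:
            raise ConfigurationError("n_streamlines must be positive")
        t = self.mesh_triangles_per_hemisphere
        if t < 4 or t % 2:
            raise ConfigurationError(
                "mesh_triangles_per_hemisphere must be an even integer >= 4 "
                "(a triangulated closed surface with V vertices has 2V-4 faces)"
            )
        for name in ("parasagittal_sigma", "asymmetry", "network_ap_sigma",
                     "voxel_size", "hemisphere_radius", "hemisphere_offset"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")
        if not 1 <= self.n_networks <= 17:
            raise ConfigurationError("n_networks must be in 1..17")
        cc = tuple(float(c) for c in self.cc_extent)
        if len(cc) != 3 or any(c <= 0 for c in cc):
            raise ConfigurationError("cc_extent must be 3 positive mm lengths")
        grad = self.network_ap_gradient
        if grad is None:
            grad = np.linspace(0.1, 0.9, self.n_networks)
        grad = tuple(float(g) for g in grad)
        if len(grad) != self.n_networks or any(not 0 <= g <= 1 for g in grad):
            raise ConfigurationError(
                "network_ap_gradient needs one entry in [0,1] per network"
            )
        # feasibility: the CC slab must fit between the hemisphere meshes
        # and within their anterior-posterior span
        gap = self.hemisphere_offset - self.hemisphere_radius * 1.1
        if cc[0] / 2 >= gap:
            raise ConfigurationError(
                "CC slab overlaps the hemisphere meshes (reduce cc_extent[0])"
            )
        if cc[1] / 2 >= self.hemisphere_radius:
            raise ConfigurationError(
                "CC slab extends beyond the mesh anterior-posterior span"
            )
        object.__setattr__(self, "cc_extent", cc)
        object.__setattr__(self, "network_ap_gradient", grad)


@dataclass(frozen=True)
class GroundTruth:
    """Planted per-streamline draws and the quantities they imply.

    Aggregate quantities are computed from the realised draws with the
    same median-of-three involvement rule the pipeline uses, so pipeline
    recovery is exact up to assignment and voxelisation."""

    network: np.ndarray  # (N,) destination network 1..n
    cc_position: np.ndarray  # (N,) passage position in [0,1], 0 = anterior
    cc_segment: np.ndarray  # (N,) anterior-most fifth 1..5
    left_vertex: np.ndarray  # (N,) local left-surface vertex id
    right_vertex: np.ndarray  # (N,) local right-surface vertex id
    hemisphere_coverage: Dict[str, float]
    network_involvement: Dict[int, float]
    disruption: Dict[int, Tuple[float, ...]]  # per network, at the 5 extents
    extents: Tuple[float, ...] = GROUND_TRUTH_EXTENTS

    def to_json(self, path) -> None:
        payload = {
            "network": self.network.tolist(),
            "cc_position": self.cc_position.tolist(),
            "cc_segment": self.cc_segment.tolist(),
            "left_vertex": self.left_vertex.tolist(),
            "right_vertex": self.right_vertex.tolist(),
            "hemisphere_coverage": self.hemisphere_coverage,
            "network_involvement": {
                str(k): v for k, v in self.network_involvement.items()
            },
            "disruption": {
                str(k): list(v) for k, v in self.disruption.items()
            },
            "extents": list(self.extents),
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        payload = json.loads(Path(path).read_text())
        return cls(
            network=np.asarray(payload["network"], dtype=np.int64),
            cc_position=np.asarray(payload["cc_position"], dtype=float),
            cc_segment=np.asarray(payload["cc_segment"], dtype=np.int64),
            left_vertex=np.asarray(payload["left_vertex"], dtype=np.int64),
            right_vertex=np.asarray(payload["right_vertex"], dtype=np.int64),
            hemisphere_coverage={
                k: float(v) for k, v in payload["hemisphere_coverage"].items()
            },
            network_involvement={
                int(k): float(v)
                for k, v in payload["network_involvement"].items()
            },
            disruption={
                int(k): tuple(float(x) for x in v)
                for k, v in payload["disruption"].items()
            },
            extents=tuple(payload["extents"]),
        )


@dataclass(frozen=True)
class OrientationField:
    """Voxelwise principal direction and anisotropy on a regular grid."""

    shape: Tuple[int, int, int]
    affine: np.ndarray
    direction: np.ndarray  # (nx, ny, nz, 3)
    anisotropy: np.ndarray  # (nx, ny, nz)

    def __post_init__(self):
        direction = np.asarray(self.direction, dtype=float)
        anisotropy = np.asarray(self.anisotropy, dtype=float)
        affine = np.asarray(self.affine, dtype=float)
        shape = tuple(int(s) for s in self.shape)
        if direction.shape != shape + (3,) or anisotropy.shape != shape:
            raise ValidationError("direction/anisotropy shape mismatch")
        norms = np.linalg.norm(direction, axis=-1)
        active = anisotropy > 0
        if active.any() and not np.allclose(norms[active], 1.0, atol=1e-6):
            raise ValidationError(
                "direction vectors must have unit norm where anisotropy > 0"
            )
        object.__setattr__(self, "shape", shape)
        object.__setattr__(self, "affine", affine)
        object.__setattr__(self, "direction", direction)
        object.__setattr__(self, "anisotropy", anisotropy)


@dataclass(frozen=True)
class SyntheticDataset:
    """One realised synthetic input bundle plus its ground truth."""

    config: SyntheticConfig
    surface_left: CorticalSurface
    surface_right: CorticalSurface
    mask: VolumeMask
    labels_left: LabelTable
    labels_right: LabelTable
    tractogram: Tractogram
    ground_truth: GroundTruth

    @property
    def surfaces(self):
        return self.surface_left, self.surface_right

    @property
    def labels(self):
        return self.labels_left, self.labels_right


# ---------------------------------------------------------------------------
# mesh construction
# ---------------------------------------------------------------------------

def _fibonacci_sphere(n: int) -> np.ndarray:
    """n well-spread unit vectors (golden-angle spiral)."""
    i = np.arange(n)
    z = 1.0 - (2.0 * i + 1.0) / n
    golden = (1.0 + np.sqrt(5.0)) / 2.0
    theta = 2.0 * np.pi * i / golden
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([r * np.cos(theta), r * np.sin(theta), z])


def _hemisphere_mesh(n_triangles: int, radius: float, offset: float):
    """Right-hemisphere deformed-sphere mesh; left is its x-mirror."""
    n_pts = (n_triangles + 4) // 2
    unit = _fibonacci_sphere(n_pts)
    hull = ConvexHull(unit, qhull_options="Qt")
    triangles = np.asarray(hull.simplices, dtype=np.int64)
    if len(triangles) != n_triangles:  # pragma: no cover - geometric guard
        raise ConfigurationError(
            f"mesh construction produced {len(triangles)} triangles, "
            f"expected {n_triangles}"
        )
    # gentle smooth radial deformation; triangles stay fixed so the mesh
    # remains valid even where the deformed point set is non-convex
    deform = 1.0 + 0.06 * np.sin(2.0 * unit[:, 0] + 1.3) * np.cos(
        1.5 * unit[:, 1] - 0.7
    ) + 0.04 * np.sin(2.5 * unit[:, 2])
    right = radius * deform[:, None] * unit
    right[:, 0] += offset
    left = right * np.array([-1.0, 1.0, 1.0])
    return left, right, triangles


def _band_labels(vertices, triangles, n_networks) -> np.ndarray:
    """Contiguous anterior-to-posterior bands of near-equal triangle count."""
    centroid_y = vertices[triangles].mean(axis=1)[:, 1]
    order = np.argsort(-centroid_y, kind="stable")  # anterior (high y) first
    labels = np.zeros(len(triangles), dtype=np.int64)
    for net, chunk in enumerate(np.array_split(order, n_networks), start=1):
        labels[chunk] = net
    return labels


def _slab_mask(cc_extent, voxel_size) -> VolumeMask:
    nx, ny, nz = (max(1, int(round(c / voxel_size))) for c in cc_extent)
    affine = np.eye(4)
    affine[0, 0] = affine[1, 1] = affine[2, 2] = voxel_size
    affine[:3, 3] = [
        -(n - 1) / 2.0 * voxel_size for n in (nx, ny, nz)
    ]
    ii, jj, kk = np.meshgrid(
        np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij"
    )
    voxels = np.column_stack([ii.ravel(), jj.ravel(), kk.ravel()])
    return VolumeMask(shape=(nx, ny, nz), affine=affine, voxels=voxels)


# ---------------------------------------------------------------------------
# dataset generation
# ---------------------------------------------------------------------------

def generate_dataset(config: SyntheticConfig) -> SyntheticDataset:
    """Generate a complete synthetic input bundle with recorded ground truth.

    Identical seeds give bit-identical output: all randomness flows
    through one ``numpy.random.default_rng(config.seed)`` stream.
    """
    rng = np.random.default_rng(config.seed)
    left_v, right_v, triangles = _hemisphere_mesh(
        config.mesh_triangles_per_hemisphere,
        config.hemisphere_radius,
        config.hemisphere_offset,
    )
    surface_left = CorticalSurface(left_v, triangles, "left")
    surface_right = CorticalSurface(right_v, triangles, "right")

    tri_labels = _band_labels(right_v, triangles, config.n_networks)
    labels_left = LabelTable(tri_labels)
    labels_right = LabelTable(tri_labels)

    mask = _slab_mask(config.cc_extent, config.voxel_size)
    segmentation = segment_cc(mask, _GT_K)
    seg_volume = segmentation.label_volume(mask)
    inv_affine = np.linalg.inv(mask.affine)

    # per-network vertex pools with para-sagittal weights
    n = config.n_streamlines
    nets = rng.integers(1, config.n_networks + 1, size=n)
    pools = {}
    for net in range(1, config.n_networks + 1):
        verts = np.unique(triangles[tri_labels == net])
        d_mid = np.abs(right_v[verts, 0])  # |x| distance from midline
        pools[net] = (verts, d_mid)

    left_vertex = np.empty(n, dtype=np.int64)
    right_vertex = np.empty(n, dtype=np.int64)
    sigma_right = config.parasagittal_sigma
    sigma_left = config.asymmetry * config.parasagittal_sigma
    for net in range(1, config.n_networks + 1):
        members = np.flatnonzero(nets == net)
        if not len(members):
            continue
        verts, d_mid = pools[net]
        for sigma, target in ((sigma_left, left_vertex),
                              (sigma_right, right_vertex)):
            w = np.exp(-0.5 * (d_mid / sigma) ** 2)
            w /= w.sum()
            target[members] = rng.choice(verts, size=len(members), p=w)

    grad = np.asarray(config.network_ap_gradient)
    t = np.clip(
        rng.normal(grad[nets - 1], config.network_ap_sigma), 1e-3, 1.0 - 1e-3
    )

    streamlines, cc_points = _build_streamlines(
        config, mask, left_v, right_v, left_vertex, right_vertex, t, rng
    )
    tractogram = Tractogram(streamlines)

    # planted anterior-most fifth: segment label of the voxel holding the
    # CC passage point (same convention the pipeline uses)
    ijk = np.rint(cc_points @ inv_affine[:3, :3].T + inv_affine[:3, 3]).astype(int)
    cc_segment = seg_volume[tuple(ijk.T)].astype(np.int64)
    if (cc_segment < 1).any():  # pragma: no cover - geometric guard
        raise ConfigurationError("a planted CC passage point missed the mask")

    gt = _plant_ground_truth(
        config, triangles, tri_labels, left_vertex, right_vertex,
        nets, t, cc_segment, surface_left, surface_right,
        labels_left, labels_right,
    )
    return SyntheticDataset(
        config=config,
        surface_left=surface_left,
        surface_right=surface_right,
        mask=mask,
        labels_left=labels_left,
        labels_right=labels_right,
        tractogram=tractogram,
        ground_truth=gt,
    )


def _build_streamlines(config, mask, left_v, right_v,
                       left_vertex, right_vertex, t, rng):
    """Vectorised polyline construction: vertex -> slab crossing -> vertex."""
    centers = mask.voxel_centers_mm()
    x_lo, x_hi = centers[:, 0].min(), centers[:, 0].max()
    y_lo, y_hi = centers[:, 1].min(), centers[:, 1].max()
    z_lo, z_hi = centers[:, 2].min(), centers[:, 2].max()

    n = len(t)
    y_t = y_hi - t * (y_hi - y_lo)  # position 0 = anterior = +Y
    z_j = rng.uniform(z_lo, z_hi, size=n) if z_hi > z_lo else np.full(n, z_lo)

    # crossing sampled at <= half-voxel spacing so every voxel column is hit
    span = max(x_hi - x_lo, config.voxel_size)
    n_cross = int(np.ceil(span / (config.voxel_size / 2.0))) + 1
    cross_x = np.linspace(x_lo, x_hi, n_cross)

    entry = np.column_stack([np.full(n, x_lo), y_t, z_j])
    exit_ = np.column_stack([np.full(n, x_hi), y_t, z_j])
    lp = left_v[left_vertex]
    rp = right_v[right_vertex]

    f = np.linspace(0.0, 1.0, 6)[:, None]
    seg_a = lp[:, None, :] * (1 - f) + entry[:, None, :] * f  # incl. both ends
    seg_b = np.empty((n, n_cross - 1, 3))
    seg_b[:, :, 0] = cross_x[1:]
    seg_b[:, :, 1] = y_t[:, None]
    seg_b[:, :, 2] = z_j[:, None]
    f2 = np.linspace(0.0, 1.0, 6)[1:, None]
    seg_c = exit_[:, None, :] * (1 - f2) + rp[:, None, :] * f2
    pts = np.concatenate([seg_a, seg_b, seg_c], axis=1)

    cc_mid = np.column_stack([np.zeros(n), y_t, z_j])
    return list(pts), cc_mid


def _plant_ground_truth(config, triangles, tri_labels, left_vertex,
                        right_vertex, nets, t, cc_segment,
                        surface_left, surface_right,
                        labels_left, labels_right) -> GroundTruth:
    n_vertices = int(triangles.max()) + 1

    def involvement_fields(stream_mask):
        fields = []
        for surf, vert in ((surface_left, left_vertex),
                           (surface_right, right_vertex)):
            counts = np.bincount(vert[stream_mask], minlength=n_vertices)
            tri = counts[triangles]
            fields.append(TriangleCountField(
                n=np.sort(tri, axis=1)[:, 1],
                any_hit=(tri >= 1).any(axis=1),
                hemisphere=surf.hemisphere,
            ))
        return tuple(fields)

    all_nets = list(range(1, config.n_networks + 1))
    everything = np.ones(len(nets), dtype=bool)
    full_fields = involvement_fields(everything)
    coverage = {
        "left": float((full_fields[0].n >= 1).mean()),
        "right": float((full_fields[1].n >= 1).mean()),
    }
    involvement = network_involvement(
        full_fields, (labels_left, labels_right), networks=all_nets
    )

    disruption = {net: [] for net in all_nets}
    for j in range(1, _GT_K + 1):
        cut = cc_segment <= j
        inv = network_involvement(
            involvement_fields(cut), (labels_left, labels_right),
            networks=all_nets,
        )
        for net in all_nets:
            disruption[net].append(inv[net])

    return GroundTruth(
        network=nets.astype(np.int64),
        cc_position=t.astype(float),
        cc_segment=cc_segment,
        left_vertex=left_vertex,
        right_vertex=right_vertex,
        hemisphere_coverage=coverage,
        network_involvement=involvement,
        disruption={k: tuple(v) for k, v in disruption.items()},
    )


# ---------------------------------------------------------------------------
# Otsu threshold
# ---------------------------------------------------------------------------

def otsu_threshold(values, n_bins: int = 256) -> float:
    """Histogram threshold maximising between-class variance.

    Builds an ``n_bins`` histogram spanning ``[min, max]`` and returns
    the bin edge that maximises the between-class variance of the two
    resulting classes (the lowest such edge on ties).
    """
    values = np.asarray(values, dtype=float).ravel()
    if n_bins < 2:
        raise ParameterError("n_bins must be >= 2")
    if values.size < 2 or np.ptp(values) == 0:
        raise DegenerateInputError(
            "Otsu threshold needs at least two distinct values"
        )
    hist, edges = np.histogram(values, bins=n_bins,
                               range=(values.min(), values.max()))
    hist = hist.astype(float)
    centers = 0.5 * (edges[:-1] + edges[1:])
    w0 = np.cumsum(hist)[:-1]
    w1 = hist.sum() - w0
    m = np.cumsum(hist * centers)
    mu0 = np.divide(m[:-1], w0, out=np.zeros_like(w0), where=w0 > 0)
    mu1 = np.divide(m[-1] - m[:-1], w1, out=np.zeros_like(w1), where=w1 > 0)
    sigma_b = w0 * w1 * (mu0 - mu1) ** 2
    sigma_b[(w0 == 0) | (w1 == 0)] = -np.inf
    return float(edges[int(np.argmax(sigma_b)) + 1])


# ---------------------------------------------------------------------------
# toy deterministic tracker
# ---------------------------------------------------------------------------

def track_streamlines(
    field: OrientationField,
    seeds: np.ndarray,
    step_mm: float,
    angular_limit_deg: float = 60.0,
    min_len_mm: float = 10.0,
    max_len_mm: float = 300.0,
    anisotropy_threshold: float = 0.0,
    seed: Optional[int] = None,
) -> Tractogram:
    """Fixed-step bidirectional Euler tracking with the stated stop rules.

    From each seed point two half-tracks are propagated along the
    nearest-voxel direction (sign-aligned with the previous step), each
    capped at ``max_len_mm / 2``.  A direction terminates when the local
    anisotropy drops below ``anisotropy_threshold``, when the turning
    angle between consecutive steps exceeds ``angular_limit_deg``, or
    when the track leaves the grid.  The two halves are concatenated and
    streamlines with total length outside ``[min_len_mm, max_len_mm]``
    are discarded.  ``seed`` (optional) jitters each seed point uniformly
    within half a voxel, emulating random initial conditions.
    """
    if step_mm <= 0:
        raise ParameterError("step_mm must be positive")
    seeds = np.asarray(seeds, dtype=float).reshape(-1, 3)
    inv = np.linalg.inv(field.affine)
    shape = np.asarray(field.shape)
    cos_limit = np.cos(np.deg2rad(angular_limit_deg))
    half_cap = max_len_mm / 2.0

    if seed is not None:
        rng = np.random.default_rng(seed)
        voxel_mm = np.abs(np.diag(field.affine)[:3])
        seeds = seeds + rng.uniform(-0.5, 0.5, size=seeds.shape) * voxel_mm

    def voxel_of(pos):
        ijk = np.rint(pos @ inv[:3, :3].T + inv[:3, 3]).astype(int)
        if (ijk < 0).any() or (ijk >= shape).any():
            return None
        return tuple(ijk)

    def half_track(start, sign):
        points = []
        pos = start.copy()
        prev = None
        length = 0.0
        while length + step_mm <= half_cap + 1e-9:
            vox = voxel_of(pos)
            if vox is None:
                break
            if field.anisotropy[vox] < anisotropy_threshold:
                break
            d = field.direction[vox]
            norm = np.linalg.norm(d)
            if norm == 0:
                break
            d = d / norm
            if prev is None:
                d = sign * d
            else:
                if np.dot(d, prev) < 0:
                    d = -d
                if np.dot(d, prev) < cos_limit - 1e-12:
                    break
            pos = pos + step_mm * d
            points.append(pos.copy())
            prev = d
            length += step_mm
        return points

    streamlines = []
    for s in seeds:
        fwd = half_track(s, +1.0)
        bwd = half_track(s, -1.0)
        pts = bwd[::-1] + [s] + fwd
        if len(pts) < 2:
            continue
        total = step_mm * (len(pts) - 1)
        if min_len_mm <= total <= max_len_mm:
            streamlines.append(np.asarray(pts))
    return Tractogram(streamlines) if streamlines else Tractogram([])


# ---------------------------------------------------------------------------
# on-disk bundles
# ---------------------------------------------------------------------------

_BUNDLE_FILES = {
    "surface_left": "surface_left.{surf}",
    "surface_right": "surface_right.{surf}",
    "mask": "cc_mask.nii.gz",
    "labels_left": "labels_left.txt",
    "labels_right": "labels_right.txt",
    "tractogram": "tractogram.tck",
    "ground_truth": "ground_truth.json",
}


def write_bundle(dataset: SyntheticDataset, out_dir,
                 surface_format: str = "gii") -> Dict[str, Path]:
    """Write a full input bundle (plus ground truth) to a directory."""
    from . import io_formats as io

    if surface_format not in ("gii", "off"):
        raise ParameterError("surface_format must be 'gii' or 'off'")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        key: out / tmpl.format(surf=surface_format)
        for key, tmpl in _BUNDLE_FILES.items()
    }
    io.write_surface(dataset.surface_left, paths["surface_left"])
    io.write_surface(dataset.surface_right, paths["surface_right"])
    io.write_mask(dataset.mask, paths["mask"])
    io.write_labels(dataset.labels_left, paths["labels_left"])
    io.write_labels(dataset.labels_right, paths["labels_right"])
    io.write_tractogram(dataset.tractogram, paths["tractogram"])
    dataset.ground_truth.to_json(paths["ground_truth"])
    return paths


def load_bundle(bundle_dir):
    """Load a bundle written by :func:`write_bundle`.

    Returns ``(surfaces, mask, labels, tractogram, ground_truth_or_None)``.
    """
    from . import io_formats as io

    bundle = Path(bundle_dir)
    surf_paths = {}
    for hemi in ("left", "right"):
        for ext in ("gii", "off"):
            cand = bundle / f"surface_{hemi}.{ext}"
            if cand.exists():
                surf_paths[hemi] = cand
                break
        else:
            raise ValidationError(f"bundle lacks a surface_{hemi} file")
    surfaces = (
        io.read_surface(surf_paths["left"], "left"),
        io.read_surface(surf_paths["right"], "right"),
    )
    mask = io.read_mask(bundle / "cc_mask.nii.gz")
    labels = (
        io.read_labels(bundle / "labels_left.txt"),
        io.read_labels(bundle / "labels_right.txt"),
    )
    tractogram = io.read_tractogram(bundle / "tractogram.tck")
    gt_path = bundle / "ground_truth.json"
    gt = GroundTruth.from_json(gt_path) if gt_path.exists() else None
    return surfaces, mask, labels, tractogram, gt
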