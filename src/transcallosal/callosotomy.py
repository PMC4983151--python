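"""Principal-axis subdivision of the corpus callosum and streamline passage.

The CC mask is split into ``k`` (default 5) segments equally spaced along
the principal eigendirection of its voxel-centre covariance, oriented so
the anterior (+Y in RAS) component is positive; segment 1 is the
anterior-most.  Each streamline is then attributed the set of segments
whose voxels its points fall in; an anterior resection of the first ``j``
segments cuts every streamline whose segment set intersects ``{1..j}``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import List, Tuple

import numpy as np

from .errors import ParameterError, ValidationError
from .io_formats import VolumeMask
from .surface_mapping import Tractogram

__all__ = [
    "CCSegmentation",
    "StreamlineSegments",
    "DEFAULT_K",
    "segment_cc",
    "streamline_segments",
]

DEFAULT_K = 5

# relative gap below which the two leading covariance eigenvalues count as tied
_DEGENERACY_RTOL = 1e-9


@dataclass(frozen=True)
class CCSegmentation:
    """Equal-width subdivision of a CC mask along its principal axis.

    ``segment_of_voxel`` is aligned with the owning mask's ``voxels``
    array; labels run 1 (anterior-most) .. k (posterior-most).
    """

    eigendirection: np.ndarray  # unit 3-vector, anterior component >= 0
    projections: np.ndarray  # per-voxel mm along eigendirection
    bin_edges: np.ndarray  # (k+1,) ascending
    segment_of_voxel: np.ndarray  # (n_voxels,) int in 1..k
    k: int

    def label_volume(self, mask: VolumeMask) -> np.ndarray:
        """Dense integer volume with segment labels at in-mask voxels."""
        dense = np.zeros(mask.shape, dtype=np.int16)
        dense[tuple(mask.voxels.T)] = self.segment_of_voxel
        return dense


@dataclass(frozen=True)
class StreamlineSegments:
    """Per-streamline CC segment traversal.

    ``anterior_most`` is 0 for streamlines with no in-mask point
    (non-callosal; excluded from callosal analyses but counted).
    """

    segment_sets: Tuple[frozenset, ...]
    anterior_most: np.ndarray  # (N,) int, 0 = non-callosal
    k: int

    @property
    def n_streamlines(self) -> int:
        return len(self.anterior_most)

    @property
    def n_non_callosal(self) -> int:
        return int(np.sum(self.anterior_most == 0))

    def cut_by(self, j: int) -> np.ndarray:
        """Boolean mask of streamlines cut by an anterior-``j`` resection.

        A streamline is cut when any of its traversed segments has label
        <= ``j``; since labels increase posteriorly this is equivalent to
        ``anterior_most <= j`` (for callosal streamlines).
        """
        if not 0 <= j <= self.k:
            raise ParameterError(f"resection depth {j} outside 0..{self.k}")
        return (self.anterior_most >= 1) & (self.anterior_most <= j)


def segment_cc(mask: VolumeMask, k: int = DEFAULT_K) -> CCSegmentation:
    """Split a CC mask into ``k`` equal-width bins along its principal axis.

    The principal eigendirection is the leading eigenvector of the
    covariance of in-mask voxel-centre mm coordinates, sign-flipped so
    its anterior (+Y) component is non-negative.  Voxel projections onto
    this axis are binned into ``k`` equal-width intervals over
    ``[min, max]``; a projection exactly on an interior bin edge goes to
    the more anterior bin.
    """
    if k < 1:
        raise ParameterError(f"k must be >= 1, got {k}")
    if mask.n_voxels < k:
        raise ValidationError(
            f"mask has {mask.n_voxels} voxels, fewer than k={k}"
        )
    centers = mask.voxel_centers_mm()
    centered = centers - centers.mean(axis=0)
    cov = centered.T @ centered / len(centered)
    evals, evecs = np.linalg.eigh(cov)  # ascending eigenvalues
    leading = evals[-1]
    if leading <= 0:
        raise ValidationError("mask has no spatial spread")
    direction = evecs[:, -1]
    tol = _DEGENERACY_RTOL * max(1.0, leading)
    tied = np.flatnonzero(evals >= leading - tol)
    if len(tied) > 1:
        warnings.warn(
            "degenerate CC mask: leading covariance eigenvalues tied; "
            "using the |Y|-then-|X| tie-break",
            stacklevel=2,
        )
        candidates = evecs[:, tied]
        order = np.lexsort(
            (np.abs(candidates[0]), np.abs(candidates[1]))
        )
        direction = candidates[:, order[-1]]
    direction = _orient_anterior(direction)

    projections = centers @ direction
    lo, hi = projections.min(), projections.max()
    if hi - lo <= 0:
        raise ValidationError("all voxel projections identical")
    edges = np.linspace(lo, hi, k + 1)
    # ascending bin index; boundary values fall in the bin above them,
    # i.e. the more anterior bin once labels are flipped below
    idx = np.clip(np.searchsorted(edges, projections, side="right") - 1, 0, k - 1)
    labels = (k - idx).astype(np.int64)  # 1 = highest projection = anterior
    return CCSegmentation(
        eigendirection=direction,
        projections=projections,
        bin_edges=edges,
        segment_of_voxel=labels,
        k=int(k),
    )


def _orient_anterior(direction: np.ndarray) -> np.ndarray:
    d = np.asarray(direction, dtype=float)
    d = d / np.linalg.norm(d)
    if d[1] < 0:
        return -d
    if d[1] == 0:
        if d[0] < 0 or (d[0] == 0 and d[2] < 0):
            return -d
    return d


def streamline_segments(
    tractogram: Tractogram, segmentation: CCSegmentation, mask: VolumeMask
) -> StreamlineSegments:
    """Attribute each streamline the CC segments its points traverse.

    Points map to voxels by rounding their inverse-affine coordinates
    (voxel-centre convention).  Streamlines with no in-mask point are
    flagged non-callosal (``anterior_most == 0``).
    """
    label_vol = segmentation.label_volume(mask)
    inv = np.linalg.inv(mask.affine)
    n = tractogram.n_streamlines
    if n == 0:
        return StreamlineSegments(
            segment_sets=(), anterior_most=np.empty(0, dtype=np.int64),
            k=segmentation.k,
        )
    lengths = np.fromiter(
        (len(sl) for sl in tractogram.streamlines), dtype=np.int64, count=n
    )
    pts = np.concatenate(tractogram.streamlines)
    sids = np.repeat(np.arange(n), lengths)
    ijk = np.rint(pts @ inv[:3, :3].T + inv[:3, 3]).astype(np.int64)
    shape = np.asarray(mask.shape)
    inside = np.all((ijk >= 0) & (ijk < shape), axis=1)
    hit_labels = np.zeros(len(pts), dtype=np.int64)
    hit_labels[inside] = label_vol[tuple(ijk[inside].T)]
    hits = hit_labels > 0

    anterior = np.zeros(n, dtype=np.int64)
    if hits.any():
        minlab = np.full(n, np.iinfo(np.int64).max)
        np.minimum.at(minlab, sids[hits], hit_labels[hits])
        touched = minlab < np.iinfo(np.int64).max
        anterior[touched] = minlab[touched]
    pairs = np.unique(np.stack([sids[hits], hit_labels[hits]], axis=1), axis=0)
    sets: List[set] = [set() for _ in range(n)]
    for sid, lab in pairs:
        sets[sid].add(int(lab))
    return StreamlineSegments(
        segment_sets=tuple(frozenset(s) for s in sets),
        anterior_most=anterior,
        k=segmentation.k,
    )
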