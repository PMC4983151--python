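"""Readers and writers for every external representation the pipeline touches.

Formats
-------
* surfaces: GIFTI (``.gii``/``.surf.gii``) via :mod:`nibabel`, with plain
  OFF and ASCII PLY fallbacks;
* tractograms: TCK (TrackVis TRK also accepted) via
  :mod:`nibabel.streamlines`, always expressed in RAS millimetres;
* volume masks: NIfTI-1 (``.nii``/``.nii.gz``), affine taken from sform
  when its code > 0, else qform, else voxel-size scaling;
* parcellation labels: GIFTI label files or whitespace-separated plain
  text, one integer per surface element;
* vulnerability profiles and the 17-to-7 network mapping: CSV.

All loaded geometry is expressed in one RAS millimetre frame, and voxel
index ``(i, j, k)`` maps through the affine to the millimetre position of
the voxel *centre*.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Optional

import nibabel as nib
import numpy as np
import pandas as pd

from .errors import FormatError, TractogramParseError, ValidationError
from .surface_mapping import CorticalSurface, Tractogram

__all__ = [
    "VolumeMask",
    "LabelTable",
    "read_surface",
    "write_surface",
    "read_tractogram",
    "write_tractogram",
    "read_mask",
    "write_mask",
    "read_labels",
    "write_labels",
    "read_profile",
    "write_profile",
    "read_mapping",
]

#: decimal places used when printing profile values to CSV
PROFILE_DECIMALS = 6


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class VolumeMask:
    """Binary voxel mask on a regular grid with a voxel-to-mm affine.

    ``voxels`` holds the integer (i, j, k) indices of in-mask voxels; the
    affine maps voxel indices to the RAS-mm position of voxel centres.
    """

    shape: tuple
    affine: np.ndarray
    voxels: np.ndarray  # (n, 3) int

    def __post_init__(self):
        shape = tuple(int(s) for s in self.shape)
        affine = np.asarray(self.affine, dtype=float)
        voxels = np.asarray(self.voxels, dtype=np.int64).reshape(-1, 3)
        if len(shape) != 3 or any(s <= 0 for s in shape):
            raise ValidationError("shape must be 3 positive integers")
        if affine.shape != (4, 4) or not np.isfinite(affine).all():
            raise ValidationError("affine must be a finite 4x4 matrix")
        if abs(np.linalg.det(affine[:3, :3])) < 1e-12:
            raise ValidationError("affine is not invertible")
        if voxels.size:
            if voxels.min() < 0 or (voxels >= np.asarray(shape)).any():
                raise ValidationError("in-mask voxel index outside shape")
        object.__setattr__(self, "shape", shape)
        object.__setattr__(self, "affine", affine)
        object.__setattr__(self, "voxels", voxels)

    @property
    def n_voxels(self) -> int:
        return len(self.voxels)

    def voxel_centers_mm(self) -> np.ndarray:
        """Millimetre coordinates of in-mask voxel centres, shape (n, 3)."""
        homog = np.hstack([self.voxels, np.ones((len(self.voxels), 1))])
        return (homog @ self.affine.T)[:, :3]

    def to_dense(self) -> np.ndarray:
        dense = np.zeros(self.shape, dtype=np.uint8)
        if len(self.voxels):
            dense[tuple(self.voxels.T)] = 1
        return dense


@dataclass(frozen=True)
class LabelTable:
    """Per-surface-element integer network labels (0 = unassigned)."""

    labels: np.ndarray
    names: Dict[int, str] = field(default_factory=dict)

    def __post_init__(self):
        labels = np.asarray(self.labels, dtype=np.int64).ravel()
        if labels.size and labels.min() < 0:
            raise ValidationError("labels must be non-negative integers")
        if len(np.unique(labels)) > 18:
            raise ValidationError("more than 18 distinct labels")
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "names", dict(self.names))

    def __len__(self) -> int:
        return len(self.labels)


# ---------------------------------------------------------------------------
# surfaces
# ---------------------------------------------------------------------------

def read_surface(path, hemisphere: str) -> CorticalSurface:
    """Read a triangulated surface (GIFTI, OFF or ASCII PLY) in millimetres."""
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix == ".gii":
        vertices, triangles = _read_gifti_surface(path)
    elif suffix == ".off":
        vertices, triangles = _read_off(path)
    elif suffix == ".ply":
        vertices, triangles = _read_ply(path)
    else:
        raise FormatError(f"unsupported surface format: {path.name}")
    return CorticalSurface(vertices, triangles, hemisphere)


def write_surface(surface: CorticalSurface, path) -> None:
    """Write a surface as GIFTI (``.gii``) or OFF (``.off``)."""
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix == ".gii":
        img = nib.gifti.GiftiImage(darrays=[
            nib.gifti.GiftiDataArray(
                surface.vertices.astype(np.float32),
                intent="NIFTI_INTENT_POINTSET",
                datatype="NIFTI_TYPE_FLOAT32",
            ),
            nib.gifti.GiftiDataArray(
                surface.triangles.astype(np.int32),
                intent="NIFTI_INTENT_TRIANGLE",
                datatype="NIFTI_TYPE_INT32",
            ),
        ])
        nib.save(img, str(path))
    elif suffix == ".off":
        with open(path, "w") as fh:
            fh.write("OFF\n")
            fh.write(f"{surface.n_vertices} {surface.n_triangles} 0\n")
            for v in surface.vertices:
                fh.write(
                    f"{float(v[0])!r} {float(v[1])!r} {float(v[2])!r}\n"
                )
            for t in surface.triangles:
                fh.write(f"3 {t[0]} {t[1]} {t[2]}\n")
    else:
        raise FormatError(f"unsupported surface format: {path.name}")


def _read_gifti_surface(path):
    try:
        img = nib.load(str(path))
        vertices = img.agg_data("pointset")
        triangles = img.agg_data("triangle")
    except Exception as exc:
        raise FormatError(f"malformed GIFTI surface {path.name}: {exc}") from exc
    if vertices is None or triangles is None or np.size(vertices) == 0:
        raise FormatError(
            f"GIFTI file {path.name} lacks a pointset/triangle array pair"
        )
    return np.asarray(vertices, dtype=float), np.asarray(triangles, dtype=np.int64)


def _read_off(path):
    with open(path) as fh:
        tokens = []
        for line in fh:
            line = line.split("#", 1)[0].strip()
            if line:
                tokens.extend(line.split())
    if not tokens or tokens[0] != "OFF":
        raise FormatError(f"{path.name}: missing OFF header")
    try:
        nv, nf = int(tokens[1]), int(tokens[2])
        pos = 4  # OFF nv nf ne
        vertices = np.array(
            [float(t) for t in tokens[pos:pos + 3 * nv]], dtype=float
        ).reshape(nv, 3)
        pos += 3 * nv
        triangles = []
        for _ in range(nf):
            arity = int(tokens[pos])
            if arity != 3:
                raise FormatError(
                    f"{path.name}: only triangular faces supported, got {arity}-gon"
                )
            triangles.append([int(t) for t in tokens[pos + 1:pos + 4]])
            pos += 1 + arity
    except (IndexError, ValueError) as exc:
        raise FormatError(f"{path.name}: truncated or malformed OFF data") from exc
    return vertices, np.asarray(triangles, dtype=np.int64).reshape(-1, 3)


def _read_ply(path):
    with open(path, "rb") as fh:
        header = []
        while True:
            line = fh.readline().decode("ascii", errors="replace").strip()
            if not line and not header:
                raise FormatError(f"{path.name}: empty file")
            header.append(line)
            if line == "end_header":
                break
            if len(header) > 200:
                raise FormatError(f"{path.name}: PLY header not terminated")
        body = fh.read().decode("ascii", errors="replace")
    if header[0] != "ply":
        raise FormatError(f"{path.name}: missing 'ply' magic")
    if not any(h.startswith("format ascii") for h in header):
        raise FormatError(f"{path.name}: only ASCII PLY is supported")
    nv = nf = None
    vertex_props = []
    current = None
    for line in header:
        parts = line.split()
        if not parts:
            continue
        if parts[0] == "element":
            current = parts[1]
            if parts[1] == "vertex":
                nv = int(parts[2])
            elif parts[1] == "face":
                nf = int(parts[2])
        elif parts[0] == "property" and current == "vertex":
            vertex_props.append(parts[-1])
    if nv is None or nf is None:
        raise FormatError(f"{path.name}: PLY header lacks vertex/face elements")
    try:
        ix, iy, iz = (vertex_props.index(c) for c in ("x", "y", "z"))
    except ValueError as exc:
        raise FormatError(f"{path.name}: PLY vertices lack x/y/z") from exc
    lines = [ln for ln in body.splitlines() if ln.strip()]
    try:
        vertices = np.array(
            [[float(lines[i].split()[j]) for j in (ix, iy, iz)] for i in range(nv)]
        )
        triangles = []
        for i in range(nv, nv + nf):
            parts = lines[i].split()
            if int(parts[0]) != 3:
                raise FormatError(f"{path.name}: only triangular faces supported")
            triangles.append([int(p) for p in parts[1:4]])
    except (IndexError, ValueError) as exc:
        raise FormatError(f"{path.name}: truncated PLY body") from exc
    return vertices, np.asarray(triangles, dtype=np.int64).reshape(-1, 3)


# ---------------------------------------------------------------------------
# tractograms
# ---------------------------------------------------------------------------

def read_tractogram(path) -> Tractogram:
    """Read a TCK (or TRK) tractogram into RAS millimetre coordinates."""
    path = Path(path)
    streamlines = []
    try:
        tfile = nib.streamlines.load(str(path), lazy_load=True)
        for sl in tfile.tractogram.streamlines:
            streamlines.append(np.asarray(sl, dtype=float))
    except TractogramParseError:
        raise
    except Exception as exc:
        raise TractogramParseError(
            f"failed to parse tractogram {path.name}: {exc}",
            streamline_index=len(streamlines),
        ) from exc
    return Tractogram(streamlines)


def write_tractogram(tractogram: Tractogram, path) -> None:
    """Write a tractogram to TCK (float32 on disk) or TRK."""
    path = Path(path)
    tgram = nib.streamlines.Tractogram(
        [np.asarray(sl, dtype=np.float32) for sl in tractogram.streamlines],
        affine_to_rasmm=np.eye(4),
    )
    if path.suffix.lower() == ".tck":
        nib.streamlines.save(tgram, str(path))
    elif path.suffix.lower() == ".trk":
        header = nib.streamlines.trk.TrkFile.create_empty_header()
        nib.streamlines.save(nib.streamlines.trk.TrkFile(tgram, header), str(path))
    else:
        raise FormatError(f"unsupported tractogram format: {path.name}")


# ---------------------------------------------------------------------------
# NIfTI masks
# ---------------------------------------------------------------------------

def read_mask(path) -> VolumeMask:
    """Read a NIfTI volume and binarise it (> 0) into a :class:`VolumeMask`.

    Affine precedence: sform when its code > 0, else qform when its code
    > 0, else scaling by the header voxel sizes.
    """
    path = Path(path)
    try:
        img = nib.load(str(path))
        data = np.asanyarray(img.dataobj)
    except Exception as exc:
        raise FormatError(f"failed to read NIfTI {path.name}: {exc}") from exc
    if data.ndim != 3:
        data = np.squeeze(data)
        if data.ndim != 3:
            raise FormatError(f"{path.name}: expected a 3-D volume")
    affine = _choose_affine(img)
    voxels = np.argwhere(data > 0)
    return VolumeMask(shape=data.shape, affine=affine, voxels=voxels)


def _choose_affine(img) -> np.ndarray:
    sform, scode = img.header.get_sform(coded=True)
    if scode and int(scode) > 0:
        return np.asarray(sform, dtype=float)
    qform, qcode = img.header.get_qform(coded=True)
    if qcode and int(qcode) > 0:
        return np.asarray(qform, dtype=float)
    zooms = img.header.get_zooms()[:3]
    affine = np.eye(4)
    affine[0, 0], affine[1, 1], affine[2, 2] = zooms
    return affine


def write_mask(mask: VolumeMask, path) -> None:
    img = nib.Nifti1Image(mask.to_dense(), mask.affine)
    img.set_sform(mask.affine, code=1)
    img.set_qform(mask.affine, code=1)
    nib.save(img, str(path))


def write_label_volume(
    labels_by_voxel: np.ndarray, mask: VolumeMask, path
) -> None:
    """Write per-voxel integer labels (aligned with ``mask.voxels``) as NIfTI."""
    dense = np.zeros(mask.shape, dtype=np.int16)
    dense[tuple(mask.voxels.T)] = labels_by_voxel
    img = nib.Nifti1Image(dense, mask.affine)
    img.set_sform(mask.affine, code=1)
    img.set_qform(mask.affine, code=1)
    nib.save(img, str(path))


# ---------------------------------------------------------------------------
# parcellation labels
# ---------------------------------------------------------------------------

def read_labels(path) -> LabelTable:
    """Read per-element labels from a GIFTI label file or plain text."""
    path = Path(path)
    if path.suffix.lower() == ".gii":
        try:
            img = nib.load(str(path))
            labels = np.asarray(img.darrays[0].data, dtype=np.int64).ravel()
        except Exception as exc:
            raise FormatError(f"malformed GIFTI labels {path.name}: {exc}") from exc
        names = {}
        if img.labeltable is not None:
            for lab in img.labeltable.labels:
                if lab.label is not None:
                    names[int(lab.key)] = lab.label
        return LabelTable(labels, names)
    try:
        labels = np.loadtxt(path, dtype=np.int64, ndmin=1)
    except Exception as exc:
        raise FormatError(f"malformed label text file {path.name}: {exc}") from exc
    return LabelTable(labels)


def write_labels(table: LabelTable, path) -> None:
    path = Path(path)
    if path.suffix.lower() == ".gii":
        darray = nib.gifti.GiftiDataArray(
            table.labels.astype(np.int32),
            intent="NIFTI_INTENT_LABEL",
            datatype="NIFTI_TYPE_INT32",
        )
        ltable = nib.gifti.GiftiLabelTable()
        for key, name in sorted(table.names.items()):
            lab = nib.gifti.GiftiLabel(key=int(key))
            lab.label = name
            ltable.labels.append(lab)
        img = nib.gifti.GiftiImage(darrays=[darray], labeltable=ltable)
        nib.save(img, str(path))
    else:
        np.savetxt(path, table.labels[:, None], fmt="%d")


# ---------------------------------------------------------------------------
# profiles and the 17 -> 7 mapping table
# ---------------------------------------------------------------------------

def write_profile(profile, path) -> None:
    """Write a vulnerability profile as CSV, values at 6 decimal places.

    One row per network, one column per resection extent; the header row
    carries the extents.  Reading the file back reproduces the values
    exactly as printed.
    """
    from .networks import VulnerabilityProfile  # local import avoids a cycle

    if not isinstance(profile, VulnerabilityProfile):
        raise ValidationError("write_profile expects a VulnerabilityProfile")
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["network"] + [f"{e:g}" for e in profile.extents])
        for name, row in zip(profile.networks, profile.values):
            writer.writerow(
                [name] + [f"{v:.{PROFILE_DECIMALS}f}" for v in row]
            )


def read_profile(path):
    from .networks import VulnerabilityProfile

    try:
        df = pd.read_csv(path)
    except Exception as exc:
        raise FormatError(f"malformed profile CSV {path}: {exc}") from exc
    if df.shape[1] < 2 or df.columns[0] != "network":
        raise FormatError(f"profile CSV {path} lacks a 'network' first column")
    extents = [float(c) for c in df.columns[1:]]
    networks = [
        int(n) if str(n).lstrip("-").isdigit() else str(n)
        for n in df["network"]
    ]
    values = df.iloc[:, 1:].to_numpy(dtype=float)
    return VulnerabilityProfile(networks=networks, extents=extents, values=values)


def read_mapping(path):
    """Read a network17 -> network7 weight table from CSV.

    Columns: ``network17``, ``network7``, ``weight``.  Weights are
    normalised so that each network17's weights sum to one.
    """
    from .networks import NetworkMapping17to7

    try:
        df = pd.read_csv(path)
    except Exception as exc:
        raise FormatError(f"malformed mapping CSV {path}: {exc}") from exc
    required = {"network17", "network7", "weight"}
    if not required.issubset(df.columns):
        raise FormatError(
            f"mapping CSV {path} must have columns {sorted(required)}"
        )
    return NetworkMapping17to7(
        network17=df["network17"].to_numpy(dtype=np.int64),
        network7=df["network7"].to_numpy(dtype=np.int64),
        weight=df["weight"].to_numpy(dtype=float),
    )
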