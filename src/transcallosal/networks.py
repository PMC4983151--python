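"""Network-level involvement, virtual-callosotomy profiles and reproducibility.

Networks are pooled across hemispheres.  A network's involvement is the
fraction of its labelled triangles (label > 0) whose per-triangle count
``n`` is at least 1; involvement at a partial resection extent is
recomputed from the endpoints of the cut streamlines only, so that the
extent-1.0 column reproduces the full-tractogram involvement exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from .callosotomy import StreamlineSegments
from .errors import ParameterError, ValidationError
from .io_formats import LabelTable
from .surface_mapping import (
    CorticalSurface,
    EndpointAssignment,
    TriangleCountField,
    _involved_mask,
    triangle_median_counts,
)

__all__ = [
    "NetworkMapping17to7",
    "VulnerabilityProfile",
    "ReproducibilityResult",
    "YEO7_NAMES",
    "default_mapping_path",
    "network_involvement",
    "callosotomy_profile",
    "downsample_17_to_7",
    "spearman_reproducibility",
]

#: conventional names of the 7-network resting-state model
YEO7_NAMES = {
    1: "Visual",
    2: "Somatomotor",
    3: "DorsalAttention",
    4: "VentralAttention",
    5: "Limbic",
    6: "Frontoparietal",
    7: "Default",
}


def default_mapping_path():
    """Path of the editable 17-to-7 network weight table shipped as data."""
    return resources.files("transcallosal.data") / "yeo17_to_7.csv"


@dataclass(frozen=True)
class NetworkMapping17to7:
    """Weighted many-to-many mapping from 17-network to 7-network labels.

    Weights are normalised on construction so each network17's weights
    sum to one (the shipped table is approximate and user-replaceable).
    """

    network17: np.ndarray
    network7: np.ndarray
    weight: np.ndarray

    def __post_init__(self):
        n17 = np.asarray(self.network17, dtype=np.int64)
        n7 = np.asarray(self.network7, dtype=np.int64)
        w = np.asarray(self.weight, dtype=float)
        if not (len(n17) == len(n7) == len(w)):
            raise ValidationError("mapping columns must have equal length")
        if (w < 0).any() or not np.isfinite(w).all():
            raise ValidationError("mapping weights must be finite and >= 0")
        normalised = w.copy()
        for src in np.unique(n17):
            rows = n17 == src
            total = w[rows].sum()
            if total <= 0:
                raise ValidationError(
                    f"weights for network17={src} sum to zero"
                )
            normalised[rows] = w[rows] / total
        object.__setattr__(self, "network17", n17)
        object.__setattr__(self, "network7", n7)
        object.__setattr__(self, "weight", normalised)


@dataclass(frozen=True)
class VulnerabilityProfile:
    """Networks x resection-extent matrix of involvement fractions."""

    networks: Sequence
    extents: Sequence[float]
    values: np.ndarray

    def __post_init__(self):
        values = np.asarray(self.values, dtype=float)
        if values.shape != (len(self.networks), len(self.extents)):
            raise ValidationError(
                "profile values must be (n_networks, n_extents)"
            )
        object.__setattr__(self, "networks", list(self.networks))
        object.__setattr__(self, "extents", [float(e) for e in self.extents])
        object.__setattr__(self, "values", values)

    def row(self, network) -> np.ndarray:
        return self.values[self.networks.index(network)]


@dataclass(frozen=True)
class ReproducibilityResult:
    """Spearman rank correlation of two paired per-triangle count vectors.

    ``rho`` is None when undefined (a constant input vector)."""

    rho: Optional[float]
    p_value: Optional[float]
    n: int


# ---------------------------------------------------------------------------
# involvement
# ---------------------------------------------------------------------------

def _pool(fields, labels):
    try:
        field_l, field_r = fields
        labels_l, labels_r = labels
    except (TypeError, ValueError) as exc:
        raise ValidationError(
            "fields and labels must be (left, right) pairs"
        ) from exc
    for f, t in ((field_l, labels_l), (field_r, labels_r)):
        if f.n_triangles != len(t):
            raise ValidationError(
                "label table does not cover the same triangles as the field"
            )
    lab = np.concatenate([labels_l.labels, labels_r.labels])
    return (field_l, field_r), lab


def network_involvement(
    fields: Tuple[TriangleCountField, TriangleCountField],
    labels: Tuple[LabelTable, LabelTable],
    rule: str = "median",
    networks: Optional[Sequence[int]] = None,
) -> Dict[int, float]:
    """Fraction of each network's triangles involved in callosal connectivity.

    Triangles of both hemispheres are pooled; label-0 (unassigned)
    triangles are excluded.  A requested network with zero triangles is
    reported as missing (NaN), not 0.
    """
    (field_l, field_r), lab = _pool(fields, labels)
    involved = np.concatenate(
        [_involved_mask(field_l, rule), _involved_mask(field_r, rule)]
    )
    present = np.unique(lab[lab > 0])
    wanted = sorted(int(n) for n in (networks if networks is not None else present))
    out: Dict[int, float] = {}
    for net in wanted:
        members = lab == net
        out[net] = float(involved[members].mean()) if members.any() else float("nan")
    return out


def _involvement_from_vertex_counts(
    vertex_counts: np.ndarray,
    surfaces: Tuple[CorticalSurface, CorticalSurface],
    labels: Tuple[LabelTable, LabelTable],
    rule: str,
    networks: Sequence[int],
) -> Dict[int, float]:
    left, right = surfaces
    nl = left.n_vertices
    fields = []
    for surf, counts in ((left, vertex_counts[:nl]), (right, vertex_counts[nl:])):
        tri = counts[surf.triangles]
        fields.append(
            TriangleCountField(
                n=np.sort(tri, axis=1)[:, 1],
                any_hit=(tri >= 1).any(axis=1),
                hemisphere=surf.hemisphere,
            )
        )
    return network_involvement(tuple(fields), labels, rule=rule, networks=networks)


# ---------------------------------------------------------------------------
# virtual callosotomy
# ---------------------------------------------------------------------------

def callosotomy_profile(
    assignment: EndpointAssignment,
    segments: StreamlineSegments,
    labels: Tuple[LabelTable, LabelTable],
    surfaces: Tuple[CorticalSurface, CorticalSurface],
    extents: Sequence[float],
    rule: str = "median",
    metric: str = "triangles",
) -> VulnerabilityProfile:
    """Predicted per-network disruption under progressive anterior resection.

    For each extent ``j/k`` the tractogram is restricted to streamlines
    cut by an anterior-``j`` resection (any traversed segment <= j), the
    per-triangle count field is rebuilt from their endpoints only, and
    per-network involvement recomputed (``metric="triangles"``).  The
    alternative ``metric="fibres"`` reports, per network, the fraction of
    its callosal streamlines that are cut.
    """
    k = segments.k
    depths = []
    for e in extents:
        j = e * k
        if not (0 <= e <= 1) or abs(j - round(j)) > 1e-9 or round(j) < 0:
            raise ParameterError(
                f"extent {e} is not aligned to 1/{k} segment granularity"
            )
        depths.append(int(round(j)))

    left, right = surfaces
    labels_l, labels_r = labels
    lab_all = np.concatenate([labels_l.labels, labels_r.labels])
    networks = [int(n) for n in np.unique(lab_all[lab_all > 0])]

    n_total_vertices = len(assignment.vertex_counts)
    if metric == "fibres":
        stream_nets = _streamline_networks(assignment, surfaces, labels)

    columns = []
    for j in depths:
        cut = segments.cut_by(j) if j > 0 else np.zeros(
            segments.n_streamlines, dtype=bool
        )
        if metric == "triangles":
            keep = cut[assignment.streamline_index] & (assignment.vertex >= 0)
            counts = np.bincount(
                assignment.vertex[keep], minlength=n_total_vertices
            )
            inv = _involvement_from_vertex_counts(
                counts, surfaces, labels, rule, networks
            )
            columns.append([inv[n] for n in networks])
        elif metric == "fibres":
            col = []
            for net in networks:
                touching = stream_nets[net]
                denom = touching.sum()
                col.append(
                    float((touching & cut).sum() / denom) if denom else float("nan")
                )
            columns.append(col)
        else:
            raise ParameterError(f"unknown metric {metric!r}")

    return VulnerabilityProfile(
        networks=networks,
        extents=list(extents),
        values=np.asarray(columns, dtype=float).T,
    )


def _streamline_networks(assignment, surfaces, labels):
    """Boolean per-streamline membership per network, via endpoint vertices.

    A vertex inherits the smallest positive label among its incident
    triangles (deterministic rule for boundary vertices); a streamline
    touches a network when either endpoint's vertex carries that label.
    """
    left, right = surfaces
    labels_l, labels_r = labels
    nl = left.n_vertices
    vertex_label = np.zeros(len(assignment.vertex_counts), dtype=np.int64)
    big = np.iinfo(np.int64).max
    for surf, table, offset in ((left, labels_l, 0), (right, labels_r, nl)):
        vl = np.full(surf.n_vertices, big)
        tri_lab = table.labels
        pos = tri_lab > 0
        for corner in range(3):
            np.minimum.at(
                vl, surf.triangles[pos, corner], tri_lab[pos]
            )
        vl[vl == big] = 0
        vertex_label[offset:offset + surf.n_vertices] = vl

    n_stream = int(assignment.streamline_index.max()) + 1 if len(
        assignment.streamline_index
    ) else 0
    assigned = assignment.vertex >= 0
    ep_label = np.zeros(len(assignment.vertex), dtype=np.int64)
    ep_label[assigned] = vertex_label[assignment.vertex[assigned]]
    out = {}
    for net in np.unique(ep_label[ep_label > 0]):
        touching = np.zeros(n_stream, dtype=bool)
        touching[assignment.streamline_index[ep_label == net]] = True
        out[int(net)] = touching
    # networks never touched still need an entry
    all_nets = np.unique(
        np.concatenate([labels_l.labels, labels_r.labels])
    )
    for net in all_nets[all_nets > 0]:
        out.setdefault(int(net), np.zeros(n_stream, dtype=bool))
    return out


# ---------------------------------------------------------------------------
# 17 -> 7 downsampling
# ---------------------------------------------------------------------------

def downsample_17_to_7(
    profile: VulnerabilityProfile, mapping: NetworkMapping17to7
) -> VulnerabilityProfile:
    """Collapse a 17-network profile to 7 networks by weighted averaging.

    Each 7-network value at each extent is the weight-normalised mean of
    its contributing 17-network values; NaN contributions (empty
    networks) are excluded from the mean.
    """
    have = set(int(n) for n in profile.networks)
    missing = set(mapping.network17.tolist()) - have
    if missing:
        raise ValidationError(
            f"profile lacks networks referenced by the mapping: {sorted(missing)}"
        )
    row_of = {int(n): i for i, n in enumerate(profile.networks)}
    nets7 = sorted(set(mapping.network7.tolist()))
    values = np.full((len(nets7), len(profile.extents)), np.nan)
    for qi, q in enumerate(nets7):
        rows = mapping.network7 == q
        srcs = mapping.network17[rows]
        w = mapping.weight[rows]
        if w.sum() <= 0:
            raise ValidationError(f"weights for network7={q} are all zero")
        contrib = np.stack([profile.values[row_of[int(s)]] for s in srcs])
        wcol = w[:, None] * np.isfinite(contrib)
        with np.errstate(invalid="ignore"):
            values[qi] = np.nansum(w[:, None] * contrib, axis=0) / wcol.sum(axis=0)
    return VulnerabilityProfile(
        networks=[int(q) for q in nets7],
        extents=profile.extents,
        values=values,
    )


# ---------------------------------------------------------------------------
# reproducibility
# ---------------------------------------------------------------------------

def spearman_reproducibility(counts_a, counts_b) -> ReproducibilityResult:
    """Spearman rank correlation between paired per-triangle count vectors.

    Ties receive average ranks; the two-sided p-value uses the
    t-approximation ``t = rho * sqrt((n - 2) / (1 - rho^2))``.  A
    constant input vector makes rho undefined (reported as None).
    """
    a = np.asarray(counts_a, dtype=float).ravel()
    b = np.asarray(counts_b, dtype=float).ravel()
    if len(a) != len(b):
        raise ValidationError("count vectors must have equal length")
    if len(a) < 3:
        raise ValidationError("need at least 3 paired elements")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        return ReproducibilityResult(rho=None, p_value=None, n=len(a))
    res = stats.spearmanr(a, b)
    return ReproducibilityResult(
        rho=float(res.statistic), p_value=float(res.pvalue), n=len(a)
    )


def plot_profile(profile: VulnerabilityProfile, path, title: str = "") -> None:
    """Render a network x extent heat map (optional figure output)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, max(3, 0.35 * len(profile.networks))))
    im = ax.imshow(profile.values, aspect="auto", cmap="viridis",
                   vmin=0.0, vmax=1.0)
    ax.set_xticks(range(len(profile.extents)))
    ax.set_xticklabels([f"{e:.0%}" for e in profile.extents])
    ax.set_yticks(range(len(profile.networks)))
    ax.set_yticklabels([str(n) for n in profile.networks])
    ax.set_xlabel("anterior resection extent")
    ax.set_ylabel("network")
    if title:
        ax.set_title(title)
    fig.colorbar(im, ax=ax, label="involvement")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
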