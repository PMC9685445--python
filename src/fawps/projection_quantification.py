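"""Whole-brain projection quantification from SWC reconstructions.

Axonal innervation density is measured as axonal length per brain region:
every axonal edge of the reconstruction is subdivided into pieces no longer
than ``step_um`` and each piece's length accrues to the region label at its
midpoint in the annotation volume.  A region is a *target* when it receives
at least 1.0 mm of axon.

SWC is the standard 7-column text format (id, type, x, y, z, radius,
parent), coordinates in micrometers; type 1 = soma, 2 = axon, 3 = dendrite.
Only axonal edges (both endpoints type 2, plus the edge connecting the
first axon node to the soma root) contribute to projection profiles.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "NeuronReconstruction",
    "RegionAnnotationVolume",
    "ProjectionProfile",
    "ProjectionMatrix",
    "read_swc",
    "write_swc",
    "axon_length_by_region",
    "define_targets",
    "multitarget_stats",
    "projection_matrix",
    "motif_membership",
]

TARGET_THRESHOLD_MM = 1.0
OUTSIDE_LABEL = "outside"

SWC_SOMA, SWC_AXON, SWC_DENDRITE = 1, 2, 3
SWC_COLUMNS = ["id", "type", "x", "y", "z", "radius", "parent"]


@dataclass
class NeuronReconstruction:
    """An SWC neuron: a rooted tree of 3D nodes in micrometers."""

    nodes: pd.DataFrame  # columns: id, type, x, y, z, radius, parent

    def __post_init__(self):
        df = self.nodes
        if list(df.columns) != SWC_COLUMNS:
            raise ValueError(f"expected columns {SWC_COLUMNS}")
        ids = df["id"].to_numpy()
        if len(np.unique(ids)) != len(ids):
            raise ValueError("duplicate node ids")
        roots = df[df["parent"] == -1]
        if len(roots) != 1:
            raise ValueError(f"expected exactly one root, found {len(roots)}")
        id_set = set(ids.tolist())
        for _, row in df.iterrows():
            p = int(row["parent"])
            if p != -1 and p not in id_set:
                raise ValueError(f"node {int(row['id'])} references missing parent {p}")
        self._check_acyclic()

    def _check_acyclic(self):
        parent = dict(zip(self.nodes["id"].astype(int), self.nodes["parent"].astype(int)))
        seen_ok: set = set()
        for nid in parent:
            path = []
            cur = nid
            while cur != -1 and cur not in seen_ok:
                if cur in path:
                    raise ValueError(f"cycle detected at node {cur}")
                path.append(cur)
                cur = parent[cur]
            seen_ok.update(path)

    @property
    def soma(self) -> pd.Series:
        return self.nodes[self.nodes["parent"] == -1].iloc[0]

    def edges(self, types: tuple = (SWC_AXON,), include_root_edge: bool = True) -> np.ndarray:
        """(n_edges, 2, 3) array of child→parent segment endpoints (µm).

        Keeps edges whose endpoints are both of a requested type, plus —
        when ``include_root_edge`` — edges from a requested-type child to
        the soma root.
        """
        df = self.nodes
        pos = {int(r.id): np.array([r.x, r.y, r.z]) for r in df.itertuples()}
        typ = dict(zip(df["id"].astype(int), df["type"].astype(int)))
        out = []
        for r in df.itertuples():
            p = int(r.parent)
            if p == -1:
                continue
            child_t, parent_t = typ[int(r.id)], typ[p]
            if child_t in types and (
                parent_t in types or (include_root_edge and parent_t == SWC_SOMA)
            ):
                out.append([pos[int(r.id)], pos[p]])
        return np.array(out) if out else np.empty((0, 2, 3))


@dataclass
class RegionAnnotationVolume:
    """3D integer label volume (0 = outside any region) with voxel geometry.

    ``labels`` is indexed (z, y, x); ``voxel_um`` is the isotropic-per-axis
    voxel pitch (µm per axis, one value per (z, y, x) axis); ``origin_um``
    is the µm coordinate of the corner of voxel (0, 0, 0).  A point p (µm,
    (x, y, z)) falls in voxel floor((p − origin)/voxel) — half-open voxel
    ownership; out-of-bounds points are "outside".
    """

    labels: np.ndarray
    voxel_um: np.ndarray  # (3,) per (z, y, x)
    origin_um: np.ndarray = field(default_factory=lambda: np.zeros(3))
    id_to_acronym: dict = field(default_factory=dict)

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3 or np.any(self.labels < 0):
            raise ValueError("labels must be a 3D non-negative integer array")
        self.voxel_um = np.broadcast_to(np.asarray(self.voxel_um, dtype=float), (3,)).copy()
        if np.any(self.voxel_um <= 0):
            raise ValueError("voxel_um must be positive")
        self.origin_um = np.asarray(self.origin_um, dtype=float).reshape(3)

    def lookup(self, points_xyz_um: np.ndarray) -> np.ndarray:
        """Region id per point ((n, 3), µm, (x, y, z) order); 0 outside."""
        pts = np.atleast_2d(np.asarray(points_xyz_um, dtype=float))
        # volume axes are (z, y, x): reverse point order
        rel = pts[:, ::-1] - self.origin_um[None, :]
        idx = np.floor(rel / self.voxel_um[None, :]).astype(int)
        shape = np.array(self.labels.shape)
        inside = np.all((idx >= 0) & (idx < shape[None, :]), axis=1)
        out = np.zeros(len(pts), dtype=self.labels.dtype)
        ii = idx[inside]
        out[inside] = self.labels[ii[:, 0], ii[:, 1], ii[:, 2]]
        return out

    def acronym(self, region_id: int) -> str:
        if region_id == 0:
            return OUTSIDE_LABEL
        return self.id_to_acronym.get(int(region_id), str(int(region_id)))


@dataclass
class ProjectionProfile:
    """Per-region axonal length (mm) for one neuron, plus its target set."""

    length_mm: dict  # acronym -> mm (includes "outside" when nonzero)
    threshold_mm: float = TARGET_THRESHOLD_MM

    @property
    def total_mm(self) -> float:
        return float(sum(self.length_mm.values()))

    @property
    def targets(self) -> set:
        return define_targets(self, self.threshold_mm)

    @property
    def n_targets(self) -> int:
        return len(self.targets)


@dataclass
class ProjectionMatrix:
    """Neurons × regions projection tables.

    ``weighted`` holds mm of axon; ``binarized`` target membership
    (1 iff weighted ≥ threshold); ``class_probabilities`` the per-class
    fraction of members targeting each region.
    """

    weighted: pd.DataFrame
    binarized: pd.DataFrame
    class_probabilities: pd.DataFrame | None = None


# ---------------------------------------------------------------------------
# SWC IO


def read_swc(path_or_buffer) -> NeuronReconstruction:
    """Read a 7-column SWC file ('#' comments allowed)."""
    df = pd.read_csv(
        path_or_buffer, comment="#", sep=r"\s+", header=None, names=SWC_COLUMNS
    )
    if df.empty:
        raise ValueError("empty SWC file")
    df = df.astype(
        {"id": int, "type": int, "x": float, "y": float, "z": float,
         "radius": float, "parent": int}
    )
    return NeuronReconstruction(nodes=df.reset_index(drop=True))


def write_swc(neuron: NeuronReconstruction, path) -> None:
    """Write the standard 7-column SWC representation."""
    buf = io.StringIO()
    buf.write("# id type x y z radius parent\n")
    for r in neuron.nodes.itertuples():
        buf.write(
            f"{int(r.id)} {int(r.type)} {r.x:.6g} {r.y:.6g} {r.z:.6g} "
            f"{r.radius:.6g} {int(r.parent)}\n"
        )
    with open(path, "w") as fh:
        fh.write(buf.getvalue())


# ---------------------------------------------------------------------------
# Length quantification


def axon_length_by_region(
    neuron: NeuronReconstruction,
    volume: RegionAnnotationVolume,
    step_um: float = 1.0,
    threshold_mm: float = TARGET_THRESHOLD_MM,
) -> ProjectionProfile:
    """Per-region axonal length by midpoint assignment of ≤ step_um pieces.

    Each axonal edge is split into ceil(len/step_um) equal pieces; each
    piece's length accrues to the region containing its midpoint.  As
    step_um → 0 this converges to exact geometric clipping.  Lengths are
    reported in mm; pieces outside the volume accrue to "outside".
    """
    if step_um <= 0:
        raise ValueError("step_um must be positive")
    edges = neuron.edges(types=(SWC_AXON,), include_root_edge=True)
    totals: dict = {}
    for a, b in edges:
        seg = b - a
        seg_len = float(np.linalg.norm(seg))
        if seg_len == 0:
            continue
        n_pieces = int(np.ceil(seg_len / step_um))
        # midpoints of equal subdivisions
        frac = (np.arange(n_pieces) + 0.5) / n_pieces
        mids = a[None, :] + frac[:, None] * seg[None, :]
        ids = volume.lookup(mids)
        piece_len = seg_len / n_pieces
        for rid, count in zip(*np.unique(ids, return_counts=True)):
            key = volume.acronym(int(rid))
            totals[key] = totals.get(key, 0.0) + piece_len * int(count)
    length_mm = {k: v / 1000.0 for k, v in totals.items()}
    return ProjectionProfile(length_mm=length_mm, threshold_mm=threshold_mm)


def define_targets(profile: ProjectionProfile, threshold_mm: float = TARGET_THRESHOLD_MM) -> set:
    """Regions receiving ≥ threshold_mm of axon (inclusive), excluding
    the out-of-atlas remainder."""
    return {
        k for k, v in profile.length_mm.items()
        if k != OUTSIDE_LABEL and v >= threshold_mm
    }


def multitarget_stats(profiles: list) -> dict:
    """Cohort summaries of the multi-target projection structure."""
    if not profiles:
        raise ValueError("empty cohort")
    n_targets = np.array([p.n_targets for p in profiles])
    per_target_lengths = np.array(
        [length for p in profiles for a, length in p.length_mm.items() if a in p.targets]
    )
    totals = np.array([p.total_mm for p in profiles])
    q1, med, q3 = np.percentile(totals, [25, 50, 75])
    return {
        "fraction_multi_target": float(np.mean(n_targets > 1)),
        "fraction_seven_plus": float(np.mean(n_targets >= 7)),
        "mean_n_targets": float(n_targets.mean()),
        "sd_n_targets": float(n_targets.std(ddof=1)) if len(n_targets) > 1 else 0.0,
        "mean_length_per_target_mm": float(per_target_lengths.mean()) if len(per_target_lengths) else 0.0,
        "sd_length_per_target_mm": float(per_target_lengths.std(ddof=1)) if len(per_target_lengths) > 1 else 0.0,
        "median_total_length_mm": float(med),
        "q1_total_length_mm": float(q1),
        "q3_total_length_mm": float(q3),
    }


def projection_matrix(
    profiles: list,
    neuron_ids: list | None = None,
    class_labels: list | None = None,
    threshold_mm: float = TARGET_THRESHOLD_MM,
) -> ProjectionMatrix:
    """Weighted (mm) and binarized neurons × regions matrices, optionally
    with per-class projection probabilities."""
    if neuron_ids is None:
        neuron_ids = list(range(len(profiles)))
    if len(neuron_ids) != len(profiles):
        raise ValueError("neuron_ids length mismatch")
    regions = sorted({a for p in profiles for a in p.length_mm if a != OUTSIDE_LABEL})
    weighted = pd.DataFrame(
        [[p.length_mm.get(r, 0.0) for r in regions] for p in profiles],
        index=neuron_ids, columns=regions,
    )
    binarized = (weighted >= threshold_mm).astype(int)
    class_probs = None
    if class_labels is not None:
        if len(class_labels) != len(profiles):
            raise ValueError("class_labels length does not match cohort")
        lab = pd.Series(class_labels, index=weighted.index)
        counts = lab.value_counts()
        if (counts == 0).any() or len(counts) == 0:
            raise ValueError("empty class")
        class_probs = binarized.groupby(lab).mean()
    return ProjectionMatrix(weighted=weighted, binarized=binarized, class_probabilities=class_probs)


def motif_membership(profile: ProjectionProfile, motif_regions: set, mode: str = "any") -> bool:
    """Whether a neuron participates in a projection motif.

    mode "any": at least one motif region is a target; mode "all": every
    motif region is a target.
    """
    if not motif_regions:
        raise ValueError("motif_regions must be non-empty")
    targets = profile.targets
    if mode == "any":
        return bool(targets & set(motif_regions))
    if mode == "all":
        return set(motif_regions) <= targets
    raise ValueError(f"unknown mode {mode!r}")
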