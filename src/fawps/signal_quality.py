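"""Image-quality metrics for reconstructed axons.

Three metrics:

* **Axonal SNR** — sampled every 40 µm of straight-line distance from the
  soma along the reconstruction; at each sampling node, SNR = (mean local
  signal − mean surrounding background) / SD of background, with the local
  signal the 6 face-adjacent voxels of a shaft point (8 in-plane neighbours
  for an axon ending) and the background a spherical voxel shell around the
  point.

* **SBR** — on a 23-pixel linear profile across a single fiber:
  (FSI − BSI)/BSI with FSI the peak value and BSI the mean of the four
  lowest pixels.

* **Colabeling ratio** — colabeled axonal segments / reference-labeled
  segments.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .projection_quantification import SWC_AXON, NeuronReconstruction

__all__ = [
    "SnrProfile",
    "FiberProfile",
    "select_sampling_points",
    "snr_at_point",
    "median_full_length_snr",
    "compute_sbr",
    "colabeling_ratio",
]

SNR_INTERVAL_UM = 40.0
FIBER_PROFILE_LEN = 23
SBR_N_LOWEST = 4


@dataclass
class SnrProfile:
    """Per-sampling-point SNR along one neuron's axon."""

    sampling_points: list  # (node_id, distance_um, snr, is_ending)

    @property
    def median_snr(self) -> float:
        return median_full_length_snr(self)

    @property
    def ending_snrs(self) -> list:
        return [s for (_, _, s, ending) in self.sampling_points if ending]


@dataclass
class FiberProfile:
    """Intensity profile of a 23-pixel line crossing a single fiber."""

    intensities: np.ndarray

    def __post_init__(self):
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.intensities.shape != (FIBER_PROFILE_LEN,):
            raise ValueError(f"profile must have exactly {FIBER_PROFILE_LEN} values")
        if np.any(self.intensities < 0):
            raise ValueError("negative intensities")


# ---------------------------------------------------------------------------
# Sampling points


def _branch_ids(neuron: NeuronReconstruction) -> dict:
    """Assign a branch index per node: a new branch starts at the root and at
    every child of a multi-child node."""
    df = neuron.nodes
    parent = dict(zip(df["id"].astype(int), df["parent"].astype(int)))
    children: dict = {}
    for nid, p in parent.items():
        children.setdefault(p, []).append(nid)
    branch: dict = {}
    next_branch = 0
    root = int(df[df["parent"] == -1].iloc[0]["id"])
    stack = [(root, next_branch)]
    next_branch += 1
    while stack:
        nid, b = stack.pop()
        branch[nid] = b
        kids = children.get(nid, [])
        if len(kids) == 1:
            stack.append((kids[0], b))
        else:
            for k in kids:
                stack.append((k, next_branch))
                next_branch += 1
    return branch


def select_sampling_points(
    neuron: NeuronReconstruction,
    interval_um: float = SNR_INTERVAL_UM,
    tolerance_um: float | None = None,
) -> list:
    """Nodes whose straight-line (Euclidean) distance to the soma is an
    integer multiple of ``interval_um``, within ``tolerance_um``.

    For each (branch, multiple) the single closest node is kept; distance
    ties break toward the lower node id.  Default tolerance is half the
    median inter-node spacing (exact multiples essentially never occur on
    real reconstructions).

    Returns a list of (node_id, distance_um, is_ending) sorted by distance.
    """
    if interval_um <= 0:
        raise ValueError("interval_um must be positive")
    df = neuron.nodes
    soma = neuron.soma
    soma_xyz = np.array([soma["x"], soma["y"], soma["z"]])
    axon = df[df["type"] == SWC_AXON]
    if axon.empty:
        return []
    xyz = axon[["x", "y", "z"]].to_numpy()
    dists = np.linalg.norm(xyz - soma_xyz[None, :], axis=1)
    ids = axon["id"].astype(int).to_numpy()
    if tolerance_um is None:
        parent = dict(zip(df["id"].astype(int), df["parent"].astype(int)))
        pos = {int(r.id): np.array([r.x, r.y, r.z]) for r in df.itertuples()}
        spacings = [
            np.linalg.norm(pos[n] - pos[parent[n]]) for n in ids if parent[n] != -1
        ]
        tolerance_um = float(np.median(spacings)) / 2.0 if spacings else interval_um / 2.0
    branch = _branch_ids(neuron)
    has_child = set(df["parent"].astype(int))
    best: dict = {}  # (branch, k) -> (offset, node_id, distance)
    for nid, d in zip(ids, dists):
        k = int(round(d / interval_um))
        if k < 1:
            continue
        offset = abs(d - k * interval_um)
        if offset > tolerance_um:
            continue
        key = (branch[nid], k)
        cur = best.get(key)
        if cur is None or (offset, nid) < (cur[0], cur[1]):
            best[key] = (offset, nid, d)
    out = [
        (nid, float(d), nid not in has_child) for (_, nid, d) in best.values()
    ]
    out.sort(key=lambda t: (t[1], t[0]))
    return out


# ---------------------------------------------------------------------------
# SNR


_FACE_NEIGHBORS_3D = np.array(
    [[1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0], [0, 0, 1], [0, 0, -1]]
)
_INPLANE_NEIGHBORS_8 = np.array(
    [[0, dy, dx] for dy in (-1, 0, 1) for dx in (-1, 0, 1) if (dy, dx) != (0, 0)]
)


def snr_at_point(
    image: np.ndarray,
    point_zyx: tuple,
    is_ending: bool = False,
    shell_radii: tuple = (3.0, 6.0),
    exclude_radius: float = 1.0,
) -> float:
    """SNR at one sampling point of a 3D image.

    Signal = mean of the point's 6 face-adjacent voxels (8 in-plane
    neighbours of the terminal voxel's plane for an ending).  Background =
    voxels in the spherical shell [r_in, r_out] around the point, excluding
    anything within ``exclude_radius`` of the signal neighbourhood.  SNR =
    (signal mean − background mean) / background SD; zero background SD
    raises (SNR undefined).
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 3:
        raise ValueError("image must be 3D")
    p = np.asarray(point_zyx, dtype=int).reshape(3)
    offsets = _INPLANE_NEIGHBORS_8 if is_ending else _FACE_NEIGHBORS_3D
    neigh = p[None, :] + offsets
    shape = np.array(image.shape)
    if np.any(neigh < 0) or np.any(neigh >= shape[None, :]):
        raise ValueError("signal neighbourhood outside image")
    signal_mean = float(image[neigh[:, 0], neigh[:, 1], neigh[:, 2]].mean())

    r_in, r_out = shell_radii
    r = int(np.ceil(r_out))
    lo = p - r
    hi = p + r + 1
    if np.any(lo < 0) or np.any(hi > shape):
        raise ValueError("background shell outside image")
    zz, yy, xx = np.mgrid[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
    dist = np.sqrt((zz - p[0]) ** 2 + (yy - p[1]) ** 2 + (xx - p[2]) ** 2)
    in_shell = (dist >= r_in) & (dist <= r_out)
    # exclude signal voxels and anything hugging the centerline point
    sig_keys = {tuple(n) for n in neigh}
    sig_keys.add(tuple(p))
    keep = in_shell.copy()
    if exclude_radius > 0:
        coords = np.stack([zz, yy, xx], axis=-1)
        for s in sig_keys:
            d2 = ((coords - np.array(s)) ** 2).sum(axis=-1)
            keep &= d2 > exclude_radius**2
    bg = image[zz[keep], yy[keep], xx[keep]]
    if bg.size < 2:
        raise ValueError("background shell empty")
    bg_sd = float(bg.std(ddof=1))
    if bg_sd == 0:
        raise ValueError("zero background SD: SNR undefined")
    return (signal_mean - float(bg.mean())) / bg_sd


def median_full_length_snr(profile: SnrProfile) -> float:
    """Median SNR over all sampling points (even count → mean of the middle
    pair)."""
    snrs = [s for (_, _, s, _) in profile.sampling_points]
    if not snrs:
        raise ValueError("empty SNR profile")
    return float(np.median(snrs))


# ---------------------------------------------------------------------------
# SBR and colabeling


def compute_sbr(profile: FiberProfile) -> float:
    """SBR = (FSI − BSI)/BSI; FSI = profile peak, BSI = mean of the 4 lowest
    pixels."""
    vals = profile.intensities
    fsi = float(vals.max())
    bsi = float(np.sort(vals)[:SBR_N_LOWEST].mean())
    if bsi <= 0:
        raise ValueError("non-positive background: SBR undefined")
    return (fsi - bsi) / bsi


def colabeling_ratio(n_colabeled: int, n_reference: int) -> float:
    """Fraction of reference-labeled axonal segments that are colabeled."""
    if n_reference <= 0:
        raise ValueError("n_reference must be > 0")
    if n_colabeled > n_reference:
        raise ValueError("colabeled count exceeds reference count")
    return n_colabeled / n_reference
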