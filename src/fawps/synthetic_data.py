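"""Synthetic-data generators with analytic ground truth.

Every input the pipeline consumes can be generated here so that each stage
is testable without external data:

* trial tensors drawn from the spatiotemporal Gaussian tuning model with a
  per-direction gain enforcing an exact target OSI,
* frame stacks with planted integer translations (motion-correction
  fixtures),
* axis-aligned box-world region annotation volumes,
* SWC neurons built from waypoint polylines with analytically clipped
  per-region lengths (exact oracles for the projection stage),
* paired landmark sets under known affine transforms,
* per-neuron cohorts with (R², OSI) class structure and a planted Spearman
  correlation between one functional index and one region's axonal length.

All randomness flows through an explicit seed; regenerating any fixture
with the same seed is bit-identical.  Region geometry is restricted to
axis-aligned boxes so clipped lengths have closed forms.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .calcium_processing import StimulusGrid, TrialTensor
from .cross_modality_matching import AffineTransform2D
from .projection_quantification import (
    SWC_AXON,
    SWC_SOMA,
    NeuronReconstruction,
    RegionAnnotationVolume,
)
from .tuning_quantification import eval_model

__all__ = [
    "GroundTruthNeuronSpec",
    "CohortSpec",
    "gen_response_tensor",
    "gen_frame_stack",
    "gen_label_volume",
    "gen_swc_neuron",
    "gen_landmark_pair",
    "gen_cohort",
    "segment_length_in_box",
]


@dataclass(frozen=True)
class GroundTruthNeuronSpec:
    """Generative parameters of one synthetic neuron.

    ``tuning_params`` = (A, sf0, tf0, sigma_sf, sigma_tf, xi): peak ΔF/F %
    amplitude, preferred spatial (cpd) and temporal (Hz) frequency, tuning
    widths (octaves), and the power-law exponent tying preferred TF to SF.
    ``osi_target`` is realized exactly in the noiseless tensor.
    ``branch_plan`` lists (waypoints µm, intended region id) axon polylines.
    """

    tuning_params: tuple  # (A, sf0, tf0, sigma_sf, sigma_tf, xi)
    osi_target: float = 0.0
    pref_orientation: str = "horizontal"
    soma_xyz: tuple = (0.0, 0.0, 0.0)
    branch_plan: tuple = ()

    def __post_init__(self):
        A, sf0, tf0, ssf, stf, _xi = self.tuning_params
        if A <= 0 or sf0 <= 0 or tf0 <= 0 or ssf <= 0 or stf <= 0:
            raise ValueError("invalid spec: A, sf0, tf0, sigma_sf, sigma_tf must be > 0")
        if not 0.0 <= self.osi_target <= 1.0:
            raise ValueError("invalid spec: osi_target must lie in [0, 1]")


@dataclass(frozen=True)
class CohortSpec:
    """Generative parameters of a synthetic neuron cohort.

    ``planted_spearman`` is the rank correlation planted between
    ``corr_feature`` (r2 or osi) and the axonal length in ``corr_region``.
    ``class_centroids`` are (R², OSI) functional-class centers;
    ``noise_sd`` the per-feature spread around them.
    """

    n_neurons: int = 38
    planted_spearman: float = 0.0
    corr_feature: str = "osi"
    corr_region: str = "MOs"
    class_centroids: tuple = ((0.8, 0.7), (0.8, 0.2), (0.3, 0.15))
    # within-class SD set so the minimum centroid spacing (0.5) is >= 10x SD
    noise_sd: float = 0.05
    region_names: tuple = ("VISp", "VISa", "VISrl", "MOs", "ACA", "SSp")
    seed: int = 0

    def __post_init__(self):
        if self.n_neurons < 2:
            raise ValueError("n_neurons must be >= 2")
        if abs(self.planted_spearman) > 1:
            raise ValueError("|planted_spearman| must be <= 1")
        if self.corr_region not in self.region_names:
            raise ValueError("corr_region must be one of region_names")
        if self.corr_feature not in ("r2", "osi"):
            raise ValueError("corr_feature must be 'r2' or 'osi'")


# ---------------------------------------------------------------------------
# Response tensors


def gen_response_tensor(
    spec: GroundTruthNeuronSpec,
    grid: StimulusGrid | None = None,
    noise_sd: float = 0.0,
    n_trials: int | None = None,
    seed: int | None = 0,
    clip_at_zero: bool = True,
) -> TrialTensor:
    """Per-trial max-ΔF/F tensor from the tuning model plus noise.

    The noiseless expectation at (sf, tf) equals the Gaussian tuning model;
    a shared per-direction gain scales the two directions of the
    non-preferred orientation by (1 − OSI)/(1 + OSI) so the generated
    tensor's OSI equals ``osi_target`` exactly in the noiseless case.
    Negative noisy draws are rectified at 0 (responses are ΔF/F maxima).
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    grid = grid or StimulusGrid()
    if n_trials is not None and n_trials != grid.n_trials:
        grid = StimulusGrid(
            temporal_freqs=grid.temporal_freqs,
            spatial_freqs=grid.spatial_freqs,
            directions=grid.directions,
            n_trials=n_trials,
            movement_s=grid.movement_s,
            rest_s=grid.rest_s,
        )
    A, sf0, tf0, ssf, stf, xi = spec.tuning_params
    tfs = np.asarray(grid.temporal_freqs)
    sfs = np.asarray(grid.spatial_freqs)
    tf_grid, sf_grid = np.meshgrid(tfs, sfs, indexing="ij")
    base = eval_model(sf_grid, tf_grid, A, sf0, tf0, ssf, stf, xi)  # (tf, sf)

    ortho_gain = (1.0 - spec.osi_target) / (1.0 + spec.osi_target)
    horizontal = {180.0, 360.0}
    gains = []
    for d in grid.directions:
        is_horizontal = float(d) in horizontal
        pref = spec.pref_orientation == ("horizontal" if is_horizontal else "vertical")
        gains.append(1.0 if pref else ortho_gain)
    gains = np.asarray(gains)

    expected = base[:, :, None] * gains[None, None, :]
    tensor = np.repeat(expected[:, :, :, None], grid.n_trials, axis=3)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        tensor = tensor + rng.normal(scale=noise_sd, size=tensor.shape)
        if clip_at_zero:
            tensor = np.clip(tensor, 0.0, None)
    return TrialTensor(dff_max=tensor, grid=grid)


# ---------------------------------------------------------------------------
# Frame stacks


def gen_frame_stack(
    n_frames: int,
    shift_schedule,
    cell_layout=((20.0, 20.0, 3.0), (40.0, 28.0, 2.5), (12.0, 44.0, 2.0)),
    frame_shape: tuple = (64, 64),
    amplitude: float = 100.0,
    noise_sd: float = 0.0,
    seed: int | None = 0,
) -> tuple:
    """Frame stack with planted integer (dy, dx) translations.

    The base frame is a sum of Gaussian cells at ``cell_layout`` (y, x,
    radius); frame i is the base circularly shifted by its scheduled shift
    plus i.i.d. pixel noise.  Returns (stack, true_shifts).
    """
    shifts = np.asarray(shift_schedule, dtype=int)
    if shifts.shape != (n_frames, 2):
        raise ValueError("shift_schedule must be (n_frames, 2)")
    bound = min(frame_shape) // 4
    if np.any(np.abs(shifts) >= bound):
        raise ValueError(f"shifts must be smaller than ¼ frame size ({bound} px)")
    yy, xx = np.mgrid[0 : frame_shape[0], 0 : frame_shape[1]]
    base = np.zeros(frame_shape)
    for cy, cx, r in cell_layout:
        base += amplitude * np.exp(-((yy - cy) ** 2 + (xx - cx) ** 2) / (2.0 * r**2))
    rng = np.random.default_rng(seed)
    frames = []
    for i in range(n_frames):
        f = np.roll(base, (shifts[i, 0], shifts[i, 1]), axis=(0, 1))
        if noise_sd > 0:
            f = f + rng.normal(scale=noise_sd, size=frame_shape)
        frames.append(f)
    return np.stack(frames), shifts


# ---------------------------------------------------------------------------
# Label volumes and SWC neurons


def gen_label_volume(
    shape_voxels: tuple,
    voxel_um,
    region_boxes,
    id_to_acronym: dict | None = None,
) -> RegionAnnotationVolume:
    """Axis-aligned box-world annotation volume.

    ``region_boxes`` is a list of (region_id, (lo_xyz_um, hi_xyz_um)) with
    half-open boxes [lo, hi): a voxel carries a region id iff its center
    lies inside the box.  Boxes must be disjoint and inside the volume.
    """
    voxel = np.broadcast_to(np.asarray(voxel_um, dtype=float), (3,)).copy()  # (z, y, x)
    labels = np.zeros(shape_voxels, dtype=np.int32)
    extent_zyx = np.asarray(shape_voxels) * voxel
    centers = [
        (np.arange(shape_voxels[ax]) + 0.5) * voxel[ax] for ax in range(3)
    ]
    for rid, (lo, hi) in region_boxes:
        lo = np.asarray(lo, dtype=float)  # (x, y, z)
        hi = np.asarray(hi, dtype=float)
        if np.any(lo >= hi):
            raise ValueError("box must have lo < hi on every axis")
        if np.any(lo[::-1] < 0) or np.any(hi[::-1] > extent_zyx):
            raise ValueError(f"region {rid} box extends outside the volume")
        masks = [
            (centers[ax] >= lo[::-1][ax]) & (centers[ax] < hi[::-1][ax]) for ax in range(3)
        ]
        region = np.ix_(*[np.nonzero(m)[0] for m in masks])
        if np.any(labels[region] != 0):
            raise ValueError(f"region {rid} overlaps a previously placed box")
        labels[region] = rid
    return RegionAnnotationVolume(
        labels=labels,
        voxel_um=voxel,
        origin_um=np.zeros(3),
        id_to_acronym=dict(id_to_acronym or {}),
    )


def segment_length_in_box(a, b, lo, hi) -> float:
    """Exact length of segment a→b inside the axis-aligned box [lo, hi)
    (µm, (x, y, z) coordinates) — the slab-clipping closed form."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    lo = np.asarray(lo, dtype=float)
    hi = np.asarray(hi, dtype=float)
    d = b - a
    t0, t1 = 0.0, 1.0
    for ax in range(3):
        if d[ax] == 0:
            if not (lo[ax] <= a[ax] < hi[ax]):
                return 0.0
        else:
            ta = (lo[ax] - a[ax]) / d[ax]
            tb = (hi[ax] - a[ax]) / d[ax]
            t0 = max(t0, min(ta, tb))
            t1 = min(t1, max(ta, tb))
    if t1 <= t0:
        return 0.0
    return float((t1 - t0) * np.linalg.norm(d))


def _resample_polyline(waypoints: np.ndarray, spacing: float) -> np.ndarray:
    """Insert nodes along each waypoint segment every ``spacing`` µm,
    keeping the waypoints themselves (geometry is exactly preserved)."""
    pts = [waypoints[0]]
    for a, b in zip(waypoints[:-1], waypoints[1:]):
        seg = b - a
        seg_len = np.linalg.norm(seg)
        if seg_len == 0:
            continue
        n = max(1, int(np.ceil(seg_len / spacing)))
        for i in range(1, n + 1):
            pts.append(a + seg * (i / n))
    return np.asarray(pts)


def gen_swc_neuron(
    spec: GroundTruthNeuronSpec,
    node_spacing: float = 5.0,
    region_boxes=None,
    id_to_acronym: dict | None = None,
) -> tuple:
    """SWC reconstruction from the spec's branch plan, with an analytic
    per-region length table.

    The soma (type 1) roots the tree; each branch polyline is resampled at
    ``node_spacing`` and attached to the soma (the connecting soma→first-
    waypoint segment, when of nonzero length, is part of the axon geometry
    and is included in the analytic table).  The table gives the exact
    clipped length (mm) of the geometry inside each region box, plus the
    "outside" remainder.

    Returns (NeuronReconstruction, {acronym: length_mm}).
    """
    if node_spacing <= 0:
        raise ValueError("node_spacing must be positive")
    soma = np.asarray(spec.soma_xyz, dtype=float)
    rows = [(1, SWC_SOMA, *soma, 5.0, -1)]
    next_id = 2
    segments = []  # (a, b) µm, axon geometry
    for waypoints, _region_intent in spec.branch_plan:
        wp = np.atleast_2d(np.asarray(waypoints, dtype=float))
        if not np.all(np.isfinite(wp)):
            raise ValueError("non-finite waypoints")
        full = wp if np.allclose(wp[0], soma) else np.vstack([soma, wp])
        nodes = _resample_polyline(full, node_spacing)
        parent = 1
        for p in nodes[1:]:  # nodes[0] is the soma position
            rows.append((next_id, SWC_AXON, *p, 0.5, parent))
            parent = next_id
            next_id += 1
        segments.extend(zip(full[:-1], full[1:]))

    neuron = NeuronReconstruction(
        nodes=pd.DataFrame(rows, columns=["id", "type", "x", "y", "z", "radius", "parent"])
    )

    id_to_acronym = dict(id_to_acronym or {})
    table: dict = {}
    total = 0.0
    for a, b in segments:
        seg_len = float(np.linalg.norm(np.asarray(b) - np.asarray(a)))
        total += seg_len
        if region_boxes:
            for rid, (lo, hi) in region_boxes:
                inside = segment_length_in_box(a, b, lo, hi)
                if inside > 0:
                    key = id_to_acronym.get(rid, str(rid))
                    table[key] = table.get(key, 0.0) + inside
    covered = sum(table.values())
    if total - covered > 1e-9:
        table["outside"] = total - covered
    return neuron, {k: v / 1000.0 for k, v in table.items()}


# ---------------------------------------------------------------------------
# Landmarks


def gen_landmark_pair(
    true_transform: AffineTransform2D,
    n: int,
    noise_sd: float = 0.0,
    seed: int | None = 0,
    extent: float = 100.0,
) -> tuple:
    """Paired landmark sets under a known affine: P2 = P1·R + T + noise.

    P1 is drawn uniformly in [0, extent]²; for n ≥ 3 draws are rejected
    until the centered P1 has rank 2 (non-collinear).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    for _ in range(1000):
        P1 = rng.uniform(0.0, extent, size=(n, 2))
        if n < 3 or np.linalg.matrix_rank(P1 - P1.mean(axis=0), tol=1e-6) == 2:
            break
    else:  # pragma: no cover
        raise RuntimeError("failed to draw non-collinear landmarks")
    P2 = P1 @ true_transform.R + true_transform.T
    if noise_sd > 0:
        P2 = P2 + rng.normal(scale=noise_sd, size=P2.shape)
    return P1, P2


# ---------------------------------------------------------------------------
# Cohorts


def gen_cohort(spec: CohortSpec) -> tuple:
    """Per-neuron table of functional indices and per-region axonal lengths
    with a planted rank correlation.

    (R², OSI) rows are drawn around the class centroids (clipped to their
    valid ranges).  The length in ``corr_region`` is a strictly monotone
    transform of a Gaussian-copula variate correlated with the normal
    scores of the chosen feature's ranks; the Pearson parameter is
    2·sin(π·ρs/6) so the population Spearman equals ``planted_spearman``
    (exact at ±1).  Other regions get independent log-normal lengths.

    Returns (table, ground_truth) where ``table`` has columns neuron_id,
    r2, osi, one mm column per region, and ``ground_truth`` records class
    labels and the planted correlation.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_neurons
    centroids = np.asarray(spec.class_centroids, dtype=float)
    classes = np.arange(n) % len(centroids)
    rng.shuffle(classes)
    feats = centroids[classes] + rng.normal(scale=spec.noise_sd, size=(n, 2))
    r2 = np.clip(feats[:, 0], -1.0, 1.0)
    osi = np.clip(feats[:, 1], 0.0, 1.0)

    feature_vals = {"r2": r2, "osi": osi}[spec.corr_feature]
    if np.ptp(feature_vals) == 0:
        raise ValueError("planted-correlation feature is constant; increase noise_sd "
                         "or separate the class centroids")
    from scipy import stats as _stats

    ranks = _stats.rankdata(feature_vals)
    z_feat = _stats.norm.ppf((ranks - 0.5) / n)
    rho_p = 2.0 * np.sin(np.pi * spec.planted_spearman / 6.0)
    eps = rng.standard_normal(n)
    z_len = rho_p * z_feat + np.sqrt(max(0.0, 1.0 - rho_p**2)) * eps
    # strictly monotone map to mm, centred well above the 1.0 mm target rule
    corr_lengths = 2.5 * np.exp(0.6 * z_len)

    data = {"neuron_id": np.arange(n), "r2": r2, "osi": osi}
    for region in spec.region_names:
        if region == spec.corr_region:
            data[region] = corr_lengths
        else:
            data[region] = np.exp(rng.normal(loc=np.log(2.0), scale=0.8, size=n))
    table = pd.DataFrame(data)
    ground_truth = {
        "class_labels": classes + 1,
        "planted_spearman": spec.planted_spearman,
        "corr_feature": spec.corr_feature,
        "corr_region": spec.corr_region,
        "centroids": centroids,
    }
    return table, ground_truth
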