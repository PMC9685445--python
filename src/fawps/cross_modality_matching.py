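"""Cross-modality cell matching between in-vivo 2D functional images and
whole-brain structural volumes.

The workflow: crop the structural block around the injection site, rigidly
rotate it so the cortical-surface normal aligns with the functional z-axis,
take a maximal-intensity projection (MIP) over a depth slab, estimate a 2D
affine transform from paired landmarks, map functional cell positions into
MIP coordinates, and assign functional↔structural cell pairs.

The landmark transform minimizes ‖P1·R + T − P2‖ over a 2×2 linear map R
and translation T.  The closed-form least-squares solution fixes
T* = mean(P2) − mean(P1) and obtains R* from the Moore–Penrose pseudoinverse
of the centered source landmarks.

Coordinate convention: points are row vectors (x, y) in pixels, origin at
the image upper-left, y increasing downward.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "AffineTransform2D",
    "LandmarkSet",
    "RigidRotation3D",
    "MatchResult",
    "rotation_to_z",
    "crop_and_mip",
    "estimate_affine",
    "apply_affine",
    "invert_affine",
    "match_cells",
    "bookkeeping_rates",
]


@dataclass(frozen=True)
class AffineTransform2D:
    """p ↦ p·R + T for row-vector points p (pixels)."""

    R: np.ndarray  # 2x2
    T: np.ndarray  # 2-vector

    def __post_init__(self):
        object.__setattr__(self, "R", np.asarray(self.R, dtype=float).reshape(2, 2))
        object.__setattr__(self, "T", np.asarray(self.T, dtype=float).reshape(2))
        if not (np.all(np.isfinite(self.R)) and np.all(np.isfinite(self.T))):
            raise ValueError("non-finite transform")

    @classmethod
    def identity(cls) -> "AffineTransform2D":
        return cls(R=np.eye(2), T=np.zeros(2))


@dataclass
class LandmarkSet:
    """Paired landmark coordinates: P1 in the functional image, P2 in the MIP."""

    P1: np.ndarray  # (n, 2)
    P2: np.ndarray  # (n, 2)

    def __post_init__(self):
        self.P1 = np.atleast_2d(np.asarray(self.P1, dtype=float))
        self.P2 = np.atleast_2d(np.asarray(self.P2, dtype=float))
        if self.P1.shape != self.P2.shape or self.P1.shape[1] != 2:
            raise ValueError("P1 and P2 must be matching (n, 2) arrays")

    @property
    def n(self) -> int:
        return self.P1.shape[0]


@dataclass(frozen=True)
class RigidRotation3D:
    """Orthonormal rotation aligning a source unit normal with +z."""

    rotation: np.ndarray  # 3x3
    source_normal: np.ndarray  # unit 3-vector


@dataclass
class MatchResult:
    """Functional↔structural cell assignment.

    ``pairs`` holds (functional id, structural id, residual pixel distance);
    ``matching_rate`` = matched / (matched + unmatched) functional cells.
    """

    pairs: list
    unmatched: list
    matching_rate: float = field(init=False)

    def __post_init__(self):
        total = len(self.pairs) + len(self.unmatched)
        self.matching_rate = len(self.pairs) / total if total else float("nan")


# ---------------------------------------------------------------------------
# Rigid rotation and MIP


def rotation_to_z(normal) -> RigidRotation3D:
    """Minimal rotation mapping a (non-zero) normal vector onto (0, 0, 1).

    Rotates about the axis normal × z.  The antiparallel case (normal ≈ −z)
    uses a 180° rotation about the x-axis by convention.
    """
    v = np.asarray(normal, dtype=float).reshape(3)
    norm = np.linalg.norm(v)
    if norm == 0:
        raise ValueError("zero normal vector")
    u = v / norm
    z = np.array([0.0, 0.0, 1.0])
    c = float(np.dot(u, z))
    axis = np.cross(u, z)
    s = np.linalg.norm(axis)
    if s < 1e-12:
        if c > 0:
            rot = np.eye(3)
        else:  # antiparallel: 180° about x
            rot = np.diag([1.0, -1.0, -1.0])
        return RigidRotation3D(rotation=rot, source_normal=u)
    axis = axis / s
    K = np.array(
        [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
    )
    rot = np.eye(3) + s * K + (1 - c) * (K @ K)
    return RigidRotation3D(rotation=rot, source_normal=u)


def crop_and_mip(volume: np.ndarray, z_start: int, z_stop: int) -> np.ndarray:
    """Maximal-intensity projection of the depth slab [z_start, z_stop).

    ``volume`` is (nz, ny, nx); the slab must be non-empty and inside it.
    """
    volume = np.asarray(volume)
    if not (0 <= z_start < z_stop <= volume.shape[0]):
        raise ValueError("empty or out-of-range depth slab")
    return volume[z_start:z_stop].max(axis=0)


# ---------------------------------------------------------------------------
# Landmark affine


class AffineSkipped(Exception):
    """Raised when fewer than three landmarks are available: the affine step
    is skipped and a fallback (translation or identity) applies."""


def estimate_affine(landmarks: LandmarkSet, allow_fallback: bool = True):
    """Least-squares 2D affine from paired landmarks.

    T* = mean(P2) − mean(P1); R* = pinv(P1 − mean(P1)) · (P2 − mean(P2)),
    the least-squares linear map on centered coordinates.

    With fewer than three landmark pairs the affine is skipped: if
    ``allow_fallback`` the pure translation mean(P2) − mean(P1) (identity R)
    is returned with ``skipped=True``, otherwise :class:`AffineSkipped` is
    raised.  Collinear source landmarks raise a rank-deficiency error.

    Returns (transform, residual_rms, skipped).
    """
    P1, P2 = landmarks.P1, landmarks.P2
    if landmarks.n < 3:
        if not allow_fallback:
            raise AffineSkipped(f"only {landmarks.n} landmarks (< 3): affine skipped")
        T = P2.mean(axis=0) - P1.mean(axis=0) if landmarks.n else np.zeros(2)
        t = AffineTransform2D(R=np.eye(2), T=T)
        res = float(np.sqrt(np.mean(np.sum((apply_affine(t, P1) - P2) ** 2, axis=1)))) if landmarks.n else 0.0
        return t, res, True
    c1 = P1.mean(axis=0)
    c2 = P2.mean(axis=0)
    P1c = P1 - c1
    if np.linalg.matrix_rank(P1c, tol=1e-9) < 2:
        raise ValueError("collinear source landmarks: rank-deficient system")
    R = np.linalg.pinv(P1c) @ (P2 - c2)
    # translation consistent with p·R + T mapping the centroid exactly
    T = c2 - c1 @ R
    t = AffineTransform2D(R=R, T=T)
    residual = float(np.sqrt(np.mean(np.sum((apply_affine(t, P1) - P2) ** 2, axis=1))))
    return t, residual, False


def apply_affine(t: AffineTransform2D, points) -> np.ndarray:
    """Map row-vector points through p·R + T."""
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    return pts @ t.R + t.T


def invert_affine(t: AffineTransform2D) -> AffineTransform2D:
    """Inverse transform: apply(invert(t), apply(t, p)) = p."""
    det = np.linalg.det(t.R)
    if abs(det) < 1e-15:
        raise ValueError("singular linear part: transform not invertible")
    R_inv = np.linalg.inv(t.R)
    return AffineTransform2D(R=R_inv, T=-t.T @ R_inv)


# ---------------------------------------------------------------------------
# Cell assignment and bookkeeping


def _descriptor_similarity(d1, d2) -> float:
    """Cosine similarity of two non-negative descriptor vectors."""
    a = np.asarray(d1, dtype=float)
    b = np.asarray(d2, dtype=float)
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        return 0.0
    return float(np.dot(a, b) / (na * nb))


def match_cells(
    functional: np.ndarray,
    structural: np.ndarray,
    max_dist: float,
    functional_descriptors=None,
    structural_descriptors=None,
    descriptor_threshold: float = 0.5,
) -> MatchResult:
    """Mutual-nearest-neighbor cell assignment within ``max_dist`` pixels.

    ``functional`` points must already be mapped into MIP coordinates.
    Candidate pairs are mutual nearest neighbours within the distance
    threshold; when per-cell fiber descriptors are supplied, pairs must also
    exceed ``descriptor_threshold`` cosine similarity.  Conflicts are
    resolved greedily by ascending distance, each structural cell used at
    most once.
    """
    F = np.atleast_2d(np.asarray(functional, dtype=float)) if len(functional) else np.empty((0, 2))
    S = np.atleast_2d(np.asarray(structural, dtype=float)) if len(structural) else np.empty((0, 2))
    if F.shape[0] == 0 or S.shape[0] == 0:
        return MatchResult(pairs=[], unmatched=list(range(F.shape[0])))
    dists = np.sqrt(((F[:, None, :] - S[None, :, :]) ** 2).sum(axis=2))
    nn_f = dists.argmin(axis=1)  # per functional cell
    nn_s = dists.argmin(axis=0)  # per structural cell
    candidates = []
    for i in range(F.shape[0]):
        j = nn_f[i]
        if nn_s[j] != i or dists[i, j] > max_dist:
            continue
        if functional_descriptors is not None and structural_descriptors is not None:
            sim = _descriptor_similarity(functional_descriptors[i], structural_descriptors[j])
            if sim < descriptor_threshold:
                continue
        candidates.append((dists[i, j], i, j))
    candidates.sort()
    used_s: set = set()
    matched_f: set = set()
    pairs = []
    for d, i, j in candidates:
        if j in used_s or i in matched_f:
            continue
        pairs.append((i, j, float(d)))
        used_s.add(j)
        matched_f.add(i)
    unmatched = [i for i in range(F.shape[0]) if i not in matched_f]
    return MatchResult(pairs=pairs, unmatched=unmatched)


def bookkeeping_rates(
    n_responsive: int,
    n_matched: int,
    n_traced: int | None = None,
    n_in_vivo: int | None = None,
) -> dict:
    """Matching / tracing / sample rates of the pipeline's attrition chain.

    matching_rate = matched / responsive; tracing_rate = traced / matched;
    sample_rate = traced / labeled-in-vivo.  Rates whose inputs are missing
    are omitted; zero denominators raise.
    """
    if n_responsive <= 0:
        raise ValueError("n_responsive must be > 0")
    rates = {"matching_rate": n_matched / n_responsive}
    if n_traced is not None:
        if n_matched <= 0:
            raise ValueError("n_matched must be > 0 to compute tracing_rate")
        rates["tracing_rate"] = n_traced / n_matched
    if n_in_vivo is not None and n_traced is not None:
        if n_in_vivo <= 0:
            raise ValueError("n_in_vivo must be > 0")
        rates["sample_rate"] = n_traced / n_in_vivo
    return rates
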