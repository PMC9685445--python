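"""Orientation and spatiotemporal-frequency tuning quantification.

Two per-neuron functional indices are computed from the condensed response
matrices:

* **OSI** — orientation selectivity index.  Responses to 180° and 360°
  motion are averaged as the horizontal-orientation response, 90° and 270°
  as the vertical; OSI = (Rpref − Rortho)/(Rpref + Rortho) where Rpref/Rortho
  are the larger/smaller of the two orientation means.

* **R²** — goodness of a 2D elliptical Gaussian fit, in log2 frequency
  coordinates, to the 5×5 (TF, SF) peak matrix:

      R(sf, tf) = A · exp(−(log2 sf − log2 sf0)² / 2σsf²)
                    · exp(−(log2 tf − log2 tfp(sf))² / 2σtf²)

  where the preferred temporal frequency drifts with spatial frequency
  through a power-law exponent ξ:

      log2 tfp(sf) = ξ·(log2 sf − log2 sf0) + log2 tf0

  ξ = 0 means separable SF/TF tuning; ξ = 1 means speed tuning.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .calcium_processing import ResponseMatrix

__all__ = [
    "OSIResult",
    "TuningFit",
    "compute_osi",
    "eval_model",
    "fit_spatiotemporal",
    "FIT_BOUNDS",
]

HORIZONTAL_DIRECTIONS = (180.0, 360.0)
VERTICAL_DIRECTIONS = (90.0, 270.0)

# Fit bounds bracket the stimulus grid by one octave on each side.
FIT_BOUNDS = {
    "sf0": (0.03125, 2.0),  # cpd
    "tf0": (0.25, 16.0),  # Hz
    "sigma": (0.3, 4.0),  # octaves
    "xi": (-2.0, 2.0),
}


@dataclass(frozen=True)
class OSIResult:
    r_pref: float
    r_ortho: float
    osi: float
    pref_orientation: str  # "horizontal" | "vertical"


@dataclass(frozen=True)
class TuningFit:
    A: float
    sf0: float
    tf0: float
    sigma_sf: float
    sigma_tf: float
    xi: float
    r2: float
    converged: bool

    @property
    def params(self) -> np.ndarray:
        return np.array([self.A, self.sf0, self.tf0, self.sigma_sf, self.sigma_tf, self.xi])


def compute_osi(matrix: ResponseMatrix) -> OSIResult:
    """Orientation selectivity index from the directional mean responses.

    Requires non-negative responses (the index's range is only defined
    there).  Returns OSI = 0 when both orientation means are zero.
    """
    by_dir = np.asarray(matrix.by_direction, dtype=float)
    dirs = tuple(matrix.grid.directions)
    if by_dir.shape[0] != len(dirs):
        raise ValueError("by_direction does not match the grid's directions")
    if np.any(by_dir < 0):
        raise ValueError("negative directional responses: OSI undefined")
    lookup = dict(zip(dirs, by_dir))
    try:
        horizontal = (lookup[180.0] + lookup[360.0]) / 2.0
        vertical = (lookup[90.0] + lookup[270.0]) / 2.0
    except KeyError as exc:
        raise ValueError(f"missing canonical direction {exc} in grid") from exc
    if horizontal >= vertical:
        r_pref, r_ortho, pref = horizontal, vertical, "horizontal"
    else:
        r_pref, r_ortho, pref = vertical, horizontal, "vertical"
    total = r_pref + r_ortho
    osi = 0.0 if total == 0 else (r_pref - r_ortho) / total
    return OSIResult(r_pref=r_pref, r_ortho=r_ortho, osi=osi, pref_orientation=pref)


def eval_model(
    sf,
    tf,
    A: float,
    sf0: float,
    tf0: float,
    sigma_sf: float,
    sigma_tf: float,
    xi: float,
):
    """Evaluate the 2D Gaussian spatiotemporal tuning model at (sf, tf).

    All logs base 2; sf in cycles/degree, tf in Hz.  Raises on non-positive
    frequencies (the log-frequency domain).
    """
    sf = np.asarray(sf, dtype=float)
    tf = np.asarray(tf, dtype=float)
    if np.any(sf <= 0) or np.any(tf <= 0):
        raise ValueError("sf and tf must be positive")
    dsf = np.log2(sf) - np.log2(sf0)
    log_tfp = xi * dsf + np.log2(tf0)
    dtf = np.log2(tf) - log_tfp
    return A * np.exp(-(dsf**2) / (2.0 * sigma_sf**2)) * np.exp(-(dtf**2) / (2.0 * sigma_tf**2))


def _algebraic_init(peak: np.ndarray, log_sfs: np.ndarray, log_tfs: np.ndarray):
    """Closed-form initial estimate by log-quadratic interpolation.

    Within one SF column the log of the model is exactly quadratic in
    log2 tf, so a parabola through three points around the column maximum
    yields that column's preferred TF, temporal width, and vertex
    amplitude; the vertex amplitudes are in turn exactly quadratic in
    log2 sf (giving A, sf0, σsf) and the vertex positions linear (giving
    ξ and tf0).  Exact on noiseless model matrices; a moment estimate
    otherwise.  Returns None when the geometry degenerates.
    """
    n_tf, n_sf = peak.shape
    cols = []
    for j in range(n_sf):
        v = peak[:, j]
        i = int(np.argmax(v))
        i0 = min(max(i - 1, 0), n_tf - 3)
        window = slice(i0, i0 + 3)
        vv = v[window]
        if np.any(vv <= 0):
            continue
        a, b, c = np.polyfit(log_tfs[window], np.log(vv), 2)
        if a >= 0:
            continue
        vertex = -b / (2 * a)
        log_amp = c - b**2 / (4 * a)
        sigma_tf = np.sqrt(-1.0 / (2 * a))
        cols.append((log_sfs[j], vertex, log_amp, sigma_tf, float(v.max())))
    if len(cols) < 3:
        return None
    lsf, vert, lamp, stf_est, w = map(np.array, zip(*cols))
    # clamp the weight range: raw column amplitudes can span hundreds of
    # orders of magnitude and destroy the conditioning of the fit
    w = np.clip(w, w.max() * 1e-3, None)
    try:
        a2, b2, c2 = np.polyfit(lsf, lamp, 2, w=w)
    except Exception:
        return None
    if a2 >= 0:
        return None
    lsf0 = -b2 / (2 * a2)
    sigma_sf = np.sqrt(-1.0 / (2 * a2))
    logA = c2 - b2**2 / (4 * a2)
    m, q = np.polyfit(lsf, vert, 1, w=w)
    ltf0 = m * lsf0 + q
    sigma_tf = float(np.average(stf_est, weights=w))
    A = float(np.exp(logA))
    return np.array([A, lsf0, ltf0, float(sigma_sf), sigma_tf, float(m)])


def _residuals(theta, log_sf, log_tf, peak):
    A, lsf0, ltf0, ssf, stf, xi = theta
    dsf = log_sf - lsf0
    dtf = log_tf - (xi * dsf + ltf0)
    model = A * np.exp(-(dsf**2) / (2.0 * ssf**2) - (dtf**2) / (2.0 * stf**2))
    return model - peak


def fit_spatiotemporal(
    matrix: ResponseMatrix,
    restarts: int = 10,
    seed: int | None = 0,
) -> TuningFit:
    """Fit the spatiotemporal tuning model to the 5×5 peak matrix.

    Multi-start nonlinear least squares over (A, log2 sf0, log2 tf0, σsf,
    σtf, ξ): the first starts place (sf0, tf0) at the grid argmax with
    A = observed peak, σ = 1.5 and ξ ∈ {−1, 0, 1}; remaining starts are
    jittered draws inside the bounds.  The best-SSR solution is kept.

    R² is the coefficient of determination 1 − SS_res/SS_tot on the 25 grid
    points (raw value, may be negative for hopeless fits).
    """
    peak = np.asarray(matrix.peak, dtype=float)
    if np.any(peak < 0):
        raise ValueError("negative responses in peak matrix")
    if np.ptp(peak) == 0:
        raise ValueError("degenerate data: all responses equal (SS_tot = 0)")
    tfs = np.asarray(matrix.grid.temporal_freqs, dtype=float)
    sfs = np.asarray(matrix.grid.spatial_freqs, dtype=float)
    log_tf_grid, log_sf_grid = np.meshgrid(np.log2(tfs), np.log2(sfs), indexing="ij")
    log_sf = log_sf_grid.ravel()
    log_tf = log_tf_grid.ravel()
    y = peak.ravel()

    # the observed grid peak can understate A by orders of magnitude when the
    # tuning center lies off-grid with narrow widths; keep the bound loose
    a_hi = 1e6 * float(y.max())
    lb = np.array(
        [1e-9, np.log2(FIT_BOUNDS["sf0"][0]), np.log2(FIT_BOUNDS["tf0"][0]),
         FIT_BOUNDS["sigma"][0], FIT_BOUNDS["sigma"][0], FIT_BOUNDS["xi"][0]]
    )
    ub = np.array(
        [a_hi, np.log2(FIT_BOUNDS["sf0"][1]), np.log2(FIT_BOUNDS["tf0"][1]),
         FIT_BOUNDS["sigma"][1], FIT_BOUNDS["sigma"][1], FIT_BOUNDS["xi"][1]]
    )

    rng = np.random.default_rng(seed)
    i_tf, i_sf = np.unravel_index(np.argmax(peak), peak.shape)
    base = np.array([y.max(), np.log2(sfs[i_sf]), np.log2(tfs[i_tf]), 1.5, 1.5, 0.0])

    starts = []
    alg = _algebraic_init(peak, np.log2(sfs), np.log2(tfs))
    if alg is not None:
        starts.append(np.clip(alg, lb + 1e-9, ub - 1e-9))
    for xi0 in (-1.0, 0.0, 1.0):
        s = base.copy()
        s[5] = xi0
        starts.append(s)
    # narrow-tuned starts past the grid edge: an off-grid peak with small σ
    # shows up only as an edge-dominated matrix
    for dsf in (-1.0, 1.0):
        s = base.copy()
        s[1] += dsf
        s[3] = 0.4
        starts.append(s)
    while len(starts) < max(restarts, 5):
        jitter = rng.normal(scale=[0.2 * max(y.max(), 1e-6), 0.7, 0.7, 0.4, 0.4, 0.5])
        starts.append(np.clip(base + jitter, lb + 1e-9, ub - 1e-9))
    starts = starts[: max(restarts, 5)]

    ss_tot = float(np.sum((y - y.mean()) ** 2))

    def _random_start():
        return np.array([
            y.max() * 10 ** rng.uniform(-0.7, 0.3),
            rng.uniform(lb[1], ub[1]),
            rng.uniform(lb[2], ub[2]),
            float(2 ** rng.uniform(np.log2(lb[3]), np.log2(ub[3]))),
            float(2 ** rng.uniform(np.log2(lb[4]), np.log2(ub[4]))),
            rng.uniform(lb[5], ub[5]),
        ])

    # escalation: when no start yields an essentially perfect fit (possible
    # for narrow off-grid optima), widen the multistart search
    max_extra_rounds = 5
    extra_per_round = 10
    best = None
    queue = list(starts)
    rounds_used = 0
    while queue:
        for s in queue:
            try:
                sol = least_squares(
                    _residuals, np.clip(s, lb + 1e-12, ub - 1e-12),
                    bounds=(lb, ub), args=(log_sf, log_tf, y),
                    xtol=1e-14, ftol=1e-14, gtol=1e-14,
                )
            except Exception:
                continue
            ssr = float(np.sum(sol.fun**2))
            if best is None or ssr < best[0]:
                best = (ssr, sol)
            if ssr < 1e-20:
                break
        queue = []
        if (
            best is not None
            and best[0] > 1e-10 * ss_tot
            and rounds_used < max_extra_rounds
        ):
            queue = [_random_start() for _ in range(extra_per_round)]
            rounds_used += 1
    if best is None:
        raise RuntimeError("all fit starts failed")
    ssr, sol = best
    A, lsf0, ltf0, ssf, stf, xi = sol.x
    r2 = 1.0 - ssr / ss_tot
    return TuningFit(
        A=float(A), sf0=float(2.0**lsf0), tf0=float(2.0**ltf0),
        sigma_sf=float(ssf), sigma_tf=float(stf), xi=float(xi),
        r2=float(r2), converged=bool(sol.success),
    )
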