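"""Two-photon calcium trace processing.

Turns raw fluorescence traces and frame stacks into trial-averaged ΔF/F
responses on the stimulus grid, applies the responsiveness filter, and
collapses the per-trial tensor into the response matrices that the tuning
stage consumes.

The stimulus protocol is a three-factor grid: 5 temporal frequencies ×
5 spatial frequencies × 4 motion directions, each condition repeated over
trials, with a rest period before each movement period.  ΔF/F is the
fractional fluorescence change (F − F0)/F0 × 100 with F0 the mean
fluorescence of the pre-stimulus rest window.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "StimulusGrid",
    "CalciumTrace",
    "TrialTensor",
    "ResponseMatrix",
    "register_frames",
    "compute_dff",
    "trial_average",
    "is_responsive",
    "build_response_matrix",
]

# Canonical stimulus protocol values.
DEFAULT_TEMPORAL_FREQS = (0.5, 1.0, 2.0, 4.0, 8.0)  # Hz
DEFAULT_SPATIAL_FREQS = (0.0625, 0.125, 0.25, 0.5, 1.0)  # cycles/degree
DEFAULT_DIRECTIONS = (90.0, 180.0, 270.0, 360.0)  # degrees
DEFAULT_N_TRIALS = 5
DEFAULT_MOVEMENT_S = 6.0
DEFAULT_REST_S = 3.0

RESPONSIVE_THRESHOLD_DFF = 10.0  # ΔF/F %
RESPONSIVE_MIN_REPEATS = 2


@dataclass(frozen=True)
class StimulusGrid:
    """The temporal-frequency × spatial-frequency × direction stimulus grid.

    Defaults describe the standard protocol: TF {0.5, 1, 2, 4, 8} Hz,
    SF {0.0625, 0.125, 0.25, 0.5, 1.0} cpd, directions {90, 180, 270, 360}°,
    5 trials per condition, 6 s movement preceded by 3 s rest (100 distinct
    stimulus conditions).
    """

    temporal_freqs: tuple = DEFAULT_TEMPORAL_FREQS
    spatial_freqs: tuple = DEFAULT_SPATIAL_FREQS
    directions: tuple = DEFAULT_DIRECTIONS
    n_trials: int = DEFAULT_N_TRIALS
    movement_s: float = DEFAULT_MOVEMENT_S
    rest_s: float = DEFAULT_REST_S

    def __post_init__(self):
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")
        for name in ("temporal_freqs", "spatial_freqs"):
            vals = getattr(self, name)
            if any(v <= 0 for v in vals):
                raise ValueError(f"{name} must be positive")

    @property
    def shape(self) -> tuple:
        """(n_tf, n_sf, n_dir, n_trials) shape of the trial tensor."""
        return (
            len(self.temporal_freqs),
            len(self.spatial_freqs),
            len(self.directions),
            self.n_trials,
        )

    @property
    def n_conditions(self) -> int:
        return len(self.temporal_freqs) * len(self.spatial_freqs) * len(self.directions)


@dataclass
class CalciumTrace:
    """A single-ROI fluorescence time series for one stimulus sweep.

    ``stimulus_onset_index``/``stimulus_offset_index`` delimit the movement
    window; samples before onset are the rest (baseline) window.
    """

    samples: np.ndarray  # fluorescence, a.u.
    frame_rate: float  # Hz
    stimulus_onset_index: int
    stimulus_offset_index: int

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("trace contains non-finite samples")
        if not (0 < self.stimulus_onset_index < self.stimulus_offset_index <= len(self.samples)):
            raise ValueError("require 0 < onset < offset <= length")


@dataclass
class TrialTensor:
    """Per-trial max-ΔF/F responses on the stimulus grid.

    ``dff_max`` is indexed [tf][sf][direction][trial] in ΔF/F %.
    """

    dff_max: np.ndarray
    grid: StimulusGrid = field(default_factory=StimulusGrid)

    def __post_init__(self):
        self.dff_max = np.asarray(self.dff_max, dtype=float)
        if self.dff_max.shape != self.grid.shape:
            raise ValueError(
                f"tensor shape {self.dff_max.shape} does not match grid {self.grid.shape}"
            )
        if not np.all(np.isfinite(self.dff_max)):
            raise ValueError("tensor contains non-finite values")


@dataclass
class ResponseMatrix:
    """Condensed responses: spatiotemporal peak matrix and directional means.

    ``peak[tf][sf]`` is the maximum over directions of the trial-mean
    max-ΔF/F — the response to one (TF, SF) pair.  ``by_direction[d]`` is the
    mean over all (TF, SF) cells of the trial-mean max-ΔF/F at direction d.
    """

    peak: np.ndarray  # (n_tf, n_sf)
    by_direction: np.ndarray  # (n_dir,)
    grid: StimulusGrid = field(default_factory=StimulusGrid)


# ---------------------------------------------------------------------------
# Motion correction


def _xcorr_shift(frame: np.ndarray, template: np.ndarray) -> tuple:
    """Integer (dy, dx) circular shift maximizing cross-correlation with the
    template, plus the normalized correlation peak."""
    f = frame - frame.mean()
    t = template - template.mean()
    corr = np.real(np.fft.ifft2(np.fft.fft2(f) * np.conj(np.fft.fft2(t))))
    peak_idx = np.unravel_index(np.argmax(corr), corr.shape)
    dy, dx = peak_idx
    # wraparound: shifts beyond half the frame are negative
    if dy > frame.shape[0] // 2:
        dy -= frame.shape[0]
    if dx > frame.shape[1] // 2:
        dx -= frame.shape[1]
    denom = np.linalg.norm(f) * np.linalg.norm(t)
    peak_corr = corr[peak_idx] / denom if denom > 0 else 0.0
    return (int(dy), int(dx)), float(peak_corr)


def register_frames(
    stack: np.ndarray,
    max_iter: int = 5,
    low_corr_threshold: float = 0.2,
) -> tuple:
    """Cross-correlation rigid motion correction of a frame stack.

    The template is the average projection of the first third of the stack;
    each frame is translated by the integer-pixel shift maximizing its
    circular cross-correlation with the template.  The template is then
    recomputed from the registered stack and registration iterated until the
    shifts stabilize or ``max_iter`` passes.

    Parameters
    ----------
    stack : (n_frames, ny, nx) array
    max_iter : maximum number of template-refinement passes.
    low_corr_threshold : frames whose normalized correlation peak falls below
        this are flagged as unreliable.

    Returns
    -------
    registered : array of the same shape, frames shifted into template frame.
    shifts : (n_frames, 2) int array of recovered (dy, dx) per frame.
    low_corr : boolean array flagging frames with weak correlation peaks.
    """
    stack = np.asarray(stack, dtype=float)
    if stack.ndim != 3 or stack.shape[0] < 3:
        raise ValueError("need a (n_frames, ny, nx) stack with >= 3 frames")
    n = stack.shape[0]
    shifts = np.zeros((n, 2), dtype=int)
    low_corr = np.zeros(n, dtype=bool)
    registered = stack.copy()
    n_template = max(1, n // 3)
    for _ in range(max_iter):
        template = registered[:n_template].mean(axis=0)
        new_shifts = np.zeros_like(shifts)
        for i in range(n):
            (dy, dx), peak = _xcorr_shift(stack[i], template)
            new_shifts[i] = (dy, dx)
            low_corr[i] = peak < low_corr_threshold
        if np.array_equal(new_shifts, shifts):
            break
        shifts = new_shifts
        registered = np.stack(
            [np.roll(stack[i], (-shifts[i, 0], -shifts[i, 1]), axis=(0, 1)) for i in range(n)]
        )
    return registered, shifts, low_corr


# ---------------------------------------------------------------------------
# ΔF/F


def compute_dff(trace: CalciumTrace) -> np.ndarray:
    """ΔF/F (%) = (F − F0)/F0 × 100 with F0 the mean of the pre-stimulus rest.

    Raises ``ValueError`` when the baseline is non-positive (ΔF/F undefined).
    """
    baseline = trace.samples[: trace.stimulus_onset_index]
    f0 = float(baseline.mean())
    if f0 <= 0:
        raise ValueError(f"degenerate baseline: F0 = {f0} <= 0")
    return (trace.samples - f0) / f0 * 100.0


def trial_average(per_trial: np.ndarray) -> np.ndarray:
    """Pointwise mean ΔF/F trace over trials (rows = trials)."""
    per_trial = np.asarray(per_trial, dtype=float)
    if per_trial.ndim != 2 or per_trial.shape[0] < 1:
        raise ValueError("need a (n_trials, n_samples) array with >= 1 trial")
    return per_trial.mean(axis=0)


def stimulus_window_max(dff: np.ndarray, onset: int, offset: int) -> float:
    """Max ΔF/F within the stimulus (movement) window only."""
    return float(np.max(dff[onset:offset]))


# ---------------------------------------------------------------------------
# Responsiveness and response matrices


def is_responsive(
    tensor: TrialTensor,
    threshold: float = RESPONSIVE_THRESHOLD_DFF,
    min_repeats: int = RESPONSIVE_MIN_REPEATS,
    across_conditions: bool = False,
) -> bool:
    """Responsiveness rule: max ΔF/F above ``threshold`` %, repeated at least
    ``min_repeats`` times.

    Default reading: some single condition exceeds the threshold in at least
    ``min_repeats`` of its trials.  With ``across_conditions=True`` the
    repeats may come from distinct conditions (alternative reading; see the
    methods note).
    """
    exceeds = tensor.dff_max > threshold
    if across_conditions:
        return int(exceeds.sum()) >= min_repeats
    per_condition = exceeds.sum(axis=-1)  # trials axis
    return bool((per_condition >= min_repeats).any())


def build_response_matrix(tensor: TrialTensor) -> ResponseMatrix:
    """Collapse a trial tensor into the peak matrix and directional means.

    peak[tf][sf] = max over directions of the trial-mean max-ΔF/F;
    by_direction[d] = mean over the (tf, sf) cells of the trial-mean
    max-ΔF/F at direction d.
    """
    trial_mean = tensor.dff_max.mean(axis=-1)  # (tf, sf, dir)
    peak = trial_mean.max(axis=-1)
    by_direction = trial_mean.mean(axis=(0, 1))
    return ResponseMatrix(peak=peak, by_direction=by_direction, grid=tensor.grid)
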