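"""Flickering two-square luminance stimuli and normalized residual evidence.

The task presents two grey squares whose luminances are redrawn on every
monitor refresh (75 Hz) from Gaussians around a bright mean (142) and a dark
mean (130), SD 55, truncated at 1 SD.  Reverse correlation operates on the
*residual evidence*: the frame-wise bright-minus-dark difference with the
fixed mean difference removed, normalized into [-1, 1] by the largest
difference the truncation bounds allow.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "TaskConfig",
    "StimulusSet",
    "generate_stimuli",
    "residual_evidence",
    "residual_to_luminance",
]


@dataclass(frozen=True)
class TaskConfig:
    """Stimulus and trial-timing constants of the luminance discrimination task.

    Attributes
    ----------
    frame_duration : float
        Seconds per stimulus frame (one 75 Hz refresh).
    mean_bright, mean_dark : float
        Mean luminance (greyscale units) of the brighter / darker square.
    noise_sd : float
        SD of the per-frame luminance noise, truncated at
        ``truncation_sds`` SDs from each mean.
    deadline : float
        Seconds allowed for the initial response, from stimulus onset.
    post_decision_window : float
        Seconds the stimuli stay on screen after the initial response.
    """

    frame_duration: float = 1.0 / 75.0
    mean_bright: float = 142.0
    mean_dark: float = 130.0
    noise_sd: float = 55.0
    truncation_sds: float = 1.0
    deadline: float = 0.8
    post_decision_window: float = 1.5

    def __post_init__(self) -> None:
        if self.frame_duration <= 0:
            raise ValueError("frame_duration must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.truncation_sds <= 0:
            raise ValueError("truncation_sds must be positive")
        if self.mean_bright <= self.mean_dark:
            raise ValueError("mean_bright must exceed mean_dark")
        if self.deadline <= 0 or self.post_decision_window < 0:
            raise ValueError("deadline/post_decision_window must be positive")

    @property
    def mean_diff(self) -> float:
        return self.mean_bright - self.mean_dark

    @property
    def truncation_halfwidth(self) -> float:
        """Half-width of the truncation box around each mean."""
        return self.truncation_sds * self.noise_sd

    @property
    def residual_scale(self) -> float:
        """Largest achievable |residual difference| given the truncation box.

        With both luminances confined to mean +/- h, the de-meaned difference
        (bright - dark) - mean_diff ranges over [-2h, 2h]; dividing by 2h maps
        residual evidence into [-1, 1].
        """
        return 2.0 * self.truncation_halfwidth

    @property
    def n_frames_total(self) -> int:
        """Frames needed to cover the longest possible trial."""
        return math.ceil(
            (self.deadline + self.post_decision_window) / self.frame_duration
        )

    def frame_onsets(self, n: int | None = None) -> np.ndarray:
        n = self.n_frames_total if n is None else n
        return np.arange(n) * self.frame_duration


@dataclass
class StimulusSet:
    """Per-trial frame luminances for both squares and their residuals."""

    bright: np.ndarray  # (n_trials, n_frames) luminance of the brighter square
    dark: np.ndarray  # (n_trials, n_frames)
    residuals: np.ndarray = field(default=None)  # (n_trials, n_frames) in [-1, 1]

    @property
    def n_trials(self) -> int:
        return self.bright.shape[0]

    @property
    def n_frames(self) -> int:
        return self.bright.shape[1]


def _truncated_normal(
    rng: np.random.Generator, mean: float, sd: float, halfwidth: float, size
) -> np.ndarray:
    """Gaussian draws with out-of-bounds values redrawn (rejection sampling).

    Rejection, not clipping: clipping would pile probability mass onto the
    truncation bounds and distort the residual distribution.
    """
    if sd == 0:
        return np.full(size, mean, dtype=float)
    out = rng.normal(mean, sd, size=size)
    bad = np.abs(out - mean) > halfwidth
    while bad.any():
        out[bad] = rng.normal(mean, sd, size=int(bad.sum()))
        bad = np.abs(out - mean) > halfwidth
    return out


def generate_stimuli(
    config: TaskConfig,
    n_trials: int,
    rng: np.random.Generator,
    n_frames: int | None = None,
) -> StimulusSet:
    """Draw the frame-by-frame luminances for a batch of trials.

    Each frame of each square is an independent truncated-Gaussian draw
    around that square's mean.  Luminances are kept continuous (no 8-bit
    rounding): the analysis operates on residuals, and quantisation would add
    structure the model does not describe.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    n_frames = config.n_frames_total if n_frames is None else n_frames
    h = config.truncation_halfwidth
    shape = (n_trials, n_frames)
    bright = _truncated_normal(rng, config.mean_bright, config.noise_sd, h, shape)
    dark = _truncated_normal(rng, config.mean_dark, config.noise_sd, h, shape)
    seq = StimulusSet(bright=bright, dark=dark)
    seq.residuals = residual_evidence(bright, dark, config)
    return seq


def residual_evidence(
    bright: np.ndarray, dark: np.ndarray, config: TaskConfig
) -> np.ndarray:
    """Normalized residual evidence: ((bright - dark) - mean_diff) / scale.

    Positive values mean more evidence for the (objectively) correct side.
    The divisor is the analytic maximum |de-meaned difference| under the
    truncation box (110 luminance units at the defaults), so one divisor
    applies to every trial and session and the output lies in [-1, 1].
    """
    bright = np.asarray(bright, dtype=float)
    dark = np.asarray(dark, dtype=float)
    if bright.shape != dark.shape:
        raise ValueError("bright and dark frame series must have equal shape")
    if config.residual_scale == 0:  # degenerate noiseless task
        return np.zeros_like(bright)
    return ((bright - dark) - config.mean_diff) / config.residual_scale


def residual_to_luminance(
    residuals: np.ndarray, config: TaskConfig, rng: np.random.Generator | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Invert the normalization back to a (bright, dark) luminance pair.

    The residual fixes only the luminance *difference*; the common component
    is redrawn (or set to its mean when ``rng`` is None), split so both
    squares stay inside their truncation boxes.  Round-trips through
    :func:`residual_evidence` exactly.
    """
    residuals = np.asarray(residuals, dtype=float)
    diff = residuals * config.residual_scale  # de-meaned difference, in [-2h, 2h]
    h = config.truncation_halfwidth
    # bright = mean_bright + u + diff/2, dark = mean_dark + u - diff/2 with
    # |u| <= h - |diff|/2 keeps both inside their boxes.
    slack = h - np.abs(diff) / 2.0
    if rng is None:
        u = np.zeros_like(diff)
    else:
        u = rng.uniform(-1.0, 1.0, size=diff.shape) * slack
    bright = config.mean_bright + u + diff / 2.0
    dark = config.mean_dark + u - diff / 2.0
    return bright, dark
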