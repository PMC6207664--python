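"""Stimulus timing and rendering for briefly displayed drifting gratings.

The duration of a grating is controlled by a temporal Gaussian envelope
applied to its contrast, with the *nominal duration* defined as twice the
envelope's standard deviation.  A display realizes the continuous envelope
as a discrete sequence of frames: the contrast of each frame is the
envelope sampled at that frame's vsync time, and the envelope is truncated
to zero beyond two standard deviations from its peak.  Under this rule the
shortest stimulus of the standard duration grid (0.01 s) occupies 3 frames
on a 120 Hz display but only 1 frame at 60 Hz; displacing the envelope
peak by half a frame period yields 2 frames of equal, sub-peak contrast —
the workaround used on fixed-60-Hz tablets, where motion cannot be defined
with a single frame.

Spatial quantities are expressed in degrees of visual angle; conversion to
pixels or centimetres (display geometry) is outside the scope of this
module.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "GratingSpec",
    "StimulusTiming",
    "FrameSchedule",
    "make_duration_grid",
    "frame_schedule",
    "effective_frame_count",
    "render_frame",
]

#: Relative half-width of the temporal envelope, in units of its SD.
#: The nominal duration is 2*sigma_t, so the envelope is truncated at
#: +/- 2*sigma_t (boundary inclusive).
TRUNCATION_SD = 2.0


@dataclass(frozen=True)
class GratingSpec:
    """Parameters of a drifting sinusoidal grating in a Gaussian window.

    Defaults reproduce the standard surround-suppression stimulus: a
    0.42-Michelson-contrast grating of 1 cycle/degree drifting at
    4 degrees/s on a 32 cd/m^2 background.  ``spatial_envelope_sd`` is
    0.5 degrees for the small stimulus and 2 degrees for the large one.
    """

    spatial_frequency: float = 1.0  # cycles / degree
    drift_speed: float = 4.0  # degrees / s
    michelson_contrast: float = 0.42  # unitless, in [0, 1]
    spatial_envelope_sd: float = 0.5  # degrees
    background_luminance: float = 32.0  # cd / m^2
    initial_phase: float = 0.0  # degrees, in [0, 360)

    def __post_init__(self) -> None:
        if not 0.0 <= self.michelson_contrast <= 1.0:
            raise ValueError("michelson_contrast must be in [0, 1]")
        if self.spatial_frequency <= 0:
            raise ValueError("spatial_frequency must be positive")
        if self.background_luminance <= 0:
            raise ValueError("background_luminance must be positive")
        if self.spatial_envelope_sd <= 0:
            raise ValueError("spatial_envelope_sd must be positive")
        if not 0.0 <= self.initial_phase < 360.0:
            raise ValueError("initial_phase must be in [0, 360)")


@dataclass(frozen=True)
class StimulusTiming:
    """Timing of one presentation: nominal duration, display rate, peak offset.

    ``peak_offset`` displaces the envelope peak relative to the vsync grid,
    in frame periods (0 = peak coincides with a frame sample; 0.5 = the
    tablet workaround for the shortest duration).
    """

    nominal_duration: float  # s
    refresh_rate: float  # Hz
    peak_offset: float = 0.0  # frames

    def __post_init__(self) -> None:
        if self.nominal_duration <= 0:
            raise ValueError("nominal_duration must be positive")
        if self.refresh_rate <= 0:
            raise ValueError("refresh_rate must be positive")

    @property
    def envelope_sd(self) -> float:
        """Temporal SD of the Gaussian envelope (s); duration = 2 * SD."""
        return self.nominal_duration / 2.0

    @property
    def frame_period(self) -> float:
        return 1.0 / self.refresh_rate


@dataclass(frozen=True)
class FrameSchedule:
    """Per-frame contrast sequence realized by a display.

    ``frame_times`` are vsync sample times in seconds relative to the
    envelope peak, strictly increasing and spaced by exactly one frame
    period; ``frame_contrasts`` are the corresponding contrasts.  Only
    frames with nonzero contrast are stored.
    """

    refresh_rate: float
    frame_times: np.ndarray = field(repr=False)
    frame_contrasts: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "frame_times", np.asarray(self.frame_times, float))
        object.__setattr__(
            self, "frame_contrasts", np.asarray(self.frame_contrasts, float)
        )
        if self.frame_times.shape != self.frame_contrasts.shape:
            raise ValueError("frame_times and frame_contrasts must align")

    @property
    def n_frames(self) -> int:
        return int(np.count_nonzero(self.frame_contrasts > 0))


def make_duration_grid(n_durations: int, d_min: float, d_max: float) -> np.ndarray:
    """Geometrically (log-)spaced duration grid from ``d_min`` to ``d_max``.

    The standard grid of the measurement protocol is
    ``make_duration_grid(7, 0.01, 0.2)``: seven durations from 10 to
    200 ms with a constant ratio between neighbours.
    """
    if n_durations < 2:
        raise ValueError("n_durations must be at least 2")
    if d_min <= 0 or d_max <= 0 or d_min >= d_max:
        raise ValueError("require 0 < d_min < d_max")
    return np.geomspace(d_min, d_max, n_durations)


def frame_schedule(timing: StimulusTiming, peak_contrast: float) -> FrameSchedule:
    """Quantize the Gaussian contrast envelope to display frames.

    Frames sit at vsync times ``(i + peak_offset) / refresh_rate`` relative
    to the envelope peak (integer ``i``); each frame's contrast is the
    Gaussian sampled at its vsync time, and contrast is forced to exactly 0
    for ``|t| > 2 * envelope_sd`` (boundary inclusive).  Only nonzero
    frames are returned.
    """
    if not 0.0 < peak_contrast <= 1.0:
        raise ValueError("peak_contrast must be in (0, 1]")
    sigma = timing.envelope_sd
    period = timing.frame_period
    half_window = TRUNCATION_SD * sigma
    # relative tolerance keeps the +/-2 sigma boundary inclusive under
    # floating-point division
    tol = half_window * 1e-12
    i_lo = int(np.ceil((-half_window - tol) / period - timing.peak_offset))
    i_hi = int(np.floor((half_window + tol) / period - timing.peak_offset))
    idx = np.arange(i_lo, i_hi + 1)
    times = (idx + timing.peak_offset) * period
    keep = np.abs(times) <= half_window + tol
    times = times[keep]
    contrasts = peak_contrast * np.exp(-(times**2) / (2.0 * sigma**2))
    return FrameSchedule(timing.refresh_rate, times, contrasts)


def effective_frame_count(schedule: FrameSchedule) -> int:
    """Number of frames with strictly positive contrast."""
    return schedule.n_frames


def render_frame(
    spec: GratingSpec, contrast: float, t: float, x_grid: np.ndarray
) -> np.ndarray:
    """Luminance profile (cd/m^2) of one frame along the drift axis.

    ``L(x, t) = L_b * (1 + c * g(x) * sin(2 pi f (x - v t) + phi))`` where
    ``g`` is the unit-peak spatial Gaussian centered on the patch.  With
    ``contrast = 0`` the output is a uniform field at the background
    luminance.
    """
    if not 0.0 <= contrast <= 1.0:
        raise ValueError("contrast must be in [0, 1]")
    x = np.asarray(x_grid, float)
    if not np.all(np.isfinite(x)):
        raise ValueError("x_grid must be finite")
    envelope = np.exp(-(x**2) / (2.0 * spec.spatial_envelope_sd**2))
    phase = np.deg2rad(spec.initial_phase)
    carrier = np.sin(
        2.0 * np.pi * spec.spatial_frequency * (x - spec.drift_speed * t) + phase
    )
    return spec.background_luminance * (1.0 + contrast * envelope * carrier)
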