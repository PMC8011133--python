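"""Step detection from vertical lower-trunk acceleration and the
temporospatial gait variables.

Gait cycles are delimited by the peaks of the (gravity-free, low-passed)
vertical lower-trunk acceleration: one peak per step, two steps per stride.
Step peaks are found with a minimum separation of half the estimated step
period (step period from the dominant spectral frequency of the vertical
axis in the 0.5-4 Hz locomotion band) and a prominence floor proportional to
the signal SD, so incidental wiggles between heel strikes are not counted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sp_signal

from .trial import CleanTrial

__all__ = ["GaitEvents", "NoGaitError", "detect_steps", "temporospatial", "TemporospatialVars"]

#: plausible step-frequency band for level walking, Hz
GAIT_BAND = (0.5, 4.0)


class NoGaitError(ValueError):
    """Raised when a signal contains no detectable gait periodicity."""


@dataclass
class GaitEvents:
    """Detected step events of one trial."""

    peak_indices: np.ndarray  # sample index of each step peak
    sampling_rate: float

    def __post_init__(self) -> None:
        self.peak_indices = np.asarray(self.peak_indices, dtype=int)
        if np.any(np.diff(self.peak_indices) <= 0):
            raise ValueError("peak indices must be strictly increasing")
        if self.n_steps < 4:
            raise ValueError(f"need >= 4 step peaks, found {self.n_steps}")

    @property
    def n_steps(self) -> int:
        return self.peak_indices.size

    @property
    def step_times(self) -> np.ndarray:
        """Step-peak times in seconds."""
        return self.peak_indices / self.sampling_rate

    @property
    def step_intervals(self) -> np.ndarray:
        """Successive-peak intervals (one per step), seconds."""
        return np.diff(self.step_times)

    @property
    def stride_durations(self) -> np.ndarray:
        """Alternate-peak intervals (one gait cycle each, overlapping),
        seconds."""
        t = self.step_times
        return t[2:] - t[:-2]

    def slice(self, t_start: float, t_end: float) -> "GaitEvents":
        """Events restricted to the time window [t_start, t_end]."""
        t = self.step_times
        keep = self.peak_indices[(t >= t_start) & (t <= t_end)]
        return GaitEvents(keep, self.sampling_rate)


@dataclass
class TemporospatialVars:
    """The five temporospatial gait variables of one trial."""

    walking_speed: float  # m/s
    step_length: float  # cm
    cadence: float  # steps/min
    step_timing_variability: float  # s, SD of successive gait-cycle durations
    n_steps: int

    def as_dict(self) -> dict[str, float]:
        return {
            "walking_speed": self.walking_speed,
            "step_length": self.step_length,
            "cadence": self.cadence,
            "step_timing_variability": self.step_timing_variability,
            "n_steps": float(self.n_steps),
        }


def _dominant_frequency(x: np.ndarray, fs: float) -> float:
    """Dominant frequency of ``x`` within the locomotion band, or raise
    :class:`NoGaitError` when no clear peak stands above the spectrum."""
    if x.size < 16 or np.std(x) < 1e-12:
        raise NoGaitError("no gait detected")
    freqs, power = sp_signal.periodogram(x, fs=fs, detrend="constant")
    band = (freqs >= GAIT_BAND[0]) & (freqs <= GAIT_BAND[1])
    if not np.any(band):
        raise NoGaitError("no gait detected")
    in_band = power[band]
    peak = in_band.max()
    floor = np.median(power[freqs > 0]) + 1e-300
    # a raw periodogram of white noise tops out around ln(n_bins) x its
    # median; a locomotor peak sits orders of magnitude above the floor
    if peak < 20.0 * floor or peak <= 0:
        raise NoGaitError("no gait detected")
    return float(freqs[band][np.argmax(in_band)])


def detect_steps(
    trial: CleanTrial,
    min_separation_frac: float = 0.5,
    prominence_frac: float = 0.3,
) -> GaitEvents:
    """Detect one peak per step on the vertical lower-trunk acceleration.

    Parameters
    ----------
    trial
        Preprocessed (gravity-free, filtered) lower-trunk trial.
    min_separation_frac
        Minimum inter-peak distance as a fraction of the estimated step
        period.
    prominence_frac
        Peak prominence floor as a fraction of the vertical-axis SD.
    """
    vt = trial.axis("vt")
    fs = trial.sampling_rate
    step_freq = _dominant_frequency(vt, fs)
    distance = max(1, int(round(min_separation_frac * fs / step_freq)))
    prominence = prominence_frac * np.std(vt)
    peaks, _ = sp_signal.find_peaks(vt, distance=distance, prominence=prominence)
    if peaks.size < 4:
        raise NoGaitError(f"only {peaks.size} step peaks found; need >= 4")
    return GaitEvents(peaks, fs)


def temporospatial(
    events: GaitEvents,
    timed_duration: float,
    distance: float = 10.0,
    window: tuple[float, float] | None = None,
    cycle: str = "stride",
) -> TemporospatialVars:
    """Compute the temporospatial variables from detected steps.

    ``walking_speed``, ``step_length`` and ``cadence`` describe the timed
    walkway segment: when ``window=(t0, t1)`` is given, only steps inside it
    are counted (the timed middle 10 m of a longer recording); otherwise all
    steps are used.  ``step_timing_variability`` — the SD of successive
    gait-cycle durations — is always taken over the entire trial.

    ``cycle`` selects what counts as a gait cycle for the variability: the
    stride (alternate-peak interval, default) or the step interval.
    """
    if timed_duration <= 0:
        raise ValueError("timed_duration must be positive")
    counted = events.slice(*window) if window is not None else events
    n_steps = counted.n_steps
    if n_steps == 0:
        raise ValueError("no steps in the timed segment")
    if cycle == "stride":
        cycles = events.stride_durations
    elif cycle == "step":
        cycles = events.step_intervals
    else:
        raise ValueError("cycle must be 'stride' or 'step'")
    variability = float(np.std(cycles, ddof=1)) if cycles.size >= 2 else np.nan
    return TemporospatialVars(
        walking_speed=distance / timed_duration,
        step_length=100.0 * distance / n_steps,
        cadence=60.0 * n_steps / timed_duration,
        step_timing_variability=variability,
        n_steps=n_steps,
    )
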