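"""Walking-stability metrics per axis and sensor site.

Six variables describe how stable and repeatable walking is, each computed
on the gravity-free, low-passed acceleration of one axis (VT, ML or AP) at
one sensor (head or lower trunk):

``rms``
    Root mean square of the acceleration: overall movement intensity.
``harmonic_ratio``
    Ratio of summed in-phase to out-of-phase stride-harmonic amplitudes.
    VT and AP repeat every *step*, so their in-phase content lies on the
    even stride harmonics and HR = sum(even) / sum(odd); ML alternates sign
    between feet, so its in-phase content is odd and the ratio is inverted.
    Higher HR = smoother, more left/right-symmetric gait.
``step_regularity`` (SR1) / ``stride_regularity`` (SR2)
    Normalised unbiased autocorrelation of the signal at the step lag and
    the stride lag; 1 means perfectly repeatable steps/strides.
``gait_symmetry``
    Closeness of SR1 and SR2 to each other: min(|SR1|,|SR2|)/max(|SR1|,|SR2|),
    in [0, 1].
``gait_variability``
    Full width at half maximum of the dominant peak of the Welch power
    spectrum, in Hz: a broader peak means less consistent cycle timing.

Harmonic amplitudes are evaluated by discrete Fourier sums at exact
multiples of the measured stride frequency over a segment trimmed to a
whole number of strides, which keeps spectral leakage from contaminating
the even/odd split.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sp_signal

from .events import GaitEvents, NoGaitError, TemporospatialVars, temporospatial
from .trial import AXES, CleanTrial

__all__ = [
    "rms",
    "unbiased_autocorr",
    "estimate_stride_frequency",
    "harmonic_amplitudes",
    "harmonic_ratio",
    "autocorr_regularity",
    "gait_symmetry",
    "gait_variability",
    "GaitVariability",
    "compute_all",
    "FeatureSet",
    "FEATURE_NAMES",
    "DegenerateHarmonicsError",
]

N_HARMONICS = 20  # harmonic-ratio convention: 10 even + 10 odd stride harmonics


class DegenerateHarmonicsError(ValueError):
    """Raised when the harmonic-ratio denominator carries no energy."""


def rms(x) -> float:
    """Root mean square, sqrt(mean(x^2)).  Expects a gravity-free signal."""
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise ValueError("empty signal")
    return float(np.sqrt(np.mean(x**2)))


def unbiased_autocorr(x, max_lag: int) -> np.ndarray:
    """Unbiased autocorrelation coefficients r(0..max_lag).

    r(tau) = [sum_t x_t x_{t+tau} / (n - tau)] / [sum_t x_t^2 / n], so that
    r(0) = 1 and a perfectly periodic signal returns to 1 at its period.
    The signal is used as given (no internal mean removal); callers pass
    gravity-free, hence zero-mean, signals.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    if not 0 < max_lag < n:
        raise ValueError(f"max_lag must be in (0, {n})")
    denom = np.dot(x, x) / n
    if denom < 1e-300:
        raise ValueError("zero-variance signal")
    full = np.correlate(x, x, mode="full")[n - 1 : n + max_lag]
    counts = n - np.arange(max_lag + 1)
    return (full / counts) / denom


def estimate_stride_frequency(
    signal,
    sampling_rate: float | None = None,
    events: GaitEvents | None = None,
    min_peak_corr: float = 0.2,
) -> float:
    """Stride (gait-cycle) frequency in Hz.

    With detected step events the estimate is 1 / mean(stride duration).
    Without events it is autocorrelation-based: the stride lag is the lag of
    the second autocorrelation peak, the first peak being the step lag for
    the step-periodic VT/AP axes this estimator is intended for.
    """
    if events is not None:
        durations = events.stride_durations
        if durations.size == 0:
            raise ValueError("events carry no stride durations")
        return float(1.0 / np.mean(durations))
    if sampling_rate is None:
        raise ValueError("sampling_rate required when no events are given")
    x = np.asarray(signal, dtype=float)
    max_lag = min(x.size - 1, int(round(4.0 * sampling_rate)))
    r = unbiased_autocorr(x, max_lag)
    min_dist = max(1, int(round(0.25 * sampling_rate)))
    peaks, props = sp_signal.find_peaks(r[1:], distance=min_dist, prominence=0.1)
    peaks = peaks + 1
    peaks = peaks[peaks >= int(0.3 * sampling_rate)]
    if peaks.size < 2 or r[peaks[1]] < min_peak_corr:
        raise NoGaitError("no periodicity detected")
    stride_lag = peaks[1]
    f = sampling_rate / stride_lag
    if not 0.25 <= f <= 2.0:
        raise NoGaitError(f"stride frequency {f:.2f} Hz outside the plausible band")
    return float(f)


def harmonic_amplitudes(
    x, sampling_rate: float, stride_frequency: float, n_harmonics: int = N_HARMONICS
) -> np.ndarray:
    """Amplitudes A_1..A_H at exact multiples of the stride frequency.

    The signal is trimmed to the nearest whole number of strides and each
    amplitude is the discrete Fourier sum A_k = (2/N)|sum_t x_t
    exp(-2*pi*i*k*f_s*t)| evaluated at f_k = k * stride_frequency.
    """
    x = np.asarray(x, dtype=float)
    fs = sampling_rate
    stride_samples = fs / stride_frequency
    n_strides = int(np.floor(x.size / stride_samples))
    if n_strides < 1:
        raise ValueError("signal shorter than one stride")
    n = int(round(n_strides * stride_samples))
    seg = x[:n]
    t = np.arange(n) / fs
    k = np.arange(1, n_harmonics + 1)
    # (H, n) complex exponential matrix; n_harmonics is small so this is cheap
    basis = np.exp(-2j * np.pi * np.outer(k * stride_frequency, t))
    return (2.0 / n) * np.abs(basis @ seg)


def harmonic_ratio(
    signal,
    sampling_rate: float,
    stride_frequency: float,
    axis: str = "vt",
    n_harmonics: int = N_HARMONICS,
    ml_inverted: bool = True,
) -> float:
    """Harmonic ratio of one axis.

    For VT/AP the ratio is sum(even harmonics) / sum(odd harmonics); for ML
    the convention is inverted (odd/even) because ML's in-phase content sits
    on the odd stride harmonics — set ``ml_inverted=False`` for the literal
    even/odd reading on every axis.
    """
    axis = axis.lower()
    if axis not in AXES:
        raise ValueError(f"axis must be one of {AXES}")
    amps = harmonic_amplitudes(signal, sampling_rate, stride_frequency, n_harmonics)
    even = amps[1::2].sum()  # k = 2, 4, ...
    odd = amps[0::2].sum()  # k = 1, 3, ...
    if axis == "ml" and ml_inverted:
        num, den = odd, even
    else:
        num, den = even, odd
    if den < 1e-12:
        raise DegenerateHarmonicsError(
            "degenerate harmonic content: denominator harmonics carry no energy"
        )
    return float(num / den)


def autocorr_regularity(
    signal,
    sampling_rate: float,
    stride_frequency: float,
    window_frac: float = 0.25,
) -> tuple[float, float]:
    """Step regularity SR1 and stride regularity SR2.

    SR1 is the maximum of the unbiased autocorrelation coefficient within
    +/- ``window_frac`` of the nominal step lag (half the stride period);
    SR2 the maximum around the stride lag.  The windows tolerate cadence
    drift within a trial.
    """
    x = np.asarray(signal, dtype=float)
    stride_lag = sampling_rate / stride_frequency
    step_lag = stride_lag / 2.0
    hi = int(np.ceil(stride_lag * (1.0 + window_frac)))
    if hi >= x.size:
        raise ValueError("signal too short for the stride-lag search window")
    r = unbiased_autocorr(x, hi)

    def window_max(center: float) -> float:
        lo = max(1, int(np.floor(center * (1.0 - window_frac))))
        up = min(hi, int(np.ceil(center * (1.0 + window_frac))))
        return float(np.max(r[lo : up + 1]))

    return window_max(step_lag), window_max(stride_lag)


def gait_symmetry(sr1: float, sr2: float) -> float:
    """Closeness of step and stride regularity: min/max of their absolute
    values, in [0, 1]; 1 means left and right steps are equally repeatable."""
    a, b = abs(sr1), abs(sr2)
    if max(a, b) < 1e-12:
        raise ValueError("both regularities are zero; symmetry undefined")
    return min(a, b) / max(a, b)


@dataclass
class GaitVariability:
    """FWHM of the dominant spectral peak."""

    width_hz: float
    peak_frequency_hz: float
    truncated: bool  # True when a half-maximum crossing fell outside the spectrum

    @property
    def normalized(self) -> float:
        """Dimensionless width: FWHM divided by the peak frequency."""
        return self.width_hz / self.peak_frequency_hz


def gait_variability(
    signal,
    sampling_rate: float,
    stride_frequency: float,
    band: tuple[float, float] = (0.5, 4.0),
) -> GaitVariability:
    """Width (FWHM, Hz) of the dominant peak of the Welch power spectrum.

    The Welch window is four stride periods long with 50 % overlap and mean
    detrending; the dominant peak is the PSD maximum in the locomotion band
    and its width is found by linear interpolation to the half-power
    crossings on either side.  A broader peak reflects larger
    cycle-to-cycle timing variability.
    """
    x = np.asarray(signal, dtype=float)
    nperseg = min(x.size, int(round(4.0 * sampling_rate / stride_frequency)))
    freqs, psd = sp_signal.welch(
        x, fs=sampling_rate, nperseg=nperseg, noverlap=nperseg // 2, detrend="constant"
    )
    in_band = (freqs >= band[0]) & (freqs <= band[1])
    if not np.any(in_band):
        raise NoGaitError("no spectral estimate inside the locomotion band")
    band_psd = psd[in_band]
    floor = np.median(psd[freqs > 0]) + 1e-300
    if band_psd.max() < 5.0 * floor:
        raise NoGaitError("no dominant spectral peak in the locomotion band")
    peak_idx = np.flatnonzero(in_band)[np.argmax(band_psd)]
    peak_power = psd[peak_idx]
    half = peak_power / 2.0

    def crossing(direction: int) -> tuple[float, bool]:
        i = peak_idx
        while 0 < i < psd.size - 1:
            j = i + direction
            if psd[j] <= half:
                # linear interpolation between samples j and i
                f = freqs[i] + (freqs[j] - freqs[i]) * (psd[i] - half) / (psd[i] - psd[j])
                return float(f), False
            i = j
        return float(freqs[i]), True

    f_left, trunc_l = crossing(-1)
    f_right, trunc_r = crossing(+1)
    return GaitVariability(
        width_hz=f_right - f_left,
        peak_frequency_hz=float(freqs[peak_idx]),
        truncated=trunc_l or trunc_r,
    )


# ---------------------------------------------------------------------------
# the full per-trial feature vector

STABILITY_METRICS = ("rms", "hr", "sr1", "sr2", "symmetry", "variability")
SITES = ("trunk", "head")
TEMPOROSPATIAL_NAMES = (
    "walking_speed",
    "step_length",
    "cadence",
    "step_timing_variability",
    "n_steps",
)

#: canonical ordering of all 41 gait features
FEATURE_NAMES: tuple[str, ...] = TEMPOROSPATIAL_NAMES + tuple(
    f"{site}_{axis}_{metric}"
    for site in SITES
    for axis in AXES
    for metric in STABILITY_METRICS
)


@dataclass
class FeatureSet:
    """The 41 gait features of one trial (or a subject average), with flags
    for values that could not be computed."""

    values: dict[str, float]
    flags: dict[str, str] = field(default_factory=dict)

    def as_array(self) -> np.ndarray:
        return np.array([self.values.get(name, np.nan) for name in FEATURE_NAMES])


def _site_key(sensor_site: str) -> str:
    return "trunk" if sensor_site == "lower_trunk" else "head"


def compute_all(
    head: CleanTrial,
    trunk: CleanTrial,
    events: GaitEvents,
    window: tuple[float, float] | None = None,
    n_harmonics: int = N_HARMONICS,
    hr_ml_inverted: bool = True,
) -> FeatureSet:
    """Compute the full 41-value gait feature vector for one trial pair.

    Temporospatial variables come from the lower-trunk step events and the
    timed 10 m duration; the six stability metrics are computed on each of
    the three axes of both sensors, using the stride frequency measured from
    the events.  A metric that cannot be computed on some axis is recorded
    as NaN with a flag, never silently dropped.
    """
    values: dict[str, float] = {}
    flags: dict[str, str] = {}

    ts = temporospatial(events, trunk.timed_duration, trunk.walkway_distance, window=window)
    values.update(ts.as_dict())

    stride_freq = estimate_stride_frequency(None, events=events)

    for trial in (trunk, head):
        site = _site_key(trial.sensor_site)
        fs = trial.sampling_rate
        for axis in AXES:
            x = trial.axis(axis)
            prefix = f"{site}_{axis}"

            def put(metric: str, fn):
                try:
                    values[f"{prefix}_{metric}"] = float(fn())
                except (ValueError, NoGaitError) as err:
                    values[f"{prefix}_{metric}"] = np.nan
                    flags[f"{prefix}_{metric}"] = str(err)

            put("rms", lambda: rms(x))
            put(
                "hr",
                lambda: harmonic_ratio(
                    x, fs, stride_freq, axis=axis,
                    n_harmonics=n_harmonics, ml_inverted=hr_ml_inverted,
                ),
            )
            try:
                sr1, sr2 = autocorr_regularity(x, fs, stride_freq)
                values[f"{prefix}_sr1"] = sr1
                values[f"{prefix}_sr2"] = sr2
                put("symmetry", lambda: gait_symmetry(sr1, sr2))
            except ValueError as err:
                for metric in ("sr1", "sr2", "symmetry"):
                    values[f"{prefix}_{metric}"] = np.nan
                    flags[f"{prefix}_{metric}"] = str(err)
            put("variability", lambda: gait_variability(x, fs, stride_freq).width_hz)

    return FeatureSet(values=values, flags=flags)
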