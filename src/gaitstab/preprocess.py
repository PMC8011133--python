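"""Preprocessing: gravity removal, zero-phase low-pass filtering and the
trial-set validity rule.

All downstream metrics assume a gravity-free signal band-limited to 22 Hz.
Gravity removal is per-axis mean subtraction over the analysed segment: the
sensors are calibrated so that a static vertical axis reads +1 g, and with
no attitude information mean subtraction is the minimal consistent
de-gravitation.  The low-pass is a second-order Butterworth at 22 Hz applied
forward and backward (zero phase), so step-peak timing is preserved; the
effective amplitude response is the squared second-order response.
"""

from __future__ import annotations

import numpy as np
from scipy import signal as sp_signal

from .trial import CleanTrial, RawTrial

__all__ = ["remove_gravity", "lowpass", "preprocess_trial", "check_trial_set_validity"]

#: relative SD of a subject's timed 10 m durations above which the trial set
#: is rejected
VALIDITY_CV_THRESHOLD = 0.05


def remove_gravity(trial: RawTrial) -> CleanTrial:
    """Subtract the per-axis mean, removing the +1 g vertical offset.

    Returns a new trial with zero-mean axes (``|mean| < 1e-9`` g).
    """
    if trial.n_samples == 0:
        raise ValueError("empty signal")
    acc = trial.acc - trial.acc.mean(axis=0, keepdims=True)
    return CleanTrial.from_raw(trial, acc, gravity_removed=True)


def lowpass(trial: RawTrial, order: int = 2, cutoff: float = 22.0) -> CleanTrial:
    """Zero-phase Butterworth low-pass (default 2nd order, 22 Hz cutoff)."""
    nyquist = trial.sampling_rate / 2.0
    if cutoff >= nyquist:
        raise ValueError(
            f"cutoff {cutoff} Hz is not below the Nyquist frequency {nyquist} Hz"
        )
    sos = sp_signal.butter(order, cutoff, btype="low", fs=trial.sampling_rate, output="sos")
    acc = sp_signal.sosfiltfilt(sos, trial.acc, axis=0)
    return CleanTrial.from_raw(trial, acc, filtered=True)


def preprocess_trial(trial: RawTrial, order: int = 2, cutoff: float = 22.0) -> CleanTrial:
    """Gravity removal followed by the zero-phase low-pass (the two commute
    to numerical precision since both are linear with unit DC gain)."""
    return lowpass(remove_gravity(trial), order=order, cutoff=cutoff)


def check_trial_set_validity(
    durations, threshold: float = VALIDITY_CV_THRESHOLD
) -> str:
    """Apply the 5 % repeatability rule to a subject's timed 10 m durations.

    A trial set is ``"invalid"`` when the coefficient of variation of the
    durations (sample SD / mean) exceeds ``threshold``, otherwise
    ``"valid"``.
    """
    durations = np.asarray(durations, dtype=float)
    if durations.size < 2:
        raise ValueError("need at least 2 durations to assess repeatability")
    if np.any(durations <= 0):
        raise ValueError("durations must be positive")
    cv = durations.std(ddof=1) / durations.mean()
    return "invalid" if cv > threshold else "valid"
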