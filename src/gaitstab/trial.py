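"""Core data containers for walking trials and trial I/O.

A trial is one pass along the walkway recorded by one body-worn tri-axial
accelerometer.  Axes follow the sensor-frame convention used throughout the
package: ML (mediolateral, x, positive right), AP (anteroposterior, y,
positive forward), VT (vertical, z, positive up).  Acceleration is in units
of g; the raw VT axis carries the +1 g gravity component until it is removed
by preprocessing.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

#: canonical axis order for the (n, 3) acceleration array
AXES = ("ml", "ap", "vt")

#: recognised sensor attachment sites
SENSOR_SITES = ("head", "lower_trunk")

#: fixed length of the timed walkway segment, metres
WALKWAY_DISTANCE_M = 10.0


@dataclass
class RawTrial:
    """One walking trial from one sensor.

    Parameters
    ----------
    subject_id
        Identifier of the walking subject.
    sensor_site
        ``"head"`` or ``"lower_trunk"``.
    sampling_rate
        Samples per second (Hz).  Must exceed 44 Hz so the 22 Hz analysis
        band is below Nyquist.
    acc
        ``(n, 3)`` array of acceleration in g, columns ordered ML, AP, VT.
    timed_duration
        Stopwatch duration of the middle 10 m of steady walking, seconds.
    walkway_distance
        Length of the timed segment, metres (10 by convention).
    """

    subject_id: str
    sensor_site: str
    sampling_rate: float
    acc: np.ndarray
    timed_duration: float
    walkway_distance: float = WALKWAY_DISTANCE_M

    def __post_init__(self) -> None:
        self.acc = np.asarray(self.acc, dtype=float)
        if self.sensor_site not in SENSOR_SITES:
            raise ValueError(f"unknown sensor site {self.sensor_site!r}")
        if self.acc.ndim != 2 or self.acc.shape[1] != 3:
            raise ValueError("acc must be an (n, 3) array ordered ML, AP, VT")
        if self.acc.shape[0] == 0:
            raise ValueError("empty signal")
        if not np.all(np.isfinite(self.acc)):
            raise ValueError("acceleration contains non-finite samples")
        if self.sampling_rate <= 44.0:
            raise ValueError(
                f"sampling rate {self.sampling_rate} Hz too low; need > 44 Hz"
            )
        if self.timed_duration <= 0:
            raise ValueError("timed_duration must be positive")

    @property
    def n_samples(self) -> int:
        return self.acc.shape[0]

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return self.n_samples / self.sampling_rate

    @property
    def time(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.sampling_rate

    def axis(self, name: str) -> np.ndarray:
        """Return one axis by name (``"ml"``, ``"ap"`` or ``"vt"``)."""
        return self.acc[:, AXES.index(name.lower())]


@dataclass
class CleanTrial(RawTrial):
    """A trial after gravity removal and/or low-pass filtering."""

    gravity_removed: bool = False
    filtered: bool = False

    @classmethod
    def from_raw(cls, trial: RawTrial, acc: np.ndarray, **flags) -> "CleanTrial":
        base = dict(
            subject_id=trial.subject_id,
            sensor_site=trial.sensor_site,
            sampling_rate=trial.sampling_rate,
            timed_duration=trial.timed_duration,
            walkway_distance=trial.walkway_distance,
        )
        if isinstance(trial, CleanTrial):
            base["gravity_removed"] = trial.gravity_removed
            base["filtered"] = trial.filtered
        base.update(flags)
        return cls(acc=acc, **base)


@dataclass
class SubjectRecord:
    """One study participant: metadata, raw trials and derived features.

    ``trials`` maps sensor site to the list of that subject's trials (one
    entry per walkway pass).  ``features`` is filled in by the feature
    extraction stage with the 41-value gait vector.
    """

    subject_id: str
    group: str  # healthy | mild | moderate | severe
    dhi: int
    age: float
    sex: str
    height: float
    weight: float
    trials: dict[str, list[RawTrial]] = field(default_factory=dict)
    features: dict[str, float] | None = None

    @property
    def is_patient(self) -> bool:
        return self.group != "healthy"

    @property
    def timed_durations(self) -> list[float]:
        """Per-trial timed 10 m durations (from the lower-trunk sensor)."""
        site = "lower_trunk" if "lower_trunk" in self.trials else next(iter(self.trials))
        return [t.timed_duration for t in self.trials[site]]


def write_trial_csv(trial: RawTrial, path: str | Path) -> None:
    """Write a trial as CSV (`time_s, acc_ml_g, acc_ap_g, acc_vt_g`) plus a
    JSON sidecar ``<path>.meta.json`` holding the trial metadata."""
    path = Path(path)
    df = pd.DataFrame(
        {
            "time_s": trial.time,
            "acc_ml_g": trial.axis("ml"),
            "acc_ap_g": trial.axis("ap"),
            "acc_vt_g": trial.axis("vt"),
        }
    )
    df.to_csv(path, index=False, float_format="%.9g")
    meta = {
        "subject_id": trial.subject_id,
        "sensor_site": trial.sensor_site,
        "sampling_rate_hz": trial.sampling_rate,
        "timed_duration_s": trial.timed_duration,
        "walkway_distance_m": trial.walkway_distance,
    }
    Path(str(path) + ".meta.json").write_text(json.dumps(meta, indent=2) + "\n")


def read_trial_csv(path: str | Path) -> RawTrial:
    """Read a trial written by :func:`write_trial_csv` (or any sensor export
    using the same column dialect and sidecar)."""
    path = Path(path)
    df = pd.read_csv(path)
    required = {"time_s", "acc_ml_g", "acc_ap_g", "acc_vt_g"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"trial CSV missing columns: {sorted(missing)}")
    meta_path = Path(str(path) + ".meta.json")
    if meta_path.exists():
        meta = json.loads(meta_path.read_text())
    else:
        # infer sampling rate from the time column; metadata defaults
        dt = float(np.median(np.diff(df["time_s"].to_numpy())))
        meta = {
            "subject_id": path.stem,
            "sensor_site": "lower_trunk",
            "sampling_rate_hz": 1.0 / dt,
            "timed_duration_s": float(df["time_s"].iloc[-1]),
            "walkway_distance_m": WALKWAY_DISTANCE_M,
        }
    acc = df[["acc_ml_g", "acc_ap_g", "acc_vt_g"]].to_numpy()
    return RawTrial(
        subject_id=str(meta["subject_id"]),
        sensor_site=meta["sensor_site"],
        sampling_rate=float(meta["sampling_rate_hz"]),
        acc=acc,
        timed_duration=float(meta["timed_duration_s"]),
        walkway_distance=float(meta.get("walkway_distance_m", WALKWAY_DISTANCE_M)),
    )
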