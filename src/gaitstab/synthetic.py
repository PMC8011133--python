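"""Synthetic tri-axial gait acceleration and cohort simulation.

The simulator produces quasi-periodic head and lower-trunk acceleration with
the harmonic structure walking imposes on a body-worn sensor:

* VT and AP oscillate mainly at the *step* frequency and its multiples —
  i.e. the **even** harmonics of the stride frequency — because both feet
  produce the same vertical/forward impulse pattern;
* ML alternates sign between left and right steps, so its power sits on the
  **odd** stride harmonics;
* left/right asymmetry scales alternate steps up and down, which transfers a
  proportional share of VT/AP power from even onto odd stride harmonics;
* cycle-to-cycle timing jitter advances the stride phase unevenly, which
  broadens every spectral line in proportion to the jitter;
* white sensor noise is added on all axes and the raw VT axis carries the
  +1 g gravity offset.

The phase is piecewise linear per stride (each stride spans exactly 2*pi but
its wall-clock duration is drawn with the configured jitter), so spectral
peak width, autocorrelation decay and step-timing variability all respond to
jitter the way they do in real signals rather than being painted on.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .trial import RawTrial, SubjectRecord, WALKWAY_DISTANCE_M

__all__ = [
    "GaitSimConfig",
    "GroupGaitParams",
    "CohortSimConfig",
    "simulate_trial",
    "simulate_cohort",
    "true_step_times",
    "DEFAULT_GROUP_PARAMS",
]

# Default per-harmonic amplitudes (g) for the lower trunk, harmonics 1..6 of
# the stride frequency.  VT/AP concentrate power on even harmonics (step
# frequency = 2 x stride frequency); ML on odd harmonics.  Magnitudes give
# axis RMS values of roughly 0.19 g (VT), 0.08 g (AP) and 0.09 g (ML),
# typical of self-paced level walking at the lower trunk.
DEFAULT_AMPS_VT = (0.03, 0.25, 0.02, 0.10, 0.01, 0.04)
DEFAULT_AMPS_AP = (0.02, 0.10, 0.015, 0.05, 0.01, 0.02)
DEFAULT_AMPS_ML = (0.12, 0.02, 0.05, 0.01, 0.02, 0.005)

# Head amplitudes relative to the trunk: the neck attenuates vertical and
# forward oscillation but head sway slightly exceeds trunk sway laterally.
HEAD_SCALE = {"vt": 0.8, "ap": 0.8, "ml": 1.1}

_MIN_STRIDES = 10


@dataclass
class GaitSimConfig:
    """Parameters of one simulated walking trial.

    Attributes
    ----------
    stride_time_mean : float
        Mean stride (two-step) duration, seconds.
    stride_time_jitter_sd : float
        Cycle-to-cycle SD of the stride duration, seconds.
    walking_speed : float
        Steady walking speed, m/s; sets the timed 10 m duration.
    asymmetry : float
        Left/right step amplitude mismatch in [0, 1): left steps are scaled
        by (1 + a), right steps by (1 - a) on the VT and AP axes.
    harmonic_amps_vt, harmonic_amps_ap, harmonic_amps_ml : tuple of float
        Amplitudes (g) of stride-frequency harmonics 1..H per axis.
    noise_sd : float
        SD of additive white sensor noise, g.
    duration : float
        Trial length, seconds; must cover at least 10 strides.
    sampling_rate : float
        Hz, default 148.
    seed : int
        Seed for the trial's random draws.
    """

    stride_time_mean: float = 1.0
    stride_time_jitter_sd: float = 0.0
    walking_speed: float = 1.2
    asymmetry: float = 0.0
    harmonic_amps_vt: tuple = DEFAULT_AMPS_VT
    harmonic_amps_ap: tuple = DEFAULT_AMPS_AP
    harmonic_amps_ml: tuple = DEFAULT_AMPS_ML
    noise_sd: float = 0.0
    duration: float = 30.0
    sampling_rate: float = 148.0
    seed: int = 0
    amplitude_scale: float = 1.0

    def validate(self) -> None:
        if self.stride_time_mean <= 0:
            raise ValueError("stride_time_mean must be positive")
        if self.sampling_rate <= 44.0:
            raise ValueError("sampling_rate must exceed 44 Hz (2 x 22 Hz band)")
        if self.duration < _MIN_STRIDES * self.stride_time_mean:
            raise ValueError(
                f"duration {self.duration} s covers fewer than "
                f"{_MIN_STRIDES} strides at stride time {self.stride_time_mean} s"
            )
        if not 0.0 <= self.asymmetry < 1.0:
            raise ValueError("asymmetry must lie in [0, 1)")
        if self.stride_time_jitter_sd < 0 or self.noise_sd < 0:
            raise ValueError("jitter and noise SDs must be non-negative")
        if self.walking_speed <= 0:
            raise ValueError("walking_speed must be positive")
        for amps in (self.harmonic_amps_vt, self.harmonic_amps_ap, self.harmonic_amps_ml):
            if np.any(np.asarray(amps) < 0):
                raise ValueError("harmonic amplitudes must be non-negative")


def _stride_durations(config: GaitSimConfig, rng: np.random.Generator) -> np.ndarray:
    """Draw jittered stride durations covering the whole trial."""
    n_draw = int(np.ceil(config.duration / config.stride_time_mean)) + 8
    durations = rng.normal(config.stride_time_mean, config.stride_time_jitter_sd, n_draw)
    durations = np.clip(durations, 0.3 * config.stride_time_mean, None)
    while durations.sum() < config.duration:
        extra = rng.normal(config.stride_time_mean, config.stride_time_jitter_sd, 8)
        durations = np.concatenate([durations, np.clip(extra, 0.3 * config.stride_time_mean, None)])
    return durations


def _stride_phase(config: GaitSimConfig, rng: np.random.Generator) -> np.ndarray:
    """Piecewise-linear stride phase phi(t): each stride advances phi by 2*pi
    over its own jittered duration."""
    n = int(round(config.duration * config.sampling_rate))
    t = np.arange(n) / config.sampling_rate
    durations = _stride_durations(config, rng)
    starts = np.concatenate([[0.0], np.cumsum(durations)])
    idx = np.searchsorted(starts, t, side="right") - 1
    frac = (t - starts[idx]) / durations[idx]
    return 2.0 * np.pi * (idx + frac)


def _harmonic_sum(phase: np.ndarray, amps) -> np.ndarray:
    out = np.zeros_like(phase)
    for k, a in enumerate(np.asarray(amps, dtype=float), start=1):
        if a != 0.0:
            out += a * np.cos(k * phase)
    return out


def true_step_times(config: GaitSimConfig) -> np.ndarray:
    """Ground-truth step times of the trial :func:`simulate_trial` would
    generate from this config.

    Steps fall where the stride phase crosses multiples of pi (the even
    harmonics that dominate VT/AP all peak there).  Reconstructs the same
    jittered stride timing as the simulator by replaying its seed.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    durations = _stride_durations(config, rng)
    starts = np.concatenate([[0.0], np.cumsum(durations)])
    times = np.sort(np.concatenate([starts[:-1], starts[:-1] + durations / 2.0]))
    return times[times < config.duration]


def simulate_trial(config: GaitSimConfig, sensor_site: str = "lower_trunk") -> RawTrial:
    """Simulate one walking trial for one sensor site.

    Returns a :class:`~gaitstab.trial.RawTrial` whose VT axis includes the
    +1 g gravity offset.  Identical config and seed give bit-identical
    output; the head and lower-trunk trials of the same config share the
    stride timing (same seed stream) and differ only in amplitude profile
    and in their independent sensor-noise draw.
    """
    config.validate()
    if sensor_site not in ("head", "lower_trunk"):
        raise ValueError(f"unknown sensor site {sensor_site!r}")
    rng = np.random.default_rng(config.seed)
    phase = _stride_phase(config, rng)

    scale = config.amplitude_scale
    site_scale = HEAD_SCALE if sensor_site == "head" else {"vt": 1.0, "ap": 1.0, "ml": 1.0}
    vt = scale * site_scale["vt"] * _harmonic_sum(phase, config.harmonic_amps_vt)
    ap = scale * site_scale["ap"] * _harmonic_sum(phase, config.harmonic_amps_ap)
    ml = scale * site_scale["ml"] * _harmonic_sum(phase, config.harmonic_amps_ml)

    if config.asymmetry > 0.0:
        # alternating-step amplitude scaling: the left step occupies the
        # first half of each stride cycle and is scaled by (1 + a), the
        # right step by (1 - a).  Applied to VT/AP, whose base pattern is
        # step-periodic, this moves even-harmonic power onto odd harmonics.
        step_sign = np.where(np.mod(phase, 2.0 * np.pi) < np.pi, 1.0, -1.0)
        modulation = 1.0 + config.asymmetry * step_sign
        vt = vt * modulation
        ap = ap * modulation

    # independent noise stream per site so head and trunk noise differ
    noise_rng = np.random.default_rng(
        np.random.SeedSequence([int(config.seed), 0 if sensor_site == "lower_trunk" else 1])
    )
    if config.noise_sd > 0.0:
        vt = vt + noise_rng.normal(0.0, config.noise_sd, vt.shape)
        ap = ap + noise_rng.normal(0.0, config.noise_sd, ap.shape)
        ml = ml + noise_rng.normal(0.0, config.noise_sd, ml.shape)

    vt = vt + 1.0  # gravity on the vertical axis
    acc = np.column_stack([ml, ap, vt])
    return RawTrial(
        subject_id=f"sim-{config.seed}",
        sensor_site=sensor_site,
        sampling_rate=config.sampling_rate,
        acc=acc,
        timed_duration=WALKWAY_DISTANCE_M / config.walking_speed,
    )


# ---------------------------------------------------------------------------
# cohort simulation


@dataclass
class GroupGaitParams:
    """Mean gait parameters of one severity group plus its DHI range."""

    walking_speed: float
    stride_time_jitter_sd: float
    asymmetry: float
    amplitude_scale: float
    dhi_range: tuple  # inclusive (low, high)


#: Severity-graded defaults: dizzier subjects walk slower, with larger
#: cycle-to-cycle timing jitter, stronger left/right asymmetry and smaller
#: overall acceleration amplitude (a conservative gait).  DHI staging is
#: mild 0-30, moderate 31-60, severe 61-100; healthy subjects score 0.
DEFAULT_GROUP_PARAMS: dict[str, GroupGaitParams] = {
    "healthy": GroupGaitParams(1.20, 0.016, 0.04, 1.00, (0, 0)),
    "mild": GroupGaitParams(1.13, 0.019, 0.10, 0.92, (0, 30)),
    "moderate": GroupGaitParams(1.10, 0.023, 0.17, 0.87, (31, 60)),
    "severe": GroupGaitParams(1.05, 0.029, 0.27, 0.80, (61, 100)),
}

GROUP_ORDER = ("healthy", "mild", "moderate", "severe")


@dataclass
class CohortSimConfig:
    """Whole-cohort simulation: group sizes, severity-graded parameter
    offsets, trials per subject and seed."""

    n_per_group: dict = field(
        default_factory=lambda: {"healthy": 27, "mild": 12, "moderate": 9, "severe": 6}
    )
    group_params: dict = field(default_factory=lambda: dict(DEFAULT_GROUP_PARAMS))
    trials_per_subject: int = 6
    base: GaitSimConfig = field(default_factory=lambda: GaitSimConfig(noise_sd=0.02))
    seed: int = 0
    # subject-level between-subject SDs around the group means
    speed_sd: float = 0.06
    jitter_sd_sd: float = 0.003
    asymmetry_sd: float = 0.03
    amplitude_scale_sd: float = 0.05
    # per-trial relative SD of the timed 10 m duration
    trial_duration_rel_sd: float = 0.012

    def validate(self) -> None:
        for g, n in self.n_per_group.items():
            if g not in GROUP_ORDER:
                raise ValueError(f"unknown group {g!r}")
            if n < 1:
                raise ValueError(f"n_per_group[{g!r}] must be >= 1")
        if self.trials_per_subject < 1:
            raise ValueError("trials_per_subject must be >= 1")


def simulate_cohort(config: CohortSimConfig) -> list[SubjectRecord]:
    """Simulate a full cohort: every subject gets ``trials_per_subject``
    walkway passes, each recorded by both the head and lower-trunk sensor.

    Subject-level gait parameters are drawn around the group means so the
    groups overlap the way clinical groups do; each trial re-draws the
    stride timing, noise and timed duration.  Fully reproducible from
    ``config.seed``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    subjects: list[SubjectRecord] = []
    sid = 0
    for group in GROUP_ORDER:
        n = config.n_per_group.get(group, 0)
        params = config.group_params[group]
        for _ in range(n):
            sid += 1
            speed = max(0.4, rng.normal(params.walking_speed, config.speed_sd))
            jitter = max(0.002, rng.normal(params.stride_time_jitter_sd, config.jitter_sd_sd))
            asym = float(np.clip(rng.normal(params.asymmetry, config.asymmetry_sd), 0.0, 0.9))
            amp = max(0.3, rng.normal(params.amplitude_scale, config.amplitude_scale_sd))
            # slower walkers take slightly longer strides (lower cadence)
            stride_time = max(
                0.7, 1.0 + 0.5 * (1.2 - speed) + rng.normal(0.0, 0.03)
            )
            lo, hi = params.dhi_range
            dhi = int(rng.integers(lo, hi + 1)) if group != "healthy" else 0
            record = SubjectRecord(
                subject_id=f"S{sid:03d}",
                group=group,
                dhi=dhi,
                age=float(np.clip(rng.normal(56.0, 12.0), 25, 75)),
                sex="F" if rng.random() < 0.6 else "M",
                height=float(rng.normal(161.0, 6.0)),
                weight=float(rng.normal(61.0, 9.0)),
                trials={"head": [], "lower_trunk": []},
            )
            for _trial in range(config.trials_per_subject):
                trial_speed = speed * (1.0 + rng.normal(0.0, config.trial_duration_rel_sd))
                trial_seed = int(rng.integers(0, 2**31 - 1))
                tconf = replace(
                    config.base,
                    stride_time_mean=stride_time,
                    stride_time_jitter_sd=jitter,
                    walking_speed=trial_speed,
                    asymmetry=asym,
                    amplitude_scale=amp,
                    noise_sd=config.base.noise_sd,
                    seed=trial_seed,
                )
                for site in ("head", "lower_trunk"):
                    t = simulate_trial(tconf, site)
                    t.subject_id = record.subject_id
                    record.trials[site].append(t)
            subjects.append(record)
    return subjects
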