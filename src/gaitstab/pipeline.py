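"""End-to-end pipeline: simulate/ingest -> preprocess -> events -> features
-> statistics -> severity classification, with reproducible outputs.

Every run is driven by a :class:`PipelineConfig`; the configuration (and its
hash) is serialised into the output bundle so any result file can be traced
back to the exact parameters and seed that produced it.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import metrics, model, stats
from .events import detect_steps
from .preprocess import check_trial_set_validity, preprocess_trial
from .synthetic import CohortSimConfig, GaitSimConfig, simulate_cohort
from .trial import SubjectRecord

__all__ = ["PipelineConfig", "run_pipeline", "extract_subject_features", "cohort_features"]

logger = logging.getLogger("gaitstab")


@dataclass
class PipelineConfig:
    """All knobs of a pipeline run, serialisable to/from YAML."""

    out_dir: str = "gaitstab_out"
    seed: int = 42
    # cohort simulation
    n_per_group: dict = field(
        default_factory=lambda: {"healthy": 27, "mild": 12, "moderate": 9, "severe": 6}
    )
    trials_per_subject: int = 6
    noise_sd: float = 0.02
    sampling_rate: float = 148.0
    trial_duration: float = 30.0
    # preprocessing
    filter_order: int = 2
    filter_cutoff: float = 22.0
    # metrics
    n_harmonics: int = 20
    hr_ml_inverted: bool = True
    # statistics
    alpha: float = 0.05
    ks_method: str = "lilliefors"
    # model
    k_components: int = 4
    folds: int = 5
    repeats: int = 10
    svm_C: float = 1.0
    leak_mode: bool = False

    def validate(self) -> None:
        if self.filter_cutoff >= self.sampling_rate / 2:
            raise ValueError(
                f"filter cutoff {self.filter_cutoff} Hz is not below Nyquist "
                f"({self.sampling_rate / 2} Hz)"
            )
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.folds < 2 or self.repeats < 1 or self.k_components < 1:
            raise ValueError("invalid model configuration")
        if self.trial_duration <= 0 or self.trials_per_subject < 1:
            raise ValueError("invalid simulation configuration")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def config_hash(self) -> str:
        """Hash of the scientific parameters (the output path is excluded so
        identical analyses hash identically wherever they are written)."""
        params = {k: v for k, v in self.to_dict().items() if k != "out_dir"}
        blob = json.dumps(params, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def extract_subject_features(
    subject: SubjectRecord, config: PipelineConfig | None = None
) -> dict[str, float]:
    """Average the 41-value gait feature vector over a subject's trials.

    Each trial pair is preprocessed, steps are detected on the lower-trunk
    vertical axis, the timed middle-10 m window is centred in the recording,
    and the per-trial features are averaged (NaN-aware) into the subject's
    feature vector.
    """
    config = config or PipelineConfig()
    rows = []
    for head_raw, trunk_raw in zip(subject.trials["head"], subject.trials["lower_trunk"]):
        head = preprocess_trial(head_raw, config.filter_order, config.filter_cutoff)
        trunk = preprocess_trial(trunk_raw, config.filter_order, config.filter_cutoff)
        events = detect_steps(trunk)
        mid = trunk.duration / 2.0
        half = min(trunk.timed_duration, trunk.duration) / 2.0
        fs = metrics.compute_all(
            head,
            trunk,
            events,
            window=(mid - half, mid + half),
            n_harmonics=config.n_harmonics,
            hr_ml_inverted=config.hr_ml_inverted,
        )
        rows.append(fs.as_array())
    mean = np.nanmean(np.vstack(rows), axis=0)
    return dict(zip(metrics.FEATURE_NAMES, mean))


def cohort_features(
    subjects: list[SubjectRecord], config: PipelineConfig | None = None
) -> pd.DataFrame:
    """Subject-level feature table: id, group, DHI plus the 41 features.

    Subjects whose timed durations fail the 5 % repeatability rule are
    dropped with a log message.
    """
    config = config or PipelineConfig()
    rows = []
    for subject in subjects:
        if (
            len(subject.timed_durations) >= 2
            and check_trial_set_validity(subject.timed_durations) == "invalid"
        ):
            logger.warning("subject %s: trial set invalid (duration CV > 5%%); dropped",
                           subject.subject_id)
            continue
        feats = extract_subject_features(subject, config)
        subject.features = feats
        rows.append({"subject_id": subject.subject_id, "group": subject.group,
                     "dhi": subject.dhi, **feats})
    return pd.DataFrame(rows)


def _simulate(config: PipelineConfig) -> list[SubjectRecord]:
    sim = CohortSimConfig(
        n_per_group=dict(config.n_per_group),
        trials_per_subject=config.trials_per_subject,
        base=GaitSimConfig(
            noise_sd=config.noise_sd,
            sampling_rate=config.sampling_rate,
            duration=config.trial_duration,
        ),
        seed=config.seed,
    )
    return simulate_cohort(sim)


def run_pipeline(
    config: PipelineConfig, subjects: list[SubjectRecord] | None = None
) -> dict:
    """Run the full analysis and write the output bundle.

    When ``subjects`` is None a synthetic cohort is simulated from the
    config.  Writes ``features.csv``, ``stats_groups.csv`` (healthy vs all
    patients), ``stats_subgroups.csv`` (mild/moderate/severe), per-fold
    ``roc_points.csv``, ``cv_summary.json`` and ``run.json`` (config +
    hash) under ``config.out_dir``; returns the in-memory results.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = config.config_hash()
    logger.info("pipeline start: config hash %s, seed %d", chash, config.seed)

    if subjects is None:
        subjects = _simulate(config)
    features = cohort_features(subjects, config)
    if features.empty:
        raise ValueError("no subject passed the trial-validity rule")
    features.insert(0, "config_hash", chash)
    features.to_csv(out / "features.csv", index=False, float_format="%.10g")

    feat_only = features.drop(columns=["config_hash"])
    # healthy vs all patients pooled
    pooled = feat_only.copy()
    pooled["group"] = np.where(pooled["group"] == "healthy", "healthy", "bppv")
    stats_groups = stats.group_comparison(
        pooled, groups=["bppv", "healthy"], alpha=config.alpha, ks_method=config.ks_method
    )
    # among DHI subgroups
    patient_groups = [g for g in ("mild", "moderate", "severe")
                      if (feat_only["group"] == g).sum() >= 2]
    stats_subgroups = (
        stats.group_comparison(
            feat_only[feat_only["group"].isin(patient_groups)],
            groups=patient_groups, alpha=config.alpha, ks_method=config.ks_method,
        )
        if len(patient_groups) >= 2
        else pd.DataFrame()
    )
    for df, name in ((stats_groups, "stats_groups.csv"), (stats_subgroups, "stats_subgroups.csv")):
        if not df.empty:
            df.insert(0, "config_hash", chash)
        df.to_csv(out / name, index=False, float_format="%.10g")

    X = feat_only[list(metrics.FEATURE_NAMES)].to_numpy()
    y = feat_only["group"].to_numpy()
    report = model.repeated_stratified_cv(
        X, y,
        folds=config.folds, repeats=config.repeats, seed=config.seed,
        k_components=config.k_components, C=config.svm_C, leak_mode=config.leak_mode,
    )
    summary = {
        "config_hash": chash,
        "seed": config.seed,
        "folds": config.folds,
        "repeats": config.repeats,
        "n_subjects": int(len(feat_only)),
        "per_class": report.summary(),
        "warnings": report.warnings,
    }
    (out / "cv_summary.json").write_text(json.dumps(summary, indent=2) + "\n")

    roc_rows = []
    for r in report.results:
        for fpr, tpr in r.roc:
            roc_rows.append({"config_hash": chash, "repeat": r.repeat, "fold": r.fold,
                             "class": r.class_label, "fpr": fpr, "tpr": tpr})
    pd.DataFrame(roc_rows).to_csv(out / "roc_points.csv", index=False, float_format="%.8g")

    (out / "run.json").write_text(
        json.dumps({"config_hash": chash, "config": config.to_dict()}, indent=2) + "\n"
    )
    logger.info("pipeline done: %d subjects, outputs in %s", len(feat_only), out)
    return {
        "features": features,
        "stats_groups": stats_groups,
        "stats_subgroups": stats_subgroups,
        "cv_report": report,
        "cv_summary": summary,
        "config_hash": chash,
    }
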