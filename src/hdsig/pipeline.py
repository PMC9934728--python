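"""End-to-end orchestration: synth → preprocess → features → evaluate → stats.

A :class:`PipelineConfig` (loadable from YAML/JSON) drives a deterministic
run: one global seed fans out to per-stage seeds via fixed offsets, every
stochastic stage owns an explicitly seeded generator, and a rerun with the
same config reproduces byte-identical summary JSON.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import classify, features, preprocess, statreport, synthgen
from .signal_io import Cohort, Modality, write_cohort

__all__ = [
    "PipelineConfig",
    "run_pipeline",
    "extract_cohort_features",
]

log = logging.getLogger("hdsig.pipeline")

# stage-seed offsets from the global seed
_SEED_SYNTH = 0
_SEED_SPLIT = 1
_SEED_MODEL = 2
_SEED_STATS = 3
_SEED_IMPORTANCE = 4


@dataclass
class PipelineConfig:
    """Nested per-stage configuration with one global seed."""

    seed: int = 0
    out_dir: str = "hdsig_run"
    #: "desk" (60 s, reduced fs, 20 patients) or "clinic" (69 patients, 1200 s)
    scale: str = "desk"
    #: overrides applied on top of the scale's EffectConfig defaults
    synth: dict = field(default_factory=dict)
    preprocess: dict = field(default_factory=dict)   # epoch_length_s, overlap_s, ptp
    features: dict = field(default_factory=dict)     # kmax
    classify: dict = field(default_factory=dict)     # models, k, tuned
    stats: dict = field(default_factory=dict)        # max_features, enabled
    write_signals: bool = False

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text)  # YAML is a JSON superset
        return cls.from_dict(data or {})

    def to_file(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    def effect_config(self) -> synthgen.EffectConfig:
        base = (
            synthgen.desk_scale_config(seed=self.seed + _SEED_SYNTH)
            if self.scale == "desk"
            else synthgen.clinic_scale_config(seed=self.seed + _SEED_SYNTH)
        )
        return base.replace(**self.synth) if self.synth else base


def extract_cohort_features(
    cohort: Cohort,
    epoch_length_s: float = 5.0,
    overlap_s: float = 1.0,
    ptp_thresholds: dict | None = None,
    kmax: int = features.HFD_KMAX,
) -> tuple[features.FeatureMatrix, dict]:
    """Preprocess every recording of every patient and assemble the matrix.

    Returns the FeatureMatrix plus a per-patient bookkeeping dict with epoch
    and dropped-epoch counts.
    """
    cohort_epochs: dict[str, dict[Modality, preprocess.EpochSet]] = {}
    labels: dict[str, int] = {}
    book: dict[str, dict] = {}
    for patient in cohort:
        per_mod = {}
        info = {}
        for modality, rec in patient.recordings.items():
            thr = (
                ptp_thresholds.get(modality, "default")
                if ptp_thresholds
                else "default"
            )
            es_all = preprocess.epochize(
                preprocess.bandpass(
                    rec,
                    preprocess.BandPassSpec(*preprocess.DEFAULT_BANDS[modality]),
                ),
                epoch_length_s,
                overlap_s,
            )
            es_all.patient_id = patient.patient_id
            thr_value = (
                preprocess.DEFAULT_PTP_THRESHOLDS[modality]
                if isinstance(thr, str)
                else thr
            )
            es = preprocess.normalize(preprocess.drop_bad_epochs(es_all, thr_value))
            per_mod[modality] = es
            info[modality.value] = {
                "epochs": es_all.n_epochs,
                "dropped": es_all.n_epochs - es.n_epochs,
            }
        cohort_epochs[patient.patient_id] = per_mod
        labels[patient.patient_id] = patient.label
        book[patient.patient_id] = info
    fm = features.assemble(cohort_epochs, labels, kmax=kmax)
    return fm, book


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run every stage and write all artifacts into ``cfg.out_dir``.

    Returns the run summary (also written as ``summary.json``).
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger = logging.getLogger("hdsig")
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    t0 = time.time()
    try:
        effect_cfg = cfg.effect_config()
        log.info("stage synth: %d patients, %.0f s each",
                 effect_cfg.n_patients, effect_cfg.duration_s)
        cohort = synthgen.generate_cohort(effect_cfg)
        if cfg.write_signals:
            write_cohort(cohort, out / "cohort")
            log.info("stage synth: wrote cohort CSVs under %s", out / "cohort")

        log.info("stage preprocess+features: extracting")
        fm, book = extract_cohort_features(
            cohort,
            epoch_length_s=cfg.preprocess.get("epoch_length_s", 5.0),
            overlap_s=cfg.preprocess.get("overlap_s", 1.0),
            kmax=cfg.features.get("kmax", features.HFD_KMAX),
        )
        log.info("stage features: matrix %d x %d", fm.n_epochs, fm.n_features)
        fm.to_csv(out / "features.csv")

        model_names = cfg.classify.get("models", ["ERT"])
        k = cfg.classify.get("k", 10)
        tuned = cfg.classify.get("tuned", False)
        reports = {}
        for name in model_names:
            spec = (
                classify.tuned_spec(name, seed=cfg.seed + _SEED_MODEL)
                if tuned and name in ("ERT", "RandomForest")
                else classify.ModelSpec(name, seed=cfg.seed + _SEED_MODEL)
            )
            res = classify.GroupCVClassifier(
                fm, spec, k=k, seed=cfg.seed + _SEED_SPLIT
            ).fit()
            reports[name] = res.to_dict()
            log.info("stage classify: %s accuracy %.2f%% auc %.3f",
                     name, res.accuracy, res.roc_auc)
        (out / "cv_report.json").write_text(json.dumps(reports, indent=1, sort_keys=True))

        stats_block = None
        if cfg.stats.get("enabled", True):
            max_features = cfg.stats.get("max_features")
            if max_features is None and fm.n_epochs <= fm.n_features + 1:
                max_features = max(1, min(fm.n_features, fm.n_epochs // 2))
                log.info("stage stats: auto feature subset of %d", max_features)
            ols_res = statreport.FeatureOLS(
                fm, max_features=max_features, seed=cfg.seed + _SEED_STATS
            ).fit()
            imp_res = statreport.TreeImportance(
                fm, seed=cfg.seed + _SEED_IMPORTANCE
            ).fit()
            (out / "stats.json").write_text(
                json.dumps(ols_res.to_dict(), indent=1, sort_keys=True)
            )
            (out / "importance.json").write_text(
                json.dumps(imp_res.to_dict(), indent=1, sort_keys=True)
            )
            stats_block = {
                "rsquared": ols_res.rsquared,
                "pvalue_bins": ols_res.pvalue_bins(),
                "n_features_tested": len(ols_res.feature_names),
                "importance_by_signal": {
                    key: {"mean": m, "se": s}
                    for key, (m, s) in imp_res.groups["signal"].items()
                },
            }
            log.info("stage stats: R^2=%.3f", ols_res.rsquared)

        summary = {
            "config": cfg.to_dict(),
            "n_patients": len(cohort),
            "n_epochs": fm.n_epochs,
            "n_features": fm.n_features,
            "feature_counts": fm.family_counts(),
            "epochs_per_patient": book,
            "cv": reports,
            "stats": stats_block,
        }
        (out / "summary.json").write_text(json.dumps(summary, indent=1, sort_keys=True))
        log.info("pipeline done in %.1f s", time.time() - t0)
        return summary
    finally:
        logger.removeHandler(handler)
        handler.close()
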