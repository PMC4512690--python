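"""One-command orchestration: extract -> (select) -> train -> evaluate.

A :class:`RunConfig` captures everything that influences the result —
input, windowing, feature flags, selection and classifier parameters, the
split fraction and every seed — and is serialized verbatim (plus its hash)
into each artifact, so any output file can be traced back to the exact
configuration that produced it.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import classifiers, evaluation, features, selection, signal_io, synthetic
from .errors import ActiwinError, SchemaError

logger = logging.getLogger("actiwin")


@dataclass
class RunConfig:
    """Full provenance of one pipeline run (YAML-serializable)."""

    # input: either file paths with a format, or the synthetic generator
    inputs: list[str] = field(default_factory=list)
    input_format: str = "synthetic"          # "pamap2" | "csv" | "synthetic"
    synthetic_subjects: int = 5
    synthetic_seconds_per_activity: float = 60.0
    synthetic_missing_rate: float = 0.0
    sensors: list[str] = field(default_factory=lambda: list(signal_io.PLACEMENTS))
    sampling_rate: float = 100.0
    # windowing / features
    window_seconds: float = 5.0
    slide_seconds: float = 1.0
    willison_threshold: float = 0.5
    include_ssi: bool = False
    interpolation_max_gap_s: float = 0.1
    window_missing_max_frac: float = 0.1
    # selection
    select: bool = False
    refset_size: int = 10
    pool_size: int = 30
    max_iterations: int = 50
    # classifier
    classifier: str = "rotation_forest"
    knn_k: int = 3
    ensemble_size: int = 10
    rotation_subset_size: int = 3
    class_bootstrap_fraction: float = 0.75
    hidden_units: int | None = None
    learning_rate: float = 0.3
    momentum: float = 0.2
    epochs: int = 500
    # evaluation
    train_fraction: float = 0.7
    seed: int = 0
    outdir: str = "actiwin_run"

    def feature_config(self) -> features.FeatureBankConfig:
        return features.FeatureBankConfig(
            window_seconds=self.window_seconds,
            slide_seconds=self.slide_seconds,
            willison_threshold=self.willison_threshold,
            include_ssi=self.include_ssi,
            missing_max_frac=self.window_missing_max_frac,
        )

    def classifier_spec(self) -> classifiers.ClassifierSpec:
        return classifiers.ClassifierSpec(
            kind=self.classifier,
            k=self.knn_k,
            ensemble_size=self.ensemble_size,
            rotation_subset_size=self.rotation_subset_size,
            class_bootstrap_fraction=self.class_bootstrap_fraction,
            hidden_units=self.hidden_units,
            learning_rate=self.learning_rate,
            momentum=self.momentum,
            epochs=self.epochs,
            seed=self.seed,
        )

    def ssrgs_config(self) -> selection.SSRGSConfig:
        return selection.SSRGSConfig(
            refset_size=self.refset_size,
            pool_size=self.pool_size,
            max_iterations=self.max_iterations,
            seed=self.seed,
        )

    def config_hash(self) -> str:
        canon = json.dumps(asdict(self), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise SchemaError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def validate(self) -> None:
        signal_io.validate_placements(self.sensors)
        if self.input_format not in ("pamap2", "csv", "synthetic"):
            raise SchemaError(f"unknown input format {self.input_format!r}")
        if self.input_format != "synthetic" and not self.inputs:
            raise SchemaError("file-based input requires at least one path")
        self.feature_config()
        self.classifier_spec()
        if self.select:
            self.ssrgs_config()


def load_recordings(cfg: RunConfig) -> list[signal_io.Recording]:
    """Stage 1: read or generate the labeled recordings."""
    if cfg.input_format == "synthetic":
        return synthetic.generate_subjects(
            cfg.synthetic_subjects,
            seconds_per_activity=cfg.synthetic_seconds_per_activity,
            sampling_rate=cfg.sampling_rate,
            seed=cfg.seed,
            missing_rate=cfg.synthetic_missing_rate,
        )
    recs = []
    for path in cfg.inputs:
        if cfg.input_format == "pamap2":
            rec = signal_io.read_pamap2(
                path, placements=tuple(cfg.sensors), sampling_rate=cfg.sampling_rate
            )
        else:
            rec = signal_io.read_csv_recording(path, sampling_rate=cfg.sampling_rate)
        recs.append(signal_io.interpolate_missing(rec, cfg.interpolation_max_gap_s))
    return recs


def extract_fused_matrix(cfg: RunConfig, recordings) -> features.FeatureMatrix:
    """Stage 2: per-sensor windowing + feature extraction, then fusion."""
    fcfg = cfg.feature_config()
    per_sensor: dict[str, list[features.FeatureMatrix]] = {p: [] for p in cfg.sensors}
    for rec in recordings:
        mats = features.extract_recording(rec, fcfg, placements=tuple(cfg.sensors))
        for p in cfg.sensors:
            per_sensor[p].append(mats[p])
    stacked = []
    for p in cfg.sensors:
        mats = per_sensor[p]
        values = np.vstack([m.values for m in mats])
        labels = np.concatenate([m.labels for m in mats])
        stacked.append(features.FeatureMatrix(mats[0].names, values, labels))
    fused = features.fuse(stacked)
    logger.info(
        "extracted %d instances x %d features from %d recording(s)",
        len(fused), fused.width, len(recordings),
    )
    return fused


def run(cfg: RunConfig) -> evaluation.EvaluationReport:
    """Execute the full pipeline and write artifacts under ``cfg.outdir``.

    Artifacts: ``run.yaml`` (the config), ``features.csv``, optionally
    ``subset.json``, ``model.joblib``, ``report.json`` and ``report.txt``;
    every JSON artifact embeds the config hash.
    """
    cfg.validate()  # fail before any compute
    chash = cfg.config_hash()
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg.to_yaml(outdir / "run.yaml")

    try:
        recordings = load_recordings(cfg)
        logger.info("loaded %d recording(s), %s samples total",
                    len(recordings), sum(len(r) for r in recordings))
        fused = extract_fused_matrix(cfg, recordings)
        fused.to_csv(outdir / "features.csv")

        if cfg.select:
            subset = selection.run_ssrgs(fused, cfg.ssrgs_config())
            logger.info("selected %d/%d features, merit %.4f",
                        len(subset), fused.width, subset.merit)
            (outdir / "subset.json").write_text(json.dumps({
                "config_hash": chash,
                "indices": list(subset.indices),
                "names": subset.names(fused),
                "merit": subset.merit,
            }, indent=2, sort_keys=True))
            fused = fused.select(subset.indices)

        train_fm, test_fm = evaluation.split(
            fused, cfg.train_fraction, seed=cfg.seed, stratified=True
        )
        logger.info("split: %d train / %d test instances", len(train_fm), len(test_fm))
        model = classifiers.train(cfg.classifier_spec(), train_fm)
        classifiers.save_model(model, outdir / "model.joblib")
        report = evaluation.evaluate(model, test_fm, split_seed=cfg.seed)
        logger.info("%s: accuracy %.3f, weighted F %.3f",
                    cfg.classifier, report.accuracy, report.weighted_f)

        payload = {"config_hash": chash, "config": asdict(cfg), "report": report.to_dict()}
        (outdir / "report.json").write_text(json.dumps(payload, indent=2, sort_keys=True))
        (outdir / "report.txt").write_text(
            report.format_table(signal_io.ACTIVITY_SHORT_LABELS) + "\n"
        )
        return report
    except ActiwinError as exc:
        raise type(exc)(f"pipeline failed (config {chash}): {exc}") from exc
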