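"""End-to-end pipeline: simulate/load walks, extract features, classify, ROC.

The pipeline is deterministic given the config seeds; every run directory
contains a manifest recording the config hash, package version, and exact
sample bookkeeping (each input walk ends up either in ``features.csv`` or in
the dropped-samples list with a reason).
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

from . import __version__
from .djnp import build_djnp, save_png
from .features_tsr import extract_features
from .pose_io import PoseSequence, read_csv, sample_frames
from .stats_ml import roc_analysis, train_svm_cv
from .synthetic_gait import CohortSpec, generate_cohort

__all__ = ["PipelineConfig", "features_table", "run_pipeline"]

logger = logging.getLogger(__name__)

FEATURE_COLUMNS = ["subject", "walk", "label", "tar", "bar", "velocity_mps", "valid", "n_frames"]


@dataclass
class PipelineConfig:
    """Knobs for one reproducible pipeline run."""

    interval_s: float = 0.3
    conf_threshold: float = 0.1
    sigma_px: float = 3.0
    downscale: int = 4
    folds: int = 10
    seed: int = 7
    svm_c: float = 1.0
    svm_gamma: str | float = "scale"
    # simulation (used when input_dir is None)
    n_subjects: int = 35
    walks_per_subject: int = 6
    frac_skew_left: float = 36 / 210
    frac_skew_right: float = 89 / 210
    skew_mean_deg: float = 1.0
    noise_sd_px: float = 1.0
    dropout_rate: float = 0.02
    input_dir: str | None = None
    djnp_examples: int = 3  # PNG exports, one per label up to this many

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def _load_walks(input_dir: str | Path) -> list[PoseSequence]:
    paths = sorted(Path(input_dir).glob("*.csv"))
    if not paths:
        raise ValueError(f"no .csv walk files found in {input_dir}")
    return [read_csv(p) for p in paths]


def features_table(
    sequences: list[PoseSequence],
    interval_s: float = 0.3,
    conf_threshold: float = 0.1,
) -> pd.DataFrame:
    """Per-walk feature rows (invalid walks kept, flagged with a reason)."""
    rows = []
    for seq in sequences:
        feats = extract_features(seq, interval_s=interval_s, conf_threshold=conf_threshold)
        n_frames = len(sample_frames(seq, interval_s))
        rows.append(
            {
                "subject": seq.subject_id,
                "walk": seq.walk_index,
                "label": seq.label,
                "tar": feats.tar,
                "bar": feats.bar,
                "velocity_mps": feats.velocity_mps,
                "valid": feats.valid,
                "n_frames": n_frames,
                "reason": feats.reason,
            }
        )
    return pd.DataFrame(rows)


def _write_features_csv(table: pd.DataFrame, path: Path) -> None:
    out = table[FEATURE_COLUMNS].copy()
    for col in ("tar", "bar", "velocity_mps"):
        out[col] = out[col].map(lambda v: f"{v:.6f}")
    out.to_csv(path, index=False)


def _roc_payload(table: pd.DataFrame) -> dict:
    """Pairwise straight-vs-skew ROC analyses for tar and bar."""
    payload: dict[str, dict] = {}
    valid = table[table["valid"]]
    straight = valid[valid["label"] == "straight"]
    for positive in ("skew_right", "skew_left"):
        group = valid[valid["label"] == positive]
        if straight.empty or group.empty:
            continue
        for feature in ("tar", "bar"):
            result = roc_analysis(
                straight[feature].to_numpy(), group[feature].to_numpy()
            )
            payload[f"straight_vs_{positive}:{feature}"] = result.to_dict()
    return payload


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> Path:
    """Run the full pipeline and write all artifacts under ``out_dir``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    log_path = out_dir / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
    root = logging.getLogger("skewgait")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    try:
        return _run(config, out_dir)
    finally:
        root.removeHandler(handler)
        handler.close()


def _run(config: PipelineConfig, out_dir: Path) -> Path:
    logger.info("stage=input config_hash=%s", config.config_hash())
    if config.input_dir:
        sequences = _load_walks(config.input_dir)
    else:
        spec = CohortSpec(
            n_subjects=config.n_subjects,
            walks_per_subject=config.walks_per_subject,
            frac_skew_left=config.frac_skew_left,
            frac_skew_right=config.frac_skew_right,
            skew_mean_deg=config.skew_mean_deg,
            noise_sd_px=config.noise_sd_px,
            dropout_rate=config.dropout_rate,
            seed=config.seed,
        )
        sequences = generate_cohort(spec)
    logger.info("stage=features n_walks=%d", len(sequences))
    table = features_table(sequences, config.interval_s, config.conf_threshold)
    _write_features_csv(table, out_dir / "features.csv")

    dropped = table[~table["valid"]]
    valid = table[table["valid"]]
    logger.info("stage=classify n_valid=%d n_dropped=%d", len(valid), len(dropped))
    report = train_svm_cv(
        valid[["tar", "bar", "velocity_mps"]].to_numpy(),
        valid["label"].to_numpy(),
        folds=config.folds,
        seed=config.seed,
        C=config.svm_c,
        gamma=config.svm_gamma,
    )
    with open(out_dir / "report.json", "w") as fh:
        json.dump(report.to_dict(), fh, indent=2)

    logger.info("stage=roc")
    with open(out_dir / "roc.json", "w") as fh:
        json.dump(_roc_payload(table), fh, indent=2)

    logger.info("stage=djnp")
    djnp_dir = out_dir / "djnp"
    djnp_dir.mkdir(exist_ok=True)
    seen: set[str] = set()
    for seq in sequences:
        if seq.label in seen or len(seen) >= config.djnp_examples:
            continue
        seen.add(seq.label)
        sampled = sample_frames(seq, config.interval_s)
        plot = build_djnp(
            sampled,
            sigma_px=config.sigma_px,
            downscale=config.downscale,
            conf_threshold=config.conf_threshold,
        )
        save_png(plot, djnp_dir / f"{seq.label}_{seq.subject_id}_w{seq.walk_index}.png")

    manifest = {
        "package_version": __version__,
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "n_walks": len(sequences),
        "n_valid": int(len(valid)),
        "n_dropped": int(len(dropped)),
        "dropped_samples": dropped[["subject", "walk", "reason"]].to_dict("records"),
        "label_counts": table["label"].value_counts().to_dict(),
    }
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    logger.info("stage=done out=%s", out_dir)
    return out_dir
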