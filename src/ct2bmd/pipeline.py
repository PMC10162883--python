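"""End-to-end experiment wiring: simulate -> features -> train -> evaluate.

The four stages are (1) image acquisition (here: synthetic phantom pairs or
user-supplied feature tables), (2) GLCM feature extraction, (3) network
training on sharp "QCT" features against calibrated density targets, and
(4) prediction from degraded "clinical CT" features of held-out phantoms.
Every report carries the seed and a hash of the configuration for
provenance.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import neuralnet, synthetic, texture
from .errors import SchemaError
from .neuralnet import BMDNetwork, TrainingConfig, TrainingRecord

logger = logging.getLogger(__name__)


@dataclass
class ExperimentConfig:
    """One reproducible run of the full synthetic experiment."""

    n_samples: int = 300
    bvtv_range: tuple[float, float] = (0.1, 0.6)
    phantom: synthetic.PhantomSpec = field(default_factory=synthetic.PhantomSpec)
    ng: int = 8
    d: int = 1
    thetas: tuple[int, ...] = texture.DEFAULT_THETAS
    symmetric: bool = False
    training: TrainingConfig = field(default_factory=TrainingConfig)
    seed: int = 7
    out_dir: str | None = None

    def to_dict(self) -> dict:
        from dataclasses import asdict

        d = asdict(self)
        d["thetas"] = list(self.thetas)
        d["bvtv_range"] = list(self.bvtv_range)
        return d

    def config_hash(self) -> str:
        d = self.to_dict()
        d.pop("out_dir", None)  # output location is not part of the experiment
        payload = json.dumps(d, sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]

    @classmethod
    def from_file(cls, path: str | Path) -> "ExperimentConfig":
        """Load from JSON or TOML; unknown keys are rejected."""
        path = Path(path)
        if path.suffix == ".toml":
            import tomllib

            with open(path, "rb") as fh:
                obj = tomllib.load(fh)
        else:
            with open(path) as fh:
                obj = json.load(fh)
        # tuples arrive as lists from JSON/TOML
        phantom_kwargs = dict(obj.pop("phantom", {}))
        if "size" in phantom_kwargs:
            phantom_kwargs["size"] = tuple(phantom_kwargs["size"])
        phantom = synthetic.PhantomSpec(**phantom_kwargs)
        kwargs = dict(obj)
        if "bvtv_range" in kwargs:
            kwargs["bvtv_range"] = tuple(kwargs["bvtv_range"])
        if "thetas" in kwargs:
            kwargs["thetas"] = tuple(kwargs["thetas"])
        if "training" in kwargs:
            tr = dict(kwargs["training"])
            if "split_fractions" in tr:
                tr["split_fractions"] = tuple(tr["split_fractions"])
            kwargs["training"] = TrainingConfig(**tr)
        kwargs["phantom"] = phantom
        return cls(**kwargs)


def _require_columns(df: pd.DataFrame, cols) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"feature table missing columns {missing}")


def split_metrics(
    pred: np.ndarray, target: np.ndarray, splits
) -> dict[str, dict[str, float]]:
    """Per-split and pooled R / MSE."""
    names = ("train", "validation", "test")
    out: dict[str, dict[str, float]] = {}
    for name, idx in zip(names, splits):
        if len(idx) >= 2:
            out[name] = {
                "r": neuralnet.correlation_coefficient(pred[idx], target[idx]),
                "mse": neuralnet.mse(pred[idx], target[idx]),
                "n": int(len(idx)),
            }
        else:
            out[name] = {"r": float("nan"), "mse": float("nan"), "n": int(len(idx))}
    out["overall"] = {
        "r": neuralnet.correlation_coefficient(pred, target),
        "mse": neuralnet.mse(pred, target),
        "n": int(len(target)),
    }
    return out


def run_training_phase(
    features: pd.DataFrame,
    config: TrainingConfig | None = None,
) -> tuple[BMDNetwork, TrainingRecord, dict]:
    """Train on a feature/target table; report R and MSE per split.

    ``features`` must have the five texture columns plus ``bmd``.
    """
    config = config or TrainingConfig()
    _require_columns(features, list(texture.FEATURE_COLUMNS) + ["bmd"])
    X = features[list(texture.FEATURE_COLUMNS)].to_numpy(dtype=float)
    y = features["bmd"].to_numpy(dtype=float)
    logger.info("training phase: %d rows, seed %d", len(y), config.seed)
    net, record, splits = neuralnet.train(X, y, config)
    pred = neuralnet.predict(net, X)
    report = {
        "seed": config.seed,
        "n_rows": int(len(y)),
        "metrics": split_metrics(pred, y, splits),
        "curves": {
            "train_mse": record.train_mse,
            "val_mse": record.val_mse,
            "test_mse": record.test_mse,
        },
        "best_epoch": record.best_epoch,
        "epochs_run": record.epochs_run,
        "stop_reason": record.stop_reason,
        "splits": {
            "train": splits[0].tolist(),
            "validation": splits[1].tolist(),
            "test": splits[2].tolist(),
        },
    }
    return net, record, report


def run_clinical_evaluation(
    net: BMDNetwork,
    clinical_features: pd.DataFrame,
    truth: pd.DataFrame | np.ndarray,
) -> dict:
    """Predict from clinical-CT features and compare against reference BMD."""
    _require_columns(clinical_features, texture.FEATURE_COLUMNS)
    if isinstance(truth, pd.DataFrame):
        _require_columns(truth, ["bmd"])
        target = truth["bmd"].to_numpy(dtype=float)
    else:
        target = np.asarray(truth, dtype=float).ravel()
    if len(target) != len(clinical_features):
        raise SchemaError(
            f"{len(clinical_features)} feature rows vs {len(target)} truth rows"
        )
    X = clinical_features[list(texture.FEATURE_COLUMNS)].to_numpy(dtype=float)
    pred = neuralnet.predict(net, X)
    table = pd.DataFrame({"predicted_bmd": pred, "true_bmd": target})
    return {
        "r": neuralnet.correlation_coefficient(pred, target),
        "mse": neuralnet.mse(pred, target),
        "n": int(len(target)),
        "per_sample": table,
    }


def run_experiment(config: ExperimentConfig) -> dict:
    """Full synthetic chain: simulate, extract, train on QCT, evaluate on
    held-out clinical renderings.  Deterministic for a fixed seed."""
    logger.info("simulating %d phantoms (seed %d)", config.n_samples, config.seed)
    feats_q, feats_c, _ = synthetic.generate_dataset(
        config.n_samples,
        config.bvtv_range,
        config.seed,
        config.phantom,
        ng=config.ng,
        d=config.d,
        thetas=config.thetas,
    )
    training = config.training
    if training.seed != config.seed:
        from dataclasses import replace

        training = replace(training, seed=config.seed)
    net, record, train_report = run_training_phase(feats_q, training)

    test_idx = np.array(train_report["splits"]["test"], dtype=int)
    clin_eval = run_clinical_evaluation(
        net,
        feats_c.iloc[test_idx].reset_index(drop=True),
        feats_c["bmd"].to_numpy()[test_idx],
    )
    report = {
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "config": config.to_dict(),
        "training": train_report,
        "clinical_evaluation": {
            "r": clin_eval["r"],
            "mse": clin_eval["mse"],
            "n": clin_eval["n"],
        },
    }
    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        net.to_json(out / "model.json", config=training)
        feats_q.to_csv(out / "features_qct.csv", index=False)
        feats_c.to_csv(out / "features_clinical.csv", index=False)
        clin_eval["per_sample"].to_csv(out / "clinical_predictions.csv", index=False)
        with open(out / "report.json", "w") as fh:
            json.dump(report, fh, indent=2)
        logger.info("wrote experiment outputs to %s", out)
    return report
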