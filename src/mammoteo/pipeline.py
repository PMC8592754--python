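"""End-to-end pipeline driver.

Chains the stages on a synthetic phantom cohort: preprocessing
(contrast stretch, optional fuzzy denoise) -> segmentation -> texture
features -> neuroevolution training -> confusion-matrix metrics on a
held-out split.  Every artifact is persisted under the configured
output directory and a run log records the configuration and all seeds,
so a rerun with the same (config, seed) reproduces the metrics exactly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from . import features as feat
from . import io_utils, network, phantom, preprocess, segment

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline", "cohort_features"]

LABEL_TO_CLASS = {phantom.BENIGN: 0, phantom.MALIGNANT: 1}


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


@dataclass
class PipelineConfig:
    """Pipeline parameters; unknown keys are rejected by :meth:`from_dict`."""

    out_dir: str = "pipeline_out"
    seed: int = 0
    n_samples: int = 60
    class_balance: float = 0.5
    image_size: int = 128
    mass_contrast: float = 0.5
    noise_sigma: float = 0.02
    denoise: bool = False
    wm_partitions: int = 7
    se: str = "identity"
    min_contrast: float = 0.35
    use_truth_mask_fallback: bool = True
    train_fraction: float = 0.7
    max_fes: int = 20_000
    pop_size: int = 150
    weight_bound: float = 5.0

    @classmethod
    def from_dict(cls, d: Dict[str, object]) -> "PipelineConfig":
        known = {f.name: f.type for f in dataclasses.fields(cls)}
        unknown = set(d) - set(known)
        if unknown:
            raise ValueError(f"unknown configuration key(s): {sorted(unknown)}")
        return cls(**d)  # type: ignore[arg-type]

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        """Parse a plain ``key = value`` text file."""
        raw: Dict[str, object] = {}
        for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"line {lineno}: expected 'key = value'")
            key, value = (s.strip() for s in line.split("=", 1))
            raw[key] = _coerce(value)
        return cls.from_dict(raw)

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _coerce(value: str) -> object:
    low = value.lower()
    if low in ("true", "false"):
        return low == "true"
    for cast in (int, float):
        try:
            return cast(value)
        except ValueError:
            pass
    return value


def _dice(a: np.ndarray, b: np.ndarray) -> float:
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    denom = a.sum() + b.sum()
    if denom == 0:
        return 1.0
    return 2.0 * float(np.sum(a & b)) / float(denom)


def cohort_features(
    samples: List[Tuple[np.ndarray, np.ndarray, str]],
    config: Optional[PipelineConfig] = None,
    rules: Optional[preprocess.FuzzyRuleBase] = None,
) -> Tuple[np.ndarray, np.ndarray, pd.DataFrame]:
    """Preprocess, segment and featurize a phantom cohort.

    Returns (feature matrix, class labels, per-sample report with Dice
    overlap and the mask source actually used).  When segmentation
    yields an empty mask the ground-truth mask is substituted (recorded
    in the report) unless the config disables the fallback, in which
    case the sample is dropped.
    """
    cfg = config or PipelineConfig()
    rows, X, y = [], [], []
    for i, (img, truth, label) in enumerate(samples):
        try:
            pp = preprocess.contrast_stretch(img)
        except preprocess.DegenerateImageError as exc:
            raise PipelineError(f"preprocess failed on sample {i}: {exc}") from exc
        if rules is not None:
            pp = preprocess.wm_denoise(pp, rules)
        try:
            mask = segment.segment(pp, se=cfg.se, min_contrast=cfg.min_contrast)
        except preprocess.DegenerateImageError as exc:
            raise PipelineError(f"segmentation failed on sample {i}: {exc}") from exc
        source = "segmentation"
        if not mask.any():
            if not (cfg.use_truth_mask_fallback and truth.any()):
                rows.append({"index": i, "label": label, "dice": 0.0, "mask_source": "dropped"})
                continue
            mask, source = truth, "truth_fallback"
        vec = feat.extract_features(pp, mask)
        X.append(vec)
        y.append(LABEL_TO_CLASS[label])
        rows.append({"index": i, "label": label, "dice": _dice(mask, truth), "mask_source": source})
    if not X:
        raise PipelineError("feature extraction: no usable samples")
    return np.asarray(X), np.asarray(y), pd.DataFrame(rows)


def _split(n: int, train_fraction: float, y: np.ndarray, rng: np.random.Generator):
    idx = np.arange(n)
    train_idx: List[int] = []
    test_idx: List[int] = []
    for cls in np.unique(y):
        members = idx[y == cls]
        members = rng.permutation(members)
        k = int(round(len(members) * train_fraction))
        k = min(max(k, 1), len(members) - 1)
        train_idx.extend(members[:k])
        test_idx.extend(members[k:])
    return np.sort(train_idx), np.sort(test_idx)


def run_pipeline(config: PipelineConfig) -> Dict[str, float]:
    """Run every stage on a synthetic cohort and persist the artifacts.

    Writes images, masks, ``features.csv``, ``model.json``,
    ``metrics.csv`` and ``runlog.json`` under ``config.out_dir`` and
    returns the metrics dict.
    """
    cfg = config
    out = Path(cfg.out_dir)
    (out / "images").mkdir(parents=True, exist_ok=True)
    (out / "masks").mkdir(parents=True, exist_ok=True)

    master = np.random.default_rng(cfg.seed)
    seed_cohort = int(master.integers(2**31 - 1))
    seed_split = int(master.integers(2**31 - 1))
    seed_train = int(master.integers(2**31 - 1))

    samples, manifest = phantom.generate_dataset(
        cfg.n_samples,
        class_balance=cfg.class_balance,
        seed=seed_cohort,
        size=(cfg.image_size, cfg.image_size),
        mass_contrast=cfg.mass_contrast,
        noise_sigma=cfg.noise_sigma,
    )
    manifest.to_csv(out / "manifest.csv", index=False)
    for i, (img, mask, _label) in enumerate(samples):
        io_utils.write_image(out / "images" / f"sample_{i:03d}.png", img)
        io_utils.write_mask(out / "masks" / f"sample_{i:03d}_truth.png", mask)

    rules = None
    if cfg.denoise:
        # train the fuzzy rule base on a clean/noisy pair from the generator
        clean_spec = phantom.PhantomSpec(
            size=(cfg.image_size, cfg.image_size), noise_sigma=0.0, seed=seed_cohort
        )
        clean, _, _ = phantom.generate_phantom(clean_spec)
        noisy, _, _ = phantom.generate_phantom(
            dataclasses.replace(clean_spec, noise_sigma=cfg.noise_sigma)
        )
        rules = preprocess.wm_build_rules(noisy, clean, k_partitions=cfg.wm_partitions)

    X, y, report = cohort_features(samples, cfg, rules)
    names = feat.feature_names()
    table = pd.DataFrame(X, columns=names)
    table.insert(0, "image_id", report.loc[report.mask_source != "dropped", "index"].values)
    table["label"] = y
    table.to_csv(out / "features.csv", index=False)
    report.to_csv(out / "segmentation_report.csv", index=False)

    rng = np.random.default_rng(seed_split)
    train_idx, test_idx = _split(len(y), cfg.train_fraction, y, rng)
    spec = network.NetworkSpec(input_len=X.shape[1])
    from .optimize import TEOConfig

    teo_cfg = TEOConfig(
        lower=-cfg.weight_bound,
        upper=cfg.weight_bound,
        pop_size=cfg.pop_size,
        max_fes=cfg.max_fes,
        seed=seed_train,
    )
    scaler = network.fit_scaler(X[train_idx])
    X_train = network.apply_scaler(X[train_idx], *scaler)
    X_test = network.apply_scaler(X[test_idx], *scaler)
    Y = network.one_hot(y[train_idx], spec.classes)
    weights, history = network.train_with_ateo(
        spec, X_train, Y, config=teo_cfg, seed=seed_train
    )
    io_utils.save_model(out / "model.json", spec, weights, scaler=scaler)
    history.to_csv(out / "training_history.csv", index=False)

    pred = network.predict(spec, weights, X_test)
    counts = network.confusion_counts(pred, y[test_idx], positive=1)
    accuracy, sensitivity, specificity = network.evaluate_metrics(counts)
    metrics = {
        "accuracy": accuracy,
        "sensitivity": sensitivity,
        "specificity": specificity,
        "train_mse": float(history["best_cost"].iloc[-1]),
        "mean_dice": float(report.loc[report.mask_source == "segmentation", "dice"].mean()),
        "n_train": int(len(train_idx)),
        "n_test": int(len(test_idx)),
    }
    pd.DataFrame(
        [{"metric": k, "value": v} for k, v in metrics.items()]
    ).to_csv(out / "metrics.csv", index=False)
    runlog = {
        "config": dataclasses.asdict(cfg),
        "config_hash": cfg.config_hash(),
        "seeds": {"cohort": seed_cohort, "split": seed_split, "train": seed_train},
    }
    (out / "runlog.json").write_text(json.dumps(runlog, indent=2))
    return metrics
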