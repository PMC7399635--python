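"""Down-sampled balanced ensemble with unanimous-vote decision fusion.

The training set is heavily imbalanced (roughly 11 negatives per positive).
The negatives are partitioned at random into k equal groups; each group is
combined with the positives (down-sampling the larger side so the subset is
exactly balanced) and one fully connected neural network is trained per
subset.  A query is called methylated only when every sub-model calls it
methylated (strict unanimity); majority voting is available as an
alternative.  For ranking/ROC purposes the k sub-model probabilities are
fused into one continuous score, by default their minimum, which is exactly
threshold-equivalent to the unanimous decision rule.

Sub-models are scikit-learn multi-layer perceptrons with hidden layers
64-128-256-128-64, ReLU activations and a logistic output, trained with the
adaptive-moment (Adam) optimizer and early stopping on an internal
validation split.  All randomness (partition, down-sampling, weight
initialisation, shuffling) fans out deterministically from one master seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import joblib
import numpy as np
from sklearn.model_selection import StratifiedKFold
from sklearn.neural_network import MLPClassifier

from . import __version__
from .encoders import FeatureMatrix, encode_batch
from .exceptions import (
    IncompatibleModelError,
    StratificationError,
    TrainingError,
    ValidationError,
)
from .io_sequences import Sample
from .metrics import EvalReport, make_report

BUNDLE_FORMAT_VERSION = 1


def spawn_seeds(master_seed: int, n: int) -> list[int]:
    """Derive n child seeds (< 2^31) deterministically from a master seed."""
    state = np.random.SeedSequence(master_seed).generate_state(n, dtype=np.uint64)
    return [int(s % (2**31 - 1)) for s in state]


@dataclass
class SubModelConfig:
    """Hyperparameters of one fully connected sub-classifier.

    ``dropout_rate`` is recorded in model manifests for provenance; the
    scikit-learn backend regularises with an L2 penalty (``alpha``) and
    early stopping rather than dropout layers.
    """

    hidden_layers: list[int] = field(default_factory=lambda: [64, 128, 256, 128, 64])
    activation: str = "relu"
    dropout_rate: float = 0.3
    epochs: int = 50
    batch_size: int = 256
    learning_rate: float = 1e-3
    optimizer_name: str = "adam"
    alpha: float = 1e-4
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.hidden_layers:
            raise ValidationError("hidden_layers must be non-empty")
        if not 0 <= self.dropout_rate < 1:
            raise ValidationError(f"dropout_rate must be in [0,1), got {self.dropout_rate}")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SubModelConfig":
        return cls(**d)


def partition_negatives(
    negative_ids: Sequence, k: int, seed: int
) -> list[np.ndarray]:
    """Randomly partition ids into k disjoint groups of near-equal size."""
    ids = np.asarray(negative_ids)
    if k < 2:
        raise ValidationError(f"k must be >= 2, got {k}")
    if k > len(ids):
        raise ValidationError(f"cannot split {len(ids)} negatives into {k} groups")
    rng = np.random.default_rng(seed)
    return np.array_split(rng.permutation(ids), k)


def build_balanced_subset(
    group: list[Sample], positives: list[Sample], seed: int = 0
) -> list[Sample]:
    """Combine one negative group with the positives into a balanced subset.

    When the sides differ in size the larger one is down-sampled at random
    (seeded) to the size of the smaller, so the output is exactly 1:1.
    """
    if not group or not positives:
        raise ValidationError("both the negative group and the positives must be non-empty")
    rng = np.random.default_rng(seed)
    neg, pos = list(group), list(positives)
    m = min(len(neg), len(pos))
    if len(neg) > m:
        neg = [neg[i] for i in rng.choice(len(neg), size=m, replace=False)]
    elif len(pos) > m:
        pos = [pos[i] for i in rng.choice(len(pos), size=m, replace=False)]
    return pos + neg


def train_submodel(
    features: FeatureMatrix | np.ndarray,
    labels: Sequence[int],
    config: SubModelConfig | None = None,
) -> MLPClassifier:
    """Train one fully connected sub-classifier on an encoded subset.

    Returns a fitted classifier whose ``predict_proba(X)[:, 1]`` is the
    probability of the positive (methylated) class.  Training is seeded and
    reproducible on a single CPU.
    """
    config = config or SubModelConfig()
    X = features.values if isinstance(features, FeatureMatrix) else np.asarray(features, dtype=float)
    y = np.asarray(labels, dtype=int)
    if X.shape[0] != len(y):
        raise ValidationError(f"{X.shape[0]} feature rows but {len(y)} labels")
    if np.isnan(X).any():
        raise ValidationError("feature matrix contains NaN")
    if len(np.unique(y)) < 2:
        raise TrainingError("training requires both classes to be present")
    if config.optimizer_name != "adam":
        raise ValidationError(f"unsupported optimizer {config.optimizer_name!r}")
    clf = MLPClassifier(
        hidden_layer_sizes=tuple(config.hidden_layers),
        activation=config.activation,
        solver="adam",
        alpha=config.alpha,
        batch_size=min(config.batch_size, max(1, (9 * X.shape[0]) // 10)),
        learning_rate_init=config.learning_rate,
        max_iter=config.epochs,
        early_stopping=True,
        validation_fraction=0.1,
        n_iter_no_change=10,
        random_state=config.seed,
    )
    clf.fit(X, y)
    return clf


@dataclass
class EnsembleModel:
    """k trained sub-classifiers plus the fusion rule and decision threshold."""

    submodels: list
    encoding: str
    delta: int
    fusion: str = "unanimous"
    score_fusion: str = "min"
    threshold: float = 0.5
    config: SubModelConfig = field(default_factory=SubModelConfig)
    seed: int = 0

    @property
    def k(self) -> int:
        return len(self.submodels)


def train_ensemble(
    samples: list[Sample],
    encoding: str = "onehot",
    k: int = 11,
    config: SubModelConfig | None = None,
    seed: int = 0,
    fusion: str = "unanimous",
    score_fusion: str = "min",
    threshold: float = 0.5,
) -> EnsembleModel:
    """Train the full k-sub-model ensemble from labeled samples.

    Negatives are partitioned into k groups; each group plus all positives
    (balanced by seeded down-sampling) trains one sub-model.  Every negative
    is used by exactly one sub-model and every positive by all of them.
    """
    config = config or SubModelConfig()
    labels = np.array([s.label for s in samples])
    if any(lab is None for lab in labels):
        raise ValidationError("training requires labeled samples")
    pos = [s for s in samples if s.label == 1]
    neg = [s for s in samples if s.label == 0]
    if not pos or not neg:
        raise TrainingError("training requires both classes to be present")
    seeds = spawn_seeds(seed, 2 * k + 1)
    groups = partition_negatives(np.arange(len(neg)), k, seeds[0])
    submodels = []
    for i, group_idx in enumerate(groups):
        subset = build_balanced_subset([neg[j] for j in group_idx], pos, seed=seeds[1 + i])
        sub_y = [s.label for s in subset]
        sub_X = encode_batch(subset, encoding)
        cfg = SubModelConfig(**{**config.to_dict(), "seed": seeds[1 + k + i]})
        submodels.append(train_submodel(sub_X, sub_y, cfg))
    return EnsembleModel(
        submodels=submodels,
        encoding=encoding,
        delta=samples[0].delta,
        fusion=fusion,
        score_fusion=score_fusion,
        threshold=threshold,
        config=config,
        seed=seed,
    )


def predict_proba(model: EnsembleModel, samples: list[Sample]) -> np.ndarray:
    """Per-sample sub-model scores: an (n, k) matrix ordered by sub-model index."""
    if samples and samples[0].delta != model.delta:
        raise ValidationError(
            f"sample delta {samples[0].delta} does not match model delta {model.delta}"
        )
    X = encode_batch(samples, model.encoding, delta=model.delta).values
    if X.shape[0] == 0:
        return np.empty((0, model.k))
    return np.column_stack([m.predict_proba(X)[:, 1] for m in model.submodels])


def fuse_decision(
    scores: Sequence[float], fusion: str = "unanimous", threshold: float = 0.5
) -> int:
    """Fuse k sub-model scores into one binary call.

    ``unanimous``: positive iff every score exceeds the threshold (the
    strict standard).  ``majority``: positive iff more than half do.
    """
    s = np.asarray(scores, dtype=float)
    if s.size == 0:
        raise ValidationError("cannot fuse an empty score list")
    votes = s > threshold
    if fusion == "unanimous":
        return int(votes.all())
    if fusion == "majority":
        return int(votes.sum() > s.size / 2)
    raise ValidationError(f"unknown fusion rule {fusion!r}")


def fuse_score(scores: Sequence[float], method: str = "min") -> float:
    """Fuse k sub-model scores into one continuous score in [0, 1].

    ``min`` is consistent with unanimity: thresholding the min-fused score
    at t reproduces the unanimous decision at t.  ``mean`` averages.
    """
    s = np.asarray(scores, dtype=float)
    if s.size == 0:
        raise ValidationError("cannot fuse an empty score list")
    if method == "min":
        return float(s.min())
    if method == "mean":
        return float(s.mean())
    raise ValidationError(f"unknown score fusion method {method!r}")


def predict(
    model: EnsembleModel, samples: list[Sample]
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Run the full ensemble: (fused scores, binary calls, sub-model score matrix)."""
    sub_scores = predict_proba(model, samples)
    fused = np.array([fuse_score(row, model.score_fusion) for row in sub_scores])
    calls = np.array(
        [fuse_decision(row, model.fusion, model.threshold) for row in sub_scores]
    )
    return fused, calls, sub_scores


@dataclass
class CVResult:
    """Cross-validation summary: fused-model report plus per-sub-model reports.

    Metric fields (sn/sp/acc/mcc/auc) are macro-averages over folds then
    repeats; the confusion counts are pooled totals over all evaluated folds.
    """

    fused: EvalReport
    submodels: list[EvalReport]
    folds: int
    repeats: int


def _mean_report(reports: list[EvalReport]) -> EvalReport:
    aucs = [r.auc for r in reports if r.auc is not None]
    return EvalReport(
        n_pos=sum(r.n_pos for r in reports),
        n_neg=sum(r.n_neg for r in reports),
        false_neg=sum(r.false_neg for r in reports),
        false_pos=sum(r.false_pos for r in reports),
        sn=float(np.mean([r.sn for r in reports])),
        sp=float(np.mean([r.sp for r in reports])),
        acc=float(np.mean([r.acc for r in reports])),
        mcc=float(np.mean([r.mcc for r in reports])),
        auc=float(np.mean(aucs)) if aucs else None,
    )


def evaluate_ensemble(
    model: EnsembleModel, samples: list[Sample]
) -> tuple[EvalReport, list[EvalReport]]:
    """Evaluate on labeled samples: fused report plus one report per sub-model."""
    labels = [s.label for s in samples]
    if any(lab is None for lab in labels):
        raise ValidationError("evaluation requires labeled samples")
    fused_scores, calls, sub_scores = predict(model, samples)
    fused_report = make_report(labels, calls, fused_scores)
    sub_reports = [
        make_report(labels, (sub_scores[:, j] > model.threshold).astype(int), sub_scores[:, j])
        for j in range(model.k)
    ]
    return fused_report, sub_reports


def cross_validate(
    samples: list[Sample],
    folds: int = 5,
    repeats: int = 1,
    config: SubModelConfig | None = None,
    seed: int = 0,
    encoding: str = "onehot",
    k: int = 11,
    fusion: str = "unanimous",
    score_fusion: str = "min",
    threshold: float = 0.5,
) -> CVResult:
    """Repeated stratified k-fold cross-validation of the full ensemble.

    Within each training fold the entire pipeline (negative partition,
    balanced subsets, sub-model training, fusion) is rebuilt from scratch;
    metrics are averaged over folds, then over repeats.  All randomness
    derives from ``seed``.
    """
    if folds < 2:
        raise ValidationError(f"folds must be >= 2, got {folds}")
    labels = np.array([s.label for s in samples])
    if any(lab is None for lab in labels):
        raise ValidationError("cross-validation requires labeled samples")
    counts = np.bincount(labels.astype(int), minlength=2)
    if counts.min() < folds:
        raise StratificationError(
            f"smallest class has {counts.min()} samples; cannot stratify into {folds} folds"
        )
    repeat_seeds = spawn_seeds(seed, 2 * repeats)
    fused_reports: list[EvalReport] = []
    sub_reports: list[list[EvalReport]] = [[] for _ in range(k)]
    for r in range(repeats):
        skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=repeat_seeds[r])
        fold_seeds = spawn_seeds(repeat_seeds[repeats + r], folds)
        for f, (train_idx, test_idx) in enumerate(skf.split(np.zeros(len(samples)), labels)):
            model = train_ensemble(
                [samples[i] for i in train_idx],
                encoding=encoding,
                k=k,
                config=config,
                seed=fold_seeds[f],
                fusion=fusion,
                score_fusion=score_fusion,
                threshold=threshold,
            )
            fused_rep, sub_rep = evaluate_ensemble(model, [samples[i] for i in test_idx])
            fused_reports.append(fused_rep)
            for j in range(k):
                sub_reports[j].append(sub_rep[j])
    return CVResult(
        fused=_mean_report(fused_reports),
        submodels=[_mean_report(reps) for reps in sub_reports],
        folds=folds,
        repeats=repeats,
    )


def save_model(model: EnsembleModel, path: str | Path) -> None:
    """Serialize an ensemble to a bundle directory (manifest + per-sub-model files)."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    manifest = {
        "format_version": BUNDLE_FORMAT_VERSION,
        "package_version": __version__,
        "encoding": model.encoding,
        "delta": model.delta,
        "k": model.k,
        "fusion": model.fusion,
        "score_fusion": model.score_fusion,
        "threshold": model.threshold,
        "seed": model.seed,
        "config": model.config.to_dict(),
    }
    (path / "manifest.json").write_text(json.dumps(manifest, indent=2))
    for i, sub in enumerate(model.submodels):
        joblib.dump(sub, path / f"submodel_{i:02d}.joblib")


def load_model(path: str | Path) -> EnsembleModel:
    """Load a bundle written by save_model; round-trip predictions are bit-identical."""
    path = Path(path)
    manifest_path = path / "manifest.json"
    if not manifest_path.exists():
        raise IncompatibleModelError(f"not a model bundle (no manifest.json): {path}")
    try:
        manifest = json.loads(manifest_path.read_text())
    except json.JSONDecodeError as exc:
        raise IncompatibleModelError(f"corrupt manifest in {path}: {exc}") from exc
    if manifest.get("format_version") != BUNDLE_FORMAT_VERSION:
        raise IncompatibleModelError(
            f"bundle format {manifest.get('format_version')!r} is not supported "
            f"(expected {BUNDLE_FORMAT_VERSION})"
        )
    submodels = []
    for i in range(manifest["k"]):
        sub_path = path / f"submodel_{i:02d}.joblib"
        try:
            submodels.append(joblib.load(sub_path))
        except Exception as exc:
            raise IncompatibleModelError(
                f"cannot load sub-model {i} from {sub_path}: {exc}"
            ) from exc
    return EnsembleModel(
        submodels=submodels,
        encoding=manifest["encoding"],
        delta=manifest["delta"],
        fusion=manifest["fusion"],
        score_fusion=manifest["score_fusion"],
        threshold=manifest["threshold"],
        config=SubModelConfig.from_dict(manifest["config"]),
        seed=manifest["seed"],
    )
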