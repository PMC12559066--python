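"""Training protocol, cross-validation splits, and evaluation metrics.

Loads are categorised into three exertion levels by the study's bins —
light 2.7-5.4 kg, medium 6.8-9.5 kg, heavy 10.9-13.6 kg — and models are
evaluated in two settings: binary (light vs heavy, medium instances
dropped from both training and testing) and three-way.

Training minimises softmax cross-entropy with AdamW under a linear-warmup
+ cosine-annealing schedule.  Each epoch, every training sequence is
mirrored horizontally with probability ``flip_prob`` and perturbed with
i.i.d. Gaussian feature noise of scale ``noise_sigma``.  At inference the
model is applied to both the original and the mirrored sequence and the
two probability vectors are averaged (test-time augmentation).

Two cross-validation protocols are provided: leave-one-subject-out
(inter-subject generalisation; one fold per subject) and a stratified
intra-subject split that holds out roughly 1/n_folds of every
(subject, load category, posture) cell.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from typing import Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.contingency_tables import mcnemar as _sm_mcnemar

from .kinematics import FLIP_SIGN, FeatureSequence, LiftInstance, flip_features
from .models import (
    SequenceBatch,
    TransformerConfig,
    build_model,
)
from .nn import AdamW, softmax_cross_entropy, warmup_cosine_lr

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# load categories


class LoadCategory(Enum):
    LIGHT = "light"
    MEDIUM = "medium"
    HEAVY = "heavy"


#: closed bins in kg; study loads fall on {2.7..5.4}, {6.8..9.5}, {10.9..13.6}
_BINS = {
    LoadCategory.LIGHT: (2.7, 5.4),
    LoadCategory.MEDIUM: (6.8, 9.5),
    LoadCategory.HEAVY: (10.9, 13.6),
}

_BIN_TOL = 1e-6


class LoadBinError(ValueError):
    """A load falls outside every category bin (no silent rounding)."""


def categorize_load(load_kg: float) -> LoadCategory:
    """Map a load in kg to its exertion category by the study bins."""
    if load_kg <= 0:
        raise LoadBinError(f"load must be positive, got {load_kg}")
    for cat, (lo, hi) in _BINS.items():
        if lo - _BIN_TOL <= load_kg <= hi + _BIN_TOL:
            return cat
    raise LoadBinError(
        f"load {load_kg} kg falls outside the category bins "
        f"{[(c.value, b) for c, b in _BINS.items()]}"
    )


def validate_instance_label(instance: LiftInstance) -> bool:
    """True when the attached label matches categorize_load(load_kg)."""
    return instance.label == categorize_load(instance.load_kg)


_LABEL_CODES = {
    2: {LoadCategory.LIGHT: 0, LoadCategory.HEAVY: 1},
    3: {LoadCategory.LIGHT: 0, LoadCategory.MEDIUM: 1, LoadCategory.HEAVY: 2},
}


def label_code(category: LoadCategory, num_classes: int) -> int:
    codes = _LABEL_CODES[num_classes]
    if category not in codes:
        raise ValueError(
            f"category {category.value!r} is not valid for the "
            f"{num_classes}-class setting"
        )
    return codes[category]


def setting_num_classes(setting: str) -> int:
    if setting == "binary":
        return 2
    if setting == "three_way":
        return 3
    raise ValueError(f"setting must be 'binary' or 'three_way', got {setting!r}")


def filter_for_setting(instances: Sequence[LiftInstance], setting: str) -> list[LiftInstance]:
    """Drop medium instances in the binary setting; pass-through otherwise."""
    if setting == "binary":
        return [i for i in instances if i.label != LoadCategory.MEDIUM]
    return list(instances)


# ---------------------------------------------------------------------------
# configs & report containers


@dataclass
class TrainConfig:
    epochs: int = 100
    warmup_epochs: int = 10
    lr: float = 1e-3
    weight_decay: float = 0.05
    batch_size: int = 32
    flip_prob: float = 0.5
    noise_sigma: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.warmup_epochs >= self.epochs:
            raise ValueError("warmup_epochs must be smaller than epochs")
        if self.lr <= 0:
            raise ValueError("lr must be positive")
        if not (0.0 <= self.flip_prob <= 1.0):
            raise ValueError("flip_prob must be in [0, 1]")


@dataclass
class EvalFragment:
    """Evaluation of one trained model on one test set."""

    accuracy: float
    confusion: np.ndarray  # rows = true, columns = predicted
    predictions: pd.DataFrame  # subject_id, task, posture, true, pred


@dataclass
class EvalReport:
    """Cross-validated results: per-fold accuracies plus breakdowns."""

    setting: str
    per_fold_accuracy: list[float]
    mean_accuracy: float
    sd_accuracy: float
    pooled_accuracy: float
    confusion: np.ndarray
    by_task: dict
    predictions: pd.DataFrame

    def to_dict(self) -> dict:
        return {
            "setting": self.setting,
            "per_fold_accuracy": self.per_fold_accuracy,
            "mean_accuracy": self.mean_accuracy,
            "sd_accuracy": self.sd_accuracy,
            "pooled_accuracy": self.pooled_accuracy,
            "confusion": self.confusion.tolist(),
            "by_task": self.by_task,
        }


# ---------------------------------------------------------------------------
# splits


def split_loso(instances: Sequence[LiftInstance]) -> list[tuple[list[LiftInstance], list[LiftInstance]]]:
    """Leave-one-subject-out folds, one per subject, in subject-id order."""
    subjects = sorted({i.subject_id for i in instances})
    if len(subjects) < 2:
        raise ValueError("leave-one-subject-out requires at least 2 subjects")
    folds = []
    for s in subjects:
        test = [i for i in instances if i.subject_id == s]
        train = [i for i in instances if i.subject_id != s]
        folds.append((train, test))
    return folds


def split_intra_subject(
    instances: Sequence[LiftInstance], n_folds: int = 3, seed: int = 0
) -> list[tuple[list[LiftInstance], list[LiftInstance]]]:
    """Stratified within-subject folds.

    Instances are grouped into (subject, load category, posture) cells and
    each cell's members are dealt round-robin to the folds' test sides, so
    every subject appears in both train and test of every fold and roughly
    1/n_folds of each cell is held out.  Cells with fewer members than
    folds contribute to training only (logged).
    """
    rng = np.random.default_rng(seed)
    cells: dict[tuple, list[int]] = {}
    for idx, inst in enumerate(instances):
        key = (inst.subject_id, categorize_load(inst.load_kg), inst.posture)
        cells.setdefault(key, []).append(idx)
    test_idx: list[set[int]] = [set() for _ in range(n_folds)]
    for key in sorted(cells, key=lambda k: (k[0], k[1].value, k[2])):
        members = np.array(cells[key])
        rng.shuffle(members)
        if len(members) < n_folds:
            logger.info("cell %s has %d < %d instances; train-only", key, len(members), n_folds)
            continue
        for f in range(n_folds):
            test_idx[f].update(members[f::n_folds].tolist())
    folds = []
    for f in range(n_folds):
        test = [instances[i] for i in sorted(test_idx[f])]
        train = [instances[i] for i in range(len(instances)) if i not in test_idx[f]]
        folds.append((train, test))
    return folds


# ---------------------------------------------------------------------------
# training


def _instance_codes(instances: Sequence[LiftInstance], num_classes: int) -> np.ndarray:
    return np.array([label_code(i.label, num_classes) for i in instances], dtype=int)


def train(
    train_set: Sequence[LiftInstance],
    model_config=None,
    train_config: TrainConfig | None = None,
    model_kind: str = "transformer",
    labels: Sequence[int] | None = None,
):
    """Train a classifier on labelled feature sequences.

    The number of classes is taken from ``model_config.num_classes``; in the
    2-class setting the train set must contain only light/heavy instances.
    ``labels`` overrides the instances' own labels (used by label-permutation
    control experiments).  Returns the final-epoch model with the per-epoch
    mean loss attached as ``model.loss_history``.
    """
    if len(train_set) == 0:
        raise ValueError("empty training set")
    if model_config is None:
        model_config = TransformerConfig()
    cfg = train_config or TrainConfig()
    num_classes = model_config.num_classes
    y = (np.asarray(labels, dtype=int) if labels is not None
         else _instance_codes(train_set, num_classes))
    if y.min() < 0 or y.max() >= num_classes:
        raise ValueError(f"labels outside [0, {num_classes})")

    rng = np.random.default_rng(cfg.seed)
    model = build_model(model_kind, model_config, seed=int(rng.integers(2**31 - 1)))
    opt = AdamW(model.parameters(), lr=cfg.lr, weight_decay=cfg.weight_decay)
    dtype = model_config.np_dtype
    feats = [i.features.values for i in train_set]
    lengths = np.array([f.shape[0] for f in feats])
    # per-channel standardisation fitted on the raw training frames
    stacked = np.concatenate(feats, axis=0)
    model.set_input_norm(stacked.mean(axis=0), np.maximum(stacked.std(axis=0), 1e-8))
    n = len(feats)
    history: list[float] = []
    for epoch in range(cfg.epochs):
        opt.lr = warmup_cosine_lr(epoch, cfg.lr, cfg.warmup_epochs, cfg.epochs)
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            T = int(lengths[idx].max())
            B = len(idx)
            x = np.zeros((B, T, feats[0].shape[1]), dtype=dtype)
            mask = np.zeros((B, T), dtype=bool)
            for row, j in enumerate(idx):
                fj = feats[j]
                if rng.random() < cfg.flip_prob:
                    fj = fj * FLIP_SIGN
                x[row, : fj.shape[0]] = fj
                mask[row, : fj.shape[0]] = True
            x = model.normalize_input(x, mask)
            # noise is added in standardised units so that "small" means
            # small relative to every channel's own scale
            if cfg.noise_sigma > 0:
                x += rng.normal(0.0, cfg.noise_sigma, x.shape).astype(dtype)
                x *= mask[..., None]
            logits = model.forward_logits(x, mask, train=True)
            loss, dlogits, _ = softmax_cross_entropy(logits, y[idx])
            opt.zero_grad()
            model.backward(dlogits)
            opt.step()
            losses.append(loss * B)
        history.append(float(np.sum(losses) / n))
    model.loss_history = history
    return model


# ---------------------------------------------------------------------------
# inference & evaluation


def predict_proba(model, sequences: Sequence[FeatureSequence], batch_size: int = 64) -> np.ndarray:
    """Plain (single-pass) class probabilities for a list of sequences."""
    out = np.empty((len(sequences), model.config.num_classes))
    order = np.argsort([len(s) for s in sequences], kind="stable")
    for start in range(0, len(order), batch_size):
        idx = order[start:start + batch_size]
        batch = SequenceBatch.from_sequences(
            [sequences[i] for i in idx], dtype=model.config.np_dtype
        )
        out[idx] = model.forward(batch).probs
    return out


def predict_tta(model, instance_or_features) -> np.ndarray:
    """Mirror-averaged prediction for a single instance.

    Returns the mean of the softmax outputs on the original sequence and on
    its horizontal mirror; the argmax is the predicted category.
    """
    f = (instance_or_features.features
         if isinstance(instance_or_features, LiftInstance) else instance_or_features)
    return predict_tta_batch(model, [f])[0]


def predict_tta_batch(model, sequences: Sequence[FeatureSequence], batch_size: int = 64) -> np.ndarray:
    p = predict_proba(model, sequences, batch_size)
    p_flip = predict_proba(model, [flip_features(s) for s in sequences], batch_size)
    return 0.5 * (p + p_flip)


def evaluate(model, test_set: Sequence[LiftInstance], setting: str) -> EvalFragment:
    """Mirror-averaged accuracy and confusion matrix on a test set."""
    if len(test_set) == 0:
        raise ValueError("empty test set")
    num_classes = setting_num_classes(setting)
    if model.config.num_classes != num_classes:
        raise ValueError(
            f"model has {model.config.num_classes} classes but setting "
            f"{setting!r} needs {num_classes}"
        )
    y = _instance_codes(test_set, num_classes)
    probs = predict_tta_batch(model, [i.features for i in test_set])
    pred = probs.argmax(axis=-1)
    confusion = np.zeros((num_classes, num_classes), dtype=int)
    np.add.at(confusion, (y, pred), 1)
    df = pd.DataFrame(
        {
            "subject_id": [i.subject_id for i in test_set],
            "task": [i.task for i in test_set],
            "posture": [i.posture for i in test_set],
            "load_kg": [i.load_kg for i in test_set],
            "true": y,
            "pred": pred,
        }
    )
    return EvalFragment(accuracy=float((pred == y).mean()), confusion=confusion, predictions=df)


# ---------------------------------------------------------------------------
# paired comparison


def mcnemar_test(
    preds_a: Sequence[int], preds_b: Sequence[int], labels: Sequence[int]
) -> tuple[float, float]:
    """McNemar's test on paired classifier predictions.

    ``b`` counts instances A got right and B got wrong, ``c`` the reverse.
    For b + c < 25 the exact two-sided binomial test is used, otherwise the
    chi-square approximation with continuity correction.  Returns
    (statistic, p-value); two identical prediction vectors give p = 1 by
    convention.
    """
    a = np.asarray(preds_a)
    bb = np.asarray(preds_b)
    y = np.asarray(labels)
    if not (len(a) == len(bb) == len(y)):
        raise ValueError("prediction and label vectors must have equal length")
    a_ok = a == y
    b_ok = bb == y
    b = int((a_ok & ~b_ok).sum())
    c = int((~a_ok & b_ok).sum())
    if b + c == 0:
        return 0.0, 1.0
    table = [[0, b], [c, 0]]
    res = _sm_mcnemar(table, exact=(b + c < 25), correction=True)
    return float(res.statistic), float(min(res.pvalue, 1.0))


# ---------------------------------------------------------------------------
# experiment orchestration


def run_synthetic_study(
    seed: int = 0,
    epochs_binary: int = 14,
    epochs_three_way: int = 10,
    epochs_null: int = 2,
    sim_config=None,
) -> dict:
    """The end-to-end parameter-recovery experiment on simulated data.

    Generates the full factorial study (19 subjects x 3 postures x 9 loads
    x lift/lower by default), extracts features, and runs leave-one-subject-
    out cross-validation with the compact Transformer in three conditions:
    binary light-vs-heavy, three-way, and a shuffled-label null (binary
    labels permuted before training, so accuracy should sit at chance).
    Returns the two EvalReports plus the null accuracy and study sizes.
    """
    from .synthetic import SimConfig, dataset_to_instances, generate_dataset

    sim = sim_config or SimConfig(seed=seed)
    records = generate_dataset(sim)
    instances = dataset_to_instances(records)

    binary_report = run_experiment(
        instances,
        ProtocolConfig(
            setting="binary",
            model_config=compact_transformer_config(2),
            train_config=TrainConfig(epochs=epochs_binary, warmup_epochs=3,
                                     lr=3e-3, seed=seed % 2**20),
        ),
    )
    three_way_report = run_experiment(
        instances,
        ProtocolConfig(
            setting="three_way",
            model_config=compact_transformer_config(3),
            train_config=TrainConfig(epochs=epochs_three_way, warmup_epochs=2,
                                     lr=3e-3, seed=seed % 2**20 + 100),
        ),
    )

    # shuffled-label null: permute the binary training labels per fold
    binary_instances = filter_for_setting(instances, "binary")
    null_rng = np.random.default_rng(seed % 2**20 + 200)
    null_acc = []
    n_null = 0
    for k, (train_set, test_set) in enumerate(split_loso(binary_instances)):
        perm = null_rng.permutation(_instance_codes(train_set, 2))
        model = train(
            train_set,
            compact_transformer_config(2),
            TrainConfig(epochs=epochs_null, warmup_epochs=1, lr=3e-3,
                        seed=seed % 2**20 + 300 + k),
            labels=perm,
        )
        frag = evaluate(model, test_set, "binary")
        null_acc.append(frag.accuracy * len(test_set))
        n_null += len(test_set)
    return {
        "binary": binary_report,
        "three_way": three_way_report,
        "null_accuracy": float(np.sum(null_acc) / n_null),
        "n_instances": len(instances),
        "n_binary": len(binary_instances),
        "n_subjects": len({i.subject_id for i in instances}),
    }


def compact_transformer_config(num_classes: int, max_len: int = 160) -> "TransformerConfig":
    """Reduced-size Transformer for CPU-scale cross-validated experiments.

    Keeps the architecture family (two pre-norm blocks, multi-head
    attention, conv projection, learned positions) at a width that trains
    in minutes on one core: embed_dim 32, 2 heads, ReLU block MLPs,
    float32, no stochastic depth.
    """
    return TransformerConfig(
        embed_dim=32,
        depth=2,
        heads=2,
        dropout_path=0.0,
        activation="relu",
        max_len=max_len,
        num_classes=num_classes,
        dtype="float32",
    )


@dataclass
class ProtocolConfig:
    """Everything needed to run one cross-validated experiment."""

    setting: str = "binary"
    split: str = "loso"  # or "intra"
    n_folds: int = 3  # intra-subject only
    split_seed: int = 0
    model_kind: str = "transformer"
    model_config: object | None = None
    train_config: TrainConfig = field(default_factory=TrainConfig)


def _accuracy_breakdown(df: pd.DataFrame) -> dict:
    out: dict = {}
    for task, tdf in df.groupby("task"):
        entry = {"all": float((tdf["true"] == tdf["pred"]).mean())}
        for posture, pdf in tdf.groupby("posture"):
            entry[posture] = float((pdf["true"] == pdf["pred"]).mean())
        out[task] = entry
    return out


def run_experiment(dataset: Sequence[LiftInstance], protocol: ProtocolConfig) -> EvalReport:
    """Split -> train per fold -> evaluate; aggregate into an EvalReport.

    Accuracy is computed per fold and summarised as mean +/- sd across folds
    (sd with one delta dof); the instance-pooled accuracy is also reported
    since fold sizes vary.  Per-instance predictions are kept for paired
    tests between methods.
    """
    instances = filter_for_setting(dataset, protocol.setting)
    num_classes = setting_num_classes(protocol.setting)
    if protocol.model_config is None:
        model_config = TransformerConfig(num_classes=num_classes)
    else:
        model_config = protocol.model_config
        if model_config.num_classes != num_classes:
            raise ValueError("model_config.num_classes inconsistent with setting")
    if protocol.split == "loso":
        folds = split_loso(instances)
    elif protocol.split == "intra":
        folds = split_intra_subject(instances, protocol.n_folds, protocol.split_seed)
    else:
        raise ValueError(f"unknown split {protocol.split!r}")

    per_fold = []
    frames = []
    confusion = np.zeros((num_classes, num_classes), dtype=int)
    for k, (train_set, test_set) in enumerate(folds):
        fold_train_cfg = TrainConfig(**{**protocol.train_config.__dict__,
                                        "seed": protocol.train_config.seed + k})
        model = train(train_set, model_config, fold_train_cfg, protocol.model_kind)
        frag = evaluate(model, test_set, protocol.setting)
        per_fold.append(frag.accuracy)
        confusion += frag.confusion
        df = frag.predictions.copy()
        df.insert(0, "fold", k)
        frames.append(df)
    preds = pd.concat(frames, ignore_index=True)
    return EvalReport(
        setting=protocol.setting,
        per_fold_accuracy=per_fold,
        mean_accuracy=float(np.mean(per_fold)),
        sd_accuracy=float(np.std(per_fold, ddof=1)) if len(per_fold) > 1 else 0.0,
        pooled_accuracy=float((preds["true"] == preds["pred"]).mean()),
        confusion=confusion,
        by_task=_accuracy_breakdown(preds),
        predictions=preds,
    )
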