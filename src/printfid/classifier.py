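"""Binary CNN print-quality classifier.

Printed-mesh images (preprocessed to 128 x 128 binary, single channel) are
labelled High (1) or Low (0) fidelity according to their aggregate
similarity SA to the CAD target, and a convolutional network is trained to
reproduce that label from the image alone. The network is four
convolution blocks (3x3 kernels, channel depths 32/64/128/256, each with
batch normalization and 2x2 max pooling), a flatten, one 256-unit ReLU
dense layer with L2 penalty, dropout 0.5, and a single sigmoid output.

Training follows an incremental protocol: a stratified 80/20
train/validation split, then training on growing subsets (250, 350, ...)
of the training pool until it is exhausted, with early stopping on
validation loss at each stage. Class imbalance is handled by class
weights plus symmetry-preserving augmentation (flips and 90-degree
rotations) of the minority class. A single seed drives the split,
initialization, augmentation and shuffling, so runs are reproducible.

The trained model, applied to a candidate image set joined to the
factorial experiment matrix, recovers the printing parameters of the best
print: among images predicted High, the one with maximal SA (ties broken
by manual similarity, then lowest run_id).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import nn
from .fidelity import PrintImage, preprocess

__all__ = [
    "LabeledImage",
    "TrainingConfig",
    "ClassifierMetrics",
    "build_classifier",
    "images_to_array",
    "make_labeled_dataset",
    "train_incremental",
    "evaluate",
    "select_best_print",
]

INPUT_SHAPE = (128, 128, 1)


@dataclass(frozen=True)
class LabeledImage:
    """One classifier example: a 128x128 image, its label and provenance."""

    image: PrintImage
    label: int
    sa_score: float
    run_id: int
    manual_score: float | None = None

    def __post_init__(self) -> None:
        if self.image.shape != INPUT_SHAPE[:2]:
            raise ValueError(
                f"classifier input must be {INPUT_SHAPE[:2]}, got {self.image.shape}"
            )
        if self.label not in (0, 1):
            raise ValueError("label must be 0 (Low) or 1 (High)")


@dataclass(frozen=True)
class TrainingConfig:
    """All knobs of the incremental training protocol.

    ``width`` scales the channel depths (width, 2w, 4w, 8w); the default 32
    gives the reference 32/64/128/256 architecture. Smaller widths are
    useful for quick studies. ``label_threshold`` is the SA percentage
    separating High from Low and is recorded in run metadata.
    """

    split_fraction: float = 0.8
    initial_dataset: int = 250
    batch_increment: int = 100
    max_epochs: int = 100
    early_stopping_patience: int = 10
    batch_size: int = 32
    learning_rate: float = 1e-3
    l2: float = 1e-4
    dropout: float = 0.5
    class_weighting: bool = True
    augmentation: bool = True
    label_threshold: float = 70.0
    width: int = 32
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.split_fraction < 1.0:
            raise ValueError("split_fraction must lie in (0, 1)")
        if self.batch_increment <= 0 or self.initial_dataset <= 0:
            raise ValueError("initial_dataset and batch_increment must be positive")

    def metadata(self) -> dict:
        return {f: getattr(self, f) for f in self.__dataclass_fields__}


@dataclass(frozen=True)
class ClassifierMetrics:
    """Threshold metrics at 0.5 plus ranking metrics.

    ``auc_roc`` is the overall ROC area (identical for either class in a
    binary one-vs-rest reading); ``auc_pr`` the overall average precision
    for the High class; ``per_class_auc_pr`` the (Low, High) pair of
    average precisions, which do differ between classes.
    """

    recall: float
    f1: float
    accuracy: float
    auc_roc: float
    auc_pr: float
    per_class_auc_pr: tuple[float, float]

    def as_dict(self) -> dict:
        d = {
            "recall": self.recall,
            "f1": self.f1,
            "accuracy": self.accuracy,
            "auc_roc": self.auc_roc,
            "auc_pr": self.auc_pr,
        }
        d["auc_pr_low"], d["auc_pr_high"] = self.per_class_auc_pr
        return d


def build_classifier(seed: int = 0, width: int = 32, l2: float = 1e-4, dropout: float = 0.5) -> nn.Sequential:
    """The four-block CNN; same seed, same initial weights."""
    rng = np.random.default_rng(seed)
    side = INPUT_SHAPE[0]
    layers: list[nn.Layer] = []
    cin = 1
    for depth in (width, 2 * width, 4 * width, 8 * width):
        layers += [
            nn.Conv3x3(cin, depth, rng),
            nn.BatchNorm(depth),
            nn.ReLU(),
            nn.MaxPool2(),
        ]
        cin = depth
        side //= 2
    layers += [
        nn.Flatten(),
        nn.Dense(side * side * cin, 256, rng, l2=l2),
        nn.ReLU(),
        nn.Dropout(dropout, rng),
        nn.Dense(256, 1, rng),
    ]
    return nn.Sequential(layers)


def images_to_array(images) -> np.ndarray:
    """Stack PrintImages (or 2-D arrays) into a float32 (N, 128, 128, 1) tensor."""
    arrs = []
    for im in images:
        px = im.pixels if isinstance(im, PrintImage) else np.asarray(im, float)
        if px.shape != INPUT_SHAPE[:2]:
            raise ValueError(f"expected {INPUT_SHAPE[:2]} images, got {px.shape}")
        arrs.append(px.astype(np.float32))
    return np.stack(arrs)[..., None]


def make_labeled_dataset(
    images: list[PrintImage],
    manifest: pd.DataFrame,
    target_size: tuple[int, int] = INPUT_SHAPE[:2],
) -> list[LabeledImage]:
    """Preprocess raw renders and join them to their manifest rows."""
    if len(images) != len(manifest):
        raise ValueError("images and manifest must have the same length")
    out = []
    for img, (_, row) in zip(images, manifest.iterrows()):
        prep = preprocess(img, target_size=target_size)
        out.append(
            LabeledImage(
                image=prep,
                label=int(row["label"]),
                sa_score=float(row["sa_pct"]),
                run_id=int(row["run_id"]),
                manual_score=(
                    float(row["manual_similarity_pct"])
                    if "manual_similarity_pct" in row
                    else None
                ),
            )
        )
    return out


_AUGMENTS = (
    lambda a: a[:, ::-1],  # horizontal flip
    lambda a: a[::-1, :],  # vertical flip
    lambda a: np.rot90(a, 1),
    lambda a: np.rot90(a, 2),
    lambda a: np.rot90(a, 3),
)


def _augment_minority(
    X: np.ndarray, y: np.ndarray, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Append flip/rotation copies of the minority class toward balance."""
    n1 = int(y.sum())
    n0 = len(y) - n1
    if n0 == n1:
        return X, y
    minority = 1 if n1 < n0 else 0
    idx = np.flatnonzero(y == minority)
    deficit = abs(n0 - n1)
    extra_X, extra_y = [], []
    k = 0
    while len(extra_X) < deficit and k < 5 * len(idx):
        i = idx[k % len(idx)]
        aug = _AUGMENTS[k % len(_AUGMENTS)]
        extra_X.append(np.ascontiguousarray(aug(X[i, :, :, 0]))[..., None])
        extra_y.append(minority)
        k += 1
    if not extra_X:
        return X, y
    Xa = np.concatenate([X, np.stack(extra_X)]).astype(np.float32)
    ya = np.concatenate([y, np.array(extra_y, dtype=y.dtype)])
    return Xa, ya


def _class_weights(y: np.ndarray) -> dict[int, float]:
    n = len(y)
    n1 = int(y.sum())
    n0 = n - n1
    return {0: n / (2.0 * max(n0, 1)), 1: n / (2.0 * max(n1, 1))}


def _train_stage(
    model: nn.Sequential,
    X: np.ndarray,
    y: np.ndarray,
    Xval: np.ndarray,
    yval: np.ndarray,
    config: TrainingConfig,
    rng: np.random.Generator,
) -> dict:
    from sklearn.metrics import recall_score

    opt = nn.Adam(model.params, lr=config.learning_rate)
    weights = _class_weights(y) if config.class_weighting else {0: 1.0, 1: 1.0}
    sw = np.where(y == 1, weights[1], weights[0])
    best_loss = np.inf
    best_weights = model.get_weights()
    patience_left = config.early_stopping_patience
    history = {"train_loss": [], "val_loss": [], "val_recall": []}
    for _epoch in range(config.max_epochs):
        order = rng.permutation(len(X))
        epoch_loss = 0.0
        for i in range(0, len(order), config.batch_size):
            sel = order[i : i + config.batch_size]
            logits = model.forward(X[sel], train=True)
            loss, dlogits = nn.bce_with_logits(logits, y[sel], sw[sel])
            model.backward(dlogits)
            opt.step(model.grads)
            epoch_loss += (loss + model.l2_loss()) * len(sel)
        history["train_loss"].append(epoch_loss / len(order))
        pval = model.predict_proba(Xval)
        val_loss, _ = nn.bce_with_logits(
            np.log(pval / (1 - pval + 1e-12) + 1e-12), yval
        )
        history["val_loss"].append(val_loss)
        history["val_recall"].append(
            float(recall_score(yval, (pval >= 0.5).astype(int), zero_division=0))
        )
        if val_loss < best_loss - 1e-6:
            best_loss = val_loss
            best_weights = model.get_weights()
            patience_left = config.early_stopping_patience
        else:
            patience_left -= 1
            if patience_left <= 0:
                break
    model.set_weights(best_weights)
    history["best_val_loss"] = best_loss
    return history


def train_incremental(
    dataset: list[LabeledImage], config: TrainingConfig | None = None
) -> tuple[nn.Sequential, dict]:
    """Train the CNN with the incremental protocol; returns (model, history).

    The dataset must contain both labels and at least
    ``config.initial_dataset`` examples. History holds, per stage, the
    subset size and the per-epoch train/validation losses and validation
    recall; the final entry's model state is the returned model.
    """
    from sklearn.model_selection import train_test_split

    config = config or TrainingConfig()
    if len(dataset) < config.initial_dataset:
        raise ValueError(
            f"dataset ({len(dataset)}) smaller than initial_dataset "
            f"({config.initial_dataset})"
        )
    y_all = np.array([d.label for d in dataset], dtype=np.float32)
    if len(np.unique(y_all)) < 2:
        raise ValueError("dataset contains a single class; both labels are required")
    X_all = images_to_array([d.image for d in dataset])

    idx_train, idx_val = train_test_split(
        np.arange(len(dataset)),
        train_size=config.split_fraction,
        stratify=y_all,
        random_state=config.seed % (2**32),
    )
    rng = np.random.default_rng(config.seed)
    idx_train = rng.permutation(idx_train)
    Xval, yval = X_all[idx_val], y_all[idx_val]

    sizes = list(range(config.initial_dataset, len(idx_train), config.batch_increment))
    if not sizes or sizes[-1] != len(idx_train):
        sizes.append(len(idx_train))
    sizes = [min(s, len(idx_train)) for s in sizes]

    model = build_classifier(
        seed=config.seed, width=config.width, l2=config.l2, dropout=config.dropout
    )
    stages = []
    for size in sizes:
        sub = idx_train[:size]
        X, y = X_all[sub], y_all[sub]
        if len(np.unique(y)) < 2:
            raise ValueError(f"stage subset of size {size} contains a single class")
        if config.augmentation:
            X, y = _augment_minority(X, y, rng)
        hist = _train_stage(model, X, y, Xval, yval, config, rng)
        hist["subset_size"] = size
        stages.append(hist)
    history = {
        "stages": stages,
        "config": config.metadata(),
        "n_train": len(idx_train),
        "n_val": len(idx_val),
        "val_indices": [int(i) for i in idx_val],
        "final_val_loss": stages[-1]["best_val_loss"],
        "final_val_recall": stages[-1]["val_recall"][
            int(np.argmin(stages[-1]["val_loss"]))
        ],
        "n_parameters": model.n_parameters(),
    }
    return model, history


def evaluate(
    model: nn.Sequential,
    dataset: list[LabeledImage] | tuple[np.ndarray, np.ndarray],
    threshold: float = 0.5,
) -> ClassifierMetrics:
    """Threshold and ranking metrics on a held-out set with both labels."""
    from sklearn.metrics import (
        accuracy_score,
        average_precision_score,
        f1_score,
        recall_score,
        roc_auc_score,
    )

    if isinstance(dataset, tuple):
        X, y = dataset
    else:
        X = images_to_array([d.image for d in dataset])
        y = np.array([d.label for d in dataset], dtype=float)
    if len(y) == 0:
        raise ValueError("empty test set")
    if len(np.unique(y)) < 2:
        raise ValueError("AUC undefined: test set contains a single class")
    p = model.predict_proba(X)
    yhat = (p >= threshold).astype(int)
    return ClassifierMetrics(
        recall=float(recall_score(y, yhat, zero_division=0)),
        f1=float(f1_score(y, yhat, zero_division=0)),
        accuracy=float(accuracy_score(y, yhat)),
        auc_roc=float(roc_auc_score(y, p)),
        auc_pr=float(average_precision_score(y, p)),
        per_class_auc_pr=(
            float(average_precision_score(1 - y, 1 - p)),
            float(average_precision_score(y, p)),
        ),
    )


def save_model(model: nn.Sequential, path, metadata: dict | None = None) -> None:
    """Serialize weights (npz) plus a JSON metadata sidecar (<path>.json)."""
    import json
    from pathlib import Path

    arrays = {f"param_{i}": p for i, p in enumerate(model.params)}
    # batch-norm running statistics are state, not parameters
    stats = {}
    for i, layer in enumerate(model.layers):
        if isinstance(layer, nn.BatchNorm):
            stats[f"bn_{i}_mean"] = layer.running_mean
            stats[f"bn_{i}_var"] = layer.running_var
    np.savez(path, **arrays, **stats)
    meta = dict(metadata or {})
    meta.setdefault("n_parameters", model.n_parameters())
    Path(str(path) + ".json").write_text(json.dumps(meta, indent=2, default=str))


def load_model(path) -> tuple[nn.Sequential, dict]:
    """Rebuild a saved classifier; architecture settings come from the sidecar."""
    import json
    from pathlib import Path

    meta = json.loads(Path(str(path) + ".json").read_text())
    model = build_classifier(
        seed=int(meta.get("seed", 0)),
        width=int(meta.get("width", 32)),
        l2=float(meta.get("l2", 1e-4)),
        dropout=float(meta.get("dropout", 0.5)),
    )
    data = np.load(path)
    model.set_weights([data[f"param_{i}"] for i in range(len(model.params))])
    for i, layer in enumerate(model.layers):
        if isinstance(layer, nn.BatchNorm):
            layer.running_mean = data[f"bn_{i}_mean"]
            layer.running_var = data[f"bn_{i}_var"]
    return model, meta


def select_best_print(
    model: nn.Sequential,
    dataset: list[LabeledImage],
    matrix: pd.DataFrame,
    threshold: float = 0.5,
) -> dict | None:
    """Identify the best print and its parameters from the experiment matrix.

    Among images the model predicts High, the one with maximal SA wins;
    ties break by manual similarity when present in the matrix join, then
    by lowest run_id. Returns ``None`` (with a warning) when nothing is
    predicted High. Every run_id must exist in the matrix.
    """
    if "run_id" not in matrix.columns:
        raise KeyError("experiment matrix must have a run_id column")
    known = set(matrix["run_id"].astype(int))
    orphans = sorted({d.run_id for d in dataset} - known)
    if orphans:
        raise KeyError(f"run_ids missing from experiment matrix: {orphans[:10]}")
    X = images_to_array([d.image for d in dataset])
    p = model.predict_proba(X)
    high = [i for i, pi in enumerate(p) if pi >= threshold]
    if not high:
        warnings.warn("no image predicted High; no best print to select", UserWarning)
        return None
    # max SA, ties by manual similarity (when known), then run_id ascending
    high.sort(
        key=lambda i: (
            -dataset[i].sa_score,
            -(dataset[i].manual_score if dataset[i].manual_score is not None else -np.inf),
            dataset[i].run_id,
        )
    )
    best = dataset[high[0]]
    row = matrix.loc[matrix["run_id"] == best.run_id].iloc[0]
    params = {
        "nozzle_G": int(row["nozzle_G"]),
        "pressure_kPa": float(row["pressure_kPa"]),
        "velocity_mm_s": float(row["velocity_mm_s"]),
        "temperature_C": float(row["temperature_C"]) if "temperature_C" in row else 32.0,
    }
    return {
        "image_index": int(high[0]),
        "source_id": best.image.source_id,
        "run_id": int(best.run_id),
        "sa_pct": float(best.sa_score),
        "probability": float(p[high[0]]),
        "parameters": params,
    }
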