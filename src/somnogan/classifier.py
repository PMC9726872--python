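"""CNN sleep stager and its training / repeated-evaluation protocol.

Four 3×3 convolution blocks (ReLU + 2×2 max pooling between them), three
fully connected layers ending in a 5-way softmax over the AASM stages,
dropout 0.5 on the hidden FC layers, Adam with a small initial learning
rate (5e-5) under step decay, cross-entropy loss, a stratified 7:3
train/test split, and the across-run mean/SD evaluation over repeated
training runs.

Splitting defaults to ``augment-train-only``: GAN-generated images are
allowed in the training arm only, so test metrics are always computed on
real images.  The ``mixed`` mode splits the mixed dataset as a
whole instead.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from . import nn
from .containers import REAL, STAGES, ImageSet
from .evaluation import EvalReport, classification_metrics, confusion_matrix

logger = logging.getLogger(__name__)

__all__ = [
    "ClassifierConfig", "SleepStager", "split_dataset", "train_classifier",
    "evaluate_classifier", "repeated_evaluation", "summarize_runs",
    "save_stager", "load_stager",
]


@dataclass(frozen=True)
class ClassifierConfig:
    """CNN architecture and training protocol.

    ``input_size`` must be divisible by 16 (four pooling halvings);
    ``lr_decay``/``lr_step_epochs`` implement the step-decay schedule.
    """

    conv_channels: tuple[int, ...] = (32, 64, 128, 256)
    fc_widths: tuple[int, ...] = (512, 128)
    n_classes: int = 5
    dropout: float = 0.5
    lr: float = 0.00005
    lr_decay: float = 0.5
    lr_step_epochs: int = 10
    epochs: int = 30
    batch_size: int = 32
    seed: int = 0
    split_ratio: float = 0.7
    input_size: int = 96
    dtype: str = "float32"

    def __post_init__(self) -> None:
        if not 0 <= self.dropout < 1:
            raise ValueError("dropout must be in [0, 1)")
        if not 0 < self.split_ratio < 1:
            raise ValueError("split ratio must be in (0, 1)")
        if self.input_size % (2 ** len(self.conv_channels)):
            raise ValueError("input size must be divisible by the total "
                             "pooling factor")


class SleepStager:
    """Wraps the CNN with its class list and prediction helpers."""

    def __init__(self, config: ClassifierConfig, classes: list[str],
                 rng: np.random.Generator) -> None:
        if len(classes) != config.n_classes:
            raise ValueError("class list length must equal n_classes")
        self.config = config
        self.classes = list(classes)
        layers: list[nn.Layer] = []
        c_in = 3
        for c in config.conv_channels:
            layers += [nn.Conv2D(c_in, c, 3, rng), nn.ReLU(), nn.MaxPool2D(2)]
            c_in = c
        spatial = config.input_size // (2 ** len(config.conv_channels))
        layers.append(nn.Flatten())
        width = spatial * spatial * c_in
        for w in config.fc_widths:
            layers += [nn.Dense(width, w, rng), nn.ReLU(),
                       nn.Dropout(config.dropout)]
            width = w
        layers.append(nn.Dense(width, config.n_classes, rng))
        self.net = nn.Sequential(*layers)
        self.net.set_rng(rng)

    def logits(self, pixels: np.ndarray, train: bool = False) -> np.ndarray:
        return self.net.forward(np.asarray(pixels), train=train)

    def predict(self, images: ImageSet, batch_size: int = 128) -> np.ndarray:
        out = []
        for i in range(0, len(images), batch_size):
            lg = self.logits(images.pixels[i:i + batch_size])
            out.append(np.argmax(lg, axis=1))
        idx = np.concatenate(out) if out else np.empty(0, dtype=int)
        return np.array([self.classes[i] for i in idx], dtype=object)


def save_stager(model: SleepStager, path) -> None:
    """Single-file checkpoint: parameters + batch-norm state + config."""
    import json
    from dataclasses import asdict

    meta = {"config": asdict(model.config), "classes": model.classes}
    arrays = {f"a{i}": a for i, a in enumerate(nn.get_state(model.net))}
    np.savez_compressed(path, meta=json.dumps(meta), **arrays)


def load_stager(path) -> SleepStager:
    import json

    with np.load(path, allow_pickle=False) as data:
        meta = json.loads(str(data["meta"]))
        config = ClassifierConfig(**meta["config"])
        with nn.default_dtype(config.dtype):
            model = SleepStager(config, meta["classes"],
                                np.random.default_rng(config.seed))
        arrays = [data[f"a{i}"] for i in range(len(data.files) - 1)]
        nn.set_state(model.net, arrays)
    return model


def split_dataset(images: ImageSet, ratio: float = 0.7, seed: int = 0,
                  mode: str = "augment-train-only",
                  ) -> tuple[ImageSet, ImageSet]:
    """Stratified train/test split.

    ``augment-train-only``: only real images are eligible for the test set;
    all generated images join the training arm.  ``mixed``: the
    mixed dataset is split as a whole, so generated images may land in the
    test set.  Classes with fewer than two members stay whole in train.
    """
    if len(images) == 0:
        raise ValueError("cannot split an empty dataset")
    if mode not in ("augment-train-only", "mixed"):
        raise ValueError(f"unknown split mode {mode!r}")
    rng = np.random.default_rng(seed)
    if mode == "augment-train-only":
        splittable = images.provenance == REAL
    else:
        splittable = np.ones(len(images), dtype=bool)
    train_mask = np.zeros(len(images), dtype=bool)
    train_mask[~splittable] = True  # generated images always train
    for stage in sorted(set(images.stages)):
        idx = np.where(splittable & (images.stages == stage))[0]
        if len(idx) < 2:
            if len(idx):
                logger.warning("class %s has < 2 splittable members; "
                               "kept whole in train", stage)
            train_mask[idx] = True
            continue
        perm = rng.permutation(idx)
        n_train = min(len(idx) - 1, max(1, int(round(ratio * len(idx)))))
        train_mask[perm[:n_train]] = True
    return images.subset(train_mask), images.subset(~train_mask)


def train_classifier(train: ImageSet, config: ClassifierConfig,
                     classes: list[str] | None = None,
                     ) -> tuple[SleepStager, dict[str, list[float]]]:
    """Train the CNN stager; returns the model and per-epoch history.

    Reproducible from ``config.seed``; requires at least two classes.
    """
    if len(train) == 0:
        raise ValueError("empty training set")
    present = set(train.stages)
    if len(present) < 2:
        raise ValueError("training set must contain at least two classes")
    if classes is None:
        classes = [s for s in STAGES if s in present] if present <= set(STAGES) \
            else sorted(present)
        if len(classes) != config.n_classes:
            config = replace(config, n_classes=len(classes))
    rng = np.random.default_rng(config.seed)
    with nn.default_dtype(config.dtype):
        model = SleepStager(config, classes, rng)
    class_idx = {c: i for i, c in enumerate(classes)}
    y = np.array([class_idx[s] for s in train.stages])
    x = np.asarray(train.pixels, dtype=config.dtype)
    opt = nn.Adam(model.net.params(), config.lr)
    history: dict[str, list[float]] = {"loss": [], "accuracy": [], "lr": []}
    for epoch in range(config.epochs):
        opt.lr = config.lr * config.lr_decay ** (epoch // config.lr_step_epochs)
        perm = rng.permutation(len(x))
        losses, correct = [], 0
        for i in range(0, len(x), config.batch_size):
            bidx = perm[i:i + config.batch_size]
            logits = model.logits(x[bidx], train=True)
            loss, dlogits = nn.softmax_cross_entropy(logits, y[bidx])
            model.net.zero_grad()
            model.net.backward(dlogits)
            opt.step()
            losses.append(loss)
            correct += int((np.argmax(logits, axis=1) == y[bidx]).sum())
        history["loss"].append(float(np.mean(losses)))
        history["accuracy"].append(correct / len(x))
        history["lr"].append(opt.lr)
    return model, history


def evaluate_classifier(model: SleepStager, test: ImageSet) -> EvalReport:
    if len(test) == 0:
        raise ValueError("empty test set")
    pred = model.predict(test)
    counts = confusion_matrix(list(test.stages), list(pred), model.classes)
    return classification_metrics(counts)


def summarize_runs(accuracies: list[float]) -> tuple[float, float]:
    """Across-run mean and population standard deviation."""
    a = np.asarray(accuracies, dtype=float)
    return float(a.mean()), float(a.std(ddof=0))


def repeated_evaluation(dataset: ImageSet, config: ClassifierConfig,
                        n_runs: int = 6, seed: int = 0,
                        mode: str = "augment-train-only") -> dict:
    """Split/train/evaluate ``n_runs`` times, varying only the seed.

    Returns per-run reports, per-class mean recall (the per-stage staging
    accuracy), and the mean ± population SD of overall accuracy.
    """
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    run_seeds = (np.random.SeedSequence(seed).generate_state(n_runs)
                 % (2 ** 31)).tolist()
    reports: list[EvalReport] = []
    for rs in run_seeds:
        train, test = split_dataset(dataset, config.split_ratio, seed=rs,
                                    mode=mode)
        model, _ = train_classifier(train, replace(config, seed=int(rs)))
        reports.append(evaluate_classifier(model, test))
    accs = [r.accuracy for r in reports]
    mean_acc, sd_acc = summarize_runs(accs)
    classes = reports[0].confusion.classes
    per_class = {c: float(np.nanmean([r.per_class[c]["recall"]
                                      for r in reports])) for c in classes}
    return {"reports": reports, "accuracies": accs,
            "mean_accuracy": mean_acc, "sd_accuracy": sd_acc,
            "per_class_recall": per_class, "seeds": run_seeds}
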