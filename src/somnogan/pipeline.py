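"""Before/after augmentation experiment orchestration.

Given a labelled image dataset with imbalanced stage counts, the pipeline
trains one GAN per under-represented stage, generates enough images to
equalise every class to the majority count, and then trains and evaluates
the CNN stager on the original versus the balanced dataset under identical
seeds and split protocol, reporting per-stage staging accuracy (recall),
overall accuracy mean ± SD across repeated runs, both aggregated confusion
matrices, per-stage Fréchet distances of generated versus real images, and
the before→after deltas.  A single master seed fans out deterministically
to every stochastic component.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .classifier import ClassifierConfig, repeated_evaluation
from .containers import GENERATED, REAL, STAGES, ImageSet
from .evaluation import RandomConvFeatures, frechet_from_images
from .rdb_dcgan import GANBundle, GANTrainConfig, sample_images, train_gan

__all__ = [
    "ExperimentConfig", "ConfigurationError", "imbalance_report",
    "balance_dataset", "run_experiment", "report_to_json", "save_report",
]


class ConfigurationError(ValueError):
    pass


@dataclass
class ExperimentConfig:
    """Everything one before/after experiment needs.

    ``balance_target`` defaults to the maximum class count ("same number of
    samples of each type"); a smaller cap supports desk-scale runs.
    """

    gan: GANTrainConfig = field(default_factory=GANTrainConfig)
    classifier: ClassifierConfig = field(default_factory=ClassifierConfig)
    n_runs: int = 6
    master_seed: int = 0
    split_mode: str = "augment-train-only"
    balance: bool = True
    balance_target: int | None = None
    fid_samples: int = 64


def imbalance_report(dataset: "ImageSet | dict[str, int]") -> dict:
    """Per-class counts and integer percentages (``round(100·count/total)``)."""
    counts = dict(dataset) if isinstance(dataset, dict) else dataset.counts()
    total = sum(counts.values())
    if total == 0:
        raise ValueError("empty dataset")
    order = [s for s in STAGES if s in counts] + \
        sorted(k for k in counts if k not in STAGES)
    return {"counts": {s: int(counts[s]) for s in order},
            "percent": {s: int(round(100.0 * counts[s] / total))
                        for s in order},
            "total": int(total)}


def balance_dataset(dataset: ImageSet, gan_bundles: dict[str, GANBundle],
                    seed: int = 0, target: int | None = None) -> ImageSet:
    """Top every class up to ``target`` (default: the majority count) with
    GAN samples; originals are kept untouched, additions carry provenance
    ``"generated"``."""
    counts = dataset.counts()
    if not counts:
        raise ValueError("empty dataset")
    target = max(counts.values()) if target is None else target
    pieces = [dataset]
    sub_seeds = np.random.SeedSequence(seed).generate_state(len(counts)) \
        % (2 ** 31)
    for i, stage in enumerate(sorted(counts)):
        deficit = target - counts[stage]
        if deficit <= 0:
            continue
        if stage not in gan_bundles:
            raise ConfigurationError(
                f"class {stage!r} needs {deficit} generated images but has "
                f"no GAN bundle")
        pieces.append(sample_images(gan_bundles[stage], deficit,
                                    seed=int(sub_seeds[i])))
    return ImageSet.concat(pieces)


def _aggregate_confusion(reports) -> tuple[np.ndarray, np.ndarray, list[str]]:
    classes = reports[0].confusion.classes
    total = np.zeros_like(reports[0].confusion.counts)
    for r in reports:
        total = total + r.confusion.counts
    sums = total.sum(axis=1, keepdims=True).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        norm = np.where(sums > 0, total / sums, 0.0)
    return total, norm, classes


def _arm_summary(out: dict) -> dict:
    counts, norm, classes = _aggregate_confusion(out["reports"])
    return {"mean_accuracy": out["mean_accuracy"],
            "sd_accuracy": out["sd_accuracy"],
            "accuracies": out["accuracies"],
            "per_class_recall": out["per_class_recall"],
            "confusion_counts": counts,
            "confusion_normalized": norm,
            "classes": classes}


def run_experiment(config: ExperimentConfig, dataset: ImageSet) -> dict:
    """Full comparison: stager on original data vs. GAN-balanced data.

    The "before" arm only ever sees real images; both arms share the same
    evaluation seeds and split protocol, so the balanced data is the only
    difference between them.
    """
    missing = set(STAGES) - set(dataset.counts())
    if missing:
        raise ValueError(f"dataset lacks stages: {sorted(missing)}")
    real = dataset.real_only()
    report: dict = {"imbalance_before": imbalance_report(real)}
    seeds = np.random.SeedSequence(config.master_seed).generate_state(
        len(STAGES) + 3) % (2 ** 31)
    stage_seed = {s: int(seeds[i]) for i, s in enumerate(STAGES)}
    eval_seed, balance_seed = int(seeds[-2]), int(seeds[-1])

    counts = real.counts()
    target = config.balance_target or max(counts.values())
    extractor = RandomConvFeatures()

    bundles: dict[str, GANBundle] = {}
    fid: dict[str, float] = {}
    balanced = real
    if config.balance:
        for stage in STAGES:
            if counts[stage] >= target:
                continue
            try:
                cfg = replace(config.gan, seed=stage_seed[stage])
                bundles[stage] = train_gan(real.of_stage(stage), cfg,
                                           stage=stage,
                                           perceptual_extractor=extractor)
                n_fid = min(config.fid_samples, counts[stage])
                if n_fid >= 2:
                    gen = sample_images(bundles[stage], n_fid,
                                        seed=stage_seed[stage] + 1)
                    fid[stage] = frechet_from_images(
                        real.of_stage(stage), gen, extractor)
            except Exception as exc:
                raise RuntimeError(f"GAN stage {stage!r} failed") from exc
        balanced = balance_dataset(real, bundles, seed=balance_seed,
                                   target=target)
    report["fid_per_stage"] = fid
    report["fid_extractor"] = extractor.name
    report["imbalance_after"] = imbalance_report(
        {s: c for s, c in balanced.counts().items()})

    before = repeated_evaluation(real, config.classifier,
                                 n_runs=config.n_runs, seed=eval_seed,
                                 mode=config.split_mode)
    if config.balance:
        after = repeated_evaluation(balanced, config.classifier,
                                    n_runs=config.n_runs, seed=eval_seed,
                                    mode=config.split_mode)
    else:
        after = before  # no-op control: arms are identical by construction
    report["before"] = _arm_summary(before)
    report["after"] = _arm_summary(after)
    report["deltas"] = {
        "mean_accuracy": report["after"]["mean_accuracy"]
        - report["before"]["mean_accuracy"],
        "per_class_recall": {
            s: report["after"]["per_class_recall"][s]
            - report["before"]["per_class_recall"][s]
            for s in report["before"]["per_class_recall"]},
    }
    report["n_generated"] = int((balanced.provenance == GENERATED).sum())
    return report


def report_to_json(report: dict) -> dict:
    """Strip non-serialisable members (per-run report objects, arrays)."""

    def conv(obj):
        if isinstance(obj, dict):
            return {k: conv(v) for k, v in obj.items() if k != "reports"}
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        if isinstance(obj, (np.floating, np.integer)):
            return obj.item()
        if isinstance(obj, (list, tuple)):
            return [conv(v) for v in obj]
        return obj

    return conv(report)


def save_report(report: dict, out_dir: str | Path) -> None:
    """Write report.json plus confusion-matrix and per-class CSV tables."""
    import pandas as pd

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "report.json", "w") as fh:
        json.dump(report_to_json(report), fh, indent=2)
    for arm in ("before", "after"):
        if arm not in report:
            continue
        classes = report[arm]["classes"]
        pd.DataFrame(report[arm]["confusion_normalized"], index=classes,
                     columns=classes).to_csv(out / f"confusion_{arm}.csv")
    rows = {arm: {**report[arm]["per_class_recall"],
                  "mean": report[arm]["mean_accuracy"],
                  "sd": report[arm]["sd_accuracy"]}
            for arm in ("before", "after") if arm in report}
    pd.DataFrame(rows).T.to_csv(out / "staging_accuracy.csv")
    if report.get("fid_per_stage"):
        pd.Series(report["fid_per_stage"]).to_csv(
            out / "fid_per_stage.csv", header=["fid"])
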