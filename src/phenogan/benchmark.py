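"""Scaled-down label-efficiency benchmark on synthetic chips.

This module pins the study conditions used throughout the test suite and
the reproduction script: 2,500 synthetic chips rendered at 48 x 48 with a
clear panicle/canopy contrast, an 80:20(:20) split, and an annotation
budget of 32 labels (about 1% of the 2,000-chip training pool, mirroring
the real study's 32-of-3,137) with the remainder available unlabeled.  The
semi-supervised GAN and the custom CNN both run at 48-pixel input with a
few hundred Adam steps; the training-length caps keep a full 3-seed
comparison tractable on one CPU core.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .chipio import ChipDataset, SplitSpec, split_dataset, subsample_budget
from .esgan import (DiscriminatorSpec, EsganModel, GeneratorSpec, TrainConfig,
                    predict_heading, train)
from .metrics import evaluate_scores
from .supervised import (CnnSpec, SupervisedTrainConfig, build_custom_cnn,
                         train_supervised)
from .synthchips import SynthConfig, generate_dataset

CHIP_SIZE = 48
N_CHIPS = 2500
N_LABELS_SMALL = 32


def benchmark_synth_config(seed: int, n_chips: int = N_CHIPS) -> SynthConfig:
    """Synthetic-population settings for the 48-pixel benchmark."""
    return SynthConfig(
        chip_size=CHIP_SIZE,
        n_chips=n_chips,
        positive_fraction=0.5,
        canopy_radius_range=(12.0, 19.0),
        canopy_green_level=0.45,
        soil_level=0.22,
        panicle_count_range=(3, 8),
        panicle_size_range=(1.5, 3.0),
        panicle_brightness=0.88,
        noise_sd=0.035,
        hue_jitter_sd=0.06,
        seed=seed,
    )


def make_benchmark_dataset(seed: int, n_chips: int = N_CHIPS) -> ChipDataset:
    return generate_dataset(benchmark_synth_config(seed, n_chips))


def esgan_train_config(seed: int) -> TrainConfig:
    return TrainConfig(batch_size=32, max_epochs=8, patience=3,
                       steps_per_epoch=25, seed=seed)


def cnn_train_config(seed: int, n_labeled: int) -> SupervisedTrainConfig:
    # few labels -> few steps per epoch -> allow more epochs (same cap logic
    # as the 300-epoch full-scale training, scaled to the step budget here)
    if n_labeled <= 64:
        return SupervisedTrainConfig(batch_size=32, max_epochs=60,
                                     patience=12, seed=seed)
    return SupervisedTrainConfig(batch_size=32, max_epochs=10,
                                 patience=3, seed=seed)


def build_benchmark_esgan(seed: int) -> EsganModel:
    return EsganModel(GeneratorSpec(image_size=CHIP_SIZE),
                      DiscriminatorSpec(image_size=CHIP_SIZE), seed=seed)


def train_esgan_on(labeled: ChipDataset, unlabeled: ChipDataset,
                   val: ChipDataset, seed: int, use_unlabeled: bool = True):
    model = build_benchmark_esgan(seed)
    cfg = esgan_train_config(seed)
    if not use_unlabeled:
        cfg.use_unlabeled = False
    model, history = train(model, labeled, unlabeled, val, cfg)
    return model, history


def train_cnn_on(labeled: ChipDataset, val: ChipDataset, seed: int):
    model = build_custom_cnn(CnnSpec(input_size=CHIP_SIZE), seed=seed)
    cfg = cnn_train_config(seed, len(labeled))
    return train_supervised(model, labeled, val, cfg)


@dataclass
class BenchmarkRun:
    """Everything one seed of the label-efficiency comparison produced."""

    seed: int
    esgan_model: EsganModel
    esgan_metrics: dict[str, float]
    cnn_small_metrics: dict[str, float]
    cnn_full_metrics: dict[str, float]
    test: ChipDataset
    n_labeled_small: int


def run_label_efficiency(seed: int, n_chips: int = N_CHIPS,
                         include_full_cnn: bool = True) -> BenchmarkRun:
    """One seed of the core experiment: GAN + CNN on 32 labels (remainder
    unlabeled for the GAN), optionally CNN on the full labeled pool."""
    ds = make_benchmark_dataset(seed, n_chips)
    train_pool, val, test = split_dataset(ds, SplitSpec(seed=seed))
    frac = N_LABELS_SMALL / len(train_pool)
    labeled, unlabeled = subsample_budget(train_pool, frac, seed)

    esgan_model, _ = train_esgan_on(labeled, unlabeled, val, seed)
    esgan_scores = predict_heading(esgan_model, test)[:, 1]
    esgan_metrics = evaluate_scores(test.labels, esgan_scores)

    cnn_small, _ = train_cnn_on(labeled, val, seed)
    cnn_small_metrics = evaluate_scores(test.labels,
                                        cnn_small.predict_scores(test))

    cnn_full_metrics = {}
    if include_full_cnn:
        cnn_full, _ = train_cnn_on(train_pool, val, seed)
        cnn_full_metrics = evaluate_scores(test.labels,
                                           cnn_full.predict_scores(test))
    return BenchmarkRun(seed=seed, esgan_model=esgan_model,
                        esgan_metrics=esgan_metrics,
                        cnn_small_metrics=cnn_small_metrics,
                        cnn_full_metrics=cnn_full_metrics,
                        test=test, n_labeled_small=len(labeled))
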