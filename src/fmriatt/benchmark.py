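"""Reference synthetic benchmarks exercising the full pipeline.

These encode the package's standard study conditions at desk scale:

* decoding benchmark — 3-class block-design dataset on a 16^3 grid, 12
  subjects, 12-frame instances, 8-frame segments, moderate SNR (activation
  amplitude 2 on noise SD 2); the attention decoder and its plain
  counterpart are trained on one subject-level fold and scored by
  majority-vote instance accuracy on held-out subjects.
* regression-transfer benchmark — the pretrained backbone is re-headed for
  trait regression and fine-tuned on a trans-set with the same subjects and
  activation geometry but a dominant trait effect on ROI amplitude
  (trait_slope 2 on noise SD 1, 4 instances per subject and class), against
  a from-scratch control at equal epochs.  Scored by subject-level Spearman
  correlation on test subjects.

Each replicate seed drives every random element (dataset, split, weights,
batching), so a replicate is a full independent pipeline run.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .attviz import collect_masks, roi_contrast_statistic
from .network import Model, ModelConfig, build_model
from .synth import GroundTruth, SynthConfig, generate_dataset
from .training import (
    SplitPlan,
    TrainConfig,
    evaluate,
    make_splits,
    train_model,
)
from .transfer import (
    TransferSpec,
    consistent_partition,
    evaluate_regression,
    swap_head,
)

SEG_LEN = 8
DECODING_EPOCHS = 40
TRANSFER_EPOCHS = 20


def decoding_conditions(seed: int) -> SynthConfig:
    return SynthConfig(seed=seed)


def transfer_conditions(seed: int) -> SynthConfig:
    # same seed => same subjects and traits as the source dataset
    return SynthConfig(seed=seed, trait_slope=2.0, noise_sd=1.0,
                       instances_per_subject_per_class=4)


@dataclass
class DecodingResult:
    seed: int
    attention_accuracy: float
    plain_accuracy: float
    attention_model: Model
    plain_model: Model
    plan: SplitPlan
    instances: list
    truth: GroundTruth
    histories: dict = field(default_factory=dict)


def run_decoding_benchmark(seed: int, epochs: int = DECODING_EPOCHS,
                           variants=("conv4d_attention", "conv4d_plain")
                           ) -> DecodingResult:
    cfg = decoding_conditions(seed)
    instances, truth = generate_dataset(cfg)
    subjects = sorted({i.subject_id for i in instances})
    plan = make_splits(subjects, seed=seed)[0]
    tr = plan.select(instances, "train")
    va = plan.select(instances, "validate")
    te = plan.select(instances, "test")
    models, accs, hists = {}, {}, {}
    for variant in variants:
        model = build_model(ModelConfig(variant=variant, seed=seed,
                                        seg_len=SEG_LEN,
                                        input_grid=cfg.grid_shape,
                                        n_classes=cfg.n_classes))
        hists[variant] = train_model(
            model, tr, va, TrainConfig(epochs=epochs, seg_len=SEG_LEN, seed=seed)
        )
        accs[variant] = evaluate(model, te, SEG_LEN).overall_accuracy
        models[variant] = model
    return DecodingResult(
        seed=seed,
        attention_accuracy=accs.get("conv4d_attention", float("nan")),
        plain_accuracy=accs.get("conv4d_plain", float("nan")),
        attention_model=models.get("conv4d_attention"),
        plain_model=models.get("conv4d_plain"),
        plan=plan, instances=instances, truth=truth, histories=hists,
    )


def interpretability_statistic(result: DecodingResult,
                               stage: int | None = None) -> dict[int, float]:
    """Final-stage class-contrast statistic S(c) on the decoding benchmark."""
    bundle = collect_masks(result.attention_model, result.instances, SEG_LEN)
    return roi_contrast_statistic(bundle, result.truth.class_rois, stage=stage)


@dataclass
class TransferResult:
    seed: int
    transfer_spearman: float
    scratch_spearman: float
    transfer_model: Model
    predictions: dict


def run_transfer_benchmark(source: Model, source_plan: SplitPlan, seed: int,
                           epochs: int = TRANSFER_EPOCHS) -> TransferResult:
    cfg = transfer_conditions(seed)
    instances, _ = generate_dataset(cfg)
    plan = consistent_partition(source_plan, instances)
    tr = plan.select(instances, "train")
    va = plan.select(instances, "validate")
    te = plan.select(instances, "test")
    tcfg = TrainConfig(epochs=epochs, lr0=1e-3, seg_len=SEG_LEN, seed=seed + 7)
    ft = swap_head(source, TransferSpec(head="regress", lr_scale=0.1,
                                        seed=seed + 7))
    train_model(ft, tr, va, tcfg)
    rep_ft = evaluate_regression(ft, te, SEG_LEN)
    scratch = build_model(ModelConfig(
        variant=source.cfg.variant, head="regress", seed=seed + 900,
        seg_len=SEG_LEN, input_grid=cfg.grid_shape, n_classes=cfg.n_classes,
    ))
    train_model(scratch, tr, va, tcfg)
    rep_sc = evaluate_regression(scratch, te, SEG_LEN)
    return TransferResult(
        seed=seed,
        transfer_spearman=rep_ft.spearman_r,
        scratch_spearman=rep_sc.spearman_r,
        transfer_model=ft,
        predictions=rep_ft.predictions,
    )
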