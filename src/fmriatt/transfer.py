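"""Transfer-learning workflows.

Two workflows mirror the two ways a pretrained decoder is reused:

* inter-task trait regression — keep the backbone of a classifier trained on
  the source task, replace the fully-connected head by a single-output
  regression head, switch to an MSE loss, and fine-tune under a
  subject-consistent partition so no test subject of the transfer stage ever
  sat in any training partition.  Performance is the Spearman rank
  correlation between predicted and observed traits on test subjects.
* inter-dataset binary classification — fine-tune on a small target dataset
  under leave-one-subject-out cross-validation.

Trait targets are z-scored on the training partition only; predictions are
reported back on the original scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .network import Model, ModelConfig, build_model
from .training import (
    ConfigurationError,
    SplitPlan,
    TrainConfig,
    evaluate,
    predict_trait,
    train_model,
)

FREEZE_POLICIES = ("none", "freeze_conv4d", "freeze_through_stage")


class LeakageError(RuntimeError):
    pass


@dataclass
class TransferSpec:
    head: str = "regress"            # "regress" or "classify"
    n_classes: int = 2               # for classify heads
    freeze_policy: str = "none"      # none | freeze_conv4d | freeze_through_stage
    freeze_stage: int = 0            # last frozen stage for freeze_through_stage
    lr_scale: float = 1.0            # lr multiplier for reused (backbone) layers
    seed: int = 0

    def __post_init__(self):
        if not (0 < self.lr_scale <= 1):
            raise ConfigurationError("lr_scale must lie in (0, 1]")
        if self.freeze_policy not in FREEZE_POLICIES:
            raise ConfigurationError(
                f"freeze_policy must be one of {FREEZE_POLICIES}"
            )
        if self.head not in ("regress", "classify"):
            raise ConfigurationError("head must be 'regress' or 'classify'")


@dataclass
class RegressionReport:
    spearman_r: float
    p_value: float
    predictions: dict = field(default_factory=dict)


def swap_head(source: Model, spec: TransferSpec) -> Model:
    """New model sharing the source backbone bit-for-bit, with a freshly
    initialized head and freeze/lr flags applied per policy."""
    cfg = ModelConfig.from_dict(source.cfg.to_dict())
    cfg = ModelConfig.from_dict({
        **cfg.to_dict(),
        "head": spec.head,
        "n_classes": spec.n_classes if spec.head == "classify"
        else source.cfg.n_classes,
        "seed": spec.seed,
    })
    model = build_model(cfg)
    state = source.state_dict()
    backbone = {k: v for k, v in state.items() if not k.startswith("fc.")}
    own = model.state_dict()
    for k in backbone:
        if k not in own:
            raise ValueError(f"incompatible backbone: source layer {k!r} "
                             "has no counterpart in the target geometry")
        if own[k].shape != backbone[k].shape:
            raise ValueError(
                f"incompatible backbone at {k!r}: source {backbone[k].shape} "
                f"vs target {own[k].shape}"
            )
    own.update(backbone)
    model.load_state_dict(own)

    def _mark(module, frozen: bool):
        for p in module.parameters():
            p.lr_scale = spec.lr_scale
            if frozen:
                p.trainable = False

    if spec.freeze_policy == "freeze_conv4d":
        _mark(model.front, True)
        for stage in model.stages:
            _mark(stage, False)
    elif spec.freeze_policy == "freeze_through_stage":
        _mark(model.front, True)
        for i, stage in enumerate(model.stages):
            _mark(stage, i <= spec.freeze_stage)
    else:
        _mark(model.front, False)
        for stage in model.stages:
            _mark(stage, False)
    return model


def consistent_partition(source_plan: SplitPlan, target_instances) -> SplitPlan:
    """Restrict the source subject partition to the transfer dataset's
    subjects; every target subject inherits its source assignment."""
    target_subjects = {i.subject_id for i in target_instances}
    unknown = target_subjects - set(source_plan.assignment)
    if unknown:
        raise KeyError(
            f"subjects absent from the source split plan: {sorted(unknown)[:5]}"
        )
    assignment = {s: source_plan.assignment[s] for s in target_subjects}
    plan = SplitPlan(fold_id=source_plan.fold_id, assignment=assignment)
    validate_transfer_plan(source_plan, plan)
    return plan


def validate_transfer_plan(source_plan: SplitPlan,
                           transfer_plan: SplitPlan) -> None:
    """Reject plans where a transfer test/validation subject was trained on
    at the source stage (individual-information leakage)."""
    source_train = set(source_plan.subjects("train"))
    for part in ("test", "validate"):
        leaked = set(transfer_plan.subjects(part)) & source_train
        if leaked:
            raise LeakageError(
                f"subjects {sorted(leaked)} are in the transfer {part} "
                "partition but were in the source training partition"
            )


def spearman(pred, obs) -> tuple[float, float]:
    """Spearman rank correlation with average ranks for ties; p-value from
    the large-sample t approximation."""
    pred = np.asarray(pred, dtype=float)
    obs = np.asarray(obs, dtype=float)
    if pred.shape != obs.shape or pred.ndim != 1:
        raise ValueError("pred and obs must be equal-length 1D sequences")
    if pred.size < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(pred) == 0 or np.ptp(obs) == 0:
        raise ValueError("correlation undefined for a constant vector")
    res = stats.spearmanr(pred, obs)
    return float(res.statistic), float(res.pvalue)


def evaluate_regression(model: Model, instances, k: int) -> RegressionReport:
    """Subject-level Spearman correlation between predicted and observed
    traits (instance predictions averaged per subject)."""
    by_subject: dict[str, list[float]] = {}
    obs: dict[str, float] = {}
    for inst in instances:
        by_subject.setdefault(inst.subject_id, []).append(
            predict_trait(model, inst, k)
        )
        obs[inst.subject_id] = inst.trait
    subjects = sorted(by_subject)
    pred = [float(np.mean(by_subject[s])) for s in subjects]
    true = [obs[s] for s in subjects]
    r, p = spearman(pred, true)
    return RegressionReport(
        spearman_r=r, p_value=p,
        predictions={s: v for s, v in zip(subjects, pred)},
    )


def loso_transfer(source: Model, target_instances, train_cfg: TrainConfig,
                  spec: TransferSpec | None = None) -> dict:
    """Leave-one-subject-out fine-tuning on a target dataset.

    One fine-tuning run per held-out subject; within each run one training
    subject is held out for validation scheduling.  Returns per-subject
    accuracies plus their mean and standard deviation.
    """
    spec = spec or TransferSpec(head="classify", n_classes=2)
    subjects = sorted({i.subject_id for i in target_instances})
    if len(subjects) < 2:
        raise ConfigurationError("leave-one-subject-out needs >= 2 subjects")
    rng = np.random.default_rng(train_cfg.seed)
    per_subject = {}
    for held in subjects:
        rest = [s for s in subjects if s != held]
        val_subject = rest[int(rng.integers(0, len(rest)))] if len(rest) > 1 else rest[0]
        train = [i for i in target_instances
                 if i.subject_id in rest and i.subject_id != val_subject]
        if not train:  # 2-subject degenerate case: validate on training data
            train = [i for i in target_instances if i.subject_id in rest]
        val = [i for i in target_instances if i.subject_id == val_subject]
        test = [i for i in target_instances if i.subject_id == held]
        model = swap_head(source, spec)
        train_model(model, train, val, train_cfg)
        report = evaluate(model, test, train_cfg.seg_len)
        per_subject[held] = report.overall_accuracy
    accs = np.array(list(per_subject.values()))
    return {
        "per_subject": per_subject,
        "mean": float(accs.mean()),
        "sd": float(accs.std(ddof=1)) if len(accs) > 1 else 0.0,
    }
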