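"""Training and evaluation protocol.

Subject-level fivefold splits (70/10/20 train/validation/test), random
contiguous-segment sampling as temporal augmentation, Adam with a
reduce-on-plateau learning-rate schedule, and instance-level inference by
summing class-probability vectors over every stride-1 temporal window
(soft majority vote; ties go to the lowest class index).

Segments are standardized (zero mean, unit variance over the whole window)
before entering the network, the usual percent-signal-change style
normalization that removes the arbitrary BOLD baseline.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
import numpy as np

from .network import Model, ModelConfig, build_model
from .nn.losses import mse_loss, softmax, softmax_cross_entropy
from .nn.optim import Adam, ReduceLROnPlateau
from .types import TaskInstance


class ConfigurationError(ValueError):
    pass


class DivergenceError(RuntimeError):
    pass


@dataclass
class SplitPlan:
    fold_id: int
    assignment: dict  # subject_id -> "train" | "validate" | "test"

    def subjects(self, part: str) -> list[str]:
        return sorted(s for s, p in self.assignment.items() if p == part)

    def select(self, instances: list[TaskInstance], part: str) -> list[TaskInstance]:
        keep = {s for s, p in self.assignment.items() if p == part}
        return [i for i in instances if i.subject_id in keep]


@dataclass
class TrainConfig:
    batch_size: int = 16
    epochs: int = 60
    lr0: float = 1e-4
    beta1: float = 0.9
    beta2: float = 0.999
    plateau_patience: int = 15
    decay_factor: float = 5.0
    seg_len: int = 8
    seed: int = 0
    standardize: bool = True
    vote: str = "soft"  # "soft" (probability sums) or "hard" (label counts)

    def __post_init__(self):
        if min(self.batch_size, self.epochs, self.plateau_patience,
               self.seg_len) < 1 or self.lr0 <= 0:
            raise ConfigurationError("all training parameters must be positive")
        if self.decay_factor <= 1:
            raise ConfigurationError("decay_factor must exceed 1")


@dataclass
class History:
    train_losses: list = field(default_factory=list)
    val_losses: list = field(default_factory=list)
    lr_events: list = field(default_factory=list)  # (epoch, new_lr)
    best_epoch: int = -1
    best_val_loss: float = float("inf")


@dataclass
class EvalReport:
    confusion: np.ndarray          # (n_classes, n_classes) counts, rows = truth
    per_class_accuracy: dict
    overall_accuracy: float


def make_splits(subjects, n_folds: int = 5, proportions=(0.7, 0.1, 0.2),
                seed: int = 0) -> list[SplitPlan]:
    """Subject-level cross-validation plans.

    The subject list is shuffled once and cut into `n_folds` disjoint test
    blocks; per fold, the remainder is split train/validation at the stated
    proportions.  Every subject is in the test partition of exactly one fold.
    """
    subjects = list(subjects)
    if abs(sum(proportions) - 1.0) > 1e-9:
        raise ConfigurationError("proportions must sum to 1")
    if len(subjects) < n_folds or len(subjects) < 3:
        raise ConfigurationError(
            f"{len(subjects)} subjects cannot fill {n_folds} folds with "
            "non-empty train/validate/test partitions"
        )
    rng = np.random.default_rng(seed)
    order = [subjects[i] for i in rng.permutation(len(subjects))]
    blocks = np.array_split(np.arange(len(order)), n_folds)
    plans = []
    for fold, block in enumerate(blocks):
        test = {order[i] for i in block}
        rest = [s for s in order if s not in test]
        frng = np.random.default_rng(seed + 1000 * (fold + 1))
        rest = [rest[i] for i in frng.permutation(len(rest))]
        train_frac = proportions[0] / (proportions[0] + proportions[1])
        n_train = int(round(train_frac * len(rest)))
        n_train = min(max(n_train, 1), len(rest) - 1)
        assignment = {s: "test" for s in test}
        assignment.update({s: "train" for s in rest[:n_train]})
        assignment.update({s: "validate" for s in rest[n_train:]})
        if not test or n_train < 1 or n_train >= len(rest):
            raise ConfigurationError("a partition came out empty")
        plans.append(SplitPlan(fold_id=fold, assignment=assignment))
    return plans


def standardize(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=np.float32)
    return (x - x.mean()) / (x.std() + 1e-6)


def sample_segment(instance: TaskInstance, k: int,
                   rng: np.random.Generator) -> np.ndarray:
    """A random contiguous k-frame window, channel axis appended: (k,x,y,z,1)."""
    if k < 1:
        raise ValueError("segment length k must be >= 1")
    n = instance.n_frames
    if n < k:
        raise ValueError(f"instance has {n} frames, shorter than segment k={k}")
    start = int(rng.integers(0, n - k + 1))
    return instance.series[start : start + k, ..., None]


def _segment_batch(instances, k: int, rng, do_standardize: bool,
                   center: bool = False) -> np.ndarray:
    segs = []
    for inst in instances:
        if center:
            start = (inst.n_frames - k) // 2
            seg = inst.series[start : start + k, ..., None]
        else:
            seg = sample_segment(inst, k, rng)
        segs.append(standardize(seg) if do_standardize else
                    np.asarray(seg, np.float32))
    return np.stack(segs, axis=0)


def _targets(instances, head: str, trait_stats=None):
    if head == "classify":
        return np.array([i.class_label for i in instances])
    traits = np.array([i.trait for i in instances], dtype=np.float64)
    if trait_stats is not None:
        mean, sd = trait_stats
        traits = (traits - mean) / sd
    return traits


def _loss_batch(model: Model, x, y):
    out = model.forward(x)
    if model.cfg.head == "classify":
        return softmax_cross_entropy(out.scores, y)
    return mse_loss(out.scores, y)


def _validation_loss(model: Model, instances, cfg: TrainConfig,
                     trait_stats) -> float:
    """Loss over every stride-1 window of every validation instance."""
    xs, ys = [], []
    for inst in instances:
        y = (inst.class_label if model.cfg.head == "classify"
             else inst.trait)
        for s in range(inst.n_frames - cfg.seg_len + 1):
            seg = inst.series[s : s + cfg.seg_len, ..., None]
            xs.append(standardize(seg) if cfg.standardize
                      else np.asarray(seg, np.float32))
            ys.append(y)
    x = np.stack(xs, axis=0)
    y = np.asarray(ys)
    if model.cfg.head == "regress" and trait_stats is not None:
        y = (y - trait_stats[0]) / trait_stats[1]
    elif model.cfg.head == "classify":
        y = y.astype(int)
    loss, _ = _loss_batch(model, x, y)
    return loss


def train_model(model: Model, train_instances, val_instances,
                cfg: TrainConfig) -> History:
    """Optimize in place; restores the best-validation snapshot at the end."""
    if not train_instances or not val_instances:
        raise ConfigurationError("train and validation sets must be non-empty")
    rng = np.random.default_rng(cfg.seed)
    opt = Adam(model.parameters(), lr=cfg.lr0, beta1=cfg.beta1, beta2=cfg.beta2)
    sched = ReduceLROnPlateau(opt, factor=cfg.decay_factor,
                              patience=cfg.plateau_patience)
    hist = History()
    if model.cfg.head == "regress":
        traits = np.array([i.trait for i in train_instances], dtype=np.float64)
        sd = traits.std()
        model.trait_stats = (float(traits.mean()), float(sd if sd > 0 else 1.0))
    trait_stats = getattr(model, "trait_stats", None)
    best_state = None
    for epoch in range(cfg.epochs):
        model.train()
        order = rng.permutation(len(train_instances))
        losses = []
        for b0 in range(0, len(order), cfg.batch_size):
            batch = [train_instances[i] for i in order[b0 : b0 + cfg.batch_size]]
            x = _segment_batch(batch, cfg.seg_len, rng, cfg.standardize)
            y = _targets(batch, model.cfg.head, trait_stats)
            loss, grad = _loss_batch(model, x, y)
            if not np.isfinite(loss):
                raise DivergenceError(
                    f"non-finite training loss at epoch {epoch}, lr={opt.lr:g}"
                )
            model.zero_grad()
            model.backward(grad)
            opt.step()
            losses.append(loss)
        model.eval()
        val_loss = _validation_loss(model, val_instances, cfg, trait_stats)
        hist.train_losses.append(float(np.mean(losses)))
        hist.val_losses.append(float(val_loss))
        if val_loss < hist.best_val_loss:
            hist.best_val_loss = float(val_loss)
            hist.best_epoch = epoch
            best_state = model.state_dict()
        if sched.step(val_loss, epoch):
            hist.lr_events.append((epoch, opt.lr))
    if best_state is not None:
        model.load_state_dict(best_state)
    model.eval()
    return hist


def _window_scores(model: Model, instance: TaskInstance, k: int,
                   do_standardize: bool = True) -> np.ndarray:
    if instance.n_frames < k:
        raise ValueError(
            f"instance has {instance.n_frames} frames, shorter than k={k}"
        )
    windows = [
        instance.series[s : s + k, ..., None]
        for s in range(instance.n_frames - k + 1)
    ]
    if do_standardize:
        windows = [standardize(w) for w in windows]
    x = np.stack([np.asarray(w, np.float32) for w in windows], axis=0)
    model.eval()
    return model.forward(x).scores


def predict_instance(model: Model, instance: TaskInstance, k: int,
                     vote: str = "soft"):
    """Majority-vote label over all stride-1 k-windows.

    Soft vote sums per-window class-probability vectors; hard vote counts
    per-window argmax labels.  Returns (label, summed score vector); exact
    ties resolve to the lowest class index.
    """
    scores = _window_scores(model, instance, k)
    probs = softmax(scores)
    if vote == "hard":
        summed = np.zeros(probs.shape[1])
        for row in probs:
            summed[int(np.argmax(row))] += 1.0
    else:
        summed = probs.sum(axis=0)
    return int(np.argmax(summed)), summed


def predict_trait(model: Model, instance: TaskInstance, k: int) -> float:
    """Window-averaged regression output, mapped back to the trait scale."""
    scores = _window_scores(model, instance, k)
    val = float(np.mean(scores))
    stats = getattr(model, "trait_stats", None)
    if stats is not None:
        val = val * stats[1] + stats[0]
    return val


def evaluate(model: Model, instances, k: int, vote: str = "soft") -> EvalReport:
    if not instances:
        raise ConfigurationError("cannot evaluate on an empty set")
    n = model.cfg.n_classes
    confusion = np.zeros((n, n), dtype=int)
    for inst in instances:
        pred, _ = predict_instance(model, inst, k, vote=vote)
        confusion[inst.class_label, pred] += 1
    per_class = {}
    for c in range(n):
        total = confusion[c].sum()
        per_class[c] = float(confusion[c, c] / total) if total else float("nan")
    overall = float(np.trace(confusion) / confusion.sum())
    return EvalReport(confusion=confusion, per_class_accuracy=per_class,
                      overall_accuracy=overall)


# -- checkpoints -----------------------------------------------------------


def save_checkpoint(path, model: Model, history: History | None = None) -> None:
    state = model.state_dict()
    meta = {"config": model.cfg.to_dict()}
    if getattr(model, "trait_stats", None) is not None:
        meta["trait_stats"] = list(model.trait_stats)
    if history is not None:
        meta["history"] = {
            "train_losses": history.train_losses,
            "val_losses": history.val_losses,
            "lr_events": history.lr_events,
            "best_epoch": history.best_epoch,
            "best_val_loss": history.best_val_loss,
        }
    np.savez(path, __meta__=np.frombuffer(
        json.dumps(meta).encode(), dtype=np.uint8), **state)


def load_checkpoint(path) -> Model:
    with np.load(path) as z:
        meta = json.loads(bytes(z["__meta__"]).decode())
        state = {k: z[k] for k in z.files if k != "__meta__"}
    model = build_model(ModelConfig.from_dict(meta["config"]))
    model.load_state_dict(state)
    if "trait_stats" in meta:
        model.trait_stats = tuple(meta["trait_stats"])
    model.eval()
    return model
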