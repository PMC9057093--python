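"""Protocol: splits, segment sampling, schedule, voting, evaluation."""

import numpy as np
import pytest

from fmriatt.network import ModelConfig, ModelOutput, build_model
from fmriatt.nn.core import Module
from fmriatt.nn.optim import Adam, ReduceLROnPlateau
from fmriatt.training import (
    ConfigurationError,
    TrainConfig,
    evaluate,
    load_checkpoint,
    make_splits,
    predict_instance,
    sample_segment,
    save_checkpoint,
    train_model,
)
from fmriatt.types import TaskInstance


class TestMakeSplits:
    def test_ten_subjects_five_folds_exact_partition(self):
        subjects = [f"s{i}" for i in range(10)]
        plans = make_splits(subjects, n_folds=5, seed=1)
        all_test = []
        for plan in plans:
            assert len(plan.subjects("test")) == 2
            assert len(plan.subjects("train")) == 7
            assert len(plan.subjects("validate")) == 1
            assert set(plan.assignment) == set(subjects)
            all_test += plan.subjects("test")
        assert sorted(all_test) == sorted(subjects)  # each tested exactly once

    def test_no_subject_straddles_partitions(self):
        plans = make_splits([f"s{i}" for i in range(13)], seed=2)
        for plan in plans:
            parts = [set(plan.subjects(p)) for p in ("train", "validate", "test")]
            assert not (parts[0] & parts[1] or parts[0] & parts[2]
                        or parts[1] & parts[2])

    def test_deterministic(self):
        subjects = [f"s{i}" for i in range(12)]
        a = make_splits(subjects, seed=9)
        b = make_splits(subjects, seed=9)
        assert [p.assignment for p in a] == [p.assignment for p in b]

    def test_too_few_subjects(self):
        with pytest.raises(ConfigurationError):
            make_splits(["a", "b"], n_folds=5)


class TestSampleSegment:
    def _instance(self, n_frames=10):
        series = np.arange(n_frames, dtype=np.float32)[:, None, None, None]
        series = np.broadcast_to(series, (n_frames, 2, 2, 2)).copy()
        return TaskInstance("s0", 0, 0.0, series)

    def test_degenerate_window_is_full_instance(self):
        inst = self._instance(7)
        seg = sample_segment(inst, 7, np.random.default_rng(0))
        assert seg.shape == (7, 2, 2, 2, 1)
        np.testing.assert_array_equal(seg[..., 0], inst.series)

    def test_start_positions_uniform(self):
        inst = self._instance(10)
        rng = np.random.default_rng(5)
        draws = 2000
        starts = [int(sample_segment(inst, 7, rng)[0, 0, 0, 0, 0])
                  for _ in range(draws)]
        counts = np.bincount(starts, minlength=4)
        # 4 start positions; 5-SE band around the uniform expectation
        p = 1 / 4
        se = np.sqrt(draws * p * (1 - p))
        assert np.all(np.abs(counts - draws * p) < 5 * se)

    def test_invalid_lengths(self):
        inst = self._instance(5)
        with pytest.raises(ValueError):
            sample_segment(inst, 0, np.random.default_rng(0))
        with pytest.raises(ValueError, match="shorter"):
            sample_segment(inst, 6, np.random.default_rng(0))


class TestSchedule:
    def test_lr_is_lr0_over_factor_pow_reductions(self):
        opt = Adam([], lr=1e-4)
        sched = ReduceLROnPlateau(opt, factor=5.0, patience=1)
        sched.step(1.0, epoch=0)
        for epoch in range(1, 4):  # stagnant validation loss
            sched.step(1.0, epoch=epoch)
            assert opt.lr == 1e-4 / 5.0**sched.n_reductions
        assert sched.n_reductions == 3

    def test_improvement_resets_patience(self):
        opt = Adam([], lr=1e-3)
        sched = ReduceLROnPlateau(opt, factor=5.0, patience=2)
        losses = [1.0, 0.9, 0.89999, 0.8, 0.79999, 0.79998]
        reduced = [sched.step(l, e) for e, l in enumerate(losses)]
        # stale epochs: 2 (idx 2, 4? ) -> single reduction after two stagnant
        assert sum(reduced) == 1 and opt.lr == pytest.approx(1e-3 / 5.0)


class _StubClassifier(Module):
    """Emits fixed per-window probability rows via log-probability scores."""

    def __init__(self, prob_rows, n_classes=2):
        super().__init__()
        self.rows = np.asarray(prob_rows, dtype=float)
        self.cfg = type("C", (), {"head": "classify", "n_classes": n_classes})()

    def forward(self, x):
        return ModelOutput(scores=np.log(self.rows[: x.shape[0]]))


def _windows_instance(n_frames, k):
    series = np.random.default_rng(0).normal(
        size=(n_frames, 2, 2, 2)
    ).astype(np.float32)
    return TaskInstance("s0", 0, 0.0, series), n_frames - k + 1


class TestMajorityVote:
    def test_single_window_argmax(self):
        inst, n_win = _windows_instance(5, 5)
        model = _StubClassifier([[0.3, 0.7]])
        label, summed = predict_instance(model, inst, 5)
        assert n_win == 1 and label == 1
        np.testing.assert_allclose(summed, [0.3, 0.7], atol=1e-9)

    def test_hand_summed_probability_vote(self):
        inst, n_win = _windows_instance(5, 3)
        rows = [[0.6, 0.4], [0.6, 0.4], [0.1, 0.9]]
        model = _StubClassifier(rows)
        label, summed = predict_instance(model, inst, 3)
        assert n_win == 3
        np.testing.assert_allclose(summed, [1.3, 1.7], atol=1e-9)
        assert label == 1

    def test_exact_tie_goes_to_lowest_class(self):
        inst, _ = _windows_instance(4, 3)
        model = _StubClassifier([[0.5, 0.5], [0.5, 0.5]])
        label, _ = predict_instance(model, inst, 3)
        assert label == 0

    def test_unanimous_windows_win(self):
        inst, _ = _windows_instance(6, 3)
        model = _StubClassifier([[0.2, 0.8]] * 4)
        for vote in ("soft", "hard"):
            label, _ = predict_instance(model, inst, 3, vote=vote)
            assert label == 1


class TestEvaluate:
    def _dataset(self, n_per_class=4, n_classes=3):
        rng = np.random.default_rng(1)
        out = []
        for c in range(n_classes):
            for i in range(n_per_class):
                series = rng.normal(size=(6, 2, 2, 2)).astype(np.float32)
                out.append(TaskInstance(f"s{c}-{i}", c, 0.0, series))
        return out

    def test_constant_predictor_on_balanced_set(self):
        data = self._dataset()
        model = _StubClassifier([[0.9, 0.05, 0.05]] * 4, n_classes=3)
        report = evaluate(model, data, 3)
        assert report.overall_accuracy == pytest.approx(1 / 3)
        assert report.confusion[:, 0].sum() == len(data)

    def test_confusion_bookkeeping(self):
        data = self._dataset()
        model = _StubClassifier([[0.9, 0.05, 0.05]] * 4, n_classes=3)
        report = evaluate(model, data, 3)
        np.testing.assert_array_equal(report.confusion.sum(axis=1), [4, 4, 4])
        assert report.overall_accuracy == pytest.approx(
            np.trace(report.confusion) / report.confusion.sum()
        )


class TestTrainModel:
    @pytest.fixture(scope="class")
    def trained(self, tiny_dataset):
        cfg, instances, _ = tiny_dataset
        subjects = sorted({i.subject_id for i in instances})
        plan = make_splits(subjects, n_folds=4, seed=0)[0]
        model = build_model(ModelConfig(
            variant="conv4d_attention", n_classes=2, input_grid=cfg.grid_shape,
            stage_channels=(8, 8, 16, 16), conv4d_channels=4, seg_len=8, seed=0,
        ))
        tcfg = TrainConfig(epochs=8, seg_len=8, seed=0, batch_size=8)
        hist = train_model(model, plan.select(instances, "train"),
                           plan.select(instances, "validate"), tcfg)
        return model, hist, plan, instances

    def test_loss_decreases(self, trained):
        _, hist, _, _ = trained
        assert hist.train_losses[-1] < hist.train_losses[0]

    def test_best_snapshot_restored(self, trained):
        _, hist, _, _ = trained
        assert hist.best_val_loss == pytest.approx(min(hist.val_losses))

    def test_checkpoint_roundtrip(self, trained, tmp_path):
        model, hist, plan, instances = trained
        path = tmp_path / "model.npz"
        save_checkpoint(path, model, hist)
        back = load_checkpoint(path)
        for (ka, pa), (kb, pb) in zip(model.named_parameters(),
                                      back.named_parameters()):
            assert ka == kb
            np.testing.assert_array_equal(pa.data, pb.data)
        x = np.random.default_rng(0).normal(
            size=(2, 8) + model.cfg.input_grid + (1,)
        ).astype(np.float32)
        np.testing.assert_allclose(
            model.eval().forward(x).scores, back.forward(x).scores, atol=1e-6
        )

    def test_identical_runs_identical_histories(self, tiny_dataset):
        cfg, instances, _ = tiny_dataset
        subjects = sorted({i.subject_id for i in instances})
        plan = make_splits(subjects, n_folds=4, seed=0)[0]

        def run():
            model = build_model(ModelConfig(
                variant="conv4d_plain", n_classes=2, input_grid=cfg.grid_shape,
                stage_channels=(4, 4, 8, 8), conv4d_channels=4, seg_len=8,
                seed=1,
            ))
            return train_model(
                model, plan.select(instances, "train"),
                plan.select(instances, "validate"),
                TrainConfig(epochs=3, seg_len=8, seed=4, batch_size=8),
            )

        h1, h2 = run(), run()
        assert h1.train_losses == h2.train_losses
        assert h1.val_losses == h2.val_losses
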