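"""Mask collection, contrasts, resampling, export."""

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pytest

from fmriatt.attviz import (
    AVERAGE,
    AttentionMask,
    UnsupportedModelError,
    collect_masks,
    contrast_mask,
    export_masks,
    rank_channels,
    upsample_to_input,
)
from fmriatt.network import ModelConfig, build_model
from fmriatt.training import standardize
from fmriatt.synth import SynthConfig, generate_dataset


@pytest.fixture(scope="module")
def small_setup():
    cfg = SynthConfig(grid_shape=(8, 8, 8), n_classes=2, n_subjects=3,
                      instances_per_subject_per_class=1, seed=21)
    instances, truth = generate_dataset(cfg)
    model = build_model(ModelConfig(
        variant="conv4d_attention", n_classes=2, input_grid=(8, 8, 8),
        stage_channels=(4, 4, 8, 8), conv4d_channels=4, seg_len=8, seed=3,
    )).eval()
    return model, instances, truth


class TestCollectMasks:
    def test_plain_model_unsupported(self, small_setup):
        _, instances, _ = small_setup
        plain = build_model(ModelConfig(
            variant="conv4d_plain", n_classes=2, input_grid=(8, 8, 8),
            stage_channels=(4, 4, 8, 8), conv4d_channels=4, seg_len=8, seed=3,
        ))
        with pytest.raises(UnsupportedModelError):
            collect_masks(plain, instances, 8)

    def test_single_window_average_is_raw_mask(self, small_setup):
        from dataclasses import replace
        model, instances, _ = small_setup
        inst = replace(instances[0], series=instances[0].series[:8])
        bundle = collect_masks(model, [inst], 8)  # 8 frames, k=8: one window
        x = standardize(inst.series[..., None])[None]
        raw = model.forward(x).masks
        for stage in range(4):
            got = bundle.masks[(stage, inst.class_label)]
            np.testing.assert_allclose(got, raw[stage][0], rtol=1e-5)

    def test_window_average_matches_hand_average(self, small_setup):
        from dataclasses import replace
        model, instances, _ = small_setup
        inst = replace(instances[0], series=instances[0].series[:9])
        bundle = collect_masks(model, [inst], 8)  # 9 frames: two windows
        m = []
        for s in (0, 1):
            x = standardize(inst.series[s : s + 8, ..., None])[None]
            m.append(model.forward(x).masks[-1][0])
        np.testing.assert_allclose(
            bundle.masks[(3, inst.class_label)], (m[0] + m[1]) / 2, rtol=1e-5
        )

    def test_condition_count_and_sample_counts(self, small_setup):
        model, instances, _ = small_setup
        bundle = collect_masks(model, instances, 8)
        assert bundle.conditions == [0, 1]
        n_windows = sum(i.n_frames - 8 + 1 for i in instances
                        if i.class_label == 0)
        assert bundle.sample_counts[0] == n_windows
        for stage in range(4):
            assert (stage, AVERAGE) in bundle.masks

    def test_order_invariance(self, small_setup):
        model, instances, _ = small_setup
        a = collect_masks(model, instances, 8)
        b = collect_masks(model, instances[::-1], 8)
        for key in a.masks:
            np.testing.assert_allclose(a.masks[key], b.masks[key], atol=1e-6)

    def test_mask_values_in_unit_interval(self, small_setup):
        model, instances, _ = small_setup
        bundle = collect_masks(model, instances, 8)
        for m in bundle.masks.values():
            assert np.all(m > 0) and np.all(m < 1)


class TestContrasts:
    def test_contrasts_sum_to_zero(self, small_setup):
        model, instances, _ = small_setup
        bundle = collect_masks(model, instances, 8)
        for stage in range(4):
            total = sum(
                contrast_mask(bundle, stage, None, c).data
                for c in bundle.conditions
            )
            np.testing.assert_allclose(total, 0.0, atol=1e-10)

    def test_identical_conditions_give_zero_contrast(self):
        from fmriatt.attviz import MaskBundle
        m = np.random.default_rng(0).random((4, 4, 4, 2))
        bundle = MaskBundle(
            masks={(0, 0): m, (0, 1): m, (0, AVERAGE): m},
            sample_counts={0: 1, 1: 1}, affines=[np.eye(4)],
            conditions=[0, 1], input_grid=(8, 8, 8), input_affine=np.eye(4),
        )
        np.testing.assert_allclose(contrast_mask(bundle, 0, 0, 1).data, 0.0)

    def test_missing_condition_raises(self, small_setup):
        model, instances, _ = small_setup
        bundle = collect_masks(model, instances, 8)
        with pytest.raises(KeyError):
            contrast_mask(bundle, 0, 0, condition=99)

    def test_rank_channels_permutation(self, small_setup):
        model, instances, _ = small_setup
        bundle = collect_masks(model, instances, 8)
        order = rank_channels(bundle, 3)
        assert sorted(order) == list(range(bundle.n_channels(3)))


class TestUpsample:
    def test_constant_preserved(self):
        mask = AttentionMask(0, 0, 0, np.full((2, 2, 2), 0.4), np.eye(4))
        up = upsample_to_input(mask, (8, 8, 8), np.eye(4))
        assert up.data.shape == (8, 8, 8)
        np.testing.assert_allclose(up.data, 0.4, rtol=1e-6)

    def test_identity_resample(self):
        data = np.random.default_rng(1).random((6, 6, 6))
        mask = AttentionMask(0, 0, 0, data, np.eye(4))
        up = upsample_to_input(mask, (6, 6, 6), np.eye(4))
        np.testing.assert_allclose(up.data, data, atol=1e-6)

    def test_linear_ramp_preserved_interior(self):
        # ramp along x: value = x index; trilinear doubling keeps linearity
        data = np.arange(4, dtype=float)[:, None, None] * np.ones((4, 4, 4))
        mask = AttentionMask(0, 0, 0, data, np.eye(4))
        up = upsample_to_input(mask, (8, 8, 8), np.eye(4))
        # interior target x-index i maps to source coordinate (i+0.5)/2-0.5
        expected = (np.arange(1, 7) + 0.5) / 2 - 0.5
        np.testing.assert_allclose(up.data[1:7, 4, 4], expected, rtol=1e-6)

    def test_singular_affine_rejected(self):
        mask = AttentionMask(0, 0, 0, np.zeros((2, 2, 2)), np.eye(4))
        with pytest.raises(ValueError, match="singular"):
            upsample_to_input(mask, (4, 4, 4), np.zeros((4, 4)))


class TestExport:
    def test_file_counts_roundtrip_and_manifest(self, small_setup, tmp_path):
        model, instances, _ = small_setup
        bundle = collect_masks(model, instances, 8)
        manifest = export_masks(bundle, tmp_path)
        n_stages, n_cond = 4, 2
        n_channels = sum(bundle.n_channels(s) for s in range(n_stages))
        expected_niftis = n_channels * (n_cond + 1) + n_channels * n_cond
        niftis = [p for p in manifest if p.endswith(".nii.gz")]
        assert len(niftis) == expected_niftis
        assert len([p for p in manifest if p.endswith(".png")]) == n_stages
        for p in manifest:
            assert Path(p).exists()
        assert json.loads((tmp_path / "manifest.json").read_text()) == manifest
        # reload one mask and compare to the bundle
        target = bundle.get(2, 1, AVERAGE)
        img = nib.load(tmp_path / "mask_stage-2_ch-1_cond-average.nii.gz")
        np.testing.assert_allclose(
            np.asarray(img.get_fdata()), target.data, rtol=1e-6
        )
        np.testing.assert_allclose(img.affine, target.affine, atol=1e-5)
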