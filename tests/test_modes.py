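"""Reconstruction, mode maps, classification, grouping and overlays."""

import numpy as np
import pytest

from bleachdmd import (
    BleachStack,
    ModeGroup,
    classify_modes,
    default_mode_groups,
    fit_dmd,
    group_reconstruct,
    mode_weight_maps,
    reconstruct,
    render_overlay,
)
from conftest import exponential_stack


def two_fluorophore_stack(n_frames=50):
    h, w = 8, 12
    left = np.zeros((h, w), bool)
    left[:, :5] = True
    right = np.zeros((h, w), bool)
    right[:, 7:] = True
    return exponential_stack([left, right], [0.01, 0.2], n_frames=n_frames), left, right


class TestReconstruct:
    def test_full_reconstruction_of_exact_rank_input(self, rank2_toy):
        model = fit_dmd(rank2_toy, rank=2)
        rec = reconstruct(model)
        err = np.linalg.norm(rec.frames - rank2_toy.frames) / np.linalg.norm(rank2_toy.frames)
        assert err <= 1e-8

    def test_sum_of_singletons_equals_all_modes(self, paper_model):
        full = reconstruct(paper_model, n_frames=20).frames
        parts = sum(
            reconstruct(paper_model, n_frames=20, which_modes=[j]).frames
            for j in range(paper_model.rank)
        )
        assert np.allclose(parts, full, atol=1e-10 * np.abs(full).max())

    def test_partition_linearity(self, paper_model):
        full = reconstruct(paper_model, n_frames=30).frames
        split = (
            reconstruct(paper_model, n_frames=30, which_modes=[0]).frames
            + reconstruct(paper_model, n_frames=30, which_modes=[1, 2]).frames
        )
        assert np.allclose(split, full, atol=1e-10 * np.abs(full).max())

    def test_reconstruction_tracks_region_means(self, paper_sim, paper_model):
        stack, truth = paper_sim
        rec = reconstruct(paper_model)
        for label, mask in truth.masks.items():
            orig = stack.frames[:, mask].mean(axis=1)
            approx = rec.frames[:, mask].mean(axis=1)
            # within 6% of the initial intensity everywhere along the decay
            assert np.max(np.abs(orig - approx)) < 0.06 * 190

    def test_total_intensity_non_increasing(self, paper_model):
        rec = reconstruct(paper_model)
        totals = rec.frames.sum(axis=(1, 2))
        assert np.all(np.diff(totals) <= 0)

    def test_empty_subset_rejected(self, paper_model):
        with pytest.raises(ValueError):
            reconstruct(paper_model, which_modes=[])


class TestModeMaps:
    def test_one_map_per_mode_with_frame_shape(self, paper_model):
        maps = mode_weight_maps(paper_model)
        assert len(maps) == paper_model.rank
        for mm in maps:
            assert mm.real_image.shape == paper_model.frame_shape

    def test_real_eigenvalue_modes_have_negligible_imag(self, paper_model):
        for mm in mode_weight_maps(paper_model):
            scale = np.abs(mm.real_image).max()
            assert np.abs(mm.imag_image).max() <= 1e-8 * scale

    def test_conjugate_pair_maps_mirror_imaginary_parts(self):
        t = np.arange(40)
        rng = np.random.default_rng(5)
        p1, p2 = rng.normal(size=(2, 4, 6))
        frames = (
            p1[None] * (np.exp(-0.01 * t) * np.cos(0.4 * t))[:, None, None]
            + p2[None] * (np.exp(-0.01 * t) * np.sin(0.4 * t))[:, None, None]
        )
        model = fit_dmd(BleachStack(frames), rank=2)
        m0, m1 = mode_weight_maps(model)
        assert np.allclose(m0.real_image, m1.real_image, atol=1e-8)
        assert np.allclose(m0.imag_image, -m1.imag_image, atol=1e-8)

    def test_each_decaying_map_peaks_in_one_region(self, paper_sim, paper_model):
        _, truth = paper_sim
        regions = list(truth.masks.values())
        claimed = set()
        for mm in mode_weight_maps(paper_model):
            cmap = mm.contribution_image
            means = [cmap[m].mean() for m in regions]
            best = int(np.argmax(means))
            assert means[best] > 3 * max(
                abs(v) for i, v in enumerate(means) if i != best
            )
            claimed.add(best)
        assert claimed == {0, 1, 2}


class TestClassify:
    def test_paper_stack_modes_all_decay(self, paper_model):
        assert classify_modes(paper_model) == ["decaying"] * 3

    def test_oscillatory_pair_detected(self):
        t = np.arange(40)
        rng = np.random.default_rng(5)
        p1, p2 = rng.normal(size=(2, 4, 6))
        frames = (
            p1[None] * (np.exp(-0.001 * t) * np.cos(0.2 * t))[:, None, None]
            + p2[None] * (np.exp(-0.001 * t) * np.sin(0.2 * t))[:, None, None]
        )
        model = fit_dmd(BleachStack(frames), rank=2)
        assert classify_modes(model) == ["oscillatory", "oscillatory"]

    def test_constant_mode_detected(self):
        model = fit_dmd(BleachStack(np.full((8, 3, 3), 7.0)), rank=1)
        assert classify_modes(model) == ["constant"]

    def test_negative_tolerance_rejected(self, paper_model):
        with pytest.raises(ValueError):
            classify_modes(paper_model, tol=-1.0)


class TestGroups:
    def test_single_group_of_all_modes_is_full_reconstruction(self, paper_model):
        groups = [ModeGroup("all", list(range(paper_model.rank)))]
        out = group_reconstruct(paper_model, groups, n_frames=10)
        full = reconstruct(paper_model, n_frames=10)
        assert np.allclose(out["all"].frames, full.frames, atol=1e-10)

    def test_per_mode_groups_recover_closed_form_decays(self):
        stack, left, right = two_fluorophore_stack()
        model = fit_dmd(stack, rank=2)
        groups = default_mode_groups(model)
        out = group_reconstruct(model, groups, n_frames=stack.n_frames)
        t = stack.times
        slow = out["background"].frames[:, left].mean(axis=1)
        fast = out["probe"].frames[:, right].mean(axis=1)
        assert np.allclose(slow, 100 * np.exp(-0.01 * t), rtol=0.05, atol=0.5)
        assert np.allclose(fast, 100 * np.exp(-0.2 * t), rtol=0.05, atol=0.5)

    def test_duplicated_group_gives_identical_stacks(self, paper_model):
        groups = [ModeGroup("a", [1]), ModeGroup("b", [1])]
        out = group_reconstruct(paper_model, groups, n_frames=5)
        assert np.array_equal(out["a"].frames, out["b"].frames)

    def test_invalid_index_rejected(self, paper_model):
        with pytest.raises(ValueError):
            group_reconstruct(paper_model, [ModeGroup("x", [99])], n_frames=5)

    def test_duplicate_indices_within_group_rejected(self):
        with pytest.raises(ValueError):
            ModeGroup("x", [1, 1])

    def test_heuristic_puts_slowest_mode_in_background(self, paper_model):
        groups = {g.label: g.mode_indices for g in default_mode_groups(paper_model)}
        slowest = int(np.argmax(paper_model.omegas.real))
        assert groups["background"] == [slowest]
        assert slowest not in groups["probe"]


class TestOverlay:
    def test_zero_second_group_gives_single_channel(self):
        a = BleachStack(np.random.default_rng(0).random((4, 5, 6)))
        b = BleachStack(np.zeros((4, 5, 6)))
        rgb = render_overlay(a, b, 0)
        assert rgb[..., 1].max() == 0 and rgb[..., 2].max() == 0
        assert rgb[..., 0].max() > 0

    def test_identical_groups_have_equal_channels(self):
        a = BleachStack(np.random.default_rng(1).random((4, 5, 6)))
        rgb = render_overlay(a, a, 2)
        assert np.array_equal(rgb[..., 0], rgb[..., 1])

    def test_fast_channel_dims_while_slow_persists(self):
        stack, left, right = two_fluorophore_stack()
        model = fit_dmd(stack, rank=2)
        out = group_reconstruct(model, default_mode_groups(model), n_frames=stack.n_frames)
        first = render_overlay(out["background"], out["probe"], 0)
        last = render_overlay(out["background"], out["probe"], stack.n_frames - 1)
        fast_drop = last[..., 1].mean() / first[..., 1].mean()
        slow_drop = last[..., 0].mean() / first[..., 0].mean()
        assert fast_drop < 0.05 < slow_drop

    def test_shape_mismatch_rejected(self):
        a = BleachStack(np.zeros((3, 4, 4)))
        b = BleachStack(np.zeros((3, 4, 5)))
        with pytest.raises(ValueError):
            render_overlay(a, b, 0)

    def test_frame_out_of_range_rejected(self):
        a = BleachStack(np.zeros((3, 4, 4)))
        with pytest.raises(ValueError):
            render_overlay(a, a, 3)
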