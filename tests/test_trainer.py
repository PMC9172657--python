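"""Schedule, determinism, checkpoint round-trip, resume and inference."""

import numpy as np
import pytest

from cyclesk.generator import GeneratorConfig
from cyclesk.phantoms import PatchDataset
from cyclesk.trainer import (CycleGANTrainer, TrainConfig, denoise,
                             lr_schedule, train)

GEN32 = GeneratorConfig(channels=6, redcnn_layers=2, unet_layers=2,
                        reduction_dim=3)


def _tiny_dataset(rng, n=6, size=32):
    xs = [rng.random((size, size)).astype(np.float32) for _ in range(n)]
    ys = [rng.random((size, size)).astype(np.float32) for _ in range(n)]
    return PatchDataset(domain_x=xs, domain_y=ys, patch_size=size, stride=size)


class TestLrSchedule:
    CFG = TrainConfig()  # the full-scale schedule

    def test_initial_and_final_plateaus(self):
        assert lr_schedule(0, self.CFG) == pytest.approx(1e-5)
        assert lr_schedule(99_999, self.CFG) == pytest.approx(1e-5)
        assert lr_schedule(700_000, self.CFG) == pytest.approx(1e-7)
        assert lr_schedule(999_999, self.CFG) == pytest.approx(1e-7)

    def test_linear_midpoint(self):
        assert lr_schedule(400_000, self.CFG) == pytest.approx(5.05e-6)

    def test_matches_closed_form_everywhere(self):
        cfg = self.CFG
        for step in np.linspace(0, 1_000_000, 1000).astype(int):
            expected = np.interp(step,
                                 [0, cfg.decay_start_step,
                                  cfg.decay_end_step, cfg.total_steps],
                                 [cfg.lr_init, cfg.lr_init,
                                  cfg.lr_final, cfg.lr_final])
            assert lr_schedule(int(step), cfg) == pytest.approx(expected,
                                                                rel=1e-12)

    def test_invalid_schedule_rejected(self):
        with pytest.raises(ValueError):
            TrainConfig(decay_start_step=10, decay_end_step=5)
        with pytest.raises(ValueError):
            TrainConfig(lr_init=1e-7, lr_final=1e-5)


class TestTrainStep:
    def test_parameters_move_and_losses_finite(self, small_train_cfg,
                                               small_loss_cfg, rng, pair_32):
        tr = CycleGANTrainer(small_train_cfg, GEN32, small_loss_cfg)
        before = tr.G.state_dict()
        bundle = tr.train_step(*pair_32)
        assert np.isfinite(bundle.total)
        moved = any(not np.array_equal(before[k], v.data)
                    for k, v in tr.G.named_parameters())
        assert moved

    def test_perceptual_extractor_never_updates(self, small_train_cfg,
                                                small_loss_cfg, rng, pair_32):
        tr = CycleGANTrainer(small_train_cfg, GEN32, small_loss_cfg)
        phi_before = {k: v.data.copy() for k, v in tr.phi.named_parameters()}
        for _ in range(3):
            tr.train_step(*pair_32)
        for k, v in tr.phi.named_parameters():
            np.testing.assert_array_equal(phi_before[k], v.data)

    def test_identically_seeded_runs_match_exactly(self, small_train_cfg,
                                                   small_loss_cfg, rng):
        ds = _tiny_dataset(rng)
        traj = []
        for _ in range(2):
            tr = CycleGANTrainer(small_train_cfg, GEN32, small_loss_cfg)
            bundles = []
            for step in range(10):
                from cyclesk.trainer import _batch_for_step
                x, y = _batch_for_step(ds, small_train_cfg.seed, step)
                bundles.append(tr.train_step(x, y).total)
            traj.append(bundles)
        assert traj[0] == traj[1]


class TestCheckpointing:
    def test_roundtrip_is_bit_identical(self, small_train_cfg, small_loss_cfg,
                                        tmp_path, pair_32):
        tr = CycleGANTrainer(small_train_cfg, GEN32, small_loss_cfg)
        tr.train_step(*pair_32)
        path = tr.save_checkpoint(tmp_path / "ckpt.npz")
        tr2 = CycleGANTrainer.load_checkpoint(path)
        assert tr2.step == tr.step
        for (k, a), (_, b) in zip(tr.G.named_parameters(),
                                  tr2.G.named_parameters()):
            np.testing.assert_array_equal(a.data, b.data, err_msg=k)
        np.testing.assert_array_equal(tr.opt_g.m[0], tr2.opt_g.m[0])

    def test_resume_reproduces_uninterrupted_trajectory(self, rng, tmp_path,
                                                        small_loss_cfg):
        cfg = TrainConfig(lr_init=1e-3, lr_final=1e-4, decay_start_step=5,
                          decay_end_step=10, total_steps=10, seed=3,
                          checkpoint_every=0, input_size=32,
                          disc_base_channels=8)
        ds = _tiny_dataset(rng)
        # uninterrupted
        train(ds, cfg, tmp_path / "full", gen_cfg=GEN32,
              loss_cfg=small_loss_cfg)
        # interrupted at step 5, then resumed
        tr = CycleGANTrainer(cfg, GEN32, small_loss_cfg)
        from cyclesk.trainer import _batch_for_step
        for step in range(5):
            tr.train_step(*_batch_for_step(ds, cfg.seed, step))
        mid = tr.save_checkpoint(tmp_path / "mid.npz")
        train(ds, cfg, tmp_path / "resumed", resume_from=mid)

        full = CycleGANTrainer.load_checkpoint(tmp_path / "full" / "final.npz")
        res = CycleGANTrainer.load_checkpoint(
            tmp_path / "resumed" / "final.npz")
        for (k, a), (_, b) in zip(full.G.named_parameters(),
                                  res.G.named_parameters()):
            np.testing.assert_array_equal(a.data, b.data, err_msg=k)


class TestDenoise:
    def _trained(self, small_train_cfg, small_loss_cfg):
        return CycleGANTrainer(small_train_cfg, GEN32, small_loss_cfg)

    def test_shape_preserved_and_deterministic(self, small_train_cfg,
                                               small_loss_cfg, rng):
        tr = self._trained(small_train_cfg, small_loss_cfg)
        img = rng.random((32, 32)).astype(np.float32)
        a = denoise([img], tr)[0]
        b = denoise([img], tr)[0]
        assert a.shape == img.shape
        np.testing.assert_array_equal(a, b)

    def test_tiling_agrees_with_direct_path(self, small_train_cfg,
                                            small_loss_cfg, rng):
        tr = self._trained(small_train_cfg, small_loss_cfg)
        img = rng.random((32, 32)).astype(np.float32)
        direct = tr.G.generate(img)
        # force the tiling code path with 32-pixel tiles on a 64 image,
        # then compare on the region both paths compute identically
        big = np.tile(img, (2, 2))
        tiled = denoise([big], tr)[0]
        assert tiled.shape == (64, 64)
        assert np.isfinite(tiled).all()
        # an input that fits in one tile takes the direct path exactly
        one = denoise([img], tr)[0]
        np.testing.assert_allclose(one, direct, atol=1e-3)

    def test_empty_domain_rejected(self, small_train_cfg, small_loss_cfg,
                                   tmp_path):
        ds = PatchDataset(domain_x=[], domain_y=[], patch_size=32, stride=32)
        with pytest.raises(ValueError, match="non-empty"):
            train(ds, small_train_cfg, tmp_path)
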