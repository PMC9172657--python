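"""Cycle-consistent adversarial training loop.

Two generators (G: low-dose -> normal-dose, F: normal-dose -> low-dose) and
two patch discriminators are optimized with Adam at batch size 1. Each step:
discriminators first (on detached fakes), then both generators jointly on
adversarial + lambda * cycle + perceptual terms. The learning rate is held at
``lr_init``, decays linearly between ``decay_start_step`` and
``decay_end_step`` down to ``lr_final``, and stays there. Training is fully
deterministic given the seed, and checkpoints capture every parameter,
optimizer moment and the RNG position so a resumed run reproduces the
uninterrupted loss trajectory exactly.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from .discriminator import PatchDiscriminator, n_stages_for
from .generator import GeneratorConfig, SKGenerator
from .losses import (LossBundle, LossConfig, PerceptualExtractor,
                     adversarial_loss, cycle_loss, perceptual_loss, total_loss)
from .nn import Adam, Tensor
from .phantoms import PatchDataset

__all__ = ["TrainConfig", "CycleGANTrainer", "lr_schedule", "train", "denoise"]


@dataclass(frozen=True)
class TrainConfig:
    """Optimization schedule; defaults are the full-scale run."""

    lr_init: float = 1e-5
    lr_final: float = 1e-7
    decay_start_step: int = 100_000
    decay_end_step: int = 700_000
    total_steps: int = 1_000_000
    batch_size: int = 1
    beta1: float = 0.9
    beta2: float = 0.999
    seed: int = 0
    checkpoint_every: int = 100_000
    input_size: int = 256            # nominal patch side fed to the networks
    disc_base_channels: int = 64

    def __post_init__(self):
        if not (self.decay_start_step < self.decay_end_step
                <= self.total_steps):
            raise ValueError("need decay_start < decay_end <= total_steps")
        if not (0 < self.lr_final < self.lr_init):
            raise ValueError("need 0 < lr_final < lr_init")


def lr_schedule(step: int, cfg: TrainConfig) -> float:
    """Piecewise-linear schedule: flat, linear decay, flat."""
    if step < cfg.decay_start_step:
        return cfg.lr_init
    if step >= cfg.decay_end_step:
        return cfg.lr_final
    frac = (step - cfg.decay_start_step) / (
        cfg.decay_end_step - cfg.decay_start_step)
    return cfg.lr_init + frac * (cfg.lr_final - cfg.lr_init)


def _to_batch(img: np.ndarray) -> Tensor:
    a = np.asarray(img, np.float32)
    if a.ndim == 2:
        a = a[None, None]
    elif a.ndim == 3:
        a = a[:, None]
    return Tensor(a)


class CycleGANTrainer:
    """Holds the four networks, the frozen extractor and optimizer state."""

    def __init__(self, cfg: TrainConfig,
                 gen_cfg: GeneratorConfig | None = None,
                 loss_cfg: LossConfig | None = None):
        self.cfg = cfg
        self.gen_cfg = gen_cfg or GeneratorConfig()
        self.loss_cfg = loss_cfg or LossConfig()
        seed = cfg.seed
        self.G = SKGenerator(self.gen_cfg, seed=seed + 11)
        self.F = SKGenerator(self.gen_cfg, seed=seed + 23)
        n_st = n_stages_for(cfg.input_size)
        self.D_X = PatchDiscriminator(cfg.input_size, cfg.disc_base_channels,
                                      seed=seed + 37, n_stages=n_st)
        self.D_Y = PatchDiscriminator(cfg.input_size, cfg.disc_base_channels,
                                      seed=seed + 41, n_stages=n_st)
        self.phi = PerceptualExtractor(
            width_factor=self.loss_cfg.vgg_width_factor, seed=seed + 53)
        kw = dict(lr=cfg.lr_init, beta1=cfg.beta1, beta2=cfg.beta2)
        self.opt_g = Adam(self.G.parameters(), **kw)
        self.opt_f = Adam(self.F.parameters(), **kw)
        self.opt_dx = Adam(self.D_X.parameters(), **kw)
        self.opt_dy = Adam(self.D_Y.parameters(), **kw)
        self.step = 0

    # -- one optimization step ---------------------------------------------

    def train_step(self, x: np.ndarray, y: np.ndarray) -> LossBundle:
        cfg, lcfg = self.cfg, self.loss_cfg
        lr = lr_schedule(self.step, cfg)
        for opt in (self.opt_g, self.opt_f, self.opt_dx, self.opt_dy):
            opt.lr = lr

        tx, ty = _to_batch(x), _to_batch(y)
        y_fake = self.G(tx)
        x_res = self.F(y_fake)
        x_fake = self.F(ty)
        y_res = self.G(x_fake)

        ls = lcfg.adversarial_form == "least_squares"

        # discriminators on detached fakes
        d_y_real = self.D_Y(ty)
        d_y_fake = self.D_Y(y_fake.detach())
        d_x_real = self.D_X(tx)
        d_x_fake = self.D_X(x_fake.detach())
        adv_g = adversarial_loss(d_y_real.detach(), d_y_fake.detach()).item()
        adv_f = adversarial_loss(d_x_real.detach(), d_x_fake.detach()).item()
        if ls:
            d_loss = (((d_y_real - 1.0) ** 2.0).mean()
                      + (d_y_fake ** 2.0).mean()
                      + ((d_x_real - 1.0) ** 2.0).mean()
                      + (d_x_fake ** 2.0).mean())
        else:
            d_loss = -(adversarial_loss(d_y_real, d_y_fake)
                       + adversarial_loss(d_x_real, d_x_fake))
        self.opt_dx.zero_grad()
        self.opt_dy.zero_grad()
        d_loss.backward()
        self._check_finite({"d_loss": d_loss}, tx, ty)
        self.opt_dx.step()
        self.opt_dy.step()

        # generators: adversarial (through the discriminators) + cycle + perceptual
        d_y_fake2 = self.D_Y(y_fake)
        d_x_fake2 = self.D_X(x_fake)
        if ls:
            g_adv = (((d_y_fake2 - 1.0) ** 2.0).mean()
                     + ((d_x_fake2 - 1.0) ** 2.0).mean())
        else:
            g_adv = ((1.0 - d_y_fake2).clamp(1e-8, 1.0).log().mean()
                     + (1.0 - d_x_fake2).clamp(1e-8, 1.0).log().mean())
        l_cyc = cycle_loss(tx, x_res, ty, y_res)
        l_perc = perceptual_loss(tx, x_res, ty, y_res, self.phi, lcfg)
        g_total = g_adv + lcfg.lambda_cyc * l_cyc + l_perc
        self.opt_g.zero_grad()
        self.opt_f.zero_grad()
        self.D_X.zero_grad()
        self.D_Y.zero_grad()
        g_total.backward()
        self._check_finite({"g_total": g_total, "l_cyc": l_cyc,
                            "l_perc": l_perc}, tx, ty)
        self.opt_g.step()
        self.opt_f.step()

        self.step += 1
        return total_loss(adv_g, adv_f, l_cyc.item(), l_perc.item(), lcfg)

    def _check_finite(self, named: dict[str, Tensor], tx: Tensor,
                      ty: Tensor) -> None:
        for name, t in named.items():
            if not np.isfinite(t.data).all():
                dump = Path("cyclesk_nan_dump.npz")
                np.savez(dump, x=tx.data, y=ty.data,
                         **{k: v.data for k, v in named.items()})
                raise RuntimeError(
                    f"non-finite value in {name} at step {self.step}; "
                    f"tensors dumped to {dump}")

    # -- checkpointing ------------------------------------------------------

    def save_checkpoint(self, path: str | Path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        arrays: dict[str, np.ndarray] = {}
        for prefix, mod in (("G", self.G), ("F", self.F),
                            ("DX", self.D_X), ("DY", self.D_Y)):
            for k, v in mod.state_dict().items():
                arrays[f"{prefix}/{k}"] = v
        for prefix, opt in (("optG", self.opt_g), ("optF", self.opt_f),
                            ("optDX", self.opt_dx), ("optDY", self.opt_dy)):
            for k, v in opt.state_dict().items():
                arrays[f"{prefix}/{k}"] = np.asarray(v)
        meta = {"step": self.step,
                "train_cfg": asdict(self.cfg),
                "gen_cfg": asdict(self.gen_cfg),
                "loss_cfg": {**asdict(self.loss_cfg),
                             "perceptual_layers": list(
                                 self.loss_cfg.perceptual_layers),
                             "perceptual_weights": list(
                                 self.loss_cfg.perceptual_weights)}}
        arrays["meta_json"] = np.frombuffer(
            json.dumps(meta).encode(), dtype=np.uint8)
        np.savez(path, **arrays)
        return path

    @classmethod
    def load_checkpoint(cls, path: str | Path) -> "CycleGANTrainer":
        data = np.load(path)
        meta = json.loads(bytes(data["meta_json"]).decode())
        loss_meta = dict(meta["loss_cfg"])
        loss_meta["perceptual_layers"] = tuple(loss_meta["perceptual_layers"])
        loss_meta["perceptual_weights"] = tuple(loss_meta["perceptual_weights"])
        tr = cls(TrainConfig(**meta["train_cfg"]),
                 GeneratorConfig(**meta["gen_cfg"]),
                 LossConfig(**loss_meta))
        for prefix, mod in (("G", tr.G), ("F", tr.F),
                            ("DX", tr.D_X), ("DY", tr.D_Y)):
            mod.load_state_dict(
                {k[len(prefix) + 1:]: data[k] for k in data.files
                 if k.startswith(prefix + "/")})
        for prefix, opt in (("optG", tr.opt_g), ("optF", tr.opt_f),
                            ("optDX", tr.opt_dx), ("optDY", tr.opt_dy)):
            opt.load_state_dict(
                {k[len(prefix) + 1:]: data[k] for k in data.files
                 if k.startswith(prefix + "/")})
        tr.step = int(meta["step"])
        return tr


def _batch_for_step(dataset: PatchDataset, seed: int,
                    step: int) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic unpaired pair for a given step.

    Each domain follows its own sequence of per-epoch permutations, so the
    pairing of X and Y samples is arbitrary and the schedule is a pure
    function of (seed, step) — which is what makes resume exact.
    """
    nx, ny = len(dataset.domain_x), len(dataset.domain_y)
    ex, px = divmod(step, nx)
    ey, py = divmod(step, ny)
    ox = np.random.default_rng((seed, 1, ex)).permutation(nx)
    oy = np.random.default_rng((seed, 2, ey)).permutation(ny)
    return dataset.domain_x[ox[px]], dataset.domain_y[oy[py]]


def train(dataset: PatchDataset, cfg: TrainConfig,
          out_dir: str | Path,
          gen_cfg: GeneratorConfig | None = None,
          loss_cfg: LossConfig | None = None,
          resume_from: str | Path | None = None,
          log_every: int = 10,
          progress: bool = False) -> Path:
    """Run the loop for ``cfg.total_steps`` steps; returns the final checkpoint."""
    if not dataset.domain_x or not dataset.domain_y:
        raise ValueError("both training domains must be non-empty")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if resume_from is not None:
        trainer = CycleGANTrainer.load_checkpoint(resume_from)
    else:
        trainer = CycleGANTrainer(cfg, gen_cfg, loss_cfg)
    log_path = out_dir / "losses.jsonl"
    t0 = time.time()
    with open(log_path, "a") as log:
        while trainer.step < cfg.total_steps:
            x, y = _batch_for_step(dataset, cfg.seed, trainer.step)
            bundle = trainer.train_step(x, y)
            s = trainer.step
            if s % log_every == 0 or s == cfg.total_steps:
                log.write(json.dumps(
                    {"step": s, "l_gan_g": bundle.l_gan_g,
                     "l_gan_f": bundle.l_gan_f, "l_cyc": bundle.l_cyc,
                     "l_perc": bundle.l_perc, "total": bundle.total,
                     "lr": lr_schedule(s - 1, cfg),
                     "wall_s": round(time.time() - t0, 2)}) + "\n")
            if progress and s % 50 == 0:
                print(f"step {s}/{cfg.total_steps} total={bundle.total:.4f}")
            if cfg.checkpoint_every and s % cfg.checkpoint_every == 0:
                trainer.save_checkpoint(out_dir / f"step_{s:08d}.npz")
    final = trainer.save_checkpoint(out_dir / "final.npz")
    return final


def denoise(images: list[np.ndarray],
            checkpoint: str | Path | CycleGANTrainer,
            tile_overlap: int | None = None) -> list[np.ndarray]:
    """Apply the trained low-dose -> normal-dose generator G.

    Inputs larger than the training patch size are tiled with half-tile
    overlap and blended by uniform averaging.
    """
    trainer = (checkpoint if isinstance(checkpoint, CycleGANTrainer)
               else CycleGANTrainer.load_checkpoint(checkpoint))
    tile = trainer.cfg.input_size
    out = []
    for img in images:
        img = np.asarray(img, np.float32)
        h, w = img.shape
        if h <= tile and w <= tile:
            out.append(trainer.G.generate(img))
            continue
        step = tile_overlap if tile_overlap is not None else tile // 2
        acc = np.zeros((h, w), np.float64)
        weight = np.zeros((h, w), np.float64)
        rows = sorted({min(r, h - tile) for r in range(0, h, step)})
        cols = sorted({min(c, w - tile) for c in range(0, w, step)})
        for r in rows:
            for c in cols:
                patch = trainer.G.generate(img[r:r + tile, c:c + tile])
                acc[r:r + tile, c:c + tile] += patch
                weight[r:r + tile, c:c + tile] += 1.0
        out.append((acc / weight).astype(np.float32))
    return out
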