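"""Adversarial training loop for the actin-to-nucleus translator.

Each iteration draws a minibatch, takes one generator step under

    L_G = L_rec(alpha) + gan_weight * L_gan_G

with the reconstruction term applied at every decoder resolution (ground
truth and mask are average/max-pooled to match; auxiliary levels get half
weight), then one discriminator step on the same fake images (detached).
Both networks use Adam.  The loop is a pure function of (data, config):
identical inputs and seed give identical loss histories and parameters.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .autograd import Tensor
from .layers import Adam
from .model import (Discriminator, LossBreakdown, ModelConfig, Translator,
                    _as_batched, _rec_terms)

__all__ = ["TrainState", "TrainingDiverged", "train", "predict",
           "save_checkpoint", "load_checkpoint", "write_training_log"]


class TrainingDiverged(RuntimeError):
    """Raised when a loss becomes non-finite during training."""


@dataclass
class TrainState:
    """Result of a training run: networks, config, and per-iteration losses."""

    iteration: int
    config: ModelConfig
    generator: Translator
    discriminator: Discriminator
    loss_history: list[LossBreakdown] = field(default_factory=list)
    rng_state: dict | None = None

    def __post_init__(self):
        if len(self.loss_history) != self.iteration:
            raise ValueError("loss_history length must equal iteration count")


def _pool_gt(gt: np.ndarray, mask: np.ndarray, side: int
             ) -> tuple[np.ndarray, np.ndarray]:
    """Downsample ground truth (mean) and mask (max) to ``side`` pixels."""
    B, _, H, _ = gt.shape
    f = H // side
    if f == 1:
        return gt, mask
    g = gt.reshape(B, 1, side, f, side, f).mean(axis=(3, 5))
    m = mask.reshape(B, 1, side, f, side, f).max(axis=(3, 5))
    return g, m


def train(train_pairs, masks, cfg: ModelConfig,
          iterations: int | None = None) -> TrainState:
    """Train the translator on (actin, nucleus) pairs with nucleus masks.

    Parameters
    ----------
    train_pairs
        Sequence of objects with ``.actin`` and ``.nucleus`` 2D arrays in
        [0, 1] (e.g. :class:`~actin2nucleus.synthetic.ImagePair`), or a
        tuple ``(actin_stack, nucleus_stack)`` of (n, H, W) arrays.
    masks
        (n, H, W) binary nucleus footprints aligned with the pairs; the M
        of the weighted reconstruction loss.
    """
    if isinstance(train_pairs, tuple):
        actin, nucleus = (np.asarray(a, np.float32) for a in train_pairs)
    else:
        actin = np.stack([np.asarray(p.actin, np.float32) for p in train_pairs])
        nucleus = np.stack([np.asarray(p.nucleus, np.float32) for p in train_pairs])
    masks = np.asarray(masks, np.float32)
    n = actin.shape[0]
    if n < 2:
        raise ValueError("need at least 2 training pairs")
    if masks.shape != nucleus.shape:
        raise ValueError("masks must align with the nucleus images")
    iters = cfg.max_iterations if iterations is None else iterations

    gen = Translator(cfg)
    disc = Discriminator(cfg)
    opt_g = Adam(gen.parameters(), lr=cfg.learning_rate_g)
    opt_d = Adam(disc.parameters(), lr=cfg.learning_rate_d)
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 0x545249]))

    actin = actin[:, None]      # NCHW
    nucleus = nucleus[:, None]
    masks = masks[:, None]
    history: list[LossBreakdown] = []

    for it in range(iters):
        idx = rng.integers(0, n, size=min(cfg.batch_size, n))
        x, y, m = actin[idx], nucleus[idx], masks[idx]

        # -- generator step (current discriminator) ------------------------
        outputs = gen.forward(x)
        fg_t, bg_t, total_t = _rec_terms(outputs[-1], y, m, cfg.alpha)
        rec_t = total_t
        for out in outputs[:-1]:
            side = out.shape[-1]
            y_s, m_s = _pool_gt(y, m, side)
            _, _, aux = _rec_terms(out, y_s, m_s, cfg.alpha)
            rec_t = rec_t + 0.5 * aux
        fake_logit = disc.logits(outputs[-1])
        g_gan_t = (-fake_logit).softplus().mean()      # -log D(fake)
        loss_g = rec_t + cfg.gan_weight * g_gan_t
        if not np.isfinite(loss_g.data):
            raise TrainingDiverged(f"generator loss non-finite at iteration {it}")
        gen.zero_grad()
        loss_g.backward()
        opt_g.step()

        # -- discriminator step on detached fakes ---------------------------
        fake = outputs[-1].data.copy()
        real_logit = disc.logits(y)
        fake_logit_d = disc.logits(fake)
        loss_d = ((-real_logit).softplus().mean()
                  + fake_logit_d.softplus().mean())    # -logD(real)-log(1-D(fake))
        if not np.isfinite(loss_d.data):
            raise TrainingDiverged(f"discriminator loss non-finite at iteration {it}")
        disc.zero_grad()
        loss_d.backward()
        opt_d.step()

        history.append(LossBreakdown(
            rec_foreground=float(fg_t.data),
            rec_background=float(bg_t.data),
            rec_total=float(total_t.data),
            gan_generator=float(g_gan_t.data),
            gan_discriminator=float(loss_d.data)))

    return TrainState(iteration=iters, config=cfg, generator=gen,
                      discriminator=disc, loss_history=history,
                      rng_state=rng.bit_generator.state)


def predict(state: TrainState, actin_image: np.ndarray) -> np.ndarray:
    """Generate the nucleus channel for one actin image (H, W) in [0, 1]."""
    if state.generator is None:
        raise ValueError("state has no trained generator")
    img = np.asarray(actin_image, np.float32)
    if img.ndim != 2:
        raise ValueError("predict expects a single 2D image")
    if img.shape[0] != state.config.image_size_px:
        raise ValueError(
            f"image side {img.shape[0]} != configured "
            f"{state.config.image_size_px}")
    return state.generator.predict_array(img)


# -- persistence -----------------------------------------------------------

def save_checkpoint(state: TrainState, path) -> None:
    """Serialize a TrainState (config + parameters + loss history) to .npz."""
    gstate = {f"g::{k}": v for k, v in state.generator.state_dict().items()}
    dstate = {f"d::{k}": v for k, v in state.discriminator.state_dict().items()}
    np.savez_compressed(
        path,
        __config__=np.frombuffer(
            json.dumps(state.config.to_dict()).encode(), dtype=np.uint8),
        __iteration__=np.array(state.iteration),
        __loss_history__=np.array([lb.as_row() for lb in state.loss_history],
                                  dtype=np.float64).reshape(-1, 5),
        **gstate, **dstate)


def load_checkpoint(path) -> TrainState:
    with np.load(path) as z:
        cfg = ModelConfig(**json.loads(bytes(z["__config__"]).decode()))
        gen = Translator(cfg)
        disc = Discriminator(cfg)
        gen.load_state_dict(
            {k[3:]: z[k] for k in z.files if k.startswith("g::")})
        disc.load_state_dict(
            {k[3:]: z[k] for k in z.files if k.startswith("d::")})
        hist = [LossBreakdown(*row) for row in z["__loss_history__"]]
        return TrainState(iteration=int(z["__iteration__"]), config=cfg,
                          generator=gen, discriminator=disc,
                          loss_history=hist)


def write_training_log(state: TrainState, path) -> None:
    """Per-iteration loss CSV: iteration, rec_fg, rec_bg, rec_total, gan_g, gan_d."""
    with open(path, "w") as fh:
        fh.write("iteration,rec_fg,rec_bg,rec_total,gan_g,gan_d\n")
        for i, lb in enumerate(state.loss_history):
            fh.write(f"{i},{lb.rec_foreground:.6f},{lb.rec_background:.6f},"
                     f"{lb.rec_total:.6f},{lb.gan_generator:.6f},"
                     f"{lb.gan_discriminator:.6f}\n")
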