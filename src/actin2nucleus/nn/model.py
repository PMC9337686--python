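"""Actin-to-nucleus image translator.

The generator follows the coarse stage of a transformer-based image
completion network: a ResNet-style CNN encoder halves the resolution once
per block and embeds the actin image into a low-resolution feature map,
whose row-major flattening (plus a learned position embedding) forms the
token sequence

    z_0 = [x_1; x_2; ...; x_N] + E_pos,

a stack of pre-norm transformer encoder layers

    z'_l = MSA(LN(z_{l-1})) + z_{l-1}
    z_l  = MLP(LN(z'_l)) + z'_l

mixes information globally, and a CNN decoder upsamples back to image
resolution, emitting an auxiliary output image after every upsampling block
(multi-resolution outputs; the final one is the prediction).  A
StyleGAN-like discriminator downsamples images to 4x4 and scores them with
a fully connected head.

Two presets are provided: ``paper`` (256 px, 4 encoder blocks, 12
transformer blocks — the full-scale geometry, not exercised by the test
suite) and ``desk`` (64 px, 2+2 blocks, narrow channels) on which training
completes in minutes on one CPU.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .autograd import Tensor
from .layers import (Adam, Conv2d, LayerNorm, Linear, Module,  # noqa: F401
                     MultiHeadSelfAttention, PixelNorm, TransformerBlock)

__all__ = [
    "ModelConfig", "TokenSequence", "LossBreakdown", "Translator",
    "Discriminator", "weighted_reconstruction_loss", "adversarial_losses",
]


@dataclass
class ModelConfig:
    """Hyperparameters of the translator and its training loop."""

    image_size_px: int = 64
    encoder_blocks: int = 2
    transformer_blocks: int = 2
    attention_heads: int = 4
    token_channels: int = 32
    base_channels: int = 16
    leaky_slope: float = 0.2
    alpha: float = 10.0
    gan_weight: float = 1.0
    learning_rate_g: float = 2e-4
    learning_rate_d: float = 2e-4
    batch_size: int = 8
    max_iterations: int = 1500
    seed: int = 0
    preset: str = "desk"

    def __post_init__(self) -> None:
        if self.image_size_px % (2 ** self.encoder_blocks):
            raise ValueError(
                f"image_size_px={self.image_size_px} not divisible by "
                f"2^{self.encoder_blocks}")
        if self.alpha < 1:
            raise ValueError("alpha must be >= 1")

    @classmethod
    def from_preset(cls, name: str, **overrides) -> "ModelConfig":
        if name == "desk":
            base = dict(image_size_px=64, encoder_blocks=2,
                        transformer_blocks=2, attention_heads=4,
                        token_channels=24, base_channels=12,
                        batch_size=4, max_iterations=1200, preset="desk")
        elif name == "paper":
            base = dict(image_size_px=256, encoder_blocks=4,
                        transformer_blocks=12, attention_heads=4,
                        token_channels=256, base_channels=64,
                        batch_size=8, max_iterations=100_000, preset="paper")
        else:
            raise ValueError(f"unknown preset {name!r}")
        base.update(overrides)
        return cls(**base)

    @property
    def feature_size(self) -> int:
        return self.image_size_px // (2 ** self.encoder_blocks)

    @property
    def n_tokens(self) -> int:
        return self.feature_size ** 2

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class TokenSequence:
    """The transformer's working representation: N tokens of C channels."""

    tokens: Tensor                    # (B, N, C), position embedding included
    position_embedding: np.ndarray    # (N, C)

    @property
    def n(self) -> int:
        return self.tokens.shape[1]

    @property
    def c(self) -> int:
        return self.tokens.shape[2]


@dataclass
class LossBreakdown:
    rec_foreground: float = 0.0
    rec_background: float = 0.0
    rec_total: float = 0.0
    gan_generator: float = 0.0
    gan_discriminator: float = 0.0

    def as_row(self) -> list[float]:
        return [self.rec_foreground, self.rec_background, self.rec_total,
                self.gan_generator, self.gan_discriminator]


class _ResBlock(Module):
    """Two conv+LeakyReLU+PixelNorm stages with an additive skip path."""

    def __init__(self, c_in: int, c_out: int, slope: float,
                 rng: np.random.Generator):
        self.slope = slope
        self.conv1 = Conv2d(c_in, c_out, 3, rng)
        self.conv2 = Conv2d(c_out, c_out, 3, rng)
        self.skip = Conv2d(c_in, c_out, 1, rng) if c_in != c_out else None
        self.norm = PixelNorm()

    def __call__(self, x: Tensor) -> Tensor:
        h = self.norm(self.conv1(x).leaky_relu(self.slope))
        h = self.norm(self.conv2(h).leaky_relu(self.slope))
        s = x if self.skip is None else self.skip(x)
        return h + s


class Encoder(Module):
    """CNN encoder: one residual block + learned stride-2 pooling per level."""

    def __init__(self, cfg: ModelConfig, rng: np.random.Generator):
        self.slope = cfg.leaky_slope
        c = cfg.base_channels
        self.stem = Conv2d(1, c, 3, rng)
        blocks, pools = [], []
        for _ in range(cfg.encoder_blocks):
            blocks.append(_ResBlock(c, c, cfg.leaky_slope, rng))
            pools.append(Conv2d(c, 2 * c, 3, rng, stride=2))
            c *= 2
        self.blocks = blocks
        self.pools = pools
        self.to_tokens = Conv2d(c, cfg.token_channels, 1, rng)

    def __call__(self, x: Tensor) -> Tensor:
        h = self.stem(x).leaky_relu(self.slope)
        for block, pool in zip(self.blocks, self.pools):
            h = pool(block(h)).leaky_relu(self.slope)
        return self.to_tokens(h)          # (B, C_tok, hf, wf)


class Decoder(Module):
    """CNN decoder mirroring the encoder, with per-level output images."""

    def __init__(self, cfg: ModelConfig, rng: np.random.Generator):
        self.slope = cfg.leaky_slope
        c = cfg.base_channels * 2 ** cfg.encoder_blocks
        self.from_tokens = Conv2d(cfg.token_channels, c, 1, rng)
        blocks, heads = [], []
        for _ in range(cfg.encoder_blocks):
            blocks.append(_ResBlock(c, c // 2, cfg.leaky_slope, rng))
            head = Conv2d(c // 2, 1, 1, rng)
            # start the sigmoid outputs near dim-image intensities: a
            # 0.5 start overshoots toward black on sparse targets and
            # saturates the foreground gradient
            head.w.data *= 0.1
            head.b.data[:] = -2.2          # sigmoid(-2.2) ~ 0.1
            heads.append(head)
            c //= 2
        self.blocks = blocks
        self.heads = heads

    def __call__(self, h: Tensor) -> list[Tensor]:
        h = self.from_tokens(h).leaky_relu(self.slope)
        outputs = []
        for block, head in zip(self.blocks, self.heads):
            h = block(h.upsample2x())
            outputs.append(head(h).sigmoid())
        return outputs


class Translator(Module):
    """Generator: encode -> transformer -> decode."""

    def __init__(self, cfg: ModelConfig, rng: np.random.Generator | None = None):
        if rng is None:
            rng = np.random.default_rng(
                np.random.SeedSequence([cfg.seed, 0x47454E]))
        self.cfg = cfg
        self.encoder = Encoder(cfg, rng)
        self.pos_embed = Tensor(
            (0.02 * rng.standard_normal((cfg.n_tokens, cfg.token_channels)))
            .astype(np.float32), requires_grad=True)
        self.transformer = [
            TransformerBlock(cfg.token_channels, cfg.attention_heads, rng)
            for _ in range(cfg.transformer_blocks)]
        self.decoder = Decoder(cfg, rng)

    # -- spec surface ------------------------------------------------------
    def encode(self, actin: Tensor | np.ndarray) -> tuple[Tensor, TokenSequence]:
        x = _as_batched(actin)
        side = x.shape[-1]
        if side % (2 ** self.cfg.encoder_blocks) or side != self.cfg.image_size_px:
            raise ValueError(
                f"image side {side} incompatible with configured "
                f"{self.cfg.image_size_px} px / {self.cfg.encoder_blocks} blocks")
        fmap = self.encoder(x)
        B, C, hf, wf = fmap.shape
        tokens = fmap.transpose(0, 2, 3, 1).reshape(B, hf * wf, C)
        tokens = tokens + self.pos_embed
        return fmap, TokenSequence(tokens, self.pos_embed.data)

    def transformer_apply(self, seq: TokenSequence) -> TokenSequence:
        z = seq.tokens
        for block in self.transformer:
            z = block(z)
        return TokenSequence(z, seq.position_embedding)

    def decode(self, seq: TokenSequence) -> list[Tensor]:
        B, N, C = seq.tokens.shape
        side = int(round(np.sqrt(N)))
        fmap = seq.tokens.reshape(B, side, side, C).transpose(0, 3, 1, 2)
        return self.decoder(fmap)

    def forward(self, actin: Tensor | np.ndarray) -> list[Tensor]:
        _, seq = self.encode(actin)
        seq = self.transformer_apply(seq)
        return self.decode(seq)

    __call__ = forward

    def predict_array(self, actin: np.ndarray) -> np.ndarray:
        """Generate a nucleus image for one actin image (H, W) in [0, 1]."""
        out = self.forward(np.asarray(actin, np.float32))[-1]
        return np.clip(out.data[0, 0], 0.0, 1.0)


class Discriminator(Module):
    """Strided-conv critic: downsample to 4x4 then a fully connected head."""

    def __init__(self, cfg: ModelConfig, rng: np.random.Generator | None = None):
        if rng is None:
            rng = np.random.default_rng(
                np.random.SeedSequence([cfg.seed, 0x444953]))
        self.cfg = cfg
        self.slope = cfg.leaky_slope
        convs = []
        side, c_in, c = cfg.image_size_px, 1, cfg.base_channels
        while side > 4:
            convs.append(Conv2d(c_in, c, 3, rng, stride=2))
            c_in, c = c, min(2 * c, 4 * cfg.base_channels)
            side //= 2
        self.convs = convs
        self.fc = Linear(c_in * side * side, 1, rng)

    def logits(self, image: Tensor | np.ndarray) -> Tensor:
        x = _as_batched(image)
        for conv in self.convs:
            x = conv(x).leaky_relu(self.slope)
        B = x.shape[0]
        return self.fc(x.reshape(B, -1))

    def __call__(self, image: Tensor | np.ndarray) -> Tensor:
        """Realness score in (0, 1) per image: 1 = real, 0 = fake."""
        return self.logits(image).sigmoid()


def _as_batched(image) -> Tensor:
    """Accept (H,W), (B,H,W) or (B,1,H,W) arrays/tensors; return NCHW Tensor."""
    t = image if isinstance(image, Tensor) else Tensor(np.asarray(image, np.float32))
    if t.ndim == 2:
        t = t.reshape(1, 1, *t.shape)
    elif t.ndim == 3:
        t = t.reshape(t.shape[0], 1, t.shape[1], t.shape[2])
    elif t.ndim != 4:
        raise ValueError(f"expected 2D-4D image array, got shape {t.shape}")
    return t


# -- losses ----------------------------------------------------------------

def _rec_terms(i_out: Tensor, i_gt: np.ndarray, mask: np.ndarray,
               alpha: float) -> tuple[Tensor, Tensor, Tensor]:
    """Foreground/background/total L1 terms (sum over pixels, mean over batch).

    Differentiable path used by the trainer; ``weighted_reconstruction_loss``
    is the plain-number wrapper.
    """
    gt = Tensor(np.asarray(i_gt, np.float32))
    m = np.asarray(mask, np.float32)
    diff = (i_out - gt).abs()
    B = diff.shape[0]
    fg = (diff * m).sum() * (1.0 / B)
    bg = (diff * (1.0 - m)).sum() * (1.0 / B)
    total = alpha * fg + bg
    return fg, bg, total


def weighted_reconstruction_loss(i_out, i_gt, mask, alpha: float = 10.0
                                 ) -> LossBreakdown:
    """Pixel-weighted L1 reconstruction loss.

    Nucleus pixels (mask == 1) are up-weighted by ``alpha`` to counter the
    foreground/background class imbalance of mostly-black nucleus images:

        L_rec = alpha * sum(M * |I_out - I_gt|) + sum((1-M) * |I_out - I_gt|)

    summed over pixels and averaged over the batch dimension (if any).
    """
    out = np.asarray(i_out.data if isinstance(i_out, Tensor) else i_out,
                     np.float32)
    gt = np.asarray(i_gt, np.float32)
    m = np.asarray(mask, np.float32)
    if out.shape != gt.shape or out.shape != m.shape:
        raise ValueError(
            f"shape mismatch: out {out.shape}, gt {gt.shape}, mask {m.shape}")
    if not np.isin(m, (0.0, 1.0)).all():
        raise ValueError("mask must be binary (0/1)")
    if alpha < 1:
        raise ValueError("alpha must be >= 1")
    fg_t, bg_t, total_t = _rec_terms(_as_batched(out), _as_batched_np(gt),
                                     _as_batched_np(m), alpha)
    return LossBreakdown(rec_foreground=float(fg_t.data),
                         rec_background=float(bg_t.data),
                         rec_total=float(total_t.data))


def _as_batched_np(a: np.ndarray) -> np.ndarray:
    return _as_batched(a).data


def adversarial_losses(d_real, d_fake) -> tuple[float, float]:
    """Generator / discriminator losses from discriminator scores in (0, 1).

    The discriminator minimizes -E[log D(real)] - E[log(1 - D(fake))] (the
    negated minimax objective); the generator uses the non-saturating form
    -E[log D(fake)].  Returns ``(gan_generator, gan_discriminator)``.
    """
    dr = np.asarray(d_real.data if isinstance(d_real, Tensor) else d_real,
                    np.float64).ravel()
    df = np.asarray(d_fake.data if isinstance(d_fake, Tensor) else d_fake,
                    np.float64).ravel()
    if dr.size == 0 or df.size == 0:
        raise ValueError("empty batch")
    eps = 1e-12
    d_loss = -(np.mean(np.log(dr + eps)) + np.mean(np.log(1.0 - df + eps)))
    g_loss = -np.mean(np.log(df + eps))
    return float(g_loss), float(d_loss)
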