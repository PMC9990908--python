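"""UNETR-style encoder–decoder for 3D multi-organ segmentation.

The input crop is divided into uniform non-overlapping cubic patches that
are flattened to 1D sequences, linearly projected into a K-dimensional
embedding space, and summed with a learnable 1D positional embedding.  A
stack of pre-norm transformer blocks encodes the sequence; hidden states
at selected depths are reshaped back onto the patch grid and merged into a
convolutional decoder through skip connections.  Each decoder stage is a
3x3x3 convolution block followed by a 2x transposed-convolution
upsampling; the bottleneck hidden state enters through a deconvolution
that doubles its resolution.  A final 1x1x1 convolution with softmax
yields per-voxel class probabilities at the original crop resolution.

The default configuration mirrors the full-scale network (patch 16,
K=768, 12 layers); ``ModelConfig.tiny()`` is a CPU-friendly miniature
used throughout the test pipeline.  The training objective is the equally
weighted sum of soft-Dice and cross-entropy losses.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor

__all__ = [
    "ModelConfig",
    "SegModel",
    "patchify",
    "unpatchify",
    "dice_ce_loss",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclass(frozen=True)
class ModelConfig:
    """Architecture hyperparameters.

    ``skip_layers`` lists the transformer depths whose hidden states feed
    the decoder; the deepest listed layer is the bottleneck.  Exactly
    log2(patch_size) depths are required so the deconvolution chains can
    bridge the patch-grid resolution back to full resolution.
    """

    patch_size: int = 16
    embed_dim: int = 768
    n_layers: int = 12
    n_heads: int = 12
    skip_layers: tuple[int, ...] = (3, 6, 9, 12)
    n_classes: int = 11
    input_size: int = 128
    feature_size: int = 16
    mlp_ratio: int = 4

    def __post_init__(self) -> None:
        p = self.patch_size
        if p < 2 or (p & (p - 1)) != 0:
            raise ValueError("patch_size must be a power of two >= 2")
        if self.input_size % p != 0:
            raise ValueError("input_size must be divisible by patch_size")
        if self.embed_dim % self.n_heads != 0:
            raise ValueError("embed_dim must be divisible by n_heads")
        if self.n_classes < 2:
            raise ValueError("need at least background + one foreground class")
        skips = tuple(sorted(self.skip_layers))
        if len(skips) != int(math.log2(p)):
            raise ValueError(
                f"need log2(patch_size)={int(math.log2(p))} skip layers, got {len(skips)}"
            )
        if self.n_layers < max(skips) or min(skips) < 1:
            raise ValueError("skip_layers must lie in 1..n_layers")
        object.__setattr__(self, "skip_layers", skips)

    @classmethod
    def tiny(cls, n_classes: int = 11, input_size: int = 64) -> "ModelConfig":
        """Miniature preset that trains in minutes on one CPU core."""
        return cls(
            patch_size=8, embed_dim=64, n_layers=4, n_heads=4,
            skip_layers=(2, 3, 4), n_classes=n_classes,
            input_size=input_size, feature_size=8,
        )

    @property
    def n_patches(self) -> int:
        return (self.input_size // self.patch_size) ** 3

    @property
    def n_up_stages(self) -> int:
        return int(math.log2(self.patch_size))


def patchify(crop: np.ndarray, patch_size: int) -> np.ndarray:
    """Split a 3D crop into flattened non-overlapping cubic patches.

    Returns an (N, P^3) array in raster order over the patch grid; the
    operation is lossless (see :func:`unpatchify`).
    """
    crop = np.asarray(crop)
    if crop.ndim != 3:
        raise ValueError("crop must be 3D")
    P = int(patch_size)
    if any(s % P for s in crop.shape):
        raise ValueError(f"crop shape {crop.shape} not divisible by patch size {P}")
    gx, gy, gz = (s // P for s in crop.shape)
    t = crop.reshape(gx, P, gy, P, gz, P).transpose(0, 2, 4, 1, 3, 5)
    return t.reshape(gx * gy * gz, P**3)


def unpatchify(patches: np.ndarray, shape: tuple[int, int, int], patch_size: int) -> np.ndarray:
    """Inverse of :func:`patchify` for the given original crop shape."""
    P = int(patch_size)
    gx, gy, gz = (s // P for s in shape)
    t = np.asarray(patches).reshape(gx, gy, gz, P, P, P).transpose(0, 3, 1, 4, 2, 5)
    return t.reshape(gx * P, gy * P, gz * P)


# -- layers ---------------------------------------------------------------

class _Module:
    def named_parameters(self, prefix: str = "") -> list[tuple[str, Tensor]]:
        out: list[tuple[str, Tensor]] = []
        for name, val in vars(self).items():
            if isinstance(val, Tensor) and val.requires_grad:
                out.append((f"{prefix}{name}", val))
            elif isinstance(val, _Module):
                out.extend(val.named_parameters(f"{prefix}{name}."))
            elif isinstance(val, list):
                for i, item in enumerate(val):
                    if isinstance(item, _Module):
                        out.extend(item.named_parameters(f"{prefix}{name}.{i}."))
        return out

    def parameters(self) -> list[Tensor]:
        return [p for _, p in self.named_parameters()]


class _Linear(_Module):
    def __init__(self, rng, n_in: int, n_out: int, dtype=np.float32):
        self.w = Tensor(ad.xavier(rng, (n_in, n_out), n_in, n_out, dtype), requires_grad=True)
        self.b = Tensor(np.zeros(n_out, dtype=dtype), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return (x @ self.w) + self.b


class _LayerNorm(_Module):
    def __init__(self, dim: int, dtype=np.float32):
        self.g = Tensor(np.ones(dim, dtype=dtype), requires_grad=True)
        self.b = Tensor(np.zeros(dim, dtype=dtype), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return ad.layer_norm(x, self.g, self.b)


class _Attention(_Module):
    def __init__(self, rng, dim: int, n_heads: int, dtype=np.float32):
        self.n_heads = n_heads
        self.head_dim = dim // n_heads
        self.q = _Linear(rng, dim, dim, dtype)
        self.k = _Linear(rng, dim, dim, dtype)
        self.v = _Linear(rng, dim, dim, dtype)
        self.proj = _Linear(rng, dim, dim, dtype)

    def __call__(self, x: Tensor) -> Tensor:
        n, dim = x.shape
        h, dh = self.n_heads, self.head_dim
        q = self.q(x).reshape(n, h, dh).transpose((1, 0, 2))
        k = self.k(x).reshape(n, h, dh).transpose((1, 0, 2))
        v = self.v(x).reshape(n, h, dh).transpose((1, 0, 2))
        scores = (q @ k.transpose((0, 2, 1))) * (1.0 / math.sqrt(dh))
        att = ad.softmax(scores, axis=-1)
        out = (att @ v).transpose((1, 0, 2)).reshape(n, dim)
        return self.proj(out)


class _TransformerBlock(_Module):
    """Pre-norm residual block: x + MHA(LN(x)); x + MLP(LN(x))."""

    def __init__(self, rng, dim: int, n_heads: int, mlp_ratio: int, dtype=np.float32):
        self.ln1 = _LayerNorm(dim, dtype)
        self.attn = _Attention(rng, dim, n_heads, dtype)
        self.ln2 = _LayerNorm(dim, dtype)
        self.fc1 = _Linear(rng, dim, dim * mlp_ratio, dtype)
        self.fc2 = _Linear(rng, dim * mlp_ratio, dim, dtype)

    def __call__(self, x: Tensor) -> Tensor:
        x = x + self.attn(self.ln1(x))
        return x + self.fc2(ad.gelu(self.fc1(self.ln2(x))))


class _ConvBlock(_Module):
    """3x3x3 convolution + instance norm + leaky ReLU."""

    def __init__(self, rng, cin: int, cout: int, dtype=np.float32):
        fan_in = cin * 27
        self.w = Tensor(ad.kaiming(rng, (cout, cin, 3, 3, 3), fan_in, dtype), requires_grad=True)
        self.b = Tensor(np.zeros(cout, dtype=dtype), requires_grad=True)
        self.ng = Tensor(np.ones((cout, 1, 1, 1), dtype=dtype), requires_grad=True)
        self.nb = Tensor(np.zeros((cout, 1, 1, 1), dtype=dtype), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        y = ad.conv3d(x, self.w, self.b)
        return ad.leaky_relu(ad.instance_norm3d(y, self.ng, self.nb))


class _Deconv(_Module):
    """2x upsampling via kernel-2 stride-2 transposed convolution."""

    def __init__(self, rng, cin: int, cout: int, dtype=np.float32):
        self.w = Tensor(ad.kaiming(rng, (cin, cout, 2, 2, 2), cin * 8, dtype), requires_grad=True)
        self.b = Tensor(np.zeros(cout, dtype=dtype), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return ad.conv_transpose3d_2x(x, self.w, self.b)


class _SkipChain(_Module):
    """Deconvolution chain lifting a token map to a decoder resolution."""

    def __init__(self, rng, embed_dim: int, width: int, n_ups: int, dtype=np.float32):
        self.first = _Deconv(rng, embed_dim, width, dtype)
        self.rest = []
        for _ in range(n_ups - 1):
            self.rest.append(_ConvBlock(rng, width, width, dtype))
            self.rest.append(_Deconv(rng, width, width, dtype))

    def __call__(self, x: Tensor) -> Tensor:
        x = self.first(x)
        for unit in self.rest:
            x = unit(x)
        return x


class SegModel(_Module):
    """The segmentation network: configuration + learnable parameters."""

    def __init__(self, config: ModelConfig, seed: int = 0, dtype=np.float32):
        rng = np.random.default_rng([int(seed), 7001])
        cfg = config
        self.config = cfg
        K, F, m = cfg.embed_dim, cfg.feature_size, cfg.n_up_stages
        widths = [F * 2**s for s in range(m)]  # widths[s] at resolution /2^s

        self.embed = _Linear(rng, cfg.patch_size**3, K, dtype)
        self.pos = Tensor(
            rng.normal(0.0, 0.02, size=(cfg.n_patches, K)).astype(dtype),
            requires_grad=True,
        )
        self.blocks = [
            _TransformerBlock(rng, K, cfg.n_heads, cfg.mlp_ratio, dtype)
            for _ in range(cfg.n_layers)
        ]
        self.enc0 = _ConvBlock(rng, 1, widths[0], dtype)
        # intermediate skips: shallowest skip layer -> finest resolution
        self.skip_chains = [
            _SkipChain(rng, K, widths[s], m - s, dtype) for s in range(1, m)
        ]
        self.bottleneck_up = _Deconv(rng, K, widths[m - 1], dtype)
        self.dec_convs = []
        self.dec_ups = []
        for s in range(m - 1, 0, -1):
            self.dec_convs.append(_ConvBlock(rng, 2 * widths[s], widths[s], dtype))
            self.dec_ups.append(_Deconv(rng, widths[s], widths[s - 1], dtype))
        self.final_conv = _ConvBlock(rng, 2 * widths[0], widths[0], dtype)
        fan = widths[0]
        self.out_w = Tensor(
            ad.xavier(rng, (cfg.n_classes, widths[0], 1, 1, 1), fan, cfg.n_classes, dtype),
            requires_grad=True,
        )
        self.out_b = Tensor(np.zeros(cfg.n_classes, dtype=dtype), requires_grad=True)

    # -- forward ----------------------------------------------------------

    def _tokens_to_grid(self, tokens: Tensor) -> Tensor:
        g = self.config.input_size // self.config.patch_size
        return tokens.reshape(g, g, g, self.config.embed_dim).transpose((3, 0, 1, 2))

    def forward_tensor(self, crop: np.ndarray) -> Tensor:
        """Forward pass returning the (C, D, H, W) probability tensor."""
        cfg = self.config
        if crop.shape != (cfg.input_size,) * 3:
            raise ValueError(f"crop shape {crop.shape} != {(cfg.input_size,)*3}")
        dtype = self.pos.dtype
        tokens = Tensor(patchify(crop, cfg.patch_size).astype(dtype))
        x = self.embed(tokens) + self.pos
        hidden: dict[int, Tensor] = {}
        for depth, block in enumerate(self.blocks, start=1):
            x = block(x)
            if depth in cfg.skip_layers:
                hidden[depth] = x
        skips = [hidden[d] for d in cfg.skip_layers]  # ascending depth
        m = cfg.n_up_stages

        enc = [self.enc0(Tensor(crop[None].astype(dtype)))]
        for s in range(1, m):
            enc.append(self.skip_chains[s - 1](self._tokens_to_grid(skips[s - 1])))

        up = self.bottleneck_up(self._tokens_to_grid(skips[-1]))
        for i, s in enumerate(range(m - 1, 0, -1)):
            x = ad.concat([up, enc[s]], axis=0)
            x = self.dec_convs[i](x)
            up = self.dec_ups[i](x)
        x = ad.concat([up, enc[0]], axis=0)
        x = self.final_conv(x)
        logits = ad.conv3d(x, self.out_w, self.out_b)
        return ad.softmax(logits, axis=0)

    def forward(self, crop: np.ndarray) -> np.ndarray:
        """Per-voxel class probabilities (C, D, H, W) for one crop."""
        with ad.no_grad():
            return self.forward_tensor(np.asarray(crop)).data

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())


# -- loss -----------------------------------------------------------------

def dice_ce_loss(
    probs: Tensor | np.ndarray,
    target: np.ndarray,
    include_background: bool = True,
    eps: float = 1e-5,
) -> Tensor:
    """Equally weighted soft-Dice + cross-entropy loss.

    ``probs`` is a (C, D, H, W) probability map (channel sums 1); ``target``
    an integer label crop of the same spatial shape with IDs < C.  Soft
    Dice per class is 2*sum(p*g)+eps over sum(p)+sum(g)+eps, averaged over
    classes (background included by default); cross-entropy is the mean
    per-voxel negative log probability of the true class.
    """
    p = probs if isinstance(probs, Tensor) else Tensor(np.asarray(probs))
    target = np.asarray(target)
    C = p.shape[0]
    if p.shape[1:] != target.shape:
        raise ValueError(f"probs spatial shape {p.shape[1:]} != target {target.shape}")
    if target.min() < 0 or target.max() >= C:
        raise ValueError(f"target IDs must be in 0..{C - 1}")
    onehot = np.zeros(p.shape, dtype=p.dtype)
    flat = target.reshape(-1)
    onehot.reshape(C, -1)[flat, np.arange(flat.size)] = 1.0
    oh = Tensor(onehot)

    p_true = (p * oh).sum(axis=0)
    ce = -(p_true.clip_min(1e-12).log().mean())

    inter = (p * oh).sum(axis=(1, 2, 3))
    card = p.sum(axis=(1, 2, 3)) + oh.sum(axis=(1, 2, 3))
    dice = (inter * 2.0 + eps) / (card + eps)
    if include_background:
        dice_mean = dice.mean()
    else:
        sel = np.ones(C, dtype=p.dtype)
        sel[0] = 0.0
        dice_mean = (dice * Tensor(sel)).sum() * (1.0 / (C - 1))
    dice_loss = 1.0 - dice_mean
    return dice_loss * 0.5 + ce * 0.5


# -- checkpoints ----------------------------------------------------------

_CKPT_SCHEMA = 1


def save_checkpoint(model: SegModel, path: str | Path) -> None:
    """Save config (JSON) + parameter blobs into a single .npz archive."""
    meta = {"schema": _CKPT_SCHEMA, "config": asdict(model.config)}
    arrays = {f"param/{name}": p.data for name, p in model.named_parameters()}
    np.savez_compressed(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8), **arrays)


def load_checkpoint(path: str | Path) -> SegModel:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    with np.load(path) as npz:
        meta = json.loads(bytes(npz["__meta__"]).decode())
        if meta.get("schema") != _CKPT_SCHEMA:
            raise ValueError(f"unsupported checkpoint schema {meta.get('schema')}")
        cfgd = meta["config"]
        cfgd["skip_layers"] = tuple(cfgd["skip_layers"])
        model = SegModel(ModelConfig(**cfgd))
        for name, p in model.named_parameters():
            stored = npz[f"param/{name}"]
            if stored.shape != p.data.shape:
                raise ValueError(f"parameter {name} shape mismatch")
            p.data = stored.astype(p.data.dtype)
    return model
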