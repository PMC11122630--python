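"""Segmentation backbones: a U-shaped CNN and a windowed-attention transformer.

The CNN is a classic U-Net split into an :class:`UNetEncoder` and a
:class:`UNetDecoder` so that several decoders (the main one plus the
feature-perturbation auxiliaries, and an EMA teacher copy) can share or
mirror one encoder.  The transformer is a compact Swin-style U-shaped
segmenter over patch embeddings with shifted-window multi-head
self-attention, patch merging on the way down and patch expansion on the
way up.

Both networks satisfy the same forward contract: an image batch
``(N, 1, H, W)`` in, a :class:`SegOutput` out with per-class logits and
softmax probabilities at full input resolution.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import autodiff as ad
from . import nn
from .autodiff import Tensor


@dataclass
class FeaturePyramid:
    """Encoder features: the bottleneck map that perturbations act on,
    plus skip connections ordered finest to coarsest."""

    bottleneck: Tensor
    skips: list[Tensor]


@dataclass
class SegOutput:
    """Per-class score map and its softmax over the class axis."""

    logits: Tensor
    probs: Tensor = field(default=None)

    def __post_init__(self):
        if self.probs is None:
            self.probs = ad.softmax(self.logits, axis=1)

    @property
    def n_classes(self) -> int:
        return self.logits.shape[1]


def _check_batched(x) -> Tensor:
    x = ad.as_tensor(x)
    if x.ndim == 3:  # single (C, H, W) image
        x = ad.reshape(x, (1,) + tuple(x.shape))
    if x.ndim != 4:
        raise ValueError(f"expected image batch (N, C, H, W), got shape {x.shape}")
    return x


class _ConvBlock(nn.Module):
    def __init__(self, in_ch, out_ch, rng):
        super().__init__()
        self.conv1 = nn.Conv2d(in_ch, out_ch, 3, rng)
        self.bn1 = nn.BatchNorm2d(out_ch)
        self.conv2 = nn.Conv2d(out_ch, out_ch, 3, rng)
        self.bn2 = nn.BatchNorm2d(out_ch)

    def forward(self, x):
        x = ad.relu(self.bn1(self.conv1(x)))
        return ad.relu(self.bn2(self.conv2(x)))


class UNetEncoder(nn.Module):
    """Contracting path; ``depth`` resolution levels, channels doubling."""

    def __init__(self, in_ch: int = 1, base_channels: int = 16, depth: int = 4,
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng if rng is not None else np.random.default_rng(0)
        self.depth = depth
        self.base_channels = base_channels
        chans = [base_channels * 2 ** i for i in range(depth)]
        prev = in_ch
        self.blocks = []
        for i, c in enumerate(chans):
            block = _ConvBlock(prev, c, rng)
            self._modules[f"block{i}"] = block
            self.blocks.append(block)
            prev = c

    def forward(self, x) -> FeaturePyramid:
        x = _check_batched(x)
        h, w = x.shape[2], x.shape[3]
        div = 2 ** (self.depth - 1)
        if h % div or w % div:
            raise ValueError(
                f"input spatial size {h}x{w} must be divisible by 2^(depth-1) = {div}")
        skips = []
        for i, block in enumerate(self.blocks):
            x = block(x)
            if i < self.depth - 1:
                skips.append(x)
                x = ad.max_pool2x2(x)
        return FeaturePyramid(bottleneck=x, skips=skips)


class UNetDecoder(nn.Module):
    """Expanding path: bilinear upsampling, skip concatenation, 1x1 head.

    Instantiated once as the main decoder and, with independent
    parameters, once per auxiliary (feature-perturbation) decoder.
    """

    def __init__(self, n_classes: int, base_channels: int = 16, depth: int = 4,
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng if rng is not None else np.random.default_rng(0)
        self.depth = depth
        self.base_channels = base_channels
        chans = [base_channels * 2 ** i for i in range(depth)]
        self.blocks = []
        for i in range(depth - 1):
            cin = chans[depth - 1 - i] + chans[depth - 2 - i]  # upsampled + skip
            cout = chans[depth - 2 - i]
            block = _ConvBlock(cin, cout, rng)
            self._modules[f"up{i}"] = block
            self.blocks.append(block)
        self.head = nn.Conv2d(chans[0], n_classes, 1, rng, padding=0)

    def forward(self, pyramid: FeaturePyramid) -> SegOutput:
        x = pyramid.bottleneck
        if len(pyramid.skips) != self.depth - 1:
            raise ValueError(
                f"pyramid has {len(pyramid.skips)} skips, decoder expects {self.depth - 1}")
        for i, block in enumerate(self.blocks):
            skip = pyramid.skips[-(i + 1)]
            x = ad.upsample_bilinear2x(x)
            if x.shape[2:] != skip.shape[2:]:
                raise ValueError(
                    f"scale mismatch: upsampled {x.shape[2:]} vs skip {skip.shape[2:]}")
            x = block(ad.concat([x, skip], axis=1))
        return SegOutput(logits=self.head(x))


class UNet(nn.Module):
    """Encoder plus main decoder; ``encode``/``decode`` exposed separately."""

    def __init__(self, n_classes: int, in_ch: int = 1, base_channels: int = 16,
                 depth: int = 4, rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng if rng is not None else np.random.default_rng(0)
        self.encoder = UNetEncoder(in_ch, base_channels, depth, rng)
        self.decoder = UNetDecoder(n_classes, base_channels, depth, rng)
        self.n_classes = n_classes

    def encode(self, x) -> FeaturePyramid:
        return self.encoder(x)

    def decode(self, pyramid: FeaturePyramid) -> SegOutput:
        return self.decoder(pyramid)

    def forward(self, x) -> SegOutput:
        return self.decode(self.encode(x))


# ---------------------------------------------------------------------
# Swin-style transformer segmenter
# ---------------------------------------------------------------------

def _window_partition(x: Tensor, h: int, w: int, c: int, win: int) -> Tensor:
    """(B, H, W, C) -> (B * nWindows, win*win, C)."""
    b = x.shape[0]
    x = ad.reshape(x, (b, h // win, win, w // win, win, c))
    x = ad.transpose(x, (0, 1, 3, 2, 4, 5))
    return ad.reshape(x, (b * (h // win) * (w // win), win * win, c))


def _window_reverse(x: Tensor, b: int, h: int, w: int, c: int, win: int) -> Tensor:
    x = ad.reshape(x, (b, h // win, w // win, win, win, c))
    x = ad.transpose(x, (0, 1, 3, 2, 4, 5))
    return ad.reshape(x, (b, h, w, c))


def _relative_index(win: int) -> np.ndarray:
    coords = np.stack(np.meshgrid(np.arange(win), np.arange(win), indexing="ij"))
    flat = coords.reshape(2, -1)
    rel = flat[:, :, None] - flat[:, None, :]
    rel = rel + (win - 1)
    return rel[0] * (2 * win - 1) + rel[1]  # (win^2, win^2)


def _shift_mask(h: int, w: int, win: int, shift: int) -> np.ndarray:
    """Attention mask for shifted windows: -100 on cross-region pairs."""
    img = np.zeros((h, w), dtype=np.int64)
    cnt = 0
    for hs in (slice(0, -win), slice(-win, -shift), slice(-shift, None)):
        for ws in (slice(0, -win), slice(-win, -shift), slice(-shift, None)):
            img[hs, ws] = cnt
            cnt += 1
    img = img.reshape(h // win, win, w // win, win).transpose(0, 2, 1, 3)
    img = img.reshape(-1, win * win)
    mask = (img[:, None, :] != img[:, :, None]).astype(nn.DTYPE) * -100.0
    return mask  # (nWindows, win^2, win^2)


class _WindowAttention(nn.Module):
    def __init__(self, dim: int, heads: int, win: int, rng,
                 use_rel_pos_bias: bool = True):
        super().__init__()
        self.dim = dim
        self.heads = heads
        self.win = win
        self.scale = (dim // heads) ** -0.5
        self.qkv = nn.Linear(dim, 3 * dim, rng)
        self.proj = nn.Linear(dim, dim, rng)
        self.use_rel_pos_bias = use_rel_pos_bias
        if use_rel_pos_bias:
            self.rel_bias = nn.Parameter(
                rng.normal(0.0, 0.02, size=((2 * win - 1) ** 2, heads)))
            self._rel_index = _relative_index(win)

    def forward(self, x: Tensor, mask: np.ndarray | None = None) -> Tensor:
        bw, n, c = x.shape
        hd = c // self.heads
        qkv = self.qkv(x)  # (bw, n, 3c)
        qkv = ad.reshape(qkv, (bw, n, 3, self.heads, hd))
        qkv = ad.transpose(qkv, (2, 0, 3, 1, 4))  # (3, bw, heads, n, hd)
        q, k, v = qkv[0], qkv[1], qkv[2]
        attn = ad.matmul(q, ad.transpose(k, (0, 1, 3, 2))) * self.scale
        if self.use_rel_pos_bias:
            bias = self.rel_bias[self._rel_index]          # (n, n, heads)
            bias = ad.transpose(bias, (2, 0, 1))           # (heads, n, n)
            attn = attn + ad.reshape(bias, (1, self.heads, n, n))
        if mask is not None:
            nw = mask.shape[0]
            attn = ad.reshape(attn, (bw // nw, nw, self.heads, n, n))
            attn = attn + mask[None, :, None, :, :]
            attn = ad.reshape(attn, (bw, self.heads, n, n))
        attn = ad.softmax(attn, axis=-1)
        out = ad.matmul(attn, v)                           # (bw, heads, n, hd)
        out = ad.transpose(out, (0, 2, 1, 3))
        out = ad.reshape(out, (bw, n, c))
        return self.proj(out)


class _SwinBlock(nn.Module):
    def __init__(self, dim: int, heads: int, win: int, shift: int, rng,
                 mlp_ratio: float = 2.0, use_rel_pos_bias: bool = True):
        super().__init__()
        self.win = win
        self.shift = shift
        self.norm1 = nn.LayerNorm(dim)
        self.attn = _WindowAttention(dim, heads, win, rng, use_rel_pos_bias)
        self.norm2 = nn.LayerNorm(dim)
        hidden = int(dim * mlp_ratio)
        self.fc1 = nn.Linear(dim, hidden, rng)
        self.fc2 = nn.Linear(hidden, dim, rng)
        self._masks: dict[tuple[int, int], np.ndarray] = {}

    def forward(self, x: Tensor, h: int, w: int) -> Tensor:
        b, _, c = x.shape
        win = self.win
        # shifting is meaningless (and blocks all cross-attention) when one
        # window already spans the grid
        shift = self.shift if win < min(h, w) else 0
        shortcut = x
        x = self.norm1(x)
        x = ad.reshape(x, (b, h, w, c))
        if shift:
            x = ad.roll(x, (-shift, -shift), axis=(1, 2))
            key = (h, w)
            if key not in self._masks:
                self._masks[key] = _shift_mask(h, w, win, shift)
            mask = self._masks[key]
        else:
            mask = None
        xw = _window_partition(x, h, w, c, win)
        xw = self.attn(xw, mask=mask)
        x = _window_reverse(xw, b, h, w, c, win)
        if shift:
            x = ad.roll(x, (shift, shift), axis=(1, 2))
        x = ad.reshape(x, (b, h * w, c))
        x = shortcut + x
        x = x + self.fc2(ad.gelu(self.fc1(self.norm2(x))))
        return x


class _PatchMerging(nn.Module):
    def __init__(self, dim: int, rng):
        super().__init__()
        self.norm = nn.LayerNorm(4 * dim)
        self.reduce = nn.Linear(4 * dim, 2 * dim, rng, bias=False)

    def forward(self, x: Tensor, h: int, w: int) -> Tensor:
        b, _, c = x.shape
        x = ad.reshape(x, (b, h // 2, 2, w // 2, 2, c))
        x = ad.transpose(x, (0, 1, 3, 2, 4, 5))
        x = ad.reshape(x, (b, (h // 2) * (w // 2), 4 * c))
        return self.reduce(self.norm(x))


class _PatchExpand(nn.Module):
    def __init__(self, dim: int, rng):
        super().__init__()
        self.expand = nn.Linear(dim, 2 * dim, rng, bias=False)
        self.norm = nn.LayerNorm(dim // 2)

    def forward(self, x: Tensor, h: int, w: int) -> Tensor:
        b, _, c = x.shape
        x = self.expand(x)  # (b, hw, 2c)
        x = ad.reshape(x, (b, h, w, 2, 2, c // 2))
        x = ad.transpose(x, (0, 1, 3, 2, 4, 5))
        x = ad.reshape(x, (b, (2 * h) * (2 * w), c // 2))
        return self.norm(x)


class SwinSeg(nn.Module):
    """Compact U-shaped Swin segmenter.

    Two encoder stages (patch merging between), two decoder stages
    (patch expansion between, with a skip from the first stage), a final
    4x patch expansion back to pixel resolution and a linear class head.
    Alternate blocks use shifted windows with the cyclic-shift masking
    scheme.
    """

    def __init__(self, n_classes: int, in_ch: int = 1, patch_size: int = 4,
                 embed_dim: int = 48, heads: int = 2, window: int = 4,
                 blocks_per_stage: int = 2, rng: np.random.Generator | None = None,
                 shifted: bool = True, use_rel_pos_bias: bool = True):
        super().__init__()
        rng = rng if rng is not None else np.random.default_rng(0)
        self.patch_size = patch_size
        self.embed_dim = embed_dim
        self.window = window
        self.in_ch = in_ch
        self.n_classes = n_classes
        self.embed = nn.Linear(in_ch * patch_size ** 2, embed_dim, rng)
        self.embed_norm = nn.LayerNorm(embed_dim)

        def stage(dim, n_blocks, name):
            blocks = []
            for i in range(n_blocks):
                shift = window // 2 if (shifted and i % 2 == 1) else 0
                blk = _SwinBlock(dim, heads, window, shift, rng,
                                 use_rel_pos_bias=use_rel_pos_bias)
                self._modules[f"{name}{i}"] = blk
                blocks.append(blk)
            return blocks

        self.enc1 = stage(embed_dim, blocks_per_stage, "enc1_")
        self.merge = _PatchMerging(embed_dim, rng)
        self.enc2 = stage(2 * embed_dim, blocks_per_stage, "enc2_")
        self.expand = _PatchExpand(2 * embed_dim, rng)
        self.skip_reduce = nn.Linear(2 * embed_dim, embed_dim, rng, bias=False)
        self.dec1 = stage(embed_dim, blocks_per_stage, "dec1_")
        self.final_expand = nn.Linear(embed_dim, patch_size ** 2 * embed_dim, rng, bias=False)
        self.final_norm = nn.LayerNorm(embed_dim)
        self.head = nn.Linear(embed_dim, n_classes, rng)

    def _patchify(self, x: Tensor) -> tuple[Tensor, int, int]:
        n, c, h, w = x.shape
        p = self.patch_size
        gh, gw = h // p, w // p
        x = ad.reshape(x, (n, c, gh, p, gw, p))
        x = ad.transpose(x, (0, 2, 4, 3, 5, 1))
        x = ad.reshape(x, (n, gh * gw, p * p * c))
        return x, gh, gw

    def forward(self, x) -> SegOutput:
        x = _check_batched(x)
        n, c, h, w = x.shape
        p, win = self.patch_size, self.window
        div = p * 2  # two stages: patch grid halves once
        if h % div or w % div:
            raise ValueError(
                f"input spatial size {h}x{w} must be divisible by patch_size*2 = {div}")
        gh, gw = h // p, w // p
        for g, nm in ((gh, "stage-1"), (gw, "stage-1"), (gh // 2, "stage-2"), (gw // 2, "stage-2")):
            if g % win:
                raise ValueError(
                    f"window size {win} does not divide the {nm} patch grid ({g})")
        tok, gh, gw = self._patchify(x)
        tok = self.embed_norm(self.embed(tok))
        for blk in self.enc1:
            tok = blk(tok, gh, gw)
        skip = tok
        tok = self.merge(tok, gh, gw)
        for blk in self.enc2:
            tok = blk(tok, gh // 2, gw // 2)
        tok = self.expand(tok, gh // 2, gw // 2)  # back to (gh, gw, embed)
        tok = self.skip_reduce(ad.concat([tok, skip], axis=-1))
        for blk in self.dec1:
            tok = blk(tok, gh, gw)
        tok = self.final_expand(tok)  # (n, gh*gw, p*p*embed)
        tok = ad.reshape(tok, (n, gh, gw, p, p, self.embed_dim))
        tok = ad.transpose(tok, (0, 1, 3, 2, 4, 5))
        tok = ad.reshape(tok, (n, h * w, self.embed_dim))
        tok = self.head(self.final_norm(tok))  # (n, h*w, classes)
        logits = ad.transpose(ad.reshape(tok, (n, h, w, self.n_classes)), (0, 3, 1, 2))
        return SegOutput(logits=logits)
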