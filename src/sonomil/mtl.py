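"""Stage 1: image-level multi-task network.

One shared backbone produces a feature map ``z`` (stride 16). A light
mask decoder — two two-way attention blocks between ``z`` and a single
learnable mask token, followed by two stride-2 transposed convolutions —
yields the segmentation feature ``s`` (stride 4) and, via a dot product
with the token mapped through a small feed-forward net, the segmentation
probability map. The predicted map then acts as a soft attention gate:
``z_m = s * pool(y_seg)`` feeds the lesion-type head and
``z_c = z * pool(y_seg)`` feeds the image-level metastasis head, so both
classifiers only see evidence inside the predicted lesion. All three
objectives are binary cross-entropies and are optimised jointly; the
gate is not detached, so the classification losses shape the attention.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .autograd import Tensor, avg_pool_to, upsample_bilinear


class ContractError(ValueError):
    pass


# -- reference backbones ---------------------------------------------------


class TinyConvBackbone(nn.Module):
    """Four stride-2 convolution stages; total stride 16.

    A deliberately small stand-in for the published segmentation
    backbones; anything exposing ``stride``, ``channels`` and the same
    call signature can be plugged in instead.
    """

    def __init__(self, rng: np.random.Generator,
                 stage_channels=(12, 24, 32, 32)):
        self.stride = 16
        self.channels = stage_channels[-1]
        c_prev = 1
        self.stages = []
        for c in stage_channels:
            self.stages.append(nn.Conv2d(c_prev, c, 3, rng, stride=2, padding=1))
            c_prev = c

    def forward(self, x: Tensor) -> Tensor:
        for conv in self.stages:
            x = conv(x).relu()
        return x


class TinyAttentionBackbone(nn.Module):
    """Patch embedding (16x16) plus self-attention blocks; stride 16."""

    def __init__(self, rng: np.random.Generator, channels: int = 32,
                 depth: int = 1, heads: int = 4):
        self.stride = 16
        self.channels = channels
        self.embed = nn.Conv2d(1, channels, 16, rng, stride=16)
        self.blocks = [nn.TransformerBlock(channels, heads, 2.0, rng)
                       for _ in range(depth)]

    def forward(self, x: Tensor) -> Tensor:
        feat = self.embed(x)
        n, c, h, w = feat.shape
        seq = feat.reshape(n, c, h * w).transpose(0, 2, 1)
        for blk in self.blocks:
            seq = blk(seq)
        return seq.transpose(0, 2, 1).reshape(n, c, h, w)


# -- mask decoder ----------------------------------------------------------


class TwoWayBlock(nn.Module):
    """Token/image interaction: token self-attention, token->image
    cross-attention, token feed-forward, then image->token cross-attention."""

    def __init__(self, dim: int, heads: int, rng: np.random.Generator):
        self.self_attn = nn.MultiheadAttention(dim, heads, rng)
        self.norm1 = nn.LayerNorm(dim)
        self.cross_t2i = nn.MultiheadAttention(dim, heads, rng)
        self.norm2 = nn.LayerNorm(dim)
        self.mlp = nn.Mlp(dim, dim * 2, rng)
        self.norm3 = nn.LayerNorm(dim)
        self.cross_i2t = nn.MultiheadAttention(dim, heads, rng)
        self.norm4 = nn.LayerNorm(dim)

    def forward(self, tokens: Tensor, image: Tensor):
        tokens = self.norm1(tokens + self.self_attn(tokens, tokens, tokens))
        tokens = self.norm2(tokens + self.cross_t2i(tokens, image, image))
        tokens = self.norm3(tokens + self.mlp(tokens))
        image = self.norm4(image + self.cross_i2t(image, tokens, tokens))
        return tokens, image


class MaskDecoder(nn.Module):
    """Single-mask decoder: two-way attention, x4 upscaling, dot-product head."""

    def __init__(self, channels: int, rng: np.random.Generator,
                 depth: int = 2, heads: int = 4):
        if channels % 4:
            raise ContractError("backbone channels must be divisible by 4")
        self.channels = channels
        self.out_channels = channels // 4
        self.mask_token = nn.parameter(rng.normal(0.0, 0.02, channels))
        self.blocks = [TwoWayBlock(channels, heads, rng) for _ in range(depth)]
        self.up1 = nn.ConvTranspose2x2(channels, channels // 2, rng)
        self.up2 = nn.ConvTranspose2x2(channels // 2, channels // 4, rng)
        self.token_mlp = nn.Mlp(channels, channels, rng,
                                out_dim=self.out_channels)

    def forward(self, z: Tensor, input_size: tuple[int, int]):
        n, c, h, w = z.shape
        if c != self.channels:
            raise ContractError(
                f"feature channels {c} != decoder channels {self.channels}")
        image = z.reshape(n, c, h * w).transpose(0, 2, 1)
        tokens = self.mask_token.reshape(1, 1, c) + Tensor(np.zeros((n, 1, c)))
        for blk in self.blocks:
            tokens, image = blk(tokens, image)
        feat = image.transpose(0, 2, 1).reshape(n, c, h, w)
        s = self.up2(self.up1(feat).relu()).relu()
        token_map = self.token_mlp(tokens)            # (n, 1, c')
        logits = (token_map.reshape(n, self.out_channels, 1, 1) * s).sum(
            axis=1, keepdims=True)
        y_low = logits.sigmoid()
        y_seg = upsample_bilinear(y_low, input_size)
        return s, tokens, y_seg


# -- heads and gating ------------------------------------------------------


class PoolLinearHead(nn.Module):
    """Global average pooling followed by a 1x1 convolution (a linear map)."""

    def __init__(self, channels: int, rng: np.random.Generator):
        self.fc = nn.Linear(channels, 1, rng)

    def forward(self, feat: Tensor) -> Tensor:
        pooled = feat.mean(axis=(2, 3))          # (n, c)
        return self.fc(pooled).sigmoid().reshape(-1)


def gate_features(z: Tensor, s: Tensor, y_seg: Tensor):
    """Mask the feature maps with the predicted segmentation.

    The full-resolution probability map is area-average pooled to each
    feature resolution and multiplied elementwise: ``z_m`` gates the
    segmentation feature ``s`` and ``z_c`` gates the backbone feature
    ``z``. Gradients flow through the attention map.
    """
    attn_s = avg_pool_to(y_seg, s.shape[2:])
    attn_z = avg_pool_to(y_seg, z.shape[2:])
    return s * attn_s, z * attn_z


@dataclass
class MtlOutputs:
    z: Tensor
    s: Tensor
    y_seg_hat: Tensor
    z_m: Tensor
    z_c: Tensor
    y_mcls_hat: Tensor
    y_cls_hat: Tensor


@dataclass
class MtlTargets:
    y_seg: np.ndarray    # (n, h, w) binary masks
    y_mcls: np.ndarray   # (n,) 1 = node view, 0 = tumor view
    y_cls: np.ndarray    # (n,) image-level pseudo-labels


@dataclass
class LossBundle:
    l_seg: Tensor
    l_mcls: Tensor
    l_cls: Tensor
    weights: tuple[float, float, float]
    total: Tensor


class MtlNet(nn.Module):
    """Backbone + mask decoder + lesion-type and metastasis heads."""

    def __init__(self, backbone: nn.Module, rng: np.random.Generator,
                 decoder_depth: int = 2, decoder_heads: int = 4):
        self.backbone = backbone
        self.decoder = MaskDecoder(backbone.channels, rng,
                                   depth=decoder_depth, heads=decoder_heads)
        self.mcls_head = PoolLinearHead(self.decoder.out_channels, rng)
        self.cls_head = PoolLinearHead(backbone.channels, rng)

    def forward(self, images: Tensor) -> MtlOutputs:
        if images.ndim != 4 or images.shape[1] != 1:
            raise ContractError("expected images of shape (n, 1, h, w)")
        h, w = images.shape[2:]
        if h % 16 or w % 16:
            raise ContractError("image size must be divisible by 16")
        z = self.backbone(images)
        s, _, y_seg = self.decoder(z, (h, w))
        z_m, z_c = gate_features(z, s, y_seg)
        return MtlOutputs(z=z, s=s, y_seg_hat=y_seg, z_m=z_m, z_c=z_c,
                          y_mcls_hat=self.mcls_head(z_m),
                          y_cls_hat=self.cls_head(z_c))


def make_pseudo_labels(patient_label: int, image_list) -> list[int]:
    """Broadcast the patient-level label to every one of its images."""
    if patient_label not in (0, 1):
        raise ValueError("patient_label must be 0 or 1")
    return [int(patient_label) for _ in image_list]


def mtl_loss(outputs: MtlOutputs, targets: MtlTargets,
             weights: tuple[float, float, float] = (1.0, 1.0, 1.0),
             eps: float = 1e-7) -> LossBundle:
    """Weighted sum of the three BCE objectives (default weights 1:1:1)."""
    y_seg = np.asarray(targets.y_seg, dtype=np.float64)
    if y_seg.shape != outputs.y_seg_hat.shape[0:1] + outputs.y_seg_hat.shape[2:]:
        raise ValueError("segmentation target/output shape mismatch")
    n = y_seg.shape[0]
    l_seg = nn.binary_cross_entropy(
        outputs.y_seg_hat.reshape(n, -1), y_seg.reshape(n, -1), eps=eps)
    l_mcls = nn.binary_cross_entropy(outputs.y_mcls_hat, targets.y_mcls, eps=eps)
    l_cls = nn.binary_cross_entropy(outputs.y_cls_hat, targets.y_cls, eps=eps)
    ws, wm, wc = weights
    total = l_seg * ws + l_mcls * wm + l_cls * wc
    return LossBundle(l_seg=l_seg, l_mcls=l_mcls, l_cls=l_cls,
                      weights=tuple(weights), total=total)
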