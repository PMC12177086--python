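"""Stage 2: patient-level multi-instance learning.

Each patient is a bag of image tokens — one 256-d token per view,
obtained by global average pooling of the gated lesion feature ``z_c``
from the frozen stage-1 model followed by a linear projection. A
learnable CLS token is prepended to every bag and a small transformer
encoder (no positional embeddings: bag order carries no information)
mixes the tokens; the final CLS embedding passes through an MLP and a
sigmoid to give the patient-level metastasis probability. Bags of
different sizes are padded and masked, so padded slots cannot influence
the output.
"""

from __future__ import annotations

import numpy as np

from . import nn
from .autograd import Tensor, concat

TOKEN_DIM = 256


class TokenExtractor(nn.Module):
    """GAP over the gated lesion feature, then a linear map to token space."""

    def __init__(self, in_channels: int, rng: np.random.Generator,
                 dim: int = TOKEN_DIM):
        self.dim = dim
        self.in_channels = in_channels
        self.proj = nn.Linear(in_channels, dim, rng)

    def forward(self, z_c: Tensor) -> Tensor:
        if z_c.ndim != 4 or z_c.shape[1] != self.in_channels:
            raise ValueError(
                f"expected (n, {self.in_channels}, h, w) feature maps, "
                f"got shape {z_c.shape}")
        return self.from_pooled(z_c.mean(axis=(2, 3)))

    def from_pooled(self, pooled: Tensor) -> Tensor:
        """Project already-pooled (n, c) features to token space."""
        if pooled.shape[-1] != self.in_channels:
            raise ValueError(
                f"pooled feature has {pooled.shape[-1]} channels, extractor "
                f"expects {self.in_channels}")
        return self.proj(pooled)


class BagTransformer(nn.Module):
    """CLS-token transformer over variable-size, padded token bags."""

    def __init__(self, rng: np.random.Generator, dim: int = TOKEN_DIM,
                 depth: int = 2, heads: int = 4, mlp_ratio: float = 2.0):
        self.dim = dim
        self.cls_token = nn.parameter(rng.normal(0.0, 0.02, dim))
        self.blocks = [nn.TransformerBlock(dim, heads, mlp_ratio, rng)
                       for _ in range(depth)]
        self.norm = nn.LayerNorm(dim)
        self.head = nn.Mlp(dim, dim // 2, rng, out_dim=1)

    def forward(self, tokens: Tensor, valid: np.ndarray) -> Tensor:
        """Probabilities for a padded batch.

        tokens: (b, s, dim); valid: boolean (b, s), True where the slot
        holds a real view token. Every bag must have >= 1 valid slot.
        """
        b, s, d = tokens.shape
        if d != self.dim:
            raise ValueError(f"token dim {d} != model dim {self.dim}")
        valid = np.asarray(valid, dtype=bool)
        if valid.shape != (b, s):
            raise ValueError("validity mask shape mismatch")
        if not valid.any(axis=1).all():
            raise ValueError("every bag needs at least one valid token")
        cls = self.cls_token.reshape(1, 1, d) + Tensor(np.zeros((b, 1, d)))
        x = concat([cls, tokens], axis=1)
        key_valid = np.concatenate(
            [np.ones((b, 1), dtype=bool), valid], axis=1)
        for blk in self.blocks:
            x = blk(x, key_valid=key_valid)
        cls_out = self.norm(x)[:, 0, :]
        return self.head(cls_out).sigmoid().reshape(-1)


def pad_bags(bags: list[np.ndarray], dim: int = TOKEN_DIM):
    """Stack variable-size bags into a padded (b, s_max, dim) batch + mask."""
    if not bags:
        raise ValueError("empty batch of bags")
    sizes = [np.asarray(b).shape[0] for b in bags]
    if min(sizes) == 0:
        raise ValueError("empty bag: every patient needs at least one token")
    s_max = max(sizes)
    batch = np.zeros((len(bags), s_max, dim))
    valid = np.zeros((len(bags), s_max), dtype=bool)
    for i, bag in enumerate(bags):
        bag = np.asarray(bag, dtype=np.float64)
        batch[i, :bag.shape[0]] = bag
        valid[i, :bag.shape[0]] = True
    return Tensor(batch), valid


def forward_bag(model: BagTransformer, bag: np.ndarray) -> float:
    """Probability for a single unpadded bag of tokens (s, dim)."""
    tokens, valid = pad_bags([np.asarray(bag)], dim=model.dim)
    return float(model(tokens, valid).data[0])


def mil_loss(probabilities: Tensor, labels, eps: float = 1e-7) -> Tensor:
    """Mean BCE between patient probabilities and binary labels."""
    return nn.binary_cross_entropy(probabilities, labels, eps=eps)
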