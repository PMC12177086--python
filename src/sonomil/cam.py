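"""Class activation maps for the pool-then-linear classification heads.

Because both heads are exactly global-average-pooling followed by a 1x1
convolution, the classic CAM is exact: the raw map is the channelwise
weighted sum of the head's input feature map with the class weights, and
its spatial mean equals the class logit minus the bias. Maps are
rectified before per-image min-max normalization (negative evidence is
not displayed), bilinearly upsampled to the input resolution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autograd import Tensor, no_grad, upsample_bilinear
from .mtl import MtlNet, PoolLinearHead


@dataclass
class Heatmap:
    grid: np.ndarray          # (h, w) in [0, 1]
    class_index: int
    raw_min: float
    raw_max: float
    degenerate: bool          # flat raw map (min == max after rectification)


def compute_cam(feature: np.ndarray, head: PoolLinearHead, class_index: int,
                output_size: tuple[int, int]) -> Heatmap:
    """CAM of a (c, h, w) feature map under a pool-then-linear head.

    ``class_index`` 1 uses the head's weights as-is; 0 negates them (a
    single-logit sigmoid head scores class 0 with the mirrored weights).
    """
    if class_index not in (0, 1):
        raise ValueError(f"class index out of range: {class_index}")
    feature = np.asarray(feature, dtype=np.float64)
    if feature.ndim != 3:
        raise ValueError("expected a (c, h, w) feature map")
    weights = head.fc.weight.data[:, 0]
    if class_index == 0:
        weights = -weights
    raw = np.tensordot(weights, feature, axes=(0, 0))
    with no_grad():
        up = upsample_bilinear(Tensor(raw[None, None]), output_size).data[0, 0]
    rect = np.maximum(up, 0.0)
    lo, hi = float(rect.min()), float(rect.max())
    if hi - lo < 1e-12:
        return Heatmap(np.zeros_like(rect), class_index,
                       float(up.min()), float(up.max()), degenerate=True)
    return Heatmap((rect - lo) / (hi - lo), class_index,
                   float(up.min()), float(up.max()), degenerate=False)


def cam_for_image(net: MtlNet, image: np.ndarray,
                  class_index: int = 1) -> Heatmap:
    """Metastasis-head CAM for one preprocessed image."""
    with no_grad():
        out = net(Tensor(np.asarray(image)[None, None]))
    return compute_cam(out.z_c.data[0], net.cls_head, class_index,
                       image.shape)


def lesion_mass_fraction(heatmap: Heatmap | np.ndarray,
                         mask: np.ndarray) -> float | None:
    """Fraction of heatmap mass inside the ground-truth lesion mask.

    Returns ``None`` (missing) for an all-zero heatmap.
    """
    grid = heatmap.grid if isinstance(heatmap, Heatmap) else np.asarray(heatmap)
    mask = np.asarray(mask, dtype=bool)
    if grid.shape != mask.shape:
        raise ValueError("heatmap/mask shape mismatch")
    total = grid.sum()
    if total <= 0:
        return None
    return float(grid[mask].sum() / total)


def save_overlay(path, image: np.ndarray, heatmap: Heatmap,
                 alpha: float = 0.45):
    """Write a PNG of the grayscale image blended with a jet-colored CAM."""
    import matplotlib
    from PIL import Image as PilImage

    cmap = matplotlib.colormaps["jet"]
    base = np.repeat(np.clip(image, 0, 1)[..., None], 3, axis=2)
    color = cmap(heatmap.grid)[..., :3]
    blend = (1 - alpha) * base + alpha * color
    PilImage.fromarray(
        np.round(blend * 255).astype(np.uint8), mode="RGB").save(path)
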