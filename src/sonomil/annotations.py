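"""Polygon annotations, manifests, rasterization and preprocessing.

Annotations use the LabelMe JSON dialect: one polygon per image, pixel
coordinates with x to the right and y down, 0-based, where integer
coordinates address pixel centers. Cohorts are described by a delimited
manifest with one row per view.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from skimage.transform import resize as _sk_resize

MANIFEST_COLUMNS = ["patient_id", "admission_index", "image_path",
                    "annotation_path", "view_type", "aln_status", "split"]

VIEW_TYPES = ("tumor", "node")
SPLITS = ("train", "internal_test", "external_test")


class AnnotationFormatError(ValueError):
    pass


@dataclass
class PolygonAnnotation:
    """A single closed lesion outline with its lesion-type label."""

    label: str
    points: np.ndarray          # (n, 2) float, columns (x, y)
    image_size: tuple[int, int]  # (height, width)

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=np.float64)
        if self.points.ndim != 2 or self.points.shape[1] != 2:
            raise AnnotationFormatError("points must be an (n, 2) array")
        if self.points.shape[0] < 3:
            raise AnnotationFormatError("polygon needs at least 3 points")
        if not np.all(np.isfinite(self.points)):
            raise AnnotationFormatError("points contain non-finite coordinates")


def read_annotation(path) -> PolygonAnnotation:
    """Parse a LabelMe-dialect JSON file holding exactly one polygon."""
    with open(path) as fh:
        doc = json.load(fh)
    for key in ("imageHeight", "imageWidth", "shapes"):
        if key not in doc:
            raise AnnotationFormatError(f"missing key: {key}")
    shapes = doc["shapes"]
    if len(shapes) != 1:
        raise AnnotationFormatError(
            f"expected exactly one shape, found {len(shapes)}")
    shape = shapes[0]
    for key in ("label", "points", "shape_type"):
        if key not in shape:
            raise AnnotationFormatError(f"missing key: shapes[0].{key}")
    if shape["shape_type"] != "polygon":
        raise AnnotationFormatError(
            f"unsupported shape_type: {shape['shape_type']!r}")
    return PolygonAnnotation(
        label=shape["label"],
        points=np.asarray(shape["points"], dtype=np.float64),
        image_size=(int(doc["imageHeight"]), int(doc["imageWidth"])),
    )


def write_annotation(path, ann: PolygonAnnotation, image_path: str = ""):
    doc = {
        "version": "5.0.1",
        "imagePath": image_path,
        "imageHeight": int(ann.image_size[0]),
        "imageWidth": int(ann.image_size[1]),
        "shapes": [{
            "label": ann.label,
            "points": [[float(x), float(y)] for x, y in ann.points],
            "shape_type": "polygon",
        }],
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)


def _polygon_area(pts: np.ndarray) -> float:
    x, y = pts[:, 0], pts[:, 1]
    return 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))


def rasterize(ann: PolygonAnnotation) -> np.ndarray:
    """Rasterize by the even-odd rule on pixel centers.

    A pixel belongs to the mask iff its center lies strictly inside the
    polygon (even-odd crossing count) or exactly on its boundary. Returns
    a boolean (height, width) array; parts of the polygon outside the
    frame are clipped.
    """
    h, w = ann.image_size
    mask = np.zeros((h, w), dtype=bool)
    pts = ann.points
    if _polygon_area(pts) == 0.0:
        warnings.warn("degenerate zero-area polygon; returning empty mask",
                      stacklevel=2)
        return mask
    x0 = max(int(np.floor(pts[:, 0].min())), 0)
    x1 = min(int(np.ceil(pts[:, 0].max())), w - 1)
    y0 = max(int(np.floor(pts[:, 1].min())), 0)
    y1 = min(int(np.ceil(pts[:, 1].max())), h - 1)
    if x0 > x1 or y0 > y1:
        return mask
    px, py = np.meshgrid(np.arange(x0, x1 + 1, dtype=np.float64),
                         np.arange(y0, y1 + 1, dtype=np.float64))
    inside = np.zeros(px.shape, dtype=bool)
    on_edge = np.zeros(px.shape, dtype=bool)
    n = len(pts)
    for i in range(n):
        ax, ay = pts[i]
        bx, by = pts[(i + 1) % n]
        crosses = (ay > py) != (by > py)
        with np.errstate(divide="ignore", invalid="ignore"):
            xint = ax + (py - ay) * (bx - ax) / (by - ay)
        inside ^= crosses & (px < xint)
        # exact-on-segment test
        ex, ey = bx - ax, by - ay
        denom = ex * ex + ey * ey
        if denom == 0.0:
            d2 = (px - ax) ** 2 + (py - ay) ** 2
        else:
            t = np.clip(((px - ax) * ex + (py - ay) * ey) / denom, 0.0, 1.0)
            d2 = (px - (ax + t * ex)) ** 2 + (py - (ay + t * ey)) ** 2
        on_edge |= d2 < 1e-18
    mask[y0:y1 + 1, x0:x1 + 1] = inside | on_edge
    return mask


# -- preprocessing --------------------------------------------------------


def _resize_pair(image: np.ndarray, mask: np.ndarray | None,
                 size: tuple[int, int]):
    """Bilinear for intensities, nearest for the binary mask."""
    img = _sk_resize(image, size, order=1, anti_aliasing=False,
                     preserve_range=True, mode="edge")
    msk = None
    if mask is not None:
        msk = _sk_resize(mask.astype(np.float64), size, order=0,
                         anti_aliasing=False, preserve_range=True,
                         mode="edge") > 0.5
    return img, msk


def draw_train_transform(rng: np.random.Generator, target_size: int,
                         scale_range: tuple[float, float] = (0.8, 1.25),
                         flip_probability: float = 0.5) -> dict:
    """Sample the augmentation applied to one training view.

    The resize factor is uniform in ``scale_range``; the crop origin is
    uniform over valid positions (negative origins mean zero-padding);
    a horizontal flip is drawn with ``flip_probability``.
    """
    scale = float(rng.uniform(*scale_range))
    interim = max(1, round(target_size * scale))
    lo, hi = (0, interim - target_size) if interim >= target_size \
        else (interim - target_size, 0)
    crop_y = int(rng.integers(lo, hi + 1))
    crop_x = int(rng.integers(lo, hi + 1))
    flip = bool(rng.random() < flip_probability)
    return {"scale": scale, "interim": interim,
            "crop_y": crop_y, "crop_x": crop_x, "flip": flip}


def apply_transform(image: np.ndarray, mask: np.ndarray | None,
                    params: dict, target_size: int):
    """Apply a sampled train transform identically to image and mask."""
    interim = params["interim"]
    img, msk = _resize_pair(image, mask, (interim, interim))
    t = target_size
    out_img = np.zeros((t, t), dtype=np.float64)
    out_msk = np.zeros((t, t), dtype=bool) if msk is not None else None
    cy, cx = params["crop_y"], params["crop_x"]
    sy0, sx0 = max(cy, 0), max(cx, 0)
    dy0, dx0 = max(-cy, 0), max(-cx, 0)
    ny = min(interim - sy0, t - dy0)
    nx = min(interim - sx0, t - dx0)
    out_img[dy0:dy0 + ny, dx0:dx0 + nx] = img[sy0:sy0 + ny, sx0:sx0 + nx]
    if out_msk is not None:
        out_msk[dy0:dy0 + ny, dx0:dx0 + nx] = msk[sy0:sy0 + ny, sx0:sx0 + nx]
    if params["flip"]:
        out_img = out_img[:, ::-1].copy()
        if out_msk is not None:
            out_msk = out_msk[:, ::-1].copy()
    return out_img, out_msk


def preprocess(image: np.ndarray, mask: np.ndarray | None, mode: str,
               target_size: int, rng: np.random.Generator | None = None):
    """Deterministic eval resize, or scale-jitter / crop / flip in train mode."""
    if mode == "eval":
        return _resize_pair(image, mask, (target_size, target_size))
    if mode == "train":
        if rng is None:
            raise ValueError("train mode requires an rng")
        params = draw_train_transform(rng, target_size)
        return apply_transform(image, mask, params, target_size)
    raise ValueError(f"unknown preprocessing mode: {mode!r}")


# -- manifests and splits --------------------------------------------------


def validate_manifest(df: pd.DataFrame, root: Path | None = None) -> pd.DataFrame:
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"manifest missing columns: {missing}")
    bad = set(df["view_type"]) - set(VIEW_TYPES)
    if bad:
        raise ValueError(f"unknown view_type values: {sorted(bad)}")
    if root is not None:
        for rel in df["image_path"]:
            if not (Path(root) / rel).exists():
                raise FileNotFoundError(f"image missing: {rel}")
    return df


def read_manifest(path) -> pd.DataFrame:
    return validate_manifest(pd.read_csv(path))


def write_manifest(path, df: pd.DataFrame):
    validate_manifest(df).to_csv(path, index=False)


def split_by_admission(df: pd.DataFrame, ratio: float = 0.8) -> pd.DataFrame:
    """Assign chronological train / internal_test splits per patient.

    Patients are ordered by ``admission_index``; the earliest
    ``floor(ratio * n)`` patients form the training split and the rest the
    internal test split. Every view of a patient shares its split.
    """
    if not 0.0 <= ratio <= 1.0:
        raise ValueError("ratio must be in [0, 1]")
    per_patient = df.drop_duplicates("patient_id")[["patient_id",
                                                    "admission_index"]]
    if per_patient["admission_index"].duplicated().any():
        raise ValueError("admission_index must be unique per patient")
    if df.groupby("patient_id")["admission_index"].nunique().gt(1).any():
        raise ValueError("inconsistent admission_index within a patient")
    ordered = per_patient.sort_values("admission_index")["patient_id"].tolist()
    n_train = int(np.floor(ratio * len(ordered)))
    assign = {pid: ("train" if i < n_train else "internal_test")
              for i, pid in enumerate(ordered)}
    out = df.copy()
    out["split"] = out["patient_id"].map(assign)
    return out
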