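"""Synthetic ultrasound-like phantom cohorts with known ground truth.

Real breast/axilla ultrasound cohorts are not publicly available, so this
module plants the clinical signs the two-stage framework is meant to
exploit into a controllable speckle phantom: hypoechoic lesions on a
multiplicative-speckle background, benign-looking lymph nodes with a
bright fatty hilum and elongated shape, and metastatic nodes with hilum
loss, rounder shape and irregular borders. Tumor views of metastatic
patients carry a weaker size/irregularity signal, so tumor-only
prediction is informative but inferior to using node views.

Each patient is a bag of M >= 1 tumor views and N >= 0 node views; a
latent metastasis score thresholded at ``label_threshold`` defines the
binary patient label, and node-view visibility may depend on that label.
Generation is counter-seeded per patient, so cohorts are reproducible to
the byte.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image
from scipy.ndimage import gaussian_filter
from skimage import measure

from .annotations import (PolygonAnnotation, split_by_admission,
                          write_annotation, write_manifest)


class ConfigurationError(ValueError):
    pass


class GeometryError(ValueError):
    pass


@dataclass
class EffectParams:
    """Label-linked shifts of lesion appearance (all >= 0; 0 = no signal).

    hilum_loss_gap
        Drop in the probability that a node view shows a fatty hilum for
        metastatic versus benign nodes.
    roundness_shift
        Increase of the node axis ratio b/a for metastatic nodes (benign
        nodes are elongated/reniform).
    irregularity_shift
        Extra radial boundary-perturbation amplitude for metastatic nodes.
    tumor_signal_shift
        Relative size increase (and half of it as extra irregularity) of
        the primary tumor in views of metastatic patients; the weak
        tumor-side correlate of node status.
    label_threshold
        Cutoff on the latent uniform metastasis score; ``None`` means
        derived from the cohort prevalence at simulation time.
    """

    hilum_loss_gap: float = 0.9
    roundness_shift: float = 0.3
    irregularity_shift: float = 0.2
    tumor_signal_shift: float = 0.12
    label_threshold: float | None = None

    def validate(self):
        for name in ("hilum_loss_gap", "roundness_shift",
                     "irregularity_shift", "tumor_signal_shift"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"effect.{name} must be >= 0")

    @classmethod
    def null(cls) -> "EffectParams":
        """All shifts zero: images statistically independent of the label."""
        return cls(hilum_loss_gap=0.0, roundness_shift=0.0,
                   irregularity_shift=0.0, tumor_signal_shift=0.0)


@dataclass
class NoiseParams:
    """Speckle/texture knobs of the phantom renderer (intensities in [0, 1])."""

    background_mean: float = 0.5
    speckle_scale: float = 0.35     # sd of the unit-mean gamma field
    smoothing_radius: float = 1.2   # px, Gaussian smoothing of the speckle
    lesion_contrast: float = 0.5    # fractional darkening inside lesions
    hilum_contrast: float = 0.3     # fractional brightening of the hilum disc


@dataclass
class LesionSpec:
    """Geometry of a single rendered lesion."""

    lesion_type: str                 # "tumor" | "node"
    center: tuple[float, float]      # (x, y) pixels
    semi_axes: tuple[float, float]   # (a, b), a >= b > 0
    rotation: float                  # radians
    irregularity: float              # radial perturbation amplitude
    lobes: int = 4                   # angular frequency of the perturbation
    phase: float = 0.0
    hilum_present: bool = False      # nodes only
    metastatic_score: float = 0.0    # patient latent score (bookkeeping)

    def max_radius(self) -> float:
        return self.semi_axes[0] * (1.0 + self.irregularity)


@dataclass
class PhantomView:
    image: np.ndarray
    annotation: PolygonAnnotation
    view_type: str
    lesion: LesionSpec
    mask: np.ndarray


@dataclass
class PhantomPatient:
    patient_id: str
    admission_index: int
    aln_status: int
    metastatic_score: float
    views: list[PhantomView] = field(default_factory=list)


@dataclass
class CohortSpec:
    n_patients: int = 400
    prevalence: float = 0.642
    image_size: int = 96
    tumor_views_range: tuple[int, int] = (1, 3)
    node_views_range: tuple[int, int] = (1, 2)
    p_node_visible_pos: float = 0.9
    p_node_visible_neg: float = 0.7
    effect: EffectParams = field(default_factory=EffectParams)
    noise: NoiseParams = field(default_factory=NoiseParams)
    seed: int = 0

    def validate(self):
        for name in ("prevalence", "p_node_visible_pos", "p_node_visible_neg"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must be a probability, got {v}")
        if self.n_patients < 1:
            raise ConfigurationError("n_patients must be >= 1")
        if self.tumor_views_range[0] < 1:
            raise ConfigurationError("tumor_views_range minimum must be >= 1")
        if self.node_views_range[0] < 0:
            raise ConfigurationError("node_views_range minimum must be >= 0")
        for name in ("tumor_views_range", "node_views_range"):
            lo, hi = getattr(self, name)
            if hi < lo:
                raise ConfigurationError(f"{name} is empty: ({lo}, {hi})")
        self.effect.validate()

    def label_threshold(self) -> float:
        if self.effect.label_threshold is not None:
            return self.effect.label_threshold
        return 1.0 - self.prevalence


def _patient_rng(seed: int, index: int) -> np.random.Generator:
    """Counter-derived substream: reproducible regardless of generation order."""
    return np.random.default_rng(np.random.SeedSequence((seed, index)))


# -- rendering -------------------------------------------------------------


def _radial_mask(lesion: LesionSpec, size: int):
    """Boolean mask of the perturbed ellipse plus its hilum disc."""
    cx, cy = lesion.center
    a, b = lesion.semi_axes
    yy, xx = np.mgrid[0:size, 0:size].astype(np.float64)
    dx, dy = xx - cx, yy - cy
    ct, st = math.cos(lesion.rotation), math.sin(lesion.rotation)
    u = dx * ct + dy * st
    v = -dx * st + dy * ct
    rho = np.hypot(u, v)
    theta = np.arctan2(v, u)
    base = a * b / np.sqrt((b * np.cos(theta)) ** 2 + (a * np.sin(theta)) ** 2)
    boundary = base * (1.0 + lesion.irregularity
                       * np.sin(lesion.lobes * theta + lesion.phase))
    mask = rho <= boundary
    hilum = np.zeros_like(mask)
    if lesion.lesion_type == "node" and lesion.hilum_present:
        r_h = 0.45 * b
        hilum = (u ** 2 + v ** 2) <= r_h ** 2
    return mask, hilum


def render_view(lesion: LesionSpec, noise: NoiseParams,
                rng: np.random.Generator, size: int):
    """Render one speckled view and its ground-truth lesion mask.

    The deterministic intensity profile (background darkened inside the
    lesion, brightened in the hilum disc) is multiplied by a smoothed
    unit-mean gamma speckle field and clipped to [0, 1].
    """
    cx, cy = lesion.center
    margin = lesion.max_radius()
    if (cx - margin < 0 or cy - margin < 0
            or cx + margin > size - 1 or cy + margin > size - 1):
        raise GeometryError("lesion extends outside the image frame")
    mask, hilum = _radial_mask(lesion, size)
    profile = noise.background_mean * (
        1.0 - noise.lesion_contrast * mask + noise.hilum_contrast * hilum)
    s2 = noise.speckle_scale ** 2
    if s2 > 0:
        speckle = rng.gamma(shape=1.0 / s2, scale=s2, size=(size, size))
        if noise.smoothing_radius > 0:
            speckle = gaussian_filter(speckle, noise.smoothing_radius,
                                      mode="reflect")
    else:
        speckle = np.ones((size, size))
    image = np.clip(profile * speckle, 0.0, 1.0)
    return image, mask


def polygonize_mask(mask: np.ndarray,
                    tolerance: float = 0.25) -> np.ndarray:
    """Trace the boundary of a single-component mask as an (n, 2) polygon.

    Vertices are (x, y) pixel coordinates on the half-level contour of the
    mask, simplified with the given tolerance; rasterizing the polygon
    back recovers the mask with IoU >= 0.95.
    """
    mask = np.asarray(mask, bool)
    if not mask.any():
        raise ValueError("cannot polygonize an empty mask")
    n_comp = measure.label(mask, connectivity=2).max()
    if n_comp != 1:
        raise ValueError(f"mask has {n_comp} components, expected exactly 1")
    padded = np.pad(mask.astype(np.float64), 1)
    contours = measure.find_contours(padded, 0.5)
    contour = max(contours, key=len)
    if np.allclose(contour[0], contour[-1]):
        contour = contour[:-1]
    contour = measure.approximate_polygon(contour, tolerance)
    # (row, col) in padded frame -> (x, y) in image frame
    pts = np.stack([contour[:, 1] - 1.0, contour[:, 0] - 1.0], axis=1)
    return pts


# -- cohort planning and simulation ----------------------------------------


def _plan_patient(spec: CohortSpec, index: int) -> PhantomPatient:
    """Draw labels, bag sizes and lesion geometry (no pixels yet)."""
    rng = _patient_rng(spec.seed, index)
    size = spec.image_size
    scale = size / 96.0
    eff = spec.effect
    score = float(rng.uniform())
    status = int(score > spec.label_threshold())

    patient = PhantomPatient(
        patient_id=f"P{index:05d}", admission_index=index,
        aln_status=status, metastatic_score=score)

    def place(a_px, b_px, irregularity, lesion_type, hilum):
        margin = a_px * (1.0 + irregularity) + 2.0
        if 2 * margin >= size:
            raise GeometryError("lesion too large for the image frame")
        cx = float(rng.uniform(margin, size - 1 - margin))
        cy = float(rng.uniform(margin, size - 1 - margin))
        return LesionSpec(
            lesion_type=lesion_type, center=(cx, cy),
            semi_axes=(a_px, b_px), rotation=float(rng.uniform(0, math.pi)),
            irregularity=irregularity, lobes=int(rng.integers(3, 8)),
            phase=float(rng.uniform(0, 2 * math.pi)),
            hilum_present=hilum, metastatic_score=score)

    n_tumor = int(rng.integers(spec.tumor_views_range[0],
                               spec.tumor_views_range[1] + 1))
    lesions: list[tuple[str, LesionSpec]] = []
    for _ in range(n_tumor):
        a = float(rng.uniform(14, 20)) * scale
        ratio = float(rng.uniform(0.55, 0.8))
        irr = 0.04
        if status:
            a *= 1.0 + eff.tumor_signal_shift
            irr += 0.5 * eff.tumor_signal_shift
        lesions.append(("tumor", place(a, ratio * a, irr, "tumor", False)))

    hi = spec.node_views_range[1]
    if hi > 0:
        p_vis = spec.p_node_visible_pos if status else spec.p_node_visible_neg
        if rng.uniform() < p_vis:
            lo = max(1, spec.node_views_range[0])
            n_node = int(rng.integers(lo, hi + 1))
            p_hilum = 0.95 - (eff.hilum_loss_gap if status else 0.0)
            for _ in range(n_node):
                a = float(rng.uniform(10, 15)) * scale
                ratio = float(rng.uniform(0.40, 0.55))
                irr = 0.03
                if status:
                    ratio = min(ratio + eff.roundness_shift, 0.95)
                    irr += eff.irregularity_shift
                hilum = bool(rng.uniform() < p_hilum)
                lesions.append(("node", place(a, ratio * a, irr, "node", hilum)))

    patient.views = [PhantomView(image=None, annotation=None, mask=None,
                                 view_type=vt, lesion=ls)
                     for vt, ls in lesions]
    return patient


def plan_cohort(spec: CohortSpec) -> list[PhantomPatient]:
    """Labels, bag composition and lesion geometry without rendering pixels."""
    spec.validate()
    return [_plan_patient(spec, i) for i in range(spec.n_patients)]


def simulate_cohort(spec: CohortSpec) -> list[PhantomPatient]:
    """Generate the full cohort: rendered views, masks and polygon outlines."""
    patients = plan_cohort(spec)
    for i, patient in enumerate(patients):
        # independent render substream so planning draws stay stable
        rng = _patient_rng(spec.seed, spec.n_patients + i)
        for view in patient.views:
            image, mask = render_view(view.lesion, spec.noise, rng,
                                      spec.image_size)
            view.image = image
            view.mask = mask
            view.annotation = PolygonAnnotation(
                label=view.view_type, points=polygonize_mask(mask),
                image_size=(spec.image_size, spec.image_size))
    return patients


def write_cohort(patients: list[PhantomPatient], out_dir,
                 train_ratio: float = 0.8) -> pd.DataFrame:
    """Write PNGs, LabelMe JSONs and the split manifest; returns the manifest."""
    out = Path(out_dir)
    (out / "images").mkdir(parents=True, exist_ok=True)
    (out / "annotations").mkdir(parents=True, exist_ok=True)
    rows = []
    for patient in patients:
        for j, view in enumerate(patient.views):
            stem = f"{patient.patient_id}_{view.view_type}_{j}"
            img_rel = f"images/{stem}.png"
            ann_rel = f"annotations/{stem}.json"
            arr = np.round(view.image * 255.0).astype(np.uint8)
            Image.fromarray(arr, mode="L").save(out / img_rel)
            write_annotation(out / ann_rel, view.annotation,
                             image_path=f"../{img_rel}")
            rows.append({
                "patient_id": patient.patient_id,
                "admission_index": patient.admission_index,
                "image_path": img_rel, "annotation_path": ann_rel,
                "view_type": view.view_type,
                "aln_status": patient.aln_status, "split": "train"})
    manifest = split_by_admission(pd.DataFrame(rows), ratio=train_ratio)
    write_manifest(out / "manifest.csv", manifest)
    return manifest


def cohort_checksum(out_dir) -> str:
    """SHA-256 over a cohort's data files (images, annotations, manifest).

    Run metadata such as logs is excluded so the checksum reflects only
    the generated cohort itself.
    """
    h = hashlib.sha256()
    root = Path(out_dir)
    paths = sorted(root.glob("images/*")) + sorted(
        root.glob("annotations/*")) + [root / "manifest.csv"]
    for path in paths:
        if path.is_file():
            h.update(path.relative_to(root).as_posix().encode())
            h.update(path.read_bytes())
    return h.hexdigest()
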