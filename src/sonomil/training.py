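"""Config-driven, seeded training and inference for both stages.

The ``paper`` profile carries the published hyperparameters (512x512
inputs, AdamW at 6e-5, 16 images per step for 10k iterations in stage 1;
4 patients per step for 100 epochs in stage 2; 256-d tokens). The
``desk`` profile is a first-class scaled-down configuration (96x96
phantoms, tiny backbone, a few hundred iterations) sized so the whole
pipeline trains in minutes on one CPU core; every quantitative check in
the test suite runs at desk scale.

Checkpoints are ``.npz`` weight archives with the resolved config and a
config hash embedded, so stage-2 training and joint prediction can
verify they are built on the stage-1 model they expect.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from . import mil, mtl, nn
from .annotations import preprocess, rasterize, read_annotation
from .autograd import Tensor, no_grad

STAGES = ("mtl", "mil")
PROFILES = ("paper", "desk")


@dataclass
class TrainConfig:
    stage: str = "mtl"
    profile: str = "paper"
    seed: int = 0
    learning_rate: float = 6e-5
    weight_decay: float = 0.01
    image_size: int = 512
    backbone: str = "conv"                 # "conv" | "attention"
    backbone_channels: tuple = (12, 24, 32, 32)
    decoder_depth: int = 2
    decoder_heads: int = 4
    loss_weights: tuple = (1.0, 1.0, 1.0)
    mtl_batch_images: int = 16
    mtl_iterations: int = 10000
    token_dim: int = 256
    mil_depth: int = 12
    mil_heads: int = 8
    mil_patients_per_step: int = 4
    mil_epochs: int = 100
    augment: bool = True

    def validate(self):
        if self.stage not in STAGES:
            raise ValueError(f"unknown stage: {self.stage!r}")
        if self.profile not in PROFILES:
            raise ValueError(f"unknown profile: {self.profile!r}")
        if self.profile == "desk":
            if self.image_size > 128:
                raise ValueError("desk profile caps image_size at 128")
            if self.mtl_iterations > 2000:
                raise ValueError("desk profile caps mtl_iterations at 2000")

    @classmethod
    def desk(cls, stage: str, seed: int = 0, **overrides) -> "TrainConfig":
        """Desk-scale defaults: CPU-trainable in minutes end to end."""
        base = dict(
            stage=stage, profile="desk", seed=seed,
            learning_rate=2e-3 if stage == "mtl" else 1e-3,
            image_size=96, backbone="conv",
            backbone_channels=(12, 24, 32, 32),
            mtl_batch_images=16, mtl_iterations=2000,
            mil_depth=2, mil_heads=4, mil_epochs=100,
            augment=False,
        )
        base.update(overrides)
        cfg = cls(**base)
        cfg.validate()
        return cfg

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for key in ("backbone_channels", "loss_weights"):
            d[key] = list(d[key])
        return d

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def _rng_children(seed: int, n: int) -> list[np.random.Generator]:
    ss = np.random.SeedSequence(seed)
    return [np.random.default_rng(child) for child in ss.spawn(n)]


def build_mtl(config: TrainConfig, rng: np.random.Generator) -> mtl.MtlNet:
    if config.backbone == "conv":
        backbone = mtl.TinyConvBackbone(rng, tuple(config.backbone_channels))
    elif config.backbone == "attention":
        backbone = mtl.TinyAttentionBackbone(
            rng, channels=int(config.backbone_channels[-1]))
    else:
        raise ValueError(f"unknown backbone: {config.backbone!r}")
    return mtl.MtlNet(backbone, rng, decoder_depth=config.decoder_depth,
                      decoder_heads=config.decoder_heads)


def build_mil(config: TrainConfig, in_channels: int,
              rng: np.random.Generator):
    extractor = mil.TokenExtractor(in_channels, rng, dim=config.token_dim)
    bag_model = mil.BagTransformer(rng, dim=config.token_dim,
                                   depth=config.mil_depth,
                                   heads=config.mil_heads)
    return extractor, bag_model


# -- data loading ----------------------------------------------------------


def load_views(manifest: pd.DataFrame, root, split: str | None = None
               ) -> list[dict]:
    """Load images and rasterized masks for (a split of) a manifest."""
    root = Path(root)
    df = manifest if split is None else manifest[manifest["split"] == split]
    views = []
    for row in df.itertuples():
        img = np.asarray(Image.open(root / row.image_path).convert("L"),
                         dtype=np.float64) / 255.0
        ann = read_annotation(root / row.annotation_path)
        views.append({
            "patient_id": row.patient_id, "view_type": row.view_type,
            "aln_status": int(row.aln_status), "split": row.split,
            "image": img, "mask": rasterize(ann)})
    return views


# -- checkpoints -----------------------------------------------------------


def save_checkpoint(path, config: TrainConfig, state: dict[str, np.ndarray],
                    extra: dict | None = None):
    meta = {"config": config.to_dict(), "config_hash": config.config_hash()}
    if extra:
        meta.update(extra)
    np.savez(path, __meta__=np.frombuffer(
        json.dumps(meta).encode(), dtype=np.uint8), **state)


def load_checkpoint(path):
    with np.load(path) as archive:
        meta = json.loads(archive["__meta__"].tobytes().decode())
        state = {k: archive[k] for k in archive.files if k != "__meta__"}
    cfg_dict = meta["config"]
    for key in ("backbone_channels", "loss_weights"):
        cfg_dict[key] = tuple(cfg_dict[key])
    config = TrainConfig(**cfg_dict)
    return config, state, meta


def load_mtl_model(path) -> tuple[TrainConfig, mtl.MtlNet]:
    config, state, _ = load_checkpoint(path)
    net = build_mtl(config, np.random.default_rng(0))
    net.load_state_dict(state)
    return config, net


# -- stage 1 training ------------------------------------------------------


def train_mtl(config: TrainConfig, manifest: pd.DataFrame, root,
              out_dir=None):
    """Train the multi-task stage on the manifest's training split."""
    config.validate()
    if config.stage != "mtl":
        raise ValueError("config.stage must be 'mtl'")
    init_rng, order_rng, aug_rng = _rng_children(config.seed, 3)
    net = build_mtl(config, init_rng)
    opt = nn.AdamW(net.parameters(), lr=config.learning_rate,
                   weight_decay=config.weight_decay)
    views = load_views(manifest, root, split="train")
    if not views:
        raise ValueError("no training views in manifest")
    size = config.image_size
    log = []
    order = order_rng.permutation(len(views))
    cursor = 0
    for step in range(config.mtl_iterations):
        batch_idx = []
        for _ in range(config.mtl_batch_images):
            if cursor == len(order):
                order = order_rng.permutation(len(views))
                cursor = 0
            batch_idx.append(order[cursor])
            cursor += 1
        imgs, masks, mcls, cls = [], [], [], []
        for i in batch_idx:
            v = views[i]
            mode = "train" if config.augment else "eval"
            img, msk = preprocess(v["image"], v["mask"], mode, size,
                                  rng=aug_rng)
            imgs.append(img[None])
            masks.append(msk.astype(np.float64))
            mcls.append(1.0 if v["view_type"] == "node" else 0.0)
            cls.append(float(mtl.make_pseudo_labels(v["aln_status"], [v])[0]))
        x = Tensor(np.stack(imgs))
        targets = mtl.MtlTargets(y_seg=np.stack(masks),
                                 y_mcls=np.array(mcls), y_cls=np.array(cls))
        out = net(x)
        bundle = mtl.mtl_loss(out, targets, weights=config.loss_weights)
        opt.zero_grad()
        bundle.total.backward()
        opt.step()
        log.append({"step": step, "l_seg": bundle.l_seg.item(),
                    "l_mcls": bundle.l_mcls.item(),
                    "l_cls": bundle.l_cls.item(),
                    "total": bundle.total.item()})
    log_df = pd.DataFrame(log)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        save_checkpoint(out_dir / "mtl.npz", config, net.state_dict())
        log_df.to_csv(out_dir / "mtl_log.csv", index=False)
        (out_dir / "mtl_config.json").write_text(
            json.dumps(config.to_dict(), indent=1))
    return net, log_df


# -- stage 1 inference helpers --------------------------------------------


def mtl_forward_views(net: mtl.MtlNet, views: list[dict], size: int,
                      batch: int = 32):
    """Eval-mode stage-1 outputs: pooled z_c features, image probabilities
    and segmentation maps for a list of views."""
    pooled, img_prob, seg_maps = [], [], []
    with no_grad():
        for start in range(0, len(views), batch):
            chunk = views[start:start + batch]
            arr = []
            for v in chunk:
                img, _ = preprocess(v["image"], None, "eval", size)
                arr.append(img[None])
            out = net(Tensor(np.stack(arr)))
            pooled.append(out.z_c.data.mean(axis=(2, 3)))
            img_prob.append(out.y_cls_hat.data)
            seg_maps.append(out.y_seg_hat.data[:, 0])
    return (np.concatenate(pooled), np.concatenate(img_prob),
            np.concatenate(seg_maps))


def _group_bags(views: list[dict], features: np.ndarray,
                tumor_only: bool = False):
    """Group per-view pooled features into per-patient bags."""
    bags: dict[str, dict] = {}
    for v, feat in zip(views, features):
        if tumor_only and v["view_type"] != "tumor":
            continue
        entry = bags.setdefault(v["patient_id"], {
            "features": [], "label": v["aln_status"], "split": v["split"]})
        entry["features"].append(feat)
    return bags


# -- stage 2 training ------------------------------------------------------


def train_mil(config: TrainConfig, manifest: pd.DataFrame, root,
              mtl_checkpoint=None, mtl_net: mtl.MtlNet | None = None,
              mtl_config: TrainConfig | None = None, out_dir=None,
              tumor_only: bool = False, cached_features=None):
    """Train the MIL stage on frozen stage-1 features.

    Pass either a stage-1 checkpoint path or an in-memory (net, config)
    pair. ``tumor_only`` drops node views from every bag (the single-view
    ablation). ``cached_features`` may hold a ``(views, pooled)`` pair of
    training-split views and their stage-1 pooled features to avoid
    recomputing the frozen forward passes.
    """
    config.validate()
    if config.stage != "mil":
        raise ValueError("config.stage must be 'mil'")
    if mtl_net is None:
        if mtl_checkpoint is None:
            raise ValueError("MIL training requires a stage-1 checkpoint")
        mtl_config, mtl_net = load_mtl_model(mtl_checkpoint)
    elif mtl_config is None:
        raise ValueError("mtl_config required with an in-memory stage-1 net")

    init_rng, order_rng = _rng_children(config.seed + 1, 2)
    if cached_features is not None:
        views, feats = cached_features
    else:
        views = load_views(manifest, root, split="train")
        feats, _, _ = mtl_forward_views(mtl_net, views, mtl_config.image_size)
    bags = _group_bags(views, feats, tumor_only=tumor_only)
    ids = sorted(bags)
    extractor, bag_model = build_mil(
        config, mtl_net.backbone.channels, init_rng)
    params = list(extractor.parameters()) + list(bag_model.parameters())
    opt = nn.AdamW(params, lr=config.learning_rate,
                   weight_decay=config.weight_decay)
    log = []
    for epoch in range(config.mil_epochs):
        order = order_rng.permutation(len(ids))
        losses = []
        for start in range(0, len(order), config.mil_patients_per_step):
            chunk = [ids[i] for i in order[start:start + config.mil_patients_per_step]]
            pooled = [np.stack(bags[pid]["features"]) for pid in chunk]
            labels = np.array([bags[pid]["label"] for pid in chunk],
                              dtype=np.float64)
            tokens = extractor.from_pooled(Tensor(np.concatenate(pooled)))
            sizes = [p.shape[0] for p in pooled]
            offs = np.cumsum([0] + sizes)
            token_bags = [tokens[a:b] for a, b in zip(offs[:-1], offs[1:])]
            s_max = max(sizes)
            dim = config.token_dim
            from .autograd import concat
            padded = []
            valid = np.zeros((len(chunk), s_max), dtype=bool)
            for i, tb in enumerate(token_bags):
                valid[i, :sizes[i]] = True
                if sizes[i] < s_max:
                    pad = Tensor(np.zeros((s_max - sizes[i], dim)))
                    tb = concat([tb, pad], axis=0)
                padded.append(tb.reshape(1, s_max, dim))
            batch = concat(padded, axis=0)
            probs = bag_model(batch, valid)
            loss = mil.mil_loss(probs, labels)
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(loss.item())
        log.append({"epoch": epoch, "loss": float(np.mean(losses))})
    log_df = pd.DataFrame(log)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        state = {f"extractor.{k}": v for k, v in extractor.state_dict().items()}
        state.update({f"bag.{k}": v for k, v in bag_model.state_dict().items()})
        save_checkpoint(out_dir / "mil.npz", config, state,
                        extra={"mtl_config_hash": mtl_config.config_hash(),
                               "tumor_only": tumor_only})
        log_df.to_csv(out_dir / "mil_log.csv", index=False)
    return (extractor, bag_model), log_df


def load_mil_model(path, in_channels: int):
    config, state, meta = load_checkpoint(path)
    extractor, bag_model = build_mil(config, in_channels,
                                     np.random.default_rng(0))
    extractor.load_state_dict(
        {k[len("extractor."):]: v for k, v in state.items()
         if k.startswith("extractor.")})
    bag_model.load_state_dict(
        {k[len("bag."):]: v for k, v in state.items() if k.startswith("bag.")})
    return config, extractor, bag_model, meta


def save_token_cache(path, views: list[dict], pooled: np.ndarray):
    """Persist per-view pooled stage-1 features with their bag metadata.

    The cache holds one row per view (patient id, view type, label,
    split) plus the pooled feature matrix, so MIL training and ablations
    can rerun without the frozen stage-1 forward passes.
    """
    np.savez(
        path,
        features=np.asarray(pooled, dtype=np.float64),
        patient_id=np.array([v["patient_id"] for v in views]),
        view_type=np.array([v["view_type"] for v in views]),
        aln_status=np.array([v["aln_status"] for v in views], dtype=np.int64),
        split=np.array([v["split"] for v in views]))


def load_token_cache(path):
    """Inverse of :func:`save_token_cache`: returns ``(views, pooled)``.

    The view dicts carry the bag metadata only (no pixel data), which is
    all the MIL stage needs.
    """
    with np.load(path) as archive:
        pooled = archive["features"]
        views = [{"patient_id": str(p), "view_type": str(t),
                  "aln_status": int(s), "split": str(sp)}
                 for p, t, s, sp in zip(archive["patient_id"],
                                        archive["view_type"],
                                        archive["aln_status"],
                                        archive["split"])]
    return views, pooled


# -- joint inference -------------------------------------------------------


def predict_patients(manifest: pd.DataFrame, root,
                     mtl_net: mtl.MtlNet, mtl_config: TrainConfig,
                     extractor: mil.TokenExtractor,
                     bag_model: mil.BagTransformer,
                     split: str | None = None,
                     tumor_only: bool = False,
                     cached_features=None) -> pd.DataFrame:
    """One deterministic probability per patient (N = 0 node views included)."""
    if cached_features is not None:
        views, feats = cached_features
    else:
        views = load_views(manifest, root, split=split)
        feats, _, _ = mtl_forward_views(mtl_net, views, mtl_config.image_size)
    bags = _group_bags(views, feats, tumor_only=tumor_only)
    rows = []
    with no_grad():
        for pid in sorted(bags):
            entry = bags[pid]
            pooled = Tensor(np.stack(entry["features"]))
            tokens = extractor.from_pooled(pooled)
            prob = mil.forward_bag(bag_model, tokens.data)
            rows.append({"patient_id": pid, "probability": prob,
                         "label": entry["label"], "split": entry["split"]})
    return pd.DataFrame(rows)


def predict_patients_from_checkpoints(manifest: pd.DataFrame, root,
                                      mtl_checkpoint, mil_checkpoint,
                                      split: str | None = None) -> pd.DataFrame:
    mtl_config, net = load_mtl_model(mtl_checkpoint)
    mil_config, extractor, bag_model, meta = load_mil_model(
        mil_checkpoint, net.backbone.channels)
    if meta.get("mtl_config_hash") != mtl_config.config_hash():
        raise ValueError("incompatible checkpoints: the MIL model was trained "
                         "on a different stage-1 configuration")
    return predict_patients(manifest, root, net, mtl_config, extractor,
                            bag_model, split=split,
                            tumor_only=bool(meta.get("tumor_only", False)))


def evaluate_segmentation(net: mtl.MtlNet, manifest: pd.DataFrame, root,
                          size: int, split: str | None = None) -> float:
    """Foreground mIoU of stage-1 segmentations against rasterized outlines."""
    from .metrics import miou
    views = load_views(manifest, root, split=split)
    _, _, seg = mtl_forward_views(net, views, size)
    gts = []
    for v in views:
        _, msk = preprocess(v["image"], v["mask"], "eval", size)
        gts.append(msk)
    return miou(list(seg), gts)
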