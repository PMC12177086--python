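"""Desk-scale end-to-end benchmark of the two-stage pipeline.

Runs the complete study loop on synthetic phantom cohorts: generate a
planted-effect cohort, train stage 1 (multi-task) and stage 2 (MIL),
score held-out patients, run the tumor-views-only ablation over several
seeds, repeat the pipeline on a null cohort (all effect shifts zero and
label-independent node visibility), and quantify CAM lesion
localization. Problem sizes default to roughly 300 training / 100 test
patients at 96 x 96 pixels — large enough for stable AUCs, small enough
to train on one CPU core in minutes.
"""

from __future__ import annotations

import tempfile
from pathlib import Path

import numpy as np

from .annotations import preprocess
from .cam import cam_for_image, lesion_mass_fraction
from .metrics import miou, roc_auc
from .phantom import CohortSpec, EffectParams, simulate_cohort, write_cohort
from .training import (TrainConfig, load_views, mtl_forward_views,
                       predict_patients, train_mil, train_mtl)


def _prepare_cohort(spec: CohortSpec, work_dir: Path, name: str,
                    train_ratio: float):
    root = work_dir / name
    patients = simulate_cohort(spec)
    manifest = write_cohort(patients, root, train_ratio=train_ratio)
    return root, manifest


def _pipeline(manifest, root, mtl_config: TrainConfig,
              mil_config: TrainConfig):
    """Train both stages; return nets plus cached split features."""
    net, _ = train_mtl(mtl_config, manifest, root)
    train_views = load_views(manifest, root, split="train")
    test_views = load_views(manifest, root, split="internal_test")
    size = mtl_config.image_size
    train_feats, _, _ = mtl_forward_views(net, train_views, size)
    test_feats, test_img_prob, test_seg = mtl_forward_views(net, test_views,
                                                            size)
    (extractor, bag_model), _ = train_mil(
        mil_config, manifest, root, mtl_net=net, mtl_config=mtl_config,
        cached_features=(train_views, train_feats))
    preds = predict_patients(manifest, root, net, mtl_config, extractor,
                             bag_model, cached_features=(test_views,
                                                         test_feats))
    cache = {"train": (train_views, train_feats),
             "test": (test_views, test_feats),
             "test_img_prob": test_img_prob, "test_seg": test_seg}
    return net, preds, cache


def cam_localization(net, test_views, test_img_prob, size: int,
                     max_views: int = 120):
    """Mean CAM lesion-mass fraction over correctly classified positive
    views, alongside the mean lesion-area fraction of those views."""
    mass, area = [], []
    for view, prob in zip(test_views, test_img_prob):
        if len(mass) >= max_views:
            break
        if view["aln_status"] != 1 or prob < 0.5:
            continue
        img, msk = preprocess(view["image"], view["mask"], "eval", size)
        heatmap = cam_for_image(net, img, class_index=1)
        frac = lesion_mass_fraction(heatmap, msk)
        if frac is None:
            continue
        mass.append(frac)
        area.append(msk.mean())
    if not mass:
        return float("nan"), float("nan"), 0
    return float(np.mean(mass)), float(np.mean(area)), len(mass)


def run_desk_benchmark(seed: int = 0, work_dir=None, n_patients: int = 400,
                       train_ratio: float = 0.75,
                       n_ablation_seeds: int = 3,
                       ablation_epochs: int = 40,
                       include_null: bool = True,
                       null_n_patients: int = 360,
                       null_mtl_iterations: int = 600) -> dict:
    """Full desk-scale study; returns a flat dict of measured quantities.

    All randomness derives from ``seed``: the phantom cohorts, weight
    initialisation and data order of every training run.
    """
    work_dir = Path(tempfile.mkdtemp()) if work_dir is None else Path(work_dir)
    work_dir.mkdir(parents=True, exist_ok=True)

    spec = CohortSpec(n_patients=n_patients, seed=seed)
    root, manifest = _prepare_cohort(spec, work_dir, "planted", train_ratio)
    mtl_cfg = TrainConfig.desk("mtl", seed=seed)
    mil_cfg = TrainConfig.desk("mil", seed=seed)
    net, preds, cache = _pipeline(manifest, root, mtl_cfg, mil_cfg)

    test_views, _ = cache["test"]
    gt_masks = [preprocess(v["image"], v["mask"], "eval",
                           mtl_cfg.image_size)[1] for v in test_views]
    results = {
        "n_train_patients": int(manifest[manifest.split == "train"]
                                ["patient_id"].nunique()),
        "n_test_patients": int(len(preds)),
        "auc_full_bag": roc_auc(preds["probability"], preds["label"]),
        "miou_foreground": miou(list(cache["test_seg"]), gt_masks),
    }

    # tumor-views-only ablation vs full bags, identical training, per seed
    full_aucs, tumor_aucs = [], []
    for k in range(n_ablation_seeds):
        sub_seed = seed + 101 + k
        cfg = TrainConfig.desk("mil", seed=sub_seed,
                               mil_epochs=ablation_epochs)
        (ext_f, bag_f), _ = train_mil(cfg, manifest, root, mtl_net=net,
                                      mtl_config=mtl_cfg,
                                      cached_features=cache["train"])
        p_f = predict_patients(manifest, root, net, mtl_cfg, ext_f, bag_f,
                               cached_features=cache["test"])
        full_aucs.append(roc_auc(p_f["probability"], p_f["label"]))
        (ext_t, bag_t), _ = train_mil(cfg, manifest, root, mtl_net=net,
                                      mtl_config=mtl_cfg, tumor_only=True,
                                      cached_features=cache["train"])
        p_t = predict_patients(manifest, root, net, mtl_cfg, ext_t, bag_t,
                               tumor_only=True, cached_features=cache["test"])
        tumor_aucs.append(roc_auc(p_t["probability"], p_t["label"]))
    results["ablation_auc_full"] = full_aucs
    results["ablation_auc_tumor_only"] = tumor_aucs

    # CAM localization on correctly classified positive held-out views
    mass, area, n_views = cam_localization(net, test_views,
                                           cache["test_img_prob"],
                                           mtl_cfg.image_size)
    results["cam_mass_fraction"] = mass
    results["lesion_area_fraction"] = area
    results["cam_n_views"] = n_views

    if include_null:
        null_spec = CohortSpec(
            n_patients=null_n_patients, seed=seed + 1,
            effect=EffectParams.null(),
            p_node_visible_pos=0.8, p_node_visible_neg=0.8)
        null_root, null_manifest = _prepare_cohort(null_spec, work_dir,
                                                   "null", train_ratio)
        null_mtl_cfg = TrainConfig.desk(
            "mtl", seed=seed, mtl_iterations=null_mtl_iterations)
        null_mil_cfg = TrainConfig.desk("mil", seed=seed, mil_epochs=30)
        _, null_preds, _ = _pipeline(null_manifest, null_root, null_mtl_cfg,
                                     null_mil_cfg)
        results["auc_null_effect"] = roc_auc(null_preds["probability"],
                                             null_preds["label"])
        results["n_null_test_patients"] = int(len(null_preds))
    return results
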