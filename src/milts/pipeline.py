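"""End-to-end orchestration: synth -> tile -> label -> train -> aggregate -> evaluate.

A flat :class:`RunConfig` carries every knob (training recipe defaults
follow the published settings: consistency weight 100, EMA decay 0.99,
SGD 1e-2 -> 1e-4 over two cosine cycles).  Every artifact is stamped with
a hash of the resolved configuration; re-running with the same config and
seed reproduces the metrics exactly on one CPU thread.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import aggregation, cohort, evaluation, mil, synthetic, tiling
from .errors import MiltsInputError

log = logging.getLogger("milts")


@dataclass
class RunConfig:
    """Flat experiment configuration (YAML round-trippable)."""

    seed: int = 0
    # synthetic cohort
    n_patients: int = 20
    slides_per_patient: int = 1
    image_size: int = 1536
    witness_rate_lo: float = 0.2
    witness_rate_hi: float = 0.5
    tissue_coverage: float = 0.7
    # data on disk instead of synthesis (directory with manifest.csv + slides/)
    data_dir: str = ""
    # masking / tiling
    mask_low: float = 0.05
    mask_high: float = 0.15
    mask_downsample: int = 32
    min_tissue_fraction: float = 0.05
    # labels
    threshold_kind: str = "tertile"
    use_planted_labels: bool = True
    # MIL training
    epochs: int = 30
    batch_size: int = 512
    base_lr: float = 1e-2
    min_lr: float = 1e-4
    lr_cycles: int = 2
    momentum: float = 0.9
    ema_decay: float = 0.99
    consistency_weight: float = 100.0
    labeled_proportion: float = -1.0       # -1 => derive from threshold_kind
    encoder_side: int = 32
    # aggregation
    aggregation: str = "attention_mlp"     # or "mean_pool"
    mlp_lr: float = 2e-4
    mlp_epochs: int = 300
    # evaluation
    bootstrap_resamples: int = 2000

    def resolved_proportion(self) -> float:
        if self.labeled_proportion > 0:
            return self.labeled_proportion
        return cohort.labeled_proportion(self.threshold_kind)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise MiltsInputError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def config_hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


@dataclass
class ExperimentResult:
    metrics: evaluation.MetricsReport
    slide_table: pd.DataFrame
    history: list[dict]
    instance_auc: float | None
    config_hash: str


def _sub_seed(seed: int, k: int) -> int:
    return int((seed * 1_000_003 + k) % (2**31 - 1))


def _load_cohort_from_dir(config: RunConfig) -> tuple[list, pd.DataFrame, dict]:
    root = Path(config.data_dir)
    manifest_path = root / "manifest.csv"
    if not manifest_path.exists():
        raise MiltsInputError(f"missing input path: {manifest_path}")
    manifest = pd.read_csv(manifest_path)
    slides = []
    for sid in manifest["slide_id"]:
        for ext in (".png", ".tif", ".tiff", ".jpg"):
            p = root / "slides" / f"{sid}{ext}"
            if p.exists():
                slides.append(tiling.load_slide(p, slide_id=str(sid)))
                break
        else:
            raise MiltsInputError(f"missing input path: {root / 'slides' / sid}")
    return slides, manifest, {}


def run_experiment(config: RunConfig, out_dir: str | Path | None = None
                   ) -> ExperimentResult:
    """Run the full pipeline and return metrics plus per-slide outputs.

    With ``out_dir`` set, the resolved config, per-epoch training log,
    metrics JSON and test-slide heatmaps are written there, and a finished
    run (matching config hash) is loaded instead of recomputed.
    """
    chash = config.config_hash()
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
        done = out / "metrics.json"
        if done.exists():
            prior = json.loads(done.read_text())
            if prior.get("config_hash") == chash:
                log.info("resuming: run %s already complete", chash)
                slide_table = pd.read_csv(out / "slides.csv")
                history = pd.read_csv(out / "training_log.csv").to_dict("records")
                m = prior["metrics"]
                return ExperimentResult(
                    evaluation.MetricsReport(**m), slide_table, history,
                    prior.get("instance_auc"), chash)
        config.to_yaml(out / "config.yaml")

    t0 = time.time()
    # ---- stage 1: data ------------------------------------------------
    truths: dict = {}
    if config.data_dir:
        slides, manifest, truths = _load_cohort_from_dir(config)
    else:
        spec = synthetic.SyntheticSpec(
            n_patients=config.n_patients,
            slides_per_patient=config.slides_per_patient,
            image_size=config.image_size,
            witness_rate_range=(config.witness_rate_lo, config.witness_rate_hi),
            tissue_coverage=config.tissue_coverage,
            seed=_sub_seed(config.seed, 1),
        )
        syn = synthetic.generate_cohort(spec)
        slides, manifest, truths = syn.slides, syn.manifest, syn.truths
    log.info("stage synth/load: %d slides (%.1fs)", len(slides), time.time() - t0)

    # ---- stage 2: mask + tile -----------------------------------------
    t0 = time.time()
    tiles_by_slide: dict[str, list[tiling.Tile]] = {}
    for slide in slides:
        mask = tiling.compute_tissue_mask(
            slide, config.mask_low, config.mask_high, config.mask_downsample)
        tiles_by_slide[slide.slide_id] = tiling.extract_tiles(
            slide, mask, min_tissue_fraction=config.min_tissue_fraction)
    log.info("stage tile: %d tiles (%.1fs)",
             sum(map(len, tiles_by_slide.values())), time.time() - t0)

    # ---- stage 3: labels + split --------------------------------------
    if config.use_planted_labels and "label" in manifest.columns:
        df = manifest.copy()
        patient_labels = {str(k): int(v) for k, v in
                          df.groupby("patient_id")["label"].max().items()}
        split = cohort.split_cohort(df["patient_id"].unique(),
                                    seed=_sub_seed(config.seed, 2),
                                    labels=patient_labels)
        df["split"] = df["patient_id"].astype(str).map(split.assignment)
    else:
        df = cohort.label_manifest(manifest, config.threshold_kind,
                                   seed=_sub_seed(config.seed, 2))
    labels = dict(zip(df["slide_id"].astype(str), df["label"].astype(int)))
    splits = dict(zip(df["slide_id"].astype(str), df["split"]))

    # ---- stage 4: MIL training ----------------------------------------
    t0 = time.time()
    train_bags = [
        mil.Bag(sid, tiles_by_slide[sid], labels[sid])
        for sid in tiles_by_slide if splits[sid] == "train" and tiles_by_slide[sid]
    ]
    model = mil.TeacherStudentMIL(
        epochs=config.epochs, batch_size=config.batch_size,
        base_lr=config.base_lr, min_lr=config.min_lr,
        lr_cycles=config.lr_cycles, momentum=config.momentum,
        ema_decay=config.ema_decay,
        consistency_weight=config.consistency_weight,
        labeled_proportion=config.resolved_proportion(),
        encoder_side=config.encoder_side,
        seed=_sub_seed(config.seed, 3),
    )
    model.fit(train_bags)
    log.info("stage train: %d bags, %d epochs (%.1fs)",
             len(train_bags), config.epochs, time.time() - t0)

    # ---- stage 5: aggregation -----------------------------------------
    t0 = time.time()
    probs_by_slide = {sid: model.predict_proba(tls)
                      for sid, tls in tiles_by_slide.items() if tls}
    classifier = None
    if config.aggregation == "attention_mlp":
        X, y = [], []
        for bag in train_bags:
            p = probs_by_slide[bag.slide_id]
            X.append((model.features(bag.instances),
                      aggregation.trimmed_stat_summary(p).values))
            y.append(bag.label)
        classifier = aggregation.SlideClassifier(
            lr=config.mlp_lr, epochs=config.mlp_epochs,
            seed=_sub_seed(config.seed, 4))
        classifier.fit(X, y)
    elif config.aggregation != "mean_pool":
        raise MiltsInputError("aggregation must be 'attention_mlp' or 'mean_pool'")
    log.info("stage aggregate: mode=%s (%.1fs)", config.aggregation,
             time.time() - t0)

    # ---- stage 6: evaluation ------------------------------------------
    rows = []
    for sid, tls in tiles_by_slide.items():
        if not tls:
            continue
        if classifier is not None:
            prob, _ = aggregation.predict_slide(tls, model, classifier)
        else:
            prob = float(np.mean(probs_by_slide[sid]))
        rows.append({"slide_id": sid, "split": splits[sid],
                     "label": labels[sid], "slide_prob": prob})
    slide_table = pd.DataFrame(rows).sort_values("slide_id").reset_index(drop=True)
    test = slide_table[slide_table["split"] == "test"]
    metrics = evaluation.evaluate_scores(
        test["slide_prob"], test["label"],
        n_resamples=config.bootstrap_resamples, seed=_sub_seed(config.seed, 5))

    instance_auc = None
    if truths:
        flags, tile_probs = [], []
        for sid in test["slide_id"]:
            truth = truths[sid]
            wit = {(int(r.x), int(r.y)): int(r.witness)
                   for r in truth.tiles.itertuples()}
            for t, p in zip(tiles_by_slide[sid], probs_by_slide[sid]):
                flags.append(wit.get((t.x, t.y), 0))
                tile_probs.append(p)
        if len(set(flags)) == 2:
            instance_auc = evaluation.roc_auc(tile_probs, flags)

    if out is not None:
        pd.DataFrame(model.history_).to_csv(out / "training_log.csv", index=False)
        slide_table.to_csv(out / "slides.csv", index=False)
        payload = {"config_hash": chash,
                   "metrics": dataclasses.asdict(metrics),
                   "instance_auc": instance_auc}
        (out / "metrics.json").write_text(json.dumps(payload, indent=2,
                                                     sort_keys=True) + "\n")
        _write_heatmaps(out / "heatmaps", slides, tiles_by_slide,
                        probs_by_slide, test["slide_id"])
    return ExperimentResult(metrics, slide_table, model.history_,
                            instance_auc, chash)


def _write_heatmaps(hm_dir: Path, slides, tiles_by_slide, probs_by_slide,
                    slide_ids) -> None:
    import imageio.v3 as iio

    hm_dir.mkdir(parents=True, exist_ok=True)
    by_id = {s.slide_id: s for s in slides}
    for sid in slide_ids:
        slide = by_id[sid]
        tls = []
        for t, p in zip(tiles_by_slide[sid], probs_by_slide[sid]):
            tls.append(dataclasses.replace(t, typicality=float(p)))
        img = evaluation.render_heatmap(
            tls, (slide.height_px, slide.width_px))
        iio.imwrite(hm_dir / f"{sid}_heatmap.png", img)
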