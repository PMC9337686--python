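"""End-to-end orchestration: simulate -> train -> predict -> detect -> match
-> stats -> metrics, under one run directory.

Every stage reads only the run directory and the configuration, and all
randomness derives from the single configured seed, so a full run is a
pure function of its :class:`PipelineConfig`: re-running with the same
config produces byte-identical reports.  Stages are idempotent — outputs
already present are reused unless ``force`` is set.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import tifffile

from . import __version__
from .detection import DetectionConfig, detect_nuclei, records_to_frame
from .matching import MatchingReport, match, matched_fraction
from .metrics import evaluate_pairs
from .nn.model import ModelConfig
from .nn.train import (load_checkpoint, predict, save_checkpoint, train,
                       write_training_log)
from .placement import PlacementNull, placement_report
from .synthetic import (RenderConfig, TileSample, generate_tiles,
                        read_dataset, split_indices, write_dataset)

__all__ = ["PipelineConfig", "PipelineStageError", "run_pipeline",
           "aggregate_match"]

log = logging.getLogger("actin2nucleus")


class PipelineStageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    out_dir: str = "run"
    seed: int = 0
    # simulate
    n_tiles: int = 340
    cells_per_tile: int = 3
    image_size_px: int = 64
    pixel_size_um: float = 0.8203125
    split_fraction: float = 0.8
    train_noise: str = "gaussian"
    test_noise: str = "none"
    psf_sigma_px: float = 0.8
    # train
    preset: str = "desk"
    iterations: int | None = None
    alpha: float = 10.0
    # analyse
    min_area_px: int = 50
    threshold_method: str = "otsu"
    thresholds_um: tuple[float, ...] = (4.0, 1.0)
    null_kind: str = "image"
    r_um: float = 4.0
    denominator: str = "all-generated"

    def to_dict(self) -> dict:
        d = asdict(self)
        d["thresholds_um"] = list(self.thresholds_um)
        return d


def _stage(name):
    def deco(fn):
        def wrapper(*a, **kw):
            log.info("stage %s: start", name)
            try:
                out = fn(*a, **kw)
            except Exception as e:          # noqa: BLE001
                log.error("stage %s: FAILED (%s)", name, e)
                raise PipelineStageError(name, e) from e
            log.info("stage %s: done", name)
            return out
        return wrapper
    return deco


def _dump_json(obj, path: Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, sort_keys=True, indent=1)


@_stage("simulate")
def _simulate(cfg: PipelineConfig, root: Path, force: bool):
    data_dir = root / "data"
    if (data_dir / "manifest.csv").exists() and not force:
        tiles = read_dataset(data_dir)
    else:
        render_tr = RenderConfig(psf_sigma_px=cfg.psf_sigma_px,
                                 noise_model=cfg.train_noise)
        render_te = RenderConfig(psf_sigma_px=cfg.psf_sigma_px,
                                 noise_model=cfg.test_noise)
        tr_idx, te_idx = split_indices(cfg.n_tiles, cfg.split_fraction,
                                       cfg.seed)
        te_set = set(int(i) for i in te_idx)
        # render train and test tiles with their own noise settings
        tiles_tr = generate_tiles(cfg.n_tiles, cfg.cells_per_tile,
                                  cfg.image_size_px, cfg.pixel_size_um,
                                  render_tr, seed=cfg.seed)
        tiles_te = generate_tiles(cfg.n_tiles, cfg.cells_per_tile,
                                  cfg.image_size_px, cfg.pixel_size_um,
                                  render_te, seed=cfg.seed)
        tiles = [tiles_te[i] if i in te_set else tiles_tr[i]
                 for i in range(cfg.n_tiles)]
        split = {t.pair.id: ("test" if i in te_set else "train")
                 for i, t in enumerate(tiles)}
        write_dataset(data_dir, tiles, split)
        # reload so in-memory data equals the quantized on-disk images and
        # a resumed run sees exactly what a fresh run saw
        tiles = read_dataset(data_dir)
    import pandas as pd
    manifest = pd.read_csv(data_dir / "manifest.csv")
    split_map = dict(zip(manifest["id"], manifest["split"]))
    train_tiles = [t for t in tiles if split_map[t.pair.id] == "train"]
    test_tiles = [t for t in tiles if split_map[t.pair.id] == "test"]
    return train_tiles, test_tiles


@_stage("train")
def _train(cfg: PipelineConfig, root: Path, train_tiles: list[TileSample],
           force: bool):
    ckpt = root / "model.ckpt.npz"
    if ckpt.exists() and not force:
        return load_checkpoint(ckpt)
    mcfg = ModelConfig.from_preset(
        cfg.preset, seed=cfg.seed, alpha=cfg.alpha,
        image_size_px=cfg.image_size_px,
        **({"max_iterations": cfg.iterations} if cfg.iterations else {}))
    masks = np.stack([t.nucleus_mask for t in train_tiles]).astype(np.float32)
    state = train([t.pair for t in train_tiles], masks, mcfg)
    save_checkpoint(state, ckpt)
    write_training_log(state, root / "training_log.csv")
    return state


@_stage("predict")
def _predict(cfg: PipelineConfig, root: Path, state,
             test_tiles: list[TileSample], force: bool):
    gen_dir = root / "generated"
    gen_dir.mkdir(exist_ok=True)
    out = {}
    for t in test_tiles:
        path = gen_dir / f"{t.pair.id}_generated.tif"
        if path.exists() and not force:
            out[t.pair.id] = tifffile.imread(path) / 65535.0
            continue
        img = predict(state, t.pair.actin)
        q = np.round(img * 65535).astype(np.uint16)
        tifffile.imwrite(path, q)
        out[t.pair.id] = q / 65535.0      # downstream sees the stored values
    return out


@_stage("detect")
def _detect(cfg: PipelineConfig, root: Path, test_tiles, generated):
    det = DetectionConfig(threshold_method=cfg.threshold_method,
                          min_area_px=cfg.min_area_px)
    gt, gen = {}, {}
    for t in test_tiles:
        gt[t.pair.id] = detect_nuclei(t.pair.nucleus, cfg.pixel_size_um, det)
        try:
            gen[t.pair.id] = detect_nuclei(generated[t.pair.id],
                                           cfg.pixel_size_um, det)
        except ValueError:
            gen[t.pair.id] = []          # all-background generated tile
    records_to_frame(gt).to_csv(root / "records_gt.csv", index=False)
    records_to_frame(gen).to_csv(root / "records_gen.csv", index=False)
    return gt, gen


def aggregate_match(gt_by_image: dict, gen_by_image: dict,
                    pixel_size_um: float) -> tuple[MatchingReport, list]:
    """Match per image, then pool pairs and counts across the test set."""
    pooled = MatchingReport(n_gt=0, n_gen=0, pixel_size_um=pixel_size_um)
    rows = []
    for image_id in sorted(gt_by_image):
        rep = match(gt_by_image[image_id], gen_by_image.get(image_id, []),
                    pixel_size_um=pixel_size_um)
        pooled.n_gt += rep.n_gt
        pooled.n_gen += rep.n_gen
        pooled.pairs.extend(rep.pairs)
        pooled.unmatched_gt.extend(rep.unmatched_gt)
        pooled.unmatched_gen.extend(rep.unmatched_gen)
        for p in rep.pairs:
            rows.append({"id": image_id, "gt_label": p.gt.label,
                         "gen_label": p.gen.label,
                         "overlap_ratio": p.overlap_ratio,
                         "distance_px": p.distance_px,
                         "distance_um": p.distance_um})
    if pooled.n_gt:
        pooled.count_error_pct = abs(pooled.n_gt - pooled.n_gen) \
            / pooled.n_gt * 100.0
    return pooled, rows


@_stage("match")
def _match(cfg: PipelineConfig, root: Path, gt, gen):
    import pandas as pd
    pooled, rows = aggregate_match(gt, gen, cfg.pixel_size_um)
    pd.DataFrame(rows, columns=["id", "gt_label", "gen_label",
                                "overlap_ratio", "distance_px",
                                "distance_um"]).to_csv(
        root / "matches.csv", index=False)
    report = {"n_gt": pooled.n_gt, "n_gen": pooled.n_gen,
              "n_paired": len(pooled.pairs),
              "count_error_pct": pooled.count_error_pct, "fractions": {}}
    for thr in cfg.thresholds_um:
        if pooled.n_gen:
            k, n, f = matched_fraction(pooled, thr,
                                       denominator=cfg.denominator)
            report["fractions"][f"{thr:g}um"] = {"k": k, "n": n,
                                                 "fraction": f}
    _dump_json(report, root / "report.json")
    return pooled


@_stage("stats")
def _stats(cfg: PipelineConfig, root: Path, pooled: MatchingReport):
    L_um = cfg.image_size_px * cfg.pixel_size_um
    null = PlacementNull.image(cfg.r_um, L_um)
    stats = placement_report(pooled, null, cfg.thresholds_um,
                             denominator=cfg.denominator)
    _dump_json(stats, root / "statistics.json")
    return stats


@_stage("metrics")
def _metrics(cfg: PipelineConfig, root: Path, test_tiles, generated):
    rep = evaluate_pairs([generated[t.pair.id] for t in test_tiles],
                         [t.pair.nucleus for t in test_tiles],
                         ids=[t.pair.id for t in test_tiles])
    _dump_json(rep.to_dict(), root / "metrics.json")
    return rep


def run_pipeline(cfg: PipelineConfig, force: bool = False) -> dict:
    """Execute the full analysis; returns the statistics dict."""
    root = Path(cfg.out_dir)
    root.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(root / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(message)s"))
    log.addHandler(handler)
    try:
        _dump_json({"config": cfg.to_dict(), "version": __version__},
                   root / "run.json")
        train_tiles, test_tiles = _simulate(cfg, root, force)
        state = _train(cfg, root, train_tiles, force)
        generated = _predict(cfg, root, state, test_tiles, force)
        gt, gen = _detect(cfg, root, test_tiles, generated)
        pooled = _match(cfg, root, gt, gen)
        stats = _stats(cfg, root, pooled)
        _metrics(cfg, root, test_tiles, generated)
        return stats
    finally:
        log.removeHandler(handler)
        handler.close()
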