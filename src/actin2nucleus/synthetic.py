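"""Synthetic paired actin/nucleus microscopy tiles.

The generator emulates the structure of confluent-fibroblast image tiles:
several non-overlapping cells per square tile, each cell a star-convex
polygon filled with fiber-like actin texture (anti-aliased thick line
segments), and a bright elliptical nucleus of ~4 µm mean radius on a
mostly-black background.  The nucleus position is a *deterministic
function of the fiber arrangement*: it sits at the intensity-weighted
centroid of the fiber midpoints (:func:`derive_nucleus_center`).  Because
the linkage is exact and known, the generated tiles act as ground truth
for every downstream stage — a translator that learns the actin texture
can in principle recover every nucleus position, and the scene records let
tests measure exactly how well it did.

Rendering applies an optional Gaussian point-spread blur and shot/readout
noise after rasterization; the returned nucleus mask is always the exact
pre-noise, pre-blur binary footprint (the ``M`` of the weighted
reconstruction loss).  Foreground occupies well under 10% of a default
tile, reproducing the class imbalance that motivates the weighted loss.

All operations are pure functions of their arguments including the seed:
per-operation RNG streams are derived from ``(seed, operation tag)``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from scipy import ndimage as ndi
from shapely.geometry import Point, Polygon
from skimage import draw as skdraw

__all__ = [
    "FiberSegment", "CellShape", "SceneSpec", "RenderConfig", "ImagePair",
    "TileSample", "PlacementError",
    "sample_scene", "derive_nucleus_center", "render_pair",
    "nucleus_mask_from_scene", "generate_tiles", "split_indices",
    "make_dataset", "write_dataset", "read_dataset",
]

#: default full-scale geometry: a 210 µm tile at 256 px
DEFAULT_TILE_UM = 210.0
DEFAULT_IMAGE_PX = 256
DEFAULT_PIXEL_UM = DEFAULT_TILE_UM / DEFAULT_IMAGE_PX   # 0.8203 µm/px
MEAN_NUCLEUS_RADIUS_UM = 4.0

_TAG_SCENE = 0x5343
_TAG_RENDER = 0x524E
_TAG_SPLIT = 0x5350


class PlacementError(RuntimeError):
    """Disjoint cell placement could not be achieved within the attempt budget."""


@dataclass
class FiberSegment:
    endpoints: tuple[tuple[float, float], tuple[float, float]]  # (row, col) px
    intensity: float            # peak value in [0, 1]
    width_px: float             # > 0

    @property
    def midpoint(self) -> tuple[float, float]:
        (r0, c0), (r1, c1) = self.endpoints
        return ((r0 + r1) / 2.0, (c0 + c1) / 2.0)


@dataclass
class CellShape:
    outline: np.ndarray                  # (K, 2) closed polygon, (row, col) px
    fibers: list[FiberSegment]
    nucleus_center: tuple[float, float]  # (row, col) px
    nucleus_radii: tuple[float, float]   # (major, minor) px
    nucleus_orientation: float           # radians
    clamped: bool = False                # True if the derived center was moved

    def polygon(self) -> Polygon:
        return Polygon([(c, r) for r, c in self.outline])

    def nucleus_polygon(self, n_points: int = 64) -> Polygon:
        t = np.linspace(0, 2 * np.pi, n_points, endpoint=False)
        a, b = self.nucleus_radii
        th = self.nucleus_orientation
        rr = self.nucleus_center[0] + a * np.cos(t) * np.cos(th) - \
            b * np.sin(t) * np.sin(th)
        cc = self.nucleus_center[1] + a * np.cos(t) * np.sin(th) + \
            b * np.sin(t) * np.cos(th)
        return Polygon(list(zip(cc, rr)))


@dataclass
class SceneSpec:
    cells: list[CellShape]
    image_size_um: float
    image_size_px: int
    pixel_size_um: float
    seed: int

    def __post_init__(self):
        if abs(self.image_size_um - self.image_size_px * self.pixel_size_um) \
                > 1e-9 * max(1.0, self.image_size_um):
            raise ValueError("image_size_um must equal image_size_px * pixel_size_um")

    def nucleus_centers(self) -> np.ndarray:
        return np.array([c.nucleus_center for c in self.cells], dtype=float)


@dataclass
class RenderConfig:
    psf_sigma_px: float = 1.0
    background_level: float = 0.02
    noise_model: str = "gaussian"       # none | gaussian | poisson
    noise_sigma: float = 0.01           # gaussian σ on [0,1] scale
    photon_scale: float = 200.0         # poisson: photons at intensity 1.0
    nucleus_intensity: float = 0.9
    bit_depth: int = 16

    def __post_init__(self):
        if self.noise_model not in ("none", "gaussian", "poisson"):
            raise ValueError(f"unknown noise model {self.noise_model!r}")
        if self.bit_depth not in (8, 16):
            raise ValueError("bit_depth must be 8 or 16")
        if not self.background_level < self.nucleus_intensity:
            raise ValueError("background_level must be below nucleus intensity")


@dataclass
class ImagePair:
    actin: np.ndarray           # 2D float in [0, 1]
    nucleus: np.ndarray         # 2D float in [0, 1]
    pixel_size_um: float
    id: str = ""

    def __post_init__(self):
        if self.actin.shape != self.nucleus.shape:
            raise ValueError("channels must share one shape")
        for name, ch in (("actin", self.actin), ("nucleus", self.nucleus)):
            if ch.min() < -1e-6 or ch.max() > 1 + 1e-6:
                raise ValueError(f"{name} channel outside [0, 1]")


@dataclass
class TileSample:
    """One generated tile with full ground truth."""
    pair: ImagePair
    nucleus_mask: np.ndarray
    scene: SceneSpec


# ---------------------------------------------------------------------------
# scene sampling
# ---------------------------------------------------------------------------

def derive_nucleus_center(fibers: list[FiberSegment]) -> tuple[float, float]:
    """Intensity-weighted centroid of the fiber midpoints.

    This functional *is* the deterministic actin-to-nucleus relation the
    synthetic data encode: the generator places each nucleus at the value
    returned here, so recovering nucleus positions from actin texture is
    well-posed by construction.
    """
    if not fibers:
        raise ValueError("need at least one fiber")
    w = np.array([f.intensity for f in fibers], dtype=float)
    mids = np.array([f.midpoint for f in fibers], dtype=float)
    if w.sum() <= 0:
        w = np.ones_like(w)
    ctr = (mids * w[:, None]).sum(axis=0) / w.sum()
    return (float(ctr[0]), float(ctr[1]))


def _star_polygon(center, radius, rng, n_vertices: int = 16,
                  roughness: float = 0.25) -> np.ndarray:
    """Star-convex polygon around ``center``; vertices within ``radius``."""
    angles = np.linspace(0, 2 * np.pi, n_vertices, endpoint=False)
    bumps = rng.uniform(1.0 - roughness, 1.0, size=n_vertices)
    # smooth the radial profile so neighbouring vertices agree
    bumps = np.convolve(np.r_[bumps[-1], bumps, bumps[0]],
                        [0.25, 0.5, 0.25], mode="valid")
    rr = center[0] + radius * bumps * np.sin(angles)
    cc = center[1] + radius * bumps * np.cos(angles)
    return np.column_stack([rr, cc])


def _sample_cell(rng, center, radius, pixel_size_um,
                 nucleus_radius_um, nucleus_radius_spread_um,
                 fibers_per_cell, center_jitter_px: float = 0.0,
                 max_fiber_attempts: int = 200) -> CellShape:
    outline = _star_polygon(center, radius, rng)
    poly = Polygon([(c, r) for r, c in outline])
    r_um = rng.normal(nucleus_radius_um, nucleus_radius_spread_um)
    r_um = float(np.clip(r_um, 0.5 * nucleus_radius_um, 1.5 * nucleus_radius_um))
    r_px = r_um / pixel_size_um
    d = rng.uniform(0.0, 0.2) * r_px
    major, minor = r_px + d, r_px - d          # mean stays exactly r_px
    orientation = rng.uniform(0, np.pi)

    n_fib = int(fibers_per_cell) if np.isscalar(fibers_per_cell) else \
        int(rng.integers(fibers_per_cell[0], fibers_per_cell[1] + 1))
    last: CellShape | None = None
    for _ in range(max_fiber_attempts):
        fibers = []
        for _ in range(n_fib):
            ang = rng.uniform(0, 2 * np.pi, size=2)
            frac = rng.uniform(0.15, 0.82, size=2)
            pts = [(center[0] + u * radius * np.sin(a),
                    center[1] + u * radius * np.cos(a))
                   for a, u in zip(ang, frac)]
            fibers.append(FiberSegment(
                endpoints=(tuple(pts[0]), tuple(pts[1])),
                intensity=float(rng.uniform(0.4, 1.0)),
                width_px=float(rng.uniform(1.0, 2.0))))
        if not all(poly.covers(Point(p[1], p[0]))
                   for f in fibers for p in f.endpoints):
            continue
        ctr = derive_nucleus_center(fibers)
        if center_jitter_px > 0:
            ctr = (ctr[0] + rng.normal(0, center_jitter_px),
                   ctr[1] + rng.normal(0, center_jitter_px))
        last = CellShape(outline, fibers, ctr, (major, minor), orientation)
        if poly.covers(last.nucleus_polygon()):
            return last
    if last is None:
        raise PlacementError("could not place fibers inside the cell outline")
    # last resort: pull the nucleus toward the cell center until it fits
    ctr = np.asarray(last.nucleus_center, dtype=float)
    target = np.asarray(center, dtype=float)
    for t in np.linspace(0.1, 1.0, 10):
        moved = tuple((1 - t) * ctr + t * target)
        cell = CellShape(outline, last.fibers, moved, (major, minor),
                         orientation, clamped=True)
        if poly.covers(cell.nucleus_polygon()):
            return cell
    raise PlacementError("could not place a nucleus inside the cell outline")


def sample_scene(n_cells: int, image_size_px: int = DEFAULT_IMAGE_PX,
                 pixel_size_um: float = DEFAULT_PIXEL_UM, seed: int = 0, *,
                 cell_radius_px: tuple[float, float] | None = None,
                 nucleus_radius_um: float = MEAN_NUCLEUS_RADIUS_UM,
                 nucleus_radius_spread_um: float = 0.3,
                 fibers_per_cell: tuple[int, int] = (6, 12),
                 center_jitter_px: float = 0.0,
                 max_attempts: int | None = None) -> SceneSpec:
    """Sample a tile layout of ``n_cells`` disjoint cells with ground truth.

    Cells are placed by rejection (dart throwing) on bounding circles; a
    :class:`PlacementError` signals an overcrowded configuration.
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    rng = np.random.default_rng(np.random.SeedSequence([seed, _TAG_SCENE]))
    if cell_radius_px is None:
        # scale cell size with tile: ~25% bounding-circle packing density
        r_hi = min(0.33 * image_size_px / np.sqrt(n_cells),
                   0.45 * image_size_px)
        cell_radius_px = (0.75 * r_hi, r_hi)
    lo, hi = cell_radius_px
    # infeasibility checks before attempting placement: the tile must hold
    # n disjoint bounding circles, each big enough to contain a nucleus
    min_cell_px = 1.45 * nucleus_radius_um / pixel_size_um
    if lo < min_cell_px:
        raise PlacementError(
            f"{n_cells} cells in a {image_size_px} px tile would need radius "
            f"{lo:.2f} px < {min_cell_px:.2f} px required to hold a "
            f"{nucleus_radius_um} um nucleus")
    if n_cells * np.pi * lo ** 2 > 0.85 * image_size_px ** 2:
        raise PlacementError(
            f"{n_cells} cells of radius >= {lo:.1f} px cannot fit disjointly "
            f"in a {image_size_px} px tile")
    budget = max_attempts if max_attempts is not None else \
        min(400 * n_cells, 200_000)
    placed: list[tuple[float, float, float]] = []   # (row, col, radius)
    attempts = 0
    while len(placed) < n_cells:
        if attempts >= budget:
            raise PlacementError(
                f"placed only {len(placed)}/{n_cells} cells after "
                f"{attempts} attempts")
        attempts += 1
        r = rng.uniform(lo, hi)
        row = rng.uniform(r * 0.7, image_size_px - r * 0.7)
        col = rng.uniform(r * 0.7, image_size_px - r * 0.7)
        if all(np.hypot(row - p[0], col - p[1]) > r + p[2] + 1.0
               for p in placed):
            placed.append((row, col, r))
    cells = [
        _sample_cell(rng, (row, col), r, pixel_size_um,
                     nucleus_radius_um, nucleus_radius_spread_um,
                     fibers_per_cell, center_jitter_px)
        for row, col, r in placed]
    return SceneSpec(cells=cells,
                     image_size_um=image_size_px * pixel_size_um,
                     image_size_px=image_size_px,
                     pixel_size_um=pixel_size_um, seed=seed)


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

def _stamp_segment(img: np.ndarray, seg: FiberSegment) -> None:
    """Add one anti-aliased thick segment to ``img`` in place."""
    (r0, c0), (r1, c1) = seg.endpoints
    half = seg.width_px / 2.0
    pad = int(np.ceil(half)) + 2
    rmin = max(0, int(np.floor(min(r0, r1))) - pad)
    rmax = min(img.shape[0], int(np.ceil(max(r0, r1))) + pad + 1)
    cmin = max(0, int(np.floor(min(c0, c1))) - pad)
    cmax = min(img.shape[1], int(np.ceil(max(c0, c1))) + pad + 1)
    if rmin >= rmax or cmin >= cmax:
        return
    rr, cc = np.mgrid[rmin:rmax, cmin:cmax]
    dr, dc = r1 - r0, c1 - c0
    L2 = dr * dr + dc * dc
    if L2 == 0:
        dist = np.hypot(rr - r0, cc - c0)
    else:
        t = np.clip(((rr - r0) * dr + (cc - c0) * dc) / L2, 0.0, 1.0)
        dist = np.hypot(rr - (r0 + t * dr), cc - (c0 + t * dc))
    cov = np.clip(half + 0.5 - dist, 0.0, 1.0)
    img[rmin:rmax, cmin:cmax] += seg.intensity * cov


def _ellipse_mask(shape, center, radii, orientation) -> np.ndarray:
    rr, cc = skdraw.ellipse(center[0], center[1], radii[0], radii[1],
                            shape=shape, rotation=orientation)
    m = np.zeros(shape, dtype=bool)
    m[rr, cc] = True
    return m


def nucleus_mask_from_scene(scene: SceneSpec) -> np.ndarray:
    """Exact binary footprint of every nucleus ellipse (pre-blur, pre-noise)."""
    shape = (scene.image_size_px, scene.image_size_px)
    mask = np.zeros(shape, dtype=bool)
    for cell in scene.cells:
        mask |= _ellipse_mask(shape, cell.nucleus_center, cell.nucleus_radii,
                              cell.nucleus_orientation)
    return mask


def render_pair(scene: SceneSpec, cfg: RenderConfig | None = None,
                seed: int = 0, pair_id: str = ""
                ) -> tuple[ImagePair, np.ndarray]:
    """Rasterize a scene into a registered (actin, nucleus) image pair.

    The actin channel contains only fiber renderings, the nucleus channel
    only nucleus ellipses (no cross-channel leakage).  With
    ``noise_model='none'`` and ``psf_sigma_px=0`` the nucleus channel takes
    exactly the two values {background_level, nucleus_intensity}.
    """
    cfg = cfg or RenderConfig()
    shape = (scene.image_size_px, scene.image_size_px)
    actin = np.zeros(shape, dtype=np.float64)
    for cell in scene.cells:
        for seg in cell.fibers:
            _stamp_segment(actin, seg)
    actin = np.clip(actin, 0.0, 1.0 - cfg.background_level)
    actin += cfg.background_level

    mask = nucleus_mask_from_scene(scene)
    nucleus = np.full(shape, cfg.background_level, dtype=np.float64)
    nucleus[mask] = cfg.nucleus_intensity

    if cfg.psf_sigma_px > 0:
        actin = ndi.gaussian_filter(actin, cfg.psf_sigma_px)
        nucleus = ndi.gaussian_filter(nucleus, cfg.psf_sigma_px)
    rng = np.random.default_rng(np.random.SeedSequence([seed, _TAG_RENDER]))
    if cfg.noise_model == "gaussian":
        actin = actin + rng.normal(0, cfg.noise_sigma, shape)
        nucleus = nucleus + rng.normal(0, cfg.noise_sigma, shape)
    elif cfg.noise_model == "poisson":
        actin = rng.poisson(actin * cfg.photon_scale) / cfg.photon_scale
        nucleus = rng.poisson(nucleus * cfg.photon_scale) / cfg.photon_scale
    actin = np.clip(actin, 0.0, 1.0)
    nucleus = np.clip(nucleus, 0.0, 1.0)
    pair = ImagePair(actin=actin, nucleus=nucleus,
                     pixel_size_um=scene.pixel_size_um, id=pair_id)
    return pair, mask


# ---------------------------------------------------------------------------
# datasets
# ---------------------------------------------------------------------------

def generate_tiles(n_tiles: int, n_cells: int = 20,
                   image_size_px: int = DEFAULT_IMAGE_PX,
                   pixel_size_um: float = DEFAULT_PIXEL_UM,
                   render_cfg: RenderConfig | None = None, seed: int = 0,
                   **scene_kwargs) -> list[TileSample]:
    """Generate ``n_tiles`` independent tiles with ground-truth scenes."""
    root = np.random.SeedSequence([seed, 0x54494C])
    tile_seeds = [int(s.generate_state(1)[0] % (2 ** 31))
                  for s in root.spawn(n_tiles)]
    out = []
    for i, ts in enumerate(tile_seeds):
        scene = sample_scene(n_cells, image_size_px, pixel_size_um, seed=ts,
                             **scene_kwargs)
        pair, mask = render_pair(scene, render_cfg, seed=ts,
                                 pair_id=f"tile{i:05d}")
        out.append(TileSample(pair=pair, nucleus_mask=mask, scene=scene))
    return out


def split_indices(n_tiles: int, split_fraction: float, seed: int
                  ) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic random train/test split; |train| = round(f * n)."""
    if not 0 < split_fraction < 1:
        raise ValueError("split_fraction must be in (0, 1)")
    if n_tiles < 2:
        raise ValueError("need at least 2 tiles to split")
    rng = np.random.default_rng(np.random.SeedSequence([seed, _TAG_SPLIT]))
    perm = rng.permutation(n_tiles)
    n_train = int(round(split_fraction * n_tiles))
    return np.sort(perm[:n_train]), np.sort(perm[n_train:])


def make_dataset(n_tiles: int, split_fraction: float = 0.8, seed: int = 0,
                 **tile_kwargs) -> tuple[list[ImagePair], list[ImagePair]]:
    """Generate tiles and split them into train/test image-pair lists."""
    train_idx, test_idx = split_indices(n_tiles, split_fraction, seed)
    tiles = generate_tiles(n_tiles, seed=seed, **tile_kwargs)
    train = [tiles[i].pair for i in train_idx]
    test = [tiles[i].pair for i in test_idx]
    return train, test


# ---------------------------------------------------------------------------
# on-disk format
# ---------------------------------------------------------------------------

def _quantize(img: np.ndarray, bit_depth: int) -> np.ndarray:
    if bit_depth == 8:
        return np.round(img * 255).astype(np.uint8)
    return np.round(img * 65535).astype(np.uint16)


def _scene_to_json(scene: SceneSpec, pair_id: str) -> dict:
    return {
        "id": pair_id,
        "image_size_um": scene.image_size_um,
        "image_size_px": scene.image_size_px,
        "pixel_size_um": scene.pixel_size_um,
        "seed": scene.seed,
        "cells": [{
            "outline": np.asarray(c.outline).tolist(),
            "fibers": [{"endpoints": [list(p) for p in f.endpoints],
                        "intensity": f.intensity,
                        "width_px": f.width_px} for f in c.fibers],
            "nucleus_center": list(c.nucleus_center),
            "nucleus_radii": list(c.nucleus_radii),
            "nucleus_orientation": c.nucleus_orientation,
            "clamped": c.clamped,
        } for c in scene.cells],
    }


def _scene_from_json(d: dict) -> SceneSpec:
    cells = [CellShape(
        outline=np.asarray(c["outline"], dtype=float),
        fibers=[FiberSegment(endpoints=(tuple(f["endpoints"][0]),
                                        tuple(f["endpoints"][1])),
                             intensity=f["intensity"],
                             width_px=f["width_px"]) for f in c["fibers"]],
        nucleus_center=tuple(c["nucleus_center"]),
        nucleus_radii=tuple(c["nucleus_radii"]),
        nucleus_orientation=c["nucleus_orientation"],
        clamped=c.get("clamped", False)) for c in d["cells"]]
    return SceneSpec(cells=cells, image_size_um=d["image_size_um"],
                     image_size_px=d["image_size_px"],
                     pixel_size_um=d["pixel_size_um"], seed=d["seed"])


def write_dataset(out_dir, tiles: list[TileSample],
                  split: dict[str, str] | None = None,
                  bit_depth: int = 16) -> None:
    """Write ``<id>_actin.tif`` / ``<id>_nucleus.tif``, scenes.json, manifest.csv."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows, scenes = [], []
    for t in tiles:
        pid = t.pair.id
        tifffile.imwrite(out / f"{pid}_actin.tif",
                         _quantize(t.pair.actin, bit_depth))
        tifffile.imwrite(out / f"{pid}_nucleus.tif",
                         _quantize(t.pair.nucleus, bit_depth))
        scenes.append(_scene_to_json(t.scene, pid))
        rows.append({"id": pid,
                     "split": (split or {}).get(pid, ""),
                     "pixel_size_um": t.pair.pixel_size_um})
    with open(out / "scenes.json", "w") as fh:
        json.dump({"scenes": scenes}, fh)
    pd.DataFrame(rows).to_csv(out / "manifest.csv", index=False)


def read_dataset(in_dir) -> list[TileSample]:
    """Read a dataset written by :func:`write_dataset`."""
    root = Path(in_dir)
    manifest = pd.read_csv(root / "manifest.csv")
    with open(root / "scenes.json") as fh:
        scene_index = {s["id"]: s for s in json.load(fh)["scenes"]}
    tiles = []
    for _, row in manifest.iterrows():
        pid = row["id"]
        actin = tifffile.imread(root / f"{pid}_actin.tif")
        nucleus = tifffile.imread(root / f"{pid}_nucleus.tif")
        denom = 255.0 if actin.dtype == np.uint8 else 65535.0
        scene = _scene_from_json(scene_index[pid])
        pair = ImagePair(actin=actin / denom, nucleus=nucleus / denom,
                         pixel_size_um=float(row["pixel_size_um"]), id=pid)
        tiles.append(TileSample(pair=pair,
                                nucleus_mask=nucleus_mask_from_scene(scene),
                                scene=scene))
    return tiles
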