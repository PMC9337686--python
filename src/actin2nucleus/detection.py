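"""Nucleus detection: binarization, connected components, region properties.

A nucleus-channel image (real or generated) is thresholded (Otsu by
default, a fixed threshold as escape hatch), labeled into connected
components, and reduced to per-nucleus records of area, centroid and
bounding box.  Components below a minimum area (default 50 px) are
discarded as thresholding noise.  Nuclei partially outside the image are
detected and counted like any other component — the automatic counter is
deliberately more permissive at image edges than a human annotator.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from skimage import measure
from skimage.filters import threshold_otsu

__all__ = [
    "DetectionConfig", "NucleusRecord", "LabelMap", "DegenerateImageError",
    "binarize", "label_components", "extract_records", "count_nuclei",
    "detect_nuclei", "records_to_frame", "records_from_frame",
]

#: minimum component area used throughout the analysis
DEFAULT_MIN_AREA_PX = 50


class DegenerateImageError(ValueError):
    """Otsu thresholding on a constant image (all-background tile)."""


@dataclass
class DetectionConfig:
    threshold_method: str = "otsu"     # "otsu" or "fixed"
    threshold_value: float = 0.5       # used when threshold_method == "fixed"
    min_area_px: int = DEFAULT_MIN_AREA_PX
    connectivity: int = 8              # 4 or 8

    def __post_init__(self):
        if self.threshold_method not in ("otsu", "fixed"):
            raise ValueError(f"unknown threshold method {self.threshold_method!r}")
        if self.min_area_px < 1:
            raise ValueError("min_area_px must be >= 1")
        if self.connectivity not in (4, 8):
            raise ValueError("connectivity must be 4 or 8")


@dataclass
class NucleusRecord:
    """One detected nucleus."""

    label: int
    area_px: int
    centroid: tuple[float, float]            # (row, col), px
    bbox: tuple[int, int, int, int]          # (min_row, min_col, height, width)
    centroid_um: tuple[float, float]         # (row, col) * pixel_size_um


@dataclass
class LabelMap:
    labels: np.ndarray       # 2D int array, 0 = background
    n_labels: int


def binarize(image: np.ndarray, cfg: DetectionConfig | None = None
             ) -> np.ndarray:
    """Threshold an intensity image in [0, 1] to a boolean foreground mask."""
    cfg = cfg or DetectionConfig()
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise ValueError("expected a single-channel 2D image")
    if cfg.threshold_method == "fixed":
        thr = cfg.threshold_value
    else:
        if np.ptp(image) == 0:
            raise DegenerateImageError(
                "constant image: Otsu threshold undefined (all-background tile)")
        thr = threshold_otsu(image, nbins=256)
    return image > thr


def label_components(mask: np.ndarray, connectivity: int = 8) -> LabelMap:
    """Connected-component labeling, labels assigned in raster-scan order."""
    mask = np.asarray(mask, dtype=bool)
    conn = 1 if connectivity == 4 else 2
    labels, n = measure.label(mask, connectivity=conn, return_num=True)
    return LabelMap(labels=labels, n_labels=n)


def extract_records(label_map: LabelMap, pixel_size_um: float,
                    cfg: DetectionConfig | None = None) -> list[NucleusRecord]:
    """Region properties per surviving component.

    Centroid is the unweighted mean of member pixel coordinates; the
    bounding box is the tight half-open axis-aligned box reported as
    (min_row, min_col, height, width).  Components smaller than
    ``cfg.min_area_px`` are removed.
    """
    cfg = cfg or DetectionConfig()
    records = []
    for rp in measure.regionprops(label_map.labels):
        if rp.area < cfg.min_area_px:
            continue
        minr, minc, maxr, maxc = rp.bbox
        cy, cx = rp.centroid
        records.append(NucleusRecord(
            label=int(rp.label),
            area_px=int(rp.area),
            centroid=(float(cy), float(cx)),
            bbox=(int(minr), int(minc), int(maxr - minr), int(maxc - minc)),
            centroid_um=(float(cy * pixel_size_um), float(cx * pixel_size_um))))
    return records


def count_nuclei(records: list[NucleusRecord]) -> int:
    return len(records)


def detect_nuclei(image: np.ndarray, pixel_size_um: float,
                  cfg: DetectionConfig | None = None) -> list[NucleusRecord]:
    """binarize -> label -> extract, in one call."""
    cfg = cfg or DetectionConfig()
    mask = binarize(image, cfg)
    lmap = label_components(mask, cfg.connectivity)
    return extract_records(lmap, pixel_size_um, cfg)


# -- records.csv -----------------------------------------------------------

def records_to_frame(records_by_image: dict[str, list[NucleusRecord]]
                     ) -> pd.DataFrame:
    rows = []
    for image_id, recs in records_by_image.items():
        for r in recs:
            rows.append({
                "id": image_id, "label": r.label, "area_px": r.area_px,
                "centroid_row": r.centroid[0], "centroid_col": r.centroid[1],
                "bbox_min_row": r.bbox[0], "bbox_min_col": r.bbox[1],
                "bbox_height": r.bbox[2], "bbox_width": r.bbox[3],
                "centroid_row_um": r.centroid_um[0],
                "centroid_col_um": r.centroid_um[1]})
    cols = ["id", "label", "area_px", "centroid_row", "centroid_col",
            "bbox_min_row", "bbox_min_col", "bbox_height", "bbox_width",
            "centroid_row_um", "centroid_col_um"]
    return pd.DataFrame(rows, columns=cols)


def records_from_frame(frame: pd.DataFrame) -> dict[str, list[NucleusRecord]]:
    out: dict[str, list[NucleusRecord]] = {}
    for _, row in frame.iterrows():
        out.setdefault(str(row["id"]), []).append(NucleusRecord(
            label=int(row["label"]), area_px=int(row["area_px"]),
            centroid=(float(row["centroid_row"]), float(row["centroid_col"])),
            bbox=(int(row["bbox_min_row"]), int(row["bbox_min_col"]),
                  int(row["bbox_height"]), int(row["bbox_width"])),
            centroid_um=(float(row["centroid_row_um"]),
                         float(row["centroid_col_um"]))))
    return out
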