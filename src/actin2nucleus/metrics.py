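"""Image-quality metrics for generated nucleus images.

l1, PSNR and SSIM are computed natively (SSIM through scikit-image with
the canonical Gaussian 11x11 / sigma 1.5 window and K1=0.01, K2=0.03).
Perceptual metrics that require pretrained feature extractors (LPIPS, FID)
are exposed only as an optional plugin registry: register a callable and
it will appear in the report; nothing is downloaded.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from skimage.metrics import structural_similarity

__all__ = ["MetricsReport", "l1_mean", "psnr", "ssim",
           "register_metric_plugin", "evaluate_pairs"]

PSNR_CAP_DB = 100.0

_PLUGINS: dict[str, Callable[[np.ndarray, np.ndarray], float]] = {}


def register_metric_plugin(name: str,
                           fn: Callable[[np.ndarray, np.ndarray], float]
                           ) -> None:
    """Register an extra per-image metric (e.g. an LPIPS implementation)."""
    _PLUGINS[name] = fn


def _check(a, b) -> tuple[np.ndarray, np.ndarray]:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    return a, b


def l1_mean(a, b) -> float:
    """Mean absolute pixel difference."""
    a, b = _check(a, b)
    return float(np.mean(np.abs(a - b)))


def psnr(a, b, data_range: float = 1.0) -> float:
    """Peak signal-to-noise ratio, 10*log10(range^2 / MSE), in dB.

    Identical images return the documented cap (100 dB) instead of inf.
    """
    a, b = _check(a, b)
    mse = float(np.mean((a - b) ** 2))
    if mse == 0:
        return PSNR_CAP_DB
    return min(PSNR_CAP_DB, float(10.0 * np.log10(data_range ** 2 / mse)))


def ssim(a, b, data_range: float = 1.0) -> float:
    """Mean structural similarity with a Gaussian window (sigma 1.5, 11x11)."""
    a, b = _check(a, b)
    if min(a.shape) < 11:
        raise ValueError("image smaller than the 11x11 SSIM window")
    return float(structural_similarity(
        a, b, data_range=data_range, gaussian_weights=True, sigma=1.5,
        win_size=11, use_sample_covariance=False, K1=0.01, K2=0.03))


@dataclass
class MetricsReport:
    per_image: list[dict] = field(default_factory=list)
    aggregates: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {"per_image": self.per_image, "aggregates": self.aggregates}


def evaluate_pairs(generated: list[np.ndarray], ground_truth: list[np.ndarray],
                   ids: list[str] | None = None) -> MetricsReport:
    """Per-image l1/PSNR/SSIM (plus registered plugins) and mean/sd aggregates."""
    if len(generated) != len(ground_truth):
        raise ValueError("generated and ground-truth lists differ in length")
    ids = ids or [f"img{i:04d}" for i in range(len(generated))]
    report = MetricsReport()
    for pid, gen, gt in zip(ids, generated, ground_truth):
        row = {"id": pid, "l1_mean": l1_mean(gen, gt),
               "psnr_db": psnr(gen, gt), "ssim": ssim(gen, gt)}
        for name, fn in _PLUGINS.items():
            row[name] = float(fn(gen, gt))
        report.per_image.append(row)
    keys = [k for k in report.per_image[0] if k != "id"] if report.per_image else []
    for key in keys:
        vals = np.array([r[key] for r in report.per_image])
        report.aggregates[key] = {"mean": float(vals.mean()),
                                  "sd": float(vals.std(ddof=1))
                                  if len(vals) > 1 else 0.0}
    return report
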