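"""Random-placement null models and binomial statistics for nucleus position.

The scientific question is whether a translator that places generated
nuclei within r = 4 µm of their real positions could be doing so by
chance.  Under the *image-level* null a centroid is dropped uniformly over
an L x L µm tile and succeeds with probability

    p = pi r^2 / L^2,

("one out of ~500" for r = 4, L = 159.41).  Under the *cell-level* null
the centroid is restricted to the cell mask eroded by the nuclear radius
(the nucleus must lie wholly inside the cell), and p is the pixel-count
ratio of the matched disk to the eroded region.  The number of correct
predictions among n trials is modeled as Binomial(n, p); the module
provides exact (Clopper-Pearson), Wilson-score and normal confidence
intervals for the observed proportion, and one-sided upper-tail p-values
P(X >= k) computed either by extended-precision log-space summation
(mpmath) or by a continuity-corrected normal approximation evaluated in
log space — both remain finite for arbitrarily extreme tails.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import mpmath
import numpy as np
from scipy import ndimage as ndi
from scipy.special import log_ndtr, ndtri
from scipy.stats import beta as beta_dist

__all__ = [
    "PlacementNull", "ProportionCI", "BinomialTest",
    "p_random_image", "p_random_cell", "proportion_ci",
    "binomial_tail_log10", "placement_report",
]

CI_METHODS = ("clopper_pearson", "wilson_score", "normal")


@dataclass
class PlacementNull:
    kind: str                    # "image" or "cell"
    r_um: float
    p: float
    L_um: float | None = None
    detail: dict = field(default_factory=dict)

    def __post_init__(self):
        if not 0 < self.p < 1:
            raise ValueError(f"null probability must be in (0,1), got {self.p}")

    @classmethod
    def image(cls, r_um: float, L_um: float) -> "PlacementNull":
        return cls(kind="image", r_um=r_um, L_um=L_um,
                   p=p_random_image(r_um, L_um))

    @classmethod
    def cell(cls, cell_mask, pixel_size_um, r_um, true_center
             ) -> "PlacementNull":
        p, detail = p_random_cell(cell_mask, pixel_size_um, r_um, true_center,
                                  return_detail=True)
        return cls(kind="cell", r_um=r_um, p=p, detail=detail)


@dataclass
class ProportionCI:
    k: int
    n: int
    p_hat: float
    level: float
    lower: float
    upper: float
    method: str

    @property
    def half_width(self) -> float:
        return (self.upper - self.lower) / 2.0


@dataclass
class BinomialTest:
    n: int
    k: int
    p0: float
    log10_pvalue: float
    approximation: str


def p_random_image(r_um: float, L_um: float) -> float:
    """Success probability of a uniform random centroid within r of the truth."""
    if r_um <= 0 or L_um <= 0:
        raise ValueError("r and L must be positive")
    if 2 * r_um >= L_um:
        raise ValueError("match disk must fit inside the image (2r < L)")
    return math.pi * r_um ** 2 / L_um ** 2


def p_random_cell(cell_mask: np.ndarray, pixel_size_um: float, r_um: float,
                  true_center: tuple[float, float],
                  return_detail: bool = False):
    """Cell-level null probability by pixel counting.

    ``allowed`` is the cell mask eroded by a discrete disk of the nuclear
    radius (positions closer than r to the cell edge are discarded);
    ``matched`` are the allowed pixels within r of the true center.
    """
    if r_um <= 0:
        raise ValueError("r_um must be positive")
    mask = np.asarray(cell_mask, dtype=bool)
    r_px = r_um / pixel_size_um
    rr = int(round(r_px))
    yy, xx = np.mgrid[-rr:rr + 1, -rr:rr + 1]
    selem = (yy ** 2 + xx ** 2) <= rr ** 2
    allowed = ndi.binary_erosion(mask, structure=selem)
    n_allowed = int(allowed.sum())
    if n_allowed == 0:
        raise ValueError("eroded cell region is empty: cell too small for nucleus")
    iy, ix = np.nonzero(allowed)
    if not allowed[int(round(true_center[0])), int(round(true_center[1]))]:
        raise ValueError("true_center must lie in the eroded (allowed) region")
    d2 = (iy - true_center[0]) ** 2 + (ix - true_center[1]) ** 2
    n_matched = int((d2 <= r_px ** 2).sum())
    p = n_matched / n_allowed
    p = min(max(p, 1.0 / (n_allowed + 1)), 1.0 - 1.0 / (n_allowed + 1))
    if return_detail:
        return p, {"n_allowed": n_allowed, "n_matched": n_matched,
                   "r_px": r_px}
    return p


def proportion_ci(k: int, n: int, level: float = 0.95,
                  method: str = "wilson_score") -> ProportionCI:
    """Binomial proportion confidence interval.

    clopper_pearson: exact interval via Beta quantiles;
    wilson_score: score-test inversion (the interval the headline
    71.0 +/- 1.0% derives from); normal: Wald interval.
    """
    if not 0 <= k <= n or n < 1:
        raise ValueError("need 0 <= k <= n, n >= 1")
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    if method not in CI_METHODS:
        raise ValueError(f"unknown CI method {method!r}")
    p_hat = k / n
    a = 1.0 - level
    if method == "clopper_pearson":
        lower = 0.0 if k == 0 else float(beta_dist.ppf(a / 2, k, n - k + 1))
        upper = 1.0 if k == n else float(beta_dist.ppf(1 - a / 2, k + 1, n - k))
    elif method == "wilson_score":
        z = float(ndtri(1 - a / 2))
        denom = 1 + z ** 2 / n
        center = (p_hat + z ** 2 / (2 * n)) / denom
        hw = z * math.sqrt(p_hat * (1 - p_hat) / n + z ** 2 / (4 * n ** 2)) / denom
        lower, upper = max(0.0, center - hw), min(1.0, center + hw)
    else:
        z = float(ndtri(1 - a / 2))
        hw = z * math.sqrt(p_hat * (1 - p_hat) / n)
        lower, upper = max(0.0, p_hat - hw), min(1.0, p_hat + hw)
    return ProportionCI(k=k, n=n, p_hat=p_hat, level=level,
                        lower=lower, upper=upper, method=method)


def binomial_tail_log10(n: int, k: int, p0: float,
                        approximation: str = "exact_log") -> float:
    """log10 of the one-sided upper tail P(X >= k), X ~ Binomial(n, p0).

    ``exact_log`` sums the tail terms in log space with mpmath extended
    precision; ``normal`` uses the continuity-corrected Gaussian upper
    tail via ``log_ndtr`` (finite for arbitrarily large z).  For k < n the
    result is always finite.
    """
    if not 0 <= k <= n:
        raise ValueError("need 0 <= k <= n")
    if not 0 < p0 < 1:
        raise ValueError("p0 must be in (0, 1)")
    if approximation not in ("exact_log", "normal"):
        raise ValueError(f"unknown approximation {approximation!r}")
    if k == 0:
        return 0.0
    if approximation == "normal":
        mu = n * p0
        sd = math.sqrt(n * p0 * (1 - p0))
        z = (k - 0.5 - mu) / sd
        return float(log_ndtr(-z) / math.log(10.0))
    with mpmath.workdps(50):
        ln_p = mpmath.log(mpmath.mpf(p0))
        ln_q = mpmath.log(1 - mpmath.mpf(p0))
        ln_fact_n = mpmath.loggamma(n + 1)
        terms = []
        for i in range(k, n + 1):
            ln_c = ln_fact_n - mpmath.loggamma(i + 1) - mpmath.loggamma(n - i + 1)
            terms.append(ln_c + i * ln_p + (n - i) * ln_q)
        m = max(terms)
        s = mpmath.fsum(mpmath.e ** (t - m) for t in terms)
        ln_tail = m + mpmath.log(s)
        return float(ln_tail / mpmath.log(10))


def placement_report(matching_report, null: PlacementNull,
                     thresholds_um: tuple[float, ...] = (4.0, 1.0),
                     level: float = 0.95,
                     denominator: str = "all-generated") -> dict:
    """Per-threshold matched fractions, CIs (all methods) and tail tests.

    The returned dict is JSON-serializable and is what the pipeline writes
    as ``statistics.json``.
    """
    from .matching import matched_fraction
    out = {"null": {"kind": null.kind, "r_um": null.r_um, "p": null.p,
                    "L_um": null.L_um},
           "n_gt": matching_report.n_gt, "n_gen": matching_report.n_gen,
           "n_paired": len(matching_report.pairs),
           "count_error_pct": matching_report.count_error_pct,
           "denominator": denominator,
           "thresholds": {}}
    for thr in thresholds_um:
        try:
            k, n, frac = matched_fraction(matching_report, thr,
                                          denominator=denominator)
        except ValueError:
            out["thresholds"][f"{thr:g}um"] = {"k": 0, "n": 0,
                                               "fraction": None}
            continue
        entry = {"k": k, "n": n, "fraction": frac, "ci": {}, "test": {}}
        for method in CI_METHODS:
            ci = proportion_ci(k, n, level, method)
            entry["ci"][method] = {"lower": ci.lower, "upper": ci.upper,
                                   "level": level}
        for approx in ("exact_log", "normal"):
            entry["test"][approx] = binomial_tail_log10(n, k, null.p, approx)
        out["thresholds"][f"{thr:g}um"] = entry
    return out
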