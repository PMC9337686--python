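"""Null-model geometry, confidence intervals and log-scale binomial tails."""

import math

import numpy as np
import pytest
from scipy import ndimage as ndi

from actin2nucleus.detection import NucleusRecord
from actin2nucleus.matching import match, matched_fraction
from actin2nucleus.placement import (PlacementNull, binomial_tail_log10,
                                     p_random_cell, p_random_image,
                                     placement_report, proportion_ci)


class TestPRandomImage:
    def test_published_one_in_five_hundred(self):
        p = p_random_image(4.0, 159.41)
        assert p == pytest.approx(1.978e-3, rel=1e-3)
        assert round(1 / p, -2) == 500          # "one out of 500"

    def test_closed_form(self):
        assert p_random_image(1, 100) == pytest.approx(math.pi * 1e-4)

    def test_invalid_geometry_rejected(self):
        with pytest.raises(ValueError):
            p_random_image(-1, 10)
        with pytest.raises(ValueError):
            p_random_image(60, 100)             # 2r >= L

    def test_monotonicity(self):
        assert p_random_image(5, 100) > p_random_image(4, 100)
        assert p_random_image(4, 200) < p_random_image(4, 100)


class TestPRandomCell:
    def test_circular_cell_closed_form(self):
        # centered nucleus in a disk cell: p -> r^2 / (R - r)^2
        R, r_um, px = 40.0, 8.0, 1.0
        yy, xx = np.mgrid[:101, :101]
        mask = (yy - 50) ** 2 + (xx - 50) ** 2 <= R ** 2
        p = p_random_cell(mask, px, r_um, (50.0, 50.0))
        assert p == pytest.approx(r_um ** 2 / (R - r_um) ** 2, rel=0.12)

    def test_large_cell_limit(self):
        # erosion negligible: p -> pi r^2 / cell area
        yy, xx = np.mgrid[:201, :201]
        mask = (yy - 100) ** 2 + (xx - 100) ** 2 <= 90 ** 2
        p = p_random_cell(mask, 1.0, 3.0, (100.0, 100.0))
        assert p == pytest.approx(math.pi * 9 / mask.sum(), rel=0.12)

    def test_pixel_count_matches_monte_carlo(self):
        # irregular blob: 1e5 uniform draws over the eroded region
        rng = np.random.default_rng(5)
        blob = rng.random((80, 80)) > 0.55
        blob = ndi.binary_closing(ndi.binary_opening(
            ndi.binary_dilation(blob, iterations=3)), iterations=2)
        lab, _ = ndi.label(blob)
        sizes = ndi.sum(blob, lab, range(lab.max() + 1))
        blob = lab == int(np.argmax(sizes[1:]) + 1)
        r_um, px = 4.0, 1.0
        selem = np.hypot(*np.mgrid[-4:5, -4:5]) <= 4
        allowed = ndi.binary_erosion(blob, structure=selem)
        iy, ix = np.nonzero(allowed)
        center = (float(iy[len(iy) // 2]), float(ix[len(ix) // 2]))
        p = p_random_cell(blob, px, r_um, center)
        draws = rng.integers(0, len(iy), size=100_000)
        d = np.hypot(iy[draws] - center[0], ix[draws] - center[1])
        mc = float((d <= r_um / px).mean())
        assert p == pytest.approx(mc, rel=0.05)

    def test_tiny_cell_rejected(self):
        mask = np.zeros((20, 20), bool)
        mask[8:12, 8:12] = True
        with pytest.raises(ValueError):
            p_random_cell(mask, 1.0, 8.0, (10.0, 10.0))


class TestProportionCI:
    def test_wilson_reproduces_published_71_pct(self):
        ci = proportion_ci(5785, 8151, 0.95, "wilson_score")
        assert round(ci.p_hat * 100, 1) == 71.0
        assert round(ci.half_width * 100, 1) == 1.0

    def test_wilson_reproduces_published_28_6_pct(self):
        ci = proportion_ci(2328, 8151, 0.95, "wilson_score")
        assert round(ci.p_hat * 100, 1) == 28.6
        assert round(ci.half_width * 100, 1) == 1.0

    def test_clopper_pearson_boundaries(self):
        assert proportion_ci(0, 50, 0.95, "clopper_pearson").lower == 0.0
        assert proportion_ci(50, 50, 0.95, "clopper_pearson").upper == 1.0

    def test_interval_contains_estimate(self):
        for method in ("clopper_pearson", "wilson_score", "normal"):
            ci = proportion_ci(30, 100, 0.95, method)
            assert ci.lower <= ci.p_hat <= ci.upper

    def test_nesting_for_small_n(self):
        cp = proportion_ci(7, 20, 0.95, "clopper_pearson")
        wi = proportion_ci(7, 20, 0.95, "wilson_score")
        center = (wi.lower + wi.upper) / 2
        assert cp.lower <= center <= cp.upper
        assert (cp.upper - cp.lower) >= (wi.upper - wi.lower)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            proportion_ci(5, 4)
        with pytest.raises(ValueError):
            proportion_ci(1, 4, level=1.5)
        with pytest.raises(ValueError):
            proportion_ci(1, 4, method="bayes")


class TestBinomialTail:
    def test_all_successes_closed_form(self):
        assert binomial_tail_log10(10, 10, 0.5) \
            == pytest.approx(math.log10(2 ** -10))

    def test_small_tail_direct_summation(self):
        # P(X >= 8 | n=10, p=.5) = (45 + 10 + 1) / 1024
        assert binomial_tail_log10(10, 8, 0.5) \
            == pytest.approx(math.log10(56 / 1024))

    def test_monotone_decreasing_in_k(self):
        vals = [binomial_tail_log10(100, k, 0.3) for k in (40, 50, 60)]
        assert vals[0] > vals[1] > vals[2]

    def test_normal_matches_exact_for_moderate_z(self):
        # regime where the Gaussian approximation is justified:
        # n p0 (1 - p0) large and z moderate
        for n, k, p0 in [(500, 300, 0.5), (2000, 1100, 0.5),
                         (100, 70, 0.6), (8151, 4200, 0.5)]:
            e = binomial_tail_log10(n, k, p0, "exact_log")
            a = binomial_tail_log10(n, k, p0, "normal")
            assert abs(a - e) / abs(e) < 0.05

    def test_extreme_tail_finite(self):
        v = binomial_tail_log10(8151, 5785, p_random_image(4.0, 159.41))
        assert math.isfinite(v) and v <= -1000

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            binomial_tail_log10(10, 11, 0.5)
        with pytest.raises(ValueError):
            binomial_tail_log10(10, 5, 0.0)


class TestCoverage:
    def test_ci_coverage_simulation(self):
        # 2000 Binomial(500, 0.7) draws: exact interval covers >= nominal,
        # Wilson stays close to nominal
        rng = np.random.default_rng(77)
        ks = rng.binomial(500, 0.7, size=2000)
        cov = {"clopper_pearson": 0, "wilson_score": 0}
        for method in cov:
            for k in ks:
                ci = proportion_ci(int(k), 500, 0.95, method)
                cov[method] += ci.lower <= 0.7 <= ci.upper
            cov[method] /= len(ks)
        assert cov["clopper_pearson"] >= 0.95 - 0.01   # Monte-Carlo slack
        assert 0.93 <= cov["wilson_score"] <= 0.97


class TestNullCalibration:
    def test_random_placement_matches_analytic_probability(self):
        # uniformly random generated centroids over the tile: the matched
        # fraction at 4 um estimates pi r^2 / L^2
        rng = np.random.default_rng(42)
        L_px, px_um, r_um, size = 64, 0.8203125, 4.0, 8
        p_true = p_random_image(r_um, L_px * px_um)
        n_trials, hits = 4000, 0
        for t in range(n_trials):
            gt_c = rng.uniform(12, L_px - 12, 2)
            gen_c = rng.uniform(4, L_px - 4, 2)
            gt = NucleusRecord(1, 64, tuple(gt_c),
                               (int(gt_c[0]) - 4, int(gt_c[1]) - 4, 8, 8),
                               tuple(gt_c * px_um))
            gen = NucleusRecord(1, 64, tuple(gen_c),
                                (int(gen_c[0]) - 4, int(gen_c[1]) - 4, 8, 8),
                                tuple(gen_c * px_um))
            rep = match([gt], [gen], pixel_size_um=px_um)
            k, n, _ = matched_fraction(rep, r_um)
            hits += k
        frac = hits / n_trials
        se = math.sqrt(p_true * (1 - p_true) / n_trials)
        assert abs(frac - p_true) <= 3 * se


class TestPlacementReport:
    def test_all_matched_synthetic_run(self):
        recs = [NucleusRecord(i, 64, (10.0 * i, 10.0 * i),
                              (10 * i - 4, 10 * i - 4, 8, 8),
                              (10.0 * i, 10.0 * i)) for i in range(1, 4)]
        rep = match(recs, recs, pixel_size_um=1.0)
        null = PlacementNull.image(4.0, 100.0)
        out = placement_report(rep, null, thresholds_um=(4.0,))
        entry = out["thresholds"]["4um"]
        assert entry["fraction"] == 1.0
        assert entry["ci"]["clopper_pearson"]["upper"] == 1.0

    def test_injected_published_counts(self):
        from actin2nucleus.matching import MatchingReport
        dists = [0.5] * 2328 + [2.0] * (5785 - 2328) + [9.0] * (8151 - 5785)
        rep = MatchingReport(n_gt=9659, n_gen=8151, pixel_size_um=1.0)
        rep.pairs = [type("P", (), {"distance_um": d})() for d in dists]
        null = PlacementNull.image(4.0, 159.41)
        out = placement_report(rep, null, thresholds_um=(4.0, 1.0))
        at4 = out["thresholds"]["4um"]
        assert at4["fraction"] == pytest.approx(0.7097, abs=1e-4)
        assert math.isfinite(at4["test"]["exact_log"])
        assert at4["test"]["exact_log"] < -1000
        # 40% of the matched nuclei lie under 1 um: 2328 / 5785
        assert 2328 / 5785 == pytest.approx(0.4024, abs=1e-4)
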