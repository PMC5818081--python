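"""Scalar metrics: volume, burden/nodules, contraction, roundness, Grubbs."""

import math

import numpy as np
import pytest
from scipy import stats

from spheroquant import (
    LungSimParams,
    ParameterError,
    SectionMasks,
    TumourMeasurement,
    cell_roundness,
    gel_contraction,
    generate_gel_masks,
    generate_lung_section,
    grubbs_outliers,
    quantify_burden,
    tumour_volume,
)


def _disc(radius, size=None, centre=None):
    size = size or 2 * radius + 20
    c = centre or (size // 2, size // 2)
    yy, xx = np.mgrid[0:size, 0:size]
    return (yy - c[0]) ** 2 + (xx - c[1]) ** 2 <= radius**2


class TestTumourVolume:
    @pytest.mark.parametrize(
        "w,l,expect",
        [(2.0, 2.0, 4.1888), (10.0, 14.0, 904.7808), (5.0, 7.0, 113.0976)],
    )
    def test_printed_formula(self, w, l, expect):
        assert tumour_volume(TumourMeasurement(w, l)) == pytest.approx(
            expect, rel=1e-9
        )

    def test_grid_against_direct_evaluation_oracle(self):
        for w in np.linspace(0.5, 20, 8):
            for l in np.linspace(0.5, 20, 8):
                got = tumour_volume(TumourMeasurement(w, l))
                assert got == pytest.approx(
                    0.5236 * ((w + l) / 2) ** 3, rel=1e-12
                )

    def test_symmetric_in_width_and_length(self):
        assert tumour_volume(TumourMeasurement(3.0, 11.0)) == tumour_volume(
            TumourMeasurement(11.0, 3.0)
        )

    def test_strictly_increasing_in_each_dimension(self):
        base = tumour_volume(TumourMeasurement(5.0, 5.0))
        assert tumour_volume(TumourMeasurement(5.5, 5.0)) > base
        assert tumour_volume(TumourMeasurement(5.0, 5.5)) > base

    def test_non_positive_dimensions_rejected(self):
        with pytest.raises(ParameterError):
            TumourMeasurement(0.0, 5.0)


class TestQuantifyBurden:
    def test_empty_tumour_mask(self):
        lung = _disc(50)
        report = quantify_burden(
            SectionMasks(lung, np.zeros_like(lung), 1.0)
        )
        assert report.pct_tumour_area == 0.0
        assert report.nodule_count == 0

    def test_tumour_equals_lung_gives_100_percent(self):
        lung = _disc(50)
        report = quantify_burden(SectionMasks(lung, lung.copy(), 1.0))
        assert report.pct_tumour_area == pytest.approx(100.0)

    def test_minimum_area_rule_filters_small_nodules(self):
        lung, tumour, areas = generate_lung_section(
            LungSimParams(nodule_areas_um2=(500, 800, 1500, 2000, 4000), seed=2)
        )
        masks = SectionMasks(lung, tumour, 1.0)
        report = quantify_burden(masks, min_area_um2=1000.0)
        assert report.nodule_count == 3
        assert all(a >= 1000.0 for a in report.nodule_areas_um2)
        gt_pct = 100.0 * sum(areas) / lung.sum()
        assert report.pct_tumour_area == pytest.approx(gt_pct, rel=0.02)

    def test_nodule_count_non_increasing_in_min_area(self):
        lung, tumour, _ = generate_lung_section(
            LungSimParams(nodule_areas_um2=(500, 1500, 2500, 5000), seed=4)
        )
        masks = SectionMasks(lung, tumour, 1.0)
        counts = [
            quantify_burden(masks, min_area_um2=m).nodule_count
            for m in (100, 1000, 2000, 10000)
        ]
        assert counts == sorted(counts, reverse=True)
        # pct is independent of the filter when sub-threshold retained
        pcts = {
            quantify_burden(masks, min_area_um2=m).pct_tumour_area
            for m in (100, 1000, 10000)
        }
        assert len(pcts) == 1

    def test_subthreshold_exclusion_flag_reduces_pct(self):
        lung, tumour, _ = generate_lung_section(
            LungSimParams(nodule_areas_um2=(500, 4000), seed=6)
        )
        masks = SectionMasks(lung, tumour, 1.0)
        with_small = quantify_burden(masks)
        without_small = quantify_burden(
            masks, include_subthreshold_in_pct=False
        )
        assert without_small.pct_tumour_area < with_small.pct_tumour_area

    def test_tumour_outside_lung_is_clipped_and_counted(self):
        lung = np.zeros((20, 20), dtype=bool)
        lung[5:15, 5:15] = True
        tumour = np.zeros_like(lung)
        tumour[0:8, 0:8] = True  # partly outside the lung
        masks = SectionMasks(lung, tumour, 1.0)
        assert masks.n_clipped_px == 64 - 9
        assert not (masks.tumour_mask & ~masks.lung_mask).any()

    def test_empty_lung_mask_rejected(self):
        with pytest.raises(ParameterError, match="lung"):
            quantify_burden(
                SectionMasks(
                    np.zeros((5, 5), bool), np.zeros((5, 5), bool), 1.0
                )
            )


class TestGelContraction:
    def test_identical_masks_give_zero(self):
        mask = _disc(40)
        assert gel_contraction(mask, mask.copy()) == 0.0

    def test_half_area_gives_50_percent(self):
        initial = np.ones((10, 10), bool)
        final = np.zeros((10, 10), bool)
        final[:5, :] = True
        assert gel_contraction(initial, final) == pytest.approx(50.0)

    def test_generated_pair_matches_requested_fraction(self):
        initial, final = generate_gel_masks(31416, 0.3)
        assert gel_contraction(initial, final) == pytest.approx(30.0, abs=1.0)

    def test_expansion_reported_negative(self):
        assert gel_contraction(_disc(20), _disc(30)) < 0

    def test_empty_initial_mask_rejected(self):
        with pytest.raises(ParameterError):
            gel_contraction(np.zeros((5, 5), bool), _disc(2, size=5))


class TestCellRoundness:
    def test_disc_is_nearly_round(self):
        assert cell_roundness(_disc(50)) >= 0.95

    def test_thin_line_is_elongated(self):
        line = np.zeros((5, 104), bool)
        line[2, 2:102] = True
        assert cell_roundness(line) < 0.1

    def test_translation_and_rotation_invariance(self):
        disc = _disc(20, size=100, centre=(30, 30))
        shifted = np.roll(disc, (25, 30), axis=(0, 1))
        assert cell_roundness(shifted) == pytest.approx(cell_roundness(disc))
        ell = np.zeros((80, 80), bool)
        yy, xx = np.mgrid[0:80, 0:80]
        ell[(yy - 40) ** 2 / 400 + (xx - 40) ** 2 / 100 <= 1] = True
        assert cell_roundness(np.rot90(ell)) == pytest.approx(
            cell_roundness(ell), rel=1e-9
        )

    def test_decreases_with_ellipse_axis_ratio(self):
        values = []
        yy, xx = np.mgrid[0:160, 0:160]
        for ratio in (1.0, 2.0, 4.0, 8.0):
            b = 15.0
            a = b * ratio
            mask = ((yy - 80) / b) ** 2 + ((xx - 80) / a) ** 2 <= 1
            values.append(cell_roundness(mask))
        assert values == sorted(values, reverse=True)

    def test_multi_component_mask_rejected(self):
        mask = np.zeros((30, 30), bool)
        mask[2:5, 2:5] = True
        mask[20:23, 20:23] = True
        with pytest.raises(ParameterError):
            cell_roundness(mask)


class TestGrubbs:
    def test_gross_outlier_flagged(self):
        report = grubbs_outliers([1.0, 2.0, 3.0, 4.0, 50.0])
        assert report.outlier_index == 4
        assert report.g_statistic > report.g_critical

    def test_tight_sample_not_flagged(self):
        report = grubbs_outliers([1.0, 2.0, 3.0, 4.0, 5.0])
        assert report.outlier_index is None

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_direct_formula_oracle(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(10, 3, rng.integers(5, 30))
        report = grubbs_outliers(x, alpha=0.05)
        n = len(x)
        g = np.max(np.abs(x - x.mean())) / x.std(ddof=1)
        t = stats.t.ppf(1 - 0.05 / (2 * n), n - 2)
        g_crit = (n - 1) / math.sqrt(n) * math.sqrt(t * t / (n - 2 + t * t))
        assert report.g_statistic == pytest.approx(g, rel=1e-12)
        assert report.g_critical == pytest.approx(g_crit, rel=1e-12)

    def test_affine_invariance(self, rng):
        x = rng.normal(0, 1, 12)
        base = grubbs_outliers(x)
        moved = grubbs_outliers(3.7 * x - 11.0)
        assert moved.g_statistic == pytest.approx(base.g_statistic, rel=1e-9)
        assert moved.outlier_index == base.outlier_index
        flipped = grubbs_outliers(-2.0 * x + 5.0)
        assert flipped.g_statistic == pytest.approx(base.g_statistic, rel=1e-9)

    def test_flag_rate_on_normal_samples_near_alpha(self, rng):
        n, reps = 6, 10000
        X = rng.normal(size=(reps, n))
        sd = X.std(axis=1, ddof=1)
        G = np.abs(X - X.mean(axis=1, keepdims=True)).max(axis=1) / sd
        t = stats.t.ppf(1 - 0.05 / (2 * n), n - 2)
        g_crit = (n - 1) / math.sqrt(n) * math.sqrt(t * t / (n - 2 + t * t))
        rate = (G > g_crit).mean()
        assert 0.03 < rate < 0.07
        # spot-check the vectorised oracle against the implementation
        r0 = grubbs_outliers(X[0])
        assert r0.g_statistic == pytest.approx(G[0], rel=1e-12)

    @pytest.mark.parametrize("values", [[1.0, 2.0], [3.0, 3.0, 3.0]])
    def test_degenerate_samples_rejected(self, values):
        with pytest.raises(ParameterError):
            grubbs_outliers(values)
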