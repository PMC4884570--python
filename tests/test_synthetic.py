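"""Synthetic cohort generator: stratification, distributions, rendering,
grader noise."""

import dataclasses

import numpy as np
import pytest
from scipy.stats import truncnorm

from conftest import gapfree_eye
from fazmorph.morphometry import classify_angle, extract_faz, measure_angiogram
from fazmorph.stats import cohen_kappa, icc_2_1, spearman_rho
from fazmorph.synthetic import (
    calibrate_aspect_ratio,
    reference_cohort_params,
    render_angiogram,
    sample_cohort,
    simulate_graders,
)
from fazmorph.types import CohortParams, FazMeasurement


def small_params(seed=0, **kw):
    base = reference_cohort_params(seed=seed)
    return dataclasses.replace(base, **kw)


class TestSampleCohort:
    def test_cohort_composition_both_layers(self):
        eyes = sample_cohort(reference_cohort_params(seed=1))
        assert len(eyes) == (25 + 29) * 2
        for layer in ("superficial", "deep"):
            sub = [e for e in eyes if e.layer == layer]
            assert sum(e.group == "control" for e in sub) == 25
            assert sum(e.group == "dr" for e in sub) == 29

    def test_same_seed_reproduces_cohort_elementwise(self):
        a = sample_cohort(reference_cohort_params(seed=7))
        b = sample_cohort(reference_cohort_params(seed=7))
        assert a == b

    def test_different_seed_changes_cohort(self):
        a = sample_cohort(reference_cohort_params(seed=7))
        b = sample_cohort(reference_cohort_params(seed=8))
        assert a != b

    @pytest.mark.parametrize("seed", range(6))
    def test_stratified_typical_counts_exact_every_seed(self, seed):
        eyes = sample_cohort(reference_cohort_params(seed=seed))
        expected = {
            ("control", "superficial"): round(0.720 * 25),  # 18
            ("control", "deep"): round(0.760 * 25),         # 19
            ("dr", "superficial"): round(0.069 * 29),       # 2
            ("dr", "deep"): round(0.138 * 29),              # 4
        }
        for (grp, layer), want in expected.items():
            sub = [e for e in eyes if e.group == grp and e.layer == layer]
            got = sum(
                classify_angle(e.faz_orientation_deg) == "typical" for e in sub
            )
            assert got == want

    def test_control_eyes_have_closed_arcades(self):
        eyes = sample_cohort(reference_cohort_params(seed=2))
        for e in eyes:
            if e.group == "control":
                assert e.n_gaps == 0 and e.dropout_fraction == 0.0
            else:
                assert e.n_gaps >= 1

    def test_horizontal_mean_converges_to_configured(self):
        # cohort mean of the ground-truth horizontal diameter approaches the
        # configured (truncated-normal) mean within 3 standard errors
        params = small_params(n_control=1000, n_dr=1000)
        cells = {
            ("control", "superficial"): (573.0, 177.0),
            ("dr", "superficial"): (753.0, 272.0),
            ("control", "deep"): (659.0, 194.0),
            ("dr", "deep"): (1009.0, 342.0),
        }
        sums = {k: [] for k in cells}
        n_seeds = 12
        for s in range(n_seeds):
            eyes = sample_cohort(dataclasses.replace(params, seed=100 + s))
            for key in cells:
                vals = [
                    e.horizontal_um
                    for e in eyes
                    if (e.group, e.layer) == key
                ]
                sums[key].append(np.mean(vals))
        for key, (mean, sd) in cells.items():
            target = truncnorm.mean(-mean / sd, np.inf, loc=mean, scale=sd)
            se = sd / np.sqrt(1000 * n_seeds)
            assert abs(np.mean(sums[key]) - target) < 3 * se

    def test_max_diameter_mean_matches_calibration(self):
        params = small_params(n_control=1000, n_dr=1000)
        eyes = []
        for s in range(6):
            eyes += sample_cohort(dataclasses.replace(params, seed=500 + s))
        for (grp, layer), want in {
            ("control", "superficial"): 661.0,
            ("dr", "deep"): 1227.0,
        }.items():
            vals = [e.max_diameter_um for e in eyes if (e.group, e.layer) == (grp, layer)]
            assert np.mean(vals) == pytest.approx(want, rel=0.02)

    def test_bcva_anticorrelates_with_faz_size(self):
        eyes = sample_cohort(reference_cohort_params(seed=3))
        sup = [e for e in eyes if e.layer == "superficial"]
        rho = spearman_rho(
            [e.max_diameter_um for e in sup], [e.bcva_letters for e in sup]
        )
        assert rho.statistic < 0
        assert 0.25 <= abs(rho.statistic) <= 0.85

    def test_validation_errors(self):
        with pytest.raises(ValueError):
            small_params(n_control=0)
        with pytest.raises(ValueError):
            small_params(bcva_slope=0.1)


class TestCalibration:
    @pytest.mark.parametrize(
        "mh,mm,f", [(573, 661, 0.72), (1009, 1227, 4 / 29), (600, 601, 0.5)]
    )
    def test_aspect_reproduces_target_ratio_by_simulation(self, mh, mm, f):
        from fazmorph.synthetic import (
            _atypical_angle,
            _directional_factor,
            _typical_angle,
        )

        q = calibrate_aspect_ratio(mh, mm, f)
        assert 0 < q < 1
        rng = np.random.default_rng(5)
        n = 200_000
        typ = rng.random(n) < f
        u = rng.random(n)
        theta = np.where(
            typ,
            [_typical_angle(x) for x in u],
            [_atypical_angle(x) for x in u],
        )
        g = np.array([_directional_factor(t, q) for t in theta])
        assert np.mean(1.0 / g) == pytest.approx(mm / mh, rel=0.005)

    def test_impossible_ratio_rejected(self):
        with pytest.raises(ValueError):
            calibrate_aspect_ratio(600, 500, 0.5)


class TestRenderAngiogram:
    def test_control_faz_simply_connected_and_interior(self):
        gt = gapfree_eye("ctl", 350.0, 280.0, 20.0, seed=21)
        region = extract_faz(render_angiogram(gt))
        from scipy import ndimage

        filled = ndimage.binary_fill_holes(region.mask)
        assert np.array_equal(filled, region.mask)  # simply connected
        border = np.concatenate(
            [region.mask[0], region.mask[-1], region.mask[:, 0], region.mask[:, -1]]
        )
        assert not border.any()

    def test_circle_roundtrip_within_5pct(self):
        gt = gapfree_eye("c300", 300.0, 299.99, 0.0, seed=22)
        m = measure_angiogram(render_angiogram(gt))
        assert m.max_um == pytest.approx(600.0, rel=0.05)

    def test_gaps_strictly_enlarge_avascular_area(self):
        base = gapfree_eye("g0", 400.0, 300.0, 30.0, seed=23)
        gapped = dataclasses.replace(base, group="dr", n_gaps=2, gap_arc_deg=25.0,
                                     dropout_fraction=0.0)
        a0 = extract_faz(render_angiogram(base, field_um=2000.0)).mask.sum()
        a2 = extract_faz(render_angiogram(gapped, field_um=2000.0)).mask.sum()
        assert a2 > a0

    def test_deterministic_given_render_seed(self):
        gt = gapfree_eye("det", 320.0, 260.0, 140.0, seed=24)
        img1 = render_angiogram(gt)
        img2 = render_angiogram(gt)
        assert np.array_equal(img1.pixels, img2.pixels)

    def test_oversized_faz_rejected(self):
        gt = gapfree_eye("big", 900.0, 800.0, 0.0, seed=25)
        with pytest.raises(ValueError):
            render_angiogram(gt, field_um=2000.0)


class TestSimulateGraders:
    @pytest.fixture
    def truth(self):
        return FazMeasurement(
            horizontal_um=600.0, vertical_um=550.0, max_um=700.0, perp_um=500.0,
            angle_deg=30.0, angle_class="atypical", eye_id="t", layer="superficial",
        )

    def test_zero_noise_returns_truth(self, truth):
        for g in simulate_graders(truth, diam_noise_sd=0.0, angle_noise_sd=0.0):
            assert g == truth

    def test_zero_angle_noise_gives_perfect_kappa(self):
        eyes = sample_cohort(reference_cohort_params(seed=4))
        labs_a, labs_b = [], []
        for i, e in enumerate(eyes[:54]):
            truth = FazMeasurement(
                horizontal_um=e.horizontal_um, vertical_um=e.vertical_um,
                max_um=e.max_diameter_um, perp_um=e.vertical_um,
                angle_deg=e.faz_orientation_deg,
                angle_class=classify_angle(e.faz_orientation_deg),
            )
            ga, gb = simulate_graders(truth, diam_noise_sd=50.0,
                                      angle_noise_sd=0.0, seed=i)
            labs_a.append(ga.angle_class)
            labs_b.append(gb.angle_class)
        assert cohen_kappa(labs_a, labs_b).statistic == pytest.approx(1.0)

    def test_default_noise_puts_icc_in_reported_band(self):
        # two graders over a pooled 54-eye layer: ICC(2,1) should land in
        # [0.7, 0.95], the band containing the clinically observed 0.857
        eyes = [e for e in sample_cohort(reference_cohort_params(seed=5))
                if e.layer == "superficial"]
        a, b = [], []
        for i, e in enumerate(eyes):
            truth = FazMeasurement(
                horizontal_um=e.horizontal_um, vertical_um=e.vertical_um,
                max_um=e.max_diameter_um, perp_um=e.vertical_um,
                angle_deg=e.faz_orientation_deg,
                angle_class=classify_angle(e.faz_orientation_deg),
            )
            ga, gb = simulate_graders(truth, seed=1000 + i)
            a.append(ga.max_um)
            b.append(gb.max_um)
        icc = icc_2_1(np.column_stack([a, b])).statistic
        assert 0.7 <= icc <= 0.95

    def test_requires_two_graders(self, truth):
        with pytest.raises(ValueError):
            simulate_graders(truth, n_graders=1)
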