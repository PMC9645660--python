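"""Morphometrics, normalisation schemes, effect sizes and dose-response fits."""

import numpy as np
import pytest
from skimage.draw import ellipse as draw_ellipse

import organotrack as ot
from organotrack.measure import (DoseResponseFit, cohens_d,
                                 coefficient_of_variation, fit_dose_response,
                                 fluorescence_per_area, fold_change_series,
                                 four_param_logistic,
                                 normalize_to_first_detection,
                                 region_properties)
from organotrack.track import TrackTable

from conftest import disk_mask


class TestRegionProperties:
    def test_disk_is_circular(self):
        lab = disk_mask((128, 128), 64, 64, 30).astype(np.int32)
        rec, = region_properties(lab)
        assert 0.9 <= rec.circularity <= 1.0
        assert rec.eccentricity < 0.2
        assert rec.solidity > 0.95
        assert rec.area == pytest.approx(np.pi * 30 ** 2, rel=0.02)
        assert not rec.touches_border

    def test_ellipse_eccentricity_closed_form(self):
        lab = np.zeros((128, 128), dtype=np.int32)
        rr, cc = draw_ellipse(64, 64, 20, 40)
        lab[rr, cc] = 1
        rec, = region_properties(lab)
        assert rec.eccentricity == pytest.approx(np.sqrt(1 - (20 / 40) ** 2), abs=0.05)

    def test_square_is_convex(self):
        lab = np.zeros((80, 80), dtype=np.int32)
        lab[10:60, 10:60] = 1
        rec, = region_properties(lab)
        assert rec.solidity == pytest.approx(1.0, abs=0.02)
        assert rec.circularity < 1.0  # squares are not circles

    def test_border_flag_and_physical_units(self):
        lab = np.zeros((64, 64), dtype=np.int32)
        lab[0:10, 5:15] = 1
        rec, = region_properties(lab, pixel_scale=2.0)
        assert rec.touches_border
        assert rec.area_um2 == rec.area * 4.0
        assert rec.perimeter_um == rec.perimeter * 2.0


class TestFoldChange:
    def test_constant_series_is_all_ones(self):
        out = fold_change_series({1: np.array([7.0, 7.0, 7.0])})
        assert np.allclose(out[1], 1.0)

    def test_simple_ratios(self):
        out = fold_change_series({1: np.array([100.0, 150.0, 200.0])})
        assert np.allclose(out[1], [1.0, 1.5, 2.0])

    def test_zero_baseline_excluded(self):
        out = fold_change_series({1: np.array([0.0, 5.0]), 2: np.array([2.0, 4.0])})
        assert 1 not in out and 2 in out

    def test_growth_fixture_matches_generator_rate(self):
        scene = ot.FixtureSpec(image_size=256, n_organoids=3, radius_range=(14, 18),
                               seed=31, boundary_irregularity=0.0)
        ts = ot.TimelapseSpec(n_frames=6, drift_per_frame=0.0, growth_rate=0.05, seed=31)
        tl = ot.make_timelapse(ts, scene)
        areas = {}
        for t, lab in enumerate(tl.labels):
            for tid, label in tl.table.labels_at(t).items():
                areas.setdefault(tid, []).append((lab == label).sum())
        fc = fold_change_series({k: np.array(v, float) for k, v in areas.items()})
        t_idx = np.arange(6)
        for series in fc.values():
            # area grows as (radius growth)^2 per frame
            assert np.allclose(series, (1.05 ** 2) ** t_idx, rtol=0.03)

    def test_scale_invariance(self):
        base = fold_change_series({1: np.array([2.0, 3.0, 5.0])})[1]
        scaled = fold_change_series({1: 17.0 * np.array([2.0, 3.0, 5.0])})[1]
        assert np.allclose(base, scaled)


class TestFluorescencePerArea:
    def test_uniform_field(self):
        lab = disk_mask((64, 64), 20, 20, 8).astype(np.int32)
        lab[disk_mask((64, 64), 45, 45, 6)] = 2
        out = fluorescence_per_area(lab, np.full((64, 64), 3.5))
        assert out[1] == pytest.approx(3.5) and out[2] == pytest.approx(3.5)

    def test_signal_confined_to_one_label(self):
        lab = disk_mask((64, 64), 20, 20, 8).astype(np.int32)
        lab[disk_mask((64, 64), 45, 45, 6)] = 2
        fluor = np.where(lab == 1, 2.0, 0.0)
        out = fluorescence_per_area(lab, fluor)
        assert out[1] == pytest.approx(2.0) and out[2] == 0.0

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            fluorescence_per_area(np.zeros((4, 4), int), np.zeros((5, 5)))

    def test_fixture_densities_recovered(self):
        scene = ot.FixtureSpec(image_size=256, n_organoids=3, radius_range=(12, 16), seed=33)
        ts = ot.TimelapseSpec(n_frames=3, drift_per_frame=0.0, growth_rate=0.0,
                              default_fluor_baseline=10.0, default_fluor_rate=0.2, seed=33)
        tl = ot.make_timelapse(ts, scene)
        for t in range(3):
            for lab_id, dens in fluorescence_per_area(tl.labels[t], tl.fluor[t]).items():
                assert dens == pytest.approx(10.0 * np.exp(0.2 * t), rel=1e-6)


class TestNormalizeToFirstDetection:
    def _table(self):
        table = TrackTable()
        tid = table.new_track(0, 1)
        table.record(tid, 1, 1)
        table.record(tid, 2, 1)
        return table, tid

    def test_constant_density_all_ones(self):
        table, tid = self._table()
        dens = {(0, 1): 4.0, (1, 1): 4.0, (2, 1): 4.0}
        out = normalize_to_first_detection(table, dens)
        assert list(out[tid].values()) == [1.0, 1.0, 1.0]

    def test_doubling_series(self):
        table, tid = self._table()
        dens = {(0, 1): 5.0, (1, 1): 10.0, (2, 1): 20.0}
        assert list(normalize_to_first_detection(table, dens)[tid].values()) == [1.0, 2.0, 4.0]

    def test_zero_birth_density_excluded(self):
        table, tid = self._table()
        dens = {(0, 1): 0.0, (1, 1): 10.0, (2, 1): 20.0}
        assert normalize_to_first_detection(table, dens) == {}

    def test_exponential_fluor_fixture(self):
        scene = ot.FixtureSpec(image_size=256, n_organoids=3, radius_range=(12, 16), seed=34)
        ts = ot.TimelapseSpec(n_frames=5, drift_per_frame=1.0, growth_rate=0.0,
                              default_fluor_rate=0.3, seed=34)
        tl = ot.make_timelapse(ts, scene)
        dens = {(t, lab): d for t in range(5)
                for lab, d in fluorescence_per_area(tl.labels[t], tl.fluor[t]).items()}
        out = normalize_to_first_detection(tl.table, dens)
        for series in out.values():
            for t, v in series.items():
                assert v == pytest.approx(np.exp(0.3 * t), rel=1e-6)


class TestCohensD:
    def test_identical_groups_zero(self):
        assert cohens_d([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == 0.0

    def test_hand_formula_oracle(self):
        # a=(2,4), b=(1,3): means 3,2; pooled SD = sqrt((2+2)/2) = sqrt(2)
        assert cohens_d([2.0, 4.0], [1.0, 3.0]) == pytest.approx(1 / np.sqrt(2))

    def test_antisymmetric(self):
        rng = np.random.default_rng(0)
        a, b = rng.normal(0, 1, 10), rng.normal(1, 2, 12)
        assert cohens_d(a, b) == pytest.approx(-cohens_d(b, a))

    def test_zero_pooled_sd_rejected(self):
        with pytest.raises(ValueError):
            cohens_d([1.0, 1.0], [2.0, 2.0])


class TestCoefficientOfVariation:
    def test_constant_values(self):
        assert coefficient_of_variation([10.0, 10.0, 10.0]) == 0.0

    def test_hand_formula(self):
        assert coefficient_of_variation([1.0, 3.0]) == pytest.approx(np.sqrt(2) / 2)

    def test_scale_invariance(self):
        v = [2.0, 5.0, 9.0]
        assert coefficient_of_variation(v) == pytest.approx(
            coefficient_of_variation([13.0 * x for x in v]))

    def test_zero_mean_rejected(self):
        with pytest.raises(ValueError):
            coefficient_of_variation([-1.0, 1.0])


class TestDoseResponse:
    def test_noiseless_recovery_within_1pct(self):
        df, truth = ot.make_dose_response(ec50=25.0, hill=1.0, noise_sd=0.0)
        fit = fit_dose_response(df["dose"], df["response"])
        assert fit.converged
        assert fit.ec50 == pytest.approx(25.0, rel=0.01)
        assert fit.bottom <= fit.top

    def test_flat_data_does_not_converge(self):
        doses = [1.0, 10.0, 100.0, 1000.0]
        fit = fit_dose_response(doses, [0.5] * 4)
        assert not fit.converged

    def test_noisy_median_recovery(self):
        errs = []
        for rep in range(20):
            df, _ = ot.make_dose_response(ec50=25.0, hill=1.0, noise_sd=0.05,
                                          replicates=1, seed=100 + rep)
            fit = fit_dose_response(df["dose"], df["response"])
            errs.append(fit.ec50)
        assert np.median(errs) == pytest.approx(25.0, rel=0.10)

    def test_increasing_response_orientation(self):
        """Death signals rise with dose; the fit handles rising curves and
        reports asymptotes in canonical bottom <= top order."""
        doses = np.array([3.0, 10.0, 30.0, 100.0, 300.0, 1000.0])
        y = four_param_logistic(doses, 25.0, 1.0, 0.1, 0.9)  # 0.1 → 0.9 rising
        fit = fit_dose_response(doses, y)
        assert fit.converged
        assert fit.ec50 == pytest.approx(25.0, rel=0.01)
        assert fit.bottom == pytest.approx(0.1, abs=0.01)
        assert fit.bottom <= fit.top

    def test_too_few_dose_levels_rejected(self):
        with pytest.raises(ValueError):
            fit_dose_response([1.0, 2.0, 3.0], [0.1, 0.2, 0.3])


class TestNormalizationVarianceProperty:
    def test_tracked_normalization_reduces_cv(self):
        """With 2-fold spread in per-organoid baseline size but uniform
        growth, per-track normalisation gives a strictly lower CV of change
        than batch normalisation to the mean baseline."""
        rng = np.random.default_rng(0)
        n = 24
        baselines = rng.uniform(1.0, 2.0, n)           # 2-fold variation
        growth = 1.6 * (1 + rng.normal(0, 0.01, n))    # uniform growth, tiny noise
        final = baselines * growth
        tracked_change = final / baselines             # per-organoid normalisation
        batch_change = final / baselines.mean()        # batch normalisation
        assert (coefficient_of_variation(tracked_change)
                < coefficient_of_variation(batch_change))
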