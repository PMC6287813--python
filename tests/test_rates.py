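import numpy as np
import pytest

from kymokin import (
    GrowthSimConfig,
    LatticeSimConfig,
    NoiseModel,
    ThresholdSettings,
    concentration_fit,
    detect_all,
    detect_boundaries,
    fit_cutoff,
    measure_rate_from_stack,
    rates_from_events,
    segment_rate,
    simulate_growing_filament_stack,
    simulate_two_sided_kymograph,
    weighted_average_rate,
)
from kymokin.boundaries import BoundarySet, Segment
from kymokin.rates import RateRecord

BLURRED_PEAK = 15.958  # peak of the psf-blurred unit-width filament, intensity 100


def movie_settings():
    return ThresholdSettings(
        low_threshold=10.0 + 0.5 * BLURRED_PEAK,
        high_threshold=2e9,
        median_window=(3, 3),
        structuring_element=("disk", 1),
    )


def linear_boundary(rate, n=101, t0=0.0, x0=0.0):
    xs = np.arange(n, dtype=float) + x0
    ts = t0 + (xs - x0) / rate
    seg = Segment(seg_id=0, vertices=np.column_stack([xs, ts]), level=1)
    return BoundarySet(
        tau_outer=ts,
        tau_inner=np.full(n, np.nan),
        phase="association",
        frame_range=(0, int(ts.max()) + 1),
        segments=[seg],
        raw_segments=[seg.copy()],
    )


class TestSegmentRate:
    def test_two_point_slope(self):
        b = linear_boundary(0.1)
        rec = segment_rate(b, (0, 0), (10, 100))
        assert rec.rate_px_per_frame == pytest.approx(0.1)
        assert rec.weight == 10

    def test_unit_conversion(self):
        b = linear_boundary(0.1)
        rec = segment_rate(b, (0, 0), (10, 100), pixel_size_nm=92.0,
                           frame_interval_s=1.0)
        assert rec.rate_nm_per_s == pytest.approx(9.2)

    def test_reversed_axis_negates_rate(self):
        b = linear_boundary(0.1, n=101)
        flipped_tau = b.tau_outer[::-1].copy()
        xs = np.arange(101, dtype=float)
        seg = Segment(0, np.column_stack([xs, flipped_tau]), 1)
        bf = BoundarySet(
            tau_outer=flipped_tau,
            tau_inner=np.full(101, np.nan),
            phase="association",
            frame_range=b.frame_range,
            segments=[seg],
            raw_segments=[seg.copy()],
        )
        r = segment_rate(b, (0, 0), (100, 1000)).rate_px_per_frame
        rf = segment_rate(bf, (0, 1000), (100, 0)).rate_px_per_frame
        assert rf == pytest.approx(-r)

    def test_coincident_positions_rejected(self):
        b = linear_boundary(0.1)
        with pytest.raises(ValueError):
            segment_rate(b, (5, 50), (5, 50))


class TestRatesFromEvents:
    def test_symmetric_growth_two_equal_opposite_records(self, exact_settings):
        cfg = LatticeSimConfig(
            lattice_length=100,
            n_frames_assoc=150,
            elongation_rate=0.5,
            forced_nucleations=((0, 50, 5),),
        )
        kymo, _ = simulate_two_sided_kymograph(cfg)
        b = detect_boundaries(kymo, exact_settings, phase="association")
        events = detect_all(b)
        recs = rates_from_events(b, events, polarity="p0-barbed")
        assert len(recs) == 2
        rates = sorted(r.rate_px_per_frame for r in recs)
        assert rates[0] == pytest.approx(-0.5, rel=0.05)
        assert rates[1] == pytest.approx(0.5, rel=0.05)
        assert {r.direction for r in recs} == {"toward_barbed", "toward_pointed"}

    def test_missing_polarity_warns_plus_minus(self, exact_settings):
        cfg = LatticeSimConfig(
            lattice_length=60, n_frames_assoc=80, elongation_rate=1.0,
            forced_nucleations=((0, 30, 5),),
        )
        kymo, _ = simulate_two_sided_kymograph(cfg)
        b = detect_boundaries(kymo, exact_settings, phase="association")
        with pytest.warns(UserWarning, match="polarity"):
            recs = rates_from_events(b, detect_all(b))
        assert {r.direction for r in recs} == {"plus", "minus"}


class TestAggregation:
    def rec(self, rate, weight, direction="plus"):
        return RateRecord(
            rate_px_per_frame=rate, rate_nm_per_s=None, direction=direction,
            span=((0, 0), (weight, rate and weight / abs(rate))), weight=weight,
            side="A", phase="association", segment_id=0,
        )

    def test_weighted_average(self):
        recs = [self.rec(10.0, 10.0), self.rec(20.0, 30.0)]
        assert weighted_average_rate(recs) == pytest.approx(17.5)

    def test_single_record_is_its_own_average(self):
        assert weighted_average_rate([self.rec(12.0, 3.0)]) == pytest.approx(12.0)

    def test_equal_rates_weight_invariant(self):
        recs = [self.rec(5.0, w) for w in (1, 7, 100)]
        assert weighted_average_rate(recs) == pytest.approx(5.0)

    def test_empty_direction_rejected(self):
        with pytest.raises(ValueError):
            weighted_average_rate([self.rec(5.0, 1.0)], direction="minus")


class TestConcentrationFit:
    def test_closed_form(self):
        # sum(c*r)/sum(c^2) = (100*110 + 200*220) / (100^2 + 200^2) = 1.1
        assert concentration_fit([(100, 110), (200, 220)]) == pytest.approx(1.1)

    def test_single_point(self):
        assert concentration_fit([(250, 300)]) == pytest.approx(300 / 250)

    def test_exclusion_window(self):
        pts = [(50, 500), (200, 220), (400, 440)]
        assert concentration_fit(pts, exclude_below=150) == pytest.approx(1.1)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            concentration_fit([])
        with pytest.raises(ValueError):
            concentration_fit([(0.0, 1.0)])


class TestMeasureSimulatedRates:
    def test_noiseless_high_rate_recovered(self):
        stack = simulate_growing_filament_stack(
            GrowthSimConfig(growth_rate=0.05, n_frames=400, seed=3)
        )
        m = measure_rate_from_stack(stack, movie_settings(), 10)
        assert m == pytest.approx(0.05, rel=0.1)

    def test_static_filament_measures_small_nonnegative(self):
        stack = simulate_growing_filament_stack(
            GrowthSimConfig(growth_rate=0.0, n_frames=200, seed=0)
        )
        m = measure_rate_from_stack(stack, movie_settings(), 5)
        assert 0.0 <= m < 0.02

    def test_low_rate_overestimated_with_noise(self):
        noise = NoiseModel(kind="gaussian", read_sigma=0.1 * BLURRED_PEAK)
        ms = []
        for seed in range(3):
            stack = simulate_growing_filament_stack(
                GrowthSimConfig(growth_rate=1e-4, n_frames=400, seed=seed, noise=noise)
            )
            ms.append(measure_rate_from_stack(stack, movie_settings(), 10))
        assert np.mean(ms) > 1e-4  # noise + pixelation floor dominates

    @pytest.mark.parametrize("k", [1, 2, 5, 10])
    def test_high_rate_identity_across_segment_lengths(self, k):
        # measured ~ actual for rates well above the cutoff, at every
        # segment length used in the calibration
        stack = simulate_growing_filament_stack(
            GrowthSimConfig(growth_rate=0.05, n_frames=400, seed=7)
        )
        m = measure_rate_from_stack(stack, movie_settings(), k)
        assert abs(m - 0.05) / 0.05 <= 0.1


class TestFitCutoff:
    @staticmethod
    def model(a, r):
        return np.where(a >= r, a, r)

    def test_exact_model_recovered(self):
        a = np.geomspace(1e-4, 0.1, 60)
        pairs = list(zip(a, self.model(a, 0.0148)))
        fit = fit_cutoff(pairs)
        assert fit.r_cutoff == pytest.approx(0.0148, abs=1e-6)
        assert fit.residual == pytest.approx(0.0, abs=1e-12)

    def test_noisy_recovery(self):
        rng = np.random.default_rng(0)
        a = np.geomspace(1e-4, 0.1, 100)
        m = self.model(a, 0.0148) + rng.normal(0, 0.001, a.size)
        fit = fit_cutoff(list(zip(a, m)))
        assert abs(fit.r_cutoff - 0.0148) < 0.002

    def test_unidentifiable_rejected(self):
        a = np.array([0.05, 0.07, 0.1])
        with pytest.raises(ValueError):
            fit_cutoff(list(zip(a, a)))  # no plateau: all pairs above any cutoff
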