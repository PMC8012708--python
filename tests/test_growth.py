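"""Diauxic growth segmentation, specific growth rates and yield arithmetic."""

import numpy as np
import pytest

from microbcr.errors import InsufficientDataError
from microbcr.growth import (
    CultivationRecord,
    detect_diauxic_shift,
    specific_growth_rate,
    summarize_cultivation,
    yield_coefficient,
)
from microbcr.synthetic import DiauxicModelParams, SyntheticConfig, make_cultivation_record


def _exp_record(mu, x0=0.1, duration=10.0, dt=0.05):
    t = np.arange(0.0, duration + dt / 2, dt)
    return CultivationRecord(t, x0 * np.exp(mu * t))


class TestSpecificGrowthRate:
    @pytest.mark.parametrize("mu", [0.403, 0.147])
    def test_exact_on_noiseless_exponential(self, mu):
        rec = _exp_record(mu)
        est, se = specific_growth_rate(rec, (0.0, 10.0))
        assert est == pytest.approx(mu, rel=1e-9)
        assert se == pytest.approx(0.0, abs=1e-9)

    def test_constant_biomass_gives_zero_rate(self):
        rec = _exp_record(0.0)
        est, _ = specific_growth_rate(rec, (0.0, 10.0))
        assert est == pytest.approx(0.0, abs=1e-12)

    def test_nonpositive_samples_excluded_with_warning(self):
        t = np.arange(0.0, 5.0, 0.5)
        x = 0.1 * np.exp(0.4 * t)
        x[3] = 0.0
        rec = CultivationRecord(t, x)
        with pytest.warns(UserWarning):
            est, _ = specific_growth_rate(rec, (0.0, 5.0))
        assert est == pytest.approx(0.4, rel=1e-9)

    def test_too_few_points_rejected(self):
        rec = _exp_record(0.4, duration=1.0, dt=0.5)
        with pytest.raises(InsufficientDataError):
            specific_growth_rate(rec, (0.0, 0.6))

    def test_unbiased_under_lognormal_noise(self):
        """Seeded simulation: mean estimate over 200 replicates within
        Monte-Carlo error of the true rate."""
        mu, sigma, n_rep = 0.403, 0.05, 200
        rng = np.random.default_rng(99)
        t = np.arange(0.5, 5.3, 1.0 / 60.0)
        base = 1.0 * np.exp(mu * (t - 0.5))
        ests = []
        for _ in range(n_rep):
            x = base * np.exp(rng.normal(0.0, sigma, size=t.shape))
            est, _ = specific_growth_rate(CultivationRecord(t, x), (0.5, 5.3))
            ests.append(est)
        ests = np.asarray(ests)
        mc_err = 3 * ests.std(ddof=1) / np.sqrt(n_rep)
        assert abs(ests.mean() - mu) < max(mc_err, 1e-4)


class TestDiauxicShiftDetection:
    def test_generator_shift_recovered_at_sampling_resolution(self, diauxic_record):
        dt = 1.0 / 60.0
        truth = diauxic_record.ground_truth["glucose_depletion_time"]
        est = detect_diauxic_shift(diauxic_record)
        assert truth == pytest.approx(5.3, abs=1e-9)
        # smoothing (5 samples) plus gradient localization: a few samples' slack
        assert est == pytest.approx(truth, abs=3 * dt)

    def test_single_phase_record_reports_no_shift(self):
        # glucose never depletes within the record: monotone CO2, no drop
        params = DiauxicModelParams(X0=0.1, S0=500.0, mu1=0.3, mu2=0.3, lag=0.0)
        rec = make_cultivation_record(params, SyntheticConfig(seed=13),
                                      duration_h=8.0)
        assert detect_diauxic_shift(rec) is None

    def test_shift_invariant_to_constant_offset(self, diauxic_record):
        base = detect_diauxic_shift(diauxic_record)
        shifted = CultivationRecord(
            diauxic_record.timestamps_h,
            diauxic_record.bdw,
            co2_offgas=diauxic_record.co2_offgas + 7.5,
        )
        assert detect_diauxic_shift(shifted) == base

    def test_shift_invariant_to_affine_rescale(self, diauxic_record):
        base = detect_diauxic_shift(diauxic_record)
        scaled = CultivationRecord(
            diauxic_record.timestamps_h,
            diauxic_record.bdw,
            co2_offgas=3.0 * diauxic_record.co2_offgas + 1.0,
        )
        assert detect_diauxic_shift(scaled) == base


class TestYieldCoefficient:
    @pytest.mark.parametrize(
        "dx, ds, ndigits, expected",
        [
            (6.3, 20.0, None, 0.315),
            (6.3, 20.0, 1, 0.3),     # glucose-phase yield as reported
            (12.1, 20.0, None, 0.605),
            (12.1, 20.0, 2, 0.61),   # total yield as reported
            (0.0, 20.0, None, 0.0),
        ],
    )
    def test_arithmetic_and_reporting_rounding(self, dx, ds, ndigits, expected):
        assert yield_coefficient(dx, ds, ndigits=ndigits) == expected

    def test_zero_consumption_rejected(self):
        with pytest.raises(ValueError):
            yield_coefficient(1.0, 0.0)


class TestSummarizeCultivation:
    def test_recovers_generator_ground_truth(self, diauxic_record):
        truth = diauxic_record.ground_truth
        res = summarize_cultivation(diauxic_record, s0=20.0)
        assert res.phase1.mu_per_h == pytest.approx(truth["mu1"], rel=0.005)
        assert res.phase2.mu_per_h == pytest.approx(truth["mu2"], rel=0.005)
        assert res.glucose_depletion_time_h == pytest.approx(
            truth["glucose_depletion_time"], abs=0.1
        )
        assert res.y1 == pytest.approx(truth["y1"], rel=0.02)
        assert res.y_total == pytest.approx(truth["y_total"], rel=0.01)
        assert res.x_max == pytest.approx(truth["x_max"], rel=0.01)

    def test_total_yield_not_below_phase1_yield(self, diauxic_record):
        res = summarize_cultivation(diauxic_record, s0=20.0)
        assert res.y_total >= res.y1

    def test_record_truncated_before_shift_has_no_phase2(self):
        rec = make_cultivation_record(
            DiauxicModelParams(), SyntheticConfig(seed=17), duration_h=4.0
        )
        res = summarize_cultivation(rec, s0=20.0)
        assert res.phase2 is None
        assert res.glucose_depletion_time_h is None

    def test_mean_of_duplicate_records_equals_single_noiseless_result(
        self, diauxic_record
    ):
        rec = diauxic_record
        mean_rec = CultivationRecord(
            rec.timestamps_h,
            (rec.bdw + rec.bdw) / 2,
            co2_offgas=(rec.co2_offgas + rec.co2_offgas) / 2,
        )
        a = summarize_cultivation(rec, s0=20.0)
        b = summarize_cultivation(mean_rec, s0=20.0)
        assert b.phase1.mu_per_h == pytest.approx(a.phase1.mu_per_h, rel=1e-12)
        assert b.glucose_depletion_time_h == a.glucose_depletion_time_h


class TestGeneratorConsistency:
    def test_mass_balance_during_glucose_phase(self, diauxic_record):
        """X(t) - X0 = Y1 (S0 - S(t)) while glucose remains."""
        rec = diauxic_record
        truth = rec.ground_truth
        t = rec.timestamps_h
        m = (t >= 0.5) & (t < truth["glucose_depletion_time"])
        x0 = rec.bdw[0]
        lhs = rec.bdw[m] - x0
        rhs = (6.3 / 20.0) * (20.0 - truth["glucose"][m])
        assert np.allclose(lhs, rhs, rtol=1e-9)

    def test_default_timeline_matches_published_narrative(self):
        p = DiauxicModelParams()
        assert p.glucose_depletion_time == pytest.approx(5.3, abs=1e-12)
        x_dep = p.X0 + p.Y1 * p.S0
        assert x_dep - p.X0 == pytest.approx(6.3)
        assert x_dep + p.Y2 * p.ethanol_max == pytest.approx(12.1)

    def test_bit_reproducible_under_fixed_seed(self):
        cfg = SyntheticConfig(seed=21, noise_sd=0.3)
        a = make_cultivation_record(DiauxicModelParams(), cfg, duration_h=6.0)
        b = make_cultivation_record(DiauxicModelParams(), cfg, duration_h=6.0)
        assert np.array_equal(a.bdw, b.bdw)
        assert np.array_equal(a.co2_offgas, b.co2_offgas)

    def test_offgas_o2_mirrors_co2_in_phase1(self, diauxic_record):
        rec = diauxic_record
        t = rec.timestamps_h
        m = (t > 1.0) & (t < 5.0)
        co2 = rec.co2_offgas[m]
        o2 = rec.o2_offgas[m]
        r = np.corrcoef(co2, o2)[0, 1]
        assert r < -0.99
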