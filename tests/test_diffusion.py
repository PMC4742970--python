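import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from curtainlab.diffusion import (
    MsdCurve,
    MsdDiffusionEstimator,
    compare_log_d,
    compute_msd,
    fit_diffusion,
    rotational_sliding_limit,
    summarize_population,
)
from curtainlab.geometry import DnaGeometry
from curtainlab.pipeline import synthetic_condition_tracks
from curtainlab.tracking import Trajectory

GEO = DnaGeometry()


def track_from_um(y_um, detected=None, dt=0.2):
    y_um = np.asarray(y_um, dtype=float)
    return Trajectory(
        molecule_id=0,
        frame_interval_s=dt,
        times_s=np.arange(len(y_um)) * dt,
        positions_um=y_um,
        detected=np.ones(len(y_um), bool) if detected is None else np.asarray(detected, bool),
        geometry=GEO,
    )


class TestMsd:
    def test_constant_position_gives_zero_msd(self):
        curve = compute_msd(track_from_um(np.full(30, 3.5)), 10)
        np.testing.assert_array_equal(curve.msd_um2, 0.0)
        np.testing.assert_array_equal(curve.n_pairs, 30 - np.arange(1, 11))

    def test_alternating_positions_forced_by_overlapping_windows(self):
        curve = compute_msd(track_from_um([0, 1, 0, 1, 0, 1]), 2)
        assert curve.msd_um2[0] == pytest.approx(1.0)
        assert curve.msd_um2[1] == pytest.approx(0.0)

    def test_uniform_drift_gives_quadratic_msd(self):
        v, dt = 0.3, 0.2
        y = v * np.arange(50) * dt
        curve = compute_msd(track_from_um(y, dt=dt), 10)
        np.testing.assert_allclose(curve.msd_um2, (v * curve.lag_times_s) ** 2, rtol=1e-10)

    def test_lag1_equals_brute_force_mean_square_step(self):
        rng = np.random.default_rng(7)
        y = np.cumsum(rng.normal(0, 0.1, 500))
        det = rng.random(500) > 0.1  # gapped track
        curve = compute_msd(track_from_um(y, detected=det), 10)
        # independent brute-force enumeration of detected pairs at lag 1
        sq, cnt = 0.0, 0
        for i in range(499):
            if det[i] and det[i + 1]:
                sq += (y[i + 1] - y[i]) ** 2
                cnt += 1
        assert curve.n_pairs[0] == cnt
        assert curve.msd_um2[0] == pytest.approx(sq / cnt, rel=1e-13)

    def test_short_track_rejected(self):
        with pytest.raises(ValueError):
            compute_msd(track_from_um(np.arange(8.0)), 10)


class TestLineFit:
    def test_exact_line_recovers_d_and_intercept(self):
        t = np.arange(1, 11) * 0.2
        curve = MsdCurve(t, 2 * 0.05 * t, np.full(10, 100))
        est = fit_diffusion(curve)
        assert est.d_um2_s == pytest.approx(0.05, abs=1e-12)
        assert est.intercept_um2 == pytest.approx(0.0, abs=1e-12)

    def test_constant_offset_moves_intercept_not_slope(self):
        t = np.arange(1, 11) * 0.2
        curve = MsdCurve(t, 2 * 0.05 * t + 0.01, np.full(10, 100))
        est = fit_diffusion(curve)
        assert est.d_um2_s == pytest.approx(0.05, abs=1e-12)
        assert est.intercept_um2 == pytest.approx(0.01, abs=1e-12)

    def test_single_lag_is_singular(self):
        with pytest.raises(ValueError):
            fit_diffusion(MsdCurve(np.array([0.2]), np.array([0.02]), np.array([9])))

    @settings(derandomize=True, max_examples=20, deadline=None)
    @given(c=st.floats(0.1, 10.0))
    def test_scale_equivariance_d_scales_as_c_squared(self, c):
        rng = np.random.default_rng(3)
        y = np.cumsum(rng.normal(0, 0.1, 300))
        d1 = fit_diffusion(compute_msd(track_from_um(y), 10)).d_um2_s
        d2 = fit_diffusion(compute_msd(track_from_um(c * y), 10)).d_um2_s
        assert d2 == pytest.approx(c**2 * d1, rel=1e-9)

    def test_localization_noise_lands_in_intercept_not_slope(self):
        sigma = 0.08
        rng = np.random.default_rng(9)
        d_clean, d_noisy, icept_shift = [], [], []
        for _ in range(20):
            y = np.cumsum(rng.normal(0, math.sqrt(2 * 0.05 * 0.2), 4000))
            noisy = y + rng.normal(0, sigma, len(y))
            e0 = fit_diffusion(compute_msd(track_from_um(y), 10))
            e1 = fit_diffusion(compute_msd(track_from_um(noisy), 10))
            d_clean.append(e0.d_um2_s)
            d_noisy.append(e1.d_um2_s)
            icept_shift.append(e1.intercept_um2 - e0.intercept_um2)
        assert np.mean(icept_shift) == pytest.approx(2 * sigma**2, rel=0.25)
        assert abs(np.mean(d_noisy) - np.mean(d_clean)) < 0.05 * np.mean(d_clean)

    def test_estimator_consistency_over_population(self):
        tracks = synthetic_condition_tracks(0.05, 200, 300, GEO, loc_sigma_bp=0.0, seed=21)
        est = MsdDiffusionEstimator().fit(tracks)
        assert est.d_coefficients_.mean() == pytest.approx(0.05, rel=0.10)


class TestPopulations:
    def test_single_estimate_summary_flagged(self):
        e = fit_diffusion(MsdCurve(np.arange(1, 11) * 0.2, 0.04 * np.arange(1, 11) * 0.2, np.full(10, 9)))
        s = summarize_population([e], "one")
        assert s.mean_d == pytest.approx(e.d_um2_s)
        assert s.sd_d == 0.0 and s.single_member

    def test_mean_of_two(self):
        t = np.arange(1, 11) * 0.2
        es = [
            fit_diffusion(MsdCurve(t, 2 * d * t, np.full(10, 9)))
            for d in (0.02, 0.04)
        ]
        assert summarize_population(es, "pair").mean_d == pytest.approx(0.03)

    def test_nucleotide_dependent_doubling_recovered_from_simulation(self):
        # ADP-like vs AMP-PNP-like populations (~2x apart)
        adp = synthetic_condition_tracks(0.025, 72, 150, GEO, seed=31)
        pnp = synthetic_condition_tracks(0.053, 50, 150, GEO, seed=32)
        m_adp = MsdDiffusionEstimator().fit(adp).d_coefficients_.mean()
        m_pnp = MsdDiffusionEstimator().fit(pnp).d_coefficients_.mean()
        assert m_pnp / m_adp == pytest.approx(0.053 / 0.025, rel=0.15)


class TestLogTTest:
    def test_identical_samples_give_p_of_one(self):
        a = [0.01, 0.02, 0.05, 0.1]
        res = compare_log_d(a, list(a))
        assert res.p_value == pytest.approx(1.0)
        assert res.ci_low < 0 < res.ci_high

    def test_salt_conditions_separate_with_high_power(self):
        # log-normal populations at the 51 mM and 176 mM means
        rng = np.random.default_rng(2)
        hits = 0
        for _ in range(50):
            a = rng.lognormal(math.log(0.031), 0.8, 47)
            b = rng.lognormal(math.log(0.12), 0.8, 49)
            if compare_log_d(a, b).p_value < 1e-3:
                hits += 1
        assert hits >= 0.95 * 50

    def test_nonpositive_values_excluded_and_counted(self):
        res = compare_log_d([0.01, 0.02, -0.01, 0.03], [0.05, 0.06, 0.07])
        assert res.n_excluded_a == 1 and res.n_excluded_b == 0

    def test_single_member_group_rejected(self):
        with pytest.raises(ValueError):
            compare_log_d([0.01], [0.02, 0.03])

    def test_agrees_with_statsmodels_welch(self):
        from statsmodels.stats.weightstats import ttest_ind as sm_ttest

        rng = np.random.default_rng(11)
        a = rng.lognormal(-3.3, 0.7, 30)
        b = rng.lognormal(-2.5, 0.9, 40)
        res = compare_log_d(a, b)
        _, p_sm, _ = sm_ttest(np.log10(a), np.log10(b), usevar="unequal")
        assert res.p_value == pytest.approx(p_sm, rel=1e-9)


class TestRotationalSlidingLimit:
    def test_viscosity_and_radius_monotonicity(self):
        base = rotational_sliding_limit()
        assert rotational_sliding_limit(viscosity_Pa_s=0.89) < 1e-3 * base
        assert rotational_sliding_limit(protein_radius_nm=10.0) < base

    def test_default_value_pinned_by_direct_formula_evaluation(self):
        # independent arithmetic: kT / [6 pi eta a (1 + (4/3)(2 pi/b)^2 (a^2*4/3... )]
        kT = 1.380649e-23 * 298.15
        a = 5e-9
        r = 5e-9
        b = 3.57e-9
        eta = 0.89e-3
        zeta = (
            6 * math.pi * eta * a
            + (2 * math.pi / b) ** 2
            * (8 * math.pi * eta * a**3 + 6 * math.pi * eta * a * r**2)
        )
        expected_um2_s = kT / zeta * 1e12
        assert rotational_sliding_limit() == pytest.approx(expected_um2_s, rel=1e-9)
        assert rotational_sliding_limit() == pytest.approx(0.270, abs=0.001)

    def test_nonphysical_inputs_rejected(self):
        with pytest.raises(ValueError):
            rotational_sliding_limit(protein_radius_nm=-1)
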