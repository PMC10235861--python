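"""Process simulator and beta-dispersion spectrum generator."""

import numpy as np
import pytest

from softsensor.simulate import (
    DielectricParams,
    ProcessConfig,
    ProcessTrajectory,
    beta_dispersion_capacitance,
    generate_spectra,
    sample_offline,
    simulate_process,
)


def constant_trajectory(vcc=20e6, diameter=15.0, viability=1.0, days=1.0):
    times = np.array([0.0, days])
    return ProcessTrajectory(
        times_days=times,
        vcc_cells_per_mL=np.full(2, vcc),
        diameter_um=np.full(2, diameter),
        viability_fraction=np.full(2, viability),
        bleed_rate=np.zeros(2),
    )


class TestProcess:
    def test_pure_exponential_growth_without_bleed(self):
        """With bleed disabled and no death, VCC follows exp(mu t) exactly."""
        cfg = ProcessConfig(target_vcc_cells_per_mL=np.inf, death_rate_per_day=0.0,
                            specific_growth_rate_per_day=0.5, duration_days=10.0)
        traj = simulate_process(cfg)
        expected = cfg.initial_vcc_cells_per_mL * np.exp(0.5 * traj.times_days)
        np.testing.assert_allclose(traj.vcc_cells_per_mL, expected, rtol=1e-9)
        assert np.all(traj.bleed_rate == 0)

    def test_zero_controller_gains_never_bleed(self):
        cfg = ProcessConfig(pid_gains=(0.0, 0.0, 0.0), duration_days=15.0)
        traj = simulate_process(cfg)
        assert np.all(traj.bleed_rate == 0)
        assert traj.vcc_cells_per_mL[-1] > cfg.target_vcc_cells_per_mL

    def test_pid_holds_vcc_within_ten_percent_of_setpoint(self):
        """Default gains regulate to the setpoint within 2 days of bleed onset."""
        cfg = ProcessConfig(target_vcc_cells_per_mL=50e6)
        traj = simulate_process(cfg)
        onset = traj.times_days[np.argmax(traj.bleed_rate > 0)]
        mask = traj.times_days >= onset + 2.0
        assert mask.any()
        rel = np.abs(traj.vcc_cells_per_mL[mask] - 50e6) / 50e6
        assert rel.max() < 0.10

    def test_diameter_ramp_reaches_configured_increase(self):
        cfg = ProcessConfig(diameter_ramp=(7.0, 10.0, 0.20), diameter_base_um=15.0)
        traj = simulate_process(cfg)
        after = traj.diameter_um[traj.times_days >= 10.0]
        np.testing.assert_allclose(after, 15.0 * 1.20, rtol=1e-12)
        before = traj.diameter_um[traj.times_days <= 7.0]
        np.testing.assert_allclose(before, 15.0, rtol=1e-12)

    def test_vcc_plateaus_near_setpoint(self):
        cfg = ProcessConfig(target_vcc_cells_per_mL=50e6)
        traj = simulate_process(cfg)
        tail = traj.vcc_cells_per_mL[traj.times_days >= 15.0]
        assert abs(tail.mean() - 50e6) / 50e6 < 0.02

    def test_runaway_growth_fails_with_day(self):
        cfg = ProcessConfig(specific_growth_rate_per_day=400.0, target_vcc_cells_per_mL=np.inf,
                            duration_days=26.0)
        with pytest.raises(Exception, match="day"):
            simulate_process(cfg)


class TestBetaDispersion:
    params = DielectricParams()

    def test_low_frequency_plateau(self):
        c0 = beta_dispersion_capacitance(20e6, 15.0, 1e-9, self.params)
        from softsensor.simulate import _dispersion_terms
        delta_eps, _, _ = _dispersion_terms(20e6, 15.0, self.params)
        expected = self.params.baseline_capacitance_Cinf + self.params.cell_constant * float(delta_eps)
        assert c0 == pytest.approx(expected, rel=1e-9)

    def test_high_frequency_limit_is_baseline(self):
        c_inf = beta_dispersion_capacitance(20e6, 15.0, 1e12, self.params)
        assert c_inf == pytest.approx(self.params.baseline_capacitance_Cinf, rel=1e-6)

    def test_debye_half_amplitude_at_characteristic_frequency(self):
        """alpha = 0 at f = fc relaxes exactly half the dispersion amplitude."""
        p = DielectricParams(cole_cole_alpha=0.0)
        from softsensor.simulate import _dispersion_terms
        delta_eps, fc_kHz, _ = _dispersion_terms(20e6, 15.0, p)
        c = beta_dispersion_capacitance(20e6, 15.0, float(fc_kHz), p)
        expected = p.baseline_capacitance_Cinf + p.cell_constant * float(delta_eps) / 2.0
        assert c == pytest.approx(expected, rel=1e-10)

    def test_debye_closed_form(self):
        """alpha = 0 equals Cinf + k*delta_eps/(1+(f/fc)^2) to 1e-12 relative."""
        p = DielectricParams(cole_cole_alpha=0.0)
        from softsensor.simulate import _dispersion_terms
        delta_eps, fc_kHz, _ = _dispersion_terms(30e6, 16.0, p)
        for f in np.geomspace(50, 20000, 25):
            c = beta_dispersion_capacitance(30e6, 16.0, f, p)
            expected = p.baseline_capacitance_Cinf + p.cell_constant * float(delta_eps) / (1 + (f / float(fc_kHz)) ** 2)
            assert c == pytest.approx(expected, rel=1e-12)

    def test_doubling_vcc_doubles_dispersion_amplitude(self):
        """The permittivity increment is linear in biovolume, hence in VCC."""
        cinf = self.params.baseline_capacitance_Cinf
        a1 = beta_dispersion_capacitance(10e6, 15.0, 1e-9, self.params) - cinf
        a2 = beta_dispersion_capacitance(20e6, 15.0, 1e-9, self.params) - cinf
        assert a2 == pytest.approx(2 * a1, rel=1e-10)

    def test_monotone_decreasing_in_frequency(self):
        f = np.geomspace(50, 20000, 200)
        c = beta_dispersion_capacitance(40e6, 15.0, f, self.params)
        assert np.all(np.diff(c) < 0)

    def test_vcc_ordering_preserved_at_every_frequency(self):
        """States differing only in VCC order the same way at all frequencies."""
        f = np.geomspace(50, 20000, 25)
        lo = beta_dispersion_capacitance(20e6, 15.0, f, self.params)
        hi = beta_dispersion_capacitance(30e6, 15.0, f, self.params)
        assert np.all(hi > lo)

    def test_diameter_confounds_low_frequency_signal(self):
        """Bigger cells at fixed VCC: low-f capacitance up, fc down."""
        from softsensor.simulate import _dispersion_terms
        c_small = beta_dispersion_capacitance(30e6, 15.0, 100.0, self.params)
        c_big = beta_dispersion_capacitance(30e6, 18.0, 100.0, self.params)
        assert c_big > c_small
        _, fc_small, _ = _dispersion_terms(30e6, 15.0, self.params)
        _, fc_big, _ = _dispersion_terms(30e6, 18.0, self.params)
        assert fc_big < fc_small

    def test_nonphysical_biovolume_rejected(self):
        with pytest.raises(ValueError, match="biovolume"):
            beta_dispersion_capacitance(5e9, 20.0, 580.0, self.params)


class TestSpectraGeneration:
    def test_noiseless_constant_trajectory_gives_identical_records(self):
        cfg = ProcessConfig(duration_days=1.0, batch_phase_days=0.0, scan_interval_s=3600.0)
        params = DielectricParams(spectrum_noise_sd=0.0)
        recs = generate_spectra(constant_trajectory(days=1.0), params, cfg)
        assert len(recs) == 25
        for r in recs[1:]:
            np.testing.assert_array_equal(r.capacitance_pF_per_cm, recs[0].capacitance_pF_per_cm)

    def test_seeded_determinism(self):
        cfg = ProcessConfig(duration_days=1.0, batch_phase_days=0.0, scan_interval_s=600.0, rng_seed=7)
        params = DielectricParams()
        a = generate_spectra(constant_trajectory(days=1.0), params, cfg)
        b = generate_spectra(constant_trajectory(days=1.0), params, cfg)
        for ra, rb in zip(a, b):
            np.testing.assert_array_equal(ra.capacitance_pF_per_cm, rb.capacitance_pF_per_cm)

    def test_noise_sd_matches_request(self):
        """Per-frequency sample sd within 10% of the configured sd at n=2000."""
        days = 1999 * 30.0 / 86400.0
        cfg = ProcessConfig(duration_days=1.0, batch_phase_days=0.0, scan_interval_s=30.0, rng_seed=11)
        params = DielectricParams(spectrum_noise_sd=0.5)
        recs = generate_spectra(constant_trajectory(days=days), params, cfg)
        assert len(recs) == 2000
        X = np.stack([r.capacitance_pF_per_cm for r in recs])
        sd = X.std(axis=0, ddof=1)
        assert np.all(np.abs(sd - 0.5) / 0.5 < 0.10)

    def test_empty_trajectory_rejected(self):
        traj = ProcessTrajectory(times_days=np.array([]), vcc_cells_per_mL=np.array([]),
                                 diameter_um=np.array([]), viability_fraction=np.array([]),
                                 bleed_rate=np.array([]))
        with pytest.raises(ValueError, match="empty"):
            generate_spectra(traj, DielectricParams(), ProcessConfig())


class TestOfflineSampling:
    def test_zero_cv_reproduces_trajectory(self):
        cfg = ProcessConfig(offline_vcc_cv=0.0)
        traj = simulate_process(cfg)
        samples = sample_offline(traj, cfg)
        t_days = np.array([s.timestamp for s in samples]) / 86400.0
        expected = np.interp(t_days, traj.times_days, traj.vcc_cells_per_mL)
        np.testing.assert_allclose([s.vcc_cells_per_mL for s in samples], expected, rtol=1e-12)

    def test_daily_sampling_count(self):
        cfg = ProcessConfig(duration_days=26.0)
        traj = simulate_process(cfg)
        assert len(sample_offline(traj, cfg)) == 27

    def test_monte_carlo_cv_recovered(self):
        """500 replicate draws at one time reproduce the configured CV."""
        cfg = ProcessConfig(offline_vcc_cv=0.05, offline_sampling_times=tuple([10.0] * 500), rng_seed=5)
        traj = simulate_process(cfg)
        vcc = np.array([s.vcc_cells_per_mL for s in sample_offline(traj, cfg)])
        cv = vcc.std(ddof=1) / vcc.mean()
        assert 0.04 < cv < 0.06

    def test_sampling_outside_span_rejected(self):
        cfg = ProcessConfig(duration_days=5.0, offline_sampling_times=(0.0, 6.0))
        traj = simulate_process(cfg)
        with pytest.raises(ValueError, match="6"):
            sample_offline(traj, cfg)

    def test_noise_substreams_independent(self):
        """Turning spectrum noise on must not shift the offline noise draws."""
        cfg = ProcessConfig(duration_days=2.0, batch_phase_days=0.0, rng_seed=3,
                            offline_sampling_times=(0.0, 1.0, 2.0))
        traj = simulate_process(cfg)
        a = sample_offline(traj, cfg)
        # regenerate spectra (consumes the spectra stream) then resample
        generate_spectra(traj, DielectricParams(), cfg)
        b = sample_offline(traj, cfg)
        assert [s.vcc_cells_per_mL for s in a] == [s.vcc_cells_per_mL for s in b]
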