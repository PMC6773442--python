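import numpy as np
import pytest
from dataclasses import replace

from helipause.substrates import HairpinSubstrate, make_hairpin
from helipause.thermo import DuplexEnergyProfile, IonicConditions, compute_bp_energies
from helipause.simulator import (
    MeasurementConfig,
    SimulationConfig,
    calibrate_prefactor,
    expected_total_time,
    generate_trace_set,
    pause_time_mean,
    render_measurement,
    simulate_atpgs_trajectory,
    simulate_trajectory,
    step_slices,
    wlc_extension_per_nt,
)


def uniform_profile(L=20, g=2.0):
    hp = HairpinSubstrate("u", "A" * L)
    prof = compute_bp_energies(hp)
    prof.g1bp[:] = g
    return hp, prof


class TestWLC:
    def test_one_bp_extension_is_08_nm_at_8pN(self):
        ext = 2 * wlc_extension_per_nt(8.0, 1.0, 0.65)
        assert round(ext, 1) == 0.8

    def test_high_force_asymptote(self):
        x = wlc_extension_per_nt(5000.0, 1.0, 0.65)
        assert 0.6 < x < 0.65

    def test_monotone_in_force(self):
        assert wlc_extension_per_nt(4.0) < wlc_extension_per_nt(8.0)

    def test_invalid_force(self):
        with pytest.raises(ValueError):
            wlc_extension_per_nt(0.0)


class TestPauseTimeMean:
    def test_models_coincide_at_n1(self, profile):
        for i in (1, 5, 100):
            sim = SimulationConfig(model="simultaneous", n=1, prefactor_s=0.1)
            dly = SimulationConfig(model="delayed", n=1, prefactor_s=0.1)
            assert pause_time_mean(i, sim, profile) == pytest.approx(
                pause_time_mean(i, dly, profile)
            )

    def test_uniform_energy_closed_forms(self):
        _, prof = uniform_profile(L=20, g=2.0)
        sim = SimulationConfig(model="simultaneous", n=5, prefactor_s=1.0)
        dly = SimulationConfig(model="delayed", n=5, prefactor_s=1.0)
        assert pause_time_mean(1, sim, prof) == pytest.approx(np.exp(10.0))
        assert pause_time_mean(1, dly, prof) == pytest.approx(5 * np.exp(2.0))

    def test_delayed_additivity(self, profile):
        dly5 = SimulationConfig(model="delayed", n=5, prefactor_s=0.01)
        dly1 = SimulationConfig(model="delayed", n=1, prefactor_s=0.01)
        sl = step_slices(len(profile), 5)[2]
        single = sum(pause_time_mean(j + 1, dly1, profile) for j in range(sl.start, sl.stop))
        assert pause_time_mean(3, dly5, profile) == pytest.approx(single)

    def test_partial_last_step(self, profile):
        # 174 bp with n=5: 35 steps, the last covering 4 bp
        dly = SimulationConfig(model="delayed", n=5, prefactor_s=1.0)
        slices = step_slices(len(profile), 5)
        assert len(slices) == 35
        assert slices[-1].stop - slices[-1].start == 4
        with pytest.raises(IndexError):
            pause_time_mean(36, dly, profile)


class TestCalibration:
    def test_expected_rate_hits_target(self, hairpin, profile, delayed_config):
        rate = len(profile) / expected_total_time(delayed_config, profile)
        assert rate == pytest.approx(46.0, rel=5e-3)

    def test_recalibration_after_energy_shift(self, hairpin, profile):
        shifted = DuplexEnergyProfile(
            substrate=profile.substrate, g1bp=profile.g1bp + 0.7,
            conditions=profile.conditions,
        )
        cfg = calibrate_prefactor(hairpin, SimulationConfig(), shifted)
        rate = len(shifted) / expected_total_time(cfg, shifted)
        assert rate == pytest.approx(46.0, rel=5e-3)

    def test_unreachable_target_rejected(self, hairpin, profile):
        cfg = SimulationConfig(target_mean_rate=150.0)  # > v_trans = 100
        with pytest.raises(ValueError):
            calibrate_prefactor(hairpin, cfg, profile)

    def test_ensemble_mean_rate_near_target(self, hairpin, profile, delayed_config):
        rates = [
            simulate_trajectory(hairpin, delayed_config, profile, seed=s).mean_rate
            for s in range(200)
        ]
        sem = np.std(rates, ddof=1) / np.sqrt(len(rates))
        assert abs(np.mean(rates) - 46.0) <= 3 * sem + 1.0  # small Jensen bias


class TestTrajectory:
    def test_full_unwinding_and_ledger_conservation(self, hairpin, profile, delayed_config):
        traj = simulate_trajectory(hairpin, delayed_config, profile, seed=3)
        assert traj.event_positions[-1] == hairpin.length
        assert traj.bp_covered.sum() == hairpin.length
        assert traj.total_time == pytest.approx(traj.pause_s.sum() + traj.trans_s.sum())

    def test_deterministic_mode_exact_total(self, hairpin, profile, delayed_config):
        cfg = replace(delayed_config, pause_draw="deterministic")
        traj = simulate_trajectory(hairpin, cfg, profile, seed=0)
        assert traj.total_time == pytest.approx(expected_total_time(cfg, profile))

    def test_monte_carlo_mean_matches_closed_form(self):
        hp, prof = uniform_profile(L=20, g=1.0)
        cfg = calibrate_prefactor(hp, SimulationConfig(n=5, target_mean_rate=10.0), prof)
        totals = [
            simulate_trajectory(hp, cfg, prof, seed=s).total_time for s in range(400)
        ]
        sem = np.std(totals, ddof=1) / np.sqrt(len(totals))
        assert abs(np.mean(totals) - expected_total_time(cfg, prof)) <= 3 * sem

    def test_half_step_mode(self, hairpin, profile, delayed_config):
        cfg = replace(delayed_config, half_step=True)
        traj = simulate_trajectory(hairpin, cfg, profile, seed=1)
        assert len(traj.event_times) == 2 * len(traj.pause_s)
        assert traj.event_positions[-1] == hairpin.length
        # first sub-release of the first full step is 2.5 bp
        assert traj.event_positions[0] == pytest.approx(2.5)


class TestRenderMeasurement:
    def test_noise_free_staircase_risers(self, hairpin, profile, delayed_config, meas):
        traj = simulate_trajectory(hairpin, delayed_config, profile, seed=2)
        clean = replace(meas, noise_sigma_nm=0.0)
        trace = render_measurement(traj, clean, seed=0)
        risers = np.unique(np.round(np.diff(trace.extension_nm), 9))
        risers = risers[risers > 0]
        nm5 = 5 * 2 * wlc_extension_per_nt(8.0, 1.0, 0.65)
        assert np.all(np.isin(np.round(risers / (nm5 / 5)), [4, 5]))
        assert trace.extension_nm[-1] == pytest.approx(hairpin.length * meas.nm_per_bp)

    def test_noise_sd_calibrated(self, hairpin, profile, delayed_config, meas):
        traj = simulate_trajectory(hairpin, delayed_config, profile, seed=2)
        trace = render_measurement(traj, meas, seed=5, pad_s=20.0)
        tail = trace.extension_nm[-3000:]
        assert np.std(tail, ddof=1) == pytest.approx(14.0, rel=0.05)

    def test_uniform_sampling(self, hairpin, profile, delayed_config, meas):
        traj = simulate_trajectory(hairpin, delayed_config, profile, seed=2)
        trace = render_measurement(traj, meas, seed=0)
        assert np.allclose(np.diff(trace.time_s), 1.0 / meas.sampling_hz)


class TestAtpgsTrajectory:
    def test_zero_analog_identical_to_plain(self, hairpin, profile, delayed_config):
        a = simulate_atpgs_trajectory(
            hairpin, delayed_config, profile, atp_mM=1.0, atpgs_mM=0.0, seed=9
        )
        b = simulate_trajectory(hairpin, delayed_config, profile, seed=9)
        assert np.array_equal(a.event_times, b.event_times)

    def test_mean_added_pause_matches_binomial_mean(self, hairpin, profile, delayed_config):
        n_traces, P = 60, 0.5 / (1.2 * 0.5 + 0.5)
        m, k_off = 5, 2.5
        added = []
        for s in range(n_traces):
            a = simulate_atpgs_trajectory(
                hairpin, delayed_config, profile,
                atp_mM=0.5, atpgs_mM=0.5, k_ratio=1.2, k_off_per_s=k_off, seed=s,
            )
            b = simulate_trajectory(hairpin, delayed_config, profile, seed=s)
            added.append(np.mean(a.pause_s) - np.mean(b.pause_s))
        sem = np.std(added, ddof=1) / np.sqrt(len(added))
        assert abs(np.mean(added) - m * P / k_off) <= 3 * sem

    def test_rate_decreases_with_analog_fraction(self, hairpin, profile, delayed_config):
        means = []
        for frac in (0.05, 0.2, 0.5):
            rates = [
                simulate_atpgs_trajectory(
                    hairpin, delayed_config, profile,
                    atp_mM=1 - frac, atpgs_mM=frac, seed=s,
                ).mean_rate
                for s in range(25)
            ]
            means.append(np.mean(rates))
        assert means[0] > means[1] > means[2]

    def test_invalid_coupling_rejected(self, hairpin, profile, delayed_config):
        with pytest.raises(ValueError):
            simulate_atpgs_trajectory(
                hairpin, delayed_config, profile, atpgs_mM=0.5, C=0.3
            )


class TestModelSeparation:
    def test_simultaneous_amplifies_pause_contrast(self, hairpin, profile):
        """With >= 1 kBT of energy contrast and n >= 3 the simultaneous model's
        max/median step-pause ratio exceeds the delayed model's."""
        for n in (3, 5):
            sim = calibrate_prefactor(
                hairpin, SimulationConfig(model="simultaneous", n=n), profile
            )
            dly = calibrate_prefactor(
                hairpin, SimulationConfig(model="delayed", n=n), profile
            )
            t_sim = simulate_trajectory(
                hairpin, replace(sim, pause_draw="deterministic"), profile, seed=0
            ).pause_s
            t_dly = simulate_trajectory(
                hairpin, replace(dly, pause_draw="deterministic"), profile, seed=0
            ).pause_s
            assert np.max(t_sim) / np.median(t_sim) > np.max(t_dly) / np.median(t_dly)


class TestGenerateTraceSet:
    def test_reproducible_and_distinct(self, hairpin, delayed_config, meas):
        a = generate_trace_set(hairpin, delayed_config, meas, n_traces=3, seed=4)
        b = generate_trace_set(hairpin, delayed_config, meas, n_traces=3, seed=4)
        for ta, tb in zip(a, b):
            assert np.array_equal(ta.extension_nm, tb.extension_nm)
        assert not np.array_equal(a[0].extension_nm, a[1].extension_nm)

    def test_ground_truth_attached(self, atpgs_traces, hairpin):
        assert all(t.trajectory is not None for t in atpgs_traces)
        assert all(
            t.trajectory.event_positions[-1] == hairpin.length for t in atpgs_traces
        )
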