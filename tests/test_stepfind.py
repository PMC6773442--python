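import numpy as np
import pytest
from dataclasses import replace

from helipause.simulator import (
    MeasurementConfig,
    render_measurement,
    simulate_trajectory,
)
from helipause.stepfind import (
    NOISY_KM_PARAMS,
    NOISY_TTEST_PARAMS,
    StepFit,
    dwell_histogram,
    extract_pauses,
    km_step_find,
    min_resolvable_rate,
    step_size_distribution,
    to_bp,
    tstep_find,
)

DT = 1.0 / 200.0


def staircase(levels, samples_per_level, sigma=0.0, rng=None):
    y = np.repeat(levels, samples_per_level).astype(float)
    if sigma > 0:
        y = y + rng.normal(0, sigma, len(y))
    return y


class TestNoiselessExactness:
    @pytest.mark.parametrize("finder", [tstep_find, km_step_find])
    def test_three_level_staircase_exact(self, finder):
        y = staircase([0.0, 4.0, 8.0], 120)
        fit = finder((y, DT))
        assert fit.n_segments == 3
        assert np.array_equal(fit.boundaries, [0, 120, 240, 360])
        assert np.allclose(fit.levels, [0.0, 4.0, 8.0])

    def test_short_trace_single_segment(self):
        y = np.zeros(30)
        fit = tstep_find((y, DT), window_samples=25)
        assert fit.n_segments == 1

    def test_km_high_snr_single_step(self, rng):
        sigma = 1.0
        y = staircase([0.0, 10.0], 200, sigma, rng)  # 10-sigma step
        fit = km_step_find((y, DT))
        assert fit.n_segments == 2
        assert abs(fit.boundaries[1] - 200) <= 2


class TestFalsePositiveControl:
    def test_false_split_rate_on_pure_noise(self):
        w, n, alpha = 25, 10_000, 0.01
        splits = []
        for s in range(10):
            rng = np.random.default_rng(100 + s)
            fit = tstep_find((rng.normal(0, 1, n), DT), window_samples=w, alpha=alpha)
            splits.append(fit.n_segments - 1)
        positions_tested = n - 2 * w + 1
        # each scan position is a level-alpha test; false splits stay below
        # the per-test budget
        assert np.mean(splits) <= alpha * positions_tested
        # and tightening alpha tightens the rate
        strict = [
            tstep_find(
                (np.random.default_rng(200 + s).normal(0, 1, n), DT),
                window_samples=w, alpha=1e-4,
            ).n_segments
            - 1
            for s in range(5)
        ]
        assert np.mean(strict) < np.mean(splits)


@pytest.fixture(scope="module")
def bench():
    rng = np.random.default_rng(42)
    meas = MeasurementConfig()
    step_nm = 5 * meas.nm_per_bp
    traces, truths = [], []
    for _ in range(6):
        durations = rng.uniform(3.0, 6.0, 25)
        samples = (durations / DT).astype(int)
        levels = np.arange(25) * step_nm
        y = np.concatenate(
            [np.full(s, lv) for s, lv in zip(samples, levels)]
        ) + rng.normal(0, 14.0, samples.sum())
        traces.append(y)
        truths.append(np.cumsum(samples)[:-1])
    return traces, truths, meas


class TestBenchmarkRecovery:
    """Resolvable regime under the 14 nm noise floor: plateau averaging must
    push the level uncertainty well below the 3.9 nm step, which needs
    multi-second pauses (see the resolvability bound)."""

    def test_recall_on_long_pauses(self, bench):
        traces, truths, meas = bench
        tp = fn = 0
        for y, truth in zip(traces, truths):
            fit = tstep_find((y, DT), **NOISY_TTEST_PARAMS)
            det = fit.boundaries[1:-1]
            used = np.zeros(len(truth), bool)
            for d in det:
                j = np.argmin(np.abs(truth - d))
                if abs(truth[j] - d) <= 60 and not used[j]:
                    used[j] = True
                    tp += 1
            fn += (~used).sum()
        assert tp / (tp + fn) >= 0.7

    def test_cross_detector_agreement(self, bench):
        traces, _, meas = bench
        fits_t = [tstep_find((y, DT), **NOISY_TTEST_PARAMS) for y in traces]
        fits_k = [km_step_find((y, DT), **NOISY_KM_PARAMS) for y in traces]
        d_t = step_size_distribution(fits_t, meas)
        d_k = step_size_distribution(fits_k, meas)
        assert abs(d_t.center_bp - d_k.center_bp) / d_t.center_bp <= 0.10
        assert d_t.center_bp == pytest.approx(5.0, abs=1.0)
        assert d_k.center_bp == pytest.approx(5.0, abs=1.0)


class TestToBp:
    def test_full_open_is_174(self, meas):
        fit = StepFit(
            boundaries=[0, 100, 200], levels=[0.0, 174 * meas.nm_per_bp],
            dt=DT, meas_config=meas,
        )
        bp = to_bp(fit)
        assert bp.levels[1] == pytest.approx(174.0)
        assert bp.levels[0] == 0.0

    def test_round_trip(self, meas):
        fit = StepFit(boundaries=[0, 10], levels=[37.5], dt=DT, meas_config=meas)
        back = replace(to_bp(fit), levels=to_bp(fit).levels * meas.nm_per_bp, units="nm")
        assert back.levels[0] == pytest.approx(37.5)


class TestDwellHistogram:
    def test_conservation_exact(self, hairpin, profile, delayed_config):
        trajs = [
            simulate_trajectory(hairpin, delayed_config, profile, seed=s)
            for s in range(10)
        ]
        hist = dwell_histogram(trajs)
        assert hist.total_dwell_s == pytest.approx(
            sum(t.total_time for t in trajs), rel=1e-12
        )

    def test_planted_pause_dominates_its_bin(self, meas):
        fits = []
        for tid in range(10):
            # staircase 0..174 bp in 2-bp levels, 0.05 s each, plus 5 s at 90 bp
            levels = np.arange(0, 176, 2.0)
            samples = np.full(len(levels), 10)
            samples[levels == 90] = 1000
            bounds = np.concatenate([[0], np.cumsum(samples)])
            fits.append(
                StepFit(boundaries=bounds, levels=levels, dt=DT, units="bp", trace_id=tid)
            )
        hist = dwell_histogram(fits)
        assert abs(hist.bin_centers[np.argmax(hist.dwell_s)] - 90) <= 1.0


class TestExtractPauses:
    def make_fit(self):
        levels = [0.0, 5.0, 10.0, 15.0, 20.0]
        samples = [20, 200, 20, 400, 20]
        bounds = np.concatenate([[0], np.cumsum(samples)])
        return StepFit(boundaries=bounds, levels=levels, dt=DT, units="bp")

    def test_threshold_monotonicity_and_selection(self):
        fit = self.make_fit()
        p_all = extract_pauses(fit, min_duration_s=0.0)
        p_long = extract_pauses(fit, min_duration_s=0.5)
        p_none = extract_pauses(fit, min_duration_s=100.0)
        assert len(p_all) >= len(p_long) >= len(p_none) == 0
        assert set(p_long["position_bp"]) == {5.0, 15.0}
        assert p_long.set_index("position_bp")["duration_s"][15.0] == pytest.approx(2.0)

    def test_requires_bp_units(self, meas):
        fit = StepFit(boundaries=[0, 10, 20, 30], levels=[0, 4, 8], dt=DT, meas_config=meas)
        with pytest.raises(ValueError):
            extract_pauses(fit)


class TestStepSizeDistribution:
    def test_noiseless_delta_at_true_size(self, meas):
        fits = []
        for tid in range(3):
            levels = np.arange(0, 40) * 5 * meas.nm_per_bp
            bounds = np.concatenate([[0], np.cumsum(np.full(40, 100))])
            fits.append(
                StepFit(boundaries=bounds, levels=levels, dt=DT,
                        meas_config=meas, trace_id=tid)
            )
        dist = step_size_distribution(fits, meas)
        assert dist.center_bp == pytest.approx(5.0, abs=0.1)
        assert np.allclose(dist.sizes_bp, 5.0)


def test_min_resolvable_rate_matches_noise_argument():
    """4-bp steps under the stated noise floor need >~300 ms pauses,
    bounding the resolvable unwinding rate at ~13 bp/s."""
    assert min_resolvable_rate(4.0, 0.3) == pytest.approx(13.3, abs=0.1)
    assert round(min_resolvable_rate(4.0, 0.3)) == 13
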