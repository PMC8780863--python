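"""Rhythm quantification: peaks, periods, phase, classification."""

import numpy as np
import pytest
from scipy.signal import lombscargle

from frqclock import (
    ModelParameters,
    apply_knockout,
    classify_entrainment,
    constant,
    default_discard,
    default_parameters,
    detect_peaks,
    estimate_period,
    light_at,
    light_response_amplitude,
    phase_angle,
    simulate,
    smoothness_ratio,
    symmetric_ld,
)
from frqclock.rhythms import circular_phase_sd


def brute_force_dominant_period(t, x, resolution=0.01, lo=0.5, hi=48.0):
    """Independent oracle: exhaustive periodogram argmax."""
    periods = np.arange(lo, min(hi, t[-1] - t[0]), resolution)
    power = lombscargle(t, x - x.mean(), 2 * np.pi / periods)
    return periods[np.argmax(power)]


class TestDetectPeaks:
    def test_sinusoid_peak_times(self):
        t = np.arange(0, 110, 0.1)
        x = np.sin(2 * np.pi * t / 22.0)
        peaks = detect_peaks((t, x), min_prominence=0.2)
        assert np.allclose(peaks, [5.5, 27.5, 49.5, 71.5, 93.5], atol=0.1)

    def test_constant_series_has_no_peaks(self):
        t = np.arange(0, 50, 0.5)
        assert len(detect_peaks((t, np.full_like(t, 3.0)))) == 0

    def test_narrow_spikes_rejected_by_prominence(self):
        # trough-aligned cosine: 5 crests at 11 + 22k with full prominence
        t = np.arange(0, 110.01, 0.1)
        x = -np.cos(2 * np.pi * t / 22.0)
        spiky = x.copy()
        spike_idx = np.arange(55, len(t), 220)  # single samples on the flanks
        spiky[spike_idx] += 0.1  # 10% of amplitude
        peaks = detect_peaks((t, spiky), min_prominence=0.5)
        assert len(peaks) == 5  # the spikes contribute no peaks
        assert np.allclose(peaks, 11.0 + 22.0 * np.arange(5), atol=0.1)

    def test_endpoints_never_peak(self):
        t = np.arange(0, 10, 0.1)
        x = -((t - 0.0) ** 2)  # maximum at the first sample
        assert len(detect_peaks((t, x), min_prominence=0.1)) == 0

    def test_nonincreasing_times_rejected(self):
        with pytest.raises(ValueError):
            detect_peaks((np.array([0.0, 1.0, 1.0]), np.array([0.0, 1.0, 0.0])))


class TestEstimatePeriod:
    def test_pure_sinusoid(self):
        t = np.arange(0, 250, 0.25)
        est = estimate_period((t, np.sin(2 * np.pi * t / 22.0)), discard=0.0)
        assert est.mean == pytest.approx(22.0, abs=0.1)
        assert est.sd == pytest.approx(0.0, abs=0.1)

    @pytest.mark.parametrize("period", [2.0, 6.0, 16.0, 22.0, 27.0])
    def test_noisy_sinusoid_matches_brute_force_oracle(self, period):
        rng = np.random.default_rng(int(period * 100))
        t = np.arange(0, 12 * period, period / 40)
        x = np.sin(2 * np.pi * t / period) + 0.1 * rng.standard_normal(len(t))
        est = estimate_period((t, x), discard=0.0)
        oracle = brute_force_dominant_period(t, x, lo=0.5 * period, hi=2 * period)
        assert est.spectral == pytest.approx(period, rel=0.02)
        assert est.spectral == pytest.approx(oracle, rel=0.02)
        assert est.mean == pytest.approx(period, rel=0.05)

    def test_too_few_peaks_flagged_undefined(self):
        t = np.arange(0, 30, 0.5)
        est = estimate_period((t, np.sin(2 * np.pi * t / 22.0)), discard=0.0)
        assert not est.defined
        assert est.mean is None


class TestPhaseAngle:
    def test_forcing_as_its_own_response_has_zero_sd(self):
        protocol = symmetric_ld(6.0, 1.0)
        t = np.arange(0.0, 40 * 12.0, 0.1)
        x = np.array([light_at(protocol, ti) for ti in t])
        offs = phase_angle((t, x), protocol, "peak", discard=0.0)
        assert len(offs) >= 10
        assert np.ptp(offs) == pytest.approx(0.0, abs=1e-9)

    def test_entrained_model_phase_is_stable(self, ld_trajectory):
        traj = ld_trajectory(6.0)
        protocol = traj.protocol
        offs = phase_angle(traj.series("F"), protocol, "peak")
        assert circular_phase_sd(offs, protocol.T) <= 0.5

    def test_free_running_series_phase_drifts(self):
        # a 21.3 h rhythm referenced to a 4 h cycle wanders the circle
        protocol = symmetric_ld(2.0, 1.0)
        t = np.arange(0.0, 300.0, 0.1)
        x = np.cos(2 * np.pi * t / 21.3)
        offs = phase_angle((t, x), protocol, "peak", discard=0.0)
        assert circular_phase_sd(offs, protocol.T) > max(0.5, 0.1 * protocol.T)

    def test_constant_protocol_rejected(self, dd_trajectory):
        with pytest.raises(ValueError, match="phase angle"):
            phase_angle(dd_trajectory.series("F"), constant(0.0))


class TestClassification:
    @pytest.mark.parametrize("half_period,expected", [
        (12.0, "entrained"),
        (2.0, "free_running"),
    ])
    def test_calibrated_model(self, ld_trajectory, half_period, expected):
        traj = ld_trajectory(half_period)
        rep = classify_entrainment(traj.series("F"), traj.protocol)
        assert rep.classification == expected

    def test_free_run_period_near_endogenous(self, ld_trajectory):
        traj = ld_trajectory(2.0)
        rep = classify_entrainment(traj.series("F"), traj.protocol)
        assert 20.0 <= rep.period_spectral <= 24.0

    def test_frq_null_dd_is_arrhythmic(self, params):
        traj = simulate(apply_knockout(params, "frq"), constant(0.0), 400.0, dt=0.05)
        rep = classify_entrainment(traj.series("F"), constant(0.0), discard=96.0)
        assert rep.classification == "arrhythmic"

    def test_insufficient_data_is_an_error(self, params):
        protocol = symmetric_ld(12.0, 1.0)
        traj = simulate(params, protocol, 120.0, dt=0.05)
        with pytest.raises(ValueError, match="insufficient"):
            classify_entrainment(traj.series("F"), protocol)

    def test_entrained_implies_forcing_band_dominance(self, ld_trajectory):
        for hp in (12.0, 6.0, 3.0):
            traj = ld_trajectory(hp)
            rep = classify_entrainment(traj.series("F"), traj.protocol)
            assert rep.classification == "entrained"
            assert rep.forcing_band_power_ratio >= 3.0

    @pytest.mark.parametrize("half_period,expected", [
        (6.0, "entrained"),
        (2.0, "free_running"),
    ])
    def test_stable_under_multiplicative_noise(self, ld_trajectory, half_period, expected):
        """5% multiplicative noise must not flip the classification
        (20 seeds)."""
        traj = ld_trajectory(half_period)
        t, x = traj.series("F")
        for seed in range(20):
            rng = np.random.default_rng(seed)
            noisy = x * (1.0 + 0.05 * rng.standard_normal(len(x)))
            rep = classify_entrainment((t, noisy), traj.protocol)
            assert rep.classification == expected, f"seed {seed}"


class TestLightResponse:
    def test_amplitude_decreases_with_shorter_cycles(self, params, ld_trajectory):
        amps = []
        for hp in (12.0, 3.0, 1.0):
            traj = ld_trajectory(hp)
            amps.append(light_response_amplitude(traj.series("M_frq"), traj.protocol))
        assert amps[0] > amps[1] > amps[2]

    def test_identical_light_dark_series_gives_zero(self):
        protocol = symmetric_ld(6.0, 1.0)
        t = np.arange(0.0, 200.0, 0.1)
        x = np.full_like(t, 2.0)
        assert light_response_amplitude((t, x), protocol, discard=96.0) == 0.0

    def test_constant_light_rejected(self, dd_trajectory):
        with pytest.raises(ValueError):
            light_response_amplitude(dd_trajectory.series("M_frq"), constant(1.0))

    def test_amplitude_scales_with_light_drive(self, params):
        """Doubling v_light about doubles the LD12:12 induction while
        the response is far from saturation."""
        protocol = symmetric_ld(12.0, 1.0)
        amps = {}
        for scale in (1.0, 2.0):
            q = ModelParameters.from_dict(
                {**params.to_dict(), "v_light": params.v_light * scale}
            )
            traj = simulate(q, protocol, 240.0, dt=0.05)
            amps[scale] = light_response_amplitude(
                traj.series("M_frq"), protocol, discard=120.0
            )
        assert 1.5 <= amps[2.0] / amps[1.0] <= 2.5


class TestSmoothness:
    def test_protein_smoother_than_mrna_at_fast_cycles(self, ld_trajectory):
        for hp in (3.0, 2.0):
            traj = ld_trajectory(hp)
            r = smoothness_ratio(traj.series("F"), traj.series("M_frq"), traj.protocol)
            assert r < 1.0

    def test_identity_ratio_is_one(self, ld_trajectory):
        traj = ld_trajectory(3.0)
        r = smoothness_ratio(traj.series("M_frq"), traj.series("M_frq"), traj.protocol)
        assert r == pytest.approx(1.0)

    def test_ratio_decreases_with_cycle_length(self, ld_trajectory):
        ratios = []
        for hp in (12.0, 6.0, 3.0, 2.0):
            traj = ld_trajectory(hp)
            ratios.append(
                smoothness_ratio(traj.series("F"), traj.series("M_frq"), traj.protocol)
            )
        assert all(a > b for a, b in zip(ratios, ratios[1:]))

    def test_mismatched_grids_rejected(self, ld_trajectory):
        traj = ld_trajectory(3.0)
        t, x = traj.series("F")
        with pytest.raises(ValueError):
            smoothness_ratio((t[:-1], x[:-1]), traj.series("M_frq"), traj.protocol)
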