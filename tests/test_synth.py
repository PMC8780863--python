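"""Synthetic-data generators: determinism, fidelity, schema round-trips."""

import io

import numpy as np
import pytest

from frqclock import (
    RaceTubeRecord,
    band_periods,
    classify_entrainment,
    condition_correlation,
    gen_condition_panel,
    gen_densitometry,
    gen_morphometry,
    gen_race_tube,
    microconidia_proportion,
    simulate,
    spectral_period,
    symmetric_ld,
)
from frqclock.rhythms import default_discard
from frqclock.synth import flat_micro_effect, peaked_micro_effect


class TestDensitometry:
    def test_noiseless_samples_match_trajectory(self, params):
        protocol = symmetric_ld(12.0, 1.0)
        df = gen_densitometry(params, protocol, interval=3.0, noise_sd=0.0,
                              seed=0, duration=48.0, dt=0.05, rescale=False)
        lead = np.ceil(default_discard(protocol) / protocol.T) * protocol.T
        traj = simulate(params, protocol, lead + 48.0, dt=0.05)
        expect = np.interp(lead + df.time_h.to_numpy(), traj.times,
                           traj.component("F"))
        assert np.allclose(df.value.to_numpy(), expect)

    def test_rescaled_max_is_one(self, params):
        df = gen_densitometry(params, symmetric_ld(12.0, 1.0), interval=3.0,
                              noise_sd=0.1, seed=1, duration=48.0, dt=0.05)
        assert df.value.max() == pytest.approx(1.0)

    def test_seeded_determinism(self, params):
        kw = dict(interval=3.0, noise_sd=0.1, duration=48.0, dt=0.05)
        a = gen_densitometry(params, symmetric_ld(6.0, 1.0), seed=7, **kw)
        b = gen_densitometry(params, symmetric_ld(6.0, 1.0), seed=7, **kw)
        assert a.equals(b)

    def test_sampled_ld12_12_classifies_entrained(self, params):
        protocol = symmetric_ld(12.0, 1.0)
        df = gen_densitometry(params, protocol, interval=3.0, noise_sd=0.1,
                              seed=3, duration=264.0, dt=0.05)
        rep = classify_entrainment(
            (df.time_h.to_numpy(), df.value.to_numpy()), protocol, discard=0.0
        )
        assert rep.classification == "entrained"

    def test_sampled_ld2_2_dominant_period_is_circadian(self, params):
        protocol = symmetric_ld(2.0, 1.0)
        df = gen_densitometry(params, protocol, interval=3.0, noise_sd=0.1,
                              seed=3, duration=168.0, dt=0.05)
        dom = spectral_period((df.time_h.to_numpy(), df.value.to_numpy()),
                              period_min=14.0)
        assert 20.0 <= dom <= 24.0

    def test_interval_below_dt_rejected(self, params):
        with pytest.raises(ValueError):
            gen_densitometry(params, symmetric_ld(6.0, 1.0), interval=0.01,
                             noise_sd=0.0, dt=0.05)


class TestRaceTubeGenerator:
    def test_24h_band_sits_on_every_mark(self):
        rec = gen_race_tube(24.0, 1.5, days=4, jitter_sd=0.0, seed=0)
        assert np.allclose(rec.band_positions, rec.mark_positions[1:-1])

    def test_dense_banding_spacing(self):
        # the LD30min:30min regime: a 1 h period at 1.5 mm/h packs bands
        # 1.5 mm apart
        rec = gen_race_tube(1.0, 1.5, days=2, jitter_sd=0.0, seed=0)
        assert np.allclose(np.diff(rec.band_positions), 1.5)

    def test_round_trip_with_jitter(self):
        rec = gen_race_tube(18.0, 1.5, days=6, jitter_sd=0.3, seed=11)
        assert band_periods(rec).mean == pytest.approx(18.0, abs=0.5)

    def test_output_passes_reader_validation(self):
        rec = gen_race_tube(22.0, 1.5, days=5, jitter_sd=0.3, seed=2)
        buf = io.StringIO(rec.to_csv())
        back = RaceTubeRecord.from_csv(buf)
        assert back.mark_positions == rec.mark_positions
        assert back.band_positions == rec.band_positions

    def test_invalid_arguments_rejected(self):
        with pytest.raises(ValueError):
            gen_race_tube(0.0, 1.5, days=5)
        with pytest.raises(ValueError):
            gen_race_tube(20.0, 1.5, days=1)


class TestMorphometry:
    def test_pure_micro_population(self):
        ms = gen_morphometry(500, 1.0, seed=0)
        assert microconidia_proportion(ms) == 1.0

    def test_pure_macro_population(self):
        ms = gen_morphometry(500, 0.0, seed=0)
        assert microconidia_proportion(ms) == 0.0

    def test_recovers_mixture_fraction_within_binomial_error(self):
        props = [
            microconidia_proportion(gen_morphometry(2000, 0.35, seed=s))
            for s in range(20)
        ]
        assert np.all(np.abs(np.array(props) - 0.35) <= 0.03)

    def test_proportion_monotone_in_micro_fraction(self):
        props = [
            microconidia_proportion(gen_morphometry(3000, f, seed=42))
            for f in (0.1, 0.3, 0.5, 0.7, 0.9)
        ]
        assert all(a < b for a, b in zip(props, props[1:]))

    def test_seeded_determinism(self):
        assert gen_morphometry(50, 0.4, seed=9) == gen_morphometry(50, 0.4, seed=9)


class TestConditionPanel:
    def test_default_effect_peaks_at_half_period_12(self):
        panel = gen_condition_panel(seed=0)
        best = panel.loc[panel.micro_fraction_true.idxmax(), "half_period_h"]
        assert best == 12.0

    def test_monotone_effect_yields_significant_correlation(self):
        panel = gen_condition_panel(seed=1)
        _, p = condition_correlation(panel.cycle_length_h, panel.micro_proportion)
        assert p <= 0.05

    def test_flat_effect_is_usually_nonsignificant(self):
        """With no true dependence the correlation should exceed the 5%
        significance level in at least 80% of seeds."""
        ns = 0
        for seed in range(100):
            panel = gen_condition_panel(effect_model=flat_micro_effect, seed=seed)
            _, p = condition_correlation(panel.cycle_length_h, panel.micro_proportion)
            ns += p > 0.05
        assert ns >= 80

    def test_flat_growth_is_usually_nonsignificant(self):
        ns = 0
        for seed in range(100):
            panel = gen_condition_panel(seed=seed)
            _, p = condition_correlation(panel.cycle_length_h,
                                         panel.mean_daily_growth_mm)
            ns += p > 0.05
        assert ns >= 80

    def test_seeded_determinism(self):
        assert gen_condition_panel(seed=4).equals(gen_condition_panel(seed=4))

    def test_too_few_conditions_rejected(self):
        with pytest.raises(ValueError):
            gen_condition_panel(half_periods=(6.0, 12.0), seed=0)
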