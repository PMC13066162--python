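"""Generator contracts: Poiseuille utilities, beat templates, reproducibility."""

import math

import numpy as np
import pytest

from pulseflux import (
    BeatShape,
    GeneratorConfig,
    SignalRecord,
    generate_dataset,
    generate_records,
    make_beat_template,
    poiseuille_flow,
    segment_pulses,
    synthesize_ldf,
    synthesize_ppg,
    tube_resistance,
)
from pulseflux.core_io import ConfigError
from pulseflux.ppg_features import ppg_feature_table, pulse_amplitude


NOISELESS = dict(
    ppg_noise_sd={
        "intralipid": {530: 0.0, 655: 0.0, 940: 0.0},
        "lpfs": {530: 0.0, 655: 0.0, 940: 0.0},
    },
    baseline_wander_amplitude=0.0,
    beat_jitter_fraction=0.0,
)


class TestPoiseuille:
    def test_resistance_formula(self):
        # 8*mu*L/(pi*r^4) with mu=1, L=pi, r=1 collapses to 8
        assert tube_resistance(1.0, math.pi, 1.0) == pytest.approx(8.0, rel=1e-12)

    def test_halving_radius_multiplies_resistance_by_16(self):
        assert tube_resistance(1.0, 1.0, 0.5) == pytest.approx(
            16.0 * tube_resistance(1.0, 1.0, 1.0), rel=1e-12
        )

    def test_resistance_at_phantom_vessel_radius(self):
        # blood-like viscosity, 10 cm segment, 2.95 mm inner diameter;
        # independent arithmetic: 8*3.5e-3*0.1 / (pi * (1.475e-3)**4)
        expected = (8.0 * 3.5e-3 * 0.1) / (math.pi * (1.475e-3) ** 4)
        assert tube_resistance(3.5e-3, 0.1, 1.475e-3) == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(1.882956e8, rel=1e-6)

    def test_zero_gradient_gives_zero_flow(self):
        assert poiseuille_flow(100.0, 100.0, 5.0) == 0.0

    def test_flow_value_and_inverse_proportionality(self):
        assert poiseuille_flow(100.0, 10.0, 45.0) == pytest.approx(2.0, rel=1e-12)
        assert poiseuille_flow(100.0, 10.0, 90.0) == pytest.approx(1.0, rel=1e-12)

    def test_composition_is_exact(self):
        mu, L, r = 3.2e-3, 0.12, 1.3e-3
        R = tube_resistance(mu, L, r)
        assert poiseuille_flow(90.0, 5.0, R) == poiseuille_flow(
            90.0, 5.0, tube_resistance(mu, L, r)
        )

    @pytest.mark.parametrize("bad", [0.0, -1.0])
    def test_domain_errors(self, bad):
        with pytest.raises(ConfigError):
            tube_resistance(bad, 1.0, 1.0)
        with pytest.raises(ConfigError):
            poiseuille_flow(1.0, 0.0, bad)


class TestBeatTemplate:
    def test_symmetric_shape(self):
        t = make_beat_template(BeatShape(0.5, 1.0, 0.0), 101)
        assert t[0] == 0.0 and t[-1] == pytest.approx(0.0, abs=1e-12)
        assert np.argmax(t) == 50 and t.max() == 1.0

    def test_end_datum_offset_is_last_sample(self):
        t = make_beat_template(BeatShape(0.3, 0.7, 0.1), 2000)
        assert t[-1] == pytest.approx(0.1, abs=1e-9)

    @pytest.mark.parametrize(
        "shape",
        [BeatShape(0.2, 0.6, 0.0), BeatShape(0.45, 1.0, 0.3), BeatShape(0.3, 0.7, 0.22)],
    )
    def test_unit_peak_and_single_maximum(self, shape):
        t = make_beat_template(shape, 500)
        assert t.max() == 1.0
        # single global maximum: strictly below 1 away from the peak sample
        assert np.sum(t == 1.0) == 1

    def test_invalid_rise_fraction_rejected(self):
        with pytest.raises(ConfigError, match="rise_fraction"):
            make_beat_template(BeatShape(rise_fraction=1.5), 100)

    def test_too_few_samples_rejected(self):
        with pytest.raises(ConfigError, match="n_samples"):
            make_beat_template(BeatShape(), 4)


class TestSynthesizePpg:
    def test_noiseless_signal_is_exactly_periodic_with_configured_amplitude(self):
        cfg = GeneratorConfig(seed=0, duration_s=30.0, filter_compensation=False, **NOISELESS)
        rec = synthesize_ppg(cfg, "intermediate", "intralipid", 655)
        spb = int(round(cfg.ppg_rate_hz * 60.0 / cfg.heart_rate_bpm))
        np.testing.assert_array_equal(rec.samples[:spb], rec.samples[spb : 2 * spb])
        amps = [pulse_amplitude(s) for s in segment_pulses(rec, 60.0)]
        assert amps and np.allclose(amps, 0.72, atol=1e-6)

    def test_same_seed_reproduces_identical_samples(self):
        a = synthesize_ppg(GeneratorConfig(seed=5), "healthy", "intralipid", 655)
        b = synthesize_ppg(GeneratorConfig(seed=5), "healthy", "intralipid", 655)
        np.testing.assert_array_equal(a.samples, b.samples)

    def test_different_seed_differs(self):
        a = synthesize_ppg(GeneratorConfig(seed=5), "healthy", "intralipid", 655)
        b = synthesize_ppg(GeneratorConfig(seed=6), "healthy", "intralipid", 655)
        assert not np.array_equal(a.samples, b.samples)

    def test_default_duration_has_480000_samples(self, default_records):
        ppg = [r for r in default_records if r.modality == "ppg"]
        assert all(r.n_samples == 480_000 for r in ppg)

    def test_amplitude_ordering_holds_in_every_window(self, ppg_table):
        """Healthy > intermediate > unhealthy per-window amplitude, every window."""
        for (bmf, wl), g in ppg_table.groupby(["bmf", "wavelength_nm"]):
            pivot = g.pivot(index="window_index", columns="phantom_class", values="amplitude")
            assert (pivot["healthy"] > pivot["intermediate"]).all(), (bmf, wl)
            assert (pivot["intermediate"] > pivot["unhealthy"]).all(), (bmf, wl)


class TestSynthesizeLdf:
    def test_constant_when_noise_and_pulsatility_are_zero(self):
        cfg = GeneratorConfig(
            seed=0,
            duration_s=30.0,
            ldf_noise_sd={"intralipid": 0.0, "lpfs": 0.0},
            ldf_pulsatile_amplitude=0.0,
        )
        rec = synthesize_ldf(cfg, "intermediate", "intralipid")
        np.testing.assert_allclose(rec.samples, 550.0, atol=1e-9)

    def test_healthy_window_means_exceed_unhealthy_in_all_windows(self, ldf_table):
        for bmf, g in ldf_table.groupby("bmf"):
            pivot = g.pivot(index="window_index", columns="phantom_class", values="dc_mean_flux")
            assert len(pivot) == 24
            assert (pivot["healthy"] > pivot["unhealthy"]).all(), bmf

    def test_intralipid_flux_spread_exceeds_lpfs(self, ldf_table):
        """The intralipid BMF shows the larger healthy-to-unhealthy flux reduction."""
        gaps = {}
        for bmf, g in ldf_table.groupby("bmf"):
            means = g.groupby("phantom_class")["dc_mean_flux"].mean()
            gaps[bmf] = means["healthy"] - means["unhealthy"]
        assert gaps["intralipid"] > gaps["lpfs"]


class TestGeneratorConfigValidation:
    def test_non_monotone_class_amplitudes_rejected(self):
        amp = GeneratorConfig().ppg_amplitude
        amp["intralipid"][655]["intermediate"] = 2.0
        with pytest.raises(ConfigError, match="ppg_amplitude"):
            GeneratorConfig(ppg_amplitude=amp)

    def test_lpfs_flux_must_stay_below_intralipid(self):
        flux = GeneratorConfig().ldf_flux_mean
        flux["lpfs"]["healthy"] = 1e4
        with pytest.raises(ConfigError, match="ldf_flux_mean"):
            GeneratorConfig(ldf_flux_mean=flux)

    def test_round_trips_through_dict(self):
        cfg = GeneratorConfig(seed=9)
        again = GeneratorConfig.from_dict(cfg.to_dict())
        assert again.to_dict() == cfg.to_dict()
        assert again.config_hash == cfg.config_hash


class TestGenerateDataset:
    def test_full_factorial_counts_and_determinism(self, tmp_path):
        cfg_dict = GeneratorConfig(seed=3).to_dict()
        cfg_dict["duration_s"] = 20.0
        cfg = GeneratorConfig.from_dict(cfg_dict)
        m1 = generate_dataset(cfg, tmp_path / "a")
        m2 = generate_dataset(cfg, tmp_path / "b")
        assert len(m1.entries) == 24
        assert len(list((tmp_path / "a").glob("*.meta.json"))) == 24
        assert len(list((tmp_path / "a").glob("*.csv"))) == 25  # 24 signals + manifest
        for rel in m1.entries["path"]:
            assert (tmp_path / "a" / rel).read_bytes() == (tmp_path / "b" / rel).read_bytes()
        assert (tmp_path / "a" / "manifest.csv").read_bytes() == (
            tmp_path / "b" / "manifest.csv"
        ).read_bytes()

    def test_in_memory_factorial_is_24_records(self, default_records):
        assert len(default_records) == 24
        assert sum(r.modality == "ppg" for r in default_records) == 18
        assert sum(r.modality == "ldf" for r in default_records) == 6
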