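import numpy as np
import pytest

from bimodalsim.bsim import (BandSnrProfile, BsimConfig, EaWeighting,
                             EcErrors, band_snrs, bisect_gain, ci_auralize,
                             ea_weight, erb_space, find_srt,
                             gammatone_filterbank, shifted_profile, sii)
from bimodalsim.electric import AceConfig, NervePopulation


@pytest.fixture(scope="module")
def ideal_cfg():
    return BsimConfig(ec_errors=EcErrors(enabled=False))


class TestSii:
    def test_bounds(self):
        assert sii(np.full(30, 20.0)) == 1.0
        assert sii(np.full(30, -20.0)) == 0.0

    def test_two_band_hand_computation(self):
        """Equal-importance bands at 0 and +15 dB: (0.5 + 1) / 2 = 0.75."""
        assert sii(np.array([0.0, 15.0])) == pytest.approx(0.75)

    def test_importance_must_normalize(self):
        with pytest.raises(ValueError, match="sum to 1"):
            sii(np.zeros(3), np.array([0.5, 0.5, 0.5]))

    def test_monotone_in_band_snr(self):
        base = np.linspace(-20, 10, 15)
        s0 = sii(base)
        for b in range(15):
            bumped = base.copy()
            bumped[b] += 3.0
            assert sii(bumped) >= s0


class TestEc:
    def test_identical_noise_cancelled_to_cap(self, ideal_cfg):
        """Diotic noise, speech on one ear only: EC reaches the SNR cap."""
        rng = np.random.default_rng(0)
        n = rng.standard_normal(8192) * 0.05
        s = rng.standard_normal(8192) * 0.05
        prof = band_snrs(s, n, np.zeros(8192), n, ideal_cfg)
        assert np.all(prof.snr_ec >= ideal_cfg.snr_cap_db - 1e-9)

    def test_better_ear_rule_when_ec_disabled_by_structure(self, ideal_cfg):
        """Ideal EC is never worse than the better monaural ear."""
        rng = np.random.default_rng(1)
        n_l = rng.standard_normal(8192) * 0.05
        n_r = rng.standard_normal(8192) * 0.05
        s = rng.standard_normal(8192) * 0.05
        prof = band_snrs(s, n_l, 0.5 * s, n_r, ideal_cfg)
        better = np.maximum(prof.snr_left, prof.snr_right)
        assert np.all(prof.snr_ec >= better - 1e-9)

    def test_interaural_delay_recovered(self, ideal_cfg):
        """EC finds a 0.5 ms noise ITD within one delay-grid step."""
        rng = np.random.default_rng(2)
        n = rng.standard_normal(16384) * 0.05
        s = rng.standard_normal(16384) * 0.05
        delay = int(round(0.5e-3 * 16000))
        prof = band_snrs(s, n, np.zeros(16384), np.roll(n, delay), ideal_cfg)
        # when equalization aligns the noise, cancellation succeeds and
        # the EC SNR far exceeds the monaural paths in nearly every band
        assert np.mean(prof.snr_ec - np.maximum(prof.snr_left,
                                                prof.snr_right)) > 10.0

    def test_length_mismatch_rejected(self, ideal_cfg):
        with pytest.raises(ValueError, match="length"):
            band_snrs(np.zeros(100), np.zeros(100), np.zeros(100),
                      np.zeros(99), ideal_cfg)

    def test_jitter_floor_disables_ec_at_high_frequencies(self):
        """Time jitter makes high-frequency cancellation impossible."""
        cfg = BsimConfig()
        rng = np.random.default_rng(3)
        n = rng.standard_normal(8192) * 0.05
        s = rng.standard_normal(8192) * 0.05
        prof = band_snrs(s, n, 0.9 * s, n, cfg)
        high = prof.center_freqs > 2000.0
        # with the floor active, EC degenerates to better-ear listening
        better = np.maximum(prof.snr_left[high], prof.snr_right[high])
        assert np.all(prof.snr_ec[high] <= better + 1.0)
        assert not np.any(prof.selected[high] == "ec")


class TestEaWeighting:
    def _profiles(self, a, e):
        freqs = erb_space(146.0, 7840.0, len(a))
        neg = np.full(len(a), -1e9)
        pa = BandSnrProfile(freqs, a, neg, neg, np.array(["left"] * len(a)))
        pe = BandSnrProfile(freqs, neg, e, neg, np.array(["right"] * len(a)))
        return pa, pe

    def test_absent_electric_passes_acoustic(self):
        a = np.linspace(-10, 10, 30)
        pa, pe = self._profiles(a, np.full(30, -1e9))
        assert np.allclose(ea_weight(pa, pe), a)

    def test_identical_profiles_identity(self):
        a = np.linspace(-5, 5, 30)
        pa, pe = self._profiles(a, a)
        assert np.allclose(ea_weight(pa, pe), a)

    def test_step_profiles_take_bandwise_maximum(self):
        """Acoustic better low, electric better high: exhaustive max."""
        a = np.where(np.arange(30) < 15, 10.0, -10.0)
        e = np.where(np.arange(30) < 15, -10.0, 10.0)
        pa, pe = self._profiles(a, e)
        assert np.allclose(ea_weight(pa, pe), np.maximum(a, e))

    def test_crossover_mode_biases_sides(self):
        a = np.full(30, 0.0)
        e = np.full(30, 0.0)
        pa, pe = self._profiles(a, e)
        w = EaWeighting(mode="crossover", crossover_hz=1000.0, depth_db=30.0)
        combined = ea_weight(pa, pe, w)
        freqs = pa.center_freqs
        assert np.allclose(combined[freqs < 700], 0.0)   # acoustic side
        assert np.allclose(combined[freqs > 1500], 0.0)  # electric side
        off_a, off_e = w.offsets(freqs)
        assert np.all(off_a <= 0) and np.all(off_e <= 0)

    def test_band_grid_mismatch_rejected(self):
        pa, _ = self._profiles(np.zeros(30), np.zeros(30))
        _, pe = self._profiles(np.zeros(30), np.zeros(30))
        pe.center_freqs = pe.center_freqs * 1.1
        with pytest.raises(ValueError, match="bands"):
            ea_weight(pa, pe)


class TestSrtSearch:
    def test_fixed_point(self):
        """Reference equal to the SII at zero gain: SRT = base SNR."""
        base = np.linspace(-20, 5, 30)
        ref = sii(base)
        cfg = BsimConfig(sii_ref_acoustic=ref)
        res = find_srt(shifted_profile(base), "acoustic", cfg,
                       base_snr_db=-4.0)
        assert res.srt_db == pytest.approx(-4.0, abs=0.05)

    def test_bisection_matches_fine_grid_oracle(self):
        base = np.linspace(-30, 10, 30)
        res = find_srt(shifted_profile(base), "acoustic", BsimConfig())
        gains = np.arange(-60.0, 60.0, 0.005)
        siis = np.array([sii(base + g) for g in gains])
        oracle = gains[int(np.argmin(np.abs(siis - 0.26)))]
        assert res.gain_db == pytest.approx(oracle, abs=0.05)

    def test_default_references(self):
        cfg = BsimConfig()
        assert cfg.sii_ref_acoustic == 0.26
        assert cfg.sii_ref_ci == 0.42
        base = np.linspace(-30, 10, 30)
        assert find_srt(shifted_profile(base), "ci",
                        cfg).reference == 0.42

    def test_bracket_invariance(self):
        base = np.linspace(-30, 10, 30)
        a = find_srt(shifted_profile(base), "acoustic",
                     BsimConfig(search_gain_bounds=(-60, 60)))
        b = find_srt(shifted_profile(base), "acoustic",
                     BsimConfig(search_gain_bounds=(-43.7, 51.2)))
        assert a.gain_db == pytest.approx(b.gain_db, abs=0.05)

    def test_non_bracketing_interval_reported(self):
        base = np.full(30, 100.0)  # SII pinned at 1 everywhere
        with pytest.raises(ValueError, match="widen"):
            find_srt(shifted_profile(base), "acoustic",
                     BsimConfig(search_gain_bounds=(-5.0, 5.0)))

    def test_bimodal_reference_flagged(self):
        base = np.linspace(-30, 10, 30)
        res = find_srt(shifted_profile(base, dominant="right"), "bimodal",
                       BsimConfig())
        assert res.reference == 0.42
        assert "dominant" in res.note

    def test_reference_range_validated(self):
        with pytest.raises(ValueError, match="\\(0, 1\\)"):
            BsimConfig(sii_ref_ci=1.5)


class TestCiAuralize:
    def test_silence_in_silence_out(self):
        s, n = ci_auralize(np.zeros(4000), np.zeros(4000))
        assert np.allclose(s, 0) and np.allclose(n, 0)

    def test_tone_energy_lands_in_mapped_band(self):
        """A single-channel tone auralizes into the matching band."""
        cfg = BsimConfig()
        t = np.arange(16000) / 16000.0
        tone = 0.2 * np.sin(2 * np.pi * 1000.0 * t)
        aur, _ = ci_auralize(tone, np.zeros(16000))
        bands = gammatone_filterbank(aur, cfg.band_freqs())
        powers = (bands ** 2).mean(axis=1)
        peak = cfg.band_freqs()[int(np.argmax(powers))]
        assert 700.0 < peak < 1400.0

    def test_amplitude_scaling_monotone(self):
        t = np.arange(8000) / 16000.0
        tone = np.sin(2 * np.pi * 1000.0 * t)
        powers = []
        for scale in (0.02, 0.05, 0.1):
            aur, _ = ci_auralize(scale * tone, np.zeros(8000))
            powers.append(np.mean(aur ** 2))
        assert powers[0] <= powers[1] <= powers[2]

    def test_deterministic(self):
        x = np.random.default_rng(0).standard_normal(4000) * 0.1
        a1, _ = ci_auralize(x, np.zeros(4000))
        a2, _ = ci_auralize(x, np.zeros(4000))
        assert np.array_equal(a1, a2)
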