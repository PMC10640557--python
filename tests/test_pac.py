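"""Modulation-index identities, surrogate z-scoring, comodulogram recovery."""

import numpy as np
import pytest

from pacsoz import (
    SurrogateSpec,
    SynthConfig,
    comodulogram,
    compute_comodulograms,
    generate_coupled_signal,
    generate_recording,
    mvl_raw,
    surrogate_z,
)
from pacsoz.bands import FrequencyBand, fir_bandpass, hilbert_phase_amplitude, segment
from pacsoz.pac import lagged_mvl

FS = 2000.0


class TestMvlRaw:
    def test_constant_vector(self):
        assert mvl_raw(np.full(100, 0.7), np.full(100, 3.0)) == pytest.approx(3.0)

    def test_uniform_phase_cancels(self):
        n = 100000
        phase = (np.arange(n) * 2 * np.pi * 37 / n) % (2 * np.pi) - np.pi
        assert mvl_raw(phase, np.ones(n)) < 1e-3

    def test_cosine_modulated_closed_form(self):
        """|E[(1 + cos(phi)) e^{i phi}]| = 1/2 for uniform phase."""
        n = 200000
        phase = (np.arange(n) * 2 * np.pi * 41 / n) % (2 * np.pi) - np.pi
        assert mvl_raw(phase, 1.0 + np.cos(phase)) == pytest.approx(0.5, abs=1e-6)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="lengths differ"):
            mvl_raw(np.zeros(10), np.zeros(11))


class TestLaggedMvl:
    def test_matches_naive_roll_oracle(self, rng):
        """FFT cross-correlation equals explicitly rolled MVL at every lag."""
        phase = rng.uniform(-np.pi, np.pi, 4096)
        amp = rng.standard_normal(4096) ** 2
        lm = lagged_mvl(phase, amp)
        for s in [0, 1, 17, 1000, 4095]:
            naive = mvl_raw(np.roll(phase, -s), amp)
            assert lm[s] == pytest.approx(naive, abs=1e-12)


class TestSurrogateZ:
    def test_scale_invariance(self, rng):
        spec = SurrogateSpec(n_surrogates=50, min_shift=100, seed=1)
        phase = rng.uniform(-np.pi, np.pi, 5000)
        amp = rng.standard_normal(5000) ** 2
        z1 = surrogate_z(phase, amp, spec, key=(0,))
        z2 = surrogate_z(phase, 10.0 * amp, spec, key=(0,))
        assert z1 == pytest.approx(z2, abs=1e-9)

    def test_seeded_determinism(self, rng):
        spec = SurrogateSpec(n_surrogates=50, min_shift=100, seed=1)
        phase = rng.uniform(-np.pi, np.pi, 5000)
        amp = rng.standard_normal(5000) ** 2
        assert surrogate_z(phase, amp, spec, key=(3,)) == surrogate_z(
            phase, amp, spec, key=(3,)
        )

    def test_degenerate_constant_input(self):
        spec = SurrogateSpec(n_surrogates=20, min_shift=10, seed=0)
        with pytest.warns(UserWarning, match="degenerate"):
            z = surrogate_z(np.zeros(1000), np.ones(1000), spec)
        assert z == 0.0

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            SurrogateSpec(n_surrogates=1).validate(1000)
        with pytest.raises(ValueError):
            SurrogateSpec(n_surrogates=10, min_shift=600).validate(1000)

    def test_strong_coupling_exceeds_3(self):
        """Noiseless maximal coupling yields a clearly significant z score."""
        cfg = SynthConfig(duration=20.0, kappa=1.0, snr_sd=0.0, seed=0)
        x = generate_coupled_signal(cfg, "SOZ")
        ph = hilbert_phase_amplitude(fir_bandpass(x, FrequencyBand(3, 4), FS), "phase")
        am = hilbert_phase_amplitude(
            fir_bandpass(x, FrequencyBand(110, 140), FS), "amplitude"
        )
        spec = SurrogateSpec(n_surrogates=100, min_shift=2000, seed=2)
        assert surrogate_z(ph, am, spec) > 3.0

    def test_kappa_monotonicity(self):
        """Mean z at the injected cell is non-decreasing in coupling depth."""
        spec = SurrogateSpec(n_surrogates=50, min_shift=2000, seed=4)
        mean_z = []
        for kappa in (0.0, 0.25, 0.5, 1.0):
            cfg = SynthConfig(
                duration=400.0, kappa=kappa, snr_sd=1.0, seed=17,
                n_soz=1, n_nsoz=1,
            )
            x = generate_coupled_signal(cfg, "SOZ")
            ph = hilbert_phase_amplitude(
                fir_bandpass(x, FrequencyBand(3, 4), FS), "phase"
            )
            am = hilbert_phase_amplitude(
                fir_bandpass(x, FrequencyBand(110, 140), FS), "amplitude"
            )
            ph_s = segment(ph, FS).segments
            am_s = segment(am, FS).segments
            zs = [
                surrogate_z(ph_s[i], am_s[i], spec, key=(int(kappa * 100), i))
                for i in range(20)
            ]
            mean_z.append(np.mean(zs))
        assert all(b >= a for a, b in zip(mean_z, mean_z[1:])), mean_z
        assert mean_z[0] < 2.0 < mean_z[-1]


class TestComodulogram:
    def test_shape_and_orientation(self, grid, fast_spec, rng):
        phases = rng.uniform(-np.pi, np.pi, (16, 8000))
        amps = rng.standard_normal((16, 8000)) ** 2
        spec = SurrogateSpec(n_surrogates=20, min_shift=500, seed=0)
        out = comodulogram(phases, amps, grid, spec)
        assert out.shape == (16, 16)

    def test_missing_band_rejected(self, grid, fast_spec, rng):
        phases = rng.uniform(-np.pi, np.pi, (15, 4000))
        amps = rng.standard_normal((16, 4000))
        with pytest.raises(ValueError, match="phase-band"):
            comodulogram(phases, amps, grid, fast_spec)

    def test_null_segment_no_extreme_cells(self, grid, rng):
        """White-noise segment: no |z| beyond 5 across the 256 cells."""
        from pacsoz.bands import channel_analytic

        x = rng.standard_normal(int(20 * FS))
        phases, amps = channel_analytic(x, grid, FS)
        spec = SurrogateSpec(n_surrogates=100, min_shift=2000, seed=8)
        out = comodulogram(phases, amps, grid, spec)
        assert np.abs(out).max() < 5.0

    def test_injected_coupling_recovered_at_correct_cell(self, grid):
        """Coupling at (3 Hz, 120 Hz): mean-comodulogram argmax in the right cell."""
        from pacsoz.bands import channel_analytic

        cfg = SynthConfig(duration=100.0, kappa=0.8, snr_sd=1.0, seed=5)
        x = generate_coupled_signal(cfg, "SOZ")
        phases, amps = channel_analytic(x, grid, FS)
        ph_s = segment(phases, FS).segments
        am_s = segment(amps, FS).segments
        spec = SurrogateSpec(n_surrogates=50, min_shift=2000, seed=6)
        mean_com = np.mean(
            [
                comodulogram(ph_s[:, s, :], am_s[:, s, :], grid, spec, key=(0, s))
                for s in range(5)
            ],
            axis=0,
        )
        a, p = np.unravel_index(np.argmax(mean_com), mean_com.shape)
        assert grid.amp_bands[a] == (110.0, 140.0)
        assert grid.phase_bands[p] in ((2.0, 3.0), (3.0, 4.0))


class TestComputeComodulograms:
    def test_tensor_shape_labels_and_determinism(self, grid):
        cfg = SynthConfig(duration=60.0, n_soz=1, n_nsoz=1, kappa=0.8, seed=3)
        rec = generate_recording(cfg)
        spec = SurrogateSpec(n_surrogates=20, min_shift=2000, seed=1)
        t1 = compute_comodulograms(rec, spec)
        assert t1.values.shape == (2, 3, 16, 16)
        assert t1.labels == ["SOZ", "NSOZ"]
        t2 = compute_comodulograms(rec, spec)
        np.testing.assert_array_equal(t1.values, t2.values)

    def test_roundtrip_io(self, tmp_path, grid):
        from pacsoz.pac import load_tensor, save_tensor

        cfg = SynthConfig(duration=40.0, n_soz=1, n_nsoz=1, seed=2)
        rec = generate_recording(cfg)
        spec = SurrogateSpec(n_surrogates=10, min_shift=1000, seed=0)
        t = compute_comodulograms(rec, spec)
        save_tensor(t, tmp_path / "t.npz", tmp_path / "t.csv")
        back = load_tensor(tmp_path / "t.npz", tmp_path / "t.csv")
        np.testing.assert_array_equal(back.values, t.values)
        assert back.labels == t.labels
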