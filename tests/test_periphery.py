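"""Periphery: audiogram fitting, Greenwood map, MOCR, rates, Poisson neurograms."""

import numpy as np
import pytest

from dinmodel import periphery as pp
from dinmodel import stimuli as st


@pytest.fixture(scope="module")
def grid():
    return pp.make_cf_grid(32)


@pytest.fixture(scope="module")
def states(grid):
    return {s.state_id: s for s in pp.table1_states(grid)}


def _silence(duration_s=0.7, sr=16_000):
    return st.NoisyStimulus(samples=np.zeros(int(duration_s * sr)),
                            sample_rate=sr, digit=0, talker_id=0,
                            speech_level_db_spl=70.0, noise_level_db_spl=0.0)


def _tone(freq, level_db, duration_s=0.7, sr=16_000):
    t = np.arange(int(duration_s * sr)) / sr
    samples = st.set_level(np.sin(2 * np.pi * freq * t), level_db)
    return st.NoisyStimulus(samples=samples, sample_rate=sr, digit=0,
                            talker_id=0, speech_level_db_spl=level_db,
                            noise_level_db_spl=0.0)


class TestCFGrid:
    def test_standard_grid_endpoints_and_spacing(self):
        g = pp.make_cf_grid(128)
        assert len(g) == 128
        assert g.cfs[0] == pytest.approx(100.0)
        assert g.cfs[-1] == pytest.approx(8000.0)
        ratios = g.cfs[1:] / g.cfs[:-1]
        assert np.allclose(ratios, ratios[0])  # log spacing
        assert np.all(np.diff(g.cfs) > 0)


class TestGreenwood:
    def test_apex_and_base_frequencies(self):
        assert pp.greenwood_map(0.0) == pytest.approx(165.4 * (1 - 0.88), rel=1e-9)
        assert pp.greenwood_map(1.0) == pytest.approx(
            165.4 * (10**2.1 - 0.88), rel=1e-9)

    def test_round_trip(self):
        x = np.random.default_rng(1).uniform(0, 1, 100)
        back = pp.greenwood_inverse(pp.greenwood_map(x))
        assert np.allclose(back, x, atol=1e-9)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            pp.greenwood_map(1.5)


class TestAudiogramFit:
    def test_normal_hearing_full_health(self, grid):
        cohc, cihc = pp.fit_audiogram(pp.nh_profile(), grid)
        assert np.all(cohc == 1.0) and np.all(cihc == 1.0)

    def test_flat_loss_attribution_ratio(self, grid):
        """30 dB flat loss splits into 20 dB OHC- and 10 dB IHC-attributed
        shifts at every CF (2/3 vs 1/3)."""
        cohc, cihc = pp.fit_audiogram(pp.flat_loss_profile(30.0), grid)
        assert np.allclose(cohc, 1.0 - 20.0 / pp.MAX_COMPONENT_LOSS_DB)
        assert np.allclose(cihc, 1.0 - 10.0 / pp.MAX_COMPONENT_LOSS_DB)

    def test_health_monotone_in_threshold_shift(self, grid):
        prev = (np.ones(len(grid)), np.ones(len(grid)))
        for shift in range(0, 121, 10):
            profile = pp.AudiometricProfile(np.full(7, float(shift)),
                                            "flat_loss")
            if shift > pp.MAX_COMPONENT_LOSS_DB * 1.5:
                with pytest.warns(UserWarning):
                    cur = pp.fit_audiogram(profile, grid)
            else:
                cur = pp.fit_audiogram(profile, grid)
            assert np.all(cur[0] <= prev[0] + 1e-12)
            assert np.all(cur[1] <= prev[1] + 1e-12)
            assert np.all((cur[0] >= 0) & (cur[0] <= 1))
            prev = cur


class TestTable1States:
    def test_twelve_states_with_expected_censuses(self, states):
        assert len(states) == 12
        censuses = {s.fiber_counts for s in states.values()}
        assert censuses == {(20, 20, 60), (0, 0, 52)}
        kinds = {s.audiogram.kind for s in states.values()}
        assert kinds == {"NH", "flat_loss", "sloping_loss"}
        assert {s.mocr_gain_db for s in states.values()} == {0.0, 20.0}

    def test_nh_states_have_full_hair_cell_health(self, states):
        s = states["NH_mocr20_anf[20,20,60]"]
        assert np.all(s.cohc == 1.0) and np.all(s.cihc == 1.0)

    def test_mocr_gain_zero_disables_reflex(self, states):
        assert states["NH_mocr0_anf[20,20,60]"].mocr_max == 0.0
        assert states["NH_mocr20_anf[20,20,60]"].mocr_max > 0.0


class TestMOCR:
    def test_disabled_reflex_is_identity(self, grid, states):
        drive = np.abs(np.random.default_rng(0).standard_normal((32, 200)))
        out = pp.mocr_effective_cohc(drive, states["NH_mocr0_anf[20,20,60]"], grid)
        assert np.allclose(out, 1.0)

    def test_full_reflex_drives_gain_to_zero_in_band(self, grid, states):
        nh = states["NH_mocr20_anf[20,20,60]"]
        full = pp.CochlearState(state_id="full", audiogram=nh.audiogram,
                                mocr_gain_db=40.0, fiber_counts=(20, 20, 60),
                                cohc=nh.cohc, cihc=nh.cihc, mocr_max=1.0)
        drive = np.full((32, 2000), 0.6)  # sustained loud envelope (~90 dB)
        out = pp.mocr_effective_cohc(drive, full, grid)
        in_band = (grid.cfs >= 1000) & (grid.cfs <= 4000)
        assert np.all(out[in_band, -10:] < 0.05)

    def test_onset_time_constant(self, grid, states):
        """A step-onset drive relaxes exponentially with the configured
        onset time constant (fit on the log residual)."""
        config = pp.PeripheryConfig()
        nh = states["NH_mocr20_anf[20,20,60]"]
        drive = np.zeros((32, 1000))
        drive[:, 200:] = 0.4
        out = pp.mocr_effective_cohc(drive, nh, grid, config)
        row = np.flatnonzero((grid.cfs >= 1000) & (grid.cfs <= 4000))[0]
        trace = out[row, 200:800]
        resid = trace - trace[-1]
        resid = resid[resid > 1e-6 * abs(trace[0] - trace[-1])]
        t = np.arange(len(resid)) / config.control_rate_hz
        slope = np.polyfit(t, np.log(resid), 1)[0]
        assert -1.0 / slope == pytest.approx(config.mocr_tau_onset_s, rel=0.15)

    def test_anti_masking_contract(self, grid, states):
        """Reflex on vs off under loud noise: effective cohc strictly lower
        in-band, bit-identical out of band."""
        tok = st.synthesize_digit(7, st.make_talkers(1, seed=3)[0])
        noisy = st.mix_with_noise(tok, 80.0, seed=9)
        config = pp.PeripheryConfig()
        on = states["NH_mocr20_anf[20,20,60]"]
        off = states["NH_mocr0_anf[20,20,60]"]
        env = pp._to_control_rate(
            pp._band_envelopes(noisy.samples, 16_000, grid, on.cohc, config),
            16_000, config.control_rate_hz)
        c_on = pp.mocr_effective_cohc(env, on, grid, config)
        c_off = pp.mocr_effective_cohc(env, off, grid, config)
        in_band = (grid.cfs >= 1000) & (grid.cfs <= 4000)
        assert np.all(c_on[in_band, 100:] < c_off[in_band, 100:])
        assert np.array_equal(c_on[~in_band], c_off[~in_band])

    def test_negative_drive_rejected(self, grid, states):
        with pytest.raises(ValueError):
            pp.mocr_effective_cohc(np.full((32, 10), -1.0),
                                   states["NH_mocr20_anf[20,20,60]"], grid)


class TestFiberRates:
    def test_silence_returns_spontaneous_rates(self, grid, states):
        rates = pp.simulate_fiber_rates(_silence(), states["NH_mocr0_anf[20,20,60]"],
                                        grid)
        config = pp.PeripheryConfig()
        for c in range(3):
            assert rates[c].mean() == pytest.approx(config.spont_rates[c],
                                                    rel=0.01)

    @pytest.mark.parametrize("k", [4, 10, 16, 22, 28])
    def test_pure_tone_tuning(self, k, grid, states):
        rates = pp.simulate_fiber_rates(_tone(grid.cfs[k], 55.0),
                                        states["NH_mocr0_anf[20,20,60]"], grid)
        assert int(np.argmax(rates[2].mean(axis=1))) == k

    def test_rate_level_function_monotone(self, grid, states):
        means = []
        for level in range(0, 101, 5):
            rates = pp.simulate_fiber_rates(
                _tone(grid.cfs[16], float(level), duration_s=0.2),
                states["NH_mocr0_anf[20,20,60]"], grid)
            means.append(rates[2][16].mean())
        assert np.all(np.diff(means) >= -1e-9)
        assert np.all(np.asarray(means) <= pp.PeripheryConfig().saturation_rate)

    def test_undersampled_input_rejected(self, states):
        wide = pp.make_cf_grid(8, 100, 10_000)
        deep = pp.table1_states(wide)[0]
        with pytest.raises(ValueError):
            pp.simulate_fiber_rates(_silence(sr=16_000), deep, wide)


class TestNeurogram:
    def test_no_fibers_gives_empty_neurogram(self, grid, states):
        nh = states["NH_mocr0_anf[20,20,60]"]
        none = pp.CochlearState(state_id="none", audiogram=nh.audiogram,
                                mocr_gain_db=0.0, fiber_counts=(0, 0, 0),
                                cohc=nh.cohc, cihc=nh.cihc, mocr_max=0.0)
        ng = pp.generate_neurogram(_silence(), none, grid, seed=0)
        assert not np.any(ng.values)

    def test_deterministic_given_seed(self, grid, states):
        tok = st.synthesize_digit(3, st.make_talkers(1, seed=0)[0])
        mix = st.mix_with_noise(tok, 60.0, seed=4)
        a = pp.generate_neurogram(mix, states["NH_mocr0_anf[20,20,60]"], grid, seed=9)
        b = pp.generate_neurogram(mix, states["NH_mocr0_anf[20,20,60]"], grid, seed=9)
        assert np.array_equal(a.values, b.values)

    def test_silent_frame_poisson_mean_oracle(self, states):
        """Empirical mean count in silent frames over 200 seeds within 3 SE
        of the analytic Poisson mean (sum of class count x spont x frame)."""
        small = pp.make_cf_grid(8)
        state = pp.table1_states(small)[2]  # NH mocr0 healthy census
        sil = _silence(duration_s=0.2)
        lam = pp.expected_silent_frame_count(state)
        counts = [pp.generate_neurogram(sil, state, small, seed=s).values.mean()
                  for s in range(200)]
        n_cells = 8 * 20
        se = np.sqrt(lam / (200 * n_cells))
        assert abs(np.mean(counts) - lam) < 3 * se

    def test_silent_frame_dispersion_is_poisson(self, states):
        """Index of dispersion (variance/mean) of silent-frame counts over
        500 seeds falls in [0.8, 1.2]."""
        small = pp.make_cf_grid(4)
        state = pp.table1_states(small)[2]
        sil = _silence(duration_s=0.05)
        counts = np.array([pp.generate_neurogram(sil, state, small, seed=s).values
                           for s in range(500)]).ravel()
        assert 0.8 <= counts.var() / counts.mean() <= 1.2

    def test_fiber_loss_lowers_total_spike_count(self, grid, states):
        tok = st.synthesize_digit(7, st.make_talkers(1, seed=1)[0])
        mix = st.mix_with_noise(tok, 65.0, seed=2)
        nh = pp.generate_neurogram(mix, states["NH_mocr0_anf[20,20,60]"],
                                   grid, seed=5)
        deg = pp.generate_neurogram(mix, states["NH_mocr0_anf[0,0,52]"],
                                    grid, seed=5)
        assert deg.values.sum() < nh.values.sum()


class TestFinalize:
    def test_z_score_exactness(self, grid, states):
        tok = st.synthesize_digit(2, st.make_talkers(1, seed=5)[0])
        mix = st.mix_with_noise(tok, 70.0, seed=1)
        raw = pp.generate_neurogram(mix, states["NH_mocr0_anf[20,20,60]"],
                                    grid, seed=3)
        fin = pp.finalize_neurogram(raw, state=states["NH_mocr0_anf[20,20,60]"])
        assert fin.values.shape == (32, 70)
        assert abs(fin.values.mean()) < 1e-6
        assert abs(fin.values.std() - 1.0) < 1e-6
        assert fin.normalized and not fin.degenerate

    def test_long_input_trimmed_from_onset(self, grid):
        rng = np.random.default_rng(0)
        values = rng.poisson(5.0, (32, 90))
        raw = pp.Neurogram(values=values, cf_grid=grid)
        fin = pp.finalize_neurogram(raw)  # no state: onset defaults to 0
        expect = values[:, :70].astype(float)
        expect = (expect - expect.mean()) / expect.std()
        assert np.allclose(fin.values, expect)

    def test_constant_input_flagged_degenerate(self, grid):
        raw = pp.Neurogram(values=np.zeros((32, 40)), cf_grid=grid)
        fin = pp.finalize_neurogram(raw)
        assert fin.degenerate
        assert not np.any(fin.values)
        assert fin.values.shape == (32, 70)
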