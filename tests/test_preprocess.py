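import numpy as np
import pandas as pd
import pytest

from lgdnovelty import paradigm as par
from lgdnovelty import preprocess as pp
from lgdnovelty import synthgen as sg
from lgdnovelty.io import ContinuousRecording


def _rec(data, rate=2000.0):
    data = np.atleast_2d(data)
    return ContinuousRecording(
        data=data, rate_hz=rate, channel_ids=[f"c{i}" for i in range(data.shape[0])]
    )


def _events_regular(n_trials, iti_ms=1500.0, start_ms=1000.0):
    rows = [
        dict(trial_index=i, block=0, sequence=1, onset_ms=start_ms + i * iti_ms,
             base_vowel="a", fifth_vowel="a", habituation=False,
             local_label="LS", global_label="GS")
        for i in range(n_trials)
    ]
    return par.EventTable(pd.DataFrame(rows, columns=par.EVENT_COLUMNS), "A")


class TestResample:
    def test_halving_length(self):
        rec = _rec(np.random.default_rng(0).normal(size=20_000))
        out = pp.resample(rec, 1000.0)
        assert out.n_samples == 10_000 and out.rate_hz == 1000.0

    def test_sinusoid_amplitude_preserved(self):
        t = np.arange(20_000) / 2000.0
        rec = _rec(np.sin(2 * np.pi * 100.0 * t))
        out = pp.resample(rec, 1000.0)
        mid = out.data[0, 1000:-1000]
        assert np.sqrt(2) * mid.std() == pytest.approx(1.0, rel=0.01)

    def test_identity_and_upsample_rejection(self):
        rec = _rec(np.ones(100))
        assert pp.resample(rec, 2000.0) is rec
        with pytest.raises(ValueError, match="[Uu]psampling"):
            pp.resample(rec, 4000.0)


class TestLineNoise:
    def test_pure_60hz_removed(self):
        t = np.arange(20_000) / 2000.0
        rec = _rec(np.sin(2 * np.pi * 60.0 * t))
        out = pp.remove_line_noise(rec, 60.0)
        core = out.data[0, 2000:-2000]
        assert core.std() < 0.1 * rec.data[0].std()

    def test_signal_without_line_noise_untouched(self):
        t = np.arange(20_000) / 2000.0
        x = np.sin(2 * np.pi * 25.0 * t) + 0.5 * np.sin(2 * np.pi * 95.0 * t)
        rec = _rec(x)
        out = pp.remove_line_noise(rec, 60.0)
        core = slice(2000, -2000)
        rms_diff = (out.data[0, core] - x[core]).std()
        assert rms_diff < 0.01 * x[core].std()

    def test_zero_in_zero_out(self):
        out = pp.remove_line_noise(_rec(np.zeros(4000)), 60.0)
        assert np.allclose(out.data, 0.0)


class TestArtifactRejection:
    def test_planted_artifact_drops_its_trial(self, paradigm_cfg, block_events):
        cfg = sg.GeneratorConfig(n_channels=1, seed=8)
        rec = sg.generate_recording(cfg, block_events, "awake", paradigm_cfg)
        rec2, times = sg.inject_artifacts(rec, rate_per_min=2.0, amplitude_sd_multiple=10.0,
                                          seed=2)
        partition = pp.reject_artifacts(rec2, block_events, 5.0)
        kept, dropped = partition["ch000"]
        onsets = block_events.trials["onset_ms"].to_numpy()
        hit_trials = {
            int(block_events.trials["trial_index"].iloc[k])
            for t_ms, _ in times
            for k in np.flatnonzero((onsets - 100 <= t_ms) & (t_ms < onsets + 1400))
        }
        assert hit_trials, "fixture should plant at least one artifact inside a trial"
        assert hit_trials <= set(dropped)

    def test_infinite_threshold_drops_nothing(self, block_events):
        rng = np.random.default_rng(3)
        rec = _rec(rng.normal(size=1_400_000), rate=1000.0)
        part = pp.reject_artifacts(rec, block_events, np.inf)
        kept, dropped = part["c0"]
        assert dropped.size == 0 and kept.size == len(block_events)

    def test_gaussian_drop_fraction_matches_theory(self):
        """P(trial dropped) = 1 - (1 - 2*Phi(-thr))^m for white noise epochs."""
        from scipy.stats import norm

        rng = np.random.default_rng(7)
        n_trials, thr = 400, 3.5
        events = _events_regular(n_trials)
        n = int(events.trials["onset_ms"].iloc[-1] + 3000)
        rec = _rec(rng.normal(size=n), rate=1000.0)
        kept, dropped = pp.reject_artifacts(rec, events, thr)["c0"]
        m = 1500  # samples per epoch window at 1000 Hz
        p_expected = 1.0 - (1.0 - 2 * norm.sf(thr)) ** m
        frac = dropped.size / n_trials
        assert frac == pytest.approx(p_expected, abs=0.1)

    def test_idempotent(self, block_events):
        rng = np.random.default_rng(5)
        rec = _rec(rng.standard_t(df=3, size=1_400_000), rate=1000.0)
        first = pp.reject_artifacts(rec, block_events, 5.0)
        kept, dropped = first["c0"]
        again = pp.reject_artifacts(rec, block_events, 5.0)
        assert np.array_equal(again["c0"][0], kept)
        assert np.array_equal(again["c0"][1], dropped)

    def test_empty_recording_rejected(self, block_events):
        rec = ContinuousRecording(data=np.empty((1, 0)), rate_hz=1000.0, channel_ids=["c0"])
        with pytest.raises(ValueError, match="empty"):
            pp.reject_artifacts(rec, block_events, 5.0)


class TestEpoching:
    def test_window_sample_count_and_reference_shift(self):
        events = _events_regular(10)
        rec = _rec(np.arange(20_000, dtype=float), rate=1000.0)
        ep = pp.epoch(rec, events, "c0", (0.0, 800.0), "trial-onset")
        assert ep.data.shape == (10, 800)
        ep5 = pp.epoch(rec, events, "c0", (0.0, 800.0), "fifth-vowel-onset")
        # the ramp recording makes the 600-ms shift directly visible
        assert np.allclose(ep5.data - ep.data, 600.0)

    def test_constant_signal_constant_epochs(self):
        events = _events_regular(5)
        rec = _rec(np.full(12_000, 3.25), rate=1000.0)
        ep = pp.epoch(rec, events, "c0", (-100.0, 800.0), "trial-onset")
        assert np.all(ep.data == 3.25)

    def test_out_of_bounds_trials_dropped(self):
        events = _events_regular(10)
        rec = _rec(np.zeros(8000), rate=1000.0)  # too short for later trials
        ep = pp.epoch(rec, events, "c0", (0.0, 800.0), "trial-onset")
        assert ep.n_trials + ep.dropped.size == 10 and ep.dropped.size > 0

    def test_epoch_average_reproduces_noiseless_kernel(self):
        """Averaging epochs of a noise-free evoked recording returns the kernel.

        Onsets are sample-aligned (zero ITI jitter) so the reproduction is
        exact; jittered onsets shift trials by up to one sample.
        """
        pcfg = par.ParadigmConfig(iti_sd_ms=0.0)
        events = par.build_session(pcfg, "A", n_blocks=1, rng_seed=0)
        kern = sg.EvokedKernel(amplitude_uv=10.0)
        cfg = sg.GeneratorConfig(
            n_channels=1, noise_1f_scale=0.0, line_noise_amp_60hz=0.0,
            hg_background_rms=0.0, hg_burst_amp=0.0, evoked_kernel=kern, seed=0,
        )
        rec = sg.generate_recording(cfg, events, "awake", pcfg)
        ep = pp.epoch(rec, events, "ch000", (0.0, 100.0), "trial-onset", pcfg)
        expected = kern.sample(2000.0)[:200]
        assert np.allclose(ep.data.mean(axis=0), expected, atol=1e-6)


class TestBaselineAndSmoothing:
    def test_baseline_mean_exactly_zero(self):
        rng = np.random.default_rng(1)
        events = _events_regular(8)
        rec = _rec(rng.normal(size=16_000) + 5.0, rate=1000.0)
        ep = pp.epoch(rec, events, "c0", (-100.0, 800.0), "trial-onset")
        out = pp.baseline_correct(ep, (-100.0, 0.0))
        base = out.data[:, out.time_ms < 0]
        assert np.allclose(base.mean(axis=1), 0.0, atol=1e-12)

    def test_baseline_of_constant_and_ramp(self):
        events = _events_regular(2)
        rec = _rec(np.full(6000, 7.0), rate=1000.0)
        ep = pp.epoch(rec, events, "c0", (-100.0, 100.0), "trial-onset")
        assert np.allclose(pp.baseline_correct(ep, (-100.0, 0.0)).data, 0.0)
        rec = _rec(np.arange(6000, dtype=float), rate=1000.0)
        ep = pp.epoch(rec, events, "c0", (-100.0, 100.0), "trial-onset")
        out = pp.baseline_correct(ep, (-100.0, 0.0))
        assert np.allclose(out.data, ep.data - ep.data[:, ep.time_ms < 0].mean(axis=1,
                                                                               keepdims=True))

    def test_baseline_outside_epoch_rejected(self):
        events = _events_regular(2)
        rec = _rec(np.zeros(6000), rate=1000.0)
        ep = pp.epoch(rec, events, "c0", (0.0, 100.0), "trial-onset")
        with pytest.raises(ValueError, match="baseline"):
            pp.baseline_correct(ep, (-100.0, 0.0))

    def test_smooth_dc_gain_and_frequency_response(self):
        assert np.allclose(pp.smooth(np.full(2000, 4.2), 1000.0), 4.2)
        t = np.arange(4000) / 1000.0
        low = pp.smooth(np.sin(2 * np.pi * 10.0 * t), 1000.0)
        assert np.sqrt(2) * low[500:-500].std() == pytest.approx(1.0, abs=0.05)
        high = pp.smooth(np.sin(2 * np.pi * 100.0 * t), 1000.0)
        assert np.sqrt(2) * high[500:-500].std() < 0.1
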