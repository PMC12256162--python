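"""Synthetic multi-channel iEEG with planted, state-dependent novelty effects.

Every downstream stage of the pipeline is testable without patient data
by simulating recordings that share the coarse statistics of intracranial
local field potentials: a 1/f ("pink") broadband background, 60-Hz line
noise, a damped-sinusoid evoked response to each vowel, a stationary
high-gamma (70-150 Hz) background with vowel-locked envelope bursts,
occasional large-amplitude artifacts, and --- on designated channels ---
additive AEP deflections or multiplicative high-gamma envelope gains on
deviant trials, scaled per arousal state.

The generator is deterministic given its config seed, so pipeline tests
can assert recovery of exactly what was planted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .io import ContinuousRecording
from .paradigm import EventTable, ParadigmConfig, fifth_vowel_onset

EFFECT_KINDS = ("AEP-LD", "HG-LD", "AEP-GD", "HG-GD")

#: "Detectable preset" amplitudes: comfortably above the noise floor for
#: within-block trial counts, used by the recovery validation study.
DETECTABLE_AEP_AMPLITUDE_UV = 30.0
DETECTABLE_HG_GAIN = 3.0

#: Default planted latencies (ms after 5th-vowel onset). GD effects are
#: planted later than LD, mirroring the longer latency of responses to
#: pattern-level (global) novelty.
DEFAULT_LATENCY_MS = {"LD": 150.0, "GD": 450.0}


@dataclass(frozen=True)
class EffectSpec:
    """One planted novelty effect on one channel.

    ``amplitude`` is microvolts for AEP kinds and a multiplicative
    high-gamma envelope gain (>= 1) for HG kinds. ``state_scaling`` maps
    arousal state to a factor in [0, 1] applied to the effect (for HG
    kinds the gain becomes ``1 + (amplitude - 1) * factor``).
    """

    channel_id: str
    effect_kind: str
    amplitude: float
    latency_ms: float | None = None
    duration_ms: float = 150.0
    state_scaling: dict = field(
        default_factory=lambda: {"awake": 1.0, "sedated": 0.5, "unresponsive": 0.0}
    )

    def __post_init__(self) -> None:
        if self.effect_kind not in EFFECT_KINDS:
            raise ValueError(f"unknown effect kind {self.effect_kind!r}")
        if self.duration_ms <= 0:
            raise ValueError("effect duration must be positive")
        lat = self.resolved_latency_ms
        if lat + self.duration_ms > 800.0:
            raise ValueError("effect must end within 800 ms of the 5th-vowel onset")
        if any(not 0.0 <= v <= 1.0 for v in self.state_scaling.values()):
            raise ValueError("state_scaling values must lie in [0, 1]")

    @property
    def resolved_latency_ms(self) -> float:
        if self.latency_ms is not None:
            return self.latency_ms
        return DEFAULT_LATENCY_MS[self.effect_kind.split("-")[1]]

    @classmethod
    def detectable(cls, channel_id: str, effect_kind: str, **kwargs) -> "EffectSpec":
        amp = DETECTABLE_AEP_AMPLITUDE_UV if effect_kind.startswith("AEP") else DETECTABLE_HG_GAIN
        return cls(channel_id=channel_id, effect_kind=effect_kind, amplitude=amp, **kwargs)


@dataclass(frozen=True)
class EvokedKernel:
    """Damped sinusoid summed at each vowel onset: minimal AEP-like morphology."""

    amplitude_uv: float = 12.0
    freq_hz: float = 6.0
    decay_ms: float = 60.0
    duration_ms: float = 300.0

    def sample(self, rate_hz: float) -> np.ndarray:
        t = np.arange(int(round(self.duration_ms * rate_hz / 1000.0))) / rate_hz
        return self.amplitude_uv * np.exp(-t / (self.decay_ms / 1000.0)) * np.sin(
            2 * np.pi * self.freq_hz * t
        )


@dataclass(frozen=True)
class GeneratorConfig:
    """Study-condition defaults for the synthetic recordings.

    Sampling at 2000 Hz (acquisition-system rate); pink-noise background
    of ~20 uV RMS; 5-uV 60-Hz line component; a stationary 5-uV high-gamma
    background on every channel (comparable to the ~6.6-uV in-band share
    of the pink noise, so multiplicative envelope gains translate into
    several-dB ERBP contrasts), plus vowel-locked high-gamma bursts on
    envelope-following channels.
    """

    n_channels: int = 4
    rate_hz: float = 2000.0
    noise_1f_scale: float = 20.0
    line_noise_amp_60hz: float = 5.0
    evoked_kernel: EvokedKernel = EvokedKernel()
    hg_background_rms: float = 5.0
    hg_burst_amp: float = 3.0
    hg_burst_band: tuple[float, float] = (70.0, 150.0)
    envelope_following_channels: tuple[str, ...] | None = None  # None = all
    spindle_amp: float = 0.0  # ~12-Hz narrowband component (sleep sanity check)
    spindle_freq_hz: float = 12.0
    artifact_rate_per_min: float = 0.0
    artifact_amplitude_sd_multiple: float = 8.0
    effects: tuple[EffectSpec, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rate_hz < 2 * self.hg_burst_band[1]:
            raise ValueError("sampling rate must be at least twice the high-gamma upper edge")
        if self.artifact_rate_per_min > 0 and self.artifact_amplitude_sd_multiple <= 5:
            raise ValueError("artifact amplitude must exceed 5 within-block SDs")

    def channel_ids(self) -> list[str]:
        return [f"ch{i:03d}" for i in range(self.n_channels)]


def _pink_noise(n: int, rate_hz: float, rms: float, rng: np.random.Generator) -> np.ndarray:
    """1/f-power noise by spectral shaping of white noise (exponent 1)."""
    if rms == 0:
        return np.zeros(n)
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, d=1.0 / rate_hz)
    f[0] = f[1] if n > 1 else 1.0
    spec /= np.sqrt(np.maximum(f, 1.0))  # flat below 1 Hz to avoid DC blowup
    x = np.fft.irfft(spec, n=n)
    sd = x.std()
    return x * (rms / sd) if sd > 0 else x


def _band_noise(
    n: int, rate_hz: float, band: tuple[float, float], rms: float, rng: np.random.Generator
) -> np.ndarray:
    """Band-limited Gaussian noise with unit-free RMS scaling."""
    if rms == 0:
        return np.zeros(n)
    white = rng.standard_normal(n)
    sos = sps.butter(4, band, btype="bandpass", fs=rate_hz, output="sos")
    x = sps.sosfiltfilt(sos, white)
    sd = x.std()
    return x * (rms / sd) if sd > 0 else x


def _effect_profile(n: int, rate_hz: float) -> np.ndarray:
    """Flat-topped (Tukey, 10% taper) unit window: mean ~ amplitude over the window."""
    return sps.windows.tukey(n, alpha=0.1)


def _deviant_mask(events: EventTable, effect_kind: str) -> np.ndarray:
    trials = events.trials
    if effect_kind.endswith("LD"):
        return (trials["local_label"] == "LD").to_numpy()
    return ((trials["global_label"] == "GD") & (~trials["habituation"])).to_numpy()


def generate_recording(
    cfg: GeneratorConfig,
    events: EventTable,
    state: str = "awake",
    paradigm: ParadigmConfig | None = None,
) -> ContinuousRecording:
    """Synthesize a continuous recording realizing ``events`` in ``state``.

    Deterministic given ``cfg.seed``: channels are synthesized from
    independent child streams of one seed sequence.
    """
    paradigm = paradigm or ParadigmConfig()
    channel_ids = cfg.channel_ids()
    for eff in cfg.effects:
        if eff.channel_id not in channel_ids:
            raise ValueError(f"effect channel {eff.channel_id!r} not in recording")

    rate = cfg.rate_hz
    onsets_ms = events.trials["onset_ms"].to_numpy()
    if np.isnan(onsets_ms).any():
        raise ValueError("event table has no onsets; run assign_onsets first")
    n = int(round((onsets_ms[-1] + 2000.0) * rate / 1000.0))
    v5 = fifth_vowel_onset(paradigm)

    vowel_offsets = np.arange(paradigm.n_vowels_per_trial) * (
        paradigm.vowel_duration_ms + paradigm.inter_vowel_gap_ms
    )
    kernel = cfg.evoked_kernel.sample(rate)
    burst_len = int(round(paradigm.vowel_duration_ms * rate / 1000.0))
    burst_win = np.hanning(burst_len) if burst_len else np.empty(0)

    env_following = (
        set(channel_ids) if cfg.envelope_following_channels is None
        else set(cfg.envelope_following_channels)
    )
    effects_by_channel: dict[str, list[EffectSpec]] = {}
    for eff in cfg.effects:
        effects_by_channel.setdefault(eff.channel_id, []).append(eff)

    root = np.random.SeedSequence(cfg.seed)
    data = np.empty((cfg.n_channels, n), dtype=np.float32)
    for ci, (ch, ss) in enumerate(zip(channel_ids, root.spawn(cfg.n_channels))):
        rng = np.random.default_rng(ss)
        x = _pink_noise(n, rate, cfg.noise_1f_scale, rng)
        if cfg.line_noise_amp_60hz:
            phase = rng.uniform(0, 2 * np.pi)
            x += cfg.line_noise_amp_60hz * np.sin(
                2 * np.pi * 60.0 * np.arange(n) / rate + phase
            )
        if cfg.spindle_amp:
            x += _band_noise(
                n, rate, (cfg.spindle_freq_hz - 2, cfg.spindle_freq_hz + 2), cfg.spindle_amp, rng
            )

        # Evoked kernel at every vowel onset of every trial.
        if cfg.evoked_kernel.amplitude_uv and kernel.size:
            for onset in onsets_ms:
                for off in vowel_offsets:
                    i0 = int(round((onset + off) * rate / 1000.0))
                    seg = kernel[: max(0, min(kernel.size, n - i0))]
                    x[i0 : i0 + seg.size] += seg

        # High-gamma component: stationary background (all channels), plus
        # vowel-locked bursts on envelope-following channels, with
        # deviant-trial envelope gains applied multiplicatively.
        hg = _band_noise(n, rate, cfg.hg_burst_band, cfg.hg_background_rms, rng)
        if ch in env_following and cfg.hg_burst_amp and burst_len:
            burst_env = np.zeros(n)
            for onset in onsets_ms:
                for off in vowel_offsets:
                    i0 = int(round((onset + off) * rate / 1000.0))
                    seg = burst_win[: max(0, min(burst_len, n - i0))]
                    burst_env[i0 : i0 + seg.size] += seg
            hg_extra = _band_noise(n, rate, cfg.hg_burst_band, cfg.hg_burst_amp, rng)
            hg = hg + hg_extra * burst_env

        gain = np.ones(n)
        for eff in effects_by_channel.get(ch, ()):
            scale = float(eff.state_scaling.get(state, 0.0))
            mask = _deviant_mask(events, eff.effect_kind)
            m = int(round(eff.duration_ms * rate / 1000.0))
            profile = _effect_profile(m, rate)
            for onset in onsets_ms[mask]:
                i0 = int(round((onset + v5 + eff.resolved_latency_ms) * rate / 1000.0))
                seg = profile[: max(0, min(m, n - i0))]
                if eff.effect_kind.startswith("AEP"):
                    x[i0 : i0 + seg.size] += eff.amplitude * scale * seg
                else:
                    gain[i0 : i0 + seg.size] *= 1.0 + (eff.amplitude - 1.0) * scale * seg
        x += hg * gain
        data[ci] = x

    rec = ContinuousRecording(
        data=data,
        rate_hz=rate,
        channel_ids=channel_ids,
        roi={ch: "synthetic" for ch in channel_ids},
        state=state,
        meta={"seed": cfg.seed, "n_trials": len(events)},
    )
    if cfg.artifact_rate_per_min > 0:
        rec, times = inject_artifacts(
            rec,
            cfg.artifact_rate_per_min,
            cfg.artifact_amplitude_sd_multiple,
            seed=int(root.generate_state(1)[0] % (2**31)),
        )
        rec.meta["artifact_times_ms"] = [t for t, _ in times]
        rec.meta["artifact_channels"] = [c for _, c in times]
    return rec


def inject_artifacts(
    recording: ContinuousRecording,
    rate_per_min: float,
    amplitude_sd_multiple: float,
    seed: int = 0,
    width_ms: float = 20.0,
) -> tuple[ContinuousRecording, list[tuple[float, str]]]:
    """Add brief large-amplitude transients at Poisson times.

    Each artifact is a Hann pulse (``width_ms`` <= 50 ms) on one randomly
    chosen channel, with peak ``amplitude_sd_multiple`` times that
    channel's pre-injection SD and random sign. Returns the modified
    recording and the ground-truth (time_ms, channel_id) list.
    """
    if amplitude_sd_multiple <= 5:
        raise ValueError("amplitude_sd_multiple must exceed 5")
    if width_ms > 50:
        raise ValueError("artifacts must be brief (<= 50 ms)")
    if rate_per_min <= 0:
        return recording, []
    rng = np.random.default_rng(seed)
    out = ContinuousRecording(
        data=recording.data.copy(),
        rate_hz=recording.rate_hz,
        channel_ids=list(recording.channel_ids),
        roi=dict(recording.roi),
        state=recording.state,
        units=recording.units,
        meta=dict(recording.meta),
    )
    minutes = recording.duration_s / 60.0
    n_art = rng.poisson(rate_per_min * minutes)
    m = int(round(width_ms * recording.rate_hz / 1000.0))
    pulse = np.hanning(m)
    times: list[tuple[float, str]] = []
    sds = recording.data.std(axis=1)
    for _ in range(n_art):
        t_ms = float(rng.uniform(0, recording.duration_s * 1000.0 - width_ms))
        ci = int(rng.integers(recording.n_channels))
        sign = 1.0 if rng.random() < 0.5 else -1.0
        i0 = int(round(t_ms * recording.rate_hz / 1000.0))
        seg = pulse[: min(m, out.n_samples - i0)]
        out.data[ci, i0 : i0 + seg.size] += (
            sign * amplitude_sd_multiple * sds[ci] * seg
        ).astype(out.data.dtype)
        times.append((t_ms, recording.channel_ids[ci]))
    times.sort()
    return out, times
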