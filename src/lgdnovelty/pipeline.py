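"""End-to-end wiring: recording + events -> per-site effect calls.

One function, :func:`analyze_recording`, runs the full chain for every
channel of a continuous recording: downsample to 1000 Hz, notch the line
frequency, mark artifact trials from whole-block statistics, build AEP
epochs (baseline-corrected, 30-Hz smoothed) and high-gamma ERBP epochs
(bandpass -> Hilbert envelope -> smoothed -> per-sequence normalized),
assemble the LD and GD contrasts, and call site effects with the
cluster-based permutation test, FDR-corrected per analysis family.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import preprocess as pp
from .clusterstats import AEP_TEST, HG_TEST, ClusterTestConfig
from .effects import ContrastSpec, SiteEffectTable, call_site_effects
from .io import ContinuousRecording
from .paradigm import EventTable, ParadigmConfig, fifth_vowel_onset
from .spectral import ERBPConfig, erbp_continuous

#: Epoch cut relative to trial onset covering baseline through the post-5th-vowel
#: analysis window: [-100, 600 + 800) ms.
EPOCH_WINDOW_MS = (-100.0, 1400.0)


@dataclass(frozen=True)
class AnalysisConfig:
    paradigm: ParadigmConfig = ParadigmConfig()
    preprocess: pp.PreprocessConfig = pp.PreprocessConfig()
    erbp: ERBPConfig = ERBPConfig()
    aep_test: ClusterTestConfig = AEP_TEST
    hg_test: ClusterTestConfig = HG_TEST
    alpha: float = 0.05
    seed: int = 0


def sequence_extents(
    events: EventTable, rate_hz: float, pad_ms: tuple[float, float] = (500.0, 1400.0)
) -> list[tuple[int, int]]:
    """Half-open sample ranges spanning each experimental sequence."""
    extents = []
    for (_, _), grp in events.trials.groupby(["block", "sequence"], sort=True):
        onsets = grp["onset_ms"].to_numpy()
        i0 = max(0, int(np.floor((onsets[0] - pad_ms[0]) * rate_hz / 1000.0)))
        i1 = int(np.ceil((onsets[-1] + pad_ms[1]) * rate_hz / 1000.0))
        extents.append((i0, i1))
    return extents


def preprocess_recording(
    recording: ContinuousRecording, cfg: AnalysisConfig
) -> ContinuousRecording:
    """Downsample and notch; returns a recording at the analysis rate."""
    rec = pp.resample(recording, cfg.preprocess.target_rate_hz)
    return pp.remove_line_noise(rec, cfg.preprocess.line_noise_hz)


def channel_contrast_epochs(
    recording: ContinuousRecording,
    events: EventTable,
    channel_id: str,
    cfg: AnalysisConfig,
    kept: np.ndarray,
    extents: list[tuple[int, int]],
) -> dict:
    """AEP and ERBP standard/deviant epoch pairs for one channel.

    Keys are ``(channel, effect, signal, state)``; epochs are sliced to
    the post-5th-vowel statistics window.
    """
    state = recording.state
    rate = recording.rate_hz
    v5 = fifth_vowel_onset(cfg.paradigm)
    stats_win = (v5 + cfg.aep_test.window_ms[0], v5 + cfg.aep_test.window_ms[1])

    # AEP chain: epoch, baseline-correct, smooth single trials, cut stats window.
    aep = pp.epoch(recording, events, channel_id, EPOCH_WINDOW_MS, "trial-onset",
                   cfg.paradigm, kept=kept)
    aep = pp.baseline_correct(aep, cfg.preprocess.baseline_window_ms)
    aep.data = pp.smooth(aep.data, rate, cfg.preprocess.smoothing_cutoff_hz,
                         cfg.preprocess.smoothing_order)
    aep = aep.time_slice(*stats_win)

    # ERBP chain on the continuous channel, then epoch the normalized power.
    erbp_sig = erbp_continuous(
        recording.get_channel(channel_id), rate, extents, cfg.erbp,
        smooth_cutoff_hz=cfg.preprocess.smoothing_cutoff_hz,
    )
    erbp_rec = ContinuousRecording(
        data=erbp_sig[None, :], rate_hz=rate, channel_ids=[channel_id],
        state=state, units="dB re sequence mean",
    )
    hg = pp.epoch(erbp_rec, events, channel_id, EPOCH_WINDOW_MS, "trial-onset",
                  cfg.paradigm, kept=kept).time_slice(*stats_win)

    out = {}
    for effect in ("LD", "GD"):
        std_idx, dev_idx = ContrastSpec(effect, "AEP").select_trials(events)
        for signal, epochs in (("AEP", aep), ("HG", hg)):
            std = epochs.select(std_idx)
            dev = epochs.select(dev_idx)
            # Re-zero the time axis to the 5th-vowel onset for reporting.
            for e in (std, dev):
                e.time_ms = e.time_ms - v5
            out[(channel_id, effect, signal, state)] = (std, dev)
    return out


def analyze_recording(
    recording: ContinuousRecording,
    events: EventTable,
    cfg: AnalysisConfig = AnalysisConfig(),
    channels: list[str] | None = None,
) -> SiteEffectTable:
    """Full pipeline for all (or selected) channels of one recording."""
    rec = preprocess_recording(recording, cfg)
    partition = pp.reject_artifacts(
        rec, events, cfg.preprocess.artifact_sd_threshold, window_ms=EPOCH_WINDOW_MS
    )
    extents = sequence_extents(events, rec.rate_hz)
    contrast_epochs = {}
    for ch in channels or rec.channel_ids:
        kept, _ = partition[ch]
        contrast_epochs.update(
            channel_contrast_epochs(rec, events, ch, cfg, kept, extents)
        )
    return call_site_effects(
        contrast_epochs, cfg.aep_test, cfg.hg_test, alpha=cfg.alpha,
        roi_map=rec.roi, seed=cfg.seed,
    )
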