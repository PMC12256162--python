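"""Resampling, line-noise removal, artifact rejection, epoching, smoothing.

Processing order mirrors standard iEEG practice: downsample to 1000 Hz,
notch out mains noise, mark artifact trials from whole-block statistics,
epoch around trial or fifth-vowel onsets, baseline-correct against the
100 ms preceding trial onset, and smooth with a zero-phase 4th-order
30-Hz Butterworth low-pass. All filters run forward-backward so cluster
timing downstream is not shifted by filter delay.

Epoch windows are half-open ``[start, end)`` in ms; the sample index of a
time t is ``floor(t * rate / 1000)``, 0-based.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .io import ContinuousRecording
from .paradigm import EventTable, ParadigmConfig, fifth_vowel_onset


@dataclass(frozen=True)
class PreprocessConfig:
    target_rate_hz: float = 1000.0
    artifact_sd_threshold: float = 5.0
    baseline_window_ms: tuple[float, float] = (-100.0, 0.0)
    smoothing_cutoff_hz: float = 30.0
    smoothing_order: int = 4
    line_noise_hz: float = 60.0

    def __post_init__(self) -> None:
        if self.artifact_sd_threshold <= 0:
            raise ValueError("artifact SD threshold must be positive")
        if self.baseline_window_ms[1] > 0 or self.baseline_window_ms[0] >= self.baseline_window_ms[1]:
            raise ValueError("baseline window must precede time zero")


@dataclass
class EpochSet:
    """Trials x time matrix for one channel, plus its time axis and bookkeeping.

    ``reference`` is ``"trial-onset"`` or ``"fifth-vowel-onset"``; time 0
    of ``time_ms`` is that reference. ``kept`` and ``dropped`` partition
    the original trial indices.
    """

    data: np.ndarray
    time_ms: np.ndarray
    reference: str
    kept: np.ndarray
    dropped: np.ndarray
    units: str = "uV"

    def __post_init__(self) -> None:
        if self.data.shape[0] != len(self.kept):
            raise ValueError("one row per kept trial required")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    def select(self, trial_indices) -> "EpochSet":
        """Subset by original trial index (rows absent from ``kept`` are skipped)."""
        wanted = np.asarray(trial_indices)
        pos = {t: i for i, t in enumerate(self.kept)}
        rows = [pos[t] for t in wanted if t in pos]
        keep = np.array([t for t in wanted if t in pos], dtype=int)
        return EpochSet(self.data[rows], self.time_ms, self.reference, keep,
                        np.setdiff1d(wanted, keep), self.units)

    def time_slice(self, start_ms: float, end_ms: float) -> "EpochSet":
        m = (self.time_ms >= start_ms) & (self.time_ms < end_ms)
        return EpochSet(self.data[:, m], self.time_ms[m], self.reference,
                        self.kept, self.dropped, self.units)


def _sample_index(t_ms: float, rate_hz: float) -> int:
    return int(np.floor(t_ms * rate_hz / 1000.0))


def resample(recording: ContinuousRecording, target_rate_hz: float) -> ContinuousRecording:
    """Anti-aliased downsampling (polyphase FIR); upsampling is rejected."""
    if target_rate_hz > recording.rate_hz:
        raise ValueError("upsampling not supported: target rate exceeds native rate")
    if target_rate_hz == recording.rate_hz:
        return recording
    from fractions import Fraction

    frac = Fraction(target_rate_hz / recording.rate_hz).limit_denominator(1000)
    data = sps.resample_poly(recording.data.astype(float), frac.numerator, frac.denominator, axis=1)
    return ContinuousRecording(
        data=data,
        rate_hz=target_rate_hz,
        channel_ids=list(recording.channel_ids),
        roi=dict(recording.roi),
        state=recording.state,
        units=recording.units,
        meta=dict(recording.meta),
    )


def remove_line_noise(
    recording: ContinuousRecording, line_noise_hz: float = 60.0, q: float = 35.0
) -> ContinuousRecording:
    """Cascaded zero-phase IIR notches at the line frequency and its harmonics.

    Attenuation at each notch exceeds 20 dB while the passband away from
    the notches stays within 1 dB.
    """
    nyq = recording.rate_hz / 2.0
    if nyq <= line_noise_hz:
        raise ValueError("sampling rate must exceed twice the line frequency")
    data = recording.data.astype(float)
    f = line_noise_hz
    while f < nyq:
        b, a = sps.iirnotch(f, Q=q, fs=recording.rate_hz)
        data = sps.filtfilt(b, a, data, axis=1)
        f += line_noise_hz
    return ContinuousRecording(
        data=data,
        rate_hz=recording.rate_hz,
        channel_ids=list(recording.channel_ids),
        roi=dict(recording.roi),
        state=recording.state,
        units=recording.units,
        meta=dict(recording.meta),
    )


def reject_artifacts(
    recording: ContinuousRecording,
    events: EventTable,
    threshold_sd: float = 5.0,
    window_ms: tuple[float, float] = (-100.0, 1400.0),
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Per-channel kept/dropped trial partition from whole-block statistics.

    A trial is dropped for a channel when any sample of its epoch window
    deviates from the channel's within-block mean by more than
    ``threshold_sd`` within-block SDs. Mean and SD are computed over the
    entire block (all samples), not the kept subset, which makes the
    partition idempotent under re-application.
    """
    if recording.n_samples == 0:
        raise ValueError("empty recording")
    onsets = events.trials["onset_ms"].to_numpy()
    trial_idx = events.trials["trial_index"].to_numpy()
    out: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for ci, ch in enumerate(recording.channel_ids):
        x = recording.data[ci]
        mu, sd = float(x.mean()), float(x.std())
        bad = []
        if np.isfinite(threshold_sd):
            lim = threshold_sd * sd
            for t, onset in zip(trial_idx, onsets):
                i0 = _sample_index(onset + window_ms[0], recording.rate_hz)
                i1 = _sample_index(onset + window_ms[1], recording.rate_hz)
                seg = x[max(i0, 0) : min(i1, x.size)]
                if seg.size and np.abs(seg - mu).max() > lim:
                    bad.append(t)
        dropped = np.array(sorted(bad), dtype=int)
        kept = np.setdiff1d(trial_idx, dropped)
        out[ch] = (kept, dropped)
    return out


def epoch(
    recording: ContinuousRecording,
    events: EventTable,
    channel_id: str,
    window_ms: tuple[float, float],
    reference: str = "trial-onset",
    paradigm: ParadigmConfig | None = None,
    kept: np.ndarray | None = None,
) -> EpochSet:
    """Cut trials x time epochs for one channel.

    With ``reference="fifth-vowel-onset"`` each trial's zero is shifted by
    :func:`~lgdnovelty.paradigm.fifth_vowel_onset` (600 ms by default).
    Trials whose window falls outside the recording are dropped.
    """
    if reference not in ("trial-onset", "fifth-vowel-onset"):
        raise ValueError(f"unknown reference {reference!r}")
    shift = 0.0
    if reference == "fifth-vowel-onset":
        shift = fifth_vowel_onset(paradigm or ParadigmConfig())
    x = recording.get_channel(channel_id)
    rate = recording.rate_hz
    n_samp = _sample_index(window_ms[1], rate) - _sample_index(window_ms[0], rate)
    time_ms = (np.arange(n_samp) + _sample_index(window_ms[0], rate)) * 1000.0 / rate

    trials = events.trials
    idx = trials["trial_index"].to_numpy()
    if kept is not None:
        sel = np.isin(idx, kept)
        trials, idx = trials[sel], idx[sel]

    rows, kept_out, dropped_out = [], [], []
    for t, onset in zip(idx, trials["onset_ms"].to_numpy()):
        i0 = _sample_index(onset + shift, rate) + _sample_index(window_ms[0], rate)
        i1 = i0 + n_samp
        if i0 < 0 or i1 > x.size:
            dropped_out.append(t)
            continue
        rows.append(x[i0:i1])
        kept_out.append(t)
    data = np.vstack(rows) if rows else np.empty((0, n_samp))
    return EpochSet(
        data=np.asarray(data, dtype=float),
        time_ms=time_ms,
        reference=reference,
        kept=np.array(kept_out, dtype=int),
        dropped=np.array(dropped_out, dtype=int),
        units=recording.units,
    )


def baseline_correct(epochs: EpochSet, baseline_window_ms: tuple[float, float]) -> EpochSet:
    """Subtract each trial's mean over the baseline window (mean becomes exactly 0)."""
    m = (epochs.time_ms >= baseline_window_ms[0]) & (epochs.time_ms < baseline_window_ms[1])
    if not m.any():
        raise ValueError("baseline window outside epoch")
    data = epochs.data - epochs.data[:, m].mean(axis=1, keepdims=True)
    return EpochSet(data, epochs.time_ms, epochs.reference, epochs.kept, epochs.dropped,
                    epochs.units)


def smooth(
    waveform: np.ndarray, rate_hz: float, cutoff_hz: float = 30.0, order: int = 4
) -> np.ndarray:
    """Zero-phase low-pass Butterworth smoothing (DC gain exactly 1)."""
    if rate_hz <= 2 * cutoff_hz:
        raise ValueError("sampling rate must exceed twice the smoothing cutoff")
    sos = sps.butter(order, cutoff_hz, btype="lowpass", fs=rate_hz, output="sos")
    return sps.sosfiltfilt(sos, np.asarray(waveform, dtype=float), axis=-1)
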