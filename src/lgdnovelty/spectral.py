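"""High-gamma event-related band power (ERBP) and band-power summaries.

ERBP follows the classical envelope-power recipe: linear-phase FIR
bandpass (order 300, 70-150 Hz), Hilbert envelope of the continuous
signal (epoching afterwards avoids epoch-edge artifacts of the analytic
signal), squaring to power, 10*log10, and per-sequence subtractive
normalization so each sequence's mean log-power is exactly 0 dB. Units
are therefore "dB re sequence mean", and the result is invariant to any
positive rescaling of the raw signal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

_LOG_FLOOR = 1e-12  # power floor, squared-uV; guards log of isolated zeros


@dataclass(frozen=True)
class ERBPConfig:
    band_hz: tuple[float, float] = (70.0, 150.0)
    fir_order: int = 300
    normalization: str = "log-power"  # or "power": divide power by sequence mean

    def __post_init__(self) -> None:
        if self.fir_order % 2:
            raise ValueError("FIR order must be even for integer group delay")
        if self.normalization not in ("log-power", "power"):
            raise ValueError("normalization must be 'log-power' or 'power'")


def bandpass_fir(
    x: np.ndarray, rate_hz: float, band: tuple[float, float] = (70.0, 150.0), order: int = 300
) -> np.ndarray:
    """Linear-phase windowed-sinc (Hamming) bandpass, group delay compensated.

    The symmetric FIR of even ``order`` (length order+1) has an integer
    group delay of order/2 samples, removed exactly so the output stays
    time-aligned with the input.
    """
    nyq = rate_hz / 2.0
    if not 0 < band[0] < band[1] < nyq:
        raise ValueError("band must lie strictly inside (0, Nyquist)")
    taps = sps.firwin(order + 1, band, pass_zero=False, window="hamming", fs=rate_hz)
    x = np.asarray(x, dtype=float)
    padded = np.concatenate([x, np.zeros(x.shape[:-1] + (order // 2,))], axis=-1)
    y = sps.lfilter(taps, 1.0, padded, axis=-1)
    return y[..., order // 2 :]


def hilbert_envelope(x: np.ndarray) -> np.ndarray:
    """Magnitude of the analytic signal."""
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("signal must be finite")
    return np.abs(sps.hilbert(x, axis=-1))


def erbp_normalize(
    envelope: np.ndarray,
    sequence_extent: tuple[int, int] | None = None,
    normalization: str = "log-power",
) -> np.ndarray:
    """Log-power normalized to the mean over one sequence extent.

    ``sequence_extent`` is a half-open sample range ``(start, stop)``
    within the envelope (default: the whole signal). With the default
    subtractive log-power normalization the output is
    ``10*log10(envelope**2)`` minus its mean over the extent, i.e. dB
    relative to the sequence's geometric-mean power; the mean over the
    extent is exactly 0. With ``normalization="power"`` the power is
    divided by its arithmetic mean over the extent instead, then logged.
    """
    env = np.asarray(envelope, dtype=float)
    i0, i1 = sequence_extent if sequence_extent is not None else (0, env.shape[-1])
    if not 0 <= i0 < i1 <= env.shape[-1]:
        raise ValueError("sequence extent outside signal")
    seg = env[..., i0:i1]
    if not np.any(seg > 0):
        raise ValueError("all-zero envelope over the sequence extent (log of zero)")
    power = np.maximum(env**2, _LOG_FLOOR)
    if normalization == "log-power":
        logp = 10.0 * np.log10(power)
        return logp - logp[..., i0:i1].mean(axis=-1, keepdims=True)
    if normalization == "power":
        return 10.0 * np.log10(power / power[..., i0:i1].mean(axis=-1, keepdims=True))
    raise ValueError("normalization must be 'log-power' or 'power'")


def erbp_continuous(
    x: np.ndarray,
    rate_hz: float,
    sequence_extents: list[tuple[int, int]],
    cfg: ERBPConfig = ERBPConfig(),
    smooth_cutoff_hz: float | None = 30.0,
) -> np.ndarray:
    """Full ERBP chain on one continuous channel.

    Bandpass -> Hilbert envelope -> optional 30-Hz zero-phase smoothing of
    the envelope -> per-sequence normalization. Samples outside every
    extent are normalized against the whole-signal mean.
    """
    from .preprocess import smooth as _smooth

    env = hilbert_envelope(bandpass_fir(x, rate_hz, cfg.band_hz, cfg.fir_order))
    if smooth_cutoff_hz:
        env = np.abs(_smooth(env, rate_hz, smooth_cutoff_hz))
    out = erbp_normalize(env, None, cfg.normalization)
    for ext in sequence_extents:
        seg = erbp_normalize(env, ext, cfg.normalization)
        out[..., ext[0] : ext[1]] = seg[..., ext[0] : ext[1]]
    return out


def band_power_summary(
    x: np.ndarray,
    rate_hz: float,
    bands: dict[str, tuple[float, float]] | None = None,
    nperseg: int = 2048,
) -> dict[str, float]:
    """Mean Welch power per band (e.g. alpha 8-14 Hz, beta 14-30 Hz) for one block."""
    bands = bands or {"alpha": (8.0, 14.0), "beta": (14.0, 30.0)}
    for name, (lo, hi) in bands.items():
        if hi > rate_hz / 2:
            raise ValueError(f"band {name!r} exceeds Nyquist")
    x = np.asarray(x, dtype=float)
    if x.size == 0 or not np.any(x):
        return {name: 0.0 for name in bands}
    f, pxx = sps.welch(x, fs=rate_hz, nperseg=min(nperseg, x.shape[-1]))
    out = {}
    for name, (lo, hi) in bands.items():
        m = (f >= lo) & (f < hi)
        out[name] = float(np.trapezoid(pxx[..., m], f[m], axis=-1)) if m.any() else 0.0
    return out
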