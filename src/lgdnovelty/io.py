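"""On-disk formats: raw float32 signal arrays with JSON sidecars, TSV tables.

The native signal container is a channel-major little-endian 32-bit float
binary file (``<name>.f32``) next to a JSON sidecar (``<name>.json``)
recording the sampling rate, channel ids, per-channel ROI labels, arousal
state, seed, and units. Event tables and summary statistics travel as TSV;
configs and results as JSON/YAML.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np


@dataclass
class ContinuousRecording:
    """Multi-channel continuous voltage recording.

    ``data`` is channels x samples, in microvolts unless ``units`` says
    otherwise. ``roi`` maps channel id to its region-of-interest label.
    """

    data: np.ndarray
    rate_hz: float
    channel_ids: list[str]
    roi: dict[str, str] = field(default_factory=dict)
    state: str = "awake"
    units: str = "uV"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data))
        if self.data.shape[0] != len(self.channel_ids):
            raise ValueError("data rows must match channel_ids")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.rate_hz

    def channel_index(self, channel_id: str) -> int:
        try:
            return self.channel_ids.index(channel_id)
        except ValueError:
            raise KeyError(f"channel {channel_id!r} not in recording") from None

    def get_channel(self, channel_id: str) -> np.ndarray:
        return self.data[self.channel_index(channel_id)]

    def save(self, path) -> None:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        self.data.astype("<f4").tofile(path.with_suffix(".f32"))
        sidecar = {
            "rate_hz": self.rate_hz,
            "channel_ids": self.channel_ids,
            "roi": self.roi,
            "state": self.state,
            "units": self.units,
            "n_samples": int(self.n_samples),
            "dtype": "<f4",
            "order": "channel-major",
            "meta": _jsonable(self.meta),
        }
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))

    @classmethod
    def load(cls, path) -> "ContinuousRecording":
        path = Path(path)
        sidecar = json.loads(path.with_suffix(".json").read_text())
        n_ch = len(sidecar["channel_ids"])
        data = np.fromfile(path.with_suffix(".f32"), dtype="<f4").reshape(n_ch, -1)
        return cls(
            data=data,
            rate_hz=sidecar["rate_hz"],
            channel_ids=sidecar["channel_ids"],
            roi=sidecar.get("roi", {}),
            state=sidecar.get("state", "awake"),
            units=sidecar.get("units", "uV"),
            meta=sidecar.get("meta", {}),
        )


def _jsonable(obj):
    """Coerce numpy scalars/arrays inside nested containers to JSON-safe types."""
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer, np.bool_)):
        return obj.item()
    return obj


def write_json(path, payload: dict) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    Path(path).write_text(json.dumps(_jsonable(payload), indent=1))


def read_json(path) -> dict:
    return json.loads(Path(path).read_text())
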