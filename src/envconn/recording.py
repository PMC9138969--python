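"""In-memory container for multichannel sensor-space EEG."""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np


@dataclass
class SensorRecording:
    """Channels x samples EEG in microvolts with geometry and reference state.

    Attributes
    ----------
    data : (n_channels, n_samples) float array, microvolts.
    rate : sampling rate in Hz.
    labels : unique channel names.
    positions : (n_channels, 3) electrode coordinates in mm (head frame), or
        None when the source format carried no geometry.
    bad_mask : boolean flag per channel.
    reference : "recording-ref" or "average".
    history : processing provenance entries (free-form strings).
    """

    data: np.ndarray
    rate: float
    labels: list[str]
    positions: np.ndarray | None = None
    bad_mask: np.ndarray | None = None
    reference: str = "recording-ref"
    history: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, float)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (channels x samples)")
        n = self.data.shape[0]
        if len(self.labels) != n:
            raise ValueError(f"got {len(self.labels)} labels for {n} channels")
        if len(set(self.labels)) != n:
            raise ValueError("channel labels must be unique")
        if self.positions is not None:
            self.positions = np.asarray(self.positions, float)
            if self.positions.shape != (n, 3):
                raise ValueError("positions must be (n_channels, 3)")
            if not np.all(np.isfinite(self.positions)):
                raise ValueError("positions must be finite")
        if self.bad_mask is None:
            self.bad_mask = np.zeros(n, bool)
        else:
            self.bad_mask = np.asarray(self.bad_mask, bool)
            if self.bad_mask.shape != (n,):
                raise ValueError("bad_mask must have one entry per channel")
        if self.rate <= 0:
            raise ValueError("sampling rate must be positive")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.rate

    def copy_with(self, **changes) -> "SensorRecording":
        changes.setdefault("history", list(self.history))
        return replace(self, **changes)
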