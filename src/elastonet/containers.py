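"""In-memory containers for RF ultrasound frames and sequences."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["RFFrame", "RFSequence"]

# Default acquisition metadata for the synthetic phantoms: a 5 MHz pulse
# sampled at 40 MHz (c = 1540 m/s), 0.3 mm line pitch.
DEFAULT_META = {
    "axial_spacing": 1540.0 / (2 * 40e6) * 1e3,  # mm per sample
    "lateral_spacing": 0.3,                       # mm per line
    "center_frequency": 5.0,                      # MHz
    "sampling_frequency": 40.0,                   # MHz
}


@dataclass
class RFFrame:
    """A single 2D radio-frequency frame (axial samples x scan lines)."""

    samples: np.ndarray
    axial_spacing: float = DEFAULT_META["axial_spacing"]
    lateral_spacing: float = DEFAULT_META["lateral_spacing"]
    center_frequency: float = DEFAULT_META["center_frequency"]
    sampling_frequency: float = DEFAULT_META["sampling_frequency"]
    timestamp: float = 0.0

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=np.float32)
        if self.samples.ndim != 2:
            raise ValueError("RF frame must be 2D (axial x lateral)")
        if not np.isfinite(self.samples).all():
            raise ValueError("RF frame contains non-finite samples")
        if self.axial_spacing <= 0 or self.lateral_spacing <= 0:
            raise ValueError("spacings must be positive")


@dataclass
class RFSequence:
    """A temporal stack of RF frames sharing one acquisition geometry."""

    frames: np.ndarray                      # (T, axial, lateral) float32
    meta: dict = field(default_factory=lambda: dict(DEFAULT_META))
    timestamps: np.ndarray | None = None
    seq_id: str = "seq"

    def __post_init__(self):
        self.frames = np.asarray(self.frames, dtype=np.float32)
        if self.frames.ndim != 3:
            raise ValueError("sequence must be (frames, axial, lateral)")
        if self.timestamps is None:
            self.timestamps = np.arange(len(self.frames), dtype=np.float64)

    def __len__(self) -> int:
        return self.frames.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]

    def frame(self, t: int) -> RFFrame:
        return RFFrame(self.frames[t], timestamp=float(self.timestamps[t]),
                       **{k: self.meta.get(k, v)
                          for k, v in DEFAULT_META.items()})
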