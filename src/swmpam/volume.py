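"""The in-memory container for 3-D photoacoustic data.

A :class:`PAVolume` holds the stack of A-lines acquired (or simulated) over
the lateral raster: ``data[i, j, k]`` is the amplitude at fast-axis index
``i``, slow-axis index ``j`` and time sample ``k``.  Lateral images derived
from a volume follow the ``(row = slow, col = fast)`` convention of
:mod:`swmpam.geometry`.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np


@dataclass
class PAVolume:
    """3-D photoacoustic amplitude volume with sampling metadata."""

    data: np.ndarray
    step_fast_um: float = 4.0
    step_slow_um: float = 6.0
    sample_rate_hz: float = 50e6

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3-D (fast, slow, time) array, got shape {self.data.shape}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("volume contains non-finite values")
        if self.step_fast_um <= 0 or self.step_slow_um <= 0 or self.sample_rate_hz <= 0:
            raise ValueError("step sizes and sample rate must be positive")

    @property
    def n_fast(self) -> int:
        return self.data.shape[0]

    @property
    def n_slow(self) -> int:
        return self.data.shape[1]

    @property
    def n_time(self) -> int:
        return self.data.shape[2]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def lateral_slice(self, k: int) -> np.ndarray:
        """Time-slice ``k`` as a 2-D image, rows = slow axis, cols = fast."""
        return self.data[:, :, k].T

    def with_data(self, data: np.ndarray) -> "PAVolume":
        """A copy of this volume carrying new samples, metadata preserved."""
        return replace(self, data=np.asarray(data))

    def copy(self) -> "PAVolume":
        return self.with_data(self.data.copy())
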