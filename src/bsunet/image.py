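"""Lightweight image container carrying physical pixel spacing."""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["ImageSlice"]


@dataclass
class ImageSlice:
    """A 2-D grayscale slice, float32 in [0, 1], with isotropic pixel
    spacing in millimetres."""
    data: np.ndarray
    spacing_mm: float = 1.5

    def __post_init__(self):
        self.data = np.asarray(self.data, np.float32)
        if self.data.ndim != 2:
            raise ValueError(f"ImageSlice must be 2-D, got {self.data.shape}")
        if self.spacing_mm <= 0:
            raise ValueError("spacing_mm must be positive")

    @property
    def shape(self):
        return self.data.shape
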