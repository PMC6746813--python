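"""Raster2D: the single-channel 2-D image type shared by every stage.

A raster is a real-valued intensity map on a regular pixel grid.  The pixel
coordinate convention used throughout the package is: integer pixel centers,
origin at index (0, 0), X = column index, Y = row index, and all spatial
frequencies expressed in cycles per pixel of the *acquisition* grid.
Reconstructed images live on a finer grid (``pixel_size < 1``) but keep their
coordinates in acquisition-pixel units, so frequencies and distances remain
directly comparable across stages.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import DimensionError

__all__ = ["Raster2D", "as_array"]


@dataclass
class Raster2D:
    """A single-channel 2-D intensity image with pixel-pitch metadata.

    Parameters
    ----------
    data
        Real-valued 2-D array, row = Y, column = X.
    pixel_size
        Pitch of one grid cell in units of acquisition pixels.  1.0 for raw
        and wide-field images; ``1 / zero_pad_factor`` for reconstructions.
    """

    data: np.ndarray
    pixel_size: float = 1.0

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise DimensionError(f"Raster2D requires a 2-D array, got ndim={self.data.ndim}")
        if self.pixel_size <= 0:
            raise DimensionError("pixel_size must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def copy(self) -> "Raster2D":
        return Raster2D(self.data.copy(), self.pixel_size)

    def __array__(self, dtype=None, copy=None):
        return np.asarray(self.data, dtype=dtype)


def as_array(image) -> np.ndarray:
    """Coerce a Raster2D or array-like to a float ndarray."""
    if isinstance(image, Raster2D):
        return image.data
    return np.asarray(image, dtype=float)
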