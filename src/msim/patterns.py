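"""Generation of thresholded multifocal excitation arrays.

A multifocal array is the superposition of two orthogonal sinusoidal stripe
patterns,

    I_ex(x, y) = I0 * [1 + m*cos(2*pi*k_x*x + phi_x) + m*cos(2*pi*k_y*y + phi_y)],

followed by a hard threshold that keeps only pixels whose value reaches a
fixed fraction of the array maximum.  Thresholding sparsifies the pattern
into a lattice of bright foci and *raises* the effective modulation depth of
the retained fundamental harmonic — the property that makes the scheme
robust when the raw modulation contrast is degraded by scattering.

Nine such arrays on a 3x3 phase grid (steps of 2*pi/3 along X and along Y)
tile the sample uniformly and supply the three-phase sets needed for
structured-illumination band separation in each direction.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .exceptions import DegenerateInputError, ParameterError
from .raster import Raster2D, as_array

__all__ = [
    "IlluminationParams",
    "PatternSet",
    "make_stripe",
    "make_multifocal_array",
    "make_pattern_set",
    "effective_modulation",
]

TWO_PI = 2.0 * np.pi
PHASE_STEP = TWO_PI / 3.0


def _reduce_phase(phi: float) -> float:
    return float(np.mod(phi, TWO_PI))


@dataclass(frozen=True)
class IlluminationParams:
    """Parameters of one multifocal excitation array.

    Attributes
    ----------
    k_x, k_y
        Stripe spatial frequencies along X and Y, cycles/pixel.
    phi_x, phi_y
        Stripe phases, radians; stored reduced to [0, 2*pi).
    m
        Modulation depth of each stripe, 0 < m <= 1.  The two-stripe
        superposition stays nonnegative only for m <= 0.5, which is the
        default; larger values are admitted but the un-thresholded array
        then dips below zero.
    I_0
        Peak (mean) illumination intensity, arbitrary units, > 0.
    threshold_frac
        Retention threshold as a fraction of the array maximum,
        0 <= threshold_frac < 1.  0 disables thresholding.
    """

    k_x: float
    k_y: float
    phi_x: float = 0.0
    phi_y: float = 0.0
    m: float = 0.5
    I_0: float = 1.0
    threshold_frac: float = 0.5

    def __post_init__(self):
        if not (self.k_x > 0 and self.k_y > 0):
            raise ParameterError("spatial frequencies k_x, k_y must be positive")
        if not (0.0 < self.m <= 1.0):
            raise ParameterError(f"modulation depth m must be in (0, 1], got {self.m}")
        if self.I_0 <= 0:
            raise ParameterError("peak intensity I_0 must be positive")
        if not (0.0 <= self.threshold_frac < 1.0):
            raise ParameterError(
                f"threshold_frac must be in [0, 1), got {self.threshold_frac}"
            )
        object.__setattr__(self, "phi_x", _reduce_phase(self.phi_x))
        object.__setattr__(self, "phi_y", _reduce_phase(self.phi_y))


@dataclass
class PatternSet:
    """The nine multifocal illumination rasters and their phase schedule.

    ``patterns[3*r + c]`` sits at grid position (row r, column c): the three
    patterns of column c share phi_x = phi_x0 + 2*pi*c/3, the three patterns
    of row r share phi_y = phi_y0 + 2*pi*r/3.  ``schedule`` lists the
    (phi_x, phi_y) pair of each pattern in the same order.
    """

    patterns: list[Raster2D]
    schedule: list[tuple[float, float]]
    params: IlluminationParams
    grid_shape: tuple[int, int] = (3, 3)

    def __post_init__(self):
        if len(self.patterns) != 9 or len(self.schedule) != 9:
            raise ParameterError("a PatternSet holds exactly 9 patterns and 9 phase pairs")

    def __len__(self) -> int:
        return len(self.patterns)

    def column(self, c: int) -> list[int]:
        """Frame indices of grid column ``c`` (shared phi_x, phi_y stepping)."""
        return [c, 3 + c, 6 + c]

    def row(self, r: int) -> list[int]:
        """Frame indices of grid row ``r`` (shared phi_y, phi_x stepping)."""
        return [3 * r, 3 * r + 1, 3 * r + 2]


def make_stripe(shape, k: float, phi: float, axis: str = "x",
                m: float = 0.5, I_0: float = 1.0) -> Raster2D:
    """One sinusoidal stripe pattern I0*[1 + m*cos(2*pi*k*coord + phi)].

    ``axis='x'`` modulates along columns (vertical stripes), ``axis='y'``
    along rows.  Evaluated at integer pixel coordinates.
    """
    rows, cols = int(shape[0]), int(shape[1])
    if rows <= 0 or cols <= 0:
        raise ParameterError(f"shape must be positive, got {shape}")
    if not (0.0 < m <= 1.0):
        raise ParameterError(f"modulation depth m must be in (0, 1], got {m}")
    if axis not in ("x", "y"):
        raise ParameterError(f"axis must be 'x' or 'y', got {axis!r}")
    if axis == "x":
        coord = np.arange(cols)[None, :]
    else:
        coord = np.arange(rows)[:, None]
    field = I_0 * (1.0 + m * np.cos(TWO_PI * k * coord + phi))
    return Raster2D(np.broadcast_to(field, (rows, cols)).copy())


def _superposition(shape, params: IlluminationParams) -> np.ndarray:
    rows, cols = int(shape[0]), int(shape[1])
    if rows <= 0 or cols <= 0:
        raise ParameterError(f"shape must be positive, got {shape}")
    x = np.arange(cols)[None, :]
    y = np.arange(rows)[:, None]
    return params.I_0 * (
        1.0
        + params.m * np.cos(TWO_PI * params.k_x * x + params.phi_x)
        + params.m * np.cos(TWO_PI * params.k_y * y + params.phi_y)
    )


def make_multifocal_array(shape, params: IlluminationParams) -> Raster2D:
    """Thresholded superposition of two orthogonal stripes.

    Pixels whose value falls below ``threshold_frac`` times the array maximum
    are zeroed; pixels exactly at the threshold are retained.  With
    ``threshold_frac = 0`` the raw superposition is returned untouched.
    """
    raw = _superposition(shape, params)
    if params.threshold_frac == 0.0:
        return Raster2D(raw)
    peak = raw.max()
    thr = params.threshold_frac * peak
    # small relative tolerance: pixels exactly at the threshold are retained
    # consistently across phase-shifted (translated) copies of the pattern
    out = np.where(raw >= thr - 1e-9 * peak, raw, 0.0)
    return Raster2D(out)


def make_pattern_set(shape, params: IlluminationParams,
                     phase_origin: tuple[float, float] = (0.0, 0.0)) -> PatternSet:
    """Build the nine-pattern 3x3 phase schedule.

    Pattern (row r, column c) has phases
    (phi_x0 + 2*pi*c/3, phi_y0 + 2*pi*r/3); frames are ordered row-major,
    phi_x varying fastest.  Advancing a phase by 2*pi/3 translates the array
    by one third of the stripe period along that axis, so the nine foci
    lattices jointly cover the sample.
    """
    phi_x0, phi_y0 = phase_origin
    patterns: list[Raster2D] = []
    schedule: list[tuple[float, float]] = []
    for r in range(3):
        for c in range(3):
            phx = _reduce_phase(phi_x0 + PHASE_STEP * c)
            phy = _reduce_phase(phi_y0 + PHASE_STEP * r)
            p = replace(params, phi_x=phx, phi_y=phy)
            patterns.append(make_multifocal_array(shape, p))
            schedule.append((phx, phy))
    base = replace(params, phi_x=_reduce_phase(phi_x0), phi_y=_reduce_phase(phi_y0))
    return PatternSet(patterns=patterns, schedule=schedule, params=base)


def effective_modulation(pattern, k: float, axis: str = "x") -> float:
    """Fundamental-harmonic modulation depth of a pattern along one axis.

    Returns 2*|F(k)| / |F(0)| where F is the pattern's Fourier coefficient at
    the carrier frequency along the chosen axis (full 2-D sum, so this is the
    coefficient at (k, 0) or (0, k)).  For an un-thresholded stripe of
    nominal depth m this recovers m; thresholding raises it.  The value feeds
    the band-separation mixing matrix in place of the nominal m.
    """
    arr = as_array(pattern)
    if k <= 0:
        raise ParameterError("carrier frequency k must be positive")
    if axis not in ("x", "y"):
        raise ParameterError(f"axis must be 'x' or 'y', got {axis!r}")
    f0 = arr.sum()
    if arr.size == 0 or abs(f0) < 1e-300:
        raise DegenerateInputError("pattern has zero mean; modulation undefined")
    n = arr.shape[1] if axis == "x" else arr.shape[0]
    coord = np.arange(n)
    phase = np.exp(-1j * TWO_PI * k * coord)
    if axis == "x":
        fk = (arr * phase[None, :]).sum()
    else:
        fk = (arr * phase[:, None]).sum()
    return float(2.0 * np.abs(fk) / np.abs(f0))
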