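"""Diffraction-limited incoherent imaging simulator and synthetic samples.

Forward model: the excitation pattern multiplies the fluorophore density and
the product is blurred by the emission point-spread function,

    I_em(x) = (I_ex(x) * S(x)) (x) PSF_em(x),

equivalently in frequency space  I_em~(k) = (I_ex~ (x) S~)(k) * OTF_em(k).
Convolution is circular (FFT-based), so stripe-phase arithmetic is exact
under periodic boundaries.

The default OTF is the 2-D diffraction-limited incoherent transfer function
of a circular pupil (the autocorrelation "chat" function): radially
symmetric, 1 at DC, monotonically decreasing, identically zero at and beyond
the cutoff frequency.  A compact-support Gaussian alternative is available.
Detection noise is a Poisson photon count at configurable scale plus
additive Gaussian read noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.fft import fft2, fftfreq, fftshift, ifft2

from .exceptions import (
    DimensionError,
    DomainError,
    LayoutError,
    ParameterError,
)
from .patterns import PatternSet
from .raster import Raster2D, as_array

__all__ = [
    "OpticalModel",
    "SampleImage",
    "BarElement",
    "NoiseConfig",
    "RawStack",
    "make_otf",
    "image_under_pattern",
    "widefield_image",
    "add_noise",
    "acquire_stack",
    "make_usaf_target",
    "make_natural_sample",
]


def disk_otf_value(rho):
    """Incoherent OTF of a circular pupil at normalized frequency rho=|k|/cutoff.

    (2/pi) * (arccos(rho) - rho*sqrt(1-rho^2)) inside the cutoff, 0 outside.
    """
    rho = np.asarray(rho, dtype=float)
    inside = rho < 1.0
    r = np.clip(rho, 0.0, 1.0)
    val = (2.0 / np.pi) * (np.arccos(r) - r * np.sqrt(1.0 - r * r))
    return np.where(inside, val, 0.0)


def gaussian_otf_value(rho, sigma: float = 0.35):
    """Compact-support Gaussian OTF: exp(-rho^2/(2 sigma^2)) truncated at rho=1."""
    rho = np.asarray(rho, dtype=float)
    return np.where(rho < 1.0, np.exp(-0.5 * (rho / sigma) ** 2), 0.0)


@dataclass
class OpticalModel:
    """Emission PSF/OTF pair on a pixel grid with a known cutoff frequency.

    ``otf_em`` is laid out in unshifted FFT order on the acquisition grid;
    ``psf_em`` is the centered (fftshifted) inverse transform, unit sum.
    ``otf_at`` evaluates the same analytic transfer function at arbitrary
    frequencies, which the reconstruction uses on enlarged grids and at
    shifted band positions.
    """

    shape: tuple[int, int]
    cutoff: float
    psf_em: Raster2D
    otf_em: np.ndarray
    kind: str = "disk"

    def otf_at(self, kx, ky) -> np.ndarray:
        """Analytic OTF value at frequencies (kx, ky) in cycles/pixel."""
        rho = np.sqrt(np.asarray(kx, float) ** 2 + np.asarray(ky, float) ** 2) / self.cutoff
        if self.kind == "gaussian":
            return gaussian_otf_value(rho)
        return disk_otf_value(rho)


def make_otf(shape, cutoff: float, kind: str = "disk") -> OpticalModel:
    """Build the diffraction-limited optical model for a grid.

    ``cutoff`` is the incoherent OTF cutoff in cycles/pixel, bounded by the
    Nyquist frequency 0.5.
    """
    if not (0.0 < cutoff <= 0.5):
        raise ParameterError(
            f"cutoff must be in (0, 0.5] cycles/pixel to avoid aliasing, got {cutoff}"
        )
    if kind not in ("disk", "gaussian"):
        raise ParameterError(f"unknown OTF kind {kind!r}")
    rows, cols = int(shape[0]), int(shape[1])
    ky = fftfreq(rows)[:, None]
    kx = fftfreq(cols)[None, :]
    rho = np.sqrt(kx**2 + ky**2) / cutoff
    if kind == "gaussian":
        otf = gaussian_otf_value(rho)
    else:
        otf = disk_otf_value(rho)
    otf = otf.astype(complex)
    psf = np.real(ifft2(otf))
    psf = psf / psf.sum()
    return OpticalModel(
        shape=(rows, cols),
        cutoff=float(cutoff),
        psf_em=Raster2D(fftshift(psf)),
        otf_em=otf,
        kind=kind,
    )


@dataclass
class BarElement:
    """One three-bar resolution element.

    ``period_px`` is the full on+off period; bars have 50% duty cycle (odd
    periods rasterize to alternating floor/ceil bar widths, keeping the
    fundamental at 1/period).  ``position`` is the (row, col) of the
    element's top-left corner; ``orientation`` 'vertical' means bars vary
    along X.  ``length`` is the bar length in pixels (default 2.5 periods,
    the standard 5:1 bar aspect).
    """

    period_px: float
    orientation: str = "vertical"
    position: tuple[int, int] = (0, 0)
    n_bars: int = 3
    length: int | None = None

    def __post_init__(self):
        if self.period_px < 2:
            raise ParameterError("bar period must be >= 2 pixels")
        if self.orientation not in ("vertical", "horizontal"):
            raise ParameterError(f"orientation must be vertical|horizontal, got {self.orientation!r}")
        if self.length is None:
            self.length = int(round(2.5 * self.period_px))

    @property
    def extent(self) -> tuple[int, int]:
        """(rows, cols) bounding box of the element."""
        across = int(np.ceil(self.n_bars * self.period_px - self.period_px / 2.0))
        if self.orientation == "vertical":
            return (self.length, across)
        return (across, self.length)

    def bar_centers(self) -> np.ndarray:
        """Coordinates (along the varying axis, image frame) of bar centers."""
        r0, c0 = self.position
        origin = c0 if self.orientation == "vertical" else r0
        return origin + self.period_px * np.arange(self.n_bars) + self.period_px / 4.0

    def gap_centers(self) -> np.ndarray:
        """Coordinates of the two inter-bar gap centers."""
        r0, c0 = self.position
        origin = c0 if self.orientation == "vertical" else r0
        return origin + self.period_px * np.arange(self.n_bars - 1) + 0.75 * self.period_px


@dataclass
class SampleImage:
    """Fluorophore density map with provenance and optional element metadata."""

    raster: Raster2D
    description: str = "custom"
    elements: list[BarElement] = field(default_factory=list)


@dataclass(frozen=True)
class NoiseConfig:
    """Detection-noise settings.

    ``photon_scale``: expected photon count at unit intensity (None disables
    shot noise).  ``gaussian_sigma``: additive read-noise standard deviation
    in intensity units.  With both disabled the image passes through
    bit-identically.
    """

    photon_scale: float | None = 200.0
    gaussian_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.photon_scale is not None and self.photon_scale <= 0:
            raise ParameterError("photon_scale must be positive or None")
        if self.gaussian_sigma < 0:
            raise ParameterError("gaussian_sigma must be nonnegative")

    @property
    def enabled(self) -> bool:
        return self.photon_scale is not None or self.gaussian_sigma > 0


@dataclass
class RawStack:
    """Nine acquired frames plus the acquisition context that produced them."""

    frames: list[Raster2D]
    pattern_set: PatternSet | None = None
    optics: OpticalModel | None = None
    noise: NoiseConfig | None = None

    def __post_init__(self):
        if self.pattern_set is not None and len(self.frames) != len(self.pattern_set):
            raise DimensionError("frame count must equal pattern count")
        shapes = {f.shape for f in self.frames}
        if len(shapes) > 1:
            raise DimensionError("all frames must share one shape")

    def __len__(self) -> int:
        return len(self.frames)


def image_under_pattern(sample, pattern, optics: OpticalModel) -> Raster2D:
    """Image of the sample under one excitation pattern.

    Pointwise product sample*pattern, circularly convolved with the emission
    PSF via the OTF.  Output is nonnegative up to FFT round-off.
    """
    s = as_array(sample.raster if isinstance(sample, SampleImage) else sample)
    p = as_array(pattern)
    if s.shape != p.shape or s.shape != tuple(optics.shape):
        raise DimensionError(
            f"shape mismatch: sample {s.shape}, pattern {p.shape}, optics {tuple(optics.shape)}"
        )
    out = np.real(ifft2(fft2(s * p) * optics.otf_em))
    return Raster2D(out)


def widefield_image(sample, optics: OpticalModel) -> Raster2D:
    """Wide-field image: the sample under uniform unit illumination."""
    s = as_array(sample.raster if isinstance(sample, SampleImage) else sample)
    return image_under_pattern(s, np.ones_like(s), optics)


def add_noise(image, noise: NoiseConfig | None) -> Raster2D:
    """Apply Poisson shot noise and Gaussian read noise to an image.

    Output = Poisson(photon_scale * I) / photon_scale + N(0, gaussian_sigma),
    reproducible under a fixed seed.  A pre-seeded Generator may be passed as
    ``noise`` being a (NoiseConfig, Generator) pair internally; callers use
    NoiseConfig.
    """
    img = as_array(image)
    rng = None
    if isinstance(noise, tuple):
        noise, rng = noise
    if noise is None or not noise.enabled:
        return Raster2D(img.copy())
    if img.min() < -1e-9 * max(img.max(), 1.0):
        raise DomainError("noisy acquisition requires a nonnegative image")
    img = np.clip(img, 0.0, None)
    if rng is None:
        rng = np.random.default_rng(noise.seed)
    out = img
    if noise.photon_scale is not None:
        out = rng.poisson(noise.photon_scale * img).astype(float) / noise.photon_scale
    if noise.gaussian_sigma > 0:
        out = out + rng.normal(0.0, noise.gaussian_sigma, size=img.shape)
    return Raster2D(out)


def acquire_stack(sample: SampleImage, pattern_set: PatternSet,
                  optics: OpticalModel, noise: NoiseConfig | None = None) -> RawStack:
    """Acquire the nine-frame raw stack in schedule order.

    One shared RNG (seeded from the noise config) draws all frames
    sequentially, so the whole stack is reproducible from a single seed.
    """
    rng = np.random.default_rng(noise.seed) if (noise is not None and noise.enabled) else None
    frames = []
    for p in pattern_set.patterns:
        clean = image_under_pattern(sample, p, optics)
        frames.append(add_noise(clean, (noise, rng)) if rng is not None else clean)
    return RawStack(frames=frames, pattern_set=pattern_set, optics=optics, noise=noise)


def make_usaf_target(shape, elements: list[BarElement]) -> SampleImage:
    """Binary three-bar resolution target in the style of a USAF-1951 chart.

    Bars are 0/1 with 50% duty cycle; each element keeps its period metadata
    for later contrast lookup.  Elements must fit inside the canvas and must
    not overlap.
    """
    rows, cols = int(shape[0]), int(shape[1])
    canvas = np.zeros((rows, cols))
    occupied = np.zeros((rows, cols), dtype=bool)
    for el in elements:
        r0, c0 = el.position
        h, w = el.extent
        if r0 < 0 or c0 < 0 or r0 + h > rows or c0 + w > cols:
            raise LayoutError(f"element {el} does not fit in shape {shape}")
        if el.orientation == "vertical":
            coord = np.arange(w)
            bars = (np.mod(coord, el.period_px) < el.period_px / 2.0) & (
                coord < el.n_bars * el.period_px
            )
            block = np.broadcast_to(bars[None, :], (h, w)).astype(float)
        else:
            coord = np.arange(h)
            bars = (np.mod(coord, el.period_px) < el.period_px / 2.0) & (
                coord < el.n_bars * el.period_px
            )
            block = np.broadcast_to(bars[:, None], (h, w)).astype(float)
        if occupied[r0 : r0 + h, c0 : c0 + w].any():
            raise LayoutError(f"element {el} overlaps a previous element")
        occupied[r0 : r0 + h, c0 : c0 + w] = True
        canvas[r0 : r0 + h, c0 : c0 + w] = block
    return SampleImage(Raster2D(canvas), description="usaf", elements=list(elements))


def make_natural_sample(shape, seed: int = 0, slope: float = 1.5) -> SampleImage:
    """Synthetic grayscale scene with natural-image (power-law) statistics.

    Stands in for a photographic test image: filtered white noise whose
    amplitude spectrum falls as 1/|k|^slope, with a few soft ridges overlaid
    for edge content, normalized to [0, 1].  Synthetic construct; it mimics
    only the spectral statistics of photographs, not their semantics.
    """
    rows, cols = int(shape[0]), int(shape[1])
    rng = np.random.default_rng(seed)
    white = rng.standard_normal((rows, cols))
    ky = fftfreq(rows)[:, None]
    kx = fftfreq(cols)[None, :]
    kmag = np.sqrt(kx**2 + ky**2)
    filt = 1.0 / (kmag + 1.0 / max(rows, cols)) ** slope
    tex = np.real(ifft2(fft2(white) * filt))
    # soft diagonal ridges give vein/edge structure
    y = np.arange(rows)[:, None]
    x = np.arange(cols)[None, :]
    ridges = np.zeros((rows, cols))
    for i in range(3):
        ang = rng.uniform(0, np.pi)
        off = rng.uniform(0, max(rows, cols))
        d = x * np.cos(ang) + y * np.sin(ang) - off
        ridges += np.exp(-0.5 * (d / (2.0 + i)) ** 2)
    img = tex - tex.min()
    img = img / img.max()
    img = 0.7 * img + 0.3 * ridges / max(ridges.max(), 1e-12)
    img = img - img.min()
    img = img / img.max()
    return SampleImage(Raster2D(img), description="photograph")
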