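"""Classical three-phase, one-orientation SIM reconstruction.

Under sinusoidal illumination I0*[1 + m*cos(2*pi*k0.x + phi)] the observed
spectrum is a mixture of three copies of the sample spectrum,

    D(k) = I0 * [ S(k) + (m/2) S(k + k0) e^{-i phi} + (m/2) S(k - k0) e^{+i phi} ] * OTF(k).

Three frames with phases stepped by 2*pi/3 give three independent linear
equations per frequency; solving them separates the center band and the two
sidebands.  Each sideband is then translated back to its true position in
frequency space (sub-pixel carriers handled by real-space phase ramps on a
zero-padded grid) and the bands are recombined with a generalized Wiener
filter, extending the support to cutoff + |k0| along the stripe axis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.fft import fft2, fftfreq, fftshift, ifft2, ifftshift

from .exceptions import ConditioningError, ParameterError, RangeError
from .optics import OpticalModel
from .raster import Raster2D, as_array

__all__ = [
    "FrequencyBands",
    "ReconFilterConfig",
    "separate_bands",
    "shift_band",
    "recombine",
    "reconstruct_1d_sim",
]

_COND_LIMIT = 1e8


@dataclass
class FrequencyBands:
    """Separated Fourier components of one three-phase frame set.

    ``center`` holds S(k)*OTF(k); ``minus_band`` the component that entered
    the mixture with weight (m/2)e^{-i phi}, i.e. S(k + k0)*OTF(k);
    ``plus_band`` the (m/2)e^{+i phi} component S(k - k0)*OTF(k).  The m/2
    and phase factors are removed by the unmixing, and the overall I0 scale
    is absorbed into the bands.  Spectra are stored in unshifted FFT layout.
    """

    center: np.ndarray
    minus_band: np.ndarray
    plus_band: np.ndarray
    carrier: tuple[float, float]
    phases: tuple[float, float, float]
    modulation: float


@dataclass(frozen=True)
class ReconFilterConfig:
    """Recombination filter settings.

    ``wiener_w`` regularizes the band recombination (adds to the summed
    squared transfer functions); ``apodization`` tapers the result toward
    the extended cutoff: 'diffraction' (the diffraction-limited OTF rescaled
    to the extended cutoff, so a point source reconstructs to an exactly
    rescaled wide-field PSF), 'triangle' (linear taper), or 'none';
    ``zero_pad_factor`` enlarges the output grid so the doubled support fits.
    """

    wiener_w: float = 1e-2
    apodization: str = "diffraction"
    zero_pad_factor: int = 2

    def __post_init__(self):
        if self.wiener_w <= 0:
            raise ParameterError("wiener_w must be positive")
        if self.apodization not in ("none", "triangle", "diffraction"):
            raise ParameterError(f"unknown apodization {self.apodization!r}")
        if int(self.zero_pad_factor) < 1:
            raise ParameterError("zero_pad_factor must be an integer >= 1")


def mixing_matrix(phases, m: float) -> np.ndarray:
    """Per-frequency mixing matrix: rows [1, (m/2)e^{-i phi_n}, (m/2)e^{+i phi_n}]."""
    ph = np.asarray(phases, dtype=float)
    return np.stack(
        [np.ones(3, complex), 0.5 * m * np.exp(-1j * ph), 0.5 * m * np.exp(1j * ph)],
        axis=1,
    )


def separate_bands(frames, phases, m: float, carrier) -> FrequencyBands:
    """Solve the three-phase linear system frequency-by-frequency.

    ``frames`` are the three phase-stepped images, ``phases`` their
    illumination phases, ``m`` the (effective) modulation depth used in the
    mixing matrix, ``carrier`` the stripe frequency vector (k_x, k_y) in
    cycles/pixel.  Raises ConditioningError when the phases are not distinct
    modulo 2*pi (or m is too small), reporting the condition number.
    """
    if len(frames) != 3 or len(phases) != 3:
        raise ParameterError("three frames and three phases are required")
    if m <= 0:
        raise ParameterError("modulation m must be positive for unmixing")
    M = mixing_matrix(phases, m)
    cond = float(np.linalg.cond(M))
    if not np.isfinite(cond) or cond > _COND_LIMIT:
        raise ConditioningError(
            f"singular mixing matrix (condition number {cond:.3g}); "
            "phases must be distinct modulo 2*pi",
            condition_number=cond,
        )
    Minv = np.linalg.inv(M)
    specs = [fft2(as_array(f)) for f in frames]
    center = sum(Minv[0, n] * specs[n] for n in range(3))
    minus = sum(Minv[1, n] * specs[n] for n in range(3))
    plus = sum(Minv[2, n] * specs[n] for n in range(3))
    return FrequencyBands(
        center=center,
        minus_band=minus,
        plus_band=plus,
        carrier=(float(carrier[0]), float(carrier[1])),
        phases=tuple(float(p) for p in phases),
        modulation=float(m),
    )


def _embed_spectrum(spec: np.ndarray, zpf: int) -> np.ndarray:
    """Zero-pad a spectrum symmetrically onto a grid enlarged by ``zpf``."""
    nr, nc = spec.shape
    big = np.zeros((zpf * nr, zpf * nc), dtype=complex)
    r0 = (zpf * nr - nr) // 2
    c0 = (zpf * nc - nc) // 2
    big[r0 : r0 + nr, c0 : c0 + nc] = fftshift(spec)
    return ifftshift(big)


def shift_band(band: np.ndarray, shift, zero_pad_factor: int = 2) -> np.ndarray:
    """Translate a spectrum by ``shift`` (cycles/pixel) on an enlarged grid.

    Returns g with g(k) = band(k - shift): content at frequency k moves to
    k + shift.  The band is first embedded into a grid enlarged by
    ``zero_pad_factor`` (shift (0, 0) is the identity embedding); sub-pixel
    shifts are realized by a real-space phase-ramp multiplication, exact for
    band-limited spectra.
    """
    zpf = int(zero_pad_factor)
    if zpf < 1:
        raise ParameterError("zero_pad_factor must be >= 1")
    sx, sy = float(shift[0]), float(shift[1])
    if abs(sx) > 0.5 * zpf or abs(sy) > 0.5 * zpf:
        raise RangeError(
            f"shift {shift} exceeds the enlarged Nyquist frequency {0.5 * zpf}"
        )
    big = _embed_spectrum(np.asarray(band, dtype=complex), zpf)
    if sx == 0.0 and sy == 0.0:
        return big
    nr, nc = big.shape
    # fine-grid coordinates in original-pixel units; unsigned x in [0, N)
    # matches the pixel convention of the forward model, so a carrier
    # e^{2 pi i k0 x} in the data is cancelled pointwise by the ramp
    y = (np.arange(nr) / zpf)[:, None]
    x = (np.arange(nc) / zpf)[None, :]
    ramp = np.exp(2j * np.pi * (sx * x + sy * y))
    return fft2(ifft2(big) * ramp)


def recombine(bands: FrequencyBands, optics: OpticalModel,
              cfg: ReconFilterConfig | None = None) -> Raster2D:
    """Generalized-Wiener recombination of the separated bands.

    Each band b carries S(k) * H_b(k) after relocation, with H_b the OTF
    shifted to the band's position.  The estimate

        S_hat(k) = sum_b conj(H_b) B_b / (sum_b |H_b|^2 + w)

    is optionally apodized by a triangle window reaching zero at the
    extended cutoff (OTF cutoff + |carrier|), then inverse-transformed.
    The result lives on the enlarged grid (pixel_size = 1/zero_pad_factor).
    """
    if cfg is None:
        cfg = ReconFilterConfig()
    zpf = int(cfg.zero_pad_factor)
    cx, cy = bands.carrier
    center_s = shift_band(bands.center, (0.0, 0.0), zpf)
    plus_s = shift_band(bands.plus_band, (-cx, -cy), zpf)
    minus_s = shift_band(bands.minus_band, (cx, cy), zpf)

    nr, nc = center_s.shape
    kyf = fftfreq(nr, d=1.0 / zpf)[:, None]
    kxf = fftfreq(nc, d=1.0 / zpf)[None, :]
    Hc = optics.otf_at(kxf, kyf)
    Hp = optics.otf_at(kxf + cx, kyf + cy)  # plus band shifted by -carrier
    Hm = optics.otf_at(kxf - cx, kyf - cy)

    num = np.conj(Hc) * center_s + np.conj(Hp) * plus_s + np.conj(Hm) * minus_s
    den = np.abs(Hc) ** 2 + np.abs(Hp) ** 2 + np.abs(Hm) ** 2 + cfg.wiener_w
    spec = num / den
    if cfg.apodization != "none":
        k_ext = optics.cutoff + float(np.hypot(cx, cy))
        if cfg.apodization == "triangle":
            apod = np.clip(1.0 - np.hypot(kxf, kyf) / k_ext, 0.0, None)
        else:  # 'diffraction': ideal OTF of a system with the extended cutoff
            from .optics import disk_otf_value

            apod = disk_otf_value(np.hypot(kxf, kyf) / k_ext)
        spec = spec * apod
    out = np.real(ifft2(spec)) * zpf**2
    return Raster2D(out, pixel_size=1.0 / zpf)


def reconstruct_1d_sim(frames, phases, carrier, optics: OpticalModel,
                       cfg: ReconFilterConfig | None = None,
                       m: float | None = None) -> Raster2D:
    """Full one-orientation SIM pipeline: separate, relocate, recombine.

    ``m`` defaults to the effective modulation of an ideal stripe (the
    caller normally supplies the measured value).
    """
    if m is None:
        m = 1.0
    bands = separate_bands(frames, phases, m, carrier)
    return recombine(bands, optics, cfg)
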