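"""Quantitative evaluation: line profiles, bar contrast, resolution, FWHM.

Resolvability uses the Michelson contrast of a three-bar element, sampled at
the element's known bar and gap centers: an element is resolved when the
contrast reaches a configurable criterion (default 0.1).  All coordinates
are expressed in acquisition-pixel units; images on finer reconstruction
grids are handled through their ``pixel_size`` metadata, so periods and
widths are directly comparable between raw and reconstructed images.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import map_coordinates

from .exceptions import DomainError, ParameterError
from .optics import BarElement, SampleImage
from .raster import Raster2D, as_array

__all__ = [
    "ResolutionReport",
    "line_profile",
    "michelson_contrast",
    "element_contrast",
    "resolution_report",
    "fwhm",
]


def _grid_and_pitch(image):
    if isinstance(image, Raster2D):
        return image.data, image.pixel_size
    return np.asarray(image, dtype=float), 1.0


def _sample(data, rows_phys, cols_phys, pitch):
    """Bilinear interpolation at physical (acquisition-pixel) coordinates."""
    coords = np.vstack([np.asarray(rows_phys) / pitch, np.asarray(cols_phys) / pitch])
    return map_coordinates(data, coords, order=1, mode="nearest")


def line_profile(image, start, end, n_samples: int = 200) -> np.ndarray:
    """Normalized intensity profile along a line segment.

    ``start``/``end`` are (row, col) in acquisition-pixel units.  Samples
    are bilinear-interpolated and min-max normalized to [0, 1]; a constant
    profile normalizes to all zeros.
    """
    data, pitch = _grid_and_pitch(image)
    r0, c0 = float(start[0]), float(start[1])
    r1, c1 = float(end[0]), float(end[1])
    if (r0, c0) == (r1, c1):
        raise ParameterError("degenerate line segment")
    extent_r = (data.shape[0] - 1) * pitch
    extent_c = (data.shape[1] - 1) * pitch
    for r, c in ((r0, c0), (r1, c1)):
        if not (0 <= r <= extent_r and 0 <= c <= extent_c):
            raise ParameterError(f"endpoint ({r}, {c}) outside image extent")
    t = np.linspace(0.0, 1.0, int(n_samples))
    vals = _sample(data, r0 + t * (r1 - r0), c0 + t * (c1 - c0), pitch)
    lo, hi = vals.min(), vals.max()
    if hi - lo < 1e-300:
        return np.zeros_like(vals)
    return (vals - lo) / (hi - lo)


def michelson_contrast(profile, peak_idx, trough_idx) -> float:
    """(mean peak - mean trough) / (mean peak + mean trough), clamped to [0, 1].

    ``peak_idx``/``trough_idx`` index the samples at the element's known bar
    and gap centers.  Negative intensities (deconvolution ringing) are
    clipped at zero, and contrast reversal (troughs brighter than bars)
    reports 0 — spurious bar-like structure does not count as resolved.
    """
    p = np.asarray(profile, dtype=float)
    peak = max(float(p[np.asarray(peak_idx)].mean()), 0.0)
    trough = max(float(p[np.asarray(trough_idx)].mean()), 0.0)
    if peak + trough <= 0:
        return 0.0
    return float(np.clip((peak - trough) / (peak + trough), 0.0, 1.0))


def element_contrast(image, element: BarElement) -> float:
    """Michelson contrast of one bar element in an image.

    Intensities are sampled at the element's bar and gap centers, averaged
    over the central portion of the bar length for robustness; raw
    (unnormalized) intensities are used so the ratio is meaningful.
    """
    data, pitch = _grid_and_pitch(image)
    r0, c0 = element.position
    h, w = element.extent
    bars = element.bar_centers()
    gaps = element.gap_centers()
    # 9 cuts spanning the middle 60% of the bar length
    frac = np.linspace(0.2, 0.8, 9)
    if element.orientation == "vertical":
        fixed = r0 + frac * (h - 1)
        peak_vals = [_sample(data, np.full_like(bars, f), bars, pitch) for f in fixed]
        trough_vals = [_sample(data, np.full_like(gaps, f), gaps, pitch) for f in fixed]
    else:
        fixed = c0 + frac * (w - 1)
        peak_vals = [_sample(data, bars, np.full_like(bars, f), pitch) for f in fixed]
        trough_vals = [_sample(data, gaps, np.full_like(gaps, f), pitch) for f in fixed]
    peak = max(float(np.mean(peak_vals)), 0.0)
    trough = max(float(np.mean(trough_vals)), 0.0)
    if peak + trough <= 0:
        return 0.0
    return float(np.clip((peak - trough) / (peak + trough), 0.0, 1.0))


@dataclass
class ResolutionReport:
    """Per-element contrast and the smallest resolved bar period."""

    smallest_resolvable_period: float | None
    per_element: list[dict]
    criterion: float
    image_id: str = ""

    def to_dict(self) -> dict:
        return {
            "smallest_resolvable_period": self.smallest_resolvable_period,
            "criterion": self.criterion,
            "image_id": self.image_id,
            "per_element": self.per_element,
        }


def resolution_report(image, target: SampleImage, criterion: float = 0.1,
                      image_id: str = "") -> ResolutionReport:
    """Evaluate every bar element of a target in a (possibly processed) image."""
    if not target.elements:
        raise ParameterError("target carries no bar-element metadata")
    per = []
    resolved_periods = []
    for el in target.elements:
        c = element_contrast(image, el)
        ok = bool(c >= criterion)
        per.append({
            "period_px": float(el.period_px),
            "orientation": el.orientation,
            "michelson_contrast": c,
            "resolved": ok,
        })
        if ok:
            resolved_periods.append(float(el.period_px))
    smallest = min(resolved_periods) if resolved_periods else None
    return ResolutionReport(
        smallest_resolvable_period=smallest,
        per_element=per,
        criterion=float(criterion),
        image_id=image_id,
    )


def fwhm(image, peak_location, axis: str = "x") -> float:
    """Full width at half maximum along one axis, in acquisition pixels.

    A local maximum is searched near ``peak_location`` (row, col, physical
    units); the half-maximum crossings on either side are located by linear
    interpolation along the 1-D cut through the peak.
    """
    data, pitch = _grid_and_pitch(image)
    if axis not in ("x", "y"):
        raise ParameterError(f"axis must be 'x' or 'y', got {axis!r}")
    ri = int(round(peak_location[0] / pitch))
    ci = int(round(peak_location[1] / pitch))
    win = max(3, int(round(5.0 / pitch)))
    r_lo, r_hi = max(0, ri - win), min(data.shape[0], ri + win + 1)
    c_lo, c_hi = max(0, ci - win), min(data.shape[1], ci + win + 1)
    patch = data[r_lo:r_hi, c_lo:c_hi]
    pr, pc = np.unravel_index(np.argmax(patch), patch.shape)
    ri, ci = r_lo + pr, c_lo + pc
    cut = data[ri, :] if axis == "x" else data[:, ci]
    ctr = ci if axis == "x" else ri
    peak = cut[ctr]
    baseline = 0.0
    if peak <= baseline:
        raise DomainError("no positive peak near the requested location")
    half = baseline + 0.5 * (peak - baseline)

    def crossing(direction: int) -> float:
        i = ctr
        while 0 <= i + direction < len(cut) and cut[i + direction] > half:
            i += direction
        j = i + direction
        if j < 0 or j >= len(cut):
            raise DomainError("half-maximum crossing not found within the image")
        # linear interpolation between samples i and j
        f = (cut[i] - half) / (cut[i] - cut[j])
        return i + direction * f

    left = crossing(-1)
    right = crossing(+1)
    return float((right - left) * pitch)
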