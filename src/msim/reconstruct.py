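"""Nine-frame multifocal SIM reconstruction.

The nine raw frames sit on a 3x3 phase grid: frames in one grid column share
the X-stripe phase and step the Y-stripe phase by 2*pi/3; frames in one grid
row share the Y-stripe phase and step the X-stripe phase.  The method:

1. For each of the 3 columns, run the standard three-phase SIM
   reconstruction along Y.  The un-processed X stripe survives in each
   result as a residual modulation whose phase is the column's shared phi_x.
2. The three column results carry residual stripes of identical frequency
   and phases 2*pi/3 apart; their plain sum cancels the modulation exactly
   (sum of three cosines a third of a turn apart is zero), yielding a
   stripe-free image with resolution enhanced along Y.
3. Repeat row-by-row for the X direction.
4. Sum the two directional images for isotropic enhancement.

Pattern parameters (carriers, 3x3 phase grid, effective modulations) are
taken from the generating PatternSet when available, or estimated from the
data: carriers from the dominant off-center peaks of the mean power
spectrum, per-frame phases from the argument of the frame's Fourier
coefficient at the carrier.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from numpy.fft import fft2

from .exceptions import EstimationError, ParameterError
from .optics import OpticalModel, RawStack
from .patterns import PatternSet, effective_modulation
from .raster import Raster2D, as_array
from .simcore import ReconFilterConfig, reconstruct_1d_sim

__all__ = [
    "StripedReconstruction",
    "EstimatedParams",
    "ReconstructionResult",
    "params_from_pattern_set",
    "estimate_pattern_parameters",
    "reconstruct_group",
    "cancel_stripes",
    "reconstruct_msim",
]

logger = logging.getLogger("msim")

TWO_PI = 2.0 * np.pi
PHASE_STEP = TWO_PI / 3.0


@dataclass
class StripedReconstruction:
    """One column- or row-wise SIM reconstruction with its residual stripe.

    The stripe left by the orthogonal, not-yet-processed direction has the
    acquisition's orthogonal carrier frequency and the group's shared phase.
    """

    image: Raster2D
    residual_stripe_frequency: float
    residual_stripe_phase: float
    residual_axis: str  # 'x' or 'y': axis along which the residual stripe varies


@dataclass
class EstimatedParams:
    """Illumination-pattern parameters used by the reconstruction.

    ``phase_grid[r, c]`` holds the (phi_x, phi_y) pair of the frame at grid
    row r, column c; ``m_x``/``m_y`` are effective fundamental-harmonic
    modulation depths along each axis.
    """

    k_x: float
    k_y: float
    phase_grid: np.ndarray  # shape (3, 3, 2)
    m_x: float
    m_y: float


@dataclass
class ReconstructionResult:
    """All products of a nine-frame reconstruction.

    ``final`` equals ``x_direction + y_direction`` pointwise; each
    directional image is normalized to carry half the wide-field mean
    intensity, so their sum is the photometry-preserving arithmetic mean of
    the two full-scale directional reconstructions.
    """

    final: Raster2D
    x_direction: Raster2D
    y_direction: Raster2D
    column_recons: list[StripedReconstruction]
    row_recons: list[StripedReconstruction]
    params_used: EstimatedParams

    def intermediates(self) -> list[Raster2D]:
        """The nine intermediate/final images in pipeline order.

        Three column reconstructions, their stripe-cancelled sum, three row
        reconstructions, their sum, and the final image.
        """
        return (
            [r.image for r in self.column_recons]
            + [self.y_direction]
            + [r.image for r in self.row_recons]
            + [self.x_direction, self.final]
        )


def params_from_pattern_set(pattern_set: PatternSet) -> EstimatedParams:
    """Ground-truth parameters from the generating pattern set.

    Modulation depths are measured on the (thresholded) patterns themselves,
    because thresholding changes the fundamental-harmonic amplitude relative
    to the nominal m.
    """
    p = pattern_set.params
    grid = np.zeros((3, 3, 2))
    for r in range(3):
        for c in range(3):
            phx, phy = pattern_set.schedule[3 * r + c]
            grid[r, c] = (phx, phy)
    m_x = effective_modulation(pattern_set.patterns[0], p.k_x, axis="x")
    m_y = effective_modulation(pattern_set.patterns[0], p.k_y, axis="y")
    return EstimatedParams(k_x=p.k_x, k_y=p.k_y, phase_grid=grid, m_x=m_x, m_y=m_y)


def _find_carrier(power_line: np.ndarray, dc_power: float) -> float:
    """Locate the dominant off-center peak of a 1-D power-spectrum line.

    Returns the carrier in cycles/pixel at FFT-bin resolution (sub-bin
    refinement happens on the continuous spectrum afterwards).  Raises
    EstimationError when no prominent local peak exists.
    """
    n = len(power_line)
    half = n // 2
    guard = max(3, int(round(0.02 * n)))
    if half - guard < 3:
        raise EstimationError("grid too small for carrier search", diagnostic=power_line)
    seg = power_line[:half].astype(float)
    i = int(np.argmax(seg[guard:half])) + guard
    peak = seg[i]
    # a genuine carrier is an interior local maximum prominent on BOTH
    # sides; a smooth decaying (unmodulated) spectrum peaks at the search
    # boundary or lacks two-sided prominence
    left = seg[max(guard, i - 8) : max(guard, i - 2)]
    right = seg[i + 3 : min(half, i + 9)]
    if (
        peak < 1e-9 * max(dc_power, 1e-300)
        or i <= guard
        or i >= half - 2
        or left.size == 0
        or right.size == 0
        or peak < 4.0 * left.max()
        or peak < 4.0 * right.max()
    ):
        raise EstimationError(
            "no significant off-center spectral peak; the stack appears "
            "unmodulated",
            diagnostic=power_line,
        )
    return i / n


def _refine_carrier(frames, k_coarse: float, axis: str) -> float:
    """Sub-bin carrier refinement on the continuous spectrum.

    Maximizes the summed squared magnitude of the frames' direct Fourier
    coefficients over a one-bin neighbourhood of the coarse FFT peak.
    """
    from scipy.optimize import minimize_scalar

    n = frames[0].shape[1] if axis == "x" else frames[0].shape[0]
    halfwidth = 1.0 / n

    def neg_power(k):
        return -sum(abs(_coeff_at(f, k, axis)) ** 2 for f in frames)

    res = minimize_scalar(neg_power, bounds=(k_coarse - halfwidth, k_coarse + halfwidth),
                          method="bounded", options={"xatol": 1e-6})
    return float(res.x)


def _coeff_at(frame: np.ndarray, k: float, axis: str) -> complex:
    """Direct Fourier coefficient of a frame at an on-axis frequency."""
    n = frame.shape[1] if axis == "x" else frame.shape[0]
    phase = np.exp(-2j * np.pi * k * np.arange(n))
    if axis == "x":
        return complex((frame * phase[None, :]).sum())
    return complex((frame * phase[:, None]).sum())


def estimate_pattern_parameters(stack: RawStack,
                                optics: OpticalModel | None = None) -> EstimatedParams:
    """Estimate carriers, the 3x3 phase grid, and modulations from the data.

    Carriers come from the dominant off-center peaks of the frame-averaged
    power spectrum along each frequency axis, refined to sub-bin precision
    on the continuous spectrum; per-frame phases from the argument of each
    mean-subtracted frame's Fourier coefficient at the carrier (equivalent
    to cross-correlating the frame spectrum with the shifted wide-field
    estimate); modulations from the OTF-compensated sideband-to-DC
    amplitude ratio.
    """
    if len(stack) != 9:
        raise ParameterError(f"expected a 9-frame stack, got {len(stack)}")
    if optics is None:
        optics = stack.optics
    frames = [as_array(f) for f in stack.frames]
    # the 9-frame average is (up to threshold discretization) the wide-field
    # image times the mean illumination: subtracting it cancels the entire
    # unmodulated component, whose spectral leakage would otherwise swamp
    # the carrier peaks at off-bin frequencies
    mean_frame = np.mean(frames, axis=0)
    residuals = [f - mean_frame for f in frames]
    dc_power = abs(fft2(mean_frame)[0, 0]) ** 2
    power = np.zeros(frames[0].shape)
    for f in residuals:
        power += np.abs(fft2(f)) ** 2
    power /= len(residuals)
    k_x = _refine_carrier(residuals, _find_carrier(power[0, :], dc_power), "x")
    k_y = _refine_carrier(residuals, _find_carrier(power[:, 0], dc_power), "y")

    grid = np.zeros((3, 3, 2))
    mx_vals, my_vals = [], []
    for r in range(3):
        for c in range(3):
            res = residuals[3 * r + c]
            fx = _coeff_at(res, k_x, "x")
            fy = _coeff_at(res, k_y, "y")
            grid[r, c] = (np.angle(fx) % TWO_PI, np.angle(fy) % TWO_PI)
            dc = frames[3 * r + c].sum()
            if abs(dc) > 0:
                mx_vals.append(2.0 * abs(fx) / abs(dc))
                my_vals.append(2.0 * abs(fy) / abs(dc))
    m_x = float(np.mean(mx_vals))
    m_y = float(np.mean(my_vals))
    if optics is not None:
        hx = float(optics.otf_at(k_x, 0.0))
        hy = float(optics.otf_at(0.0, k_y))
        if hx > 1e-6:
            m_x /= hx
        if hy > 1e-6:
            m_y /= hy
    return EstimatedParams(k_x=float(k_x), k_y=float(k_y), phase_grid=grid,
                           m_x=m_x, m_y=m_y)


def reconstruct_group(frames, varying_axis: str, params: EstimatedParams,
                      optics: OpticalModel, cfg: ReconFilterConfig | None = None,
                      group_index: int = 0) -> StripedReconstruction:
    """Three-phase SIM reconstruction of one grid column or row.

    ``varying_axis='y'`` reconstructs a grid *column* (phi_y steps, phi_x
    shared): resolution is enhanced along Y and the X stripe survives.
    ``varying_axis='x'`` reconstructs a grid *row*, enhancing X and leaving
    a Y stripe.  ``group_index`` selects the column/row phases from
    ``params.phase_grid``.
    """
    if varying_axis not in ("x", "y"):
        raise ParameterError(f"varying_axis must be 'x' or 'y', got {varying_axis!r}")
    if varying_axis == "y":
        phases = params.phase_grid[:, group_index, 1]
        carrier = (0.0, params.k_y)
        m = params.m_y
        residual_freq = params.k_x
        residual_phase = float(np.angle(np.mean(np.exp(1j * params.phase_grid[:, group_index, 0]))))
        residual_axis = "x"
    else:
        phases = params.phase_grid[group_index, :, 0]
        carrier = (params.k_x, 0.0)
        m = params.m_x
        residual_freq = params.k_y
        residual_phase = float(np.angle(np.mean(np.exp(1j * params.phase_grid[group_index, :, 1]))))
        residual_axis = "y"
    image = reconstruct_1d_sim(frames, phases, carrier, optics, cfg, m=m)
    return StripedReconstruction(
        image=image,
        residual_stripe_frequency=float(residual_freq),
        residual_stripe_phase=residual_phase % TWO_PI,
        residual_axis=residual_axis,
    )


def cancel_stripes(group_recons, phases=None) -> Raster2D:
    """Average three reconstructions whose residual stripes are 2*pi/3 apart.

    For inputs of the form A(x)*[1 + c*cos(2 pi k_ar x + phi_n)] with phases
    phi + 2*pi*n/3 the average equals A(x) exactly, because the three
    cosines sum to zero.  Phases off the 2*pi/3 grid (tolerance 0.1 rad)
    produce a logged warning; the average is still returned.
    """
    images = [r.image if isinstance(r, StripedReconstruction) else r for r in group_recons]
    if len(images) != 3:
        raise ParameterError("stripe cancellation needs exactly three images")
    if phases is None:
        phases = [r.residual_stripe_phase for r in group_recons
                  if isinstance(r, StripedReconstruction)]
    if len(phases) == 3:
        ph = np.asarray(phases, dtype=float)
        for a in range(3):
            b = (a + 1) % 3
            d = np.angle(np.exp(1j * (ph[b] - ph[a])))
            if min(abs(abs(d) - PHASE_STEP), abs(abs(d) - 2 * PHASE_STEP)) > 0.1:
                logger.warning(
                    "residual stripe phases %s are not on a 2*pi/3 grid; "
                    "stripes may not cancel", np.round(ph, 3)
                )
                break
    arrays = [as_array(im) for im in images]
    out = (arrays[0] + arrays[1] + arrays[2]) / 3.0
    ps = images[0].pixel_size if isinstance(images[0], Raster2D) else 1.0
    return Raster2D(out, pixel_size=ps)


def reconstruct_msim(stack: RawStack, optics: OpticalModel | None = None,
                     cfg: ReconFilterConfig | None = None,
                     params: EstimatedParams | None = None,
                     estimate_params: bool = False) -> ReconstructionResult:
    """Full nine-frame multifocal SIM reconstruction.

    Parameter resolution order: an explicit ``params`` argument, then the
    stack's own pattern set (known-parameter mode, the default for
    simulated data), then blind estimation from the frames
    (``estimate_params=True`` forces the latter).
    """
    if len(stack) != 9:
        raise ParameterError(f"a 3x3 multifocal stack needs exactly 9 frames, got {len(stack)}")
    if optics is None:
        optics = stack.optics
    if optics is None:
        raise ParameterError("an OpticalModel is required (stack carries none)")
    if cfg is None:
        cfg = ReconFilterConfig()
    if params is None:
        if stack.pattern_set is not None and not estimate_params:
            params = params_from_pattern_set(stack.pattern_set)
        else:
            params = estimate_pattern_parameters(stack, optics)

    frames = stack.frames
    column_recons = [
        reconstruct_group([frames[c], frames[c + 3], frames[c + 6]], "y",
                          params, optics, cfg, group_index=c)
        for c in range(3)
    ]
    row_recons = [
        reconstruct_group([frames[3 * r], frames[3 * r + 1], frames[3 * r + 2]], "x",
                          params, optics, cfg, group_index=r)
        for r in range(3)
    ]
    y_direction = cancel_stripes(column_recons)
    x_direction = cancel_stripes(row_recons)

    # photometric normalization: each directional image carries half the
    # wide-field mean, so final = x + y preserves it.
    frame_mean = float(np.mean([as_array(f).mean() for f in frames]))
    if stack.pattern_set is not None:
        illum_mean = float(np.mean([as_array(p).mean() for p in stack.pattern_set.patterns]))
        target_mean = frame_mean / max(illum_mean, 1e-300)
    else:
        target_mean = frame_mean
    for img in (x_direction, y_direction):
        mu = img.data.mean()
        if mu > 0:
            img.data *= 0.5 * target_mean / mu
        else:
            logger.warning("directional image has non-positive mean; skipping normalization")

    final = Raster2D(x_direction.data + y_direction.data,
                     pixel_size=x_direction.pixel_size)
    return ReconstructionResult(
        final=final,
        x_direction=x_direction,
        y_direction=y_direction,
        column_recons=column_recons,
        row_recons=row_recons,
        params_used=params,
    )
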