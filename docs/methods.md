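# Methods

## Imaging model

All simulation and reconstruction is 2-D, single-channel, on a regular pixel
grid: integer pixel centers, origin at index (0, 0), X = column index,
Y = row index, spatial frequencies in cycles per acquisition pixel.
Acquisition follows the incoherent wide-field model: the excitation pattern
multiplies the fluorophore density and the product is convolved with the
emission PSF.  Convolution is circular (FFT-based); stripe-phase arithmetic
and stripe cancellation are exact under periodic boundaries, at the price of
wrap-around at the frame edge, so synthetic scenes keep a margin around
their content.

The emission OTF is the diffraction-limited transfer function of a circular
pupil — the pupil autocorrelation `(2/π)(arccos ρ − ρ√(1−ρ²))` with
`ρ = |k|/k_c` — radially symmetric, 1 at DC, identically zero at and beyond
the cutoff `k_c` (≤ 0.5 cycles/px to avoid aliasing).  A compact-support
Gaussian OTF is available as a configuration alternative.  The hard zero
beyond the cutoff makes the spectral-support invariants exact to machine
precision, which the test suite exploits.

## Multifocal excitation arrays

An array is `I₀[1 + m·cos(2πk_x x + φ_x) + m·cos(2πk_y y + φ_y)]` with
values below `threshold_frac × max` set to zero.  Defaults and rationale:

- `m = 0.5` — the largest modulation for which the two-stripe superposition
  is nonnegative everywhere (each stripe contributes amplitude `m` about the
  unit mean).  Larger values are admitted but the un-thresholded field then
  dips below zero and is physically meaningful only after thresholding.
- `threshold_frac = 0.5` — the retention threshold is not fixed by theory;
  half the array maximum reproduces a sparse lattice of bright foci while
  retaining enough flux for uniform coverage (nine-pattern sum coefficient
  of variation well under 0.25 on commensurate grids).  Pixels exactly at
  the threshold are retained, with a 1e−9 relative tolerance so that
  floating-point ties resolve identically across the phase-shifted copies
  of one pattern — without it the nine patterns are not an exact
  translation family and stripe cancellation leaves a percent-level residue.
- carriers `k_x = k_y = 0.8 × k_c` unless configured; resolution gain grows
  with the carrier, so experiments probing the resolution limit use
  0.95 × k_c.  Grids on which `1/(3k)` is an integer number of pixels make
  the 2π/3 phase step an exact translation; this is recommended (and used by
  the exactness tests) but not enforced.

Thresholding sparsifies the pattern and **raises the effective modulation
depth** of its fundamental harmonic.  The reconstruction therefore never
uses the nominal `m`: `effective_modulation` measures `2|F(k₀)|/|F(0)|` on
the actual pattern and that value enters the band-separation matrix.
Thresholded arrays also contain harmonics beyond the three-term form
(2k₀, and cross terms at (±k_x, ±k_y)); for carriers above `k_c/√2` all of
them fall outside the OTF support and never reach the detector, which is the
operating regime of every default here.  At lower carriers the harmonics
alias into the separated bands and are a known artifact source.

## Noise

Detection noise is Poisson shot noise at `photon_scale` expected photons per
unit intensity (default 200 — tens of photons per pixel at typical frame
intensities, visibly noisy but reconstructable) plus additive Gaussian read
noise (default sigma = 2% of the clean frame maximum in the noise study).
One seeded generator draws all nine frames sequentially, so a stack is
reproducible from a single integer.

## Reconstruction

Band separation solves the per-frequency 3×3 system with mixing rows
`[1, (m/2)e^{−iφ_n}, (m/2)e^{+iφ_n}]`; matrices with condition number above
1e8 (repeated phases) are rejected with the condition number reported.

Band relocation embeds each separated spectrum in a grid enlarged by
`zero_pad_factor` (default 2, enough to hold the doubled support) and
realizes the — generally sub-bin — carrier shift by multiplying the
real-space field by a phase ramp `e^{2πi k₀·x}`.  The ramp uses unsigned
coordinates `x ∈ [0, N)`, the same convention under which the patterns were
generated, so a data carrier is cancelled pointwise.  For carriers that are
not integer FFT bins the relocated off-bin content is represented by its
Dirichlet (trigonometric) interpolation; identities that are exact on
commensurate grids hold only approximately off-grid, with the discrepancy
concentrated at the frame boundary.

Recombination is a generalized Wiener filter:
`Ŝ = Σ_b conj(H_b)·B_b / (Σ_b |H_b|² + w)` with `H_b` the OTF evaluated at
each band's shifted position (computed analytically on the enlarged
frequency grid, preserving exact zeros).  Choices:

- `wiener_w = 1e−2` by default — appropriate for photon-limited data, where
  it suppresses noise amplification near the edges of the shifted OTF
  supports.  Noise-free analyses use `1e−3` (the packaged
  `NOISE_FREE_FILTER`): with no noise to amplify, weak regularization keeps
  the response near unity across the whole extended support, which is what
  lets bar periods just inside the support limit retain measurable
  contrast.
- Apodization default `'diffraction'`: the disk-pupil OTF rescaled to the
  extended cutoff `k_c + |k₀|`.  Under it a point source reconstructs to an
  exactly rescaled wide-field PSF, so the measured FWHM ratio matches the
  support-ratio prediction (`≈ 1/1.9` for carriers at 0.9 k_c; measured
  0.52 for one orientation, 0.64 for the two-direction sum).  A linear
  `'triangle'` taper and `'none'` are available; `'none'` maximizes
  band-edge contrast (used in the noise-free resolution experiment) at the
  cost of ringing.

The full nine-frame pipeline reconstructs the three grid columns (Y
enhancement, shared-`φ_x` residual stripe), averages them — the 2π/3-spaced
residual phases cancel the stripe exactly, and every pattern harmonic with
any `φ_x` dependence cancels with them — then the three rows likewise, and
sums the two directional images.  Each directional image is normalized to
half the wide-field mean intensity (estimated as the frame mean divided by
the mean illumination), so the final image preserves wide-field photometry
and equals the pointwise sum of the two stored directional images.  The
center band is deliberately counted once per direction with no re-weighting,
matching the plain summation of the procedure this package implements.

Pattern parameters come from the generating `PatternSet` when the stack
carries one (known-parameter mode, the default in simulation) or are
estimated from the data: the nine-frame average — which cancels all
modulated components — is subtracted from each frame (without this, the
spectral leakage of the unmodulated component swamps off-bin carriers);
carriers are the prominent off-center peaks of the residual power spectrum
along each frequency axis, refined to sub-bin precision by maximizing the
continuous-spectrum magnitude; per-frame phases are the arguments of the
residual frames' Fourier coefficients at the carrier; modulation depths are
the OTF-compensated sideband-to-DC ratios.  A stack without a prominent
two-sided spectral peak (e.g. unmodulated frames) raises an estimation
error carrying the diagnostic spectrum.

## Synthetic data, and what it does not capture

The bar target stacks three-bar elements (50% duty cycle, 5:1 bar aspect)
at chosen periods; odd periods rasterize to alternating floor/ceil bar
widths, keeping the fundamental at `1/period`.  The photographic stand-in
(`make_natural_sample`) is a synthetic texture — power-law-filtered noise
with soft ridges — that mimics only the spectral statistics of natural
images.  The simulator omits 3-D structure, depth-induced aberration,
scattering, out-of-focus background, and camera gain/offset calibration, so
passing tests demonstrate correctness of the reconstruction arithmetic and
its behavior under shot/read noise, not robustness to the full complexity
of experimental MSIM data.

## Evaluation

Resolvability of a bar element is its Michelson contrast
`(peak − trough)/(peak + trough)`, sampled by bilinear interpolation at the
element's known bar and gap centers and averaged over the central 60% of
the bar length; negative intensities (deconvolution ringing) are clipped at
zero and contrast reversal counts as unresolved.  The criterion defaults to
0.1 — lenient enough to call a faint but clearly periodic rendition
resolved, strict enough to reject the near-zero contrast at the OTF cutoff.
FWHM is measured by linear interpolation of the half-maximum crossings
along a 1-D cut through the peak.  All metric coordinates are in
acquisition-pixel units; reconstructed images on the 2× finer grid carry
`pixel_size = 0.5` metadata so periods and widths remain directly
comparable.

## Experiment problem sizes

The packaged experiments use a 512×512 grid for the noise-free
resolution-doubling study (periods 20–4 px, cutoff 0.1, carriers 0.095) and
a 128×128 grid with 20 noise seeds for the thresholded-versus-plain pattern
comparison; both complete in seconds and their outputs are exactly what the
test suite and `scripts/acceptance.py` assert.
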