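# msim — nine-frame multifocal structured-illumination microscopy

Simulation and reconstruction tools for multifocal structured-illumination
microscopy (MSIM) using only **nine raw images**.  The package is for
microscopists and image-analysis researchers who want to prototype,
validate, or teach the reconstruction: it generates thresholded multifocal
excitation arrays, simulates raw-data acquisition under a diffraction-limited
wide-field model with realistic noise, reconstructs a super-resolved image,
and quantifies the resolution gain.

## The method

Wide-field fluorescence imaging obeys

```
I_em(x) = (I_ex(x) · S(x)) ⊗ PSF_em(x)         ⇔        Ĩ_em(k) = (Ĩ_ex ⊛ S̃)(k) · OTF_em(k)
```

so spatial frequencies of the fluorophore density `S` beyond the OTF cutoff
`k_c` are lost.  Structured illumination at carrier `k₀` mixes frequencies
`|k| ≤ k_c + k₀` into the passband: with a sinusoidal pattern
`I_ex = I₀[1 + m·cos(2πk₀x + φ)]` each acquired spectrum is the three-band
mixture

```
Ĩ_em(k) = I₀ [ S̃(k) + (m/2) S̃(k+k₀) e^{−iφ} + (m/2) S̃(k−k₀) e^{+iφ} ] · OTF_em(k).
```

Three phases stepped by 2π/3 give three independent equations per frequency;
solving them separates the bands, which are relocated in Fourier space and
recombined with a generalized Wiener filter — classical three-phase SIM,
doubling resolution along one axis.

The multifocal variant excites with the superposition of two orthogonal
stripes,

```
I_ex(x, y) = I₀ [ 1 + m·cos(2πk_x x + φ_x) + m·cos(2πk_y y + φ_y) ],
```

thresholded so that only the brightest lattice of foci survives — which
raises the effective modulation depth of the retained fundamental.  Nine
patterns on a 3×3 phase grid (2π/3 steps along X and along Y) tile the
sample uniformly.  Reconstruction proceeds:

1. **Column-wise** three-phase SIM along Y (the three frames of a grid
   column share `φ_x` and step `φ_y`).  Each result still carries the
   unprocessed X stripe.
2. The three column results have stripe phases 2π/3 apart; their **sum
   cancels the stripe exactly** (Σₙ cos(θ + 2πn/3) = 0), yielding a
   stripe-free, Y-enhanced image.
3. The same **row-wise** for X.
4. The two directional images are **summed** for isotropic twofold
   enhancement — from nine raw frames total.

## Worked example

```python
import numpy as np
from msim import *

shape = (256, 256)
optics = make_otf(shape, cutoff=0.1)                      # wide-field limit: 10 px period
params = IlluminationParams(k_x=0.095, k_y=0.095)         # carriers just under the cutoff
patterns = make_pattern_set(shape, params)

target = make_usaf_target(shape, [
    BarElement(period_px=16, orientation="vertical", position=(30, 30)),
    BarElement(period_px=8,  orientation="vertical", position=(30, 120)),
    BarElement(period_px=6,  orientation="vertical", position=(130, 30)),
])
stack = acquire_stack(target, patterns, optics)           # nine raw frames
result = reconstruct_msim(stack, cfg=NOISE_FREE_FILTER)

wf = widefield_image(target, optics)
for label, image in [("wide-field", wf), ("reconstruction", result.final)]:
    rep = resolution_report(image, target, criterion=0.1)
    rows = ", ".join(f"{e['period_px']:.0f} px: {e['michelson_contrast']:.2f}"
                     for e in rep.per_element)
    print(f"{label:15s} contrast {rows}  -> smallest resolved: "
          f"{rep.smallest_resolvable_period}")
```

prints

```
wide-field      contrast 16 px: 0.36, 8 px: 0.00, 6 px: 0.00  -> smallest resolved: 16.0
reconstruction  contrast 16 px: 1.00, 8 px: 0.62, 6 px: 0.40  -> smallest resolved: 6.0
```

With the OTF cutoff at 0.1 cycles/px the wide-field image cannot transfer
the 8-px (0.125 cycles/px) or 6-px bars at all — their Michelson contrast is
zero — while the nine-frame reconstruction, whose support extends to
`cutoff + carrier = 0.195` cycles/px, renders both with clear contrast: a
better-than-twofold improvement in the smallest resolved period on this
layout.  `result` also exposes the directional images and the three
column/row reconstructions with their residual-stripe bookkeeping.

A shell workflow is available too:

```bash
msim simulate   --sample usaf --config cfg.yaml --out stack.tif
msim reconstruct --stack stack.tif --out recon.tif [--estimate-params]
msim evaluate   --image recon.tif --target stack.target.yaml --report report.json --pixel-size 0.5
```

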