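"""Reading and writing patterns, raw stacks, samples, and reconstructions.

Images travel as single-channel 32-bit float TIFF (multi-page for stacks);
acquisition metadata travels in a YAML sidecar next to the TIFF.  Sidecar
keys for a pattern set: k_x, k_y, phi_x0, phi_y0, m, I_0, threshold_frac,
shape; a raw-stack sidecar adds the phase schedule, the optics cutoff/kind,
and the noise configuration.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import tifffile
import yaml

from .exceptions import ParameterError
from .optics import NoiseConfig, OpticalModel, RawStack, make_otf
from .patterns import IlluminationParams, PatternSet, make_pattern_set
from .raster import Raster2D, as_array

__all__ = [
    "save_image",
    "load_image",
    "save_pattern_set",
    "load_pattern_set",
    "save_stack",
    "load_stack",
    "load_sample_image",
]


def _sidecar_path(tiff_path) -> Path:
    return Path(tiff_path).with_suffix(".yaml")


def save_image(image, path) -> None:
    """Write one raster as a 32-bit float TIFF."""
    tifffile.imwrite(str(path), as_array(image).astype(np.float32))


def load_image(path, pixel_size: float = 1.0) -> Raster2D:
    return Raster2D(tifffile.imread(str(path)).astype(float), pixel_size=pixel_size)


def save_pattern_set(pattern_set: PatternSet, tiff_path, yaml_path=None) -> None:
    """Write the nine patterns as a multi-page TIFF plus a YAML sidecar."""
    yaml_path = yaml_path or _sidecar_path(tiff_path)
    arr = np.stack([as_array(p) for p in pattern_set.patterns]).astype(np.float32)
    tifffile.imwrite(str(tiff_path), arr)
    p = pattern_set.params
    meta = {
        "k_x": float(p.k_x),
        "k_y": float(p.k_y),
        "phi_x0": float(p.phi_x),
        "phi_y0": float(p.phi_y),
        "m": float(p.m),
        "I_0": float(p.I_0),
        "threshold_frac": float(p.threshold_frac),
        "shape": [int(s) for s in pattern_set.patterns[0].shape],
        "schedule": [[float(a), float(b)] for a, b in pattern_set.schedule],
    }
    Path(yaml_path).write_text(yaml.safe_dump(meta, sort_keys=False))


def load_pattern_set(tiff_path, yaml_path=None) -> PatternSet:
    yaml_path = yaml_path or _sidecar_path(tiff_path)
    meta = yaml.safe_load(Path(yaml_path).read_text())
    arr = tifffile.imread(str(tiff_path)).astype(float)
    if arr.ndim != 3 or arr.shape[0] != 9:
        raise ParameterError(f"expected a 9-page pattern TIFF, got shape {arr.shape}")
    params = IlluminationParams(
        k_x=meta["k_x"], k_y=meta["k_y"], phi_x=meta["phi_x0"], phi_y=meta["phi_y0"],
        m=meta["m"], I_0=meta["I_0"], threshold_frac=meta["threshold_frac"],
    )
    return PatternSet(
        patterns=[Raster2D(a) for a in arr],
        schedule=[tuple(s) for s in meta["schedule"]],
        params=params,
    )


def save_stack(stack: RawStack, tiff_path, yaml_path=None) -> None:
    """Write a raw stack as a 9-page TIFF plus a YAML sidecar."""
    yaml_path = yaml_path or _sidecar_path(tiff_path)
    arr = np.stack([as_array(f) for f in stack.frames]).astype(np.float32)
    tifffile.imwrite(str(tiff_path), arr)
    meta: dict = {"n_frames": len(stack.frames),
                  "shape": [int(s) for s in stack.frames[0].shape]}
    if stack.pattern_set is not None:
        p = stack.pattern_set.params
        meta["pattern"] = {
            "k_x": float(p.k_x), "k_y": float(p.k_y),
            "phi_x0": float(p.phi_x), "phi_y0": float(p.phi_y),
            "m": float(p.m), "I_0": float(p.I_0),
            "threshold_frac": float(p.threshold_frac),
        }
        meta["schedule"] = [[float(a), float(b)] for a, b in stack.pattern_set.schedule]
    if stack.optics is not None:
        meta["optics"] = {"cutoff": float(stack.optics.cutoff), "kind": stack.optics.kind}
    if stack.noise is not None:
        meta["noise"] = {
            "photon_scale": None if stack.noise.photon_scale is None else float(stack.noise.photon_scale),
            "gaussian_sigma": float(stack.noise.gaussian_sigma),
            "seed": int(stack.noise.seed),
        }
    Path(yaml_path).write_text(yaml.safe_dump(meta, sort_keys=False))


def load_stack(tiff_path, yaml_path=None) -> RawStack:
    """Load a raw stack; the pattern set and optics are rebuilt from the sidecar."""
    yaml_path = yaml_path or _sidecar_path(tiff_path)
    meta = yaml.safe_load(Path(yaml_path).read_text())
    arr = tifffile.imread(str(tiff_path)).astype(float)
    if arr.ndim != 3:
        raise ParameterError(f"expected a multi-page TIFF stack, got shape {arr.shape}")
    frames = [Raster2D(a) for a in arr]
    shape = frames[0].shape
    pattern_set = None
    if "pattern" in meta:
        pm = meta["pattern"]
        params = IlluminationParams(
            k_x=pm["k_x"], k_y=pm["k_y"], phi_x=pm["phi_x0"], phi_y=pm["phi_y0"],
            m=pm["m"], I_0=pm["I_0"], threshold_frac=pm["threshold_frac"],
        )
        pattern_set = make_pattern_set(shape, params,
                                       phase_origin=(pm["phi_x0"], pm["phi_y0"]))
    optics = None
    if "optics" in meta:
        optics = make_otf(shape, meta["optics"]["cutoff"],
                          kind=meta["optics"].get("kind", "disk"))
    noise = None
    if "noise" in meta:
        nm = meta["noise"]
        noise = NoiseConfig(photon_scale=nm["photon_scale"],
                            gaussian_sigma=nm["gaussian_sigma"], seed=nm["seed"])
    return RawStack(frames=frames, pattern_set=pattern_set, optics=optics, noise=noise)


def load_sample_image(path) -> Raster2D:
    """Load any single-channel image file as a sample, normalized to [0, 1]."""
    p = Path(path)
    if p.suffix.lower() in (".tif", ".tiff"):
        arr = tifffile.imread(str(p)).astype(float)
    else:
        import imageio.v3 as iio

        arr = np.asarray(iio.imread(str(p)), dtype=float)
    if arr.ndim == 3:
        arr = arr.mean(axis=-1)
    arr = arr - arr.min()
    if arr.max() > 0:
        arr = arr / arr.max()
    return Raster2D(arr)
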