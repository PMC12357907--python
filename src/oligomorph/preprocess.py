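"""Image conditioning chain.

Order of the canonical chain: 8-bit conversion, pseudo-flat-field correction,
median smoothing, sliding-paraboloid background subtraction, contrast
enhancement.  Channel routing (which channel gets which steps) lives in the
pipeline configuration; each function here is channel-agnostic.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy import ndimage as ndi
from skimage.morphology import disk

from oligomorph.image import ChannelImage

log = logging.getLogger(__name__)

_EPS = 1e-6


def to_8bit(image: ChannelImage) -> ChannelImage:
    """Linearly rescale the image's own min-max range to [0, 255].

    A constant image has zero dynamic range and maps to all zeros.
    """
    px = np.asarray(image.pixels, dtype=float)
    if px.size == 0:
        raise ValueError("empty image")
    lo, hi = float(px.min()), float(px.max())
    if hi <= lo:
        out = np.zeros_like(px, dtype=np.uint8)
    else:
        scaled = (px - lo) * 255.0 / (hi - lo)
        out = np.floor(scaled + 0.5).astype(np.uint8)  # round half up
    img = image.with_pixels(out, "to_8bit")
    img.bit_depth = 8
    return img


def pseudo_flat_field(image: ChannelImage, blur_radius_px: float) -> ChannelImage:
    """Divide by a heavily blurred copy of the image, preserving the mean.

    Approximates multiplicative shading removal when the blur radius is much
    larger than any real structure; output clipped to [0, 255].
    """
    if blur_radius_px < 1:
        raise ValueError("blur_radius_px must be >= 1")
    if blur_radius_px < min(image.shape) / 10:
        log.warning("pseudo_flat_field blur radius %.1f px is small relative to the "
                    "image and may flatten real structure", blur_radius_px)
    px = np.asarray(image.pixels, dtype=float)
    # radius ~ 3 sigma; normalized convolution so edges average in-image pixels only
    sigma = blur_radius_px / 3.0
    weight = ndi.gaussian_filter(np.ones_like(px), sigma=sigma, mode="constant")
    background = ndi.gaussian_filter(px, sigma=sigma, mode="constant") / np.maximum(weight, _EPS)
    corrected = px / np.maximum(background, _EPS)
    mean_in = px.mean()
    mean_corr = corrected.mean()
    if mean_corr > _EPS:
        corrected *= mean_in / mean_corr
    out = np.clip(np.round(corrected), 0, 255).astype(image.pixels.dtype)
    return image.with_pixels(out, f"pseudo_flat_field(r={blur_radius_px:g})")


def median_smooth(image: ChannelImage, radius_px: int) -> ChannelImage:
    """Median filter over a disc neighbourhood with reflective edges."""
    if radius_px < 1:
        raise ValueError("radius_px must be >= 1")
    footprint = disk(radius_px)
    out = ndi.median_filter(image.pixels, footprint=footprint, mode="reflect")
    return image.with_pixels(out, f"median_smooth(r={radius_px})")


def _paraboloid_1d(radius_px: float, half_width: int) -> np.ndarray:
    d = np.arange(-half_width, half_width + 1, dtype=float)
    return -(d**2) / (2.0 * radius_px)


def subtract_background_paraboloid(image: ChannelImage, radius_px: float) -> ChannelImage:
    """Estimate background by sliding a paraboloid under the intensity surface.

    Implemented as grayscale opening with a paraboloid-shaped structuring
    function z = -d^2 / (2 r), separable along rows and columns under the
    (min, +)/(max, +) algebra, then subtracted; result is >= 0.
    """
    if radius_px < 1:
        raise ValueError("radius_px must be >= 1")
    px = np.asarray(image.pixels, dtype=float)
    # beyond this distance the paraboloid is deeper than the full 8-bit range
    half = int(min(np.ceil(np.sqrt(2.0 * radius_px * 255.0)), max(px.shape)))
    kern = _paraboloid_1d(radius_px, half)
    bg = px
    for axis in (0, 1):
        shape = [1, 1]
        shape[axis] = kern.size
        bg = ndi.grey_erosion(bg, structure=kern.reshape(shape), mode="nearest")
    for axis in (0, 1):
        shape = [1, 1]
        shape[axis] = kern.size
        bg = ndi.grey_dilation(bg, structure=kern.reshape(shape), mode="nearest")
    out = np.clip(np.round(px - bg), 0, 255).astype(image.pixels.dtype)
    return image.with_pixels(out, f"subtract_background_paraboloid(r={radius_px:g})")


def enhance_contrast(image: ChannelImage, saturated_fraction: float) -> ChannelImage:
    """Linear stretch saturating ``saturated_fraction`` of pixels symmetrically.

    The saturated_fraction/2 and 1 - saturated_fraction/2 quantiles map to 0
    and 255; values outside clip.
    """
    if not (0 <= saturated_fraction < 0.5):
        raise ValueError("saturated_fraction must be in [0, 0.5)")
    px = np.asarray(image.pixels, dtype=float)
    lo = np.quantile(px, saturated_fraction / 2)
    hi = np.quantile(px, 1 - saturated_fraction / 2)
    if hi <= lo:
        log.warning("enhance_contrast: zero dynamic range, image returned unchanged")
        return image.with_pixels(image.pixels.copy(), "enhance_contrast(degenerate)")
    out = np.clip(np.round((px - lo) * (255.0 / (hi - lo))), 0, 255)
    return image.with_pixels(out.astype(image.pixels.dtype),
                             f"enhance_contrast(sat={saturated_fraction:g})")


# canonical per-channel step routing; the pipeline reads these defaults
DEFAULT_ROUTING: dict[str, tuple[str, ...]] = {
    # flat-field on MBP and O4; background subtraction on O4 and DAPI;
    # contrast enhancement on DAPI and O4; median smoothing on all
    "DAPI": ("to_8bit", "median_smooth", "subtract_background_paraboloid", "enhance_contrast"),
    "O4": ("to_8bit", "pseudo_flat_field", "median_smooth",
           "subtract_background_paraboloid", "enhance_contrast"),
    "MBP": ("to_8bit", "pseudo_flat_field", "median_smooth"),
}

DEFAULT_PARAMS: dict[str, dict] = {
    "pseudo_flat_field": {"blur_radius_px": None},  # None -> image width / 3
    "median_smooth": {"radius_px": 2},
    "subtract_background_paraboloid": {"radius_px": 50},
    "enhance_contrast": {"saturated_fraction": 0.0035},
}

_STEP_FUNCS = {
    "to_8bit": to_8bit,
    "pseudo_flat_field": pseudo_flat_field,
    "median_smooth": median_smooth,
    "subtract_background_paraboloid": subtract_background_paraboloid,
    "enhance_contrast": enhance_contrast,
}


def run_chain(image: ChannelImage, steps: tuple[str, ...] | None = None,
              params: dict[str, dict] | None = None) -> ChannelImage:
    """Apply the canonical conditioning chain for the image's channel.

    ``steps`` overrides the default routing (explicit scrambling is allowed but
    must be requested); ``params`` overrides per-step keyword arguments.
    """
    if steps is None:
        steps = DEFAULT_ROUTING[image.channel]
    merged = {k: dict(v) for k, v in DEFAULT_PARAMS.items()}
    for k, v in (params or {}).items():
        merged.setdefault(k, {}).update(v)
    out = image
    for step in steps:
        if step not in _STEP_FUNCS:
            raise ValueError(f"unknown preprocessing step {step!r}")
        kwargs = dict(merged.get(step, {}))
        if step == "pseudo_flat_field" and kwargs.get("blur_radius_px") is None:
            kwargs["blur_radius_px"] = out.shape[1] / 3
        out = _STEP_FUNCS[step](out, **kwargs)
    return out
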