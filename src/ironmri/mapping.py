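"""Pixel-wise T2* estimation and parametric map rendering.

The pixel-based route fits the mono-exponential model to every in-mask
pixel's own echo time-course and assembles the estimates into a
:class:`T2StarMap`; ROI statistics are then taken over the map.  This is
the generic counterpart of vendor colour-map tools, and deliberately the
opposite order of operations from :func:`ironmri.relaxometry.roi_mean_series`
(fit-then-average vs average-then-fit): the two agree exactly on noiseless
uniform data and diverge on noisy data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .core import EchoTrain, ImageStack
from .exceptions import (DegenerateFitError, EmptyROIError, InvalidInputError)
from .relaxometry import MonoExponentialDecayModel, TruncationPolicy

__all__ = ["T2StarMap", "pixelwise_fit", "map_roi_mean", "render_map"]

logger = logging.getLogger(__name__)

#: colours reserved for pixels without a valid fit (RGB, 0-255)
INVALID_COLOR = (0, 0, 0)

#: default colour scales (ms) spanning the clinically relevant ranges
DEFAULT_COLOR_SCALES = {"heart": (0.0, 50.0), "liver": (0.0, 20.0),
                        "pancreas": (0.0, 20.0)}


@dataclass(frozen=True)
class T2StarMap:
    """Per-pixel T2* (ms) with a validity mask.

    ``values`` is NaN wherever ``valid`` is False; all defined values are
    positive.
    """

    values: np.ndarray
    valid: np.ndarray
    echo_train: EchoTrain

    def __post_init__(self) -> None:
        if self.values.shape != self.valid.shape:
            raise InvalidInputError("values and valid grids must match in shape")

    @property
    def n_valid(self) -> int:
        return int(self.valid.sum())


def pixelwise_fit(stack: ImageStack, mask: np.ndarray,
                  policy: TruncationPolicy | None = None) -> T2StarMap:
    """Fit every in-mask pixel independently.

    Pixels whose fit fails (non-decaying time-course, optimizer failure,
    too few positive signals) are marked invalid — never interpolated or
    fabricated — and their count is logged.

    Parameters
    ----------
    stack : ImageStack
    mask : boolean array, same spatial shape as the stack
    policy : TruncationPolicy, optional
        When given, each pixel fit applies automated late-echo truncation.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != stack.spatial_shape:
        raise InvalidInputError(
            f"mask shape {mask.shape} does not match stack {stack.spatial_shape}"
        )
    if not mask.any():
        raise InvalidInputError("ROI mask is empty")

    values = np.full(stack.spatial_shape, np.nan)
    valid = np.zeros(stack.spatial_shape, dtype=bool)
    n_failed = 0
    for iy, ix in zip(*np.nonzero(mask)):
        model = MonoExponentialDecayModel(stack.echo_train,
                                          stack.data[iy, ix, :])
        try:
            res = model.fit(truncation=policy)
        except (DegenerateFitError, InvalidInputError):
            n_failed += 1
            continue
        values[iy, ix] = res.t2star
        valid[iy, ix] = True
    if n_failed:
        logger.info("pixelwise_fit: %d of %d pixels failed and were marked "
                    "invalid", n_failed, int(mask.sum()))
    return T2StarMap(values=values, valid=valid, echo_train=stack.echo_train)


def map_roi_mean(t2map: T2StarMap, mask: np.ndarray) -> tuple[float, int]:
    """Arithmetic mean of valid in-mask map values.

    Returns
    -------
    (mean_t2star_ms, n_excluded) : tuple
        ``n_excluded`` counts in-mask pixels without a valid fit.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != t2map.values.shape:
        raise InvalidInputError("mask shape does not match map")
    use = mask & t2map.valid
    n_excluded = int(mask.sum() - use.sum())
    if not use.any():
        raise EmptyROIError("no valid pixels inside the ROI")
    return float(t2map.values[use].mean()), n_excluded


def render_map(t2map: T2StarMap, color_scale: tuple[float, float],
               path=None, cmap: str = "turbo") -> np.ndarray:
    """Render the map to an RGB image with a fixed value-to-colour mapping.

    Values are clipped to ``color_scale = (lo, hi)`` in ms and mapped
    linearly through the named matplotlib colormap; invalid pixels get the
    reserved colour ``INVALID_COLOR`` (black).  Rendering is deterministic:
    the same map yields a byte-identical PNG.

    Returns the uint8 RGB array; writes a PNG when ``path`` is given.
    """
    import matplotlib

    lo, hi = float(color_scale[0]), float(color_scale[1])
    if not hi > lo:
        raise InvalidInputError(f"empty colour range ({lo}, {hi})")
    norm = np.clip((np.nan_to_num(t2map.values, nan=lo) - lo) / (hi - lo), 0, 1)
    rgba = matplotlib.colormaps[cmap](norm)
    rgb = np.round(rgba[..., :3] * 255).astype(np.uint8)
    rgb[~t2map.valid] = INVALID_COLOR
    if path is not None:
        from PIL import Image

        Image.fromarray(rgb, mode="RGB").save(path, format="PNG")
    return rgb
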