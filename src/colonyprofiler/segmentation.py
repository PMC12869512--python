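"""Colony segmentation on the reference channel.

The colony footprint is defined once, on the reference-marker channel
(the channel stained to delineate the colony), by Gaussian smoothing followed
by thresholding — Otsu by default, or a user-fixed value.  Holes are filled,
objects smaller than a 20 µm disk are rejected as debris, and each remaining
connected component becomes one :class:`ColonyMask`.  The same footprint and
threshold are then reused for every quantified channel of that colony, so that
section comparisons across channels are over identical pixels.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage import filters, measure, morphology

from .stack_io import ConfigError, FieldStack, RunConfig, logger


@dataclass
class ColonyMask:
    """A single colony footprint with segmentation provenance."""

    mask: np.ndarray
    colony_id: str
    source_plane: int
    source_channel: str
    threshold_used: float
    pixel_size: float
    touches_border: bool = False

    @property
    def area_px(self) -> int:
        return int(self.mask.sum())

    @property
    def equivalent_diameter(self) -> float:
        """Diameter (µm) of the disk with the same area as the mask."""
        return 2.0 * math.sqrt(self.area_px / math.pi) * self.pixel_size


def _min_area_px(config: RunConfig, pixel_size: float) -> int:
    r_px = (config.min_object_diameter / 2.0) / pixel_size
    return max(1, int(round(math.pi * r_px * r_px)))


def segment_colony(
    stack: FieldStack,
    plane: int,
    config: RunConfig,
    id_prefix: str = "colony",
) -> list[ColonyMask]:
    """Segment colony footprints on one plane of the reference channel.

    The reference plane is Gaussian-smoothed (``config.smoothing_sigma`` µm),
    thresholded (Otsu or fixed), hole-filled, and cleaned of objects below the
    minimum-area floor.  One :class:`ColonyMask` per connected component is
    returned, largest first; masks are disjoint and hole-free by construction.
    Components touching the image border have a censored distance-to-background
    and are dropped when ``config.exclude_border`` (the default), with a log
    notice.  No foreground at all yields an empty list plus a warning, not an
    exception.
    """
    img = stack.plane("reference_marker", plane)
    sigma_px = config.smoothing_sigma / stack.pixel_size
    smoothed = filters.gaussian(img, sigma=sigma_px, preserve_range=True) if sigma_px > 0 else img

    if config.threshold == "fixed":
        thr = float(config.threshold_value)
        lo, hi = float(img.min()), float(img.max())
        if not lo <= thr <= hi:
            raise ConfigError(
                f"fixed threshold {thr} outside intensity range [{lo}, {hi}] of the reference plane"
            )
    else:
        if np.ptp(smoothed) == 0:
            logger.warning("segment_colony: constant reference plane, no foreground")
            return []
        thr = float(filters.threshold_otsu(smoothed))

    binary = smoothed > thr
    binary = ndi.binary_fill_holes(binary)
    binary = morphology.remove_small_objects(binary, max_size=_min_area_px(config, stack.pixel_size) - 1)
    if not binary.any():
        logger.warning("segment_colony: no foreground after thresholding (plane %d)", plane)
        return []

    labeled = measure.label(binary, connectivity=1)
    masks: list[ColonyMask] = []
    border = np.zeros_like(binary)
    border[0, :] = border[-1, :] = border[:, 0] = border[:, -1] = True
    comps = sorted(
        range(1, labeled.max() + 1), key=lambda l: -(labeled == l).sum()
    )
    kept = 0
    for lab in comps:
        comp = labeled == lab
        touches = bool((comp & border).any())
        if touches and config.exclude_border:
            logger.info("segment_colony: dropping border-touching component (plane %d)", plane)
            continue
        kept += 1
        masks.append(
            ColonyMask(
                mask=comp,
                colony_id=f"{id_prefix}_{kept:02d}",
                source_plane=plane,
                source_channel="reference_marker",
                threshold_used=thr,
                pixel_size=stack.pixel_size,
                touches_border=touches,
            )
        )
    return masks


def filter_colonies(masks: list[ColonyMask], config: RunConfig) -> list[ColonyMask]:
    """Keep colonies whose equivalent diameter lies in the advisory window.

    The window bounds are inclusive; a ``colony_diameter_window`` of ``None``
    disables the filter and returns the input unchanged.  An empty result is
    permitted.
    """
    if config.colony_diameter_window is None:
        return list(masks)
    lo, hi = config.colony_diameter_window
    return [m for m in masks if lo <= m.equivalent_diameter <= hi]
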