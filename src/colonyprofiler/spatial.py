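"""Fractional-depth plane selection and concentric-ring intensity profiling.

A segmented colony footprint is partitioned into concentric sections by the
Euclidean distance of every colony pixel to the nearest background pixel: the
outer ring spans the first 15 µm inwards from the periphery (roughly one cell),
the middle ring the next 15 µm, and the inner section is the remaining area.
Section mean intensities are expressed relative to the whole-colony mean on the
same plane, which makes them invariant to per-plane illumination or staining
scale.  Three planes — at 30 %, 50 % and 70 % of the stack depth — are analysed
per colony and their relative means pooled by an unweighted average.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import ndimage as ndi

from .segmentation import ColonyMask
from .stack_io import ConfigError, FieldStack, SECTIONS

#: integer codes used in RingPartition.labels
BACKGROUND = 0
SECTION_CODES = {name: i + 1 for i, name in enumerate(SECTIONS)}


def select_planes(plane_count: int, depth_fractions: Sequence[float]) -> list[int]:
    """1-based plane indices at the given fractional depths of a z-stack.

    Each fraction ``f`` maps to ``round(f * plane_count)`` with ties rounded
    away from zero, clamped to ``[1, plane_count]``; duplicates are dropped
    and the result is sorted.  A 100-plane stack with the default fractions
    (0.30, 0.50, 0.70) therefore yields planes 30, 50 and 70.
    """
    if plane_count < 1:
        raise ConfigError(f"plane_count must be >= 1, got {plane_count}")
    for f in depth_fractions:
        if not 0 < f <= 1:
            raise ConfigError(f"depth fraction {f} outside (0, 1]")
    # round half away from zero (fractions are positive, so floor(x + 0.5))
    idx = {min(plane_count, max(1, math.floor(f * plane_count + 0.5)))
           for f in depth_fractions}
    return sorted(idx)


@dataclass
class RingPartition:
    """Per-pixel section labels for one colony footprint.

    ``labels`` is an integer grid: 0 background, 1 outer, 2 middle, 3 inner.
    ``distance_map`` holds each pixel's Euclidean distance to the nearest
    background pixel in µm (0 outside the mask).
    """

    labels: np.ndarray
    widths_used: tuple[float, ...]
    distance_map: np.ndarray
    section_names: tuple[str, ...] = SECTIONS

    def section_mask(self, name: str) -> np.ndarray:
        return self.labels == SECTION_CODES[name]


def partition_rings(
    mask: ColonyMask | np.ndarray,
    pixel_size: float,
    widths: Sequence[float] = (15.0, 15.0),
    section_names: Sequence[str] = SECTIONS,
) -> RingPartition:
    """Partition a colony mask into concentric sections by distance inwards.

    The distance transform assigns every colony pixel its Euclidean distance
    (in pixels, scaled to µm) to the nearest background pixel.  With widths
    ``(w1, w2)`` the outer section is ``0 < d <= w1``, the middle
    ``w1 < d <= w1 + w2`` and the inner everything deeper — half-open toward
    the interior so each pixel receives exactly one label.  Sections may be
    empty (a colony thinner than the first ring is entirely outer); this is
    recorded, not an error.
    """
    if pixel_size <= 0:
        raise ConfigError(f"pixel_size must be > 0, got {pixel_size}")
    if any(w <= 0 for w in widths):
        raise ConfigError(f"ring widths must be > 0, got {list(widths)}")
    if len(section_names) != len(widths) + 1:
        raise ConfigError("need exactly one more section name than ring widths")
    grid = mask.mask if isinstance(mask, ColonyMask) else np.asarray(mask, bool)
    if not grid.any():
        raise ValueError("partition_rings: empty mask")
    dist = ndi.distance_transform_edt(grid) * pixel_size
    cum = np.cumsum(list(widths))
    labels = np.zeros(grid.shape, dtype=np.uint8)
    inside = grid
    labels[inside] = 1 + np.digitize(dist[inside], cum, right=True)
    return RingPartition(
        labels=labels,
        widths_used=tuple(float(w) for w in widths),
        distance_map=dist,
        section_names=tuple(section_names),
    )


@dataclass
class SectionProfile:
    """Mean intensity of each colony section on one plane of one channel.

    ``section_means`` maps each section name plus ``"total"`` to the
    arithmetic mean of raw intensities over that region (NaN for an empty
    section).  ``relative_means`` divides each section mean by the total
    colony mean; undefined values (empty section, zero total) stay NaN and
    the profile is flagged.
    """

    colony_id: str
    plane: int
    channel: str
    section_means: Mapping[str, float]
    relative_means: Mapping[str, float]
    section_areas: Mapping[str, int]
    flags: list[str] = field(default_factory=list)

    @property
    def section_names(self) -> list[str]:
        return [s for s in self.section_means if s != "total"]

    def to_rows(self) -> list[dict]:
        rows = []
        for sec in [*self.section_names, "total"]:
            rows.append(
                {
                    "colony_id": self.colony_id,
                    "plane": self.plane,
                    "channel": self.channel,
                    "section": sec,
                    "area_px": self.section_areas[sec],
                    "mean_intensity": self.section_means[sec],
                    "relative_mean": 1.0 if sec == "total" else self.relative_means[sec],
                    "flags": ";".join(self.flags),
                }
            )
        return rows


def section_means(
    stack: FieldStack,
    plane: int,
    channel: str,
    partition: RingPartition,
    colony_id: str = "colony",
) -> SectionProfile:
    """Raw and relative section means for one plane/channel of a colony.

    The total mean is computed over the full mask; by construction it equals
    the area-weighted average of the section means, and the area-weighted
    average of the relative means is 1 whenever all sections are non-empty.
    """
    img = stack.plane(channel, plane)
    if img.shape != partition.labels.shape:
        raise ValueError("partition grid does not match stack frame shape")
    flags: list[str] = []
    means: dict[str, float] = {}
    areas: dict[str, int] = {}
    for name in partition.section_names:
        sel = partition.section_mask(name)
        areas[name] = int(sel.sum())
        if areas[name] == 0:
            means[name] = float("nan")
            flags.append(f"empty_section:{name}")
        else:
            means[name] = float(img[sel].mean())
    whole = partition.labels != BACKGROUND
    areas["total"] = int(whole.sum())
    means["total"] = float(img[whole].mean())
    rel: dict[str, float] = {}
    if means["total"] == 0:
        flags.append("zero_total_mean")
        rel = {name: float("nan") for name in partition.section_names}
    else:
        rel = {name: means[name] / means["total"] for name in partition.section_names}
    return SectionProfile(
        colony_id=colony_id,
        plane=plane,
        channel=channel,
        section_means=means,
        relative_means=rel,
        section_areas=areas,
        flags=flags,
    )


@dataclass
class ColonyRecord:
    """Per-colony relative section means pooled over the analysed planes."""

    colony_id: str
    treatment: str
    biological_replicate: str
    channel: str
    relative_means: Mapping[str, float]
    n_planes_pooled: int
    flags: list[str] = field(default_factory=list)

    def to_rows(self) -> list[dict]:
        return [
            {
                "colony_id": self.colony_id,
                "treatment": self.treatment,
                "biological_replicate": self.biological_replicate,
                "channel": self.channel,
                "section": sec,
                "relative_mean": val,
                "n_planes_pooled": self.n_planes_pooled,
                "flags": ";".join(self.flags),
            }
            for sec, val in self.relative_means.items()
        ]


def pool_colony(
    profiles: Sequence[SectionProfile],
    treatment: str = "",
    biological_replicate: str = "",
) -> ColonyRecord:
    """Unweighted mean of per-plane relative section means for one colony.

    All profiles must share colony id and channel.  A section missing (NaN)
    on any plane propagates as missing in the pooled record.
    """
    profiles = list(profiles)
    if not profiles:
        raise ValueError("pool_colony: empty profile list")
    ids = {p.colony_id for p in profiles}
    channels = {p.channel for p in profiles}
    if len(ids) > 1 or len(channels) > 1:
        raise ValueError(
            f"pool_colony: profiles mix colonies {sorted(ids)} / channels {sorted(channels)}"
        )
    sections = profiles[0].section_names
    pooled = {
        sec: float(np.mean([p.relative_means[sec] for p in profiles])) for sec in sections
    }
    flags = sorted({f for p in profiles for f in p.flags})
    return ColonyRecord(
        colony_id=profiles[0].colony_id,
        treatment=treatment,
        biological_replicate=biological_replicate,
        channel=profiles[0].channel,
        relative_means=pooled,
        n_planes_pooled=len(profiles),
        flags=flags,
    )
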