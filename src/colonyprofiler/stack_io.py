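"""Image-stack and table I/O, plus run configuration.

The pipeline's in-memory image container is :class:`FieldStack`, a
four-dimensional intensity grid indexed ``(channel, plane, row, col)`` with a
micrometre pixel calibration and a role assigned to every channel.  Stacks are
persisted as multi-page TIFF with the axis order recorded in the ImageJ-style
metadata; tables go through CSV.  :class:`RunConfig` holds every tunable of the
ring-quantification macro (ring widths, fractional depths, threshold mode,
significance level) and validates itself on construction.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import tifffile
import yaml

logger = logging.getLogger("colonyprofiler")

#: channel roles understood by the pipeline
CHANNEL_ROLES = (
    "nuclear",
    "reference_marker",
    "quantified_marker_1",
    "quantified_marker_2",
)

#: colony section names, ordered from the periphery inwards
SECTIONS = ("outer", "middle", "inner")


class ConfigError(ValueError):
    """Raised when a configuration value violates its contract."""


class FormatError(ValueError):
    """Raised when an input file does not match the expected layout."""


@dataclass
class FieldStack:
    """A multi-channel, multi-plane field of view with µm calibration.

    Parameters
    ----------
    intensities
        Array of shape ``(n_channels, n_planes, rows, cols)``; finite,
        non-negative.
    channel_roles
        Maps channel index to one of :data:`CHANNEL_ROLES`.  Exactly one
        channel must carry the ``reference_marker`` role (the channel the
        colony boundary is thresholded on).
    pixel_size
        Lateral pixel size in µm/pixel.
    provenance
        Free-text source note (path, acquisition comment).
    """

    intensities: np.ndarray
    channel_roles: Mapping[int, str]
    pixel_size: float
    provenance: str = ""

    def __post_init__(self) -> None:
        arr = np.asarray(self.intensities, dtype=float)
        if arr.ndim != 4:
            raise FormatError(
                f"intensities must be 4-D (channel, plane, row, col); got ndim={arr.ndim}"
            )
        if not np.all(np.isfinite(arr)):
            raise FormatError("intensities must be finite")
        if arr.min() < 0:
            raise FormatError("intensities must be non-negative")
        if self.pixel_size <= 0:
            raise ConfigError(f"pixel_size must be > 0, got {self.pixel_size}")
        roles = dict(self.channel_roles)
        if set(roles) != set(range(arr.shape[0])):
            raise ConfigError(
                f"channel_roles keys {sorted(roles)} do not match channel axis "
                f"of length {arr.shape[0]}"
            )
        for idx, role in roles.items():
            if role not in CHANNEL_ROLES:
                raise ConfigError(f"unknown channel role {role!r} for channel {idx}")
        n_ref = sum(1 for r in roles.values() if r == "reference_marker")
        if n_ref != 1:
            raise ConfigError(
                f"exactly one reference_marker channel required, found {n_ref}"
            )
        self.intensities = arr
        self.channel_roles = roles

    # -- convenience accessors -------------------------------------------------
    @property
    def n_channels(self) -> int:
        return self.intensities.shape[0]

    @property
    def n_planes(self) -> int:
        return self.intensities.shape[1]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.intensities.shape[2:]

    def channel_index(self, role: str) -> int:
        """Index of the (unique) channel carrying *role*."""
        hits = [i for i, r in self.channel_roles.items() if r == role]
        if not hits:
            raise ConfigError(f"no channel with role {role!r}")
        if len(hits) > 1:
            raise ConfigError(f"multiple channels with role {role!r}")
        return hits[0]

    def plane(self, role: str, plane: int) -> np.ndarray:
        """2-D view of one plane (1-based index) of the channel with *role*."""
        if not 1 <= plane <= self.n_planes:
            raise IndexError(f"plane {plane} out of range 1..{self.n_planes}")
        return self.intensities[self.channel_index(role), plane - 1]

    @property
    def quantified_roles(self) -> list[str]:
        return [
            r
            for r in ("quantified_marker_1", "quantified_marker_2")
            if any(v == r for v in self.channel_roles.values())
        ]


@dataclass
class RunConfig:
    """All tunables of the ring-quantification pipeline.

    Defaults reproduce the standard macro: two 15 µm rings (outer, middle)
    with the remainder as the inner section, planes analysed at 30/50/70 %
    of the stack depth, Otsu thresholding of the smoothed reference channel,
    an advisory 80–100 µm colony diameter window, and alpha = 0.05.
    """

    ring_widths: Sequence[float] = (15.0, 15.0)
    section_names: Sequence[str] = SECTIONS
    depth_fractions: Sequence[float] = (0.30, 0.50, 0.70)
    threshold: str = "otsu"  # "otsu" | "fixed"
    threshold_value: float | None = None
    smoothing_sigma: float = 1.0  # µm
    colony_diameter_window: tuple[float, float] | None = (80.0, 100.0)
    min_object_diameter: float = 20.0  # µm; debris rejection floor
    exclude_border: bool = True
    segment_per_plane: bool = False
    normalize_per_plane: bool = True
    alpha: float = 0.05
    aggregation_mode: str = "technical"  # "technical" | "biological"
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if any(w <= 0 for w in self.ring_widths):
            raise ConfigError(f"ring_widths must all be > 0, got {list(self.ring_widths)}")
        if len(self.section_names) != len(self.ring_widths) + 1:
            raise ConfigError(
                "section_names must have one more entry than ring_widths "
                f"({len(self.section_names)} names for {len(self.ring_widths)} widths)"
            )
        fr = list(self.depth_fractions)
        if any(not (0 < f <= 1) for f in fr):
            raise ConfigError(f"depth_fractions must lie in (0, 1], got {fr}")
        if any(b <= a for a, b in zip(fr, fr[1:])):
            raise ConfigError(f"depth_fractions must be strictly increasing, got {fr}")
        if self.threshold not in ("otsu", "fixed"):
            raise ConfigError(f"threshold must be 'otsu' or 'fixed', got {self.threshold!r}")
        if self.threshold == "fixed" and self.threshold_value is None:
            raise ConfigError("threshold 'fixed' requires threshold_value")
        if self.smoothing_sigma < 0:
            raise ConfigError(f"smoothing_sigma must be >= 0, got {self.smoothing_sigma}")
        if self.colony_diameter_window is not None:
            lo, hi = self.colony_diameter_window
            if not (0 < lo <= hi):
                raise ConfigError(
                    f"colony_diameter_window must satisfy 0 < min <= max, got {(lo, hi)}"
                )
        if not 0 < self.alpha < 1:
            raise ConfigError(f"alpha must lie in (0, 1), got {self.alpha}")
        if self.aggregation_mode not in ("technical", "biological"):
            raise ConfigError(
                f"aggregation_mode must be 'technical' or 'biological', got {self.aggregation_mode!r}"
            )

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["ring_widths"] = list(self.ring_widths)
        d["section_names"] = list(self.section_names)
        d["depth_fractions"] = list(self.depth_fractions)
        if self.colony_diameter_window is not None:
            d["colony_diameter_window"] = list(self.colony_diameter_window)
        return d

    @classmethod
    def from_file(cls, path: str | Path, **overrides) -> "RunConfig":
        """Load a YAML or JSON config document; keyword overrides win."""
        path = Path(path)
        text = path.read_text()
        data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        if data is None:
            data = {}
        if not isinstance(data, dict):
            raise ConfigError(f"config file {path} must hold a mapping")
        unknown = set(data) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ConfigError(f"unknown config fields in {path}: {sorted(unknown)}")
        data.update({k: v for k, v in overrides.items() if v is not None})
        if "colony_diameter_window" in data and data["colony_diameter_window"] is not None:
            data["colony_diameter_window"] = tuple(data["colony_diameter_window"])
        return cls(**data)


# -- TIFF stack I/O ---------------------------------------------------------------


def write_stack(stack: FieldStack, path: str | Path) -> Path:
    """Write a FieldStack as multi-page TIFF with CZYX axis order.

    Channel roles, pixel size and provenance are stored in the TIFF
    description as JSON so a round trip preserves them.
    """
    path = Path(path)
    meta = {
        "axes": "CZYX",
        "pixel_size_um": stack.pixel_size,
        "channel_roles": {str(k): v for k, v in stack.channel_roles.items()},
        "provenance": stack.provenance,
    }
    tifffile.imwrite(
        path, stack.intensities.astype(np.float32), metadata=meta, photometric="minisblack"
    )
    return path


def read_stack(
    path: str | Path,
    channel_role_map: Mapping[int, str] | None = None,
    pixel_size: float | None = None,
) -> FieldStack:
    """Read a TIFF stack into a validated :class:`FieldStack`.

    An explicit ``pixel_size`` argument always overrides the value stored in
    the file metadata; likewise ``channel_role_map``.  2-D and 3-D files are
    promoted to 4-D: a 3-D array is taken as ``(plane, row, col)`` for a
    single channel unless metadata says ``CYX``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with tifffile.TiffFile(path) as tf:
        arr = tf.asarray()
        meta = tf.shaped_metadata[0] if tf.shaped_metadata else {}
    axes = meta.get("axes", "")
    if arr.ndim == 2:
        arr = arr[None, None]
    elif arr.ndim == 3:
        arr = arr[:, None] if axes == "CYX" else arr[None]
    elif arr.ndim == 4:
        if axes == "ZCYX":
            arr = arr.transpose(1, 0, 2, 3)
        # CZYX (ours) or unmarked: assume channel-major
    else:
        raise FormatError(f"{path}: cannot interpret TIFF with ndim={arr.ndim}")
    roles = channel_role_map
    if roles is None:
        stored = meta.get("channel_roles")
        if stored is None:
            raise ConfigError(f"{path}: no channel_role_map given and none stored in file")
        roles = {int(k): v for k, v in stored.items()}
    px = pixel_size if pixel_size is not None else meta.get("pixel_size_um")
    if px is None:
        raise ConfigError(f"{path}: pixel size missing from metadata; pass pixel_size explicitly")
    return FieldStack(
        intensities=np.asarray(arr, dtype=float),
        channel_roles=dict(roles),
        pixel_size=float(px),
        provenance=meta.get("provenance") or str(path),
    )


# -- tabular result I/O -----------------------------------------------------------


def write_results(records: Sequence, path: str | Path) -> Path:
    """Serialize a homogeneous list of result records to CSV.

    Accepts lists of :class:`~colonyprofiler.spatial.SectionProfile`,
    :class:`~colonyprofiler.spatial.ColonyRecord` or
    :class:`~colonyprofiler.stats.StatResult` — anything exposing
    ``to_rows()`` returning a list of flat dicts.  Profiles expand to one row
    per (colony, plane, channel, section) including the ``total`` section.
    """
    records = list(records)
    if not records:
        raise ValueError("write_results: empty record list")
    kinds = {type(r) for r in records}
    if len(kinds) > 1:
        raise ValueError(
            f"write_results: mixed record kinds {sorted(k.__name__ for k in kinds)}"
        )
    if not hasattr(records[0], "to_rows"):
        raise TypeError(f"records of type {type(records[0]).__name__} lack to_rows()")
    rows = [row for rec in records for row in rec.to_rows()]
    df = pd.DataFrame(rows)
    path = Path(path)
    df.to_csv(path, index=False, float_format="%.17g")
    return path


def setup_logging(logfile: str | Path | None = None, level: int = logging.INFO) -> None:
    """Route pipeline logging to stderr and optionally a timestamped file log."""
    handlers: list[logging.Handler] = [logging.StreamHandler()]
    if logfile is not None:
        handlers.append(logging.FileHandler(logfile))
    fmt = logging.Formatter("%(asctime)s %(levelname)s %(name)s: %(message)s")
    logger.setLevel(level)
    for h in handlers:
        h.setFormatter(fmt)
        logger.addHandler(h)
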