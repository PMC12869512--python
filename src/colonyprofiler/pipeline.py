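"""End-to-end orchestration: segment -> ring partition -> profile -> stats.

`run_profile` turns a set of fields (stacks plus treatment/replicate
metadata) into pooled per-colony section records; `run_stats` applies both
comparison families — sections within each treatment, and treatments against
vehicle per section — to such a record table.  Every run emits a manifest
capturing the resolved configuration, inputs, seed and outputs, which fully
determines the run.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from . import __version__
from .segmentation import filter_colonies, segment_colony
from .spatial import (
    ColonyRecord,
    SectionProfile,
    partition_rings,
    pool_colony,
    section_means,
    select_planes,
)
from .stack_io import FieldStack, RunConfig, logger, write_results
from .stats import StatConfig, StatResult, compare_sections_within_group, compare_treatments_vs_vehicle


@dataclass
class RunManifest:
    """Record of everything that determines one pipeline run."""

    config: dict
    inputs: list[str]
    seed: int
    outputs: list[str] = field(default_factory=list)
    timings: dict = field(default_factory=dict)
    version: str = __version__

    def to_dict(self) -> dict:
        return {
            "config": self.config,
            "inputs": self.inputs,
            "seed": self.seed,
            "outputs": self.outputs,
            "timings": self.timings,
            "version": self.version,
        }


def profile_stack(
    stack: FieldStack,
    config: RunConfig,
    treatment: str = "",
    biological_replicate: str = "",
    id_prefix: str = "colony",
) -> tuple[list[SectionProfile], list[ColonyRecord]]:
    """Profile every accepted colony in one field.

    Planes are selected at the configured fractional depths; the colony
    boundary is segmented once on the middle selected plane of the reference
    channel and reused for all analysed planes (per-plane re-segmentation is
    available via ``config.segment_per_plane``).  Relative section means are
    computed per plane and channel, then pooled per colony.
    """
    planes = select_planes(stack.n_planes, config.depth_fractions)
    seg_plane = planes[len(planes) // 2]
    masks = filter_colonies(segment_colony(stack, seg_plane, config, id_prefix), config)
    profiles: list[SectionProfile] = []
    records: list[ColonyRecord] = []
    for mask in masks:
        partitions = {seg_plane: partition_rings(mask, stack.pixel_size, config.ring_widths,
                                                 config.section_names)}
        for channel in stack.quantified_roles:
            per_plane = []
            for plane in planes:
                if config.segment_per_plane and plane not in partitions:
                    plane_masks = filter_colonies(
                        segment_colony(stack, plane, config, id_prefix), config
                    )
                    # match by best footprint overlap with the reference mask
                    best = max(plane_masks, key=lambda m: (m.mask & mask.mask).sum(), default=mask)
                    partitions[plane] = partition_rings(
                        best, stack.pixel_size, config.ring_widths, config.section_names
                    )
                part = partitions.get(plane, partitions[seg_plane])
                per_plane.append(section_means(stack, plane, channel, part, mask.colony_id))
            profiles.extend(per_plane)
            records.append(pool_colony(per_plane, treatment, biological_replicate))
    return profiles, records


def run_profile(
    inputs: Sequence[tuple[FieldStack, Mapping[str, str]]],
    config: RunConfig,
    out_dir: str | Path | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, RunManifest]:
    """Profile many fields; returns per-plane and pooled tables plus a manifest.

    ``inputs`` pairs each stack with its metadata (``treatment``,
    ``biological_replicate``, optional ``field_id``).  When ``out_dir`` is
    given, ``profiles.csv``, ``colony_records.csv`` and ``manifest`` paths
    are written there.
    """
    t0 = time.perf_counter()
    manifest = RunManifest(config=config.to_dict(), inputs=[], seed=config.seed)
    all_profiles: list[SectionProfile] = []
    all_records: list[ColonyRecord] = []
    for i, (stack, meta) in enumerate(inputs):
        missing = {"treatment", "biological_replicate"} - set(meta)
        if missing:
            raise ValueError(f"input {i}: metadata lacks {sorted(missing)}")
        field_id = meta.get("field_id", f"field_{i:03d}")
        manifest.inputs.append(f"{field_id} ({stack.provenance})")
        profs, recs = profile_stack(
            stack,
            config,
            treatment=meta["treatment"],
            biological_replicate=meta["biological_replicate"],
            id_prefix=field_id,
        )
        all_profiles.extend(profs)
        all_records.extend(recs)
    profiles_df = pd.DataFrame([r for p in all_profiles for r in p.to_rows()])
    records_df = pd.DataFrame([r for c in all_records for r in c.to_rows()])
    manifest.timings["profile_s"] = round(time.perf_counter() - t0, 3)
    if out_dir is not None and all_records:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        p1 = write_results(all_profiles, out_dir / "profiles.csv")
        p2 = write_results(all_records, out_dir / "colony_records.csv")
        manifest.outputs += [str(p1), str(p2)]
    return profiles_df, records_df, manifest


def run_stats(
    records: pd.DataFrame,
    config: RunConfig,
    vehicle_label: str = "vehicle",
) -> dict[tuple, StatResult]:
    """Both comparison families on a pooled colony-record table.

    Per channel: (i) sections compared within each treatment; (ii) each
    treatment compared to vehicle, separately per section.  With a single
    treatment and no vehicle group the vs-vehicle family is skipped with a
    logged notice.  Groups with fewer than two observations yield flagged
    insufficient-n results rather than errors.

    Keys of the returned mapping are ``("sections", channel, treatment)`` and
    ``("vs_vehicle", channel, section)``.
    """
    needed = {"channel", "treatment", "section", "relative_mean", "colony_id"}
    missing = needed - set(records.columns)
    if missing:
        raise ValueError(f"records table lacks columns {sorted(missing)}")
    known = set(config.section_names)
    bad = set(records["section"]) - known
    if bad:
        raise ValueError(f"unknown section names {sorted(bad)}; expected {sorted(known)}")
    if config.aggregation_mode == "biological":
        records = (
            records.groupby(
                ["channel", "treatment", "biological_replicate", "section"], sort=False
            )["relative_mean"]
            .mean()
            .reset_index()
            .assign(colony_id=lambda d: d["biological_replicate"])
        )
    stat_cfg = StatConfig(alpha=config.alpha)
    results: dict[tuple, StatResult] = {}
    for channel, chan_df in records.groupby("channel", sort=False):
        for treatment, tdf in chan_df.groupby("treatment", sort=False):
            df = tdf.rename(columns={"relative_mean": "value"})
            results[("sections", channel, treatment)] = compare_sections_within_group(
                df[["section", "value"]], stat_cfg
            )
        treatments = set(chan_df["treatment"])
        if vehicle_label not in treatments or len(treatments) < 2:
            logger.info(
                "run_stats: skipping vs-vehicle family for channel %s "
                "(need a %r group and at least one treatment)", channel, vehicle_label,
            )
            continue
        for section, sdf in chan_df.groupby("section", sort=False):
            df = sdf.rename(columns={"relative_mean": "value"})
            results[("vs_vehicle", channel, section)] = compare_treatments_vs_vehicle(
                df[["treatment", "value"]], vehicle_label, stat_cfg
            )
    return results
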