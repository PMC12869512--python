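"""Synthetic colony stacks and Ct tables with known ground truth.

Every downstream stage of the pipeline is validated against data this module
generates: roughly disk-shaped colonies (default 90 µm diameter, matching the
80-100 µm colonies the analysis targets) with a monotone radial intensity
profile, a nuclear and a reference channel rendered as the colony footprint,
Poisson photon noise followed by additive Gaussian read noise, and per-plane
multiplicative modulation across the z-stack.  The radial coordinate of every
profile is the distance from the colony *boundary* (not the centre), the same
coordinate the ring partition uses, so the analytic per-section means carried
in :class:`GroundTruth` are exact under the section geometry.

The companion generator for expression data draws Ct tables whose expected
2^-ddCt equals a stated true fold change.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from .qpcr import DEFAULT_REFERENCE_GENES, CtTable
from .stack_io import SECTIONS, FieldStack, write_stack

PROFILE_KINDS = ("uniform", "peripheral_high", "central_high", "linear_radial")


@dataclass
class ColonyProfile:
    """Radial intensity profile as a function of depth-from-boundary d (µm).

    * ``uniform``: constant ``base_intensity``.
    * ``peripheral_high``: ``base * (1 + (c - 1) * exp(-d / decay_length))`` —
      equals ``base * c`` at the periphery and decays to ``base`` centrally,
      so the periphery/centre contrast is ``c = contrast_ratio``.
    * ``central_high``: the mirrored profile,
      ``base * (c - (c - 1) * exp(-d / decay_length))`` — ``base`` at the
      periphery rising to ``base * c`` centrally (centre/periphery = c).
    * ``linear_radial``: linear ramp from ``base * c`` at the boundary to
      ``base`` at the deepest point (``d = colony_radius``); c < 1 gives a
      centrally increasing ramp.
    """

    kind: str = "uniform"
    base_intensity: float = 100.0
    contrast_ratio: float = 1.5
    decay_length: float = 15.0  # µm

    def __post_init__(self) -> None:
        if self.kind not in PROFILE_KINDS:
            raise ValueError(f"unknown profile kind {self.kind!r}")
        if self.base_intensity <= 0:
            raise ValueError("base_intensity must be > 0")
        if self.contrast_ratio <= 0:
            raise ValueError("contrast_ratio must be > 0")
        if self.decay_length <= 0:
            raise ValueError("decay_length must be > 0")

    def intensity(self, depth: np.ndarray, colony_radius: float) -> np.ndarray:
        """Noiseless intensity at boundary depth *depth* (µm, >= 0)."""
        d = np.asarray(depth, dtype=float)
        b, c, lam = self.base_intensity, self.contrast_ratio, self.decay_length
        if self.kind == "uniform":
            return np.full_like(d, b)
        if self.kind == "peripheral_high":
            return b * (1.0 + (c - 1.0) * np.exp(-d / lam))
        if self.kind == "central_high":
            return b * (c - (c - 1.0) * np.exp(-d / lam))
        # linear_radial
        frac = np.clip(d / colony_radius, 0.0, 1.0)
        return b * (c + (1.0 - c) * frac)


@dataclass
class SyntheticColonySpec:
    """Geometry, profile and noise of one simulated colony.

    ``gaussian_sd`` is additive read noise in intensity units;
    ``poisson_scale`` converts intensity to expected photon counts (0 turns
    shot noise off).  ``plane_modulation`` multiplies each plane of the
    noiseless signal, emulating depth-dependent illumination/attenuation;
    it defaults to all ones.  ``speckle_sd`` optionally adds a static
    mean-one log-normal cell-texture field within the colony (off by
    default; no particular value is asserted for real colonies).
    """

    colony_radius: float = 45.0  # µm
    center: tuple[float, float] | None = None  # (x, y) µm; None = field centre
    profile: ColonyProfile = field(default_factory=ColonyProfile)
    gaussian_sd: float = 0.0
    poisson_scale: float = 0.0
    n_planes: int = 1
    plane_modulation: Sequence[float] | None = None
    pixel_size: float = 0.5  # µm/px
    seed: int = 0
    speckle_sd: float = 0.0
    colony_id: str = "colony_01"

    def __post_init__(self) -> None:
        if self.colony_radius <= 0:
            raise ValueError("colony_radius must be > 0")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be > 0")
        if self.n_planes < 1:
            raise ValueError("n_planes must be >= 1")
        if self.gaussian_sd < 0 or self.poisson_scale < 0 or self.speckle_sd < 0:
            raise ValueError("noise parameters must be >= 0")
        if self.plane_modulation is None:
            self.plane_modulation = tuple(1.0 for _ in range(self.n_planes))
        else:
            self.plane_modulation = tuple(float(m) for m in self.plane_modulation)
            if len(self.plane_modulation) != self.n_planes:
                raise ValueError(
                    f"plane_modulation length {len(self.plane_modulation)} != n_planes {self.n_planes}"
                )
            if any(m <= 0 for m in self.plane_modulation):
                raise ValueError("plane_modulation factors must be > 0")


@dataclass
class GroundTruth:
    """Exact noiseless state of a generated field.

    ``analytic_section_means`` holds, per colony x channel role x section
    (plus ``total``), the mean of the unmodulated noiseless profile over the
    pixels of that section; sections are defined by nearest-background-pixel
    distance on the true mask, the same geometry the pipeline's ring
    partition applies, so these means are exact oracles for it.
    """

    noiseless_stack: np.ndarray  # (channel, plane, row, col), incl. background
    mask: np.ndarray  # union of all colony footprints
    colony_masks: dict[str, np.ndarray]
    section_labels: dict[str, np.ndarray]  # 0 bg, 1 outer, 2 middle, 3 inner
    analytic_section_means: pd.DataFrame


DEFAULT_CHANNEL_ORDER = ("nuclear", "reference_marker", "quantified_marker_1")


def _default_channel_profiles() -> dict[str, ColonyProfile | None]:
    # nuclear / reference channels are flat footprints; None means
    # "use the colony's own profile" (the quantified marker).
    return {
        "nuclear": ColonyProfile(kind="uniform", base_intensity=150.0),
        "reference_marker": ColonyProfile(kind="uniform", base_intensity=200.0),
        "quantified_marker_1": None,
    }


def generate_field(
    specs: Sequence[SyntheticColonySpec],
    field_size: tuple[int, int] = (256, 256),
    background_level: float = 0.0,
    channel_profiles: Mapping[str, ColonyProfile | None] | None = None,
    ring_widths: Sequence[float] = (15.0, 15.0),
    seed: int | None = None,
) -> tuple[FieldStack, GroundTruth]:
    """Render one field of view containing the given colonies.

    The noiseless expectation of every pixel is ``background_level`` plus
    the colony profile evaluated at that pixel's analytic distance from the
    colony boundary, scaled by the plane modulation factor.  Shot noise
    (Poisson on scaled photon counts) and additive Gaussian read noise are
    then applied independently per pixel, plane and channel; negative values
    are clipped at zero.  Identical inputs and seed give bit-identical
    output.

    ``channel_profiles`` maps channel role to the profile rendered on that
    channel; a value of ``None`` uses each colony's own profile.  Channel
    order follows the mapping's insertion order (default: nuclear,
    reference_marker, quantified_marker_1).
    """
    specs = list(specs)
    if not specs:
        raise ValueError("generate_field: no colony specs")
    rows, cols = field_size
    if rows <= 0 or cols <= 0:
        raise ValueError(f"field dimensions must be positive, got {field_size}")
    px = specs[0].pixel_size
    n_planes = specs[0].n_planes
    for s in specs:
        if s.pixel_size != px or s.n_planes != n_planes:
            raise ValueError("all colonies in a field must share pixel_size and n_planes")
    if seed is None:
        seed = specs[0].seed
    profiles = dict(channel_profiles) if channel_profiles is not None else _default_channel_profiles()
    roles = list(profiles)

    # pixel-centre coordinates in µm
    yy, xx = np.mgrid[0:rows, 0:cols]
    xc = (xx + 0.5) * px
    yc = (yy + 0.5) * px

    colony_masks: dict[str, np.ndarray] = {}
    depth_fields: dict[str, np.ndarray] = {}  # analytic distance from boundary, µm
    for s in specs:
        cx, cy = s.center if s.center is not None else (cols * px / 2.0, rows * px / 2.0)
        if (cx - s.colony_radius < 0 or cy - s.colony_radius < 0
                or cx + s.colony_radius > cols * px or cy + s.colony_radius > rows * px):
            raise ValueError(
                f"colony {s.colony_id!r} (centre ({cx}, {cy}) µm, radius {s.colony_radius} µm) "
                f"extends beyond the {cols * px} x {rows * px} µm field"
            )
        r = np.hypot(xc - cx, yc - cy)
        mask = r <= s.colony_radius
        if s.colony_id in colony_masks:
            raise ValueError(f"duplicate colony_id {s.colony_id!r}")
        colony_masks[s.colony_id] = mask
        depth_fields[s.colony_id] = np.where(mask, s.colony_radius - r, 0.0)

    # unmodulated noiseless signal per channel (plane factor applied below)
    base_planes = np.full((len(roles), rows, cols), float(background_level))
    for ci, role in enumerate(roles):
        for s in specs:
            prof = profiles[role] if profiles[role] is not None else s.profile
            m = colony_masks[s.colony_id]
            base_planes[ci][m] += prof.intensity(depth_fields[s.colony_id][m], s.colony_radius)

    modulation = np.asarray(specs[0].plane_modulation, dtype=float)
    noiseless = base_planes[:, None, :, :] * modulation[None, :, None, None]

    rng = np.random.default_rng(seed)
    signal = noiseless
    if any(s.speckle_sd > 0 for s in specs):
        texture = np.ones((rows, cols))
        for s in specs:
            if s.speckle_sd > 0:
                m = colony_masks[s.colony_id]
                sig = math.sqrt(math.log(1.0 + s.speckle_sd**2))
                texture[m] = rng.lognormal(-sig**2 / 2.0, sig, size=int(m.sum()))
        signal = noiseless * texture[None, None, :, :]

    noisy = signal.copy()
    pscale = specs[0].poisson_scale
    if pscale > 0:
        noisy = rng.poisson(noisy * pscale).astype(float) / pscale
    gsd = max(s.gaussian_sd for s in specs)
    if gsd > 0:
        noisy = noisy + rng.normal(0.0, gsd, size=noisy.shape)
    noisy = np.clip(noisy, 0.0, None)

    stack = FieldStack(
        intensities=noisy,
        channel_roles={i: r for i, r in enumerate(roles)},
        pixel_size=px,
        provenance=f"synthetic field, seed={seed}",
    )

    truth = GroundTruth(
        noiseless_stack=noiseless,
        mask=np.any(list(colony_masks.values()), axis=0),
        colony_masks=colony_masks,
        section_labels={
            cid: _section_labels(m, px, ring_widths) for cid, m in colony_masks.items()
        },
        analytic_section_means=_section_mean_table(
            base_planes, roles, colony_masks, px, ring_widths
        ),
    )
    return stack, truth


def _section_labels(mask: np.ndarray, pixel_size: float, widths: Sequence[float]) -> np.ndarray:
    """Ring labels on the true mask by nearest-background-pixel distance."""
    dist = ndi.distance_transform_edt(mask) * pixel_size
    labels = np.zeros(mask.shape, dtype=np.uint8)
    labels[mask] = 1 + np.digitize(dist[mask], np.cumsum(list(widths)), right=True)
    return labels


def _section_mean_table(
    base_planes: np.ndarray,
    roles: Sequence[str],
    colony_masks: Mapping[str, np.ndarray],
    pixel_size: float,
    widths: Sequence[float],
) -> pd.DataFrame:
    rows = []
    for cid, mask in colony_masks.items():
        labels = _section_labels(mask, pixel_size, widths)
        for ci, role in enumerate(roles):
            img = base_planes[ci]
            for code, name in enumerate(SECTIONS, start=1):
                sel = labels == code
                rows.append(
                    {
                        "colony_id": cid,
                        "channel": role,
                        "section": name,
                        "analytic_mean": float(img[sel].mean()) if sel.any() else float("nan"),
                        "area_px": int(sel.sum()),
                    }
                )
            rows.append(
                {
                    "colony_id": cid,
                    "channel": role,
                    "section": "total",
                    "analytic_mean": float(img[mask].mean()),
                    "area_px": int(mask.sum()),
                }
            )
    return pd.DataFrame(rows)


def export_field(
    stack: FieldStack,
    truth: GroundTruth,
    outdir: str | Path,
    name: str = "field",
    spec_info: dict | None = None,
) -> dict[str, Path]:
    """Write a generated field as TIFF plus ground-truth CSV and JSON sidecar."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "tiff": outdir / f"{name}.tif",
        "truth_csv": outdir / f"{name}_ground_truth.csv",
        "sidecar": outdir / f"{name}.json",
    }
    write_stack(stack, paths["tiff"])
    truth.analytic_section_means.to_csv(paths["truth_csv"], index=False)
    sidecar = {
        "pixel_size_um": stack.pixel_size,
        "channel_roles": {str(k): v for k, v in stack.channel_roles.items()},
        "axis_order": "CZYX",
        "spec": spec_info or {},
    }
    paths["sidecar"].write_text(json.dumps(sidecar, indent=2))
    return paths


# -- synthetic Ct tables ----------------------------------------------------------


def generate_ct_table(
    genes: Sequence[str],
    treatments: Sequence[str],
    n_bio_reps: int,
    true_fold_changes: Mapping[str, float],
    ct_noise_sd: float = 0.0,
    seed: int = 0,
    reference_genes: Sequence[str] = DEFAULT_REFERENCE_GENES,
    vehicle_label: str = "vehicle",
    n_tech_reps: int = 2,
    sample_shift_sd: float = 0.3,
) -> CtTable:
    """Draw a Ct table whose expected 2^-ddCt equals the stated fold changes.

    Each gene gets a base Ct (uniform 20-30 cycles); each sample (treatment x
    biological replicate) gets a loading shift applied to *all* its genes,
    which the reference-gene normalization must cancel.  Non-vehicle samples
    subtract ``log2(fold_change)`` cycles from each target gene.  Technical
    replicates add independent Gaussian Ct noise of SD ``ct_noise_sd``.
    Reference genes must be listed with fold change 1.
    """
    genes = list(genes)
    for ref in reference_genes:
        if ref not in genes:
            raise ValueError(f"reference gene {ref!r} missing from gene list")
        if true_fold_changes.get(ref, 1.0) != 1.0:
            raise ValueError(f"reference gene {ref!r} must have fold change 1")
    if vehicle_label not in treatments:
        raise ValueError(f"treatments must include the vehicle label {vehicle_label!r}")
    for g, fc in true_fold_changes.items():
        if fc <= 0:
            raise ValueError(f"fold change for {g!r} must be > 0, got {fc}")
    rng = np.random.default_rng(seed)
    base_ct = {g: rng.uniform(20.0, 30.0) for g in genes}
    rows = []
    for treatment in treatments:
        for rep in range(1, n_bio_reps + 1):
            sample = f"{treatment}_r{rep}"
            shift = rng.normal(0.0, sample_shift_sd) if sample_shift_sd > 0 else 0.0
            for g in genes:
                fc = 1.0 if treatment == vehicle_label else true_fold_changes.get(g, 1.0)
                mu = base_ct[g] - math.log2(fc) + shift
                for tech in range(1, n_tech_reps + 1):
                    noise = rng.normal(0.0, ct_noise_sd) if ct_noise_sd > 0 else 0.0
                    rows.append(
                        {
                            "sample": sample,
                            "treatment": treatment,
                            "biological_replicate": f"r{rep}",
                            "gene": g,
                            "technical_replicate": tech,
                            "ct": mu + noise,
                        }
                    )
    return CtTable(pd.DataFrame(rows), tuple(reference_genes))
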