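"""Shared fixtures: small synthetic fields and brute-force oracles."""

import numpy as np
import pytest
from scipy.spatial.distance import cdist

from colonyprofiler import ColonyProfile, RunConfig, SyntheticColonySpec, generate_field


@pytest.fixture
def config():
    return RunConfig()


@pytest.fixture
def noiseless_uniform_field():
    """One noiseless uniform colony (radius 45 µm) centred in a 256 px field."""
    spec = SyntheticColonySpec(profile=ColonyProfile(kind="uniform"), n_planes=3)
    return generate_field([spec])


@pytest.fixture
def noiseless_peripheral_field():
    spec = SyntheticColonySpec(
        profile=ColonyProfile(kind="peripheral_high", contrast_ratio=1.5), n_planes=3
    )
    return generate_field([spec])


def brute_force_ring_labels(mask: np.ndarray, pixel_size: float, widths) -> np.ndarray:
    """O(n*m) oracle: each colony pixel's min distance to any background pixel.

    Independent of the distance-transform path: enumerates every
    foreground/background pixel pair.  Labels: 0 bg, 1 outer, 2 middle,
    3 inner, with ring boundaries closed toward the periphery
    (d <= w1 -> outer, w1 < d <= w1+w2 -> middle).
    """
    fg = np.argwhere(mask)
    bg = np.argwhere(~mask)
    assert len(fg) and len(bg), "oracle needs both foreground and background"
    dmin = cdist(fg.astype(float), bg.astype(float)).min(axis=1) * pixel_size
    cum = np.cumsum(list(widths))
    labels = np.zeros(mask.shape, dtype=np.uint8)
    for (r, c), d in zip(fg, dmin):
        labels[r, c] = 1 + int(np.sum(d > cum))
    return labels


def random_blob_mask(rng: np.random.Generator, size: int = 64) -> np.ndarray:
    """Random connected-ish foreground blob with guaranteed background."""
    from scipy import ndimage as ndi

    noise = ndi.gaussian_filter(rng.normal(size=(size, size)), sigma=6)
    mask = noise > np.quantile(noise, 0.7)
    mask[0, :] = mask[-1, :] = mask[:, 0] = mask[:, -1] = False
    if not mask.any():
        mask[size // 2, size // 2] = True
    return mask
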