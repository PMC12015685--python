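"""Seeded generator of Miscanthus-like plot chips.

Each chip shows a textured soil background and a roughly circular green
canopy whose size and hue vary chip-to-chip (emulating a genetically diverse
breeding population).  Positive-class chips ("heading" plants) additionally
carry small bright silver-white speckles — emerged panicles — placed in the
upper half of the canopy, where panicles top the culms.  The class signal is
therefore exactly the one the real imagery carries: presence of small bright
objects at the canopy top, confounded by canopy/soil appearance variation.

Per-chip provenance (speckle masks, canopy geometry) is recorded so tests
can evaluate classifiers and activation maps against pixel-level ground
truth; classifiers themselves never see it.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter

from .chipio import ChipDataset, ImageChip, round_half_up

# Fixed channel tints: soil is brownish (R > G > B), canopy is green-dominant.
_SOIL_TINT = np.array([1.20, 1.00, 0.75], dtype=np.float32)
_CANOPY_TINT = np.array([0.60, 1.00, 0.45], dtype=np.float32)


@dataclass
class SynthConfig:
    """Appearance and sampling parameters for synthetic plot chips.

    Intensities are in [0, 1] and refer to the green channel; the green
    ordering panicle_brightness > canopy_green_level > soil_level is what
    makes the scene physically sensible (bright inflorescences over a green
    canopy over darker soil).
    """

    chip_size: int = 108
    n_chips: int = 100
    positive_fraction: float = 0.5
    canopy_radius_range: tuple[float, float] = (28.0, 43.0)
    canopy_green_level: float = 0.45
    soil_level: float = 0.22
    panicle_count_range: tuple[int, int] = (3, 8)
    panicle_size_range: tuple[float, float] = (3.0, 6.0)
    panicle_brightness: float = 0.88
    noise_sd: float = 0.035
    hue_jitter_sd: float = 0.06
    center_jitter_frac: float = 0.04
    seed: int = 0

    def __post_init__(self) -> None:
        if self.chip_size < 16:
            raise ValueError("chip_size must be >= 16")
        for name in ("positive_fraction", "canopy_green_level", "soil_level",
                     "panicle_brightness"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if not (self.panicle_brightness > self.canopy_green_level > self.soil_level):
            raise ValueError("need panicle_brightness > canopy_green_level > "
                             "soil_level (green channel)")
        if self.panicle_count_range[0] < 1:
            raise ValueError("panicle_count_range minimum must be >= 1")
        for rng_field in ("canopy_radius_range", "panicle_count_range",
                          "panicle_size_range"):
            lo, hi = getattr(self, rng_field)
            if lo > hi or lo <= 0:
                raise ValueError(f"{rng_field} must be (min, max) with 0 < min <= max")
        if self.canopy_radius_range[1] > self.chip_size / 2:
            raise ValueError("canopy radius cannot exceed half the chip size")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass
class ChipProvenance:
    """Generator-side ground truth for one chip (never shown to models)."""

    canopy_center: tuple[float, float]
    canopy_radius: float
    canopy_mask: np.ndarray           # bool HxW
    speckle_mask: np.ndarray          # bool HxW, empty for the negative class
    n_panicles: int


def generate_chip(config: SynthConfig, label: int,
                  stream: np.random.Generator) -> tuple[ImageChip, ChipProvenance]:
    """Render one chip for the given heading label (0 or 1).

    All randomness is drawn sequentially from ``stream``, so an identical
    (config, stream state) pair reproduces the chip bit for bit.  Output is
    quantised to the 8-bit grid, matching what a PNG round trip preserves.
    """
    if label not in (0, 1):
        raise ValueError(f"label must be 0 or 1, got {label!r}")
    s = config.chip_size
    yy, xx = np.mgrid[0:s, 0:s].astype(np.float32)

    # soil: tinted base level plus band-correlated smooth texture and grain
    soil_g = config.soil_level
    texture = gaussian_filter(stream.normal(0.0, 1.0, (s, s)), s / 24.0)
    texture /= max(np.abs(texture).max(), 1e-6)
    img = (soil_g * _SOIL_TINT)[None, None, :] * (1.0 + 0.25 * texture[:, :, None])
    img = img.astype(np.float32)

    # canopy disc with per-chip hue/size jitter and radial falloff
    radius = float(stream.uniform(*config.canopy_radius_range))
    jit = s * config.center_jitter_frac
    cy = s / 2.0 + float(stream.normal(0.0, jit))
    cx = s / 2.0 + float(stream.normal(0.0, jit))
    green = float(np.clip(config.canopy_green_level
                          + stream.normal(0.0, config.hue_jitter_sd), 0.12, 0.95))
    rr = np.sqrt((yy - cy) ** 2 + (xx - cx) ** 2)
    falloff = 1.0 - 0.35 * np.clip(rr / radius, 0.0, 1.0) ** 2
    canopy_tex = 1.0 + 0.18 * gaussian_filter(stream.normal(0.0, 1.0, (s, s)), 1.2)
    canopy_g = green * falloff * canopy_tex
    canopy = canopy_g[:, :, None] * _CANOPY_TINT[None, None, :]
    alpha = np.clip((radius - rr) / 1.5, 0.0, 1.0)[:, :, None]
    img = (1.0 - alpha) * img + alpha * canopy

    # panicles: bright near-white Gaussian blobs in the upper half of the disc
    speckle = np.zeros((s, s), dtype=np.float32)
    n_panicles = 0
    if label == 1:
        lo, hi = config.panicle_count_range
        n_panicles = int(stream.integers(lo, hi + 1))
        for _ in range(n_panicles):
            r = radius * 0.85 * np.sqrt(stream.uniform())
            theta = stream.uniform(0.0, np.pi)       # upper half: y above centre
            py = cy - r * np.sin(theta)
            px = cx + r * np.cos(theta)
            size = stream.uniform(*config.panicle_size_range)
            sigma = max(size / 2.355, 0.5)           # size ~ blob FWHM in pixels
            d2 = (yy - py) ** 2 + (xx - px) ** 2
            speckle = np.maximum(speckle, np.exp(-d2 / (2.0 * sigma ** 2)).astype(np.float32))
    if n_panicles:
        # screen blend toward silver-white keeps values bounded by 1
        blob = (config.panicle_brightness * speckle)[:, :, None]
        img = img + blob * (1.0 - img)

    img = img + stream.normal(0.0, config.noise_sd, (s, s, 3)).astype(np.float32)
    img = np.clip(img, 0.0, 1.0)
    img = np.round(img * 255.0).astype(np.float32) / 255.0

    prov = ChipProvenance(
        canopy_center=(cy, cx), canopy_radius=radius,
        canopy_mask=rr <= radius,
        speckle_mask=speckle > np.exp(-2.0),
        n_panicles=n_panicles)
    return ImageChip(img, (0.0, 1.0)), prov


def generate_dataset(config: SynthConfig) -> ChipDataset:
    """Generate ``n_chips`` chips with round-half-up class balance.

    The label sequence and every chip are functions of ``config.seed`` only.
    """
    if config.n_chips < 2:
        raise ValueError("n_chips must be >= 2")
    stream = np.random.default_rng(config.seed)
    n_pos = round_half_up(config.positive_fraction * config.n_chips)
    labels = np.zeros(config.n_chips, dtype=np.int64)
    labels[:n_pos] = 1
    labels = labels[stream.permutation(config.n_chips)]
    chips, provs, ids = [], [], []
    width = len(str(config.n_chips - 1))
    for i, label in enumerate(labels):
        chip, prov = generate_chip(config, int(label), stream)
        chips.append(chip)
        provs.append(prov)
        ids.append(f"chip_{i:0{width}d}")
    return ChipDataset(chips=chips, labels=labels, ids=ids, provenance=provs)


def save_config(config: SynthConfig, path: str | Path) -> None:
    lines = [f"{k} = {v}" for k, v in vars(config).items()]
    Path(path).write_text("\n".join(lines) + "\n")
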