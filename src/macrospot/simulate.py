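"""Synthetic membrane-scan generator with ground truth.

Emulates a scanned protein filter membrane: a smooth background with a linear
gradient and i.i.d. pixel noise, high-contrast ink guide dots at every block
center, and clone spots rendered as uniform disks whose amplitude is the
clone's binder strength times a multiplicative lognormal factor (scanned
chemiluminescence/fluorescence spot intensities are nonnegative and
right-skewed, so variability is modelled multiplicatively). Failed deposits
and channel-specific artifact smears can be injected, and every image is a
deterministic function of (design, truth, noise model, channel).
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .design import ArrayDesign, make_design
from .errors import GeometryError, InvalidDesignError
from .registration import Affine

#: Guide dots are rendered at a fixed amplitude of 5x the background level so
#: they are detectable regardless of probe binding.
GUIDE_DOT_GAIN = 5.0

CHANNEL_A = "dAb"
CHANNEL_B = "dAb-rFc"


@dataclass(frozen=True)
class NoiseModel:
    """Acquisition-noise parameters of the simulated scanner.

    background_level
        Mean background intensity (arbitrary intensity units).
    background_gradient
        Linear background slope (units per pixel) along (row, col); models
        uneven membrane illumination/wetting.
    pixel_noise_sd
        SD of i.i.d. Gaussian pixel noise, intensity units.
    spot_cv
        Coefficient of variation of the realized spot amplitude (lognormal,
        multiplicative). 0 renders spots at exactly their nominal strength.
    seed
        Base seed; combined with the channel label so the two probe images of
        one membrane get independent but reproducible noise.
    """

    background_level: float = 100.0
    background_gradient: tuple[float, float] = (0.02, 0.02)
    pixel_noise_sd: float = 4.0
    spot_cv: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.background_level <= 0:
            raise InvalidDesignError("background_level must be > 0")
        if self.pixel_noise_sd < 0 or self.spot_cv < 0:
            raise InvalidDesignError("noise magnitudes must be >= 0")

    def rng(self, channel: str) -> np.random.Generator:
        tag = zlib.crc32(channel.encode("utf-8")) & 0x7FFFFFFF
        return np.random.default_rng([int(self.seed) & 0x7FFFFFFF, tag])


@dataclass(frozen=True)
class GroundTruth:
    """What the generator deposited; the oracle for recovery tests.

    binder_strength
        clone id -> {channel label -> intensity added above background}.
        Clones absent from the mapping have strength 0 everywhere.
    failed_spots
        (channel, block_row, block_col, position) whose deposit is suppressed
        — the failure mode behind replicate-inconsistent detections.
    artifact_spots
        (channel, (row, col), intensity) smears at arbitrary, non-grid
        positions, rendered as spot-sized disks.
    """

    binder_strength: Mapping[str, Mapping[str, float]] = field(default_factory=dict)
    failed_spots: frozenset[tuple[str, int, int, int]] = frozenset()
    artifact_spots: tuple[tuple[str, tuple[float, float], float], ...] = ()

    def __post_init__(self) -> None:
        for clone, per_channel in self.binder_strength.items():
            for channel, s in per_channel.items():
                if s < 0:
                    raise InvalidDesignError(
                        f"negative strength for {clone}/{channel}")

    def strength(self, clone: str, channel: str) -> float:
        return float(self.binder_strength.get(clone, {}).get(channel, 0.0))

    def validate_against(self, design: ArrayDesign) -> None:
        spots = design.clone_spots()
        valid = {addr for pair in spots.values() for addr in pair}
        for (channel, br, bc, pos) in self.failed_spots:
            if (br, bc, pos) not in valid:
                raise InvalidDesignError(
                    f"failed spot {(br, bc, pos)} not in design")
        for clone in self.binder_strength:
            if clone not in spots:
                raise InvalidDesignError(f"unknown clone {clone!r} in truth")


def _paint_disk(image: np.ndarray, center: np.ndarray, radius: float,
                amplitude: float) -> None:
    """Add `amplitude` to every pixel whose index lies within `radius` of
    `center` (Euclidean distance on the integer pixel grid)."""
    r0 = max(int(np.floor(center[0] - radius)), 0)
    r1 = min(int(np.ceil(center[0] + radius)), image.shape[0] - 1)
    c0 = max(int(np.floor(center[1] - radius)), 0)
    c1 = min(int(np.ceil(center[1] + radius)), image.shape[1] - 1)
    if r1 < r0 or c1 < c0:
        return
    rr, cc = np.mgrid[r0:r1 + 1, c0:c1 + 1]
    mask = (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius ** 2
    image[r0:r1 + 1, c0:c1 + 1][mask] += amplitude


def _lognormal_factor(rng: np.random.Generator, cv: float) -> float:
    if cv == 0:
        return 1.0
    sigma = np.sqrt(np.log1p(cv ** 2))
    return float(rng.lognormal(mean=-sigma ** 2 / 2, sigma=sigma))


def simulate_image(design: ArrayDesign, truth: GroundTruth, noise: NoiseModel,
                   channel: str, *, shape: tuple[int, int] | None = None,
                   transform: Affine | None = None) -> np.ndarray:
    """Render one probe channel of the membrane as a float64 image.

    `transform` maps nominal design coordinates to image coordinates
    (default identity) so scanned translation/rotation/scale can be
    emulated; `shape` defaults to the nominal grid extent. Raises
    :class:`GeometryError` if any spot disk would fall outside the image.
    """
    truth.validate_against(design)
    if shape is None:
        shape = design.nominal_shape()
    transform = transform or Affine.identity()

    centers = {}
    for br, bc in design.blocks():
        for pos in range(9):
            centers[(br, bc, pos)] = transform(design.spot_center(br, bc, pos))

    pad = max(design.spot_radius, design.guide_dot_radius)
    for (br, bc, pos), ctr in centers.items():
        if (ctr[0] < pad or ctr[0] > shape[0] - 1 - pad
                or ctr[1] < pad or ctr[1] > shape[1] - 1 - pad):
            raise GeometryError(
                f"spot ({br},{bc},{pos}) at {ctr} does not fit in image "
                f"of shape {shape}")

    rng = noise.rng(channel)
    rows = np.arange(shape[0], dtype=float)[:, None]
    cols = np.arange(shape[1], dtype=float)[None, :]
    gr, gc = noise.background_gradient
    image = noise.background_level + gr * rows + gc * cols
    image = np.broadcast_to(image, shape).copy()
    if noise.pixel_noise_sd > 0:
        image += rng.normal(0.0, noise.pixel_noise_sd, size=shape)

    for br, bc in design.blocks():
        _paint_disk(image, centers[(br, bc, 0)], design.guide_dot_radius,
                    GUIDE_DOT_GAIN * noise.background_level)

    for clone, pair in sorted(design.clone_spots().items()):
        s = truth.strength(clone, channel)
        if s <= 0:
            continue
        for (br, bc, pos) in pair:
            amp = s * _lognormal_factor(rng, noise.spot_cv)
            if (channel, br, bc, pos) in truth.failed_spots:
                continue
            _paint_disk(image, centers[(br, bc, pos)], design.spot_radius, amp)

    for (art_channel, (r, c), intensity) in truth.artifact_spots:
        if art_channel == channel:
            _paint_disk(image, np.array([r, c]), design.spot_radius, intensity)

    return image


def rendered_spot_count(design: ArrayDesign, truth: GroundTruth,
                        channel: str) -> int:
    """Number of clone spots that actually receive a deposit in a channel:
    replicates of positive-strength clones minus that channel's failures."""
    n = 0
    for clone, pair in design.clone_spots().items():
        if truth.strength(clone, channel) <= 0:
            continue
        for (br, bc, pos) in pair:
            if (channel, br, bc, pos) not in truth.failed_spots:
                n += 1
    return n


def dual_probe_scenario(seed: int, *, strength: float = 24.0
                        ) -> tuple[np.ndarray, np.ndarray, ArrayDesign, GroundTruth]:
    """The packaged two-channel screening scenario.

    A 10x10-block membrane (400 clones) probed with two antibody formats.
    Clones G1-G5 are strong duplicate-consistent binders in channel A (dAb).
    In channel B (dAb-rFc), G1 binds at both replicate spots while G2 and G3
    each lose one replicate to a failed deposit, and G6/G7 are strong
    channel-B-only binders. Everything else has strength 0. With the
    replicate-consistency rule the dual-format intersection is exactly {G1};
    without it, {G1, G2, G3}.

    Returns (image_A, image_B, design, truth); deterministic given seed.
    """
    design = make_design(10, 10).with_clone_ids({
        (1, 1, 1): "G1", (1, 1, 2): "G2", (1, 1, 3): "G3", (1, 1, 4): "G4",
        (1, 2, 1): "G5", (1, 2, 2): "G6", (1, 2, 3): "G7",
    })
    # One replicate of G2 (slot 2: positions 2,7) and of G3 (slot 3:
    # positions 3,6) fails in channel B only.
    truth = GroundTruth(
        binder_strength={
            "G1": {CHANNEL_A: strength, CHANNEL_B: strength},
            "G2": {CHANNEL_A: strength, CHANNEL_B: strength},
            "G3": {CHANNEL_A: strength, CHANNEL_B: strength},
            "G4": {CHANNEL_A: strength},
            "G5": {CHANNEL_A: strength},
            "G6": {CHANNEL_B: strength},
            "G7": {CHANNEL_B: strength},
        },
        failed_spots=frozenset({
            (CHANNEL_B, 1, 1, 7),
            (CHANNEL_B, 1, 1, 6),
        }),
    )
    noise = NoiseModel(seed=seed)
    image_a = simulate_image(design, truth, noise, CHANNEL_A)
    image_b = simulate_image(design, truth, noise, CHANNEL_B)
    return image_a, image_b, design, truth
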