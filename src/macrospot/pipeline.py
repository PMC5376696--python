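"""End-to-end pipeline: scan images -> registered grid -> spot z-scores ->
per-channel hit lists -> dual-format common hits.

Every stage is deterministic given its inputs and the configuration, so a
rerun with the same files produces byte-identical output tables.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import io as msio
from .config import PipelineConfig
from .design import ArrayDesign
from .errors import RegistrationError
from .hits import CloneScore, HitList, call_hits, intersect_channels, score_clones
from .quantify import QuantParams, SpotQuant, quantify_array
from .registration import (RegistrationResult, detect_guide_dots, fit_grid,
                           locate_spots)

logger = logging.getLogger("macrospot")


@dataclass
class ChannelResult:
    """Everything computed for one probe channel."""

    channel: str
    registration: RegistrationResult | None
    quants: list[SpotQuant]
    scores: list[CloneScore]
    hits: HitList


@dataclass
class PipelineResult:
    channels: dict[str, ChannelResult]
    common: HitList


def quant_params(config: PipelineConfig) -> QuantParams:
    q = config.quantification
    return QuantParams(
        annulus_inner_pad=q.annulus_inner_pad,
        annulus_outer_pad=q.annulus_outer_pad,
        spread_floor=q.spread_floor,
        saturation_fraction=q.saturation_fraction,
        min_annulus_pixels=q.min_annulus_pixels,
    )


def process_channel(image: np.ndarray, design: ArrayDesign,
                    config: PipelineConfig, channel: str, *,
                    saturation_level: float | None = None) -> ChannelResult:
    """Register, quantify and call hits for one channel image.

    A registration failure (e.g. a blank membrane) is downgraded to a
    warning and yields an empty hit list rather than aborting the run.
    """
    t0 = time.perf_counter()
    try:
        dots = detect_guide_dots(
            image, design, threshold_k=config.registration.threshold_k,
            area_bounds=(config.registration.area_low,
                         config.registration.area_high))
        registration = fit_grid(dots, design)
    except RegistrationError as exc:
        logger.warning("[%s] registration failed (%s); emitting empty hit list",
                       channel, exc)
        return ChannelResult(
            channel=channel, registration=None, quants=[], scores=[],
            hits=HitList(channel=channel, entries=(),
                         z_min=config.calling.z_min))
    logger.info("[%s] registration: %d dots used, rms %.3f px (%.2fs)",
                channel, registration.n_dots_used, registration.residual_rms,
                time.perf_counter() - t0)

    t0 = time.perf_counter()
    spots = locate_spots(registration, design, image_shape=image.shape)
    quants = quantify_array(
        image, spots, spot_radius=design.spot_radius,
        guide_dot_radius=design.guide_dot_radius,
        params=quant_params(config), saturation_level=saturation_level)
    logger.info("[%s] quantified %d spots (%.2fs)", channel, len(quants),
                time.perf_counter() - t0)

    scores = score_clones(quants, design, z_min=config.calling.z_min)
    hits = call_hits(scores, config.calling.z_min, channel=channel,
                     require_duplicate=config.calling.require_duplicate)
    logger.info("[%s] %d hits at z_min=%.2f", channel, len(hits),
                config.calling.z_min)
    return ChannelResult(channel=channel, registration=registration,
                         quants=quants, scores=scores, hits=hits)


def run_pipeline(config: PipelineConfig,
                 image_a: str | Path | np.ndarray,
                 image_b: str | Path | np.ndarray,
                 layout: str | Path | ArrayDesign,
                 outdir: str | Path | None = None,
                 channels: tuple[str, str] = ("dAb", "dAb-rFc")
                 ) -> PipelineResult:
    """Full dual-channel run; optionally writes all stage TSVs to `outdir`.

    `image_a`/`image_b` may be TIFF paths or in-memory arrays; `layout` a
    layout TSV path or an ArrayDesign. Outputs (when `outdir` given):
    registration_<channel>.tsv, quant_<channel>.tsv, hits_<channel>.tsv,
    hits_common.tsv and config_echo.txt.
    """
    design = (layout if isinstance(layout, ArrayDesign)
              else msio.read_layout(layout, config.geometry))

    results: dict[str, ChannelResult] = {}
    for channel, image in zip(channels, (image_a, image_b)):
        ceiling = None
        if not isinstance(image, np.ndarray):
            scan = msio.read_image(image)
            image, ceiling = scan.data, scan.saturation_level
        results[channel] = process_channel(
            np.asarray(image, dtype=float), design, config, channel,
            saturation_level=ceiling)

    common = intersect_channels(results[channels[0]].hits,
                                results[channels[1]].hits)
    logger.info("common hits across %s and %s: %d", channels[0], channels[1],
                len(common))

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for channel, res in results.items():
            tag = channel.replace("/", "_")
            if res.registration is not None:
                msio.write_registration(res.registration,
                                        outdir / f"registration_{tag}.tsv")
            msio.write_quants(res.quants, design, outdir / f"quant_{tag}.tsv")
            msio.write_hits(res.hits, outdir / f"hits_{tag}.tsv")
        msio.write_hits(common, outdir / "hits_common.tsv")
        from .config import save_config
        save_config(config, outdir / "config_echo.txt")

    return PipelineResult(channels=results, common=common)
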