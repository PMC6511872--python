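"""End-to-end per-nucleus analysis: segment → QC → normalize → ratio →
zones → radial profile → P/I → texture.

This is the library-level composition the command-line interface wraps.
Quality-control flags are batch statistics (the blur rule needs a batch
mean and SD), so the flagging step runs over all nuclei of a batch at
once in :func:`analyze_batch`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .colocalization import ColocResult
from .image_io import AnalysisConfig, ChannelMap, ImageStack
from .quality_control import (QCFlags, QCMetrics, flag_outliers,
                              percent_extreme_pixels, power_log_log_slope)
from .ratiometric import (RatioImage, inverse_ratio_image, normalize_channels,
                          ratio_image)
from .segmentation import NucleusMask, segment_nuclei, smooth_channel, threshold_auto
from .texture import GlcmSpec, TextureResult, periphery_texture
from .zonation import (RadialProfile, ZoneMap, distance_zone_map,
                       radial_profile, relative_ratio_PI)

logger = logging.getLogger(__name__)


@dataclass
class NucleusResult:
    """Everything the pipeline measures for one nucleus."""

    image_id: str
    nucleus_id: int
    group: str
    mask: NucleusMask
    ratio: RatioImage
    zones: ZoneMap
    profile: RadialProfile
    pi_ratio: float
    texture: TextureResult | None = None
    qc: QCMetrics | None = None
    flags: QCFlags | None = None
    coloc: ColocResult | None = None


def analyze_stack(stack: ImageStack, channel_map: ChannelMap,
                  config: AnalysisConfig, image_id: str = "image",
                  group: str = "", with_texture: bool = True
                  ) -> list[NucleusResult]:
    """Run the full single-image pipeline; QC flags are left unset here."""
    seg = segment_nuclei(stack, channel_map, config)
    results: list[NucleusResult] = []
    for nucleus in seg.masks:
        try:
            norm = normalize_channels(stack, nucleus, channel_map, config)
            ratio = ratio_image(norm, config.ratio_epsilon)
            zones = distance_zone_map(nucleus, config.n_zones,
                                      mode=config.zone_mode,
                                      fill_holes=config.fill_holes)
            profile = radial_profile(ratio, zones, nucleus_id=nucleus.label)
            pi = relative_ratio_PI(profile, config.peripheral_zones,
                                   pooling=config.pi_pooling).value
        except ValueError as err:
            logger.info("%s nucleus %d skipped: %s", image_id, nucleus.label, err)
            continue
        texture = None
        if with_texture:
            inverse = inverse_ratio_image(norm, config.ratio_epsilon)
            try:
                texture = periphery_texture(
                    inverse, zones, GlcmSpec(levels=config.glcm_levels),
                    n_periphery_zones=config.texture_periphery_zones)
            except ValueError as err:
                logger.info("%s nucleus %d texture skipped: %s",
                            image_id, nucleus.label, err)
        qc = _nucleus_qc(stack, channel_map, nucleus, config)
        results.append(NucleusResult(
            image_id=image_id, nucleus_id=nucleus.label, group=group,
            mask=nucleus, ratio=ratio, zones=zones, profile=profile,
            pi_ratio=pi, texture=texture, qc=qc))
    return results


def _nucleus_qc(stack: ImageStack, channel_map: ChannelMap,
                nucleus: NucleusMask, config: AnalysisConfig) -> QCMetrics | None:
    """Whole-field blur/Otsu metrics plus per-object saturation."""
    plane = np.asarray(stack.channel(channel_map.total, nucleus.slice_index),
                       dtype=float)
    bdm = stack.bit_depth_max if stack.bit_depth_max is not None else config.bit_depth_max
    if bdm is None:
        logger.warning("bit_depth_max unknown for float input; QC skipped")
        return None
    try:
        slope = power_log_log_slope(plane)
        smoothed = smooth_channel(plane, config.smoothing_size,
                                  sigma=config.smoothing_sigma)
        otsu_norm = threshold_auto(smoothed) / bdm
    except ValueError:
        return None
    pct_min, pct_max = percent_extreme_pixels(plane, nucleus.mask, bdm)
    return QCMetrics(power_log_log_slope=slope, percent_minimal=pct_min,
                     percent_maximal=pct_max, otsu_threshold=otsu_norm)


def apply_qc(results: Sequence[NucleusResult],
             config: AnalysisConfig) -> list[NucleusResult]:
    """Batch-flag outliers and drop them (unless ``keep_flagged``)."""
    results = list(results)
    with_qc = [r for r in results if r.qc is not None]
    flags = flag_outliers([r.qc for r in with_qc], config)
    for r, fl in zip(with_qc, flags):
        r.flags = fl
        if fl.excluded:
            logger.info("%s nucleus %d QC-flagged (blur=%s sat=%s snr=%s)",
                        r.image_id, r.nucleus_id, fl.blur_outlier,
                        fl.saturation_outlier, fl.snr_outlier)
    if config.keep_flagged:
        return results
    return [r for r in results
            if r.flags is None or not r.flags.excluded]


def analyze_batch(stacks: Sequence[tuple[str, ImageStack]],
                  channel_map: ChannelMap, config: AnalysisConfig,
                  group: str = "", with_texture: bool = True
                  ) -> list[NucleusResult]:
    """Analyze a batch of images and apply the batch QC rules."""
    results: list[NucleusResult] = []
    for image_id, stack in stacks:
        results.extend(analyze_stack(stack, channel_map, config,
                                     image_id=image_id, group=group,
                                     with_texture=with_texture))
    return apply_qc(results, config)
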