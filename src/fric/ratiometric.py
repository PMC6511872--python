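"""Per-nucleus channel normalization and the euchromatin/total-chromatin ratio.

Each channel is normalized within the nucleus mask so that acquisition gain,
expression level and laser power cancel; the pixelwise ratio of the
normalized euchromatin-marker channel (H3.3) to the normalized
total-chromatin channel (H2B) is then a unit-centred map of relative
euchromatin content: >1 relatively euchromatic, <1 relatively
heterochromatic.  The inverse ratio (H2B/H3.3) highlights heterochromatin
and is the input to the texture measurements.

The primary normalization divides by the in-mask mean, which makes "no
enrichment" exactly 1.  A studentized variant ((x − mean)/sd, re-centred at
1) is available behind a config flag for users who also want unit variance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .image_io import AnalysisConfig, ChannelMap, ImageStack
from .segmentation import NucleusMask


@dataclass
class NormalizedChannels:
    """Mask-restricted normalized channels; NaN outside the mask."""

    euc_norm: np.ndarray
    tot_norm: np.ndarray
    mask: np.ndarray
    norm_stats: dict[str, tuple[float, float]]  # channel -> (mean, variance)


@dataclass
class RatioImage:
    """Pixelwise ratio over a nucleus mask; NaN outside / on excluded pixels."""

    ratio: np.ndarray
    mask: np.ndarray          # pixels carrying a valid ratio value
    excluded_pixels: int = 0  # denominator <= epsilon

    @property
    def values(self) -> np.ndarray:
        return self.ratio[self.mask]


def normalize_channels(stack: ImageStack, nucleus: NucleusMask,
                       channel_map: ChannelMap,
                       config: AnalysisConfig | None = None) -> NormalizedChannels:
    """Normalize both histone channels within one nucleus mask."""
    if config is None:
        config = AnalysisConfig()
    mask = nucleus.mask
    if mask.sum() < config.min_mask_pixels:
        raise ValueError(
            f"mask area {mask.sum()} below minimum {config.min_mask_pixels}")

    out = {}
    stats = {}
    for role in (channel_map.euchromatin, channel_map.total):
        plane = np.asarray(stack.channel(role, nucleus.slice_index), dtype=float)
        vals = plane[mask]
        mean = float(vals.mean())
        var = float(vals.var(ddof=0))
        if mean <= 0:
            raise ValueError(f"channel {role!r} has non-positive in-mask mean")
        norm = np.full(plane.shape, np.nan)
        if config.normalization_mode == "studentized":
            if var == 0:
                raise ValueError(f"channel {role!r} is constant in mask")
            # unit-variance z-score re-centred at 1 so the mean stays 1
            norm[mask] = (vals - mean) / np.sqrt(var) + 1.0
        else:
            norm[mask] = vals / mean
        out[role] = norm
        stats[role] = (mean, var)
    return NormalizedChannels(euc_norm=out[channel_map.euchromatin],
                              tot_norm=out[channel_map.total],
                              mask=mask, norm_stats=stats)


def _divide(num: np.ndarray, den: np.ndarray, mask: np.ndarray,
            epsilon: float) -> RatioImage:
    excluded = mask & ~(den > epsilon)
    n_excluded = int(excluded.sum())
    if n_excluded > 0.10 * mask.sum():
        raise ValueError(
            f"{n_excluded} of {int(mask.sum())} pixels have near-zero "
            "denominator: degenerate nucleus")
    good = mask & (den > epsilon)
    ratio = np.full(num.shape, np.nan)
    ratio[good] = num[good] / den[good]
    return RatioImage(ratio=ratio, mask=good, excluded_pixels=n_excluded)


def ratio_image(norm: NormalizedChannels,
                epsilon: float = 1e-6) -> RatioImage:
    """Euchromatin / total-chromatin ratio (high = relative euchromatin)."""
    return _divide(norm.euc_norm, norm.tot_norm, norm.mask, epsilon)


def inverse_ratio_image(norm: NormalizedChannels,
                        epsilon: float = 1e-6) -> RatioImage:
    """Total-chromatin / euchromatin ratio (high = relative heterochromatin)."""
    return _divide(norm.tot_norm, norm.euc_norm, norm.mask, epsilon)
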