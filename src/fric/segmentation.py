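"""Nucleus segmentation and equatorial-slice selection.

Nuclei are segmented on the total-chromatin channel (H2B), which outlines
the whole nucleus: the channel is Gaussian-smoothed, thresholded with Otsu's
method, labelled, and filtered by equivalent circular diameter and a border
rule.  For z-stacks, each nucleus is tracked across slices by centroid
overlap and analysed in its equatorial section — the slice where its
cross-sectional area is largest.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.measure import label as _sk_label
from skimage.measure import regionprops

from .image_io import AnalysisConfig, ChannelMap, ImageStack

logger = logging.getLogger(__name__)


@dataclass
class NucleusMask:
    """One segmented nucleus on one z-slice.

    ``mask`` is a full-frame boolean raster; ``label`` is the scan-order id
    assigned at labelling time and is stable for identical inputs.
    """

    label: int
    mask: np.ndarray              # (H, W) bool
    slice_index: int = 0

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.area == 0:
            raise ValueError("nucleus mask is empty")

    @property
    def area(self) -> int:
        return int(self.mask.sum())

    @property
    def equivalent_diameter(self) -> float:
        """Diameter of the circle with the same area, 2*sqrt(area/pi)."""
        return 2.0 * np.sqrt(self.area / np.pi)

    @property
    def centroid(self) -> tuple[float, float]:
        ys, xs = np.nonzero(self.mask)
        return float(ys.mean()), float(xs.mean())


@dataclass
class SegmentationResult:
    masks: list[NucleusMask] = field(default_factory=list)
    threshold_value: float = float("nan")
    smoothed_used: bool = True


def smooth_channel(image: np.ndarray, size: float,
                   sigma: float | None = None) -> np.ndarray:
    """Gaussian-smooth a 2-D image.

    *size* is a feature size (diameter); the Gaussian sigma is size/2.35
    (FWHM convention) unless *sigma* is given explicitly.  Reflect padding
    keeps total intensity conserved up to boundary effects.
    """
    if size < 1:
        raise ValueError("smoothing size must be >= 1")
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise ValueError("smooth_channel expects a 2-D image")
    s = sigma if sigma is not None else size / 2.35
    return ndimage.gaussian_filter(image, sigma=s, mode="reflect")


def threshold_auto(image: np.ndarray) -> float:
    """Global automatic threshold (Otsu) maximizing between-class variance."""
    image = np.asarray(image)
    flat = image.ravel()
    if np.all(flat == flat[0]):
        raise ValueError("cannot threshold a constant image")
    return float(threshold_otsu(image))


def label_and_filter(binary: np.ndarray, min_diameter: float,
                     border_exclude: bool = True,
                     fill_holes: bool = True,
                     slice_index: int = 0) -> list[NucleusMask]:
    """Label connected components and keep nucleus-sized, interior objects.

    8-connectivity; objects are kept when their equivalent circular
    diameter exceeds *min_diameter* and (with *border_exclude*) no pixel
    lies on the image border.  Holes (nucleoli) are filled before area
    measurement so the radial zones later cover the full nuclear disc.
    Labels are reassigned 1..k in scan order of the retained objects.
    """
    binary = np.asarray(binary, dtype=bool)
    labelled = _sk_label(binary, connectivity=2)
    kept: list[NucleusMask] = []
    h, w = binary.shape
    for region in regionprops(labelled):
        obj = labelled == region.label
        if fill_holes:
            obj = ndimage.binary_fill_holes(obj)
        if border_exclude:
            ys, xs = np.nonzero(obj)
            if ys.min() == 0 or xs.min() == 0 or ys.max() == h - 1 or xs.max() == w - 1:
                continue
        area = int(obj.sum())
        eq_diam = 2.0 * np.sqrt(area / np.pi)
        if eq_diam <= min_diameter:
            continue
        kept.append(NucleusMask(label=len(kept) + 1, mask=obj,
                                slice_index=slice_index))
    return kept


def select_equatorial_slice(masks_per_slice: list[list[NucleusMask]]
                            ) -> list[NucleusMask]:
    """Pick each nucleus's largest-area (equatorial) section across slices.

    Nuclei are tracked across z by testing whether a mask's centroid falls
    inside a mask on the next slice (nuclei are static within one
    acquisition, so centroid-in-mask overlap suffices).  Area ties resolve
    to the lower slice index.
    """
    tracks: list[list[NucleusMask]] = []
    for slice_masks in masks_per_slice:
        for m in slice_masks:
            cy, cx = m.centroid
            iy, ix = int(round(cy)), int(round(cx))
            for track in tracks:
                prev = track[-1]
                if prev.slice_index < m.slice_index and prev.mask[iy, ix]:
                    track.append(m)
                    break
            else:
                tracks.append([m])
    selected = []
    for track in tracks:
        best = max(track, key=lambda m: (m.area, -m.slice_index))
        selected.append(best)
    for new_label, m in enumerate(selected, start=1):
        m.label = new_label
    return selected


def segment_nuclei(stack: ImageStack, channel_map: ChannelMap,
                   config: AnalysisConfig) -> SegmentationResult:
    """Segment nuclei on the total-chromatin channel of every slice.

    Smoothing → Otsu threshold → labelling/filtering per slice, then
    equatorial-slice selection per nucleus.  An image with no nuclei yields
    an empty result (with a warning), not an error.
    """
    total = stack.channel(channel_map.total)
    masks_per_slice: list[list[NucleusMask]] = []
    threshold = float("nan")
    for z in range(stack.n_slices):
        plane = np.asarray(total[z], dtype=float)
        smoothed = smooth_channel(plane, config.smoothing_size,
                                  sigma=config.smoothing_sigma)
        try:
            threshold = threshold_auto(smoothed)
        except ValueError:
            masks_per_slice.append([])
            continue
        binary = smoothed > threshold
        masks_per_slice.append(
            label_and_filter(binary, config.min_diameter,
                             border_exclude=config.border_exclude,
                             fill_holes=config.fill_holes, slice_index=z))
    selected = select_equatorial_slice(masks_per_slice)
    if not selected:
        logger.warning("no nuclei found after size/border filtering")
    return SegmentationResult(masks=selected, threshold_value=threshold,
                              smoothed_used=True)
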