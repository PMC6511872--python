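"""Image-quality metrics and outlier exclusion.

Three failure modes of live-cell acquisitions are screened:

* blur — the slope of the log-log radially averaged power spectrum
  (PowerLogLogSlope); defocused or motion-blurred frames lose high spatial
  frequencies and their slope becomes more negative;
* saturation — the percentage of object pixels pinned at the detector
  maximum (or at zero);
* poor signal-to-noise — an Otsu threshold (on the [0, 1] normalized
  intensity scale) far above the batch-typical value.

An image or nucleus is excluded when its spectral slope deviates more than
2 SD from the batch average, when more than 0.2% of object pixels are
saturated, or when its Otsu threshold lies more than 0.15 above the batch
median.  Exclusion is automatic here (the original screening was a manual
removal of the same outliers); a keep-flagged switch retains flagged items
with annotation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .image_io import AnalysisConfig

logger = logging.getLogger(__name__)


@dataclass
class QCMetrics:
    """Per-image (slope, Otsu) and per-object (saturation) quality metrics."""

    power_log_log_slope: float
    percent_minimal: float
    percent_maximal: float
    otsu_threshold: float  # on [0, 1] normalized intensity scale

    def __post_init__(self) -> None:
        for name in ("percent_minimal", "percent_maximal"):
            v = getattr(self, name)
            if not 0.0 <= v <= 100.0:
                raise ValueError(f"{name} must lie in [0, 100], got {v}")


@dataclass
class QCFlags:
    blur_outlier: bool = False
    saturation_outlier: bool = False
    snr_outlier: bool = False

    @property
    def excluded(self) -> bool:
        return self.blur_outlier or self.saturation_outlier or self.snr_outlier


def power_log_log_slope(image: np.ndarray) -> float:
    """Least-squares slope of log10(radial PSD) vs log10(frequency).

    The 2-D power spectrum is averaged over annuli of constant spatial
    frequency up to Nyquist; the fit excludes the DC bin and the single
    highest-frequency bin, both of which are estimation-noisy.  Sharper
    images give a less negative slope.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise ValueError("expected a 2-D image")
    if min(image.shape) < 16:
        raise ValueError("image side must be >= 16 px")
    if np.all(image == image.flat[0]):
        raise ValueError("constant image has no AC power")

    f = np.fft.fft2(image - image.mean())
    psd = np.abs(f) ** 2
    fy = np.fft.fftfreq(image.shape[0])
    fx = np.fft.fftfreq(image.shape[1])
    radius = np.sqrt(fy[:, None] ** 2 + fx[None, :] ** 2)

    n_bins = min(image.shape) // 2
    edges = np.linspace(0.0, 0.5, n_bins + 1)
    which = np.digitize(radius.ravel(), edges) - 1
    valid = (which >= 0) & (which < n_bins)
    sums = np.bincount(which[valid], weights=psd.ravel()[valid], minlength=n_bins)
    counts = np.bincount(which[valid], minlength=n_bins)
    with np.errstate(invalid="ignore", divide="ignore"):
        radial = sums / counts
    centers = 0.5 * (edges[:-1] + edges[1:])

    # drop DC-adjacent first bin and the top bin; keep positive-power bins
    keep = (counts > 0) & (radial > 0)
    keep[0] = False
    keep[-1] = False
    if keep.sum() < 2:
        raise ValueError("too few spectral bins for a slope fit")
    slope = np.polyfit(np.log10(centers[keep]), np.log10(radial[keep]), 1)[0]
    return float(slope)


def percent_extreme_pixels(image: np.ndarray, mask: np.ndarray,
                           bit_depth_max: float) -> tuple[float, float]:
    """Percentages of in-mask pixels at 0 and at the detector maximum."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask")
    vals = np.asarray(image)[mask]
    n = vals.size
    pct_min = 100.0 * np.count_nonzero(vals == 0) / n
    pct_max = 100.0 * np.count_nonzero(vals >= bit_depth_max) / n
    return float(pct_min), float(pct_max)


def flag_outliers(metrics: Sequence[QCMetrics],
                  config: AnalysisConfig | None = None) -> list[QCFlags]:
    """Apply the batch outlier rules to a set of QC metric records.

    * blur: |slope − batch mean| > qc_slope_sd × batch SD (skipped with a
      warning when the batch has fewer than two members);
    * saturation: percent_maximal > qc_saturation_pct;
    * signal-to-noise: otsu_threshold > batch median + qc_otsu_dev.

    The result is invariant to batch ordering.
    """
    if config is None:
        config = AnalysisConfig()
    metrics = list(metrics)
    flags = [QCFlags() for _ in metrics]
    if not metrics:
        return flags

    slopes = np.array([m.power_log_log_slope for m in metrics], dtype=float)
    if len(metrics) >= 2:
        mean, sd = slopes.mean(), slopes.std(ddof=1)
        if sd > 0:
            for fl, s in zip(flags, slopes):
                fl.blur_outlier = bool(abs(s - mean) > config.qc_slope_sd * sd)
    else:
        logger.warning("blur rule skipped: need >= 2 images for a batch SD")

    otsus = np.array([m.otsu_threshold for m in metrics], dtype=float)
    otsu_ref = float(np.median(otsus))
    for fl, m in zip(flags, metrics):
        fl.saturation_outlier = bool(m.percent_maximal > config.qc_saturation_pct)
        fl.snr_outlier = bool(m.otsu_threshold > otsu_ref + config.qc_otsu_dev)
    return flags
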