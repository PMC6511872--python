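"""Image and table I/O: multi-channel TIFF reading, result tables, configuration.

The pipeline consumes two-channel (or more) fluorescence images — one channel
marking euchromatin (e.g. H3.3-EGFP) and one marking total chromatin (e.g.
H2B-mCherry) — stored as plain or OME-TIFF, optionally as z-stacks.  Pixel
calibration is taken from OME metadata when present; an explicit value in the
analysis configuration takes precedence (with a warning), since metadata
written by acquisition software is frequently stale or instrument-specific.
"""

from __future__ import annotations

import logging
import re
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import tifffile
import yaml

logger = logging.getLogger(__name__)

#: schema version stamped into every results table this package writes
TABLE_SCHEMA_VERSION = 1


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class ImageStack:
    """A multi-channel, optionally multi-slice fluorescence image.

    Parameters
    ----------
    channels
        Mapping from channel name to a ``(n_slices, height, width)`` array.
        2-D arrays are promoted to a single slice.
    pixel_size_xy
        Lateral pixel size in micrometres, or ``None`` if unknown.
    z_step
        Axial slice spacing in micrometres, or ``None``.
    bit_depth_max
        Maximum representable intensity (e.g. 65535 for 16-bit).  Inferred
        from the dtype for integer data; must be supplied for float data if
        saturation QC is wanted.
    """

    channels: dict[str, np.ndarray]
    pixel_size_xy: float | None = None
    z_step: float | None = None
    bit_depth_max: float | None = None

    def __post_init__(self) -> None:
        if not self.channels:
            raise ValueError("ImageStack requires at least one channel")
        promoted = {}
        for name, arr in self.channels.items():
            arr = np.asarray(arr)
            if arr.ndim == 2:
                arr = arr[np.newaxis]
            if arr.ndim != 3:
                raise ValueError(f"channel {name!r} must be 2-D or 3-D, got {arr.ndim}-D")
            promoted[name] = arr
        shapes = {a.shape for a in promoted.values()}
        if len(shapes) > 1:
            raise ValueError(f"channels have mismatched shapes: {sorted(shapes)}")
        for name, arr in promoted.items():
            if np.issubdtype(arr.dtype, np.floating) and np.nanmin(arr) < 0:
                raise ValueError(f"channel {name!r} contains negative intensities")
        self.channels = promoted
        if self.pixel_size_xy is not None and self.pixel_size_xy <= 0:
            raise ValueError("pixel_size_xy must be positive")
        if self.bit_depth_max is None:
            dt = next(iter(promoted.values())).dtype
            if np.issubdtype(dt, np.integer):
                self.bit_depth_max = float(np.iinfo(dt).max)

    @property
    def n_slices(self) -> int:
        return next(iter(self.channels.values())).shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return next(iter(self.channels.values())).shape[1:]

    def channel(self, name: str, slice_index: int | None = None) -> np.ndarray:
        """Return one channel, optionally restricted to one z-slice."""
        if name not in self.channels:
            raise KeyError(f"channel {name!r} not in stack (have {sorted(self.channels)})")
        arr = self.channels[name]
        return arr if slice_index is None else arr[slice_index]


@dataclass(frozen=True)
class ChannelMap:
    """Assignment of biological roles to image channels.

    Channel references are OME channel names, bare indices (``"0"``) or
    ``"ch<k>"`` style indices.
    """

    euchromatin: str
    total: str
    extra: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.euchromatin == self.total:
            raise ValueError("euchromatin and total channels must differ")

    @property
    def all_channels(self) -> tuple[str, ...]:
        return (self.euchromatin, self.total) + tuple(self.extra)


_ALLOWED_ZONE_MODES = ("equal_width", "equal_area")
_ALLOWED_NORM_MODES = ("mean", "studentized")
_ALLOWED_PI_POOLING = ("pixels", "zone_means")
_ALLOWED_TEXTURE_REGIONS = ("zones", "pixels")


@dataclass
class AnalysisConfig:
    """All tunable parameters of the pipeline, with their standard defaults.

    The defaults reproduce the published protocol: Gaussian smoothing of
    size 5, a 50-pixel minimum nucleus diameter, 40 equal-width radial
    zones with the 3 outermost defining the periphery P, texture over the
    10 outermost zones with an 8-level co-occurrence matrix, and outlier
    exclusion at 2 SD blur deviation / 0.2% saturation / 0.15 above the
    reference Otsu threshold, at significance level alpha = 0.05.
    """

    smoothing_size: float = 5.0       # CellProfiler-style artifact size (px)
    smoothing_sigma: float | None = None  # explicit Gaussian sigma override
    min_diameter: float = 50.0        # px, equivalent circular diameter
    n_zones: int = 40
    peripheral_zones: int | None = None   # resolved to min(3, n_zones - 1)
    texture_periphery_zones: int = 10
    glcm_levels: int = 8
    qc_slope_sd: float = 2.0          # blur rule: deviation in batch SDs
    qc_saturation_pct: float = 0.2    # % of object pixels at bit_depth_max
    qc_otsu_dev: float = 0.15         # on [0, 1] normalized intensity
    alpha: float = 0.05
    ratio_epsilon: float = 1e-6
    min_mask_pixels: int = 100
    zone_mode: str = "equal_width"
    normalization_mode: str = "mean"
    pi_pooling: str = "pixels"
    texture_region: str = "zones"
    fill_holes: bool = True
    border_exclude: bool = True
    pixel_size_xy: float | None = None  # µm; overrides file metadata
    z_step: float | None = None         # µm
    bit_depth_max: float | None = None  # required for float images
    holm_correction: bool = False
    keep_flagged: bool = False
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_zones < 2:
            raise ValueError("n_zones must be >= 2")
        if self.peripheral_zones is None:
            self.peripheral_zones = min(3, self.n_zones - 1)
        if not 1 <= self.peripheral_zones < self.n_zones:
            raise ValueError("peripheral_zones must lie in [1, n_zones)")
        if self.texture_periphery_zones < 1:
            raise ValueError("texture_periphery_zones must be >= 1")
        if self.glcm_levels < 2:
            raise ValueError("glcm_levels must be >= 2")
        for name in ("smoothing_size", "min_diameter", "qc_slope_sd",
                     "qc_saturation_pct", "qc_otsu_dev", "ratio_epsilon"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.zone_mode not in _ALLOWED_ZONE_MODES:
            raise ValueError(f"zone_mode must be one of {_ALLOWED_ZONE_MODES}")
        if self.normalization_mode not in _ALLOWED_NORM_MODES:
            raise ValueError(f"normalization_mode must be one of {_ALLOWED_NORM_MODES}")
        if self.pi_pooling not in _ALLOWED_PI_POOLING:
            raise ValueError(f"pi_pooling must be one of {_ALLOWED_PI_POOLING}")
        if self.texture_region not in _ALLOWED_TEXTURE_REGIONS:
            raise ValueError(f"texture_region must be one of {_ALLOWED_TEXTURE_REGIONS}")

    @property
    def sigma(self) -> float:
        """Gaussian sigma used for smoothing.

        The smoothing size follows the CellProfiler convention of a feature
        *diameter*: sigma = size / 2.35 (FWHM-to-sigma conversion).
        """
        if self.smoothing_sigma is not None:
            return self.smoothing_sigma
        return self.smoothing_size / 2.35


def load_config(path: str | Path | None = None,
                overrides: Mapping | None = None) -> AnalysisConfig:
    """Load an :class:`AnalysisConfig` from a YAML file.

    A missing or empty file yields the defaults.  Unknown keys are rejected
    rather than ignored, so typos do not silently fall back to defaults.
    """
    data: dict = {}
    if path is not None:
        text = Path(path).read_text()
        loaded = yaml.safe_load(text)
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ValueError(f"config file {path} must contain a mapping")
        data.update(loaded)
    if overrides:
        data.update(overrides)
    known = {f.name for f in fields(AnalysisConfig)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return AnalysisConfig(**data)


# ---------------------------------------------------------------------------
# TIFF reading / writing
# ---------------------------------------------------------------------------

_OME_NS = re.compile(r"\{.*\}")


def _strip_ns(tag: str) -> str:
    return _OME_NS.sub("", tag)


def _parse_ome(ome_xml: str) -> tuple[list[str], float | None, float | None]:
    """Extract channel names and physical pixel sizes from OME-XML."""
    names: list[str] = []
    px = pz = None
    try:
        root = ET.fromstring(ome_xml)
    except ET.ParseError:
        return names, px, pz
    for elem in root.iter():
        tag = _strip_ns(elem.tag)
        if tag == "Pixels":
            if px is None and elem.get("PhysicalSizeX"):
                px = float(elem.get("PhysicalSizeX"))
            if pz is None and elem.get("PhysicalSizeZ"):
                pz = float(elem.get("PhysicalSizeZ"))
        elif tag == "Channel":
            names.append(elem.get("Name") or f"ch{len(names)}")
    return names, px, pz


def _resolve_channel(ref: str, names: Sequence[str], n_channels: int) -> int:
    """Map a channel reference (name, index, or 'ch<k>') to an index."""
    if ref in names:
        return list(names).index(ref)
    m = re.fullmatch(r"(?:ch)?(\d+)", ref)
    if m:
        idx = int(m.group(1))
        if idx < n_channels:
            return idx
    raise KeyError(
        f"channel {ref!r} not found: file has {n_channels} channel(s)"
        + (f" named {list(names)}" if names else "")
    )


def read_stack(path: str | Path, channel_map: ChannelMap,
               config: AnalysisConfig | None = None) -> ImageStack:
    """Read a TIFF / OME-TIFF into an :class:`ImageStack`.

    The returned stack carries only the channels declared in *channel_map*,
    keyed by their mapped reference.  Calibration comes from OME metadata;
    a ``pixel_size_xy`` / ``z_step`` in *config* overrides it.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with tifffile.TiffFile(str(path)) as tf:
        series = tf.series[0]
        data = series.asarray()
        axes = series.axes
        ome_names: list[str] = []
        px = pz = None
        if tf.ome_metadata:
            ome_names, px, pz = _parse_ome(tf.ome_metadata)

    data = _to_czyx(data, axes)
    n_channels = data.shape[0]

    channels: dict[str, np.ndarray] = {}
    for ref in channel_map.all_channels:
        idx = _resolve_channel(ref, ome_names, n_channels)
        channels[ref] = data[idx]

    pixel_size, z_step = px, pz
    if config is not None:
        if config.pixel_size_xy is not None:
            if px is not None and not np.isclose(px, config.pixel_size_xy):
                logger.warning(
                    "config pixel_size_xy=%.4g overrides file metadata %.4g",
                    config.pixel_size_xy, px)
            pixel_size = config.pixel_size_xy
        if config.z_step is not None:
            z_step = config.z_step
    bit_depth = config.bit_depth_max if config is not None else None
    return ImageStack(channels=channels, pixel_size_xy=pixel_size,
                      z_step=z_step, bit_depth_max=bit_depth)


def _to_czyx(data: np.ndarray, axes: str) -> np.ndarray:
    """Reorder an arbitrary tifffile axis string into (C, Z, Y, X)."""
    axes = axes.upper().replace("S", "C").replace("I", "Z").replace("Q", "Z")
    if data.ndim == 2:
        return data[np.newaxis, np.newaxis]
    order = [ax for ax in axes if ax in "CZYX"]
    if len(order) != data.ndim or sorted(set(order)) != sorted(order):
        raise ValueError(f"cannot interpret TIFF axes {axes!r} with shape {data.shape}")
    arr = data
    for missing in "CZYX":
        if missing not in order:
            arr = arr[np.newaxis]
            order.insert(0, missing)
    perm = [order.index(ax) for ax in "CZYX"]
    return np.transpose(arr, perm)


def write_stack(path: str | Path, stack: ImageStack,
                channel_names: Sequence[str] | None = None) -> None:
    """Write an :class:`ImageStack` as OME-TIFF with channel names and calibration."""
    path = Path(path)
    names = list(channel_names) if channel_names is not None else list(stack.channels)
    data = np.stack([stack.channels[n] for n in stack.channels])  # (C, Z, Y, X)
    metadata: dict = {"axes": "CZYX", "Channel": {"Name": names}}
    if stack.pixel_size_xy is not None:
        metadata["PhysicalSizeX"] = stack.pixel_size_xy
        metadata["PhysicalSizeY"] = stack.pixel_size_xy
        metadata["PhysicalSizeXUnit"] = metadata["PhysicalSizeYUnit"] = "µm"
    if stack.z_step is not None:
        metadata["PhysicalSizeZ"] = stack.z_step
        metadata["PhysicalSizeZUnit"] = "µm"
    tifffile.imwrite(str(path), data, ome=True, metadata=metadata)


# ---------------------------------------------------------------------------
# Result tables
# ---------------------------------------------------------------------------

def profiles_to_table(records: Iterable) -> pd.DataFrame:
    """Build the per-nucleus radial-profile table.

    *records* is an iterable of :class:`fric.pipeline.NucleusResult`-like
    objects exposing ``image_id``, ``nucleus_id``, ``group``, ``profile``
    (with ``zone_means`` and ``zone_pixel_counts``), ``pi_ratio`` and
    ``flags``.  One row per nucleus; zone columns are ``zone_1..zone_n``
    ordered periphery → interior.
    """
    records = list(records)
    n_zones = None
    rows = []
    for rec in records:
        prof = rec.profile
        if n_zones is None:
            n_zones = prof.n_zones
        elif prof.n_zones != n_zones:
            raise ValueError("all profiles must share n_zones")
        row: dict = {
            "schema_version": TABLE_SCHEMA_VERSION,
            "image_id": rec.image_id,
            "nucleus_id": rec.nucleus_id,
            "group": rec.group,
            "n_zones": prof.n_zones,
            "pi_ratio": rec.pi_ratio,
        }
        for k in range(prof.n_zones):
            row[f"zone_{k + 1}"] = prof.zone_means[k]
        for k in range(prof.n_zones):
            row[f"count_{k + 1}"] = prof.zone_pixel_counts[k]
        flags = getattr(rec, "flags", None)
        row["blur_outlier"] = bool(flags.blur_outlier) if flags else False
        row["saturation_outlier"] = bool(flags.saturation_outlier) if flags else False
        row["snr_outlier"] = bool(flags.snr_outlier) if flags else False
        row["excluded"] = bool(flags.excluded) if flags else False
        rows.append(row)
    if not rows:
        cols = ["schema_version", "image_id", "nucleus_id", "group",
                "n_zones", "pi_ratio", "blur_outlier", "saturation_outlier",
                "snr_outlier", "excluded"]
        return pd.DataFrame(columns=cols)
    return pd.DataFrame(rows)


def write_profile_table(records: Iterable, path: str | Path) -> None:
    """Write the per-nucleus profile table as RFC-4180 CSV (UTF-8, '.' decimal)."""
    profiles_to_table(records).to_csv(path, index=False)


def read_profile_table(path: str | Path) -> pd.DataFrame:
    """Read a profile CSV written by :func:`write_profile_table`."""
    df = pd.read_csv(path)
    if "schema_version" in df.columns and len(df):
        versions = set(df["schema_version"].unique())
        if versions - {TABLE_SCHEMA_VERSION}:
            logger.warning("profile table schema version(s) %s differ from %s",
                           versions, TABLE_SCHEMA_VERSION)
    return df


def zone_columns(df: pd.DataFrame) -> list[str]:
    """Ordered list of zone_k columns present in a profile table."""
    cols = [c for c in df.columns if re.fullmatch(r"zone_\d+", c)]
    return sorted(cols, key=lambda c: int(c.split("_")[1]))
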