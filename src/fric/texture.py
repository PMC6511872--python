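"""Gray-level co-occurrence texture of the (inverse-)ratio image.

Structural organization of chromatin is quantified as the Haralick
variance of a gray-level co-occurrence matrix (GLCM).  The region of
interest (the heterochromatin-weighted inverse ratio, by default) is
quantized to 8 levels between its own minimum and maximum; pair
frequencies at the four unit offsets are accumulated symmetrically and
normalized, and the variance of the level index under that distribution
measures how structured (speckled, domain-forming) the region is — zero
for a flat region, growing with speckle amplitude.

Texture is evaluated both over the peripheral band (the 10 outermost
radial zones) and over the whole nucleus, because peripheral
heterochromatin remodelling changes the periphery without necessarily
changing the bulk.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .ratiometric import RatioImage
from .zonation import ZoneMap

#: the four unit-distance offsets (E, S, SE, SW); with symmetry this
#: covers all 8 neighbours
DEFAULT_OFFSETS: tuple[tuple[int, int], ...] = ((0, 1), (1, 0), (1, 1), (1, -1))


@dataclass(frozen=True)
class GlcmSpec:
    levels: int = 8
    offsets: tuple[tuple[int, int], ...] = DEFAULT_OFFSETS
    symmetric: bool = True
    normalized: bool = True

    def __post_init__(self) -> None:
        if self.levels < 2:
            raise ValueError("levels must be >= 2")
        if not self.offsets:
            raise ValueError("at least one offset required")


@dataclass
class TextureResult:
    variance_periphery: float
    variance_whole: float
    spec: GlcmSpec = field(default_factory=GlcmSpec)


def quantize_image(image: np.ndarray, mask: np.ndarray, levels: int) -> np.ndarray:
    """Quantize in-mask intensities into ``levels`` equal-width bins.

    The binning is min–max relative to the region, so adding a constant to
    the raw image leaves the result unchanged.  The minimum maps to level 1
    and the maximum to ``levels``; a constant region maps entirely to
    level 1.  Pixels outside the mask are 0.
    """
    image = np.asarray(image, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    out = np.zeros(image.shape, dtype=np.int32)
    vals = image[mask]
    if vals.size == 0:
        return out
    lo, hi = float(np.nanmin(vals)), float(np.nanmax(vals))
    if hi == lo:
        out[mask] = 1
        return out
    q = np.floor((vals - lo) / (hi - lo) * levels).astype(int) + 1
    out[mask] = np.clip(q, 1, levels)
    return out


def glcm(quantized: np.ndarray, region: np.ndarray,
         spec: GlcmSpec = GlcmSpec()) -> np.ndarray:
    """Co-occurrence probability matrix over an irregular region.

    Only pixel pairs with *both* members inside the region contribute, so
    pairs crossing the region boundary are excluded.  Counts are summed
    over all offsets, symmetrized, and normalized to total probability 1.
    """
    region = np.asarray(region, dtype=bool)
    q = np.asarray(quantized)
    L = spec.levels
    counts = np.zeros((L, L), dtype=float)
    h, w = q.shape
    for dy, dx in spec.offsets:
        ys = slice(max(0, -dy), min(h, h - dy))
        xs = slice(max(0, -dx), min(w, w - dx))
        ys2 = slice(max(0, dy), min(h, h + dy))
        xs2 = slice(max(0, dx), min(w, w + dx))
        both = region[ys, xs] & region[ys2, xs2]
        a = q[ys, xs][both] - 1
        b = q[ys2, xs2][both] - 1
        np.add.at(counts, (a, b), 1.0)
    if spec.symmetric:
        counts = counts + counts.T
    total = counts.sum()
    if total == 0:
        raise ValueError("no valid in-region pixel pairs for any offset")
    if spec.normalized:
        counts /= total
    return counts


def glcm_variance(P: np.ndarray, atol: float = 1e-8) -> float:
    """Haralick variance of a normalized co-occurrence matrix.

    variance = Σ_ij (i − µ)² P(i, j) with µ = Σ_ij i·P(i, j) over the
    (1-based) row level index; for a symmetric matrix the row and column
    forms coincide.
    """
    P = np.asarray(P, dtype=float)
    if abs(P.sum() - 1.0) > atol:
        raise ValueError("co-occurrence matrix must be normalized to sum 1")
    i = np.arange(1, P.shape[0] + 1, dtype=float)[:, None]
    mu = float((i * P).sum())
    return float(((i - mu) ** 2 * P).sum())


def region_glcm_variance(image: np.ndarray, region: np.ndarray,
                         spec: GlcmSpec = GlcmSpec()) -> float:
    """Quantize a region and return its GLCM variance in one step."""
    q = quantize_image(image, region, spec.levels)
    return glcm_variance(glcm(q, region, spec))


def periphery_texture(ratio: RatioImage, zones: ZoneMap,
                      spec: GlcmSpec = GlcmSpec(),
                      n_periphery_zones: int = 10) -> TextureResult:
    """GLCM variance of a ratio (or inverse-ratio) image, periphery and whole.

    The periphery is the ``n_periphery_zones`` outermost radial zones;
    quantization is performed per region so that each variance reflects
    local structure on its own intensity range.
    """
    if zones.n_zones < n_periphery_zones:
        raise ValueError(
            f"zone map has {zones.n_zones} zones, need >= {n_periphery_zones}")
    peri = zones.periphery_mask(n_periphery_zones) & ratio.mask
    whole = zones.mask & ratio.mask
    if peri.sum() < 2:
        raise ValueError("peripheral region too small for texture")
    return TextureResult(
        variance_periphery=region_glcm_variance(ratio.ratio, peri, spec),
        variance_whole=region_glcm_variance(ratio.ratio, whole, spec),
        spec=spec,
    )
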