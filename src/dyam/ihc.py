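"""PD-L1 immunohistochemistry spatial-expression quantification.

A masked RGB slide image is color-deconvolved into DAB (the brown PD-L1
chromogen) and hematoxylin (blue counterstain) optical-density channels;
per-pixel gray-level co-occurrence matrices over a small kernel around each
tumor pixel yield feature maps whose summary statistics form two feature
vectors:

* IHC-A (18 features): six statistics of the GLCM-autocorrelation map plus
  twelve statistics of the masked DAB intensity distribution.
* IHC-G (150 features): the same six statistics of all 25 GLCM feature maps.

The tumor proportion score (TPS) — the fraction of viable tumor cells with
membranous staining — accompanies the texture blocks; slides with fewer than
100 viable tumor cells are non-evaluable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.color import hdx_from_rgb, separate_stains

from ._texture import GLCM_FEATURE_NAMES, glcm_features, pixel_glcm_stack, quantize

#: Summary statistics applied to each feature map (and to autocorrelation).
SUMMARY_STATS = ("mean", "sd", "skewness", "kurtosis", "median", "max")

#: Statistics of the masked DAB pixel-intensity distribution in IHC-A.
INTENSITY_STATS = (
    "mean",
    "sd",
    "skewness",
    "kurtosis",
    "median",
    "max",
    "min",
    "range",
    "p10",
    "p90",
    "iqr",
    "uniformity",
)

IHC_A_NAMES = tuple(f"autocorrelation_{s}" for s in SUMMARY_STATS) + tuple(
    f"intensity_{s}" for s in INTENSITY_STATS
)
IHC_G_NAMES = tuple(f"{feat}_{s}" for feat in GLCM_FEATURE_NAMES for s in SUMMARY_STATS)

#: Minimum viable tumor cells for a TPS call.
MIN_TUMOR_CELLS = 100
#: PD-L1 positivity cut: TPS >= 1%.
TPS_POSITIVE = 0.01


@dataclass
class StainMaps:
    """Deconvolved stain intensities and the tumor mask they live on."""

    dab_intensity: np.ndarray
    hematoxylin_intensity: np.ndarray
    tumor_mask: np.ndarray

    def __post_init__(self) -> None:
        if not (self.dab_intensity.shape == self.hematoxylin_intensity.shape == self.tumor_mask.shape):
            raise ValueError("stain maps and mask must share shape")


@dataclass
class TextureSummary:
    """IHC-A (18), IHC-G (150) feature vectors and the slide TPS."""

    ihc_a: np.ndarray
    ihc_g: np.ndarray
    tps: float | None = None

    def __post_init__(self) -> None:
        self.ihc_a = np.asarray(self.ihc_a, dtype=float)
        self.ihc_g = np.asarray(self.ihc_g, dtype=float)
        if self.ihc_a.shape != (len(IHC_A_NAMES),):
            raise ValueError(f"ihc_a must have length {len(IHC_A_NAMES)}")
        if self.ihc_g.shape != (len(IHC_G_NAMES),):
            raise ValueError(f"ihc_g must have length {len(IHC_G_NAMES)}")


def deconvolve_stain(rgb_image: np.ndarray, tumor_mask: np.ndarray, stain_matrix: np.ndarray | None = None) -> StainMaps:
    """Separate an H-DAB slide into hematoxylin and DAB optical densities.

    Uses the published H-DAB stain vectors by default (overridable).  A pure
    white pixel has zero optical density in both channels; intensities are
    clipped at zero.
    """
    rgb_image = np.asarray(rgb_image)
    tumor_mask = np.asarray(tumor_mask, dtype=bool)
    if rgb_image.shape[:2] != tumor_mask.shape:
        raise ValueError("image and mask shapes differ")
    if not tumor_mask.any():
        raise ValueError("empty tumor mask")
    if rgb_image.dtype != np.float64:
        rgb_image = rgb_image.astype(float) / (255.0 if rgb_image.max() > 1 else 1.0)
    conv = np.linalg.inv(stain_matrix) if stain_matrix is not None else hdx_from_rgb
    # separate_stains scales optical density by 1/log10(1e6); undo it
    stains = separate_stains(rgb_image, conv) * np.log10(1e6)
    hema = np.clip(stains[..., 0], 0.0, None)
    dab = np.clip(stains[..., 1], 0.0, None)
    return StainMaps(dab_intensity=dab, hematoxylin_intensity=hema, tumor_mask=tumor_mask)


def glcm_pixel_map(
    intensity_map: np.ndarray,
    tumor_mask: np.ndarray,
    kernel: int = 3,
    n_gray_levels: int = 16,
    glcm_feature_set: tuple[str, ...] = GLCM_FEATURE_NAMES,
) -> dict[str, np.ndarray]:
    """Per-pixel GLCM feature maps over a ``kernel`` x ``kernel`` window.

    The intensity map is quantized to ``n_gray_levels`` equal-width gray
    levels over the masked range; each masked pixel's co-occurrence matrix is
    accumulated symmetrically over the four canonical in-plane directions
    within its window.  Pixels outside the mask (or whose window holds no
    co-occurring pair) carry NaN.
    """
    intensity_map = np.asarray(intensity_map, dtype=float)
    tumor_mask = np.asarray(tumor_mask, dtype=bool)
    if intensity_map.shape != tumor_mask.shape:
        raise ValueError("map and mask shapes differ")
    if not tumor_mask.any():
        raise ValueError("empty tumor mask")
    if n_gray_levels < 2:
        raise ValueError("n_gray_levels must be >= 2")
    levels = np.zeros(intensity_map.shape, dtype=int)
    levels[tumor_mask], _ = quantize(intensity_map[tumor_mask], n_levels=n_gray_levels)
    stack, valid = pixel_glcm_stack(levels, tumor_mask, n_gray_levels, kernel=kernel)
    feats = glcm_features(stack[valid])  # (n_valid, 25)
    unknown = set(glcm_feature_set) - set(GLCM_FEATURE_NAMES)
    if unknown:
        raise ValueError(f"unknown GLCM features: {sorted(unknown)}")
    maps: dict[str, np.ndarray] = {}
    for name in glcm_feature_set:
        m = np.full(intensity_map.shape, np.nan)
        m[valid] = feats[:, GLCM_FEATURE_NAMES.index(name)]
        maps[name] = m
    return maps


def _stat(values: np.ndarray, stat: str) -> float:
    """One summary statistic; moment statistics of a constant sample are 0."""
    x = np.asarray(values, dtype=float)
    mean = x.mean()
    std = x.std()
    if stat == "mean":
        return float(mean)
    if stat == "sd":
        return float(std)
    if stat == "skewness":
        return float(((x - mean) ** 3).mean() / std**3) if std > 0 else 0.0
    if stat == "kurtosis":
        return float(((x - mean) ** 4).mean() / std**4 - 3.0) if std > 0 else 0.0
    if stat == "median":
        return float(np.median(x))
    if stat == "max":
        return float(x.max())
    if stat == "min":
        return float(x.min())
    if stat == "range":
        return float(x.max() - x.min())
    if stat == "p10":
        return float(np.percentile(x, 10))
    if stat == "p90":
        return float(np.percentile(x, 90))
    if stat == "iqr":
        return float(np.percentile(x, 75) - np.percentile(x, 25))
    if stat == "uniformity":
        hist, _ = np.histogram(x, bins=16)
        p = hist / hist.sum()
        return float((p**2).sum())
    raise ValueError(f"unknown statistic {stat!r}")


def summarize_texture(
    feature_maps: dict[str, np.ndarray],
    dab_intensity: np.ndarray,
    tumor_mask: np.ndarray,
    tps: float | None = None,
) -> TextureSummary:
    """Collapse per-pixel feature maps into the IHC-A / IHC-G vectors."""
    tumor_mask = np.asarray(tumor_mask, dtype=bool)
    missing = set(GLCM_FEATURE_NAMES) - set(feature_maps)
    if missing:
        raise ValueError(f"feature maps missing: {sorted(missing)}")
    intensities = np.asarray(dab_intensity, dtype=float)[tumor_mask]
    if intensities.size == 0:
        raise ValueError("empty tumor mask")

    def masked(name: str) -> np.ndarray:
        vals = feature_maps[name][tumor_mask]
        vals = vals[np.isfinite(vals)]
        if vals.size == 0:
            raise ValueError(f"feature map {name!r} has no valid pixels in mask")
        return vals

    auto = masked("autocorrelation")
    ihc_a = [_stat(auto, s) for s in SUMMARY_STATS] + [_stat(intensities, s) for s in INTENSITY_STATS]
    ihc_g = [_stat(masked(feat), s) for feat in GLCM_FEATURE_NAMES for s in SUMMARY_STATS]
    return TextureSummary(ihc_a=np.array(ihc_a), ihc_g=np.array(ihc_g), tps=tps)


def compute_tps(stained_cell_count: int, viable_tumor_cell_count: int) -> tuple[float | None, bool]:
    """Tumor proportion score and positivity flag.

    Returns ``(tps, positive)``; a slide with fewer than 100 viable tumor
    cells is non-evaluable and returns ``(None, False)``.
    """
    if stained_cell_count < 0 or viable_tumor_cell_count < 0:
        raise ValueError("cell counts must be nonnegative")
    if stained_cell_count > viable_tumor_cell_count:
        raise ValueError("stained cells cannot exceed viable tumor cells")
    if viable_tumor_cell_count < MIN_TUMOR_CELLS:
        return None, False
    tps = stained_cell_count / viable_tumor_cell_count
    return tps, tps >= TPS_POSITIVE


def featurize_slide(
    rgb_image: np.ndarray,
    tumor_mask: np.ndarray,
    tps: float | None = None,
    kernel: int = 3,
    n_gray_levels: int = 16,
) -> TextureSummary:
    """Full slide pipeline: deconvolve, map per-pixel GLCMs, summarize."""
    stains = deconvolve_stain(rgb_image, tumor_mask)
    maps = glcm_pixel_map(stains.dab_intensity, tumor_mask, kernel=kernel, n_gray_levels=n_gray_levels)
    return summarize_texture(maps, stains.dab_intensity, tumor_mask, tps=tps)
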