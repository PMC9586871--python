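"""CT lesion texture features, segmentation-perturbation robustness and
patient-level aggregation.

Feature reduction follows a stability-under-perturbation scheme: each lesion
segmentation is perturbed a number of times (default ten), features are
recomputed on every perturbed mask, and a per-feature robustness *z* score is
formed as the within-lesion perturbation variance (averaged over lesions)
divided by the feature's variance across the whole cohort.  Features whose z
is below a threshold (default 0.15) vary only slightly relative to their
cohort-wide dynamic range and are retained.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from ._texture import (
    FIRST_ORDER_NAMES,
    GLCM_FEATURE_NAMES,
    aggregate_glcm,
    first_order_features,
    glcm_features,
    quantize,
)
from .records import LesionBag  # noqa: F401  (re-exported container)

#: Canonical feature order: first-order family then GLCM family.
RADIOMICS_FEATURE_NAMES = tuple(f"firstorder_{n}" for n in FIRST_ORDER_NAMES) + tuple(
    f"glcm_{n}" for n in GLCM_FEATURE_NAMES
)


@dataclass
class RadiomicsConfig:
    """Extraction settings: gray-level bin width and histogram bins."""

    bin_width: float = 25.0
    first_order_bins: int = 16

    def __post_init__(self) -> None:
        if self.bin_width <= 0:
            raise ValueError("bin_width must be positive")
        if self.first_order_bins < 2:
            raise ValueError("first_order_bins must be >= 2")


@dataclass
class RobustnessReport:
    """Per-feature robustness z scores and the retained-feature set."""

    z: dict[str, float]
    threshold: float = 0.15
    degenerate: set[str] = field(default_factory=set)

    @property
    def retained(self) -> set[str]:
        return {name for name, z in self.z.items() if z < self.threshold}

    def to_dict(self) -> dict:
        return {
            "threshold": self.threshold,
            "z": self.z,
            "retained": sorted(self.retained),
            "degenerate": sorted(self.degenerate),
        }


def extract_radiomics(volume: np.ndarray, mask: np.ndarray, config: RadiomicsConfig | None = None) -> np.ndarray:
    """Texture feature vector (first-order + GLCM families) of one ROI.

    Intensities inside ``mask`` are discretized with a fixed bin width before
    co-occurrence accumulation over all symmetric 3-D (or 2-D) offsets.
    Feature order is :data:`RADIOMICS_FEATURE_NAMES`.
    """
    config = config or RadiomicsConfig()
    volume = np.asarray(volume, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if volume.shape != mask.shape:
        raise ValueError("volume and mask grids differ")
    if not mask.any():
        raise ValueError("empty mask")
    roi = volume[mask]
    fo = first_order_features(roi, n_bins=config.first_order_bins)
    levels = np.zeros(volume.shape, dtype=int)
    roi_levels, n_levels = quantize(roi, bin_width=config.bin_width)
    levels[mask] = roi_levels
    P = aggregate_glcm(levels, mask, n_levels)
    glcm = glcm_features(P)
    return np.concatenate([[fo[n] for n in FIRST_ORDER_NAMES], glcm])


def perturb_segmentation(
    mask: np.ndarray,
    n_perturbations: int = 10,
    seed: int | None = None,
    patch_radius: int = 2,
    flip_fraction: float = 0.3,
    min_voxels: int = 8,
    dice_floor: float = 0.5,
) -> list[np.ndarray]:
    """Boundary-patch perturbations of a binary segmentation.

    Each perturbation flips spherical patches centred on randomly chosen
    boundary voxels (adding patches centred on outside-boundary voxels,
    removing those centred inside), emulating supervoxel-style contour
    randomization.  Flipping stops before the Dice overlap with the original
    would drop below ``dice_floor``; results never become empty.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask")
    if mask.sum() < min_voxels:
        raise ValueError(f"mask too small to perturb (< {min_voxels} voxels)")
    rng = np.random.default_rng(seed)
    out: list[np.ndarray] = []
    inner = mask & ~ndimage.binary_erosion(mask)
    outer = ndimage.binary_dilation(mask) & ~mask
    boundary = np.argwhere(inner | outer)
    n_patches = max(1, int(round(flip_fraction * len(boundary) / (2 * patch_radius + 1))))
    footprint = _ball(patch_radius, mask.ndim)
    orig_sum = int(mask.sum())
    for _ in range(n_perturbations):
        perturbed = mask.copy()
        centers = boundary[rng.choice(len(boundary), size=n_patches, replace=False)]
        for c in centers:
            patch = _patch_slices(c, patch_radius, mask.shape)
            fp = footprint[tuple(slice(p.start - (ci - patch_radius), p.stop - (ci - patch_radius)) for p, ci in zip(patch, c))]
            candidate = perturbed.copy()
            if mask[tuple(c)]:
                candidate[patch] &= ~fp
            else:
                candidate[patch] |= fp
            inter = int((candidate & mask).sum())
            dice = 2.0 * inter / (candidate.sum() + orig_sum)
            if candidate.any() and dice >= dice_floor:
                perturbed = candidate
        out.append(perturbed)
    return out


def _ball(radius: int, ndim: int) -> np.ndarray:
    grids = np.indices((2 * radius + 1,) * ndim) - radius
    return (grids**2).sum(axis=0) <= radius**2


def _patch_slices(center, radius, shape):
    return tuple(slice(max(0, c - radius), min(s, c + radius + 1)) for c, s in zip(center, shape))


def dice(a: np.ndarray, b: np.ndarray) -> float:
    """Dice overlap of two binary masks."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    denom = a.sum() + b.sum()
    if denom == 0:
        raise ValueError("both masks empty")
    return 2.0 * float((a & b).sum()) / float(denom)


def robustness_z(
    original_features: np.ndarray,
    perturbed_features: np.ndarray,
    threshold: float = 0.15,
    feature_names: tuple[str, ...] | None = None,
) -> RobustnessReport:
    """Robustness z scores from original and perturbed feature matrices.

    Parameters
    ----------
    original_features : (n_lesions, n_features)
        Features of the unperturbed segmentations across the cohort.
    perturbed_features : (n_lesions, n_perturbations, n_features)
        Features recomputed on each perturbed segmentation.
    threshold : float
        Retention cut; features with ``z < threshold`` are kept.

    For each feature, ``z`` is the perturbation variance within a lesion,
    averaged over lesions, divided by the feature's variance across the
    cohort of original segmentations.  A feature constant across the cohort
    has no dynamic range to compare against; it is flagged degenerate and
    excluded from the retained set.
    """
    orig = np.asarray(original_features, dtype=float)
    pert = np.asarray(perturbed_features, dtype=float)
    if orig.ndim != 2 or pert.ndim != 3:
        raise ValueError("expected (lesions, features) and (lesions, perturbations, features)")
    if orig.shape[0] != pert.shape[0] or orig.shape[1] != pert.shape[2]:
        raise ValueError("original and perturbed feature shapes disagree")
    if orig.shape[0] < 2:
        raise ValueError("need >= 2 lesions")
    if pert.shape[1] < 2:
        raise ValueError("need >= 2 perturbations per lesion")
    names = feature_names or tuple(f"f{i}" for i in range(orig.shape[1]))
    within = pert.var(axis=1, ddof=1).mean(axis=0)  # mean over lesions
    cohort = orig.var(axis=0, ddof=1)
    z: dict[str, float] = {}
    degenerate: set[str] = set()
    for k, name in enumerate(names):
        if cohort[k] <= 0:
            degenerate.add(name)
        else:
            z[name] = float(within[k] / cohort[k])
    return RobustnessReport(z=z, threshold=threshold, degenerate=degenerate)


def aggregate_lesion_scores(scores) -> float:
    """Patient-level score: arithmetic mean of per-lesion predictions."""
    scores = np.asarray(scores, dtype=float)
    if scores.size == 0:
        raise ValueError("no lesion scores to aggregate")
    return float(scores.mean())
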