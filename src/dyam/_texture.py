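"""Gray-level co-occurrence (GLCM) and first-order texture primitives.

This module is the package's texture engine: gray-level quantization,
co-occurrence accumulation (whole-ROI for 3-D lesions, per-pixel 3x3-kernel
maps for 2-D stain images) and a bank of 25 GLCM functionals plus a
first-order statistics family.  Gray levels are numbered 1..Ng inside the
feature formulas, matching the standard radiomics convention.

All GLCM feature functions are batched: they accept a stack of normalized
co-occurrence matrices of shape (..., Ng, Ng) and return (...,) arrays, so a
whole image's per-pixel matrices are reduced in one vectorized pass.
"""

from __future__ import annotations

import numpy as np

# Canonical in-plane offsets (symmetric pairs are accumulated in both
# directions, so four offsets cover all eight neighbours).
OFFSETS_2D = ((0, 1), (1, 0), (1, 1), (1, -1))

# Thirteen unique 3-D directions (26-connectivity, one of each +/- pair).
OFFSETS_3D = tuple(
    (dz, dy, dx)
    for dz in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dx in (-1, 0, 1)
    if (dz, dy, dx) > (0, 0, 0)
)

#: Fixed order of the 25 GLCM functionals.  ``dissimilarity`` coincides with
#: ``difference_average`` under the symmetric convention; it is retained so the
#: bank covers the full classic catalogue (see docs/methods.md).
GLCM_FEATURE_NAMES = (
    "autocorrelation",
    "joint_average",
    "cluster_prominence",
    "cluster_shade",
    "cluster_tendency",
    "contrast",
    "correlation",
    "difference_average",
    "difference_entropy",
    "difference_variance",
    "dissimilarity",
    "joint_energy",
    "joint_entropy",
    "imc1",
    "imc2",
    "idm",
    "idmn",
    "id",
    "idn",
    "inverse_variance",
    "maximum_probability",
    "sum_average",
    "sum_entropy",
    "sum_squares",
    "mcc",
)

FIRST_ORDER_NAMES = (
    "mean",
    "median",
    "minimum",
    "maximum",
    "p10",
    "p90",
    "iqr",
    "range",
    "mad",
    "variance",
    "skewness",
    "kurtosis",
    "energy",
    "rms",
    "entropy",
    "uniformity",
)


def quantize(values: np.ndarray, n_levels: int | None = None, bin_width: float | None = None):
    """Discretize intensities into integer gray levels ``0..Ng-1``.

    Exactly one of ``n_levels`` (equal-width bins spanning the observed range)
    or ``bin_width`` (fixed-width bins anchored at the minimum) must be given.
    Returns ``(levels, n_levels)``.
    """
    values = np.asarray(values, dtype=float)
    if (n_levels is None) == (bin_width is None):
        raise ValueError("give exactly one of n_levels or bin_width")
    lo = float(values.min())
    hi = float(values.max())
    if bin_width is not None:
        if bin_width <= 0:
            raise ValueError("bin_width must be positive")
        levels = np.floor((values - lo) / bin_width).astype(int)
        return levels, int(levels.max()) + 1
    if n_levels < 2:
        raise ValueError("n_levels must be >= 2")
    if hi == lo:
        return np.zeros(values.shape, dtype=int), n_levels
    levels = np.floor((values - lo) / (hi - lo) * n_levels).astype(int)
    np.clip(levels, 0, n_levels - 1, out=levels)
    return levels, n_levels


def _xlog2x(p: np.ndarray) -> np.ndarray:
    out = np.zeros_like(p)
    nz = p > 0
    out[nz] = p[nz] * np.log2(p[nz])
    return out


def glcm_features(P: np.ndarray) -> np.ndarray:
    """Evaluate the 25-feature bank on normalized symmetric GLCMs.

    Parameters
    ----------
    P : array of shape (..., Ng, Ng)
        Normalized (rows+columns sum to 1 per matrix) symmetric co-occurrence
        probabilities.

    Returns
    -------
    array of shape (..., 25) in :data:`GLCM_FEATURE_NAMES` order.
    """
    P = np.asarray(P, dtype=float)
    ng = P.shape[-1]
    i = np.arange(1, ng + 1, dtype=float)
    ii = i[:, None] * np.ones(ng)  # row gray level
    jj = np.ones((ng, 1)) * i[None, :]  # column gray level

    px = P.sum(axis=-1)  # marginal over j, shape (..., Ng); == py by symmetry
    mu = (px * i).sum(axis=-1)  # mean gray level
    sigma2 = (px * (i - mu[..., None]) ** 2).sum(axis=-1)

    def s(weight):  # contract a per-cell weight against P
        return (P * weight).sum(axis=(-2, -1))

    autocorrelation = s(ii * jj)
    joint_average = s(ii)
    dev = ii + jj - 2.0 * mu[..., None, None]
    cluster_prominence = s(dev**4)
    cluster_shade = s(dev**3)
    cluster_tendency = s(dev**2)
    contrast = s((ii - jj) ** 2)
    with np.errstate(invalid="ignore", divide="ignore"):
        correlation = np.where(sigma2 > 0, (autocorrelation - mu**2) / sigma2, 1.0)

    # diagonal-band marginals p_{x-y}(k), k = 0..Ng-1 and p_{x+y}(k), k = 2..2Ng
    k_minus = np.arange(ng, dtype=float)
    p_minus = np.stack(
        [np.trace(P, offset=0, axis1=-2, axis2=-1)]
        + [
            np.trace(P, offset=k, axis1=-2, axis2=-1)
            + np.trace(P, offset=-k, axis1=-2, axis2=-1)
            for k in range(1, ng)
        ],
        axis=-1,
    )
    # anti-diagonal k = i + j maps to diagonal offset k - ng - 1 of the
    # row-reversed matrix
    k_plus = np.arange(2, 2 * ng + 1, dtype=float)
    p_plus = np.stack(
        [
            np.trace(P[..., ::-1, :], offset=off, axis1=-2, axis2=-1)
            for off in range(1 - ng, ng)
        ],
        axis=-1,
    )

    difference_average = (p_minus * k_minus).sum(axis=-1)
    difference_entropy = -_xlog2x(p_minus).sum(axis=-1)
    difference_variance = (p_minus * (k_minus - difference_average[..., None]) ** 2).sum(axis=-1)
    dissimilarity = s(np.abs(ii - jj))

    joint_energy = s(P)
    joint_entropy = -_xlog2x(P).sum(axis=(-2, -1))

    hx = -_xlog2x(px).sum(axis=-1)
    pxpy = px[..., :, None] * px[..., None, :]
    log_pxpy = np.zeros_like(pxpy)
    nz = pxpy > 0
    log_pxpy[nz] = np.log2(pxpy[nz])
    hxy1 = -(P * log_pxpy).sum(axis=(-2, -1))
    hxy2 = -_xlog2x(pxpy).sum(axis=(-2, -1))
    with np.errstate(invalid="ignore", divide="ignore"):
        imc1 = np.where(hx > 0, (joint_entropy - hxy1) / hx, 0.0)
    imc2 = np.sqrt(np.clip(1.0 - np.exp(-2.0 * (hxy2 - joint_entropy)), 0.0, None))

    absdiff = np.abs(ii - jj)
    idm = s(1.0 / (1.0 + (ii - jj) ** 2))
    idmn = s(1.0 / (1.0 + ((ii - jj) / ng) ** 2))
    id_ = s(1.0 / (1.0 + absdiff))
    idn = s(1.0 / (1.0 + absdiff / ng))
    inv_w = np.zeros((ng, ng))
    off_diag = absdiff > 0
    inv_w[off_diag] = 1.0 / (ii - jj)[off_diag] ** 2
    inverse_variance = s(inv_w)

    maximum_probability = P.max(axis=(-2, -1))
    sum_average = (p_plus * k_plus).sum(axis=-1)
    sum_entropy = -_xlog2x(p_plus).sum(axis=-1)
    sum_squares = s((ii - mu[..., None, None]) ** 2)
    mcc = _mcc(P, px)

    feats = [
        autocorrelation,
        joint_average,
        cluster_prominence,
        cluster_shade,
        cluster_tendency,
        contrast,
        correlation,
        difference_average,
        difference_entropy,
        difference_variance,
        dissimilarity,
        joint_energy,
        joint_entropy,
        imc1,
        imc2,
        idm,
        idmn,
        id_,
        idn,
        inverse_variance,
        maximum_probability,
        sum_average,
        sum_entropy,
        sum_squares,
        mcc,
    ]
    return np.stack(feats, axis=-1)


def _mcc(P: np.ndarray, px: np.ndarray) -> np.ndarray:
    """Maximal correlation coefficient: sqrt of the second-largest eigenvalue
    of Q(i,j) = sum_k P(i,k) P(j,k) / (px(i) px(k)).

    Matrices supported on fewer than two gray levels are degenerate; their MCC
    is defined as 1.
    """
    with np.errstate(invalid="ignore", divide="ignore"):
        inv = np.where(px > 0, 1.0 / px, 0.0)
    A = P * inv[..., :, None]  # P(i,k)/px(i)
    B = P * inv[..., None, :]  # P(j,k)/px(k) indexed [j, k]
    Q = A @ np.swapaxes(B, -1, -2)
    ev = np.abs(np.linalg.eigvals(Q))
    ev = np.sort(ev, axis=-1)
    second = ev[..., -2] if ev.shape[-1] >= 2 else np.ones(ev.shape[:-1])
    mcc = np.sqrt(np.clip(second, 0.0, 1.0))
    degenerate = (px > 0).sum(axis=-1) < 2
    return np.where(degenerate, 1.0, mcc)


def aggregate_glcm(levels: np.ndarray, mask: np.ndarray, n_levels: int, offsets=None) -> np.ndarray:
    """Whole-ROI symmetric GLCM, accumulated over all offsets.

    ``levels`` is an integer array (any dimensionality); only pairs with both
    voxels inside ``mask`` count.  Returns the normalized (Ng, Ng) matrix.
    """
    levels = np.asarray(levels)
    mask = np.asarray(mask, dtype=bool)
    if levels.shape != mask.shape:
        raise ValueError("levels and mask shapes differ")
    if offsets is None:
        offsets = OFFSETS_3D if levels.ndim == 3 else OFFSETS_2D
    counts = np.zeros(n_levels * n_levels)
    for off in offsets:
        sl_a, sl_b = [], []
        ok = True
        for dim, d in zip(levels.shape, off):
            lo, hi = max(0, -d), dim - max(0, d)
            if hi <= lo:
                ok = False
                break
            sl_a.append(slice(lo, hi))
            sl_b.append(slice(lo + d, hi + d))
        if not ok:
            continue
        a = levels[tuple(sl_a)]
        b = levels[tuple(sl_b)]
        valid = mask[tuple(sl_a)] & mask[tuple(sl_b)]
        av, bv = a[valid], b[valid]
        counts += np.bincount(av * n_levels + bv, minlength=n_levels * n_levels)
        counts += np.bincount(bv * n_levels + av, minlength=n_levels * n_levels)
    total = counts.sum()
    if total == 0:
        raise ValueError("ROI too small for any co-occurrence pair")
    return (counts / total).reshape(n_levels, n_levels)


def pixel_glcm_stack(
    levels: np.ndarray,
    mask: np.ndarray,
    n_levels: int,
    kernel: int = 3,
    offsets=OFFSETS_2D,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-pixel symmetric GLCMs over a ``kernel`` x ``kernel`` neighbourhood.

    For every pixel q the co-occurrence pairs whose both endpoints lie inside
    q's kernel window (and inside ``mask``) are accumulated.  Returns
    ``(glcms, valid)`` where ``glcms`` has shape (H, W, Ng, Ng) with
    normalized matrices at valid pixels, and ``valid`` marks masked pixels
    whose window contained at least one pair.
    """
    if kernel < 3 or kernel % 2 == 0:
        raise ValueError("kernel must be an odd integer >= 3")
    levels = np.asarray(levels)
    mask = np.asarray(mask, dtype=bool)
    if levels.ndim != 2 or levels.shape != mask.shape:
        raise ValueError("levels/mask must be 2-D arrays of equal shape")
    H, W = levels.shape
    r = kernel // 2
    counts = np.zeros((H * W, n_levels * n_levels))
    for dy, dx in offsets:
        y0, y1 = max(0, -dy), H - max(0, dy)
        x0, x1 = max(0, -dx), W - max(0, dx)
        if y1 <= y0 or x1 <= x0:
            continue
        a = levels[y0:y1, x0:x1]
        b = levels[y0 + dy : y1 + dy, x0 + dx : x1 + dx]
        ok = mask[y0:y1, x0:x1] & mask[y0 + dy : y1 + dy, x0 + dx : x1 + dx]
        py, px = np.nonzero(ok)
        if py.size == 0:
            continue
        code_ab = a[ok] * n_levels + b[ok]
        code_ba = b[ok] * n_levels + a[ok]
        py = py + y0
        px = px + x0
        # window centers q = p + (sy, sx) whose kernel contains both endpoints
        for sy in range(-r + max(0, dy), r - max(0, -dy) + 1):
            for sx in range(-r + max(0, dx), r - max(0, -dx) + 1):
                qy = py + sy
                qx = px + sx
                inb = (qy >= 0) & (qy < H) & (qx >= 0) & (qx < W)
                flat = qy[inb] * W + qx[inb]
                np.add.at(counts, (flat, code_ab[inb]), 1.0)
                np.add.at(counts, (flat, code_ba[inb]), 1.0)
    totals = counts.sum(axis=1)
    valid = (totals > 0) & mask.ravel()
    glcms = np.zeros((H * W, n_levels, n_levels))
    glcms[valid] = (counts[valid] / totals[valid, None]).reshape(-1, n_levels, n_levels)
    return glcms.reshape(H, W, n_levels, n_levels), valid.reshape(H, W)


def first_order_features(values: np.ndarray, n_bins: int = 16) -> dict[str, float]:
    """First-order intensity statistics of a 1-D sample of ROI intensities.

    Histogram-based statistics (entropy, uniformity) use ``n_bins`` equal-width
    bins over the observed range.  Skewness and kurtosis of a constant sample
    are defined as 0 by convention (excess kurtosis is reported).
    """
    x = np.asarray(values, dtype=float).ravel()
    if x.size == 0:
        raise ValueError("empty ROI")
    mean = float(x.mean())
    var = float(x.var())
    std = var**0.5
    centered = x - mean
    skew = float((centered**3).mean() / std**3) if std > 0 else 0.0
    kurt = float((centered**4).mean() / std**4 - 3.0) if std > 0 else 0.0
    hist, _ = np.histogram(x, bins=n_bins)
    p = hist / hist.sum()
    entropy = float(-_xlog2x(p).sum())
    q10, q25, q50, q75, q90 = np.percentile(x, [10, 25, 50, 75, 90])
    return {
        "mean": mean,
        "median": float(q50),
        "minimum": float(x.min()),
        "maximum": float(x.max()),
        "p10": float(q10),
        "p90": float(q90),
        "iqr": float(q75 - q25),
        "range": float(x.max() - x.min()),
        "mad": float(np.abs(centered).mean()),
        "variance": var,
        "skewness": skew,
        "kurtosis": kurt,
        "energy": float((x**2).sum()),
        "rms": float(np.sqrt((x**2).mean())),
        "entropy": entropy,
        "uniformity": float((p**2).sum()),
    }
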