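"""Gray-level co-occurrence matrices and Haralick texture statistics.

The GLCM at displacement (d, theta) is the joint distribution of quantized
gray levels of pixel pairs separated by that offset, restricted to a mask.
Intensities are linearly quantized to G levels over the masked min-max range.
From the normalized (and, by default, symmetrized) matrix the 13 classic
Haralick statistics are computed with natural logarithms and the convention
0*log(0) = 0.

A difference-of-Gaussians band-pass denoiser is provided for mammogram ROIs.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import numpy as np
from scipy.ndimage import gaussian_filter

from .errors import ContractError, DegenerateInputError
from .io_formats import ImageGrid

__all__ = [
    "GLCMConfig",
    "HARALICK_NAMES",
    "dog_denoise",
    "compute_glcm",
    "haralick_features",
    "glcm_feature_vector",
]

HARALICK_NAMES = (
    "asm",
    "contrast",
    "correlation",
    "variance",
    "idm",
    "sum_average",
    "sum_variance",
    "sum_entropy",
    "entropy",
    "difference_variance",
    "difference_entropy",
    "imc1",
    "imc2",
)

# pixel offsets (drow, dcol) per orientation, for distance 1; scaled by d
_OFFSETS = {0: (0, 1), 45: (-1, 1), 90: (-1, 0), 135: (-1, -1)}


@dataclasses.dataclass(frozen=True)
class GLCMConfig:
    distance: int = 1
    orientations: tuple[int, ...] = (0, 45, 90, 135)
    gray_levels: int = 64
    symmetric: bool = True
    average_over_orientations: bool = True
    dog_sigmas: tuple[float, float] = (1.0, 2.0)

    def __post_init__(self) -> None:
        if self.distance < 1:
            raise ContractError("distance must be >= 1")
        if self.gray_levels < 2:
            raise ContractError("gray_levels must be >= 2")
        if self.dog_sigmas[0] >= self.dog_sigmas[1]:
            raise ContractError("dog_sigmas must satisfy narrow < wide")
        for theta in self.orientations:
            if theta % 180 not in _OFFSETS and theta % 45 != 0:
                raise ContractError(f"unsupported orientation {theta}")


def dog_denoise(
    image: ImageGrid | np.ndarray, sigma_narrow: float = 1.0, sigma_wide: float = 2.0
) -> np.ndarray:
    """Difference-of-Gaussians band-pass, rescaled to the input's value range.

    A constant image degenerates to a constant at the input's midpoint.
    """
    if sigma_narrow >= sigma_wide:
        raise ContractError("sigma_narrow must be < sigma_wide")
    arr = image.values if isinstance(image, ImageGrid) else np.asarray(image, dtype=float)
    band = gaussian_filter(arr, sigma_narrow) - gaussian_filter(arr, sigma_wide)
    in_lo, in_hi = float(arr.min()), float(arr.max())
    b_lo, b_hi = float(band.min()), float(band.max())
    if b_hi == b_lo:
        return np.full_like(arr, 0.5 * (in_lo + in_hi))
    return in_lo + (band - b_lo) * (in_hi - in_lo) / (b_hi - b_lo)


def quantize(arr: np.ndarray, mask: np.ndarray, gray_levels: int) -> np.ndarray:
    """Linear quantization to 0..G-1 over the masked min-max range."""
    vals = arr[mask]
    lo, hi = float(vals.min()), float(vals.max())
    if hi == lo:
        return np.zeros(arr.shape, dtype=np.intp)
    q = np.floor((arr - lo) / (hi - lo) * gray_levels).astype(np.intp)
    return np.clip(q, 0, gray_levels - 1)


def _offset(distance: int, theta: int) -> tuple[int, int]:
    theta = theta % 180
    if theta not in _OFFSETS:
        raise ContractError(f"orientation must be a multiple of 45 degrees, got {theta}")
    dr, dc = _OFFSETS[theta]
    return dr * distance, dc * distance


def compute_glcm(
    image: ImageGrid | np.ndarray,
    mask: np.ndarray | None = None,
    distance: int = 1,
    theta: int = 0,
    gray_levels: int = 64,
    symmetric: bool = True,
) -> np.ndarray:
    """Normalized G x G co-occurrence matrix at displacement (distance, theta).

    Only pairs with both pixels inside the mask are counted; ``symmetric``
    adds the transposed counts before normalization.
    """
    arr = image.values if isinstance(image, ImageGrid) else np.asarray(image, dtype=float)
    if mask is None:
        mask = np.ones(arr.shape, dtype=bool)
    if not mask.any():
        raise DegenerateInputError("empty mask")
    q = quantize(arr, mask, gray_levels)
    dr, dc = _offset(distance, theta)
    h, w = arr.shape
    r0 = max(0, -dr)
    r1 = min(h, h - dr)
    c0 = max(0, -dc)
    c1 = min(w, w - dc)
    if r0 >= r1 or c0 >= c1:
        raise DegenerateInputError("image smaller than the pair displacement")
    a = q[r0:r1, c0:c1]
    b = q[r0 + dr : r1 + dr, c0 + dc : c1 + dc]
    valid = mask[r0:r1, c0:c1] & mask[r0 + dr : r1 + dr, c0 + dc : c1 + dc]
    if not valid.any():
        raise DegenerateInputError("no valid pixel pair at this displacement")
    counts = np.zeros((gray_levels, gray_levels))
    np.add.at(counts, (a[valid], b[valid]), 1.0)
    if symmetric:
        counts = counts + counts.T
    return counts / counts.sum()


def haralick_features(glcm: np.ndarray) -> dict[str, float]:
    """The 13 classic Haralick statistics of a normalized GLCM.

    Natural logarithms; 0*log 0 := 0.  If a marginal SD is zero the
    correlation is returned as 0 (degenerate, e.g. a constant image).
    """
    p = np.asarray(glcm, dtype=float)
    if p.ndim != 2 or p.shape[0] != p.shape[1]:
        raise ContractError("GLCM must be square")
    if not np.isclose(p.sum(), 1.0, atol=1e-8):
        raise ContractError("GLCM must be normalized to sum 1")
    g = p.shape[0]
    i = np.arange(g, dtype=float)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    px = p.sum(axis=1)
    py = p.sum(axis=0)
    mu_x = float(i @ px)
    mu_y = float(i @ py)
    sd_x = float(np.sqrt(((i - mu_x) ** 2) @ px))
    sd_y = float(np.sqrt(((i - mu_y) ** 2) @ py))

    def _ent(q: np.ndarray) -> float:
        q = q[q > 0]
        return float(-(q * np.log(q)).sum())

    # p_{x+y}(k), k = 0..2G-2 ; p_{x-y}(k), k = 0..G-1
    p_sum = np.zeros(2 * g - 1)
    np.add.at(p_sum, (ii + jj).astype(int), p)
    p_diff = np.zeros(g)
    np.add.at(p_diff, np.abs(ii - jj).astype(int), p)

    asm = float((p**2).sum())
    contrast = float(((ii - jj) ** 2 * p).sum())
    if sd_x > 0 and sd_y > 0:
        correlation = float((((ii - mu_x) * (jj - mu_y) * p).sum()) / (sd_x * sd_y))
    else:
        correlation = 0.0
    variance = float((((ii - mu_x) ** 2) * p).sum())
    idm = float((p / (1.0 + (ii - jj) ** 2)).sum())
    k_sum = np.arange(2 * g - 1, dtype=float)
    sum_average = float(k_sum @ p_sum)
    sum_variance = float(((k_sum - sum_average) ** 2) @ p_sum)
    sum_entropy = _ent(p_sum)
    entropy = _ent(p)
    k_diff = np.arange(g, dtype=float)
    mu_diff = float(k_diff @ p_diff)
    difference_variance = float(((k_diff - mu_diff) ** 2) @ p_diff)
    difference_entropy = _ent(p_diff)

    hxy = entropy
    outer = np.outer(px, py)
    pos = p > 0  # p(i,j) > 0 implies both marginals > 0
    hxy1 = float(-(p[pos] * np.log(outer[pos])).sum())
    pos2 = outer > 0
    hxy2 = float(-(outer[pos2] * np.log(outer[pos2])).sum())
    hx = _ent(px)
    hy = _ent(py)
    denom = max(hx, hy)
    imc1 = (hxy - hxy1) / denom if denom > 0 else 0.0
    imc2 = float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - hxy)))))

    return {
        "asm": asm,
        "contrast": contrast,
        "correlation": correlation,
        "variance": variance,
        "idm": idm,
        "sum_average": sum_average,
        "sum_variance": sum_variance,
        "sum_entropy": sum_entropy,
        "entropy": entropy,
        "difference_variance": difference_variance,
        "difference_entropy": difference_entropy,
        "imc1": imc1,
        "imc2": imc2,
    }


def glcm_feature_vector(
    roi: ImageGrid | np.ndarray,
    mask: np.ndarray | None = None,
    config: GLCMConfig | None = None,
) -> dict[str, float]:
    """Haralick vector per orientation, averaged or concatenated.

    Averaged mode yields 13 features named ``h_{feature}``; concatenated mode
    yields 13 x len(orientations) features named ``h_{feature}_o{deg}``.
    """
    config = config or GLCMConfig()
    per_orientation: list[dict[str, float]] = []
    for theta in config.orientations:
        glcm = compute_glcm(
            roi, mask, config.distance, theta, config.gray_levels, config.symmetric
        )
        per_orientation.append(haralick_features(glcm))
    if config.average_over_orientations:
        return {
            f"h_{name}": float(np.mean([feats[name] for feats in per_orientation]))
            for name in HARALICK_NAMES
        }
    out: dict[str, float] = {}
    for theta, feats in zip(config.orientations, per_orientation):
        for name in HARALICK_NAMES:
            out[f"h_{name}_o{theta}"] = feats[name]
    return out
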