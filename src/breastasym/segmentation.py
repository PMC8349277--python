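"""Body extraction and left/right breast ROI splitting for thermograms.

Pipeline: (optional crop) -> Otsu threshold keeping the warmer class ->
morphological opening then closing -> largest connected component ->
vertical split at the mask midline -> per-side inframammary-fold location by
row-projected horizontal edge energy -> tight ROI pair, with the right ROI
horizontally mirrored so oriented textures correspond between the sides.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import ndimage
from skimage.morphology import closing, disk, opening

from .errors import ContractError, DegenerateInputError, SegmentationFailure
from .io_formats import ImageGrid

__all__ = [
    "SegmentationConfig",
    "BreastROIPair",
    "otsu_threshold",
    "segment_body",
    "horizontal_edge_map",
    "split_breasts",
    "segment_and_split",
]

# 3x3 horizontal-edge operator (Sobel): responds to intensity change across rows.
_SOBEL_H = np.array([[1, 2, 1], [0, 0, 0], [-1, -2, -1]], dtype=float)


@dataclasses.dataclass(frozen=True)
class SegmentationConfig:
    histogram_bins: int = 256
    morph_radius: int = 3
    min_component_fraction: float = 0.01
    edge_operator: str = "sobel-horizontal"
    split_method: str = "midline"  # {midline, mask-centroid}
    mirror_right: bool = True
    crop: tuple[int, int, int, int] | None = None  # (row0, row1, col0, col1)

    def __post_init__(self) -> None:
        if self.histogram_bins < 2:
            raise ContractError("histogram_bins must be >= 2")
        if self.morph_radius < 1:
            raise ContractError("morph_radius must be >= 1")
        if not 0 < self.min_component_fraction < 1:
            raise ContractError("min_component_fraction must be in (0, 1)")
        if self.split_method not in ("midline", "mask-centroid"):
            raise ContractError(f"unknown split_method {self.split_method!r}")


@dataclasses.dataclass
class BreastROIPair:
    """Left/right breast ROIs plus their masks and segmentation diagnostics.

    ROI arrays are the tight bounding boxes of their masks; when
    ``mirror_right`` the right ROI and mask are flipped left-to-right.
    """

    left_roi: np.ndarray
    right_roi: np.ndarray
    left_mask: np.ndarray
    right_mask: np.ndarray
    body_mask: np.ndarray
    split_column: int
    bottom_boundary_rows: tuple[int, int]  # (left, right)
    threshold: float


def otsu_threshold(image: ImageGrid | np.ndarray, bins: int = 256) -> float:
    """Otsu's threshold: the histogram cut maximizing between-class variance.

    The histogram spans the image's min-max range with ``bins`` bins; the
    returned level is the bin edge of the best cut, in image units.  Ties are
    broken toward the lower threshold.
    """
    arr = image.values if isinstance(image, ImageGrid) else np.asarray(image, dtype=float)
    lo, hi = float(arr.min()), float(arr.max())
    if lo == hi:
        raise DegenerateInputError("constant image: no threshold separates it")
    counts, edges = np.histogram(arr, bins=bins, range=(lo, hi))
    return _otsu_from_histogram(counts, edges)


def _otsu_from_histogram(counts: np.ndarray, edges: np.ndarray) -> float:
    """Exhaustive between-class-variance maximization over all bin cuts."""
    counts = np.asarray(counts, dtype=float)
    total = counts.sum()
    centers = 0.5 * (edges[:-1] + edges[1:])
    w0 = np.cumsum(counts)[:-1]  # cut after bin t: bins 0..t are class 0
    w1 = total - w0
    mu0 = np.cumsum(counts * centers)[:-1]
    mu1 = (counts * centers).sum() - mu0
    with np.errstate(divide="ignore", invalid="ignore"):
        m0 = np.where(w0 > 0, mu0 / w0, 0.0)
        m1 = np.where(w1 > 0, mu1 / w1, 0.0)
    sigma_b = w0 * w1 * (m0 - m1) ** 2
    best = int(np.argmax(sigma_b))  # argmax takes the first (lowest) maximizer
    return float(edges[best + 1])


def segment_body(image: ImageGrid | np.ndarray, config: SegmentationConfig | None = None) -> np.ndarray:
    """Binary body mask: warm class at the Otsu cut, cleaned by morphology,
    reduced to the largest 8-connected component."""
    config = config or SegmentationConfig()
    arr = image.values if isinstance(image, ImageGrid) else np.asarray(image, dtype=float)
    if config.crop is not None:
        r0, r1, c0, c1 = config.crop
        full = np.zeros(arr.shape, dtype=bool)
        full[r0:r1, c0:c1] = segment_body(arr[r0:r1, c0:c1], dataclasses.replace(config, crop=None))
        return full
    level = otsu_threshold(arr, config.histogram_bins)
    mask = arr > level  # keep the warmer/brighter class
    selem = disk(config.morph_radius)
    mask = closing(opening(mask, selem), selem).astype(bool)
    labeled, n = ndimage.label(mask, structure=np.ones((3, 3)))
    if n == 0:
        raise SegmentationFailure("no foreground component after thresholding/morphology")
    sizes = ndimage.sum_labels(np.ones_like(labeled), labeled, index=np.arange(1, n + 1))
    largest = int(np.argmax(sizes)) + 1
    mask = labeled == largest
    if mask.sum() < config.min_component_fraction * arr.size:
        raise SegmentationFailure(
            f"largest component covers {mask.sum() / arr.size:.4f} of the image, "
            f"below min_component_fraction={config.min_component_fraction}"
        )
    return mask


def horizontal_edge_map(image: ImageGrid | np.ndarray) -> np.ndarray:
    """Absolute response of the 3x3 horizontal Sobel operator (zero border)."""
    arr = image.values if isinstance(image, ImageGrid) else np.asarray(image, dtype=float)
    if arr.shape[0] < 3 or arr.shape[1] < 3:
        raise ContractError("edge map needs an image of at least 3x3")
    resp = ndimage.convolve(arr, _SOBEL_H, mode="constant", cval=0.0)
    resp[0, :] = resp[-1, :] = 0.0
    resp[:, 0] = resp[:, -1] = 0.0
    return np.abs(resp)


def _fold_row(edge: np.ndarray, side_mask: np.ndarray, body_rows: tuple[int, int]) -> int:
    """Inframammary fold = row of maximal horizontal-edge energy in the lower
    half of the body, restricted to the side's column span (plus a one-pixel
    apron so the body/background boundary itself contributes)."""
    rmin, rmax = body_rows
    cols = np.where(side_mask.any(axis=0))[0]
    c0, c1 = cols.min(), cols.max() + 1
    row_mid = (rmin + rmax) // 2
    lo = row_mid
    hi = min(rmax + 1, edge.shape[0] - 1)
    profile = edge[lo : hi + 1, c0:c1].sum(axis=1)
    return int(lo + np.argmax(profile))


def split_breasts(
    image: ImageGrid | np.ndarray,
    body_mask: np.ndarray,
    config: SegmentationConfig | None = None,
    threshold: float = float("nan"),
) -> BreastROIPair:
    """Split the body mask into left/right breast ROIs.

    The split column is the midline of the mask's column span (or the mask
    centroid column); each side's lower boundary is the row maximizing the
    row-summed horizontal edge energy in the lower half of the body.
    """
    config = config or SegmentationConfig()
    arr = image.values if isinstance(image, ImageGrid) else np.asarray(image, dtype=float)
    if not body_mask.any():
        raise SegmentationFailure("empty body mask")
    rows_any = np.where(body_mask.any(axis=1))[0]
    cols_any = np.where(body_mask.any(axis=0))[0]
    rmin, rmax = int(rows_any.min()), int(rows_any.max())
    cmin, cmax = int(cols_any.min()), int(cols_any.max())
    if config.split_method == "midline":
        split_col = (cmin + cmax + 1) // 2
    else:
        split_col = int(round(ndimage.center_of_mass(body_mask)[1]))
    col_idx = np.arange(arr.shape[1])
    left_side = body_mask & (col_idx[None, :] < split_col)
    right_side = body_mask & (col_idx[None, :] >= split_col)
    if not left_side.any() or not right_side.any():
        raise SegmentationFailure(f"split at column {split_col} leaves an empty side")

    edge = horizontal_edge_map(arr)
    fold_left = _fold_row(edge, left_side, (rmin, rmax))
    fold_right = _fold_row(edge, right_side, (rmin, rmax))

    row_idx = np.arange(arr.shape[0])
    left_mask = left_side & (row_idx[:, None] <= fold_left)
    right_mask = right_side & (row_idx[:, None] <= fold_right)
    if not left_mask.any() or not right_mask.any():
        raise SegmentationFailure("a breast mask is empty after fold cropping")

    left_roi, left_mask_c = _tight_crop(arr, left_mask)
    right_roi, right_mask_c = _tight_crop(arr, right_mask)
    if config.mirror_right:
        right_roi = right_roi[:, ::-1]
        right_mask_c = right_mask_c[:, ::-1]
    return BreastROIPair(
        left_roi=left_roi,
        right_roi=right_roi,
        left_mask=left_mask_c,
        right_mask=right_mask_c,
        body_mask=body_mask,
        split_column=int(split_col),
        bottom_boundary_rows=(fold_left, fold_right),
        threshold=threshold,
    )


def _tight_crop(arr: np.ndarray, mask: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    rows = np.where(mask.any(axis=1))[0]
    cols = np.where(mask.any(axis=0))[0]
    sl = np.s_[rows.min() : rows.max() + 1, cols.min() : cols.max() + 1]
    return arr[sl].copy(), mask[sl].copy()


def segment_and_split(
    image: ImageGrid | np.ndarray, config: SegmentationConfig | None = None
) -> BreastROIPair:
    """Full segmentation: body extraction followed by the left/right split."""
    config = config or SegmentationConfig()
    arr = image.values if isinstance(image, ImageGrid) else np.asarray(image, dtype=float)
    level = otsu_threshold(
        arr if config.crop is None else arr[config.crop[0] : config.crop[1], config.crop[2] : config.crop[3]],
        config.histogram_bins,
    )
    mask = segment_body(arr, config)
    return split_breasts(arr, mask, config, threshold=level)
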