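"""Synthetic bilateral thermogram scenes and mammogram-like texture patches.

The thermogram generator emulates the physical premise of thermographic
screening: the temperature patterns of the two breasts of a healthy subject
are closely mirror-symmetric, while a tumour's angiogenesis produces a
localized hot spot on one side.  A scene is a cool constant background plus,
inside an elliptical body region,

* a baseline skin temperature,
* a mirror-symmetric smooth temperature field (vasculature-scale variation),
* a mirror-symmetric oriented sinusoidal texture (skin texture),
* an optional one-sided isotropic Gaussian hot spot of amplitude ``deltaT``,
* for the malignant regime, an additional high-frequency oriented
  micro-texture confined to the lesion side, and
* i.i.d. Gaussian pixel noise.

Mirror symmetry is exact by construction (the left half is reflected onto the
right before one-sided components are added), so with no lesion and no noise
the left ROI equals the horizontally mirrored right ROI bit for bit.

The texture-patch generator produces small gray-level-quantized patches
(checkerboard, grating, or smoothed noise) with a controllable correlation
length, standing in for pre-segmented mammogram mass/background ROIs.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import numpy as np
from scipy.ndimage import gaussian_filter

from .errors import ContractError
from .io_formats import DatasetManifest, ImageGrid, ManifestRecord, PixelKind

__all__ = [
    "ThermoSceneParams",
    "ThermoScene",
    "TexturePatchParams",
    "DatasetRanges",
    "generate_thermogram",
    "generate_dataset",
    "default_separable_dataset",
    "generate_texture_patch",
    "generate_patch_dataset",
]


@dataclasses.dataclass(frozen=True)
class ThermoSceneParams:
    """Parameters of one synthetic bilateral thermogram.

    Temperatures in deg C, lengths in pixels.  ``body_ellipse`` is
    (center_row, center_col, semi_axis_rows, semi_axis_cols); the default
    centers the ellipse on the vertical midline so mirror symmetry is exact.
    """

    height: int = 128
    width: int = 128
    baseline_temp: float = 33.0
    background_offset: float = -8.0  # background = baseline + offset (cool)
    body_ellipse: tuple[float, float, float, float] | None = None
    smooth_field_amplitude: float = 0.5
    smooth_field_scale: float = 16.0
    texture_amplitude: float = 0.3
    texture_frequency: float = 0.06  # cycles/pixel
    texture_orientation: float = 20.0  # degrees
    lesion_amplitude: float = 0.0  # deltaT of the hot spot
    lesion_sigma: float = 8.0
    lesion_side: str = "none"  # {left, right, none}
    lesion_center: tuple[float, float] | None = None  # (row, col)
    micro_texture: bool = False  # malignant regime: oriented texture in lesion
    micro_texture_frequency: float = 0.25
    micro_texture_orientation: float = 30.0
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.lesion_side not in ("left", "right", "none"):
            raise ContractError(f"lesion_side must be left/right/none, got {self.lesion_side!r}")
        if self.lesion_amplitude < 0 or self.noise_sd < 0:
            raise ContractError("lesion_amplitude and noise_sd must be nonnegative")
        if self.height < 16 or self.width < 16:
            raise ContractError("scene must be at least 16x16 pixels")

    def ellipse(self) -> tuple[float, float, float, float]:
        if self.body_ellipse is not None:
            return self.body_ellipse
        return (
            (self.height - 1) / 2.0,
            (self.width - 1) / 2.0,
            0.40 * self.height,
            0.42 * self.width,
        )

    def default_lesion_center(self) -> tuple[float, float]:
        cr, cc, ar, ac = self.ellipse()
        dx = 0.45 * ac
        return (cr, cc - dx) if self.lesion_side == "left" else (cr, cc + dx)


@dataclasses.dataclass
class ThermoScene:
    """A generated scene with its ground truth."""

    grid: ImageGrid
    body_mask: np.ndarray
    left_mask: np.ndarray
    right_mask: np.ndarray
    lesion_mask: np.ndarray
    label: str
    params: ThermoSceneParams


def _symmetrize(field: np.ndarray) -> np.ndarray:
    """Reflect the left half onto the right about the vertical midline."""
    out = field.copy()
    w = field.shape[1]
    for j in range(w // 2, w):
        out[:, j] = field[:, w - 1 - j]
    return out


def _lesion_inside_body(params: ThermoSceneParams, center: tuple[float, float]) -> bool:
    cr, cc, ar, ac = params.ellipse()
    margin = 2.0 * params.lesion_sigma
    if ar <= margin or ac <= margin:
        return False
    dr = (center[0] - cr) / (ar - margin)
    dc = (center[1] - cc) / (ac - margin)
    return dr * dr + dc * dc <= 1.0


def generate_thermogram(params: ThermoSceneParams) -> ThermoScene:
    """Render one scene.  Identical ``params`` (same seed) give identical output."""
    rng = np.random.default_rng(params.seed)
    h, w = params.height, params.width
    cr, cc, ar, ac = params.ellipse()

    rows, cols = np.mgrid[0:h, 0:w].astype(float)
    body = ((rows - cr) / ar) ** 2 + ((cols - cc) / ac) ** 2 <= 1.0

    # mirror-symmetric smooth component
    smooth = gaussian_filter(rng.standard_normal((h, w)), params.smooth_field_scale)
    sd = smooth.std()
    if sd > 0:
        smooth = (smooth - smooth.mean()) / sd * params.smooth_field_amplitude
    smooth = _symmetrize(smooth)

    # mirror-symmetric oriented texture
    th = np.deg2rad(params.texture_orientation)
    phase = 2 * np.pi * params.texture_frequency * (cols * np.cos(th) + rows * np.sin(th))
    texture = _symmetrize(params.texture_amplitude * np.cos(phase))

    field = params.baseline_temp + smooth + texture

    lesion_mask = np.zeros((h, w), dtype=bool)
    if params.lesion_side != "none" and params.lesion_amplitude > 0:
        center = params.lesion_center or params.default_lesion_center()
        if not _lesion_inside_body(params, center):
            raise ContractError(
                f"lesion at {center} with sigma {params.lesion_sigma} not inside body ellipse"
            )
        d2 = (rows - center[0]) ** 2 + (cols - center[1]) ** 2
        bump = params.lesion_amplitude * np.exp(-0.5 * d2 / params.lesion_sigma**2)
        field = field + bump
        lesion_mask = d2 <= (2.0 * params.lesion_sigma) ** 2
        if params.micro_texture:
            mt = np.deg2rad(params.micro_texture_orientation)
            mphase = 2 * np.pi * params.micro_texture_frequency * (
                cols * np.cos(mt) + rows * np.sin(mt)
            )
            envelope = np.exp(-0.5 * d2 / (2.0 * params.lesion_sigma) ** 2)
            field = field + 0.4 * params.lesion_amplitude * envelope * np.cos(mphase)

    if params.noise_sd > 0:
        field = field + rng.normal(0.0, params.noise_sd, (h, w))

    image = np.full((h, w), params.baseline_temp + params.background_offset)
    image[body] = field[body]

    mid = w / 2.0
    left_mask = body & (cols < mid)
    right_mask = body & (cols >= mid)
    label = "normal" if params.lesion_side == "none" or params.lesion_amplitude == 0 else (
        "malignant" if params.micro_texture else "benign"
    )
    return ThermoScene(
        grid=ImageGrid(image, PixelKind.TEMPERATURE),
        body_mask=body,
        left_mask=left_mask,
        right_mask=right_mask,
        lesion_mask=lesion_mask & body,
        label=label,
        params=params,
    )


# ---------------------------------------------------------------------------
# dataset generation
# ---------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class DatasetRanges:
    """Per-class sampling regimes for :func:`generate_dataset`.

    Benign lesions are small smooth hot spots; malignant lesions are hotter
    and carry an extra high-frequency oriented micro-texture, so both the
    Gabor-energy and GLCM feature families see class signal.  The hot-spot
    amplitudes (0.5-3 degC) reflect the qualitative angiogenesis premise only.
    """

    benign_amplitude: tuple[float, float] = (0.5, 1.2)
    benign_sigma: tuple[float, float] = (6.0, 10.0)
    malignant_amplitude: tuple[float, float] = (1.5, 3.0)
    malignant_sigma: tuple[float, float] = (5.0, 9.0)
    noise_sd: float = 0.2

    def draw(self, label: str, rng: np.random.Generator) -> tuple[float, float]:
        lo_a, hi_a = self.benign_amplitude if label == "benign" else self.malignant_amplitude
        lo_s, hi_s = self.benign_sigma if label == "benign" else self.malignant_sigma
        return rng.uniform(lo_a, hi_a), rng.uniform(lo_s, hi_s)


def generate_dataset(
    n_per_class: Mapping[str, int],
    ranges: DatasetRanges | None = None,
    seed: int = 0,
    base_params: ThermoSceneParams | None = None,
) -> tuple[list[ThermoScene], DatasetManifest]:
    """Generate a labeled scene collection plus its manifest.

    ``n_per_class`` maps labels (from {normal, benign, malignant}) to counts.
    All randomness flows from one generator seeded with ``seed``.
    """
    if not n_per_class or any(n < 1 for n in n_per_class.values()):
        raise ContractError("each requested class needs a count >= 1")
    for label in n_per_class:
        if label not in ("normal", "benign", "malignant"):
            raise ContractError(f"unknown class {label!r}")
    ranges = ranges or DatasetRanges()
    base = base_params or ThermoSceneParams()
    rng = np.random.default_rng(seed)

    scenes: list[ThermoScene] = []
    records: list[ManifestRecord] = []
    idx = 0
    for label in ("normal", "benign", "malignant"):
        for _ in range(n_per_class.get(label, 0)):
            scene_seed = int(rng.integers(0, 2**31 - 1))
            overrides: dict = {"seed": scene_seed, "noise_sd": ranges.noise_sd}
            if label != "normal":
                amp, sigma = ranges.draw(label, rng)
                side = "left" if rng.random() < 0.5 else "right"
                cr, cc, ar, ac = base.ellipse()
                for _attempt in range(10):
                    row = cr + rng.uniform(-0.25, 0.25) * ar
                    dx = (0.35 + rng.uniform(0.0, 0.15)) * ac
                    col = cc - dx if side == "left" else cc + dx
                    trial = dataclasses.replace(
                        base, lesion_sigma=sigma, lesion_side=side
                    )
                    if _lesion_inside_body(trial, (row, col)):
                        break
                overrides.update(
                    lesion_amplitude=amp,
                    lesion_sigma=sigma,
                    lesion_side=side,
                    lesion_center=(row, col),
                    micro_texture=(label == "malignant"),
                )
            params = dataclasses.replace(base, **overrides)
            scene = generate_thermogram(params)
            assert scene.label == label
            scenes.append(scene)
            records.append(
                ManifestRecord(
                    path=f"scene_{idx:04d}_{label}.txt",
                    subject_id=f"S{idx:04d}",
                    label=label,
                )
            )
            idx += 1
    manifest = DatasetManifest(records, provenance=f"synthetic bilateral thermograms, seed={seed}")
    return scenes, manifest


def default_separable_dataset(
    n_per_class: int = 40, delta_t: float = 2.0, noise_sd: float = 0.2, seed: int = 0
) -> tuple[list[ThermoScene], DatasetManifest]:
    """The standard separable benchmark: normals vs full-model lesions.

    Lesioned scenes carry the complete lesion model (a delta_t hot spot plus
    the angiogenic oriented micro-texture) at fixed amplitude; a smooth bump
    alone has almost no energy inside the 0.088-0.25 cycles/px filter band
    and would sit at the noise-asymmetry floor.
    """
    ranges = DatasetRanges(
        malignant_amplitude=(delta_t, delta_t),
        malignant_sigma=(8.0, 8.0),
        noise_sd=noise_sd,
    )
    return generate_dataset({"normal": n_per_class, "malignant": n_per_class}, ranges, seed)


# ---------------------------------------------------------------------------
# texture patches (mammogram branch)
# ---------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class TexturePatchParams:
    size: int = 64
    gray_levels: int = 64
    base_pattern: str = "smoothed-noise"  # {checker, grating, smoothed-noise}
    correlation_length: float = 4.0
    contrast_gain: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.size < 8:
            raise ContractError("patch size must be >= 8")
        if self.gray_levels < 2:
            raise ContractError("gray_levels must be >= 2")
        if self.base_pattern not in ("checker", "grating", "smoothed-noise"):
            raise ContractError(f"unknown base_pattern {self.base_pattern!r}")


def generate_texture_patch(params: TexturePatchParams) -> ImageGrid:
    """Render a quantized texture patch in gray levels 0..gray_levels-1."""
    rng = np.random.default_rng(params.seed)
    n, g = params.size, params.gray_levels
    rows, cols = np.mgrid[0:n, 0:n].astype(float)
    if params.base_pattern == "checker":
        pattern = ((rows + cols) % 2).astype(float)
    elif params.base_pattern == "grating":
        pattern = 0.5 + 0.5 * np.cos(2 * np.pi * cols / max(params.correlation_length, 1.0))
    else:
        field = gaussian_filter(rng.standard_normal((n, n)), params.correlation_length)
        lo, hi = field.min(), field.max()
        pattern = (field - lo) / (hi - lo) if hi > lo else np.full((n, n), 0.5)
    value = 0.5 + params.contrast_gain * (pattern - 0.5)
    levels = np.clip(np.rint(value * (g - 1)), 0, g - 1)
    return ImageGrid(levels, PixelKind.INTENSITY8)


def generate_patch_dataset(
    n_per_class: Mapping[str, int], seed: int = 0, size: int = 64, gray_levels: int = 64
) -> tuple[list[tuple[ImageGrid, str]], DatasetManifest]:
    """Labeled texture patches emulating pre-segmented mammogram ROIs.

    Class regimes: normal = long-correlation smooth texture; benign = shorter
    correlation, mild contrast; malignant = short correlation, high contrast
    (busy fine texture).  The regimes differ in GLCM statistics by design.
    """
    if not n_per_class or any(n < 1 for n in n_per_class.values()):
        raise ContractError("each requested class needs a count >= 1")
    regimes = {
        "normal": {"correlation_length": 6.0, "contrast_gain": 1.0},
        "benign": {"correlation_length": 3.0, "contrast_gain": 1.3},
        "malignant": {"correlation_length": 1.2, "contrast_gain": 2.0},
    }
    rng = np.random.default_rng(seed)
    patches: list[tuple[ImageGrid, str]] = []
    records: list[ManifestRecord] = []
    idx = 0
    for label in ("normal", "benign", "malignant"):
        for _ in range(n_per_class.get(label, 0)):
            reg = regimes[label]
            params = TexturePatchParams(
                size=size,
                gray_levels=gray_levels,
                base_pattern="smoothed-noise",
                correlation_length=reg["correlation_length"] * rng.uniform(0.85, 1.15),
                contrast_gain=reg["contrast_gain"],
                seed=int(rng.integers(0, 2**31 - 1)),
            )
            patches.append((generate_texture_patch(params), label))
            records.append(
                ManifestRecord(
                    path=f"patch_{idx:04d}_{label}.png",
                    subject_id=f"P{idx:04d}",
                    label=label,
                )
            )
            idx += 1
    return patches, DatasetManifest(records, provenance=f"synthetic texture patches, seed={seed}")
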