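"""Gabor filter bank, texture-energy features, and the bilateral asymmetry signature.

The bank follows the classic multichannel filtering design: real Gabor
filters (a Gaussian envelope modulating a cosine carrier), whose frequency-
domain transfer function is a pair of symmetrically spaced Gaussians at
(u, v) = (+-f cos(theta), +-f sin(theta)).  The envelope spreads follow the
-6 dB bandwidth design with a one-octave frequency bandwidth and a 45-degree
orientation bandwidth:

    sigma_x = sqrt(ln 2) * (2**B + 1) / (sqrt(2) * pi * f * (2**B - 1))
    sigma_y = sqrt(ln 2) / (sqrt(2) * pi * f * tan(B_theta / 2))

with the circular option sigma_y := sigma_x for equal spatial coverage in all
directions.  The default bank covers four radial frequencies
{0.25, 0.176, 0.125, 0.088} cycles/pixel (half-octave spacing from
f_max = 0.25) at five orientations {0, 36, 72, 108, 144} degrees -- 20
filters in total.

Per ROI, each filter contributes one scalar texture energy: the mean (or sum)
of the absolute filter response over the breast mask, after subtracting the
masked mean intensity so constant offsets carry no signal.  The asymmetry
signature is the per-filter difference between left- and right-breast
energies; it is near zero for a mirror-symmetric healthy scene and grows
with one-sided thermal or textural anomalies.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Sequence

import numpy as np
from scipy import ndimage

from .errors import ContractError
from .io_formats import ImageGrid

__all__ = [
    "GaborBankConfig",
    "GaborFilterSpec",
    "FeatureVector",
    "AsymmetrySignature",
    "compute_sigmas",
    "build_filter_bank",
    "filter_response",
    "extract_feature_vector",
    "asymmetry_signature",
    "feature_names",
]

DEFAULT_FREQUENCIES = (0.25, 0.176, 0.125, 0.088)
DEFAULT_ORIENTATIONS = (0.0, 36.0, 72.0, 108.0, 144.0)


@dataclasses.dataclass(frozen=True)
class GaborBankConfig:
    """Configuration of the oriented band-pass filter bank.

    ``frequencies`` are the listed radial center frequencies (cycles/pixel).
    Set ``frequency_spacing`` to ``"half-octave"`` or ``"octave"`` to derive
    them from ``fmax`` instead: f_i = fmax / s**(i-1) with s = sqrt(2) or 2.
    """

    fmax: float = 0.25
    frequencies: tuple[float, ...] = DEFAULT_FREQUENCIES
    n_frequencies: int = 4
    frequency_spacing: str = "listed"  # {listed, half-octave, octave}
    n_orientations: int = 5
    frequency_bandwidth: float = 1.0  # octaves
    orientation_bandwidth: float = 45.0  # degrees
    circular_sigma: bool = True
    kernel_truncation: float = 3.0  # kernel half-width in multiples of sigma
    energy_mode: str = "mean-abs"  # {sum-abs, mean-abs}

    def __post_init__(self) -> None:
        if self.frequency_spacing not in ("listed", "half-octave", "octave"):
            raise ContractError(f"unknown frequency_spacing {self.frequency_spacing!r}")
        if self.n_orientations < 1:
            raise ContractError("n_orientations must be >= 1")
        if self.frequency_bandwidth <= 0:
            raise ContractError("frequency_bandwidth must be > 0")
        if not 0 < self.orientation_bandwidth < 180:
            raise ContractError("orientation_bandwidth must be in (0, 180) degrees")
        for f in self.frequency_set():
            if not 0 < f <= 0.5:
                raise ContractError(f"frequency {f} outside (0, 0.5] cycles/pixel")
        if self.energy_mode not in ("sum-abs", "mean-abs"):
            raise ContractError(f"unknown energy_mode {self.energy_mode!r}")

    def frequency_set(self) -> tuple[float, ...]:
        if self.frequency_spacing == "listed":
            return tuple(self.frequencies)
        step = math.sqrt(2.0) if self.frequency_spacing == "half-octave" else 2.0
        return tuple(self.fmax / step**i for i in range(self.n_frequencies))

    def orientation_set(self) -> tuple[float, ...]:
        # O_j = (j-1) * 180 / V degrees, j = 1..V
        return tuple(j * 180.0 / self.n_orientations for j in range(self.n_orientations))


@dataclasses.dataclass(frozen=True)
class GaborFilterSpec:
    """One filter of the bank: center frequency f (cycles/pixel), orientation
    theta (degrees), envelope spreads sigma_x (along the wave) and sigma_y
    (across it), and the sampled zero-mean real kernel."""

    f: float
    theta: float
    sigma_x: float
    sigma_y: float
    kernel: np.ndarray


@dataclasses.dataclass(frozen=True)
class FeatureVector:
    """Ordered per-filter texture energies for one breast side.

    Ordering is frequency-major, orientation-minor, matching the bank."""

    energies: np.ndarray
    side: str = ""
    names: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        arr = np.asarray(self.energies, dtype=float)
        if arr.ndim != 1:
            raise ContractError("energies must be a flat vector")
        object.__setattr__(self, "energies", arr)


@dataclasses.dataclass(frozen=True)
class AsymmetrySignature:
    """Per-filter left-right energy differences (absolute by default)."""

    values: np.ndarray
    mode: str = "absolute"
    names: tuple[str, ...] = ()

    @property
    def norm(self) -> float:
        return float(np.linalg.norm(self.values))


def compute_sigmas(
    f: float,
    frequency_bandwidth: float = 1.0,
    orientation_bandwidth: float = 45.0,
    circular: bool = True,
) -> tuple[float, float]:
    """Envelope spreads from the -6 dB frequency/orientation bandwidth design."""
    if f <= 0:
        raise ContractError("center frequency must be positive")
    b = frequency_bandwidth
    sigma_x = math.sqrt(math.log(2)) * (2**b + 1) / (math.sqrt(2) * math.pi * f * (2**b - 1))
    sigma_y = math.sqrt(math.log(2)) / (
        math.sqrt(2) * math.pi * f * math.tan(math.radians(orientation_bandwidth) / 2)
    )
    if circular:
        sigma_y = sigma_x
    return sigma_x, sigma_y


def _sample_kernel(f: float, theta_deg: float, sx: float, sy: float, truncation: float) -> np.ndarray:
    half = int(math.ceil(truncation * max(sx, sy)))
    coords = np.arange(-half, half + 1, dtype=float)
    x, y = np.meshgrid(coords, coords)  # x across columns, y down rows
    th = math.radians(theta_deg)
    xp = x * math.cos(th) + y * math.sin(th)
    yp = -x * math.sin(th) + y * math.cos(th)
    envelope = np.exp(-0.5 * (xp**2 / sx**2 + yp**2 / sy**2)) / (2 * math.pi * sx * sy)
    kernel = envelope * np.cos(2 * math.pi * f * xp)
    return kernel - kernel.mean()  # DC removal: constant regions yield zero response


def build_filter_bank(config: GaborBankConfig | None = None) -> list[GaborFilterSpec]:
    """One filter per (frequency, orientation) pair, frequency-major order."""
    config = config or GaborBankConfig()
    bank: list[GaborFilterSpec] = []
    for f in config.frequency_set():
        sx, sy = compute_sigmas(
            f, config.frequency_bandwidth, config.orientation_bandwidth, config.circular_sigma
        )
        for theta in config.orientation_set():
            bank.append(
                GaborFilterSpec(
                    f=f,
                    theta=theta,
                    sigma_x=sx,
                    sigma_y=sy,
                    kernel=_sample_kernel(f, theta, sx, sy, config.kernel_truncation),
                )
            )
    return bank


def feature_names(config: GaborBankConfig | None = None, prefix: str = "g") -> tuple[str, ...]:
    """Column names ``{prefix}_f{freq}_o{deg}`` in bank order."""
    config = config or GaborBankConfig()
    return tuple(
        f"{prefix}_f{f:g}_o{theta:g}"
        for f in config.frequency_set()
        for theta in config.orientation_set()
    )


def filter_response(
    roi: ImageGrid | np.ndarray,
    roi_mask: np.ndarray | None,
    filt: GaborFilterSpec,
) -> np.ndarray:
    """Convolve the mean-subtracted ROI with one kernel (reflect padding).

    The mean subtracted is that of the masked pixels, so background never
    biases the response; output has the ROI's shape.
    """
    arr = roi.values if isinstance(roi, ImageGrid) else np.asarray(roi, dtype=float)
    kh, kw = filt.kernel.shape
    if arr.shape[0] < kh or arr.shape[1] < kw:
        raise ContractError(
            f"ROI {arr.shape} smaller than kernel {filt.kernel.shape}; use a larger "
            "ROI or a smaller kernel_truncation"
        )
    if roi_mask is None:
        roi_mask = np.ones(arr.shape, dtype=bool)
    if not roi_mask.any():
        raise ContractError("empty ROI mask")
    centered = arr - arr[roi_mask].mean()
    return ndimage.convolve(centered, filt.kernel, mode="reflect")


def extract_feature_vector(
    roi: ImageGrid | np.ndarray,
    roi_mask: np.ndarray | None,
    bank: Sequence[GaborFilterSpec],
    energy_mode: str = "mean-abs",
    side: str = "",
) -> FeatureVector:
    """Per-filter texture energy over the masked ROI.

    ``sum-abs``: E_k = sum over masked pixels of |response|; ``mean-abs``
    divides by the mask pixel count so energies are comparable across breast
    sizes.
    """
    if not bank:
        raise ContractError("empty filter bank")
    if energy_mode not in ("sum-abs", "mean-abs"):
        raise ContractError(f"unknown energy_mode {energy_mode!r}")
    arr = roi.values if isinstance(roi, ImageGrid) else np.asarray(roi, dtype=float)
    if roi_mask is None:
        roi_mask = np.ones(arr.shape, dtype=bool)
    if not roi_mask.any():
        raise ContractError("empty ROI mask")
    energies = np.empty(len(bank))
    for k, filt in enumerate(bank):
        resp = filter_response(arr, roi_mask, filt)
        total = np.abs(resp[roi_mask]).sum()
        energies[k] = total / roi_mask.sum() if energy_mode == "mean-abs" else total
    return FeatureVector(energies=energies, side=side)


def asymmetry_signature(
    left: FeatureVector, right: FeatureVector, mode: str = "absolute"
) -> AsymmetrySignature:
    """Elementwise left-right energy difference: the classifier's input."""
    if mode not in ("absolute", "signed"):
        raise ContractError(f"unknown mode {mode!r}")
    if left.energies.shape != right.energies.shape:
        raise ContractError(
            f"feature length mismatch: {left.energies.shape} vs {right.energies.shape}"
        )
    diff = left.energies - right.energies
    if mode == "absolute":
        diff = np.abs(diff)
    return AsymmetrySignature(values=diff, mode=mode, names=left.names or right.names)
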