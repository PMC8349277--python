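"""Readers and writers for every external representation the pipelines touch.

Supported formats
-----------------
* Grayscale images: PNG, PGM (P2/P5) and TIFF, 8- or 16-bit.  RGB rasters are
  collapsed to luma with the fixed ITU-R BT.601 weights 0.299/0.587/0.114 so
  that grayscale conversion is identical across image libraries.
* Thermal cameras exported as plain-text temperature matrices (row-major,
  whitespace- or semicolon-delimited, one image row per line, values in deg C).
* Feature tables and dataset manifests: CSV with a header line.
* Metrics reports: JSON (see :mod:`breastasym.metrics`).
"""

from __future__ import annotations

import dataclasses
import enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from PIL import Image

from .errors import ContractError, FormatError, ValidationError

__all__ = [
    "PixelKind",
    "ImageGrid",
    "ManifestRecord",
    "DatasetManifest",
    "LUMA_WEIGHTS",
    "TEMPERATURE_BAND",
    "read_image",
    "write_image",
    "read_temperature_matrix",
    "write_temperature_matrix",
    "write_feature_table",
    "read_feature_table",
    "read_manifest",
    "write_manifest",
]

#: ITU-R BT.601 luma weights used for RGB -> grayscale collapse.
LUMA_WEIGHTS = (0.299, 0.587, 0.114)

#: Plausible skin-temperature band in deg C; readers reject values outside it.
TEMPERATURE_BAND = (15.0, 45.0)

LABELS = ("normal", "benign", "malignant")


class PixelKind(str, enum.Enum):
    INTENSITY8 = "intensity8"
    INTENSITY16 = "intensity16"
    TEMPERATURE = "temperature"


@dataclasses.dataclass(frozen=True)
class ImageGrid:
    """A 2D scalar field: image intensity in native units, or temperature in deg C.

    ``values`` is row-major with a top-left origin; ``shape`` is (M rows, N cols).
    """

    values: np.ndarray
    pixel_kind: PixelKind = PixelKind.INTENSITY8

    def __post_init__(self) -> None:
        arr = np.asarray(self.values, dtype=float)
        if arr.ndim != 2 or arr.shape[0] < 1 or arr.shape[1] < 1:
            raise FormatError(f"image grid must be 2D and non-empty, got shape {arr.shape}")
        if not np.all(np.isfinite(arr)):
            raise ValidationError("image grid contains non-finite values")
        if self.pixel_kind == PixelKind.TEMPERATURE:
            lo, hi = TEMPERATURE_BAND
            if arr.min() < lo or arr.max() > hi:
                raise ValidationError(
                    f"temperature values outside plausible band [{lo}, {hi}] degC: "
                    f"range [{arr.min():.2f}, {arr.max():.2f}]"
                )
        object.__setattr__(self, "values", arr)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def height(self) -> int:
        return self.values.shape[0]

    @property
    def width(self) -> int:
        return self.values.shape[1]


@dataclasses.dataclass(frozen=True)
class ManifestRecord:
    path: str
    subject_id: str
    label: str
    laterality: str = ""  # "", "left" or "right" for pre-split ROIs
    split: str = ""

    def __post_init__(self) -> None:
        if self.label not in LABELS:
            raise ValidationError(f"label {self.label!r} not in {LABELS}")


@dataclasses.dataclass
class DatasetManifest:
    records: list[ManifestRecord]
    provenance: str = ""

    def __post_init__(self) -> None:
        paths = [r.path for r in self.records]
        if len(set(paths)) != len(paths):
            raise ValidationError("manifest contains duplicate image paths")

    def __len__(self) -> int:
        return len(self.records)

    def counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for r in self.records:
            out[r.label] = out.get(r.label, 0) + 1
        return out


# ---------------------------------------------------------------------------
# images
# ---------------------------------------------------------------------------

def read_image(path: str | Path, pixel_kind: PixelKind | str = PixelKind.INTENSITY8) -> ImageGrid:
    """Read a PNG/PGM/TIFF raster into an :class:`ImageGrid`.

    RGB(A) inputs are converted to grayscale with the fixed luma weights
    0.299/0.587/0.114 and rounded back to the native integer scale.
    """
    pixel_kind = PixelKind(pixel_kind)
    path = Path(path)
    try:
        with Image.open(path) as im:
            im.load()
            arr = np.asarray(im)
    except FileNotFoundError:
        raise
    except Exception as exc:  # PIL raises a zoo of types
        raise OSError(f"cannot read image file {path}: {exc}") from exc
    if arr.ndim == 3:
        if arr.shape[2] >= 3:
            w = np.asarray(LUMA_WEIGHTS)
            arr = np.rint(arr[:, :, :3].astype(float) @ w)
        else:
            arr = arr[:, :, 0]
    if arr.size == 0:
        raise FormatError(f"zero-area raster in {path}")
    return ImageGrid(arr.astype(float), pixel_kind)


def write_image(grid: ImageGrid | np.ndarray, path: str | Path, bit_depth: int = 8) -> Path:
    """Write an array or grid as an 8- or 16-bit grayscale raster."""
    arr = grid.values if isinstance(grid, ImageGrid) else np.asarray(grid, dtype=float)
    path = Path(path)
    if bit_depth == 8:
        im = Image.fromarray(np.clip(np.rint(arr), 0, 255).astype(np.uint8), mode="L")
    elif bit_depth == 16:
        im = Image.fromarray(np.clip(np.rint(arr), 0, 65535).astype(np.uint16))
    else:
        raise ContractError(f"bit_depth must be 8 or 16, got {bit_depth}")
    im.save(path)
    return path


# ---------------------------------------------------------------------------
# temperature matrices
# ---------------------------------------------------------------------------

def read_temperature_matrix(path: str | Path, dialect: str = "whitespace") -> ImageGrid:
    """Read a plain-text temperature matrix (one image row per line).

    ``dialect`` is ``"whitespace"`` or ``"semicolon"``.  Rows must all have the
    same length; values must fall in the plausible band ``TEMPERATURE_BAND``.
    """
    if dialect not in ("whitespace", "semicolon"):
        raise ContractError(f"unknown dialect {dialect!r}")
    path = Path(path)
    rows: list[list[float]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            tokens = line.split(";") if dialect == "semicolon" else line.split()
            try:
                row = [float(t) for t in tokens if t.strip()]
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-numeric token ({exc})") from exc
            if rows and len(row) != len(rows[0]):
                raise FormatError(
                    f"{path}:{lineno}: ragged row of length {len(row)}, expected {len(rows[0])}"
                )
            rows.append(row)
    if not rows:
        raise FormatError(f"{path}: empty temperature matrix")
    return ImageGrid(np.asarray(rows, dtype=float), PixelKind.TEMPERATURE)


def write_temperature_matrix(
    grid: ImageGrid | np.ndarray, path: str | Path, dialect: str = "whitespace", decimals: int = 4
) -> Path:
    if dialect not in ("whitespace", "semicolon"):
        raise ContractError(f"unknown dialect {dialect!r}")
    arr = grid.values if isinstance(grid, ImageGrid) else np.asarray(grid, dtype=float)
    sep = ";" if dialect == "semicolon" else " "
    path = Path(path)
    with open(path, "w") as fh:
        for row in arr:
            fh.write(sep.join(f"{v:.{decimals}f}" for v in row) + "\n")
    return path


# ---------------------------------------------------------------------------
# feature tables and manifests
# ---------------------------------------------------------------------------

def write_feature_table(
    rows: Iterable[tuple[str, str, Mapping[str, float]]], path: str | Path
) -> Path:
    """Write (record id, label, feature dict) rows as CSV.

    Column order is ``id, label`` followed by the sorted feature names; floats
    are rendered at 6 significant digits.  All rows must share one feature set.
    """
    rows = list(rows)
    if not rows:
        raise ContractError("no rows to write")
    names = sorted(rows[0][2].keys())
    for rid, _, feats in rows:
        if sorted(feats.keys()) != names:
            raise ContractError(f"row {rid!r} has a different feature set")
    df = pd.DataFrame(
        [[rid, label] + [feats[n] for n in names] for rid, label, feats in rows],
        columns=["id", "label"] + names,
    )
    df.to_csv(path, index=False, float_format="%.6g")
    return Path(path)


def read_feature_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#")
    if "id" not in df.columns or "label" not in df.columns:
        raise FormatError(f"{path}: feature table must have 'id' and 'label' columns")
    return df


def write_manifest(manifest: DatasetManifest, path: str | Path) -> Path:
    df = pd.DataFrame([dataclasses.asdict(r) for r in manifest.records])
    path = Path(path)
    with open(path, "w") as fh:
        if manifest.provenance:
            for line in manifest.provenance.splitlines():
                fh.write(f"# {line}\n")
        df.to_csv(fh, index=False)
    return path


def read_manifest(path: str | Path) -> DatasetManifest:
    path = Path(path)
    provenance: list[str] = []
    with open(path) as fh:
        lines = fh.readlines()
    body = []
    for line in lines:
        if line.startswith("#"):
            provenance.append(line.lstrip("# ").rstrip("\n"))
        else:
            body.append(line)
    from io import StringIO

    df = pd.read_csv(StringIO("".join(body)), dtype=str).fillna("")
    required = {"path", "subject_id", "label"}
    if not required.issubset(df.columns):
        raise FormatError(f"{path}: manifest missing columns {required - set(df.columns)}")
    records = [
        ManifestRecord(
            path=row["path"],
            subject_id=row["subject_id"],
            label=row["label"],
            laterality=row.get("laterality", ""),
            split=row.get("split", ""),
        )
        for _, row in df.iterrows()
    ]
    return DatasetManifest(records, provenance="\n".join(provenance))
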