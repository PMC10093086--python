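"""Image I/O, ROI placement and case manifests for antecedent mammogram analysis.

Conventions used throughout the package:

* arrays are row-major with 0-based indices;
* every crop window is half-open, ``[r0, r0+h) x [c0, c0+w)``;
* the craniocaudal (CC) view is the only view handled; the chest wall lies
  along one vertical image edge and the nipple points toward the other.

Intensities are carried as floating point but preserved losslessly for
integer input formats.  Pixel spacing (the paper's cohort was digitized at
70 um x 70 um) is metadata only -- nothing in the package resamples.
"""

from __future__ import annotations

import datetime as _dt
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Sequence

import numpy as np
import pandas as pd

ROI_SIZE = 512  # side, in pixels, of the standard parenchymal ROI

LATERALITIES = ("left", "right")
LABELS = ("malignant", "benign")


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class ImageGrid:
    """A single grayscale mammographic image plus acquisition metadata."""

    intensities: np.ndarray
    pixel_spacing_mm: tuple[float, float] = (0.07, 0.07)
    laterality: str = "left"
    view: str = "CC"
    exam_date: _dt.date | None = None

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.intensities.ndim != 2:
            raise ValueError("image must be a 2D grid")
        if not np.all(np.isfinite(self.intensities)):
            raise ValueError("image contains non-finite intensities")
        if min(self.pixel_spacing_mm) <= 0:
            raise ValueError("pixel spacing must be positive")
        if self.laterality not in LATERALITIES:
            raise ValueError(f"laterality must be one of {LATERALITIES}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.intensities.shape


@dataclass
class ROIPatch:
    """A square ROI cut from a parent image, with provenance.

    ``origin`` is the (row, col) of the top-left corner in the parent image;
    ``provenance`` records case/exam/laterality and whether the center came
    from the manifest (manual) or the automated heuristic.
    """

    intensities: np.ndarray
    origin: tuple[int, int] = (0, 0)
    case_id: str = ""
    exam_index: int = 0
    laterality: str = "left"
    manual_center: bool = True
    size: int = ROI_SIZE

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.intensities.shape != (self.size, self.size):
            raise ValueError(
                f"ROI must be {self.size}x{self.size}, got {self.intensities.shape}"
            )


@dataclass
class Exam:
    """One screening exam: a date and a per-breast payload.

    The payload is whatever stage of the pipeline the case is at -- an
    :class:`ImageGrid`, an :class:`ROIPatch`, a texture-parameter record from
    the synthetic generator, or a feature vector.
    """

    date_years: float  # exam time in fractional years from an arbitrary origin
    left: Any = None
    right: Any = None

    def side(self, laterality: str) -> Any:
        return self.left if laterality == "left" else self.right


@dataclass
class Case:
    """One woman: future-biopsy label, affected side, ordered antecedent exams."""

    case_id: str
    label: str
    affected_laterality: str
    exams: list[Exam] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.label not in LABELS:
            raise ValueError(f"label must be one of {LABELS}")
        if self.affected_laterality not in LATERALITIES:
            raise ValueError(f"affected_laterality must be one of {LATERALITIES}")
        dates = [e.date_years for e in self.exams]
        if any(b <= a for a, b in zip(dates, dates[1:])):
            raise ValueError("exam dates must be strictly increasing")

    @property
    def n_exams(self) -> int:
        return len(self.exams)

    @property
    def y(self) -> int:
        """Binary label: 1 = future malignant, 0 = future benign."""
        return int(self.label == "malignant")

    def contralateral(self) -> str:
        return "right" if self.affected_laterality == "left" else "left"


# ---------------------------------------------------------------------------
# Reading and writing images
# ---------------------------------------------------------------------------

def read_image(
    path: str | Path,
    format: str | None = None,
    pixel_spacing_mm: tuple[float, float] | None = None,
    laterality: str = "left",
) -> ImageGrid:
    """Read a grayscale PNG/TIFF/DICOM image into an :class:`ImageGrid`.

    Integer formats round-trip losslessly.  Pixel spacing is taken from the
    DICOM ``PixelSpacing`` tag when present; otherwise the caller-supplied
    (manifest) value is used with a warning, defaulting to 70 um.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = (format or path.suffix.lstrip(".")).lower()
    if fmt in ("png", "tif", "tiff"):
        from PIL import Image

        with Image.open(path) as im:
            arr = np.asarray(im)
        if arr.ndim == 3:  # collapse accidental RGB
            arr = arr[..., 0]
        spacing = pixel_spacing_mm
        if spacing is None:
            warnings.warn(f"{path.name}: no pixel spacing available, assuming 0.07 mm")
            spacing = (0.07, 0.07)
        return ImageGrid(arr.astype(float), spacing, laterality=laterality)
    if fmt in ("dcm", "dicom"):
        import pydicom

        ds = pydicom.dcmread(str(path))
        arr = ds.pixel_array.astype(float)
        if getattr(ds, "PixelSpacing", None) is not None:
            spacing = (float(ds.PixelSpacing[0]), float(ds.PixelSpacing[1]))
        elif pixel_spacing_mm is not None:
            warnings.warn(f"{path.name}: DICOM lacks PixelSpacing, using manifest value")
            spacing = pixel_spacing_mm
        else:
            warnings.warn(f"{path.name}: no pixel spacing available, assuming 0.07 mm")
            spacing = (0.07, 0.07)
        return ImageGrid(arr, spacing, laterality=laterality)
    raise ValueError(f"unsupported image format: {fmt!r}")


def write_image_png16(path: str | Path, intensities: np.ndarray) -> None:
    """Write a 2D array as 16-bit grayscale PNG (values clipped to [0, 65535])."""
    from PIL import Image

    arr = np.clip(np.asarray(intensities), 0, 65535).astype(np.uint16)
    Image.fromarray(arr).save(str(path))


# ---------------------------------------------------------------------------
# ROI extraction
# ---------------------------------------------------------------------------

def extract_roi(
    image: ImageGrid | np.ndarray,
    center: tuple[int, int],
    size: int = ROI_SIZE,
    *,
    case_id: str = "",
    exam_index: int = 0,
    manual_center: bool = True,
) -> ROIPatch:
    """Cut the ``size`` x ``size`` window centered at ``center`` (row, col).

    The window is ``[r-size//2, r-size//2+size)`` in each axis and must lie
    fully inside the image; out-of-bounds windows raise rather than zero-fill.
    No interpolation is performed.
    """
    arr = image.intensities if isinstance(image, ImageGrid) else np.asarray(image, float)
    lat = image.laterality if isinstance(image, ImageGrid) else "left"
    r, c = int(center[0]), int(center[1])
    r0, c0 = r - size // 2, c - size // 2
    if r0 < 0 or c0 < 0 or r0 + size > arr.shape[0] or c0 + size > arr.shape[1]:
        raise ValueError(
            f"ROI window [{r0},{r0 + size}) x [{c0},{c0 + size}) exceeds "
            f"image bounds {arr.shape}"
        )
    patch = arr[r0 : r0 + size, c0 : c0 + size].copy()
    return ROIPatch(
        patch,
        origin=(r0, c0),
        case_id=case_id,
        exam_index=exam_index,
        laterality=lat,
        manual_center=manual_center,
        size=size,
    )


def default_center(
    image: ImageGrid | np.ndarray,
    manifest_center: tuple[int, int] | None = None,
    size: int = ROI_SIZE,
) -> tuple[int, int]:
    """Automated surrogate for manual ROI placement posterior to the nipple.

    A manifest-provided (manual) center always wins.  Otherwise the breast
    foreground is segmented by Otsu's threshold; the center row is the
    foreground centroid row, and the center column sits half an ROI side
    posterior (toward the chest-wall edge) of the nipple-side foreground
    extremum.  The chest wall is taken to be the vertical edge with the
    greater foreground contact.
    """
    if manifest_center is not None:
        return (int(manifest_center[0]), int(manifest_center[1]))
    from skimage.filters import threshold_otsu

    arr = image.intensities if isinstance(image, ImageGrid) else np.asarray(image, float)
    if arr.max() <= arr.min():
        raise ValueError("empty foreground: image is constant")
    mask = arr > threshold_otsu(arr)
    if not mask.any():
        raise ValueError("empty foreground after Otsu thresholding")
    rows, cols = np.nonzero(mask)
    row = int(round(rows.mean()))
    # chest wall = vertical edge with more foreground pixels touching it
    left_contact = int(mask[:, 0].sum())
    right_contact = int(mask[:, -1].sum())
    on_row = cols[rows == row]
    if on_row.size == 0:
        on_row = cols
    if right_contact >= left_contact:  # chest wall on the right, nipple to the left
        nipple_col = int(on_row.min())
        col = nipple_col + size // 2
    else:
        nipple_col = int(on_row.max())
        col = nipple_col - size // 2
    return (row, col)


# ---------------------------------------------------------------------------
# Manifests
# ---------------------------------------------------------------------------

MANIFEST_COLUMNS = [
    "case_id",
    "label",
    "affected_laterality",
    "exam_index",
    "exam_date",
    "laterality",
    "image_path",
]


def write_manifest(rows: Sequence[dict], path: str | Path) -> pd.DataFrame:
    """Write a per-image cohort manifest CSV; returns the frame written."""
    df = pd.DataFrame(list(rows))
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"manifest missing required columns: {missing}")
    df = df.sort_values(["case_id", "exam_index", "laterality"]).reset_index(drop=True)
    df.to_csv(path, index=False)
    return df


def read_manifest(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"manifest missing required columns: {missing}")
    return df
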