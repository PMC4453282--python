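"""Reading and writing the image and text formats the CLI speaks.

Grayscale hosts travel as 8-bit PNG or binary PGM (maxval 255), logos as
8-bit-per-channel RGB PNG, patient records as plain text (ASCII subset of
UTF-8). DICOM input is supported read-only when pydicom is installed:
pixel data is window-scaled to 8 bits; DICOM writing is out of scope.
"""

from __future__ import annotations

from pathlib import Path

import imageio.v3 as iio
import numpy as np

from .errors import ConfigurationError

__all__ = ["read_gray", "write_gray", "read_rgb", "write_rgb",
           "read_record", "write_record"]


def read_gray(path: str | Path) -> np.ndarray:
    """Load an 8-bit grayscale host image (PNG/PGM, or DICOM if available)."""
    path = Path(path)
    if path.suffix.lower() in {".dcm", ".dicom"}:
        return _read_dicom(path)
    img = iio.imread(path)
    if img.ndim == 3:  # collapse an RGB(A) scan of a grayscale image
        img = np.asarray(img)[..., :3].mean(axis=2)
        img = np.rint(img)
    img = np.asarray(img)
    if img.dtype != np.uint8:
        if img.max() > 255 or img.min() < 0:
            raise ConfigurationError(f"{path}: not an 8-bit image")
        img = img.astype(np.uint8)
    return img


def _read_dicom(path: Path) -> np.ndarray:
    try:
        import pydicom
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise ConfigurationError(
            "DICOM input requires the optional pydicom dependency"
        ) from exc
    ds = pydicom.dcmread(path)
    arr = ds.pixel_array.astype(np.float64)
    lo, hi = arr.min(), arr.max()
    if hi == lo:
        return np.zeros(arr.shape, dtype=np.uint8)
    return np.rint((arr - lo) * 255.0 / (hi - lo)).astype(np.uint8)


def write_gray(path: str | Path, image: np.ndarray) -> None:
    image = np.ascontiguousarray(image, dtype=np.uint8)
    iio.imwrite(Path(path), image)


def read_rgb(path: str | Path) -> np.ndarray:
    img = np.asarray(iio.imread(Path(path)))
    if img.ndim == 2:
        img = np.stack([img] * 3, axis=2)
    if img.shape[2] == 4:
        img = img[..., :3]
    if img.dtype != np.uint8:
        raise ConfigurationError(f"{path}: logo must be 8 bits per channel")
    return img


def write_rgb(path: str | Path, image: np.ndarray) -> None:
    iio.imwrite(Path(path), np.ascontiguousarray(image, dtype=np.uint8))


def read_record(path: str | Path) -> str:
    text = Path(path).read_text(encoding="utf-8")
    if not text.isascii():
        raise ConfigurationError(f"{path}: patient record must be ASCII")
    return text


def write_record(path: str | Path, record: str) -> None:
    Path(path).write_text(record, encoding="utf-8")
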