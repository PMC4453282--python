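"""Lung-field segmentation and RONI detection.

The watermarking scheme hides data only where it cannot harm diagnosis:
the lung lobes (the region of interest, ROI) are segmented and everything
else is the region of non-interest (RONI). The RONI is further split into
the band between the two lobes (reserved for the logo watermark) and the
remaining surround (reserved for the patient-information index).

Two properties of this stage are load-bearing for the whole scheme:

* **LSB invariance** — thresholding is performed on intensities with bit 0
  cleared (``value & 0xFE``), so embedding payload bits in bit 0 can never
  move a pixel across the threshold. The receiver re-runs segmentation on
  the watermarked image and obtains the *identical* RoniMap, which is what
  lets it locate the payload without any side channel.
* **Determinism** — Otsu's threshold, fixed 8-connectivity, a fixed 3x3
  cross closing, and an explicit tie-break make the map a pure function of
  the image.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu

from .errors import EmptyBandError, SegmentationError

__all__ = [
    "LobeComponent",
    "RoniMap",
    "threshold_lungs",
    "remove_border_artifacts",
    "extract_lobes",
    "detect_roni",
]

_EIGHT = np.ones((3, 3), dtype=bool)  # 8-connectivity structuring element
_CROSS = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)


@dataclass(frozen=True)
class LobeComponent:
    """One segmented lung lobe: its pixel mask and inclusive bounding box."""

    mask: np.ndarray  # bool, full image shape
    row_min: int
    row_max: int
    col_min: int
    col_max: int

    @property
    def size(self) -> int:
        return int(self.mask.sum())


@dataclass(frozen=True)
class RoniMap:
    """Partition of an image into ROI, logo band, and index surround.

    ``interlobe_pixels`` and ``surround_pixels`` are (N, 2) arrays of
    (row, col) coordinates in column-major order (all rows of column 0,
    then column 1, ...). Each listed pixel carries exactly one embeddable
    bit (its LSB), so the capacities equal the list lengths.
    """

    shape: tuple[int, int]
    roi_mask: np.ndarray  # bool — the two lobes; never modified by embedding
    lobes: tuple[LobeComponent, LobeComponent]  # (left, right) by centroid column
    interlobe_pixels: np.ndarray  # (N, 2) int
    surround_pixels: np.ndarray  # (M, 2) int

    @property
    def size_host_logo(self) -> int:
        return int(self.interlobe_pixels.shape[0])

    @property
    def size_host_index(self) -> int:
        return int(self.surround_pixels.shape[0])


def _check_image(image: np.ndarray) -> np.ndarray:
    image = np.asarray(image)
    if image.ndim != 2 or image.size == 0:
        raise SegmentationError("expected a non-empty 2-D grayscale image")
    if image.dtype != np.uint8:
        if image.min() < 0 or image.max() > 255:
            raise SegmentationError("intensities must lie in [0, 255]")
        image = image.astype(np.uint8)
    return image


def threshold_lungs(image: np.ndarray) -> np.ndarray:
    """Global Otsu mask of dark (air-filled) pixels (at or below threshold).

    Computed on LSB-zeroed intensities so the mask is identical for any
    two images that differ only in bit 0. The mask covers both lung
    interiors and the dark background outside the body; the background is
    removed by :func:`remove_border_artifacts`.
    """
    image = _check_image(image)
    stable = image & 0xFE
    if stable.min() == stable.max():
        raise SegmentationError("constant image: no threshold separates classes")
    threshold = threshold_otsu(stable)
    return stable <= threshold


def remove_border_artifacts(mask: np.ndarray) -> np.ndarray:
    """Delete every 8-connected component that touches the image border.

    On a thresholded CT slice this removes the dark background (always
    border-connected) and any artifacts hanging off the frame, leaving the
    interior lung fields untouched.
    """
    mask = np.ascontiguousarray(mask, dtype=bool)
    if not mask.any():
        return mask.copy()
    labels, n = ndimage.label(mask, structure=_EIGHT)
    border = np.concatenate([
        labels[0, :], labels[-1, :], labels[:, 0], labels[:, -1]
    ])
    doomed = np.unique(border[border > 0])
    if doomed.size == 0:
        return mask.copy()
    keep = np.ones(n + 1, dtype=bool)
    keep[doomed] = False
    keep[0] = False
    return keep[labels]


def extract_lobes(mask: np.ndarray) -> tuple[LobeComponent, LobeComponent]:
    """Pick the two largest components as (left, right) lung lobes.

    Components are ranked by pixel count; equal sizes are broken in favour
    of the smaller centroid column so the choice is deterministic. Raises
    :class:`SegmentationError` when fewer than two components exist.
    """
    mask = np.ascontiguousarray(mask, dtype=bool)
    labels, n = ndimage.label(mask, structure=_EIGHT)
    if n < 2:
        raise SegmentationError(f"expected two lung lobes, found {n} component(s)")
    sizes = ndimage.sum_labels(mask, labels, index=np.arange(1, n + 1))
    centroids = ndimage.center_of_mass(mask, labels, index=np.arange(1, n + 1))
    order = sorted(range(n), key=lambda i: (-sizes[i], centroids[i][1]))
    picked = sorted(order[:2], key=lambda i: centroids[i][1])  # left first
    lobes = []
    for i in picked:
        m = labels == i + 1
        rows, cols = np.nonzero(m)
        lobes.append(LobeComponent(
            mask=m,
            row_min=int(rows.min()), row_max=int(rows.max()),
            col_min=int(cols.min()), col_max=int(cols.max()),
        ))
    return lobes[0], lobes[1]


def _column_major(mask: np.ndarray) -> np.ndarray:
    """(N, 2) (row, col) coordinates of True pixels, column-major order."""
    cols, rows = np.nonzero(mask.T)
    return np.column_stack([rows, cols])


def detect_roni(image: np.ndarray) -> RoniMap:
    """Full RONI detection: threshold, clean, extract lobes, split RONI.

    The inter-lobe band is every non-lobe pixel whose row lies in the
    overlap of the two lobes' row ranges and whose column lies strictly
    between the left lobe's rightmost and the right lobe's leftmost
    column. Everything else outside the lobes is surround.
    """
    image = _check_image(image)
    mask = threshold_lungs(image)
    mask = remove_border_artifacts(mask)
    # one small closing to seal pepper holes before picking components
    mask = ndimage.binary_closing(mask, structure=_CROSS)
    left, right = extract_lobes(mask)

    if left.col_max >= right.col_min:
        raise EmptyBandError(
            "lung lobes overlap horizontally: no inter-lobe band exists"
        )

    roi = left.mask | right.mask
    band = np.zeros(image.shape, dtype=bool)
    r_lo = max(left.row_min, right.row_min)
    r_hi = min(left.row_max, right.row_max)
    if r_lo <= r_hi and left.col_max + 1 <= right.col_min - 1:
        band[r_lo:r_hi + 1, left.col_max + 1:right.col_min] = True
    band &= ~roi

    surround = ~roi & ~band

    return RoniMap(
        shape=image.shape,
        roi_mask=roi,
        lobes=(left, right),
        interlobe_pixels=_column_major(band),
        surround_pixels=_column_major(surround),
    )
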