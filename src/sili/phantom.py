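"""Synthetic thorax-slice phantoms, logos, and patient records.

Real chest CT archives cannot be redistributed, so every pipeline in this
package is exercised on seeded synthetic data: an axial thorax slice with a
bright elliptical body on a near-black background and two dark, mirrored
elliptical lung fields (optionally carrying small bright nodules), an RGB
logo, and a printable-ASCII patient record. The phantom deliberately has
the gross intensity structure that makes threshold segmentation of lungs
work on genuine CT — dark air-filled lungs inside bright soft tissue —
without attempting Hounsfield-unit realism.

The generator also returns its own ground-truth lung masks so the
segmentation stage can be scored (Jaccard per lobe) against a known answer.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError

__all__ = [
    "BACKGROUND_LEVEL",
    "BODY_LEVEL",
    "LUNG_LEVEL",
    "NODULE_LEVEL",
    "PhantomSpec",
    "PhantomCT",
    "generate_phantom_ct",
    "generate_logo",
    "generate_patient_record",
]

# Nominal 8-bit intensities before texture noise. Background is near-black
# and soft tissue near-white so one global threshold separates air from body.
BACKGROUND_LEVEL = 2
BODY_LEVEL = 200
LUNG_LEVEL = 25
NODULE_LEVEL = 170

# Printable characters used for synthetic records. NUL (the index codec's
# cap character) is not printable, so it can never occur here.
_RECORD_ALPHABET = string.ascii_letters + string.digits + string.punctuation + " "


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry and noise of one synthetic thorax slice.

    Axes are (row semi-axis, column semi-axis) in pixels. ``lung_offset``
    is the horizontal distance of each lung centre from the image centre,
    so the mediastinum band between the lungs is
    ``2 * (lung_offset - lung_axes[1])`` columns wide. ``noise_sd`` is the
    standard deviation of additive Gaussian texture noise in 8-bit levels.
    Defaults (for the default 256x256 frame) give anatomy-like proportions:
    lungs each roughly a third of the body width with a ~30-column
    mediastinum.
    """

    rows: int = 256
    cols: int = 256
    body_axes: tuple[float, float] = None  # type: ignore[assignment]
    lung_axes: tuple[float, float] = None  # type: ignore[assignment]
    lung_offset: float = None  # type: ignore[assignment]
    noise_sd: float = 6.0
    n_nodules: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.body_axes is None:
            object.__setattr__(self, "body_axes", (0.44 * self.rows, 0.46 * self.cols))
        if self.lung_axes is None:
            object.__setattr__(self, "lung_axes", (0.28 * self.rows, 0.15 * self.cols))
        if self.lung_offset is None:
            object.__setattr__(self, "lung_offset", 0.25 * self.cols)
        if self.rows < 64 or self.cols < 64:
            raise ConfigurationError("phantom must be at least 64x64 pixels")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")
        if self.n_nodules < 0:
            raise ConfigurationError("n_nodules must be >= 0")
        gap = 2.0 * (self.lung_offset - self.lung_axes[1])
        if gap < 4.0:
            raise ConfigurationError(
                f"lung ellipses must leave >= 4 columns of mediastinum, got {gap:.1f}"
            )


@dataclass(frozen=True)
class PhantomCT:
    """A generated slice plus the ground truth it was drawn from."""

    image: np.ndarray  # uint8, rows x cols
    left_lung: np.ndarray  # bool ground-truth mask
    right_lung: np.ndarray  # bool ground-truth mask
    spec: PhantomSpec = field(repr=False)

    @property
    def lung_mask(self) -> np.ndarray:
        return self.left_lung | self.right_lung


def _ellipse_mask(rows: int, cols: int, center: tuple[float, float],
                  axes: tuple[float, float]) -> np.ndarray:
    rr, cc = np.ogrid[:rows, :cols]
    return ((rr - center[0]) / axes[0]) ** 2 + ((cc - center[1]) / axes[1]) ** 2 <= 1.0


def generate_phantom_ct(spec: PhantomSpec) -> PhantomCT:
    """Render one seeded synthetic lung CT slice.

    Deterministic for a given spec: the same seed yields a bit-identical
    image. Raises :class:`ConfigurationError` if the requested geometry
    does not place both lung ellipses strictly inside the body ellipse or
    lets a lung touch the image border.
    """
    rows, cols = spec.rows, spec.cols
    r0, c0 = (rows - 1) / 2.0, (cols - 1) / 2.0

    body = _ellipse_mask(rows, cols, (r0, c0), spec.body_axes)
    left = _ellipse_mask(rows, cols, (r0, c0 - spec.lung_offset), spec.lung_axes)
    right = _ellipse_mask(rows, cols, (r0, c0 + spec.lung_offset), spec.lung_axes)

    _validate_geometry(body, left, right)

    img = np.full((rows, cols), BACKGROUND_LEVEL, dtype=np.float64)
    img[body] = BODY_LEVEL
    img[left | right] = LUNG_LEVEL

    rng = np.random.default_rng(spec.seed)
    for i in range(spec.n_nodules):
        lung_center_col = c0 - spec.lung_offset if i % 2 == 0 else c0 + spec.lung_offset
        radius = float(rng.uniform(1.5, 3.0))
        # keep nodules well interior so ground-truth masks stay ellipses
        dr = rng.uniform(-0.6, 0.6) * spec.lung_axes[0]
        dc = rng.uniform(-0.5, 0.5) * spec.lung_axes[1]
        nodule = _ellipse_mask(rows, cols, (r0 + dr, lung_center_col + dc),
                               (radius, radius))
        img[nodule & (left | right)] = NODULE_LEVEL

    if spec.noise_sd > 0:
        img += rng.normal(0.0, spec.noise_sd, size=img.shape)

    image = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    return PhantomCT(image=image, left_lung=left, right_lung=right, spec=spec)


def _validate_geometry(body: np.ndarray, left: np.ndarray, right: np.ndarray) -> None:
    if (left & right).any():
        raise ConfigurationError("lung ellipses overlap")
    lungs = left | right
    if (lungs & ~body).any():
        raise ConfigurationError("lung ellipses extend outside the body ellipse")
    border = np.zeros_like(lungs)
    border[0, :] = border[-1, :] = True
    border[:, 0] = border[:, -1] = True
    if (lungs & border).any():
        raise ConfigurationError("lung ellipses touch the image border")
    # strict interior: every lung pixel's 4-neighbourhood must stay in the body
    for shift in ((1, 0), (-1, 0), (0, 1), (0, -1)):
        if (np.roll(lungs, shift, axis=(0, 1)) & ~body).any():
            raise ConfigurationError("lung ellipses touch the body boundary")
    left_cols = np.nonzero(left.any(axis=0))[0]
    right_cols = np.nonzero(right.any(axis=0))[0]
    if right_cols.min() - left_cols.max() - 1 < 4:
        raise ConfigurationError("lungs must be separated by >= 4 columns")


def generate_logo(rows: int, cols: int, seed: int) -> np.ndarray:
    """Seeded RGB logo (rows x cols x 3, uint8) with >= 2 distinct colors.

    Drawn as a small random palette applied in blocks so the logo has
    visible structure rather than per-pixel noise; a 1x1 logo is the
    degenerate single-pixel case.
    """
    if not (1 <= rows <= 255 and 1 <= cols <= 255):
        raise ConfigurationError("logo dimensions must be in 1..255")
    rng = np.random.default_rng(seed)
    palette = rng.integers(0, 256, size=(4, 3), dtype=np.uint8)
    block = max(1, min(rows, cols) // 4)
    rr, cc = np.meshgrid(np.arange(rows) // block, np.arange(cols) // block,
                         indexing="ij")
    idx = (rr + 2 * cc + rng.integers(0, 4, size=(rows, cols))) % 4
    logo = palette[idx]
    if rows * cols > 1 and np.unique(logo.reshape(-1, 3), axis=0).shape[0] < 2:
        logo = logo.copy()
        logo[0, 0, 0] ^= 0x80
    return logo


def generate_patient_record(n_chars: int, seed: int) -> str:
    """Seeded printable-ASCII record of exactly ``n_chars`` characters.

    The returned text never contains the index codec's cap character
    (NUL), so its embedded size is exactly ``(n_chars + 1) * 8`` bits.
    """
    if n_chars < 0:
        raise ValueError("n_chars must be >= 0")
    rng = np.random.default_rng(seed)
    chars = rng.integers(0, len(_RECORD_ALPHABET), size=n_chars)
    return "".join(_RECORD_ALPHABET[i] for i in chars)
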