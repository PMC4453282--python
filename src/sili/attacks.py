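"""Channel attacks applied to watermarked images.

Four families mirror what a transmitted scan realistically suffers:
impulse (salt-and-pepper) noise, contrast reduction, motion blur, and
unauthorized extraction attempts. All attacks are total functions that
return a valid 8-bit image of the same shape; the unauthorized-access
probe returns a protection rate instead.

Salt-and-pepper draws two independent uniform fields per seed — one
selecting which pixels are corrupted, one choosing salt vs pepper — so
for a fixed seed the corrupted set at a lower density is a subset of the
set at any higher density. That nesting makes degradation monotone in
density seed-by-seed, not just in expectation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .crypto import KeyMaterial
from .errors import AuthenticationAlert, ParameterError
from .segmentation import RoniMap
from .watermark_codec import extract_logo

__all__ = [
    "AttackSpec",
    "salt_pepper",
    "adjust_contrast",
    "motion_blur",
    "unauthorized_access",
]


@dataclass(frozen=True)
class AttackSpec:
    """One attack with its parameters; used by the evaluation grid / CLI."""

    kind: str
    density: float | None = None  # salt_pepper
    level: int | None = None  # contrast
    length: float | None = None  # motion_blur
    theta: float | None = None  # motion_blur, degrees
    seed: int = 0

    _REQUIRED = {
        "salt_pepper": ("density",),
        "contrast": ("level",),
        "motion_blur": ("length", "theta"),
        "unauthorized": (),
    }

    def __post_init__(self) -> None:
        if self.kind not in self._REQUIRED:
            raise ParameterError(f"unknown attack kind {self.kind!r}")
        for name in self._REQUIRED[self.kind]:
            if getattr(self, name) is None:
                raise ParameterError(f"attack {self.kind!r} requires parameter {name!r}")

    def apply(self, image: np.ndarray) -> np.ndarray:
        if self.kind == "salt_pepper":
            return salt_pepper(image, self.density, self.seed)
        if self.kind == "contrast":
            return adjust_contrast(image, self.level)
        if self.kind == "motion_blur":
            return motion_blur(image, self.length, self.theta)
        raise ParameterError(f"attack {self.kind!r} does not transform an image")

    def label(self) -> str:
        if self.kind == "salt_pepper":
            return f"salt_pepper(density={self.density})"
        if self.kind == "contrast":
            return f"contrast(level={self.level})"
        if self.kind == "motion_blur":
            return f"motion_blur(length={self.length}, theta={self.theta})"
        return self.kind


def _check_image(image: np.ndarray) -> np.ndarray:
    image = np.asarray(image)
    if image.dtype != np.uint8:
        raise ParameterError("attacks operate on 8-bit images")
    return image


def salt_pepper(image: np.ndarray, density: float, seed: int) -> np.ndarray:
    """Impulse noise: each pixel independently corrupted to 0 or 255.

    ``density`` is the per-pixel corruption probability; polarity is an
    even coin. Deterministic per seed, and density-nested for a fixed
    seed (see module docstring).
    """
    image = _check_image(image)
    if not 0.0 <= density <= 1.0:
        raise ParameterError(f"density must be in [0, 1], got {density}")
    rng = np.random.default_rng(seed)
    select = rng.random(image.shape) < density
    salt = rng.random(image.shape) < 0.5
    out = image.copy()
    out[select & salt] = 255
    out[select & ~salt] = 0
    return out


def adjust_contrast(image: np.ndarray, level: int) -> np.ndarray:
    """Compress the full intensity range into [level, 255 - level].

    The linear remap v -> round(level + v*(255 - 2*level)/255) is monotone
    non-decreasing; level 0 is the identity.
    """
    image = _check_image(image)
    if not 0 <= level <= 127:
        raise ParameterError(f"contrast level must be in [0, 127], got {level}")
    lut = np.clip(
        np.rint(level + np.arange(256) * (255 - 2 * level) / 255.0), 0, 255
    ).astype(np.uint8)
    return lut[image]


def _motion_kernel(length: float, theta: float) -> np.ndarray:
    n_taps = int(round(length))
    if n_taps <= 1:
        return np.ones((1, 1))
    rad = np.deg2rad(theta)
    offsets = np.arange(n_taps) - (n_taps - 1) / 2.0
    # image rows grow downward, so a positive angle tilts the line upward
    drows = np.rint(-offsets * np.sin(rad)).astype(int)
    dcols = np.rint(offsets * np.cos(rad)).astype(int)
    half_r, half_c = np.abs(drows).max(), np.abs(dcols).max()
    kernel = np.zeros((2 * half_r + 1, 2 * half_c + 1))
    for dr, dc in zip(drows, dcols):
        kernel[half_r + dr, half_c + dc] += 1.0
    return kernel / kernel.sum()


def motion_blur(image: np.ndarray, length: float, theta: float) -> np.ndarray:
    """Convolve with a normalized line kernel (replicated borders).

    Sub-pixel lengths (< 1 after rounding to taps, e.g. the 0.1 and 0.9
    settings) degenerate to a single-tap identity kernel, leaving the
    image unchanged.
    """
    image = _check_image(image)
    if length < 0:
        raise ParameterError(f"blur length must be >= 0, got {length}")
    kernel = _motion_kernel(length, theta)
    if kernel.size == 1:
        return image.copy()
    blurred = ndimage.convolve(image.astype(np.float64), kernel, mode="nearest")
    return np.clip(np.rint(blurred), 0, 255).astype(np.uint8)


def unauthorized_access(image: np.ndarray, roni: RoniMap,
                        wrong_keys: list[KeyMaterial]) -> float:
    """Protection rate (%) against extraction with keys the sender never used.

    Runs :func:`extract_logo` under every supplied key and reports
    ``100 * alerts / attempts``. An empty key list is vacuously 100%
    protected. If any key unexpectedly succeeds (e.g. the true key slipped
    into the list), the rate drops below 100 and a warning is emitted.
    """
    if not wrong_keys:
        return 100.0
    alerts = 0
    for key in wrong_keys:
        try:
            extract_logo(image, roni, key)
        except AuthenticationAlert:
            alerts += 1
    rate = 100.0 * alerts / len(wrong_keys)
    if rate < 100.0:
        warnings.warn(
            f"{len(wrong_keys) - alerts} extraction attempt(s) were NOT rejected; "
            "check that the true key is not in the wrong-key list",
            stacklevel=2,
        )
    return rate
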