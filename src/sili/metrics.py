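"""Image-quality metrics: mean squared error and peak SNR.

MSE is computed in exact integer arithmetic before the final division,
averaged over every sample (all m*n pixels of a grayscale image, or all
m*n*3 channel values of an RGB one). PSNR follows the 8-bit convention

    PSNR = 20*log10(255) - 10*log10(MSE)   [dB]

and is infinite exactly when the two images are identical — serialized as
the string ``"inf"`` in JSON reports.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import DimensionError

__all__ = ["MAX_I", "QualityReport", "mse", "psnr", "quality_report"]

MAX_I = 255


def _pair(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    x, y = np.asarray(x), np.asarray(y)
    if x.shape != y.shape:
        raise DimensionError(f"image shapes differ: {x.shape} vs {y.shape}")
    if x.size == 0:
        raise DimensionError("images must be non-empty")
    return x.astype(np.int64), y.astype(np.int64)


def mse(x: np.ndarray, y: np.ndarray) -> float:
    """Mean squared intensity difference, in squared 8-bit levels."""
    xi, yi = _pair(x, y)
    diff = xi - yi
    return float(int(np.sum(diff * diff)) / diff.size)


def psnr(x: np.ndarray, y: np.ndarray) -> float:
    """Peak signal-to-noise ratio in dB; ``math.inf`` for identical images."""
    err = mse(x, y)
    if err == 0.0:
        return math.inf
    return 20.0 * math.log10(MAX_I) - 10.0 * math.log10(err)


@dataclass(frozen=True)
class QualityReport:
    """MSE/PSNR pair for one image comparison."""

    mse: float
    psnr: float
    max_i: int = MAX_I

    def to_json_dict(self) -> dict:
        return {
            "mse": self.mse,
            "psnr": "inf" if math.isinf(self.psnr) else self.psnr,
            "max_i": self.max_i,
        }


def quality_report(x: np.ndarray, y: np.ndarray) -> QualityReport:
    err = mse(x, y)
    return QualityReport(
        mse=err,
        psnr=math.inf if err == 0.0 else 20.0 * math.log10(MAX_I) - 10.0 * math.log10(err),
    )
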