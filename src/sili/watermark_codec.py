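"""Keyed logo watermarking in the inter-lobe band.

The RGB logo authenticates the sender. Its bits — a 32-bit header
(16-bit magic ``0x5A3C``, 8-bit rows, 8-bit cols) followed by the pixel
bytes in row-major order, channels R,G,B, MSB-first — are XOR-ed with a
DES-OFB keystream derived from the encrypted secret key and written one
bit per pixel into bit 0 of the inter-lobe band pixels (column-major
order).

At the receiver the first 32 band bits are decrypted with the keystream
and the header checked. A wrong key turns the header into pseudo-random
garbage, so the magic test fails with probability 1 - 2^-16 and the size
sanity check rejects most of the remainder: extraction halts with an
:class:`AuthenticationAlert` and emits nothing (fail-closed). With the
correct key on an attack-corrupted image, extraction proceeds best-effort
whenever the header still verifies, so payload degradation can be
quantified with PSNR.

Capacity rule: the band must offer at least ``n_pixels * 3 * 8 + 32`` bits.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .crypto import KeyMaterial
from .errors import AuthenticationAlert, CapacityError, GeometryError
from .segmentation import RoniMap

__all__ = [
    "MAGIC",
    "HEADER_BITS",
    "WatermarkHeader",
    "watermark_capacity_ok",
    "required_bits",
    "embed_logo",
    "extract_logo",
]

MAGIC = 0x5A3C
HEADER_BITS = 32


@dataclass(frozen=True)
class WatermarkHeader:
    """32-bit header: magic || logo rows || logo cols."""

    logo_rows: int
    logo_cols: int
    magic: int = MAGIC

    def __post_init__(self) -> None:
        if not (1 <= self.logo_rows <= 255 and 1 <= self.logo_cols <= 255):
            raise ValueError("logo dimensions must be in 1..255")

    def to_bits(self) -> np.ndarray:
        data = np.array(
            [self.magic >> 8, self.magic & 0xFF, self.logo_rows, self.logo_cols],
            dtype=np.uint8,
        )
        return np.unpackbits(data)

    @classmethod
    def from_bits(cls, bits: np.ndarray) -> "WatermarkHeader":
        b = np.packbits(np.asarray(bits[:HEADER_BITS], dtype=np.uint8))
        magic = (int(b[0]) << 8) | int(b[1])
        hdr = object.__new__(cls)
        object.__setattr__(hdr, "magic", magic)
        object.__setattr__(hdr, "logo_rows", int(b[2]))
        object.__setattr__(hdr, "logo_cols", int(b[3]))
        return hdr


def required_bits(logo_rows: int, logo_cols: int) -> int:
    """Band bits needed: pixels x 3 channels x 8 bits, plus the header."""
    return logo_rows * logo_cols * 3 * 8 + HEADER_BITS


def watermark_capacity_ok(size_host_logo: int, logo: np.ndarray) -> bool:
    """True iff the band can hold this logo under the capacity rule."""
    logo = _check_logo(logo)
    return size_host_logo >= required_bits(logo.shape[0], logo.shape[1])


def _check_logo(logo: np.ndarray) -> np.ndarray:
    logo = np.asarray(logo)
    if logo.ndim != 3 or logo.shape[2] != 3:
        raise ValueError("logo must be an rows x cols x 3 RGB array")
    if not (1 <= logo.shape[0] <= 255 and 1 <= logo.shape[1] <= 255):
        raise ValueError("logo dimensions must be in 1..255")
    if logo.dtype != np.uint8:
        if logo.min() < 0 or logo.max() > 255:
            raise ValueError("logo channel values must lie in [0, 255]")
        logo = logo.astype(np.uint8)
    return logo


def _check_geometry(image: np.ndarray, roni: RoniMap) -> np.ndarray:
    image = np.asarray(image)
    if image.ndim != 2 or image.shape != roni.shape:
        raise GeometryError(
            f"RoniMap is for shape {roni.shape}, image has shape {image.shape}"
        )
    return image


def embed_logo(image: np.ndarray, roni: RoniMap, logo: np.ndarray,
               keys: KeyMaterial) -> np.ndarray:
    """Return a copy of ``image`` carrying the keystream-protected logo.

    Only pixels listed in ``roni.interlobe_pixels`` change, each by at
    most one intensity level. Raises :class:`CapacityError` (input
    untouched) when the band is too small.
    """
    image = _check_geometry(image, roni)
    logo = _check_logo(logo)
    need = required_bits(logo.shape[0], logo.shape[1])
    if roni.size_host_logo < need:
        raise CapacityError(
            f"logo needs {need} bits but the inter-lobe band offers "
            f"{roni.size_host_logo}; capacity rule n_p*n_c*8+32 violated"
        )
    header = WatermarkHeader(logo.shape[0], logo.shape[1])
    payload = np.concatenate([header.to_bits(), np.unpackbits(logo.reshape(-1))])
    cipher = payload ^ keys.keystream(payload.size)

    out = image.copy()
    coords = roni.interlobe_pixels[:cipher.size]
    rows, cols = coords[:, 0], coords[:, 1]
    out[rows, cols] = (out[rows, cols] & 0xFE) | cipher
    return out


def extract_logo(image: np.ndarray, roni: RoniMap, keys: KeyMaterial) -> np.ndarray:
    """Decrypt and verify the header, then reassemble the logo.

    Raises :class:`AuthenticationAlert` when the header does not verify
    (wrong key, un-watermarked image, or corruption of the header bits);
    in that case nothing is returned — the alert is the whole result.
    """
    image = _check_geometry(image, roni)
    if roni.size_host_logo < HEADER_BITS:
        raise AuthenticationAlert("inter-lobe band too small to hold a header")

    coords = roni.interlobe_pixels
    band_bits = (image[coords[:, 0], coords[:, 1]] & 1).astype(np.uint8)

    header_bits = band_bits[:HEADER_BITS] ^ keys.keystream(HEADER_BITS)
    header = WatermarkHeader.from_bits(header_bits)
    if header.magic != MAGIC:
        raise AuthenticationAlert(
            "watermark header magic mismatch: wrong key or image not watermarked"
        )
    if header.logo_rows < 1 or header.logo_cols < 1:
        raise AuthenticationAlert("watermark header declares an empty logo")
    need = required_bits(header.logo_rows, header.logo_cols)
    if need > roni.size_host_logo:
        raise AuthenticationAlert(
            f"declared logo ({header.logo_rows}x{header.logo_cols}) needs {need} "
            f"bits but the band offers {roni.size_host_logo}"
        )

    cipher = band_bits[HEADER_BITS:need]
    plain = cipher ^ keys.keystream(need)[HEADER_BITS:]
    data = np.packbits(plain)
    return data.reshape(header.logo_rows, header.logo_cols, 3)
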