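"""Patient-information indexing: LSB embedding with a cap terminator.

The record is written one bit per pixel into bit 0 of the RONI surround
pixels (column-major order), each character as 8 bits MSB-first, followed
by a NUL (0x00) *cap character* that marks the end of the string. The host
must therefore offer at least ``(n_chars + 1) * 8`` bits of surround
capacity. Because only bit 0 changes, no pixel moves by more than one
intensity level and the segmented ROI is untouched.

The index is deliberately not keystream-protected: authentication is
enforced at the pipeline level, where index extraction only runs after the
keyed logo watermark has verified the sender.
"""

from __future__ import annotations

import numpy as np

from .errors import CapacityError, GeometryError, MalformedIndexError
from .segmentation import RoniMap

__all__ = [
    "CAP_CHARACTER",
    "index_capacity",
    "embed_index",
    "extract_index",
]

CAP_CHARACTER = "\x00"


def _check_geometry(image: np.ndarray, roni: RoniMap) -> np.ndarray:
    image = np.asarray(image)
    if image.ndim != 2 or image.shape != roni.shape:
        raise GeometryError(
            f"RoniMap is for shape {roni.shape}, image has shape {image.shape}"
        )
    return image


def _encode_record(text: str) -> np.ndarray:
    """Record + cap as a flat 0/1 bit array, 8 bits MSB-first per character."""
    try:
        payload = text.encode("ascii")
    except UnicodeEncodeError as exc:
        raise ValueError("patient record must be ASCII (8 bits per character)") from exc
    if 0 in payload:
        raise ValueError("patient record must not contain the NUL cap character")
    data = np.frombuffer(payload + b"\x00", dtype=np.uint8)
    return np.unpackbits(data)


def index_capacity(size_host_index: int) -> int:
    """Largest record length (characters) a surround of this size can hold.

    The capacity rule is ``size_host >= (n_chars + 1) * 8``: every
    character costs 8 bits and the cap costs 8 more. A surround smaller
    than one cap cannot hold even an empty record.
    """
    if size_host_index < 0:
        raise ValueError("size_host_index must be >= 0")
    if size_host_index < 8:
        raise CapacityError(
            f"surround offers {size_host_index} bits; even the 8-bit cap does not fit"
        )
    return size_host_index // 8 - 1


def embed_index(image: np.ndarray, roni: RoniMap, record: str) -> np.ndarray:
    """Return a copy of ``image`` carrying ``record`` in its surround LSBs.

    Refuses (raising :class:`CapacityError`, input untouched) when the
    record plus cap exceeds the surround capacity. Pixels outside the
    surround list — in particular the whole ROI and the inter-lobe logo
    band — are bit-identical in the result.
    """
    image = _check_geometry(image, roni)
    bits = _encode_record(record)
    if bits.size > roni.size_host_index:
        raise CapacityError(
            f"record needs {bits.size} bits but the surround offers "
            f"{roni.size_host_index}; capacity rule (n_chars+1)*8 violated"
        )
    out = image.copy()
    coords = roni.surround_pixels[:bits.size]
    rows, cols = coords[:, 0], coords[:, 1]
    out[rows, cols] = (out[rows, cols] & 0xFE) | bits
    return out


def extract_index(image: np.ndarray, roni: RoniMap) -> str:
    """Read surround LSBs until the cap character and return the record.

    Raises :class:`MalformedIndexError` when the surround is exhausted
    without ever seeing the cap — the image does not carry a well-formed
    index for this RoniMap.
    """
    image = _check_geometry(image, roni)
    coords = roni.surround_pixels
    n_bytes = coords.shape[0] // 8
    if n_bytes == 0:
        raise MalformedIndexError("surround too small to contain a cap character")
    coords = coords[:n_bytes * 8]
    bits = (image[coords[:, 0], coords[:, 1]] & 1).astype(np.uint8)
    data = np.packbits(bits)
    caps = np.nonzero(data == 0)[0]
    if caps.size == 0:
        raise MalformedIndexError("no cap character found: index missing or corrupted")
    return data[:caps[0]].tobytes().decode("latin-1")
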