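"""DES encryption of the secret key and the keyed embedding bitstream.

The sender turns the (scan number, image number) pair into an encrypted
secret key with single-block DES under an 8-byte user key; that ciphertext
then seeds an output-feedback (OFB) chain whose bits are XOR-ed with the
watermark payload. DES is implemented here directly from FIPS 46-3 in pure
integer arithmetic so the bitstream is reproducible bit-for-bit on any
platform; correctness is pinned by published known-answer vectors in the
test suite. DES is of course obsolete as a cipher — it is used here as the
scheme's keyed pseudo-random permutation, not as a security claim.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np

from .errors import KeyLengthError

__all__ = [
    "KeyMaterial",
    "des_encrypt_block",
    "des_decrypt_block",
    "encrypt_secret_key",
    "decrypt_secret_key",
    "keystream",
]

# ---------------------------------------------------------------------------
# FIPS 46-3 tables. Bit positions are 1-based from the MSB, as printed in the
# standard.
# ---------------------------------------------------------------------------

_IP = (
    58, 50, 42, 34, 26, 18, 10, 2,
    60, 52, 44, 36, 28, 20, 12, 4,
    62, 54, 46, 38, 30, 22, 14, 6,
    64, 56, 48, 40, 32, 24, 16, 8,
    57, 49, 41, 33, 25, 17, 9, 1,
    59, 51, 43, 35, 27, 19, 11, 3,
    61, 53, 45, 37, 29, 21, 13, 5,
    63, 55, 47, 39, 31, 23, 15, 7,
)

_FP = (
    40, 8, 48, 16, 56, 24, 64, 32,
    39, 7, 47, 15, 55, 23, 63, 31,
    38, 6, 46, 14, 54, 22, 62, 30,
    37, 5, 45, 13, 53, 21, 61, 29,
    36, 4, 44, 12, 52, 20, 60, 28,
    35, 3, 43, 11, 51, 19, 59, 27,
    34, 2, 42, 10, 50, 18, 58, 26,
    33, 1, 41, 9, 49, 17, 57, 25,
)

_E = (
    32, 1, 2, 3, 4, 5,
    4, 5, 6, 7, 8, 9,
    8, 9, 10, 11, 12, 13,
    12, 13, 14, 15, 16, 17,
    16, 17, 18, 19, 20, 21,
    20, 21, 22, 23, 24, 25,
    24, 25, 26, 27, 28, 29,
    28, 29, 30, 31, 32, 1,
)

_P = (
    16, 7, 20, 21, 29, 12, 28, 17,
    1, 15, 23, 26, 5, 18, 31, 10,
    2, 8, 24, 14, 32, 27, 3, 9,
    19, 13, 30, 6, 22, 11, 4, 25,
)

_PC1 = (
    57, 49, 41, 33, 25, 17, 9,
    1, 58, 50, 42, 34, 26, 18,
    10, 2, 59, 51, 43, 35, 27,
    19, 11, 3, 60, 52, 44, 36,
    63, 55, 47, 39, 31, 23, 15,
    7, 62, 54, 46, 38, 30, 22,
    14, 6, 61, 53, 45, 37, 29,
    21, 13, 5, 28, 20, 12, 4,
)

_PC2 = (
    14, 17, 11, 24, 1, 5,
    3, 28, 15, 6, 21, 10,
    23, 19, 12, 4, 26, 8,
    16, 7, 27, 20, 13, 2,
    41, 52, 31, 37, 47, 55,
    30, 40, 51, 45, 33, 48,
    44, 49, 39, 56, 34, 53,
    46, 42, 50, 36, 29, 32,
)

_SHIFTS = (1, 1, 2, 2, 2, 2, 2, 2, 1, 2, 2, 2, 2, 2, 2, 1)

_SBOX = (
    (
        14, 4, 13, 1, 2, 15, 11, 8, 3, 10, 6, 12, 5, 9, 0, 7,
        0, 15, 7, 4, 14, 2, 13, 1, 10, 6, 12, 11, 9, 5, 3, 8,
        4, 1, 14, 8, 13, 6, 2, 11, 15, 12, 9, 7, 3, 10, 5, 0,
        15, 12, 8, 2, 4, 9, 1, 7, 5, 11, 3, 14, 10, 0, 6, 13,
    ),
    (
        15, 1, 8, 14, 6, 11, 3, 4, 9, 7, 2, 13, 12, 0, 5, 10,
        3, 13, 4, 7, 15, 2, 8, 14, 12, 0, 1, 10, 6, 9, 11, 5,
        0, 14, 7, 11, 10, 4, 13, 1, 5, 8, 12, 6, 9, 3, 2, 15,
        13, 8, 10, 1, 3, 15, 4, 2, 11, 6, 7, 12, 0, 5, 14, 9,
    ),
    (
        10, 0, 9, 14, 6, 3, 15, 5, 1, 13, 12, 7, 11, 4, 2, 8,
        13, 7, 0, 9, 3, 4, 6, 10, 2, 8, 5, 14, 12, 11, 15, 1,
        13, 6, 4, 9, 8, 15, 3, 0, 11, 1, 2, 12, 5, 10, 14, 7,
        1, 10, 13, 0, 6, 9, 8, 7, 4, 15, 14, 3, 11, 5, 2, 12,
    ),
    (
        7, 13, 14, 3, 0, 6, 9, 10, 1, 2, 8, 5, 11, 12, 4, 15,
        13, 8, 11, 5, 6, 15, 0, 3, 4, 7, 2, 12, 1, 10, 14, 9,
        10, 6, 9, 0, 12, 11, 7, 13, 15, 1, 3, 14, 5, 2, 8, 4,
        3, 15, 0, 6, 10, 1, 13, 8, 9, 4, 5, 11, 12, 7, 2, 14,
    ),
    (
        2, 12, 4, 1, 7, 10, 11, 6, 8, 5, 3, 15, 13, 0, 14, 9,
        14, 11, 2, 12, 4, 7, 13, 1, 5, 0, 15, 10, 3, 9, 8, 6,
        4, 2, 1, 11, 10, 13, 7, 8, 15, 9, 12, 5, 6, 3, 0, 14,
        11, 8, 12, 7, 1, 14, 2, 13, 6, 15, 0, 9, 10, 4, 5, 3,
    ),
    (
        12, 1, 10, 15, 9, 2, 6, 8, 0, 13, 3, 4, 14, 7, 5, 11,
        10, 15, 4, 2, 7, 12, 9, 5, 6, 1, 13, 14, 0, 11, 3, 8,
        9, 14, 15, 5, 2, 8, 12, 3, 7, 0, 4, 10, 1, 13, 11, 6,
        4, 3, 2, 12, 9, 5, 15, 10, 11, 14, 1, 7, 6, 0, 8, 13,
    ),
    (
        4, 11, 2, 14, 15, 0, 8, 13, 3, 12, 9, 7, 5, 10, 6, 1,
        13, 0, 11, 7, 4, 9, 1, 10, 14, 3, 5, 12, 2, 15, 8, 6,
        1, 4, 11, 13, 12, 3, 7, 14, 10, 15, 6, 8, 0, 5, 9, 2,
        6, 11, 13, 8, 1, 4, 10, 7, 9, 5, 0, 15, 14, 2, 3, 12,
    ),
    (
        13, 2, 8, 4, 6, 15, 11, 1, 10, 9, 3, 14, 5, 0, 12, 7,
        1, 15, 13, 8, 10, 3, 7, 4, 12, 5, 6, 11, 0, 14, 9, 2,
        7, 11, 4, 1, 9, 12, 14, 2, 0, 6, 10, 13, 15, 3, 5, 8,
        2, 1, 14, 7, 4, 10, 8, 13, 15, 12, 9, 0, 3, 5, 6, 11,
    ),
)


def _permute(value: int, width: int, table: tuple[int, ...]) -> int:
    out = 0
    for pos in table:
        out = (out << 1) | ((value >> (width - pos)) & 1)
    return out


def _build_sp() -> tuple[tuple[int, ...], ...]:
    # Fuse each S-box with the P permutation: SP[i][6-bit chunk] is the
    # 32-bit, already-P-permuted contribution of S-box i.
    tables = []
    for i, box in enumerate(_SBOX):
        entries = []
        for chunk in range(64):
            row = ((chunk >> 4) & 2) | (chunk & 1)
            col = (chunk >> 1) & 0xF
            s_out = box[(row << 4) | col] << (28 - 4 * i)
            entries.append(_permute(s_out, 32, _P))
        tables.append(tuple(entries))
    return tuple(tables)


_SP = _build_sp()


@lru_cache(maxsize=4096)
def _subkeys(key: bytes) -> tuple[int, ...]:
    if len(key) != 8:
        raise KeyLengthError(f"DES key must be exactly 8 bytes, got {len(key)}")
    k = int.from_bytes(key, "big")
    cd = _permute(k, 64, _PC1)
    c, d = cd >> 28, cd & 0xFFFFFFF
    keys = []
    for shift in _SHIFTS:
        c = ((c << shift) | (c >> (28 - shift))) & 0xFFFFFFF
        d = ((d << shift) | (d >> (28 - shift))) & 0xFFFFFFF
        keys.append(_permute((c << 28) | d, 56, _PC2))
    return tuple(keys)


def _feistel(right: int, subkey: int) -> int:
    e = _permute(right, 32, _E) ^ subkey
    out = 0
    for i in range(8):
        out |= _SP[i][(e >> (42 - 6 * i)) & 0x3F]
    return out


def _des_block(key: bytes, block8: bytes, decrypt: bool) -> bytes:
    keys = _subkeys(key)
    if decrypt:
        keys = keys[::-1]
    block = _permute(int.from_bytes(block8, "big"), 64, _IP)
    left, right = block >> 32, block & 0xFFFFFFFF
    for sk in keys:
        left, right = right, left ^ _feistel(right, sk)
    # final swap undoes the last exchange
    pre = (right << 32) | left
    return _permute(pre, 64, _FP).to_bytes(8, "big")


def des_encrypt_block(key: bytes, plaintext: bytes) -> bytes:
    """Encrypt one 64-bit block with single-DES (FIPS 46-3, 16 rounds)."""
    if len(plaintext) != 8:
        raise ValueError(f"DES block must be 8 bytes, got {len(plaintext)}")
    return _des_block(key, plaintext, decrypt=False)


def des_decrypt_block(key: bytes, ciphertext: bytes) -> bytes:
    """Decrypt one 64-bit block with single-DES."""
    if len(ciphertext) != 8:
        raise ValueError(f"DES block must be 8 bytes, got {len(ciphertext)}")
    return _des_block(key, ciphertext, decrypt=True)


# ---------------------------------------------------------------------------
# Secret-key handling
# ---------------------------------------------------------------------------

def encrypt_secret_key(user_key: bytes, scan_number: int, image_number: int) -> bytes:
    """Encrypt (scan number, image number) into the 8-byte secret key.

    The two identifiers are packed big-endian into one DES block and
    encrypted under the sender's user key. Parity bits of the key are not
    checked (they do not affect the key schedule).
    """
    plaintext = struct.pack(">II", scan_number, image_number)
    return des_encrypt_block(user_key, plaintext)


def decrypt_secret_key(user_key: bytes, ciphertext: bytes) -> tuple[int, int]:
    """Invert :func:`encrypt_secret_key`, returning (scan, image) numbers."""
    if len(ciphertext) != 8:
        raise ValueError(f"ciphertext must be 8 bytes, got {len(ciphertext)}")
    scan_number, image_number = struct.unpack(">II", des_decrypt_block(user_key, ciphertext))
    return scan_number, image_number


def keystream(user_key: bytes, encrypted_secret_key: bytes, n_bits: int) -> np.ndarray:
    """DES-OFB bitstream seeded by the encrypted secret key.

    block_0 is the encrypted secret key itself; each successive block is
    the DES encryption of the previous one under the user key. The emitted
    bits are those of block_1, block_2, ... (MSB first), truncated to
    ``n_bits``, returned as a uint8 array of 0/1 for direct XOR with
    payload bits.
    """
    if n_bits < 0:
        raise ValueError("n_bits must be >= 0")
    out = bytearray()
    state = encrypted_secret_key
    while len(out) * 8 < n_bits:
        state = des_encrypt_block(user_key, state)
        out.extend(state)
    bits = np.unpackbits(np.frombuffer(bytes(out), dtype=np.uint8))
    return bits[:n_bits]


@dataclass(frozen=True)
class KeyMaterial:
    """Everything key-related both ends of the channel need.

    The receiver re-derives ``encrypted_secret_key`` from the same
    (user key, scan number, image number) triple it holds out-of-band;
    a mismatch on any of the three yields a different keystream and
    therefore an authentication alert at extraction time.
    """

    user_key: bytes
    scan_number: int
    image_number: int
    encrypted_secret_key: bytes = field(init=False)

    def __post_init__(self) -> None:
        if len(self.user_key) != 8:
            raise KeyLengthError(
                f"DES user key must be exactly 8 bytes, got {len(self.user_key)}"
            )
        for name in ("scan_number", "image_number"):
            v = getattr(self, name)
            if not 0 <= v < 2**32:
                raise ValueError(f"{name} must fit in an unsigned 32-bit integer")
        object.__setattr__(
            self,
            "encrypted_secret_key",
            encrypt_secret_key(self.user_key, self.scan_number, self.image_number),
        )

    @classmethod
    def from_hex(cls, hex_key: str, scan_number: int, image_number: int) -> "KeyMaterial":
        """Build from the CLI's 16-hex-character key representation."""
        try:
            key = bytes.fromhex(hex_key)
        except ValueError as exc:
            raise KeyLengthError(f"key is not valid hex: {hex_key!r}") from exc
        return cls(key, scan_number, image_number)

    def keystream(self, n_bits: int) -> np.ndarray:
        return keystream(self.user_key, self.encrypted_secret_key, n_bits)
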