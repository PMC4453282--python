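"""Sender and receiver pipelines wired end-to-end.

Sender: encrypt the secret key, segment the CT and detect RONI, embed the
patient-information index in the surround, embed the keyed logo in the
inter-lobe band, and report capacities and imperceptibility PSNR.

Receiver: re-derive the key material, re-run segmentation on the received
image (LSB-invariant, so the recovered RoniMap matches the sender's),
extract and verify the logo — this is the authentication gate — and only
then extract the patient record. On an authentication alert the receiver
stops fail-closed: no partial patient data is ever emitted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .crypto import KeyMaterial
from .errors import AuthenticationAlert, SiliError
from .index_codec import embed_index, extract_index, index_capacity
from .metrics import quality_report
from .segmentation import RoniMap, detect_roni
from .watermark_codec import embed_logo, extract_logo, required_bits

__all__ = ["PipelineConfig", "SenderResult", "ReceiverResult", "run_sender", "run_receiver"]

REPORT_SCHEMA_VERSION = 1


@dataclass(frozen=True)
class PipelineConfig:
    """Key material and knobs shared by both pipeline directions."""

    hex_key: str
    scan_number: int
    image_number: int
    seed: int = 0

    def key_material(self) -> KeyMaterial:
        return KeyMaterial.from_hex(self.hex_key, self.scan_number, self.image_number)


@dataclass(frozen=True)
class SenderResult:
    watermarked: np.ndarray
    roni: RoniMap
    report: dict = field(repr=False)


@dataclass(frozen=True)
class ReceiverResult:
    authenticated: bool
    logo: np.ndarray | None
    record: str | None
    report: dict = field(repr=False)


def _stage(name: str):
    """Re-raise any library error with the failing pipeline stage named."""
    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and isinstance(exc, SiliError):
                exc.args = (f"[{name}] {exc}",)
            return False

    return _Ctx()


def run_sender(ct: np.ndarray, logo: np.ndarray, record: str,
               keys: KeyMaterial) -> SenderResult:
    """Embed index then logo into the CT's RONI; ROI stays bit-identical."""
    with _stage("segmentation"):
        roni = detect_roni(ct)
    with _stage("index embedding"):
        indexed = embed_index(ct, roni, record)
    with _stage("logo embedding"):
        watermarked = embed_logo(indexed, roni, logo, keys)

    quality = quality_report(ct, watermarked)
    report = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "stage": "sender",
        "size_host_index": roni.size_host_index,
        "size_host_logo": roni.size_host_logo,
        "index_capacity_chars": index_capacity(roni.size_host_index),
        "logo_bits_required": required_bits(logo.shape[0], logo.shape[1]),
        "record_chars": len(record),
        "host_vs_watermarked": quality.to_json_dict(),
        "roi_pixels": int(roni.roi_mask.sum()),
    }
    return SenderResult(watermarked=watermarked, roni=roni, report=report)


def run_receiver(image: np.ndarray, keys: KeyMaterial) -> ReceiverResult:
    """Authenticate via the logo watermark, then extract the record.

    Returns ``authenticated=False`` (with no logo and no record) when the
    keyed header fails verification; segmentation failures propagate as
    :class:`~sili.errors.SegmentationError` since without a RoniMap there
    is nothing to verify.
    """
    with _stage("segmentation"):
        roni = detect_roni(image)

    report: dict = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "stage": "receiver",
        "size_host_index": roni.size_host_index,
        "size_host_logo": roni.size_host_logo,
    }

    try:
        logo = extract_logo(image, roni, keys)
    except AuthenticationAlert as alert:
        report["authenticated"] = False
        report["alert"] = str(alert)
        return ReceiverResult(authenticated=False, logo=None, record=None, report=report)

    with _stage("index extraction"):
        record = extract_index(image, roni)

    report["authenticated"] = True
    report["logo_shape"] = list(logo.shape)
    report["record_chars"] = len(record)
    return ReceiverResult(authenticated=True, logo=logo, record=record, report=report)
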