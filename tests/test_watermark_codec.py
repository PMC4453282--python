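"""Keyed logo watermark: capacity law, lossless roundtrip, fail-closed auth."""

import math

import numpy as np
import pytest

from sili.crypto import KeyMaterial
from sili.errors import AuthenticationAlert, CapacityError, GeometryError
from sili.index_codec import embed_index
from sili.metrics import psnr
from sili.phantom import generate_logo
from sili.watermark_codec import (
    HEADER_BITS,
    embed_logo,
    extract_logo,
    required_bits,
    watermark_capacity_ok,
)


class TestCapacityLaw:
    def test_16x16_boundary(self):
        logo = generate_logo(16, 16, seed=3)
        assert required_bits(16, 16) == 6176
        assert watermark_capacity_ok(6176, logo)
        assert not watermark_capacity_ok(6175, logo)

    def test_1x1_needs_56_bits(self):
        logo = generate_logo(1, 1, seed=0)
        assert watermark_capacity_ok(56, logo)
        assert not watermark_capacity_ok(55, logo)

    def test_exhaustive_against_brute_force(self):
        """Verdicts match the raw inequality for all small logos/capacities."""
        for rows in range(1, 9):
            for cols in range(1, 9):
                logo = np.zeros((rows, cols, 3), dtype=np.uint8)
                need = rows * cols * 3 * 8 + 32
                capacities = np.arange(0, 2001)
                got = np.array([watermark_capacity_ok(int(c), logo)
                                for c in capacities])
                assert np.array_equal(got, capacities >= need)


class TestRoundtrip:
    def test_lossless_recovery(self, phantom7, roni7, logo16, keys):
        wm = embed_logo(phantom7.image, roni7, logo16, keys)
        out = extract_logo(wm, roni7, keys)
        assert np.array_equal(out, logo16)
        assert math.isinf(psnr(logo16, out))

    def test_only_band_pixels_change_by_at_most_one(self, phantom7, roni7, logo16, keys):
        wm = embed_logo(phantom7.image, roni7, logo16, keys)
        diff = np.abs(wm.astype(int) - phantom7.image.astype(int))
        assert diff.max() <= 1
        changed = np.argwhere(diff > 0)
        band = set(map(tuple, roni7.interlobe_pixels))
        assert all(tuple(p) in band for p in changed)

    def test_imperceptibility_bound(self, phantom7, roni7, logo16, keys):
        # MSE <= 6176/65536 gives PSNR >= 20log10(255) - 10log10(6176/65536)
        wm = embed_logo(phantom7.image, roni7, logo16, keys)
        bound = 20 * math.log10(255) - 10 * math.log10(6176 / 65536)
        assert psnr(phantom7.image, wm) >= bound > 48.13

    def test_commutes_with_index_embedding(self, phantom7, roni7, logo16, keys,
                                           record24):
        a = embed_logo(embed_index(phantom7.image, roni7, record24),
                       roni7, logo16, keys)
        b = embed_index(embed_logo(phantom7.image, roni7, logo16, keys),
                        roni7, record24)
        assert np.array_equal(a, b)

    def test_roundtrip_various_logo_sizes(self, phantom7, roni7, keys):
        for rows, cols in [(1, 1), (3, 17), (16, 16)]:
            logo = generate_logo(rows, cols, seed=rows * 31 + cols)
            wm = embed_logo(phantom7.image, roni7, logo, keys)
            assert np.array_equal(extract_logo(wm, roni7, keys), logo)


class TestCapacityEnforcement:
    def test_oversized_logo_refused_input_untouched(self, phantom7, roni7, keys):
        big = generate_logo(100, 100, seed=1)  # 240032 bits >> band
        before = phantom7.image.copy()
        with pytest.raises(CapacityError):
            embed_logo(phantom7.image, roni7, big, keys)
        assert np.array_equal(phantom7.image, before)

    def test_shape_mismatch_is_geometry_error(self, roni7, logo16, keys):
        with pytest.raises(GeometryError):
            embed_logo(np.zeros((10, 10), dtype=np.uint8), roni7, logo16, keys)


class TestAuthentication:
    def test_wrong_keys_always_alert(self, phantom7, roni7, logo16, keys):
        wm = embed_logo(phantom7.image, roni7, logo16, keys)
        rng = np.random.default_rng(42)
        for _ in range(200):
            wrong = KeyMaterial(rng.bytes(8), keys.scan_number, keys.image_number)
            if wrong.user_key == keys.user_key:
                continue
            with pytest.raises(AuthenticationAlert):
                extract_logo(wm, roni7, wrong)

    def test_wrong_scan_or_image_number_alerts(self, phantom7, roni7, logo16, keys):
        wm = embed_logo(phantom7.image, roni7, logo16, keys)
        for scan, image in [(keys.scan_number + 1, keys.image_number),
                            (keys.scan_number, keys.image_number + 1)]:
            wrong = KeyMaterial(keys.user_key, scan, image)
            with pytest.raises(AuthenticationAlert):
                extract_logo(wm, roni7, wrong)

    def test_unwatermarked_image_alerts(self, phantom7, roni7, keys):
        with pytest.raises(AuthenticationAlert):
            extract_logo(phantom7.image, roni7, keys)

    def test_heavy_band_corruption_is_total(self, phantom7, roni7, logo16, keys):
        """Salt-and-pepper at density 0.5 on the band: alert or a logo, no crash."""
        wm = embed_logo(phantom7.image, roni7, logo16, keys)
        rng = np.random.default_rng(9)
        coords = roni7.interlobe_pixels
        hit = rng.random(len(coords)) < 0.5
        vals = np.where(rng.random(hit.sum()) < 0.5, 0, 255).astype(np.uint8)
        wm[coords[hit, 0], coords[hit, 1]] = vals
        try:
            out = extract_logo(wm, roni7, keys)
            assert out.ndim == 3 and out.shape[2] == 3
        except AuthenticationAlert:
            pass

    def test_header_bits_are_keystream_protected(self, phantom7, roni7, logo16, keys):
        """Band LSBs carry no cleartext header: the magic is never in plain."""
        wm = embed_logo(phantom7.image, roni7, logo16, keys)
        coords = roni7.interlobe_pixels[:HEADER_BITS]
        raw = np.packbits((wm[coords[:, 0], coords[:, 1]] & 1).astype(np.uint8))
        assert (int(raw[0]) << 8 | int(raw[1])) != 0x5A3C
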