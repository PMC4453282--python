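# Methods

## The scheme

`sili` implements spatial-domain, irreversible, region-constrained LSB
watermarking of 8-bit lung CT slices with two payloads:

* the **index** — the patient-information string, so the scan carries its
  own retrieval metadata;
* the **authentication mark** — an RGB logo protected by a keyed
  bitstream, so the receiver can verify the sender and reject any
  extraction attempt made with the wrong key.

Both payloads are confined to the region of non-interest. The segmented
lung lobes (ROI) pass through the sender bit-identical: embedding writes
only bit 0 of pixels outside them, so no pixel anywhere changes by more
than one intensity level.

## Segmentation and the RONI partition

Lung parenchyma is air-filled and therefore dark relative to soft tissue.
The pipeline is:

1. **Threshold.** Otsu's method on LSB-zeroed intensities (`v & 0xFE`);
   dark class = values at or below the threshold. Working on the 7 high
   bits makes the mask — and everything derived from it — invariant to
   any change of bit 0, which is exactly the set of changes embedding can
   make. The receiver therefore recomputes the same RoniMap from the
   watermarked image. A constant image (no two classes) is a
   segmentation failure.
2. **Border-artifact removal.** Every 8-connected dark component touching
   the image border is deleted; this removes the background air around
   the body and any gantry/edge artifacts.
3. **Closing.** One binary closing with a 3x3 cross seals single-pixel
   holes (noise, small bright nodules) before components are ranked.
4. **Lobe extraction.** The two largest components are the lobes, labeled
   left/right by centroid column; equal sizes break toward the smaller
   centroid column for determinism. Fewer than two components is a
   segmentation failure.
5. **Partition.** The inter-lobe band is every non-lobe pixel whose row
   lies in the intersection of the lobes' bounding-box row ranges and
   whose column lies strictly between the left lobe's rightmost and the
   right lobe's leftmost column. The surround is every remaining
   non-lobe pixel. Both lists are ordered column-major (all rows of
   column 0, then column 1, ...), matching the single-column flattening
   convention of the embedding algorithms; coordinates are 0-based with
   inclusive boxes.

The band hosts the logo; the surround hosts the index. Restricting the
index to the surround (rather than flattening the whole image) keeps
every written bit out of the ROI by construction.

## Key material and the bitstream

The pair (scan number, image number) — two unsigned 32-bit integers,
packed big-endian — is encrypted as one DES block under the sender's
8-byte user key, producing the **encrypted secret key**. DES is
implemented from the FIPS 46-3 tables in pure integer arithmetic and is
pinned by four published known-answer vectors in the test suite; it is
used as the scheme's keyed pseudo-random permutation, not as a modern
security primitive.

The embedding bitstream is DES-OFB: block_0 is the encrypted secret key,
block_{i+1} = DES(user_key, block_i), and the emitted bits are those of
block_1, block_2, ... MSB-first. The stream has the prefix property
(extraction can decrypt the 32-bit header before deciding how much more
to read) and empirically balanced bits (~0.5 over 10^4 bits).

## Codecs

**Index.** Characters are 8-bit ASCII, MSB-first, written into surround
LSBs in list order and terminated by a NUL (0x00) cap character; records
therefore may not contain NUL, and the capacity law is
`size_host >= (n_chars + 1) * 8`. Extraction reads LSBs, regroups bytes,
and stops at the first NUL; a missing cap raises a malformed-index error.
The index is *not* keystream-protected: authentication is enforced at the
pipeline level, where index extraction runs only after the keyed logo
header has verified. Embedding refuses (input untouched) when capacity
is violated.

**Logo.** Payload = 32-bit header (16-bit magic 0x5A3C, 8-bit rows, 8-bit
cols) followed by logo bytes in row-major pixel order, channels R,G,B,
MSB-first; the whole payload is XOR-ed with the keystream and written to
band LSBs. Capacity law: `size_host >= n_pixels * 3 * 8 + 32`; logo
dimensions are capped at 255 so they fit the 8-bit header fields.
Extraction decrypts the header and raises an authentication alert when
the magic mismatches, a dimension is zero, or the declared logo would
exceed the band capacity; a wrong key randomizes the header, so the
false-accept probability is at most 2^-16 per attempt (magic alone) and
in practice far lower because the random dimensions must also satisfy
the capacity law. With the correct key on a corrupted image, extraction
proceeds best-effort whenever the header still verifies, so degraded
logos can be scored with PSNR.

Because the two payloads occupy disjoint pixel sets, index-then-logo and
logo-then-index embedding commute bit-exactly.

## Attacks and evaluation

* **Salt-and-pepper** (densities 0.01, 0.02): each pixel is corrupted to
  0 or 255. The generator draws one uniform field to select pixels and an
  independent field for polarity, so for a fixed seed the corrupted set
  at a lower density is a *subset* of that at a higher density — payload
  damage is monotone in density seed-by-seed, not just on average.
* **Contrast reduction** (levels 10, 30): the monotone remap
  `v -> round(level + v*(255 - 2*level)/255)`, compressing [0,255] into
  [level, 255-level].
* **Motion blur** (length/theta 0.1 and 0.9): convolution with a
  normalized line kernel, replicated borders; lengths that round to a
  single tap are the identity, so the sub-pixel settings are lossless by
  construction.
* **Unauthorized access**: extraction attempted under lists of wrong
  keys; the protection rate is the fraction of attempts that alert.

The evaluation reports two PSNRs per attack because they answer different
questions: *image PSNR* (watermarked vs attacked) measures channel damage
to the scan, and *logo PSNR* (original vs re-extracted, receiver-side
re-segmentation included) measures payload survival. A logo that cannot
be extracted — authentication alert or corrupted declared size — scores
0.0 dB (total loss). Bit-exact survival is infinite.

Expected behavior of the grid, all verified by the test suite: the clean
channel and both blur settings are lossless (infinite PSNR); impulse
noise yields alerts or degraded logos, strictly worse at density 0.02
than 0.01; contrast reduction at *any* level destroys the LSB payload
(an intensity remap scrambles pixel parities over the band's intensity
range, ~50% bit error), so both levels score 0.0 dB logo PSNR while the
image PSNR degrades smoothly and strictly with level. This asymmetry is
inherent to spatial LSB embedding, not an implementation artifact:
finite logo-survival figures under contrast attacks are only achievable
by transform-domain or redundant encodings, which are out of scope here.

## The phantom generator

Real chest CT archives cannot be shipped, so all tests run on seeded
synthetic slices: background near 0, an elliptical body near 200, two
mirrored dark lung ellipses near 25, optional small bright nodules, and
Gaussian texture noise (sd 6 levels by default — strong enough to give
every pixel a live LSB, far too weak to threaten a threshold that sits
mid-range between the classes). Defaults for the 256x256 frame: body
semi-axes (0.44, 0.46) of the frame, lung semi-axes (0.28, 0.15), lung
centres offset 0.25 of the width from centre, 3 nodules. This yields a
~51-column mediastinum band of 7488 embeddable bits, sized so the default
16x16 logo (6176 bits required) fits with margin. The generator returns
its own ground-truth lung masks; segmentation recovers them at Jaccard
>= 0.95 per lobe (typically >= 0.99).

What the phantom does **not** emulate: Hounsfield calibration, lobe
fissures, airways and vessels, pleural effusion, patient-table artifacts,
or anatomy where the lungs touch. Passing tests show the scheme's logic —
geometry, capacity, bit-exactness, keying — is correct; they do not show
that threshold segmentation succeeds on every clinical scan. On real data
a failed or shifted segmentation surfaces as a segmentation error or an
authentication alert, never as silently wrong patient data.

## Numerical and design choices

* MSE is accumulated in exact 64-bit integer arithmetic before the single
  division; RGB comparisons average over all m*n*3 samples.
* PSNR uses MAX_I = 255 and is infinite iff MSE = 0; serialized as the
  string `"inf"` in JSON.
* Problem sizes in tests and the acceptance script (200 roundtrips for
  indexing accuracy, 100 phantoms x 100 wrong keys for protection, 30
  seeds for degradation ordering) are the package's study conditions,
  chosen to make the binary claims (100% rates, infinite PSNRs) exact
  and the ordering claims statistically unambiguous.
* The receiver recomputes the RoniMap from the received image rather
  than trusting a transmitted map; this is why LSB-invariant
  segmentation is load-bearing. The flip side is a known limitation:
  impulse noise that attaches to a lobe and stretches its bounding box
  by even one column shifts the band and destroys header alignment —
  observed as authentication alerts under salt-and-pepper in the
  evaluation, and scored as logo loss.
* Keys are accepted as 16 hex characters on the CLI; the encrypted
  secret key is never transmitted in-band — both ends derive it from the
  (user key, scan number, image number) triple they hold.
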