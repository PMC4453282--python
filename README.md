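# sili — secured, authenticated indexing of lung CT images

`sili` lets a sender transmit an 8-bit lung CT slice that *carries its own
metadata*: the patient-information text is hidden inside the scan (so the
image indexes itself) and a keyed RGB logo watermark authenticates the
sender. Both payloads live exclusively in the **region of non-interest
(RONI)** — the tissue band between the lung lobes and the area surrounding
them — so the diagnostically relevant lung fields are bit-identical before
and after embedding. It is aimed at medical-imaging researchers studying
spatial-domain watermarking and at anyone who needs a reproducible,
fully-tested reference for RONI-based LSB embedding.

## How it works

1. **Segmentation.** Lung fields are dark on CT. Otsu's threshold on
   LSB-zeroed intensities (`v & 0xFE`) separates air from tissue;
   8-connected components touching the image border (the outside-body
   background) are removed; the two largest remaining components are the
   lobes (the ROI). The band between the lobes' bounding boxes is reserved
   for the logo, and every other non-lobe pixel for the index. Because
   thresholding ignores bit 0, the receiver re-derives the *identical*
   pixel map from the watermarked image — no side channel is needed.

2. **Key handling.** The sender's scan number and image number are packed
   into one 64-bit block and encrypted with single-block DES under an
   8-byte user key, yielding the *encrypted secret key*. A DES-OFB chain
   seeded by that ciphertext produces the keystream that protects the logo.

3. **Indexing.** Each record character is written as 8 bits (MSB first)
   into bit 0 of the surround pixels in column-major order, terminated by
   a NUL *cap character*. Capacity rule: `size_host >= (n_chars + 1) * 8`.

4. **Logo watermarking.** A 32-bit header (magic `0x5A3C`, logo rows,
   logo cols) plus the logo bytes are XOR-ed with the keystream and written
   into the inter-lobe band LSBs. Capacity rule:
   `size_host >= n_pixels * 3 * 8 + 32`. Extraction under any other key
   decrypts the header into garbage, the magic check fails, and the
   receiver stops with an authentication alert — no payload is emitted.

5. **Evaluation.** Quality is scored with
   `MSE = (1/mn) * sum (X_ij - Y_ij)^2` and
   `PSNR = 20*log10(255) - 10*log10(MSE)` (infinite for identical images),
   under an attack grid of salt-and-pepper noise, contrast reduction, and
   motion blur.

## Worked example

```python
import numpy as np
from sili import KeyMaterial, run_sender, run_receiver, psnr
from sili.phantom import PhantomSpec, generate_phantom_ct, generate_logo

ph = generate_phantom_ct(PhantomSpec(seed=7))        # 256x256 synthetic slice
logo = generate_logo(16, 16, seed=3)                 # sender's RGB logo
keys = KeyMaterial.from_hex("A1B2C3D4E5F60718", scan_number=5, image_number=12)

sent = run_sender(ph.image, logo, "PATIENT:0042;AGE:57", keys)
print(sent.roni.size_host_logo)                      # 7488  band bits >= 6176 needed
print(sent.report["host_vs_watermarked"]["psnr"])    # 61.33 dB imperceptibility

got = run_receiver(sent.watermarked, keys)
print(got.authenticated, got.record)                 # True PATIENT:0042;AGE:57
print(np.array_equal(got.logo, logo), psnr(logo, got.logo))  # True inf
```

The inter-lobe band offers 7488 embeddable bits, comfortably above the
6176 required by a 16x16 RGB logo; double embedding changes the host by
an MSE of only 0.048 (61.33 dB PSNR), and the clean channel returns both
payloads bit-exactly (infinite logo PSNR). A wrong key — a different user
key, scan number, or image number — makes `got.authenticated` come back
`False` with no record or logo.

The same flow is available from the shell:

```bash
sili phantom --seed 7 --out-ct ct.png --out-logo logo.png --out-record patient.txt
sili embed --ct ct.png --logo logo.png --record patient.txt \
     --key A1B2C3D4E5F60718 --scan 5 --image 12 --out wm.png --report sender.json
sili extract --in wm.png --key A1B2C3D4E5F60718 --scan 5 --image 12 \
     --out-logo logo_out.png --out-record patient_out.txt
sili evaluate-attacks --seed 7        # PSNR grid over the standard attacks
```

`sili extract` exits with code 2 on an authentication alert and 3 when
segmentation fails.

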