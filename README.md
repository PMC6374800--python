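# urseg

Automatic segmentation of the two forearm long bones (ulna and radius) in
grayscale radiographs, built around 1-D dynamic-programming minimum-cost
path tracing.

The pipeline:

1. **Preprocess** — crop the invalid/collimated borders from the intensity
   projections, downsample (bilinear, default ratio 0.7), rotate the forearm
   to run left-to-right with the wrist at the right, extract and clean the
   forearm mask (background set to exactly 0), bilateral-filter and
   histogram-equalize over the mask.
2. **Seeds** — locate the distal-end column `x0` at the deepest interior
   minimum of the forearm-mask vertical projection (left of its maximum),
   then find four seed points on the bone-shaft edges as the four most
   prominent peaks of a mid-shaft vertical gradient profile, validated as
   two bright-interior bone pairs.
3. **Cost maps** — a vertical map `I1 = l1*f_Gy + (1-l1)*f_c` and a
   horizontal map `I2 = l2*f_Gx + (1-l2)*f_c`, where `f_G` is the scaled
   inverted Sobel gradient magnitude and `f_c` the inverted binary Canny
   edge mask (defaults `l1 = 0.3`, `l2 = 0.7`).
4. **Tracing** — 3-connected minimum-cost paths via the seam recurrence,
   traced in chained windows along the shaft (both directions from each
   seed), plus an endpoint-anchored top-to-bottom wrist-joint trace
   restricted to the `x0 ± n/10` column band; the six paths are merged into
   two closed contours and mapped back to original-image coordinates.
5. **Metrics** — DSC / sensitivity / false-positive rate from pixel
   confusion counts, and symmetric mean absolute (MAD) and signed (MSD)
   boundary distances, reported for the whole image and for
   proximal/middle/distal thirds of the ground-truth extent.

A synthetic phantom generator (`urseg.phantom`) renders radiograph-like
forearms (tapered bone bands, wrist neck and hand blob, smooth background
nonuniformity, texture, noise, four orientations, normal/low exposure) with
exact ground-truth masks and contours, so the full pipeline is testable
without clinical data.

## Tests

```sh
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance criteria (DP optimality vs
exhaustive enumeration, metric formula checks, phantom parameter recovery,
exposure robustness, downsample stability, determinism/geometry).

## CLI

```sh
# segment one radiograph (8/16-bit grayscale PNG or TIFF)
urseg run --input IMG.png --out OUT_DIR [--ratio 0.7] [--lambda1 0.3] \
          [--lambda2 0.7] [--window 64] [--save-intermediate]

# evaluate a predicted mask against ground truth (0/255 PNGs)
urseg eval --gt GT.png --pred PRED.png --report report.json

# generate a phantom suite with ground truth
urseg phantom --n 20 --seed 1 --out PHANTOM_DIR
```

`urseg run` writes `contours.json`, per-bone vertex CSVs, 0/255 mask PNGs
at the original resolution and an `overlay.png`; exit code 3 means seed
detection failed, 4 any other pipeline failure.

## Library use

```python
from urseg import PhantomParams, generate_phantom, segment_image, regional_report

truth = generate_phantom(PhantomParams(seed=1))
contours = segment_image(truth.image)      # URContours: polygons + masks
report = regional_report(
    truth.bone_masks[0] | truth.bone_masks[1],
    contours.masks[0] | contours.masks[1],
    truth.bone_contours,
    [contours.bone1, contours.bone2],
)
```
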