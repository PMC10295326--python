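# trabeculagen

Clinical multidetector CT (MDCT) resolves vertebral bone at roughly
0.2–0.5 mm — coarser than a single trabecula — so the microstructural
metrics that predict fragility fractures (bone volume fraction BV/TV,
trabecular thickness Tb.Th, trabecular separation Tb.Sp) cannot be measured
from it directly, while micro-CT, which can measure them, is ex-vivo only.
`trabeculagen` implements, end to end and on synthetic ground truth, the
pipeline that bridges the two: generate micro-CT-like images from
MDCT-resolution input with an unpaired image-to-image translation GAN, and
measure bone structure metrics on the result. It is aimed at researchers in
bone image analysis who want a fully checkable, desk-scale testbed for this
procedure — every stage is exercised on 3-D phantoms whose BV/TV is exact
by construction.

The package provides:

* **phantom** — synthetic vertebrae: thresholded Gaussian-random-field
  trabecular microstructure with exact BV/TV and calibrated Tb.Th inside an
  elliptical body with cortical shell and posterior canal; rendered both as
  isotropic 52 µm micro-CT-like stacks and as blurred, noisy ~0.2 mm MDCT-like
  stacks with half the slice count.
* **morphometry** — IsoData (intermeans) global thresholding, cylindrical
  VOIs (standard 15 mm × 5 mm), BV/TV by voxel counting, and model-free
  Tb.Th/Tb.Sp by the largest-inscribed-sphere local thickness
  (distance transform + distance ridge + sphere painting, exact against a
  brute-force oracle).
* **pairing** — slice correspondence between MDCT and micro-CT stacks via
  SIFT keypoint distances and dynamic time warping, with 2:1 MDCT slice
  replication (250 MDCT × 2 → 500 pairs per specimen).
* **translate** — the translation model: content encoder, class encoder and
  AdaIN-conditioned decoder, patch discriminator, adversarial +
  reconstruction + feature-matching objective

      min_G max_D  L_GAN(D, G) + λ_R L_R(G) + λ_F L_F(G)

  trained on unpaired slices of the two classes; pure NumPy with its own
  reverse-mode autodiff (no GPU required).
* **evaluate** — SSIM, FID (seed-frozen random convolutional embedding,
  pluggable), and the statistics battery (Friedman, Mann–Whitney U, paired
  t, K–S, Levene, OLS with R²/F, Fisher-z correlation comparison, ICC(2,1)).
* **cli / pipeline** — `trabeculagen simulate|pair|train|translate|measure|evaluate|run`
  with one YAML config, a run manifest and checksum-gated stage re-runs.

See `docs/methods.md` for the models, defaults and their rationale, and for
what phantom results do and do not establish about real scans.

## Worked example

```python
from trabeculagen.phantom import (PhantomSpec, generate_trabecular_volume,
                                  render_micro_ct, render_mdct)
from trabeculagen.morphometry import CylindricalVOI, measure_stack
from trabeculagen.pairing import pair_stacks

spec = PhantomSpec(                      # a small 10 mm vertebra
    extent_mm=(1.56, 10.0, 10.0), body_semiaxes_mm=(4.4, 4.6),
    canal_radius_mm=1.2, gt_region_mm=(1.2, 4.0, 4.0), seed=11,
)
gt = generate_trabecular_volume(spec)
print(f"ground truth: BV/TV={gt.bvtv_true:.4f}  "
      f"Tb.Th={gt.tbth_true_mm:.4f} mm  Tb.Sp={gt.tbsp_true_mm:.4f} mm")

micro = render_micro_ct(gt)
mdct = render_mdct(gt)
ext = micro.extent_mm
voi = CylindricalVOI(center=(ext[0]/2, ext[1]/2, ext[2]/2),
                     diameter_mm=5.0, height_mm=1.2)
res = measure_stack(micro, voi)
print(f"measured:     BV/TV={res.bvtv:.4f}  Tb.Th={res.tbth_mm:.4f} mm  "
      f"Tb.Sp={res.tbsp_mm:.4f} mm  (IsoData threshold {res.threshold_used:.1f})")

pairing = pair_stacks(mdct, micro)
ok = sum(abs(i - j//2) <= 1 for i, j in pairing.pairs) / len(pairing.pairs)
print(f"pairing: {len(pairing.pairs)} pairs; "
      f"{100*ok:.0f}% within one slice of construction truth")
```

prints

```
ground truth: BV/TV=0.1800  Tb.Th=0.1914 mm  Tb.Sp=0.5242 mm
measured:     BV/TV=0.1629  Tb.Th=0.1937 mm  Tb.Sp=0.5317 mm  (IsoData threshold 118.2)
pairing: 30 pairs; 97% within one slice of construction truth
```

The ground-truth BV/TV hits the 0.18 target exactly (the threshold is an
order statistic); the measured value on the *noisy* rendering is biased
slightly low by noise voxels flipping across the IsoData threshold in this
small 5 mm demonstration VOI — on noise-free renderings with the full
15 mm × 5 mm VOI the recovery error is below 0.01 (see the acceptance
script). Tb.Th is recovered to ~1%. The pairing stage, given stacks whose
true correspondence is micro slice 2i ↔ MDCT slice i by construction,
recovers 97% of pairs to within one slice.

A full study (simulate → pair → train → translate → measure → evaluate)
runs from one config:

```bash
trabeculagen run --config configs/example.yaml --seed 0
```

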