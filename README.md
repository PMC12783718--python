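# cryptomorph

Explainable computer vision for **cryptic morphological divergence**:
detecting and quantifying shape differences between genetically defined
groups ("clades") of a species that no human observer has described.

The motivating setting is limpet shells photographed under standardized
conditions, where mitochondrial or genomic data split a species into a
Northern and a Southern clade with no reported external differences. The
package implements the full analysis loop for such data and, because the
original photograph collections are not required, ships a synthetic
shell-image generator with *planted* clade effects of known magnitude so
every stage can be validated against ground truth:

1. **Resampling classification** — a small, fully deterministic NumPy CNN
   is trained to predict clade from the image under a seeded repeated
   protocol (per class: 120 train / 30 validation at full scale, Even-test
   and Full-test held-out sets, a 100-specimen cap per collection location,
   rotation/flip/scale augmentation of train/val batches only), and scored
   by macro-F1 = mean over classes of 2·P·R/(P+R).
2. **Mixed-group control** — the same experiment re-run with the two class
   labels replaced by synthetic classes containing equal numbers of
   true-Northern and true-Southern specimens. Any genuine clade signal is
   destroyed by construction, so test F1 must fall to ~0.5; a gap between
   clade-based and mixed-group F1 is evidence the classifier uses real
   clade-specific features rather than batch artefacts.
3. **SmoothGrad saliency** — per-pixel attribution of the class score,
   averaged over noise-perturbed copies of the input, quantified as
   attention *enrichment* of a ground-truth region (saliency mass fraction
   ÷ area fraction).
4. **Shape morphometrics** — sub-pixel contours from binary masks,
   normalized to major-axis length 1.0, described by circularity
   (4πA/P²), eccentricity (√(a²−b²)/a), solidity (A/hull), extent
   (A/bounding box) and minor-axis length (b/a), compared between clades
   with Mann–Whitney U tests.
5. **Karcher-mean shapes** — per-clade average outlines via iterative
   rigid alignment and point-wise averaging, with six landmarks at
   25/50/75% of maximum height on both margins, yielding the clade
   contrasts: percent minor-axis narrowing and the mean
   quartile-width/central-width ratio.

See `docs/methods.md` for the models, assumptions and numerical choices.

## Worked example

```python
import numpy as np
from cryptomorph import (GeneratorConfig, ImageDataset, generate_dataset,
                         desk_scale_protocol, desk_scale_model_config,
                         run_iterations, extract_contour, normalize_outline,
                         karcher_mean, clade_contrast)

# 400 synthetic keyhole-limpet shells, two clades, planted contrasts:
# Northern keyhole 12% narrower and centrally pinched (ratio 1.425)
cfg = GeneratorConfig.preset("keyhole_like", n_per_clade=200, seed=42)
records = generate_dataset(cfg, "data")
ds = ImageDataset(records, "data")

# clade-based vs mixed-group classification, 20 seeded iterations
proto = desk_scale_protocol(base_seed=100, n_iterations=20)
model_cfg = desk_scale_model_config(seed=0)
clade = run_iterations(ds, proto, model_cfg, mixed=False)
mixed = run_iterations(ds, proto, model_cfg, mixed=True)
print(np.median(clade.macro_f1_values("even")),
      np.median(mixed.macro_f1_values("even")))
# 0.96249...  0.44958...   <- clade models learn, the control sits at chance

# Karcher-mean keyhole comparison
outlines = {"Northern": [], "Southern": []}
for rec in records:
    mask = ds.mask(rec.specimen_id, "keyhole")
    outlines[rec.clade].append(normalize_outline(extract_contour(mask)))
contrast = clade_contrast(karcher_mean(outlines["Northern"]),
                          karcher_mean(outlines["Southern"]))
print(contrast.quartile_over_central_ratio_N,
      contrast.quartile_over_central_ratio_S)
# 1.4252...  0.8778...    <- planted Northern ratio 1.425 recovered;
#                            an un-pinched ellipse gives sqrt(3)/2 = 0.866
```

The first pair of numbers is the headline control experiment: the
clade-based median Even-test macro-F1 is far above the mixed-group
control's, which sits at the two-class chance level. The second pair shows
the mean-shape analysis recovering the planted Northern keyhole pinch
(quartile widths 42.5% greater than the central width) while the Southern
mean stays an ellipse.

A command-line interface wraps each stage
(`cryptomorph generate|split|train-eval|saliency|shapes|karcher|report`)
and `cryptomorph pipeline --out runs/demo` executes the whole loop at desk
scale.

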