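# peroxiquant

Quantitative image analysis of protein distributions around peroxisomes in
multicolor STED/confocal fluorescence microscopy.

Peroxisomes are small organelles (≈130–650 nm across) whose import machinery
(PEX5, PEX14, PEX11β) organizes into sub-diffraction membrane domains. With a
confocal matrix-marker channel (e.g. GFP–SCP2) identifying actively importing
peroxisomes and one or two STED channels (<60 nm lateral FWHM, 20 nm pixels)
resolving immunostained membrane proteins, this package quantifies, per
organelle region:

- **Detection** — peroxisomes as maxima of the Gaussian-smoothed (σ = 2.0)
  matrix channel under ImageJ Find-Maxima prominence semantics (noise
  tolerance 10): a candidate of value *v* is accepted unless a higher pixel is
  reachable along a path staying above *v* − tolerance. A 19-px (380 nm)
  circular region is placed on each maximum, with a matched random control
  region translated ≤180 px away from any matrix signal.
- **Registration** — inter-acquisition drift by exhaustive ±18 px product
  search and confocal↔STED chromatic shift from bead-field centroids.
- **Intensity statistics** — per-cell Pearson correlation of region-integrated
  intensities (gᵢ, rᵢ); normalized intensity histograms (25 bins on [0,1],
  each cell scaled by its maximum peroxisomal integral); Gaussian peak fits;
  FWHM of line profiles; one-way ANOVA with Tukey HSD across conditions.
- **Morphology** — Kapur maximum-entropy ("MaxEntropy") thresholding of each
  region, despeckle + erode, then per-cluster (perimeter, area) against the
  circular reference (πd, πd²/4): round clusters sit near the curve, rings
  and fragments above it.
- **Colocalization** — pixel-wise Pearson r over the disc pixels of two STED
  channels, with two nulls: a *flip* control (one channel mirrored about the
  vertical axis through the region center, calibrating coincidental
  correlation from dense packing) and the *random* regions.
- **Compartmentalization** — per channel, patch maxima (σ = 1.0 smoothing,
  3×3 maximum filter, retain ≥50% of the patch maximum); the mean
  nearest-maxima distance between channels, paired with the region's Pearson
  value. Segregated domains give large distances and low correlation.

Since no raw microscopy data accompany the source study, a first-class
synthetic scene generator (`peroxiquant.scene`) renders ground-truthed
multichannel images — filled matrix discs, dot/ring/ellipse membrane staining
with Gaussian angular domains at a controllable inter-channel offset,
confocal/STED Gaussian PSFs, Poisson noise, and an optional filament channel
mimicking mitochondrial TOM20 — so every stage is validated against known
truth.

## Worked example

```python
import numpy as np
from peroxiquant import (SceneSpec, generate_scene, find_maxima, make_regions,
                         coloc_histograms, compartmentalization_table)

spec = SceneSpec(image_size_px=(512, 512), n_organelles=30,
                 diameter_range_nm=(200, 340), morphology_mix={"ring": 1.0},
                 domain_offset_deg=0.0, seed=41, min_separation_nm=1100)
stack, truth = generate_scene(spec)

maxima = find_maxima(stack.channels[0], sigma=2.0, noise_tolerance=10)
regions = make_regions(maxima, stack.shape, diameter_px=19)
res = coloc_histograms(stack, regions, ch1=1, ch2=2)
print({k: round(v, 3) for k, v in res.medians.items()})
```

With congruent domains (offset 0°) this prints

```
{'real': 0.987, 'flip': 0.025, 'random': nan}
```

— the two protein channels correlate almost perfectly within peroxisomal
regions, while mirroring one channel destroys the correlation (the flip
median ≈ 0 shows the signal is congruent structure, not dense packing). The
same scene at 90° domain offset gives a real median of ≈0.02: spatially
segregated domains are read as uncorrelated. The numbered scripts under
`analysis/` run these studies end to end; `analysis/06_compartmentalization.py`
sweeps the domain offset 0→180° and reports a pooled Spearman
ρ(distance, Pearson) of −0.92 over 250 regions — the anticorrelation between
compartmentalization and colocalization the pipeline is built to expose.

A full run over a scene or a TIFF directory, with CSV/figure outputs and a
JSON report, is one command:

```bash
peroxiquant run --config run.yaml
```

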