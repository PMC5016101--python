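# Methods

## The measurement model

All quantities are computed within fixed circular regions (diameter 19 px =
380 nm at the 20 nm pixel size; 293 pixels by enumeration of pixel centers
within d/2 of the center) anchored on detected peroxisomes. Anchoring on
maxima of the *confocal* matrix-marker channel, not the STED protein
channels, means region placement is independent of the protein staining
under study; the matched random regions (uniform translation ≤180 px,
resampled while touching any peroxisomal disc or any matrix signal) give a
paired null with identical pixel counts, which is why border-crossing
regions are dropped rather than clipped.

### Detection

Find-Maxima prominence semantics on the σ = 2.0 smoothed channel: a
candidate local maximum (8-neighborhood; equal-valued plateaus collapse to
their rounded centroid) of value *v* is rejected iff a strictly higher pixel
is 8-connected to it through pixels above *v* − tolerance. Smoothing uses
reflective boundaries so adding a constant to the image provably leaves the
accepted set unchanged (the tolerance acts on differences only). A constant
image has no maxima. Two exact short-circuits (the global maximum is always
accepted; a candidate whose tolerance floor undercuts the image minimum can
reach every pixel and is rejected whenever anything higher exists) eliminate
the per-candidate connected-component analysis for the thousands of weak
background maxima a Poisson background produces, without changing the
accepted set.

The exclusion mask for random regions — pixels whose σ = 2.0 smoothed value
exceeds the background median plus the noise tolerance — reuses the
detection scale; the source procedure names no explicit threshold, so this
is a package choice.

### Registration

Drift between repeated matrix-channel acquisitions is found by exhaustive
integer search over ±18 px, scoring each offset by the pixelwise product
over the overlap. The *unnormalized* product sum is the default: for a
zero-filled translated copy it is exactly maximized at the true shift
(Cauchy–Schwarz), whereas dividing by the overlap pixel count biases the
argmax outward whenever image borders are darker than the interior —
shrinking the overlap by one row raises the mean faster than a 1-px
misalignment lowers the product. `normalize=True` restores the mean-score
variant; `literal_minimum=True` selects the minimum instead of the maximum,
preserving the printed form of the source procedure even though only the
maximum registers nonnegative images. Ties break toward the smallest offset
magnitude. The chromatic confocal↔STED offset is the mean displacement of
mutually nearest (≤10 px) background-subtracted intensity-weighted bead
centroids, requiring ≥3 matches; drift is corrected by integer zero-fill
translation, chromatic shift by bilinear interpolation.

### Intensity, morphology, colocalization, compartmentalization

*Intensity*: region integrals (gᵢ, rᵢ) per cell; Pearson correlation
(error on zero variance); histograms on 25 fixed bins over [0,1] after
dividing by the cell's maximum *peroxisomal* integral — reused for that
cell's random regions, whose rare values >1 are kept in the top bin and
counted. Pooling adds raw counts. The Gaussian summary of a histogram is an
unweighted least-squares fit to bin centers (≥5 nonzero bins required).
Line-profile FWHM uses bilinear sampling at 1-px steps, baseline = profile
minimum, and linear interpolation of the half-level crossings.

*Morphology*: Kapur–Sahoo–Wong maximum-entropy threshold on a 256-bin
histogram of the patch rescaled to [0,255], maximizing the summed Shannon
entropies of the two partitions; exact ties (empty boundary bins make
adjacent cuts identical partitions) resolve to the lowest bin within 1e−10
of the maximum. The binary mask is despeckled (3×3 median) and eroded one
iteration (ImageJ erode(count) convention, count = 1 ⇒ full 3×3 erosion;
note the median step also trims convex corners). Clusters are 8-connected;
area is the pixel count and perimeter the count of cluster pixels with a
4-neighbor outside. Against the circular reference (πd, πd²/4) the
boundary-pixel perimeter of a rasterized disc sits systematically ~10–19%
below πd (it is not asymptotically πd-consistent); the measured
(perimeter, area) *pair* stays within 15% of the reference point and the
qualitative reading — rings and fragments far above the curve, discs near
it — is unaffected.

*Colocalization*: Pearson over disc pixels only (corner pixels of the
bounding square belong to neighboring space). The flip control mirrors one
channel's patch about the vertical axis through the region center; the disc
support is mirror-symmetric, so the statistic stays defined on the same
pixel set and flipping twice is the identity. Zero-variance patches yield
NaN and are excluded from histograms (40 bins on [−1,1]) with logged counts
rather than scored 0 — an undefined statistic should not shift histogram
mass.

*Compartmentalization*: per channel, the patch is smoothed at σ = 1.0, local
maxima are pixels equal to their 3×3 maximum filter, and only maxima at
≥50% of the patch's (disc-restricted) global maximum are retained — a
relative rule, so the result is invariant to positive rescaling. Flat
patches (all zero, or peak-to-peak <1e−9 of the maximum) are excluded. The
region's distance is the mean of *both* directed nearest-neighbor distance
sets between the two maxima lists (the source text does not fix the
direction; the symmetric mean is used and documented), paired with the
region's real-variant Pearson value.

## The synthetic scenes

The generator emulates the study's imaging conditions: 20 nm pixels,
organelle diameters uniform on 130–650 nm, a confocal matrix channel
(250 nm FWHM PSF) of filled discs, STED protein channels (60 nm FWHM), and
Poisson noise over a uniform background (0.1 counts/px by default; the
study reports no background or labeling-density statistics, so photon
budgets — 2×10⁴ matrix, 10⁴ protein counts per organelle — are package
choices sized to give the strong signal-to-background of the study's
images). Channel means are normalized so a noiseless channel's total is
exactly photon_budget × n_organelles. A non-finite photon budget renders
the noiseless mean itself.

Morphology classes fix the protein pattern: `dot` renders the protein as a
filled disc (a sub-resolution organelle whose staining the PSF dominates —
both protein channels identical, and the rendered spot is literally
disc ⊗ Gaussian, which the FWHM tests exploit); `ring` and `ellipse` render
a 2-px (40 nm) rim — membrane thickness is sub-resolution, so appearance is
PSF-dominated — weighted by Gaussian angular domains over a 5% uniform
floor. Channel B's domain angles are channel A's plus the configured offset,
so the true rim separation is radius × offset in radians. The angular
domain width defaults to σ = 80 nm of arc: the study's reported cluster
perimeters (≈265–530 nm) imply protein domains extending hundreds of nm
along the rim, and narrower domains would make region Pearson saturate near
zero beyond ~90° offset (patterns stop overlapping at the PSF scale) rather
than decline across the full angular range. Organelle centers are
rejection-sampled with a minimum spacing (default 900 nm) so scenes are
resolvable; coordinates are 0-based (row, col) and angles counterclockwise
from the +col axis. The optional filament channel is a persistent random
walk, independent of all organelles.

What the scenes do *not* model: vectorial/realistic STED PSFs, detector
read noise (photon-counting APD detection), antibody-linkage displacement,
3-D structure, tubulated peroxisomes, or spatially varying background.
Passing tests therefore validate the *estimators* — detection semantics,
registration exactness, the statistics and their controls — on data whose
ground truth is known, not the biological values of the original study:
the printed per-protein correlation coefficients, histogram peaks, cluster
sizes and colocalization medians are properties of microscopy data that
were never deposited, and this package does not attempt to reproduce them.

## Numerical choices and problem sizes

Degenerate inputs are errors or flagged exclusions, never silent zeros:
constant images (registration, thresholding), zero-variance patches
(Pearson), empty maxima sets (distance records). Detection ties: plateau
centroids round half-to-even; drift ties prefer the smallest offset. The
test suite and the acceptance script size their simulations for a
single-CPU desk run — 24×24 oracle images, a 112×112 noiseless scene for
the full ±18 px drift sweep, 640×640 scenes of 50 ring organelles per
offset for the compartmentalization sweep, and 832×832 scenes of 100
organelles for intensity-recovery — sizes at which every check completes in
seconds to a few minutes while keeping ≥45 valid regions per condition.

One statistical note: a Pearson estimate from 100 regions at ρ ≈ 0.71
carries sampling error (1−ρ²)/√n ≈ 0.05, so intensity-correlation recovery
is asserted on the mean over 10 seeds (SE ≈ 0.016) with a 3σ bound per
seed.

## Known limitations

- Drift is integer-valued by design (the search window is a pixel grid);
  subpixel drift aliases to its nearest integer.
- The boundary-pixel perimeter underestimates true contour length by a
  direction-dependent factor; comparisons are meaningful against the πd
  curve as a reference shape, not as absolute contour lengths.
- `estimate_chromatic_shift` assumes an approximately uniform translation;
  field-dependent chromatic distortion is out of scope.
- The flip control acts on the disc patch (not its bounding square); for
  patterns symmetric about the region's vertical axis it equals the real
  value by construction.
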