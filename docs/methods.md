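# Methods

## Overview

`morindex` measures how strongly CD3⁺ immune cells colocalize with tumor
cells in IHC-stained colorectal tissue. The analysis chain is: segment
tumor-epithelial texture, detect and classify individual nuclei, bin the
classified nuclei over a square tessellation of the tumor region, and
summarize the two spatial distributions with the Morisita–Horn index. All
stages are classical and deterministic given a configuration; the only
random element is the k-means initialization, controlled by a seed.

## Epithelium segmentation

Tumor epithelium is assumed to be the texture-rich tissue class. The
grayscale patch (luminance 0.299 R + 0.587 G + 0.114 B) is filtered with a
Gabor bank of wavelength 2 px and orientations 30°, 60°, …, 180° — one
complex quadrature pair per orientation, one-octave bandwidth. Filter
magnitudes are Gaussian-smoothed with σ = 3 × wavelength (tying the
averaging scale to the filter scale), standardized per plane, and
augmented with standardized row/column coordinate planes (unit feature
weight). A 2-cluster k-means (k-means++, fixed seed, at most 5 iterations)
partitions the pixels; the cluster with the higher mean smoothed Gabor
energy is declared epithelium, on the rationale that epithelium is the
texture-rich class. The mask is refined by closing (disk radius 5 px),
hole filling and removal of components below 500 px; all three are
configurable.

Two numerical choices make the stage exactly invariant to adding a
constant to the input image: kernels are made strictly zero-mean, and the
image's DC component is subtracted before convolution (otherwise the
zero-padded convolution borders would leak the offset). Degenerate inputs
(a perfectly constant feature stack) raise an explicit error rather than
returning an arbitrary bisection.

## Stain model and nucleus classification

Pixels are unmixed by Beer–Lambert color deconvolution with the published
H-DAB absorption vectors (hematoxylin ≈ (0.65, 0.70, 0.29), DAB ≈
(0.27, 0.57, 0.78) in RGB optical density, third vector their cross
product). Optical densities are clipped to [0, 3]; saturated black pixels
therefore hit the cap in both channels rather than producing infinities.

Immune positivity is detected on the DAB channel, mapped to 8 bits over a
fixed reference range of 0–2 OD so the contrast gate means the same thing
in every patch. The Bernsen rule is applied per pixel over a centered
77 × 77 window with reflective padding: if the local max − min contrast is
below 15 the pixel is background (low-contrast regions are non-immune);
otherwise the pixel is foreground iff it exceeds the local mid-range
(max + min)/2.

Nucleus instances come from a marker-controlled watershed: Otsu threshold
on the combined (hematoxylin + DAB) density defines foreground, the
smoothed Euclidean distance transform provides the topography, local
maxima at least 7 px apart seed the flood, and instances under 40 px are
discarded (defaults sized for 40× magnification, ~0.25 µm/px). The
watershed stands in for nucleus-splitting software whose internals are not
otherwise specified; it is a standard, well-understood choice.

Classification priority is strict: a nucleus with ≥ 50% of its pixels in
the Bernsen mask is immune, regardless of location; otherwise it is tumor
if its centroid lies in the epithelium mask, else stroma. The three
classes always partition the instances.

## Tessellation and the Morisita–Horn index

The tumor region (an externally supplied binary mask, or the whole study
extent when absent) is divided into h × h px cells, h = 1024 by default,
anchored at the mask's bounding-box origin with half-open intervals
[start, start + h). Each nucleus belongs to exactly one cell by centroid.
A cell's area d_i is its count of tumor-mask-true pixels, so partially
covered edge cells are judged by their actual tissue area; cells with no
tumor tissue are dropped. The low-density exclusion removes cells with
n_i / d_i ≤ 0.0002 (inclusive boundary, exactly as the rule is stated),
where n_i counts all nuclei including stroma.

Over the included cells, proportions p_i^l = n_i^l / Σ n_i^l (immune) and
p_i^c = n_i^c / Σ n_i^c (tumor) feed

    Mor = 2 Σ p_i^l p_i^c / (Σ (p_i^l)² + Σ (p_i^c)²).

The index is 0 iff the supports are disjoint and 1 iff the proportion
vectors are identical. When either population is absent after filtering
the index is reported as an explicit *undefined* flag, never as 0 — zero
has the distinct ecological meaning of full segregation, and conflating
the two would corrupt downstream survival groupings.

Patient stratification uses a quantile cutoff (default the median,
`numpy.quantile` linear interpolation) with "high" meaning strictly above
the cutoff. The quantile is configuration-exposed because published
cohort splits labelled "50%" do not always correspond to an exact median
split; ties all fall to "low" with a warning.

## Synthetic data

The fixtures module generates the two kinds of ground-truthed input the
tests rely on.

**Point patterns.** Per-polygon immune/tumor counts with a colocalization
parameter θ ∈ [0, 1]: shared per-polygon weights are drawn once from a
flat Dirichlet; each nucleus independently follows the shared weights with
probability θ and otherwise its class's disjoint placement (immune
uniform over the first half of the polygons, tumor over the second half).
θ = 0 therefore gives disjoint supports and an index of exactly 0; θ = 1
gives two multinomial draws from one distribution and a mean index above
0.95 at 500 points per type on a 4 × 4 grid. The per-point mixture makes
the expected index smooth and monotone in θ.

**Rendered patches.** Nuclei are elliptical stain deposits composed on a
white background through the same Beer–Lambert model and stain vectors the
deconvolution stage inverts — hematoxylin at 0.85 peak OD for tumor and
stroma nuclei, DAB at 0.9 for immune nuclei — with optional Gaussian
intensity noise. Epithelial neighborhoods (disks of 2.5 × the semi-major
axis around tumor nuclei) carry an oriented sinusoidal grating at the
Gabor bank's own wavelength (period 2 px, 0.4 OD amplitude). The grating
period was chosen in-band deliberately: an off-band grating cannot be
distinguished from the broad-band edge energy of isolated dark nuclei by
a 2-cluster split, and the planted region would not be separable — the
amplitude is likewise set so grating energy dominates nucleus-rim energy.
The default layout places tumor nuclei (and hence texture) in the left
part of the patch and immune/stroma nuclei in the right, with centers
rejection-sampled to a minimum spacing so nuclei never touch.

What the renderer deliberately does *not* model: nucleus chromatin
texture, stain variation between slides, overlapping/touching nucleus
clumps beyond simple draw-order occlusion, scanner artifacts, and the
nine-class tissue heterogeneity a real slide shows. Passing the synthetic
recovery tests therefore demonstrates the stages are implemented
correctly and wired together coherently — not that the pipeline reaches
any particular accuracy on clinical material.

## Evaluation metrics

Pixel-level one-vs-rest confusion counts per class give Accuracy
(TP+TN)/total, Dice 2TP/(2TP+FP+FN), and MIoU — the mean over all k+1
categories (background included) of TP/(TP+FP+FN). A class absent from
both rasters is excluded from MIoU with a warning by default (optionally
scored 1). Dice of a class empty in both rasters is undefined and
reported as such. An auxiliary greedy instance matcher (IoU ≥ 0.5,
highest first, one-to-one) supports the synthetic recovery tests; it is
not one of the pixel metrics.

## Problem sizes used in tests

Synthetic recovery runs use 256 × 256 px patches with 50 nuclei
(20 tumor, 20 immune, 10 stroma) over 10 seeds at noise levels 0 and 3
(8-bit intensity units); point-pattern statistics use 4 × 4 grids with
500 nuclei per type over 100 seeds; Bernsen equivalence uses 1,000 random
images up to 64 × 64 plus 77-px-window checks on 100 × 100 images. These
sizes exercise every code path at full parameter realism (the Bernsen
window, grid geometry and density threshold are the production values)
while keeping the whole suite fast.

## Known limitations

- The epithelium stage assumes epithelium is the *most* textured class; on
  tissues where stroma is equally textured the energy-based cluster
  selection can flip.
- The watershed splits touching nuclei only when their distance-transform
  peaks are at least `min_sep_px` apart; dense clumps under-segment.
- `d_i` for edge polygons is the clipped tissue area, which interacts with
  the density threshold: a mostly-glass edge cell needs proportionally
  fewer nuclei to be retained than a full cell.
- The Bernsen 8-bit mapping fixes the 0–2 OD range; grossly over-stained
  material saturating beyond 2 OD compresses contrast.
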