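# morindex

Quantifying tumor–immune spatial colocalization in IHC-stained colorectal
tissue with the Morisita–Horn index.

## What this package does

In CD3-stained immunohistochemistry (IHC) slides, the *spatial arrangement*
of immune cells relative to tumor cells — not just their density — carries
prognostic information: patients whose T cells intermingle with tumor cells
tend to fare better than patients whose immune cells sit segregated at the
tumor margin. `morindex` turns raw RGB image patches (nominally 1024×1024 px
at 40×, ~0.25 µm/px) into a single per-patient colocalization score using
classical, fully reproducible computer-vision stages:

1. **Epithelium segmentation** — a Gabor filter bank (wavelength 2 px,
   orientations 30°–180° in 30° steps), Gaussian-smoothed magnitude
   features plus spatial coordinates, 2-cluster k-means (≤ 5 iterations),
   and morphological refinement isolate the texture-rich tumor-epithelial
   regions.
2. **Nucleus segmentation & classification** — H-DAB color deconvolution
   splits hematoxylin (blue, all nuclei) from DAB (brown, CD3⁺ immune
   cells); the Bernsen local threshold (77-px window, contrast gate 15) on
   the DAB channel marks immune-positive staining; a marker-controlled
   watershed on the combined stain density segments individual nuclei,
   which are then classified **immune** (≥ half their pixels
   DAB-positive), else **tumor** (centroid in epithelium), else **stroma**.
3. **Spatial statistics** — the tumor region is tessellated into h×h
   (default 1024 px) square polygons; polygons with total nucleus density
   n_i/d_i ≤ 0.0002 are excluded; per-polygon immune and tumor counts are
   normalized into proportions p_i^l, p_i^c and combined into the
   Morisita–Horn index

   Mor = 2 Σᵢ p_i^l p_i^c / (Σᵢ (p_i^l)² + Σᵢ (p_i^c)²)

   which is 0 when the two populations never share a polygon (segregation)
   and 1 when their spatial distributions coincide (colocalization).
   A 50%-quantile cutoff stratifies patients into Mor-high / Mor-low
   groups; survival columns pass through for downstream Kaplan–Meier/Cox
   tooling (e.g. `lifelines` or R `survival`).

The upstream deep-learning tissue classifier that delineates the tumor
region is treated as an input boundary: any binary tumor mask is accepted,
and without one the whole patch is analyzed.

It is aimed at computational-pathology researchers who want a transparent,
dependency-light baseline for tumor-microenvironment colocalization
analysis, plus a synthetic-data module for validating every stage against
known ground truth.

## Worked example

```python
from morindex import (PatternSpec, generate_point_pattern,
                      morisita_horn_from_counts)

for theta in (0.0, 0.5, 1.0):
    pattern = generate_point_pattern(PatternSpec((4, 4), 500, 500, theta, seed=1))
    res = morisita_horn_from_counts(pattern)
    print(f"colocalization {theta:.1f}: Mor-index = {res.value:.3f} "
          f"({res.n_polygons_included} polygons)")
```

```
colocalization 0.0: Mor-index = 0.000 (16 polygons)
colocalization 0.5: Mor-index = 0.720 (16 polygons)
colocalization 1.0: Mor-index = 0.983 (16 polygons)
```

At colocalization 0 the generator confines immune and tumor nuclei to
disjoint polygon subsets, so the index is exactly 0; at 1 both populations
sample the same spatial weights and the index approaches 1.

The full imaging pipeline on a rendered synthetic patch (tumor nuclei on
the left in textured epithelium, immune and stroma nuclei on the right):

```python
from morindex import (PatchEntry, PipelineConfig, random_nucleus_layout,
                      render_ihc_patch, run_pipeline)

layout = random_nucleus_layout(20, 20, 10, (256, 256), seed=3)
patch, truth = render_ihc_patch(layout, (256, 256), noise_sd=2.0, seed=3)
result = run_pipeline([PatchEntry(patch)],
                      config=PipelineConfig(h_px=64, min_region_px=200))
print(f"polygons: {result.mor.n_polygons_included} included, "
      f"{result.mor.n_polygons_excluded} excluded")
print(f"Mor-index = {result.mor.value:.3f}")
```

```
polygons: 16 included, 0 excluded
Mor-index = 0.000
```

All 50 planted nuclei are recovered with the correct classes, and because
the fixture deliberately segregates the two populations, the study-level
index is 0.

The same pipeline is available from the shell:

```bash
morindex simulate --size 256 --seed 3 --out-dir study/
morindex run --patch study/patch.png --out-dir study/out/
morindex --help   # simulate, segment-epithelium, segment-nuclei,
                  # tessellate, mor-index, evaluate, stratify, run
```

## Layout

- `src/morindex/fixtures.py` — synthetic point patterns and the H-DAB patch renderer
- `src/morindex/epithelium.py` — Gabor/k-means tumor-epithelium segmentation
- `src/morindex/nuclei.py` — stain deconvolution, Bernsen, watershed, classification
- `src/morindex/spatial.py` — tessellation, density filter, Morisita–Horn, stratification
- `src/morindex/evaluation.py` — Accuracy / Dice / MIoU and instance matching
- `src/morindex/io.py`, `pipeline.py`, `cli.py` — formats, orchestration, CLI
- `docs/methods.md` — model assumptions, parameter choices, limitations
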