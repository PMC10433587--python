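"""Synthetic IHC data with known ground truth.

Two generators drive all downstream testing:

``generate_point_pattern``
    Per-polygon immune/tumor counts on a square tessellation with a
    controllable colocalization parameter, spanning fully segregated
    (disjoint polygon supports, Morisita-Horn index exactly 0) to fully
    colocalized (both populations drawn from one shared per-polygon
    weight vector, index near 1).

``render_ihc_patch``
    A physically motivated H-DAB patch renderer.  Nuclei are elliptical
    stain deposits composed on a white background through the Beer-Lambert
    law with the same published stain vectors the deconvolution stage
    uses: hematoxylin-blue for tumor and stroma nuclei, DAB-brown for
    immune nuclei.  Epithelial neighborhoods around tumor nuclei carry an
    oriented sinusoidal grating so the Gabor texture stage has signal.

These emulate the features the pipeline consumes (stain colors, texture,
spatial point patterns) -- not photorealistic histology.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.draw import ellipse as draw_ellipse

from .errors import InvalidSpecError
from .nuclei import CLASSES, DAB_OD, HEMATOXYLIN_OD, LabeledNuclei
from .spatial import PolygonCounts

__all__ = [
    "PatternSpec",
    "NucleusSpec",
    "generate_point_pattern",
    "render_ihc_patch",
    "random_nucleus_layout",
    "textured_patch",
]

# Renderer defaults: peak optical densities typical of well-stained IHC,
# and a grating that lands inside the Gabor bank's passband.
HEMATOXYLIN_PEAK_OD = 0.85
DAB_PEAK_OD = 0.9
TEXTURE_AMPLITUDE_OD = 0.4
TEXTURE_PERIOD_PX = 2.0
TEXTURE_ANGLE_DEG = 60.0
TEXTURE_RADIUS_FACTOR = 2.5


@dataclass(frozen=True)
class PatternSpec:
    """Recipe for a synthetic tumor/immune point pattern.

    ``colocalization`` interpolates between segregation and colocation by
    a per-point mixture: each nucleus independently follows the shared
    per-polygon weight vector with probability ``colocalization`` and the
    class-specific disjoint placement otherwise.
    """

    grid_dims: tuple[int, int]
    n_immune: int
    n_tumor: int
    colocalization: float
    seed: int

    def __post_init__(self):
        rows, cols = self.grid_dims
        if rows < 1 or cols < 1 or rows * cols < 2:
            raise InvalidSpecError("grid must contain at least 2 polygons")
        if self.n_immune < 0 or self.n_tumor < 0:
            raise InvalidSpecError("counts must be non-negative")
        if not 0.0 <= self.colocalization <= 1.0:
            raise InvalidSpecError("colocalization must lie in [0, 1]")


@dataclass(frozen=True)
class NucleusSpec:
    """Ground-truth ellipse for one rendered nucleus."""

    center: tuple[float, float]  # (row, col) px
    axes: tuple[float, float]  # (semi-major, semi-minor) px
    orientation: float  # degrees
    cls: str  # tumor | immune | stroma

    def __post_init__(self):
        if self.axes[0] <= 0 or self.axes[1] <= 0:
            raise InvalidSpecError("nucleus axes must be positive")
        if self.cls not in CLASSES:
            raise InvalidSpecError(f"unknown nucleus class {self.cls!r}")


def generate_point_pattern(
    spec: PatternSpec, polygon_area_px: int = 1024 * 1024
) -> PolygonCounts:
    """Draw per-polygon immune and tumor counts with known colocalization.

    Placement model (seeded, hence a pure function of the spec):

    * shared weights ``w`` ~ Dirichlet(1) over all polygons;
    * disjoint supports: immune restricted (uniformly) to the first half
      of the polygons, tumor to the remaining ones;
    * each nucleus follows ``w`` with probability ``colocalization`` and
      its class's disjoint placement otherwise.

    At colocalization 0 the supports never overlap, so the Morisita-Horn
    index of the output is exactly 0; at 1 both populations sample the
    same spatial distribution and the index approaches 1.
    """
    rows, cols = spec.grid_dims
    n_poly = rows * cols
    rng = np.random.default_rng(spec.seed)
    shared_w = rng.dirichlet(np.ones(n_poly))
    half = n_poly // 2
    w_immune_only = np.zeros(n_poly)
    w_immune_only[:half] = 1.0 / half
    w_tumor_only = np.zeros(n_poly)
    w_tumor_only[half:] = 1.0 / (n_poly - half)

    def place(n: int, disjoint_w: np.ndarray) -> np.ndarray:
        n_shared = rng.binomial(n, spec.colocalization)
        c = rng.multinomial(n_shared, shared_w)
        c = c + rng.multinomial(n - n_shared, disjoint_w)
        return c

    counts_immune = place(spec.n_immune, w_immune_only)
    counts_tumor = place(spec.n_tumor, w_tumor_only)
    grid_r, grid_c = np.unravel_index(np.arange(n_poly), (rows, cols))
    return PolygonCounts(
        row=grid_r,
        col=grid_c,
        area_px=np.full(n_poly, polygon_area_px),
        n_immune=counts_immune,
        n_tumor=counts_tumor,
        n_total=counts_immune + counts_tumor,
        included=np.ones(n_poly, dtype=bool),
    )


def render_ihc_patch(
    nuclei: list[NucleusSpec],
    size: tuple[int, int] = (256, 256),
    noise_sd: float = 0.0,
    seed: int = 0,
    texture: bool = True,
) -> tuple[np.ndarray, LabeledNuclei]:
    """Render an RGB H-DAB patch plus its ground-truth instance labels.

    Stain amounts accumulate in optical-density space and are composed on
    a white background via ``I = 255 * 10**(-A . S)`` per channel.
    Overlapping nuclei are resolved by draw order (later wins).  Gaussian
    noise with standard deviation ``noise_sd`` (8-bit intensity units) is
    added last.
    """
    n_rows, n_cols = size
    if n_rows < 64 or n_cols < 64:
        raise InvalidSpecError("patch must be at least 64 x 64")
    for spec in nuclei:
        r, c = spec.center
        if not (0 <= r < n_rows and 0 <= c < n_cols):
            raise InvalidSpecError(f"nucleus center {spec.center} outside patch")

    label = np.zeros(size, dtype=np.int32)
    classes: dict[int, str] = {}
    for i, spec in enumerate(nuclei, start=1):
        rr, cc = draw_ellipse(
            spec.center[0],
            spec.center[1],
            spec.axes[0],
            spec.axes[1],
            shape=size,
            rotation=np.deg2rad(spec.orientation),
        )
        label[rr, cc] = i
        classes[i] = spec.cls

    a_hema = np.zeros(size, dtype=float)
    a_dab = np.zeros(size, dtype=float)

    if texture:
        # oriented grating in the epithelial neighborhood of tumor nuclei
        tex_region = np.zeros(size, dtype=bool)
        rr_grid, cc_grid = np.meshgrid(
            np.arange(n_rows), np.arange(n_cols), indexing="ij"
        )
        for spec in nuclei:
            if spec.cls != "tumor":
                continue
            radius = TEXTURE_RADIUS_FACTOR * spec.axes[0]
            d2 = (rr_grid - spec.center[0]) ** 2 + (cc_grid - spec.center[1]) ** 2
            tex_region |= d2 <= radius**2
        theta = np.deg2rad(TEXTURE_ANGLE_DEG)
        phase = (
            2.0
            * np.pi
            * (rr_grid * np.sin(theta) + cc_grid * np.cos(theta))
            / TEXTURE_PERIOD_PX
        )
        grating = 0.5 * (1.0 + np.sin(phase))
        a_hema[tex_region & (label == 0)] += (
            TEXTURE_AMPLITUDE_OD * grating[tex_region & (label == 0)]
        )

    for i, spec in enumerate(nuclei, start=1):
        mask = label == i
        if spec.cls == "immune":
            a_dab[mask] = DAB_PEAK_OD
        else:
            a_hema[mask] = HEMATOXYLIN_PEAK_OD

    h_vec = HEMATOXYLIN_OD / np.linalg.norm(HEMATOXYLIN_OD)
    d_vec = DAB_OD / np.linalg.norm(DAB_OD)
    od_rgb = a_hema[..., None] * h_vec + a_dab[..., None] * d_vec
    rgb = 255.0 * 10.0 ** (-od_rgb)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        rgb = rgb + rng.normal(0.0, noise_sd, rgb.shape)
    patch = np.clip(np.round(rgb), 0, 255).astype(np.uint8)

    truth = LabeledNuclei.from_raster(label, classes=classes)
    return patch, truth


def random_nucleus_layout(
    n_tumor: int,
    n_immune: int,
    n_stroma: int,
    size: tuple[int, int] = (256, 256),
    seed: int = 0,
    min_center_dist: float = 21.0,
    margin: float = 12.0,
) -> list[NucleusSpec]:
    """Sample a non-touching layout with spatially separated compartments.

    Tumor nuclei (and hence the rendered epithelial texture) occupy the
    left part of the patch; immune and stroma nuclei the right part, with
    a clear gap in between so the planted epithelium region does not reach
    the non-tumor compartment.  Centers are rejection-sampled to keep at
    least ``min_center_dist`` apart, so rendered nuclei never touch.
    """
    rng = np.random.default_rng(seed)
    n_rows, n_cols = size

    def sample_region(n: int, c_lo: float, c_hi: float, placed: list) -> list:
        out = []
        tries = 0
        while len(out) < n:
            tries += 1
            if tries > 100000:
                raise InvalidSpecError(
                    "could not place nuclei; lower counts or enlarge the patch"
                )
            r = rng.uniform(margin, n_rows - margin)
            c = rng.uniform(c_lo, c_hi)
            if all(
                (r - pr) ** 2 + (c - pc) ** 2 >= min_center_dist**2
                for pr, pc in placed + [(o[0], o[1]) for o in out]
            ):
                out.append((r, c))
        return out

    left_hi = 0.40 * n_cols
    right_lo = 0.60 * n_cols
    placed: list[tuple[float, float]] = []
    tumor_centers = sample_region(n_tumor, margin, left_hi, placed)
    placed += tumor_centers
    other_centers = sample_region(n_immune + n_stroma, right_lo, n_cols - margin, placed)

    specs = []
    for (r, c) in tumor_centers:
        specs.append(_random_nucleus(rng, (r, c), "tumor"))
    for j, (r, c) in enumerate(other_centers):
        cls = "immune" if j < n_immune else "stroma"
        specs.append(_random_nucleus(rng, (r, c), cls))
    return specs


def _random_nucleus(rng, center, cls) -> NucleusSpec:
    a = rng.uniform(5.5, 7.5)
    b = rng.uniform(4.0, 5.5)
    return NucleusSpec(
        center=center, axes=(a, b), orientation=rng.uniform(0, 180), cls=cls
    )


def textured_patch(
    size: tuple[int, int] = (128, 128),
    fraction: float = 0.5,
    seed: int = 0,
    noise_sd: float = 2.0,
    background: float = 230.0,
    amplitude: float = 80.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Grayscale patch whose left ``fraction`` carries the grating texture.

    Returns ``(image, truth_mask)``; used to exercise the Gabor/k-means
    epithelium stage in isolation.
    """
    if not 0.0 < fraction < 1.0:
        raise InvalidSpecError("fraction must be in (0, 1)")
    n_rows, n_cols = size
    rng = np.random.default_rng(seed)
    rr, cc = np.meshgrid(np.arange(n_rows), np.arange(n_cols), indexing="ij")
    theta = np.deg2rad(TEXTURE_ANGLE_DEG)
    phase = 2.0 * np.pi * (rr * np.sin(theta) + cc * np.cos(theta)) / TEXTURE_PERIOD_PX
    img = np.full(size, background, dtype=float)
    truth = cc < fraction * n_cols
    img[truth] -= amplitude * 0.5 * (1.0 + np.sin(phase[truth]))
    if noise_sd > 0:
        img += rng.normal(0.0, noise_sd, size)
    return np.clip(img, 0, 255), truth
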