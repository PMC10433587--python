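"""End-to-end orchestration: patches (+ tumor mask) -> Mor-index.

Stage order: epithelium -> nuclei -> classify -> tessellate -> density
filter -> Morisita-Horn.  The upstream tissue classifier that produced the
tumor mask is an input boundary, not a component: any binary mask is
accepted, and with no mask the whole study area is treated as tumor
region.  Every run is fully reproducible from the configuration (the only
randomness is the k-means seed), and every intermediate artifact can be
written for audit.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as mio
from .epithelium import (
    GaborBankSpec,
    build_gabor_bank,
    cluster_epithelium,
    gabor_features,
    refine_mask,
    rgb_to_gray,
)
from .errors import InvalidInputError
from .nuclei import (
    LabeledNuclei,
    NucleusRecord,
    bernsen_mask,
    classify_nuclei,
    count_nuclei,
    dab_to_8bit,
    deconvolve_stains,
    segment_nuclei_watershed,
)
from .spatial import (
    DEFAULT_DENSITY_TAU,
    DEFAULT_H_PX,
    MorResult,
    PolygonCounts,
    filter_low_density,
    morisita_horn_from_counts,
    tessellate_counts,
)

logger = logging.getLogger("morindex")

__all__ = ["PipelineConfig", "PatchEntry", "PipelineResult", "run_pipeline", "run_study"]


@dataclass(frozen=True)
class PipelineConfig:
    """All stage parameters with the published defaults.

    Defaults reproduce the printed settings: Gabor wavelength 2 with
    orientations 30-180 in steps of 30, 2-cluster k-means capped at 5
    iterations, Bernsen window 77 / contrast 15, tessellation cell 1024 px,
    density threshold 0.0002, stratification quantile 0.5.
    """

    # epithelium
    gabor_wavelength: float = 2.0
    gabor_orientations: tuple[float, ...] = (30.0, 60.0, 90.0, 120.0, 150.0, 180.0)
    gabor_smooth_sigma: float | None = None
    kmeans_k: int = 2
    kmeans_max_iter: int = 5
    kmeans_seed: int = 0
    dilation_radius_px: int = 5
    erosion_radius_px: int = 5
    min_region_px: int = 500
    # nuclei
    od_cap: float = 3.0
    dab_od_range: tuple[float, float] = (0.0, 2.0)
    bernsen_window_px: int = 77
    bernsen_contrast: float = 15.0
    min_sep_px: int = 7
    min_area_px: int = 40
    watershed_smooth_sigma: float = 1.0
    immune_overlap_frac: float = 0.5
    # spatial
    h_px: int = DEFAULT_H_PX
    density_tau: float = DEFAULT_DENSITY_TAU
    cutoff_quantile: float = 0.5

    def __post_init__(self):
        GaborBankSpec(self.gabor_wavelength, tuple(self.gabor_orientations))
        if self.kmeans_k < 2 or self.kmeans_max_iter < 1:
            raise InvalidInputError("kmeans_k >= 2 and kmeans_max_iter >= 1 required")
        if self.bernsen_window_px < 3 or self.bernsen_window_px % 2 == 0:
            raise InvalidInputError("bernsen_window_px must be odd and >= 3")
        if self.bernsen_contrast < 0:
            raise InvalidInputError("bernsen_contrast must be non-negative")
        if self.h_px < 1:
            raise InvalidInputError("h_px must be >= 1")
        if self.density_tau < 0:
            raise InvalidInputError("density_tau must be non-negative")
        if not 0.0 <= self.cutoff_quantile <= 1.0:
            raise InvalidInputError("cutoff_quantile must lie in [0, 1]")
        if not 0.0 <= self.immune_overlap_frac <= 1.0:
            raise InvalidInputError("immune_overlap_frac must lie in [0, 1]")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["gabor_orientations"] = list(self.gabor_orientations)
        d["dab_od_range"] = list(self.dab_od_range)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise InvalidInputError(f"unknown config keys: {sorted(unknown)}")
        d = dict(d)
        for key in ("gabor_orientations", "dab_od_range"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        path = Path(path)
        text = path.read_text()
        if path.suffix.lower() == ".toml":
            import tomllib

            data = tomllib.loads(text)
        else:
            import yaml

            data = yaml.safe_load(text)
        if not isinstance(data, dict):
            raise InvalidInputError(f"config {path} is not a mapping")
        return cls.from_dict(data)


@dataclass(frozen=True)
class PatchEntry:
    """One patch plus its (row, col) offset in study coordinates."""

    patch: np.ndarray
    offset: tuple[int, int] = (0, 0)


@dataclass
class PatchArtifacts:
    epithelium_mask: np.ndarray
    immune_mask: np.ndarray
    nuclei: LabeledNuclei


@dataclass
class PipelineResult:
    mor: MorResult
    counts: PolygonCounts
    records: list[NucleusRecord]  # centroids in study coordinates
    per_patch: list[PatchArtifacts]
    log: list[dict]
    errors: list[str] = field(default_factory=list)  # per-file failures (skipped)

    def nuclei_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "instance_id": [r.instance_id for r in self.records],
                "class": [r.cls for r in self.records],
                "centroid_row": [r.centroid[0] for r in self.records],
                "centroid_col": [r.centroid[1] for r in self.records],
                "area_px": [r.area_px for r in self.records],
            }
        )


def segment_patch(patch: np.ndarray, config: PipelineConfig) -> PatchArtifacts:
    """Run the segmentation stages (epithelium, nuclei, classify) on one patch."""
    spec = GaborBankSpec(config.gabor_wavelength, tuple(config.gabor_orientations))
    bank = build_gabor_bank(spec)
    fs = gabor_features(rgb_to_gray(patch), bank, smooth_sigma=config.gabor_smooth_sigma)
    roi = cluster_epithelium(
        fs, k=config.kmeans_k, max_iter=config.kmeans_max_iter, seed=config.kmeans_seed
    )
    epithelium = refine_mask(
        roi,
        dilation_radius_px=config.dilation_radius_px,
        erosion_radius_px=config.erosion_radius_px,
        min_region_px=config.min_region_px,
    )
    stains = deconvolve_stains(patch, od_cap=config.od_cap)
    immune = bernsen_mask(
        dab_to_8bit(stains.dab_od, config.dab_od_range),
        window_px=config.bernsen_window_px,
        contrast_threshold=config.bernsen_contrast,
    )
    raw = segment_nuclei_watershed(
        stains,
        min_sep_px=config.min_sep_px,
        min_area_px=config.min_area_px,
        smooth_sigma=config.watershed_smooth_sigma,
    )
    classified = classify_nuclei(
        raw, epithelium, immune, immune_overlap_frac=config.immune_overlap_frac
    )
    return PatchArtifacts(epithelium, immune, classified)


def run_pipeline(
    entries: list[PatchEntry],
    tumor_mask: np.ndarray | None = None,
    config: PipelineConfig = PipelineConfig(),
) -> PipelineResult:
    """Segment every patch, pool nuclei in study space, compute the index.

    ``tumor_mask`` is a binary raster in study coordinates; None means the
    whole study extent is treated as tumor region.
    """
    if not entries:
        raise InvalidInputError("no patches given")
    log: list[dict] = []
    per_patch: list[PatchArtifacts] = []
    records: list[NucleusRecord] = []
    next_id = 1
    max_r = max(e.offset[0] + e.patch.shape[0] for e in entries)
    max_c = max(e.offset[1] + e.patch.shape[1] for e in entries)
    for k, entry in enumerate(entries):
        art = segment_patch(entry.patch, config)
        per_patch.append(art)
        n_t, n_i, n_s = count_nuclei(art.nuclei)
        log.append(
            {
                "stage": "segment",
                "patch": k,
                "offset": list(entry.offset),
                "n_tumor": n_t,
                "n_immune": n_i,
                "n_stroma": n_s,
            }
        )
        logger.info(
            "patch %d: %d tumor, %d immune, %d stroma nuclei", k, n_t, n_i, n_s
        )
        dr, dc = entry.offset
        for r in art.nuclei.records:
            records.append(
                NucleusRecord(
                    instance_id=next_id,
                    centroid=(r.centroid[0] + dr, r.centroid[1] + dc),
                    area_px=r.area_px,
                    cls=r.cls,
                )
            )
            next_id += 1

    if tumor_mask is None:
        tumor_mask = np.ones((max_r, max_c), dtype=bool)
    counts = tessellate_counts(
        [r.centroid for r in records],
        [r.cls for r in records],
        tumor_mask,
        h_px=config.h_px,
    )
    counts = filter_low_density(counts, tau=config.density_tau)
    log.append(
        {
            "stage": "tessellate",
            "h_px": config.h_px,
            "density_tau": config.density_tau,
            "n_polygons": len(counts),
            "n_included": counts.n_included,
            "n_excluded": counts.n_excluded,
        }
    )
    mor = morisita_horn_from_counts(counts)
    log.append({"stage": "mor_index", "value": mor.value, "defined": mor.defined})
    logger.info(
        "Mor-index %s over %d polygons (%d excluded)",
        mor.value,
        mor.n_polygons_included,
        mor.n_polygons_excluded,
    )
    return PipelineResult(mor, counts, records, per_patch, log)


def run_study(
    patch_paths: list,
    offsets: list[tuple[int, int]] | None = None,
    tumor_mask_path=None,
    config: PipelineConfig = PipelineConfig(),
    out_dir=None,
    skip_unreadable: bool = False,
) -> PipelineResult:
    """File-level wrapper: read inputs, run, write every artifact.

    Outputs under ``out_dir``: per-patch epithelium/immune masks and
    instance TIFFs, pooled ``nuclei.csv``/``nuclei.geojson``, the
    per-polygon ``polygon_counts.csv``, ``mor.json`` and ``log.json``.
    With ``skip_unreadable`` a bad patch file is recorded in
    ``result.errors`` and the remaining patches are still processed.
    """
    if offsets is None:
        offsets = [(0, 0)] * len(patch_paths)
    if len(offsets) != len(patch_paths):
        raise InvalidInputError("offsets and patch_paths length mismatch")
    if len(patch_paths) > 1 and len(set(offsets)) == 1:
        raise InvalidInputError(
            "multiple patches need distinct offsets (patch-coordinate manifest)"
        )
    entries, errors = [], []
    for p, o in zip(patch_paths, offsets):
        try:
            entries.append(PatchEntry(mio.read_patch(p), tuple(o)))
        except InvalidInputError:
            if not skip_unreadable:
                raise
            errors.append(str(p))
            logger.warning("skipping unreadable patch %s", p)
    if not entries:
        raise InvalidInputError("no readable patches")
    tumor_mask = mio.read_mask(tumor_mask_path) if tumor_mask_path else None
    result = run_pipeline(entries, tumor_mask, config)
    result.errors = errors
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for k, art in enumerate(result.per_patch):
            mio.write_mask(out / f"epithelium_{k:03d}.png", art.epithelium_mask)
            mio.write_mask(out / f"immune_{k:03d}.png", art.immune_mask)
            mio.write_instance_tiff(out / f"instances_{k:03d}.tif", art.nuclei.instance_raster)
            mio.write_nuclei_geojson(out / f"nuclei_{k:03d}.geojson", art.nuclei)
        result.nuclei_dataframe().to_csv(out / "nuclei.csv", index=False)
        mio.write_counts_csv(out / "polygon_counts.csv", result.counts)
        mio.write_mor_json(out / "mor.json", result.mor)
        (out / "log.json").write_text(
            json.dumps({"config": config.to_dict(), "stages": result.log}, indent=1)
        )
    return result
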