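"""Tumor-immune spatial colocalization over a square tessellation.

The tumor region of a slide (or patch) is divided into an ``h x h`` pixel
grid of "polygons".  Per-polygon immune and tumor nucleus counts are turned
into proportion vectors and compared with the Morisita-Horn similarity
index,

    Mor = 2 * sum_i(p_i^l * p_i^c) / (sum_i (p_i^l)^2 + sum_i (p_i^c)^2),

where ``p_i^l`` (immune) and ``p_i^c`` (tumor) are the per-polygon shares of
each population.  Mor = 0 means the two populations never share a polygon
(fully segregated); Mor = 1 means their spatial distributions coincide.

Polygons with very low total nucleus density (``n_i / d_i <= tau``, with
``d_i`` the tissue pixel area of the polygon) are excluded before the index
is computed; they are typically tissue folds, fat or glass.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import EmptyInputError, InvalidInputError

__all__ = [
    "PolygonCounts",
    "Proportions",
    "MorResult",
    "PatientRecord",
    "tessellate_counts",
    "filter_low_density",
    "compute_proportions",
    "morisita_horn",
    "morisita_horn_from_counts",
    "stratify_patients",
]

DEFAULT_H_PX = 1024
DEFAULT_DENSITY_TAU = 0.0002


@dataclass
class PolygonCounts:
    """Per-polygon nucleus counts over a square tessellation.

    Attributes
    ----------
    row, col : arrays of int
        Grid indices of each polygon (0-based, anchored at the tumor-mask
        bounding box origin).
    area_px : array of int
        ``d_i`` -- number of tumor-mask pixels inside the polygon.
    n_immune, n_tumor, n_total : arrays of int
        Per-polygon counts; ``n_total`` includes stroma nuclei and is the
        quantity the density filter uses.
    included : array of bool
        False for polygons excluded by the low-density rule.
    """

    row: np.ndarray
    col: np.ndarray
    area_px: np.ndarray
    n_immune: np.ndarray
    n_tumor: np.ndarray
    n_total: np.ndarray
    included: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.row = np.asarray(self.row, dtype=np.int64)
        self.col = np.asarray(self.col, dtype=np.int64)
        self.area_px = np.asarray(self.area_px, dtype=np.int64)
        self.n_immune = np.asarray(self.n_immune, dtype=np.int64)
        self.n_tumor = np.asarray(self.n_tumor, dtype=np.int64)
        self.n_total = np.asarray(self.n_total, dtype=np.int64)
        if self.included is None:
            self.included = np.ones(self.row.shape, dtype=bool)
        self.included = np.asarray(self.included, dtype=bool)
        n = len(self.row)
        for name in ("col", "area_px", "n_immune", "n_tumor", "n_total", "included"):
            if len(getattr(self, name)) != n:
                raise InvalidInputError(f"field {name!r} length mismatch")
        if np.any(self.area_px <= 0):
            raise InvalidInputError("polygon pixel areas must be positive")
        if np.any(self.n_total < self.n_immune + self.n_tumor):
            raise InvalidInputError("n_total must be >= n_immune + n_tumor")

    def __len__(self) -> int:
        return len(self.row)

    @property
    def n_included(self) -> int:
        return int(self.included.sum())

    @property
    def n_excluded(self) -> int:
        return int((~self.included).sum())

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "polygon_row": self.row,
                "polygon_col": self.col,
                "d_px": self.area_px,
                "n_immune": self.n_immune,
                "n_tumor": self.n_tumor,
                "n_total": self.n_total,
                "included": self.included,
            }
        )

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "PolygonCounts":
        required = {"polygon_row", "polygon_col", "d_px", "n_immune", "n_tumor",
                    "n_total", "included"}
        missing = required - set(df.columns)
        if missing:
            raise InvalidInputError(f"counts table missing columns: {sorted(missing)}")
        return cls(
            row=df["polygon_row"].to_numpy(),
            col=df["polygon_col"].to_numpy(),
            area_px=df["d_px"].to_numpy(),
            n_immune=df["n_immune"].to_numpy(),
            n_tumor=df["n_tumor"].to_numpy(),
            n_total=df["n_total"].to_numpy(),
            included=df["included"].to_numpy(),
        )


@dataclass(frozen=True)
class Proportions:
    """Per-polygon population shares over the included polygons.

    ``p_immune`` / ``p_tumor`` are None ("undefined") when the respective
    population has zero total count: a share of nothing is meaningless and
    must not silently become zero.
    """

    p_immune: np.ndarray | None
    p_tumor: np.ndarray | None

    @property
    def defined(self) -> bool:
        return self.p_immune is not None and self.p_tumor is not None


@dataclass(frozen=True)
class MorResult:
    """Morisita-Horn index with polygon bookkeeping.

    ``value`` is None when the index is undefined (one population absent
    after filtering) -- distinct from 0, which means true segregation.
    """

    value: float | None
    n_polygons_included: int
    n_polygons_excluded: int

    @property
    def defined(self) -> bool:
        return self.value is not None


@dataclass
class PatientRecord:
    patient_id: str
    mor_value: float | None
    group: str | None = None
    survival_time: float | None = None
    event: int | None = None


def tessellate_counts(
    centroids: Sequence[tuple[float, float]] | np.ndarray,
    classes: Sequence[str],
    tumor_mask: np.ndarray,
    h_px: int = DEFAULT_H_PX,
) -> PolygonCounts:
    """Bin classified nucleus centroids into an ``h x h`` square grid.

    The grid is anchored at the tumor-mask bounding-box origin with
    half-open cells ``[r0 + k*h, r0 + (k+1)*h)``.  Each nucleus belongs to
    exactly one polygon (by centroid).  ``d_i`` is the count of mask-true
    pixels inside the cell; cells with no tumor tissue are dropped, along
    with any centroid falling in them or outside the bounding box.

    Parameters
    ----------
    centroids : (n, 2) array of (row, col) pixel coordinates
    classes : length-n sequence over {"tumor", "immune", "stroma"}
    tumor_mask : 2-D bool raster defining the tumor region
    h_px : side of the square tessellation cell in pixels (default 1024)
    """
    if h_px < 1:
        raise InvalidInputError("h_px must be >= 1")
    tumor_mask = np.asarray(tumor_mask, dtype=bool)
    if tumor_mask.ndim != 2:
        raise InvalidInputError("tumor_mask must be 2-D")
    centroids = np.asarray(centroids, dtype=float).reshape(-1, 2)
    classes = list(classes)
    if len(classes) != len(centroids):
        raise InvalidInputError("classes and centroids length mismatch")
    bad = set(classes) - {"tumor", "immune", "stroma"}
    if bad:
        raise InvalidInputError(f"unknown nucleus classes: {sorted(bad)}")

    rows_true, cols_true = np.nonzero(tumor_mask)
    if rows_true.size == 0:
        empty = np.empty(0, dtype=np.int64)
        return PolygonCounts(empty, empty, empty, empty, empty, empty,
                             np.empty(0, dtype=bool))
    r0, c0 = int(rows_true.min()), int(cols_true.min())
    r1, c1 = int(rows_true.max()), int(cols_true.max())
    n_grid_rows = (r1 - r0) // h_px + 1
    n_grid_cols = (c1 - c0) // h_px + 1

    # d_i per cell: histogram the mask-true pixel coordinates
    cell_r = (rows_true - r0) // h_px
    cell_c = (cols_true - c0) // h_px
    area = np.zeros((n_grid_rows, n_grid_cols), dtype=np.int64)
    np.add.at(area, (cell_r, cell_c), 1)

    counts_imm = np.zeros_like(area)
    counts_tum = np.zeros_like(area)
    counts_tot = np.zeros_like(area)
    if len(centroids):
        gr = np.floor((centroids[:, 0] - r0) / h_px).astype(np.int64)
        gc = np.floor((centroids[:, 1] - c0) / h_px).astype(np.int64)
        in_grid = (gr >= 0) & (gr < n_grid_rows) & (gc >= 0) & (gc < n_grid_cols)
        cls_arr = np.asarray(classes, dtype=object)
        for mask_cls, target in (
            (cls_arr == "immune", counts_imm),
            (cls_arr == "tumor", counts_tum),
            (np.ones(len(cls_arr), dtype=bool), counts_tot),
        ):
            sel = mask_cls & in_grid
            np.add.at(target, (gr[sel], gc[sel]), 1)

    keep = area > 0
    kr, kc = np.nonzero(keep)
    return PolygonCounts(
        row=kr,
        col=kc,
        area_px=area[keep],
        n_immune=counts_imm[keep],
        n_tumor=counts_tum[keep],
        n_total=counts_tot[keep],
        included=np.ones(kr.size, dtype=bool),
    )


def filter_low_density(
    counts: PolygonCounts, tau: float = DEFAULT_DENSITY_TAU
) -> PolygonCounts:
    """Mark polygons with total density ``n_i / d_i <= tau`` as excluded.

    The boundary is inclusive: a polygon exactly at the threshold is
    excluded.  Counts and areas are left untouched; only ``included``
    changes.
    """
    density = counts.n_total / counts.area_px
    return replace(counts, included=density > tau)


def compute_proportions(counts: PolygonCounts) -> Proportions:
    """Normalize per-polygon counts into population shares.

    Sums run over *included* polygons only.  A population with zero total
    count yields an undefined (None) proportion vector.
    """
    if counts.n_included == 0:
        raise EmptyInputError("no included polygons to compute proportions over")
    imm = counts.n_immune[counts.included].astype(float)
    tum = counts.n_tumor[counts.included].astype(float)
    p_imm = imm / imm.sum() if imm.sum() > 0 else None
    p_tum = tum / tum.sum() if tum.sum() > 0 else None
    return Proportions(p_immune=p_imm, p_tumor=p_tum)


def morisita_horn(
    props: Proportions,
    n_polygons_included: int | None = None,
    n_polygons_excluded: int = 0,
) -> MorResult:
    """Evaluate the Morisita-Horn index on proportion vectors.

    Returns an undefined (flagged) result if either population is absent;
    0 iff the supports are disjoint; 1 iff the two vectors are identical.
    """
    if not props.defined:
        n_inc = n_polygons_included
        if n_inc is None:
            vec = props.p_immune if props.p_immune is not None else props.p_tumor
            n_inc = len(vec) if vec is not None else 0
        return MorResult(None, n_inc, n_polygons_excluded)
    pl = np.asarray(props.p_immune, dtype=float)
    pc = np.asarray(props.p_tumor, dtype=float)
    if pl.shape != pc.shape:
        raise InvalidInputError("proportion vectors differ in length")
    num = 2.0 * float(np.dot(pl, pc))
    den = float(np.dot(pl, pl) + np.dot(pc, pc))
    value = num / den
    n_inc = len(pl) if n_polygons_included is None else n_polygons_included
    return MorResult(value, n_inc, n_polygons_excluded)


def morisita_horn_from_counts(
    counts: PolygonCounts, tau: float | None = None
) -> MorResult:
    """Density-filter (optionally), normalize, and evaluate in one call."""
    if tau is not None:
        counts = filter_low_density(counts, tau)
    if counts.n_included == 0:
        return MorResult(None, 0, counts.n_excluded)
    props = compute_proportions(counts)
    return morisita_horn(props, counts.n_included, counts.n_excluded)


def stratify_patients(
    records: Sequence[PatientRecord], quantile: float = 0.5
) -> list[PatientRecord]:
    """Split patients into high/low groups at a quantile of the Mor-index.

    The cutoff is ``numpy.quantile`` (linear interpolation) of the defined
    values; a patient is "high" iff its value is strictly above the cutoff.
    Records with an undefined index are left ungrouped.
    """
    if not 0.0 <= quantile <= 1.0:
        raise InvalidInputError("quantile must be in [0, 1]")
    defined = [r for r in records if r.mor_value is not None]
    if len(defined) < 2:
        raise EmptyInputError("need >= 2 records with a defined Mor-index")
    values = np.array([r.mor_value for r in defined], dtype=float)
    cutoff = float(np.quantile(values, quantile))
    if np.all(values == values[0]):
        warnings.warn(
            "all Mor-index values identical; every patient assigned to 'low'",
            stacklevel=2,
        )
    out = []
    for r in records:
        if r.mor_value is None:
            out.append(replace_record(r, group=None))
        else:
            out.append(replace_record(r, group="high" if r.mor_value > cutoff else "low"))
    return out


def replace_record(r: PatientRecord, **kw) -> PatientRecord:
    d = dict(
        patient_id=r.patient_id,
        mor_value=r.mor_value,
        group=r.group,
        survival_time=r.survival_time,
        event=r.event,
    )
    d.update(kw)
    return PatientRecord(**d)
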