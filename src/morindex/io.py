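"""File formats: patches, masks, instance labels, GeoJSON and CSV tables.

All writers have a matching reader and write -> read is the identity on
every field.  Nuclei go out three ways: a 16-bit instance-label TIFF, a
QuPath-compatible GeoJSON FeatureCollection (polygon boundaries with a
``classification`` property), and a flat CSV.
"""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile
from skimage import measure

from .errors import InvalidInputError
from .nuclei import LabeledNuclei, NucleusRecord
from .spatial import MorResult, PatientRecord, PolygonCounts

__all__ = [
    "read_patch",
    "write_patch",
    "read_mask",
    "write_mask",
    "read_instance_tiff",
    "write_instance_tiff",
    "nuclei_to_geojson",
    "nuclei_from_geojson",
    "write_nuclei_geojson",
    "read_nuclei_geojson",
    "write_nuclei_csv",
    "read_nuclei_csv",
    "write_counts_csv",
    "read_counts_csv",
    "write_patients_csv",
    "read_patients_csv",
    "write_mor_json",
    "read_mor_json",
]

_TIFF_EXT = {".tif", ".tiff"}


def read_patch(path) -> np.ndarray:
    """Read an RGB patch (PNG or TIFF) as a uint8 array."""
    path = Path(path)
    try:
        if path.suffix.lower() in _TIFF_EXT:
            arr = tifffile.imread(path)
        else:
            arr = iio.imread(path)
    except Exception as exc:  # noqa: BLE001 - surface file context
        raise InvalidInputError(f"cannot read patch {path}: {exc}") from exc
    arr = np.asarray(arr)
    if arr.ndim == 3 and arr.shape[2] == 4:
        arr = arr[..., :3]
    return arr


def write_patch(path, patch: np.ndarray) -> None:
    path = Path(path)
    patch = np.asarray(patch, dtype=np.uint8)
    if path.suffix.lower() in _TIFF_EXT:
        tifffile.imwrite(path, patch)
    else:
        iio.imwrite(path, patch)


def read_mask(path) -> np.ndarray:
    """Read a binary mask: any non-zero pixel is True."""
    return read_patch(path).astype(bool) if Path(path).suffix.lower() in _TIFF_EXT \
        else np.asarray(iio.imread(path)).astype(bool)


def write_mask(path, mask: np.ndarray) -> None:
    """Write a binary mask as an 8-bit 0/255 raster."""
    arr = (np.asarray(mask, dtype=bool).astype(np.uint8)) * 255
    write_patch(path, arr)


def write_instance_tiff(path, raster: np.ndarray) -> None:
    raster = np.asarray(raster)
    if raster.max() > np.iinfo(np.uint16).max:
        raise InvalidInputError("more than 65535 instances; cannot write uint16 TIFF")
    tifffile.imwrite(Path(path), raster.astype(np.uint16))


def read_instance_tiff(path) -> np.ndarray:
    try:
        return tifffile.imread(Path(path)).astype(np.int32)
    except Exception as exc:  # noqa: BLE001
        raise InvalidInputError(f"cannot read instance TIFF {path}: {exc}") from exc


def _instance_polygon(mask: np.ndarray) -> list[list[float]]:
    """Outer boundary of one instance as [x, y] = [col, row] pairs."""
    padded = np.pad(mask, 1)
    contours = measure.find_contours(padded.astype(float), 0.5)
    if not contours:
        return []
    contour = max(contours, key=len) - 1.0  # undo padding
    return [[float(c), float(r)] for r, c in contour]


def nuclei_to_geojson(nuclei: LabeledNuclei) -> dict:
    """QuPath-dialect FeatureCollection.

    Each nucleus becomes a Polygon feature with a ``classification`` name
    in {Tumor, Immune, Stroma}; centroid and area ride along as
    measurements so the record round-trips exactly.
    """
    features = []
    for r in nuclei.records:
        mask = nuclei.instance_raster == r.instance_id
        ring = _instance_polygon(mask)
        if ring and ring[0] != ring[-1]:
            ring.append(ring[0])
        feature = {
            "type": "Feature",
            "id": r.instance_id,
            "geometry": {"type": "Polygon", "coordinates": [ring]},
            "properties": {
                "objectType": "detection",
                "measurements": {
                    "centroid_row": r.centroid[0],
                    "centroid_col": r.centroid[1],
                    "area_px": r.area_px,
                },
            },
        }
        if r.cls is not None:
            feature["properties"]["classification"] = {"name": r.cls.capitalize()}
        features.append(feature)
    return {"type": "FeatureCollection", "features": features}


def nuclei_from_geojson(obj: dict) -> list[NucleusRecord]:
    if obj.get("type") != "FeatureCollection" or "features" not in obj:
        raise InvalidInputError("not a GeoJSON FeatureCollection")
    records = []
    for i, feat in enumerate(obj["features"]):
        try:
            props = feat["properties"]
            meas = props["measurements"]
            cls = props.get("classification", {}).get("name")
            records.append(
                NucleusRecord(
                    instance_id=int(feat["id"]),
                    centroid=(float(meas["centroid_row"]), float(meas["centroid_col"])),
                    area_px=int(meas["area_px"]),
                    cls=cls.lower() if cls else None,
                )
            )
        except (KeyError, TypeError, ValueError) as exc:
            raise InvalidInputError(f"malformed GeoJSON feature #{i}: {exc}") from exc
    return records


def write_nuclei_geojson(path, nuclei: LabeledNuclei) -> None:
    Path(path).write_text(json.dumps(nuclei_to_geojson(nuclei), indent=1))


def read_nuclei_geojson(path) -> list[NucleusRecord]:
    try:
        obj = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise InvalidInputError(f"malformed GeoJSON {path}: {exc}") from exc
    return nuclei_from_geojson(obj)


NUCLEI_COLUMNS = ["instance_id", "class", "centroid_row", "centroid_col", "area_px"]


def write_nuclei_csv(path, nuclei: LabeledNuclei | pd.DataFrame) -> None:
    df = nuclei if isinstance(nuclei, pd.DataFrame) else nuclei.to_dataframe()
    df.to_csv(Path(path), index=False)


def read_nuclei_csv(path) -> list[NucleusRecord]:
    df = _read_csv(path, NUCLEI_COLUMNS)
    records = []
    for i, row in df.iterrows():
        cls = row["class"]
        cls = None if (pd.isna(cls) or cls == "") else str(cls)
        try:
            records.append(
                NucleusRecord(
                    instance_id=int(row["instance_id"]),
                    centroid=(float(row["centroid_row"]), float(row["centroid_col"])),
                    area_px=int(row["area_px"]),
                    cls=cls,
                )
            )
        except (TypeError, ValueError) as exc:
            raise InvalidInputError(f"{path}: bad record at line {i + 2}: {exc}") from exc
    return records


COUNTS_COLUMNS = [
    "polygon_row", "polygon_col", "d_px", "n_immune", "n_tumor", "n_total", "included",
]


def write_counts_csv(path, counts: PolygonCounts) -> None:
    counts.to_dataframe().to_csv(Path(path), index=False)


def read_counts_csv(path) -> PolygonCounts:
    return PolygonCounts.from_dataframe(_read_csv(path, COUNTS_COLUMNS))


PATIENT_COLUMNS = ["patient_id", "mor_index", "n_polygons_included", "group"]


def write_patients_csv(path, records, n_polygons=None) -> None:
    """Patient table; survival columns pass through for downstream tools."""
    rows = []
    for i, r in enumerate(records):
        row = {
            "patient_id": r.patient_id,
            "mor_index": r.mor_value if r.mor_value is not None else "",
            "n_polygons_included": (n_polygons[i] if n_polygons else ""),
            "group": r.group if r.group is not None else "",
        }
        if r.survival_time is not None:
            row["survival_time_months"] = r.survival_time
        if r.event is not None:
            row["event"] = r.event
        rows.append(row)
    pd.DataFrame(rows).to_csv(Path(path), index=False)


def read_patients_csv(path) -> list[PatientRecord]:
    df = _read_csv(path, ["patient_id", "mor_index"])
    records = []
    for _, row in df.iterrows():
        mor = row["mor_index"]
        records.append(
            PatientRecord(
                patient_id=str(row["patient_id"]),
                mor_value=None if pd.isna(mor) else float(mor),
                group=row.get("group") if isinstance(row.get("group"), str) else None,
                survival_time=(
                    float(row["survival_time_months"])
                    if "survival_time_months" in row and pd.notna(row["survival_time_months"])
                    else None
                ),
                event=(
                    int(row["event"])
                    if "event" in row and pd.notna(row["event"])
                    else None
                ),
            )
        )
    return records


def write_mor_json(path, result: MorResult) -> None:
    Path(path).write_text(
        json.dumps(
            {
                "mor_index": result.value,
                "defined": result.defined,
                "n_polygons_included": result.n_polygons_included,
                "n_polygons_excluded": result.n_polygons_excluded,
            },
            indent=1,
        )
    )


def read_mor_json(path) -> MorResult:
    obj = json.loads(Path(path).read_text())
    return MorResult(
        value=obj["mor_index"],
        n_polygons_included=obj["n_polygons_included"],
        n_polygons_excluded=obj["n_polygons_excluded"],
    )


def _read_csv(path, required_columns) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # noqa: BLE001 - name the file and cause
        raise InvalidInputError(f"cannot parse CSV {path}: {exc}") from exc
    missing = set(required_columns) - set(df.columns)
    if missing:
        raise InvalidInputError(f"{path}: missing columns {sorted(missing)}")
    return df
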