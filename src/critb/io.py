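"""Readers and writers for the pipeline's standard formats.

Rasters travel as ESRI ASCII grids (ncols/nrows/xllcorner/yllcorner/
cellsize/NODATA_value header, rows top-first), occurrences and villages
as CSV, expert range masks as GeoJSON polygons, binary range maps as
KML (one polygon per connected patch, cell-boundary outlines), and
assessment reports as JSON + CSV.
"""

from __future__ import annotations

import json
import xml.etree.ElementTree as ET
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
from shapely.geometry import box, shape
from shapely.ops import unary_union

from .grid import GridSpec, PointSet, Raster, connected_components
from .sdm import RangeMap

__all__ = [
    "read_asc",
    "write_asc",
    "read_occurrences_csv",
    "write_occurrences_csv",
    "read_villages_csv",
    "write_villages_csv",
    "read_expert_polygons",
    "write_range_kml",
    "write_assessment_report",
    "read_assessment_json",
]

_ASC_KEYS = ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize")


def read_asc(path: str | Path, kind: str = "continuous", categories: dict[int, str] | None = None) -> Raster:
    """Read an ESRI ASCII grid. Row 0 of the stored array is the *bottom* row."""
    path = Path(path)
    header: dict[str, float] = {}
    data_lines: list[str] = []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            key = parts[0].lower()
            if not data_lines and key in _ASC_KEYS + ("nodata_value",):
                header[key] = float(parts[1])
            else:
                data_lines.append(line)
    missing = [k for k in _ASC_KEYS if k not in header]
    if missing:
        raise ValueError(f"malformed ESRI ASCII header, missing: {missing}")
    ncols, nrows = int(header["ncols"]), int(header["nrows"])
    values = np.loadtxt(data_lines, ndmin=2)
    if values.shape != (nrows, ncols):
        raise ValueError(
            f"data block is {values.shape}, header declares ({nrows}, {ncols})"
        )
    spec = GridSpec(
        n_rows=nrows,
        n_cols=ncols,
        cell_size_km=header["cellsize"],
        origin_x_km=header["xllcorner"],
        origin_y_km=header["yllcorner"],
    )
    return Raster(
        spec,
        values[::-1],  # file stores top row first
        nodata=header.get("nodata_value", -9999.0),
        kind=kind,
        categories=categories,
    )


def write_asc(raster: Raster, path: str | Path, fmt: str = "%.8g") -> None:
    spec = raster.spec
    with open(path, "w") as fh:
        fh.write(f"ncols {spec.n_cols}\n")
        fh.write(f"nrows {spec.n_rows}\n")
        fh.write(f"xllcorner {spec.origin_x_km:.8g}\n")
        fh.write(f"yllcorner {spec.origin_y_km:.8g}\n")
        fh.write(f"cellsize {spec.cell_size_km:.8g}\n")
        fh.write(f"NODATA_value {raster.nodata:.8g}\n")
        np.savetxt(fh, raster.values[::-1], fmt=fmt)


def read_occurrences_csv(path: str | Path) -> PointSet:
    df = pd.read_csv(path)
    attrs = {"species": df["species"].to_numpy(dtype=object)}
    if "coord_error_km" in df.columns:
        attrs["coord_error_km"] = df["coord_error_km"].to_numpy(dtype=float)
    return PointSet(df[["x_km", "y_km"]].to_numpy(dtype=float), attrs)


def write_occurrences_csv(points: PointSet, path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "species": points.attributes.get(
                "species", np.array(["unknown"] * len(points), dtype=object)
            ),
            "x_km": points.x,
            "y_km": points.y,
            "coord_error_km": points.attributes.get("coord_error_km", np.zeros(len(points))),
        }
    )
    df.to_csv(path, index=False)


def read_villages_csv(path: str | Path) -> PointSet:
    df = pd.read_csv(path)
    return PointSet(
        df[["x_km", "y_km"]].to_numpy(dtype=float),
        {"population": df["population"].to_numpy(dtype=int)},
    )


def write_villages_csv(villages: PointSet, path: str | Path) -> None:
    pd.DataFrame(
        {
            "x_km": villages.x,
            "y_km": villages.y,
            "population": villages.attributes["population"],
        }
    ).to_csv(path, index=False)


def read_expert_polygons(path: str | Path) -> list:
    """Read polygons from a GeoJSON file (Feature/FeatureCollection/geometry)."""
    with open(path) as fh:
        gj = json.load(fh)
    geoms = []
    if gj.get("type") == "FeatureCollection":
        for feat in gj["features"]:
            geoms.append(shape(feat["geometry"]))
    elif gj.get("type") == "Feature":
        geoms.append(shape(gj["geometry"]))
    else:
        geoms.append(shape(gj))
    out = []
    for g in geoms:
        if g.geom_type == "MultiPolygon":
            out.extend(g.geoms)
        else:
            out.append(g)
    return out


_KML_NS = "http://www.opengis.net/kml/2.2"


def _polygon_element(parent: ET.Element, poly) -> None:
    p = ET.SubElement(parent, "Polygon")
    ob = ET.SubElement(ET.SubElement(p, "outerBoundaryIs"), "LinearRing")
    coords = " ".join(f"{x:.6f},{y:.6f},0" for x, y in poly.exterior.coords)
    ET.SubElement(ob, "coordinates").text = coords
    for ring in poly.interiors:
        ib = ET.SubElement(ET.SubElement(p, "innerBoundaryIs"), "LinearRing")
        ET.SubElement(ib, "coordinates").text = " ".join(
            f"{x:.6f},{y:.6f},0" for x, y in ring.coords
        )


def write_range_kml(range_map: RangeMap, path: str | Path, name: str = "range") -> None:
    """Write the range as KML: one placemark per connected patch.

    Patch outlines are the unions of the occupied cells' square
    boundaries (planar km coordinates; no geodetic reprojection).
    """
    mask = range_map.mask
    if not mask.cells.any():
        raise ValueError("cannot write KML for an empty range")
    spec = mask.spec
    patches = connected_components(mask)
    ET.register_namespace("", _KML_NS)
    kml = ET.Element(f"{{{_KML_NS}}}kml")
    doc = ET.SubElement(kml, "Document")
    ET.SubElement(doc, "name").text = name
    for pid in range(1, patches.n_patches + 1):
        i, j = np.nonzero(patches.labels == pid)
        boxes = [
            box(
                spec.origin_x_km + jj * spec.cell_size_km,
                spec.origin_y_km + ii * spec.cell_size_km,
                spec.origin_x_km + (jj + 1) * spec.cell_size_km,
                spec.origin_y_km + (ii + 1) * spec.cell_size_km,
            )
            for ii, jj in zip(i, j)
        ]
        geom = unary_union(boxes)
        pm = ET.SubElement(doc, "Placemark")
        ET.SubElement(pm, "name").text = f"{name} patch {pid}"
        if geom.geom_type == "Polygon":
            _polygon_element(pm, geom)
        else:  # diagonal-only contact can split the union into a MultiPolygon
            mg = ET.SubElement(pm, "MultiGeometry")
            for g in geom.geoms:
                _polygon_element(mg, g)
    ET.ElementTree(kml).write(path, xml_declaration=True, encoding="unicode")


_CSV_COLUMNS = [
    "species_id",
    "eoo_km2",
    "aoo_km2",
    "elev_min_m",
    "elev_max_m",
    "ra_lqh_percent",
    "severely_fragmented",
    "n_locations",
    "eoo_restricted",
    "aoo_restricted",
]


def write_assessment_report(records, out_dir: str | Path) -> tuple[Path, Path]:
    """Write assessment records as JSON (full) and CSV (one row per species).

    RA_LQH is printed with 2 decimals in the CSV. Returns the two paths.
    """
    from .assessment import AssessmentRecord  # local import to avoid a cycle

    if isinstance(records, AssessmentRecord):
        records = [records]
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    json_path = out_dir / "assessment.json"
    with open(json_path, "w") as fh:
        json.dump([asdict(r) for r in records], fh, indent=2, default=_json_default)
    rows = []
    for r in records:
        rows.append(
            {
                "species_id": r.species_id,
                "eoo_km2": r.range_metrics.eoo_km2,
                "aoo_km2": r.range_metrics.aoo_km2,
                "elev_min_m": r.range_metrics.elev_min_m,
                "elev_max_m": r.range_metrics.elev_max_m,
                "ra_lqh_percent": round(r.fragmentation.ra_lqh_percent, 2),
                "severely_fragmented": r.fragmentation.severely_fragmented,
                "n_locations": r.locations.n_locations,
                "eoo_restricted": r.screens["eoo_restricted"],
                "aoo_restricted": r.screens["aoo_restricted"],
            }
        )
    csv_path = out_dir / "assessment.csv"
    pd.DataFrame(rows, columns=_CSV_COLUMNS).to_csv(csv_path, index=False)
    return json_path, csv_path


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, frozenset):
        return sorted(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")


def read_assessment_json(path: str | Path) -> list[dict]:
    with open(path) as fh:
        return json.load(fh)


def write_bundle(bundle, out_dir: str | Path) -> Path:
    """Write every part of a synthetic landscape bundle to ``out_dir``.

    Layout: ``env_XX.asc`` per continuous layer, ``soil/vegetation/
    ecoregion/landuse/dem.asc``, ``true_suitability.asc``,
    ``occurrences.csv``, ``villages.csv`` and a ``truth.json`` sidecar
    holding the generating parameters and master seed.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for k, layer in enumerate(bundle.env_layers):
        write_asc(layer, out_dir / f"env_{k:02d}.asc")
    for nm in ("soil", "vegetation", "ecoregion", "landuse", "dem"):
        write_asc(getattr(bundle, nm), out_dir / f"{nm}.asc", fmt="%.8g")
    write_asc(bundle.true_suitability, out_dir / "true_suitability.asc")
    if bundle.occurrences is not None:
        write_occurrences_csv(bundle.occurrences, out_dir / "occurrences.csv")
    write_villages_csv(bundle.villages, out_dir / "villages.csv")
    with open(out_dir / "truth.json", "w") as fh:
        json.dump(
            {
                "seed": bundle.seed,
                "intercept": bundle.truth.intercept,
                "env_coefficients": list(bundle.truth.env_coefficients),
                "categorical_effects": bundle.truth.categorical_effects,
                "occupancy_threshold": bundle.truth.occupancy_threshold,
            },
            fh,
            indent=2,
            default=_json_default,
        )
    return out_dir
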