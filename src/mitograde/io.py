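"""Flat-file I/O: detections CSV/GeoJSON, region GeoJSON, score tables, reports.

Detections are the ingestion boundary of the pipeline — no whole-slide
raster format is ever read. Coordinates are normalized to microns on
ingest; the ``unit`` column (``px`` or ``um``) decides whether the slide's
microns-per-pixel is applied.

Dialects
--------
detections CSV  : header ``slide_id,x,y,unit,confidence``
regions GeoJSON : FeatureCollection of Polygons; a top-level ``metadata``
                  object carries ``mpp`` (and optionally ``unit``,
                  defaulting to ``px``) and ``slide_id``
scores CSV      : ``slide_id,reader_id,condition,score,specimen_type,
                  zone_x,zone_y,zone_radius_um``
confusion JSON  : ``{"labels": [1,2,3], "counts": [[...],[...],[...]]}``
"""

from __future__ import annotations

import csv
import json
import math
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from shapely.geometry import Polygon, mapping, shape
from shapely.geometry.polygon import orient

from .agreement import AgreementReport, ConfusionMatrix3
from .geometry import PointUm, SlideFrame
from .hotspots import HotspotResult, MitosisDetection

__all__ = [
    "read_detections",
    "write_detections",
    "read_regions",
    "write_regions",
    "hotspots_to_dict",
    "write_hotspots",
    "hotspots_to_geojson",
    "read_scores",
    "write_scores",
    "read_confusion_matrix",
    "write_confusion_matrix",
    "write_reports",
]

SCORE_COLUMNS = [
    "slide_id", "reader_id", "condition", "score",
    "specimen_type", "zone_x", "zone_y", "zone_radius_um",
]


class ParseError(ValueError):
    """Malformed input file; the message names the offending row."""


def _frame_from_extent(
    pts_um: Sequence[PointUm], mpp: float, slide_id: str
) -> SlideFrame:
    if pts_um:
        w = max(1, math.ceil(max(p.x for p in pts_um) / mpp) + 1)
        h = max(1, math.ceil(max(p.y for p in pts_um) / mpp) + 1)
    else:
        w = h = 1
    return SlideFrame(mpp=mpp, width_px=w, height_px=h, slide_id=slide_id)


def read_detections(
    path: str | Path, mpp: float | None = None
) -> tuple[list[MitosisDetection], SlideFrame]:
    """Read mitosis detections from CSV or GeoJSON, normalized to microns.

    For pixel-unit rows the microns-per-pixel must come either from the
    ``mpp`` argument or (GeoJSON) the file's metadata. The returned frame's
    extent is the tight pixel bounding box of the detections when the file
    does not state one.
    """
    path = Path(path)
    if path.suffix.lower() in {".json", ".geojson"}:
        return _read_detections_geojson(path, mpp)
    return _read_detections_csv(path, mpp)


def _read_detections_csv(
    path: Path, mpp: float | None
) -> tuple[list[MitosisDetection], SlideFrame]:
    dets: list[MitosisDetection] = []
    slide_id = ""
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        required = {"slide_id", "x", "y", "unit", "confidence"}
        if reader.fieldnames is None or not required <= set(reader.fieldnames):
            raise ParseError(
                f"{path}: expected header with columns {sorted(required)}"
            )
        for lineno, row in enumerate(reader, start=2):
            try:
                x, y = float(row["x"]), float(row["y"])
                conf = float(row["confidence"])
            except (TypeError, ValueError) as e:
                raise ParseError(f"{path} line {lineno}: {e}") from None
            unit = (row["unit"] or "").strip().lower()
            if unit == "px":
                if mpp is None:
                    raise ParseError(
                        f"{path} line {lineno}: pixel units but no mpp supplied"
                    )
                x, y = x * mpp, y * mpp
            elif unit != "um":
                raise ParseError(
                    f"{path} line {lineno}: unknown unit {unit!r} (use px or um)"
                )
            if not (0.0 <= conf <= 1.0):
                raise ParseError(
                    f"{path} line {lineno}: confidence {conf} outside [0, 1]"
                )
            slide_id = row["slide_id"] or slide_id
            dets.append(
                MitosisDetection(
                    pos=PointUm(x, y), confidence=conf,
                    id=f"{row['slide_id']}_r{lineno}",
                )
            )
    frame = _frame_from_extent([d.pos for d in dets], mpp or 1.0, slide_id)
    return dets, frame


def _read_detections_geojson(
    path: Path, mpp: float | None
) -> tuple[list[MitosisDetection], SlideFrame]:
    with open(path) as fh:
        doc = json.load(fh)
    meta = doc.get("metadata", {})
    mpp = mpp if mpp is not None else meta.get("mpp")
    unit = meta.get("unit", "px")
    slide_id = meta.get("slide_id", "")
    if unit == "px" and mpp is None:
        raise ParseError(f"{path}: pixel coordinates but no mpp in metadata")
    scale = mpp if unit == "px" else 1.0
    dets: list[MitosisDetection] = []
    for i, feat in enumerate(doc.get("features", [])):
        geom = feat.get("geometry") or {}
        if geom.get("type") != "Point":
            raise ParseError(f"{path} feature {i}: expected Point geometry")
        x, y = (float(v) * scale for v in geom["coordinates"][:2])
        conf = float(feat.get("properties", {}).get("confidence", 1.0))
        if not (0.0 <= conf <= 1.0):
            raise ParseError(f"{path} feature {i}: confidence outside [0, 1]")
        dets.append(
            MitosisDetection(pos=PointUm(x, y), confidence=conf,
                             id=f"{slide_id}_f{i}")
        )
    if "width_px" in meta and "height_px" in meta and mpp is not None:
        frame = SlideFrame(mpp=mpp, width_px=int(meta["width_px"]),
                           height_px=int(meta["height_px"]), slide_id=slide_id)
    else:
        frame = _frame_from_extent([d.pos for d in dets], mpp or 1.0, slide_id)
    return dets, frame


def write_detections(
    path: str | Path, dets: Sequence[MitosisDetection], slide_id: str = ""
) -> None:
    """Write detections as CSV in microns (full float precision)."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["slide_id", "x", "y", "unit", "confidence"])
        for d in dets:
            w.writerow([slide_id, repr(float(d.pos.x)), repr(float(d.pos.y)),
                        "um", repr(float(d.confidence))])


def read_regions(path: str | Path, mpp: float | None = None) -> list[Polygon]:
    """Read tumor-region polygons from GeoJSON, normalized to microns.

    Exterior rings are normalized counter-clockwise and holes clockwise;
    holes are honored by downstream point-in-polygon tests. A
    self-intersecting ring is a validation error, not silently repaired.
    """
    path = Path(path)
    with open(path) as fh:
        doc = json.load(fh)
    meta = doc.get("metadata", {})
    mpp = mpp if mpp is not None else meta.get("mpp")
    unit = meta.get("unit", "px")
    if unit == "px" and mpp is None:
        raise ParseError(f"{path}: pixel coordinates but no mpp in metadata")
    scale = mpp if unit == "px" else 1.0
    polys: list[Polygon] = []
    for i, feat in enumerate(doc.get("features", [])):
        geom = shape(feat["geometry"])
        if geom.geom_type == "MultiPolygon":
            parts = list(geom.geoms)
        elif geom.geom_type == "Polygon":
            parts = [geom]
        else:
            raise ParseError(
                f"{path} feature {i}: expected Polygon, got {geom.geom_type}"
            )
        for part in parts:
            if not part.is_valid:
                raise ParseError(
                    f"{path} feature {i}: invalid polygon (self-intersection?)"
                )
            scaled = Polygon(
                [(x * scale, y * scale) for x, y in part.exterior.coords],
                [[(x * scale, y * scale) for x, y in ring.coords]
                 for ring in part.interiors],
            )
            polys.append(orient(scaled))
    return polys


def write_regions(
    path: str | Path, polys: Sequence[Polygon], slide_id: str = ""
) -> None:
    """Write polygons (micron coordinates) as GeoJSON with unit metadata."""
    doc = {
        "type": "FeatureCollection",
        "metadata": {"unit": "um", "slide_id": slide_id},
        "features": [
            {"type": "Feature", "properties": {}, "geometry": mapping(p)}
            for p in polys
        ],
    }
    with open(path, "w") as fh:
        json.dump(doc, fh)


def hotspots_to_dict(result: HotspotResult) -> dict:
    """JSON-ready hotspot report: params echo + per-hotspot geometry/scores."""
    p = result.params
    return {
        "slide_id": result.slide_id,
        "params": {
            "core_area_mm2": p.core_area_mm2,
            "context_area_mm2": p.context_area_mm2,
            "epsilon": p.epsilon,
            "confidence_threshold": p.confidence_threshold,
            "top_k": p.top_k,
        },
        "hotspots": [
            {
                "rank": i + 1,
                "center_um": [c.center.x, c.center.y],
                "radius_um": p.context_radius_um,
                "n_core": c.n_core,
                "n_context": c.n_context,
                "score": c.score,
            }
            for i, c in enumerate(result.selected)
        ],
    }


def write_hotspots(path: str | Path, result: HotspotResult) -> None:
    with open(path, "w") as fh:
        json.dump(hotspots_to_dict(result), fh, indent=2)


def hotspots_to_geojson(result: HotspotResult, n_vertices: int = 64) -> dict:
    """Hotspot display zones as 64-gon polygon approximations for viewers."""
    feats = []
    r = result.params.context_radius_um
    theta = np.linspace(0.0, 2.0 * np.pi, n_vertices, endpoint=False)
    for i, c in enumerate(result.selected):
        ring = [
            (c.center.x + r * math.cos(t), c.center.y + r * math.sin(t))
            for t in theta
        ]
        ring.append(ring[0])
        feats.append(
            {
                "type": "Feature",
                "properties": {
                    "rank": i + 1, "score": c.score,
                    "n_core": c.n_core, "n_context": c.n_context,
                },
                "geometry": {"type": "Polygon", "coordinates": [ring]},
            }
        )
    return {
        "type": "FeatureCollection",
        "metadata": {"unit": "um", "slide_id": result.slide_id},
        "features": feats,
    }


def read_scores(path: str | Path) -> pd.DataFrame:
    """Read a reader-score table; validates scores are in {1, 2, 3}."""
    df = pd.read_csv(path)
    missing = {"slide_id", "reader_id", "condition", "score"} - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing columns {sorted(missing)}")
    bad = ~df["score"].isin([1, 2, 3])
    if bad.any():
        rows = (df.index[bad] + 2).tolist()
        raise ParseError(f"{path}: scores outside {{1,2,3}} at lines {rows}")
    return df


def write_scores(path: str | Path, records: pd.DataFrame) -> None:
    cols = [c for c in SCORE_COLUMNS if c in records.columns]
    records.to_csv(path, index=False, columns=cols)


def read_confusion_matrix(path: str | Path) -> ConfusionMatrix3:
    with open(path) as fh:
        doc = json.load(fh)
    return ConfusionMatrix3(np.asarray(doc["counts"], dtype=float))


def write_confusion_matrix(path: str | Path, cm: ConfusionMatrix3) -> None:
    with open(path, "w") as fh:
        json.dump(
            {"labels": [1, 2, 3],
             "counts": cm.counts.astype(int).tolist(),
             "orientation": "rows=rater A (investigator), cols=rater B (consensus)"},
            fh, indent=2,
        )


def write_reports(
    json_path: str | Path | None,
    csv_path: str | Path | None,
    reports: Sequence[AgreementReport],
) -> None:
    """Write agreement reports as JSON and/or a flat CSV (one row each)."""
    rows = [r.to_row() for r in reports]
    if json_path is not None:
        with open(json_path, "w") as fh:
            json.dump(rows, fh, indent=2)
    if csv_path is not None:
        pd.DataFrame(rows).to_csv(csv_path, index=False)
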