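"""Plain-text interchange: GeoJSON scenes, CSV cells/cohorts/matrices,
JSON models, YAML configs."""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from shapely import wkt as shapely_wkt
from shapely.geometry import Polygon

from .records import CellRecord
from .regression import LinearModel
from .synthetic import CohortConfig, SceneConfig, SceneGroundTruth


def scene_to_geojson(scene: SceneGroundTruth) -> dict:
    """Scene as a GeoJSON FeatureCollection: Point features for centers,
    Polygon features for contours (properties: class, grade, area)."""
    features = []
    for c in scene.cells:
        props = {"class": c.cell_class}
        if c.grade is not None:
            props["grade"] = c.grade
        if c.area is not None:
            props["area"] = c.area
        features.append({
            "type": "Feature",
            "geometry": {"type": "Point", "coordinates": [c.x, c.y]},
            "properties": props,
        })
        if c.contour is not None:
            ring = c.contour.tolist()
            ring.append(ring[0])
            features.append({
                "type": "Feature",
                "geometry": {"type": "Polygon", "coordinates": [ring]},
                "properties": props,
            })
    return {
        "type": "FeatureCollection",
        "features": features,
        "properties": {
            "canvas_width": scene.canvas_width,
            "canvas_height": scene.canvas_height,
            "magnification": scene.magnification_tag,
        },
    }


def geojson_to_cells(doc: dict) -> list[CellRecord]:
    """Cells from a FeatureCollection; contours re-attach to the point
    of the same class sharing their centroid position."""
    points = []
    polygons = []
    for feat in doc.get("features", []):
        geom = feat.get("geometry", {})
        props = feat.get("properties", {})
        if geom.get("type") == "Point":
            points.append((geom["coordinates"], props))
        elif geom.get("type") == "Polygon":
            polygons.append((geom["coordinates"][0], props))
    cells = []
    used = [False] * len(polygons)
    for (x, y), props in points:
        contour = None
        for i, (ring, _) in enumerate(polygons):
            if used[i]:
                continue
            poly = Polygon(ring)
            cx, cy = poly.centroid.x, poly.centroid.y
            if abs(cx - x) < 2.0 and abs(cy - y) < 2.0:
                contour = np.asarray(ring[:-1], dtype=float)
                used[i] = True
                break
        cells.append(CellRecord(
            cell_class=props["class"], x=float(x), y=float(y), contour=contour,
            area=props.get("area"), grade=props.get("grade"),
        ))
    return cells


def write_scene_geojson(scene: SceneGroundTruth, path) -> None:
    Path(path).write_text(json.dumps(scene_to_geojson(scene)))


def read_scene_geojson(path) -> SceneGroundTruth:
    doc = json.loads(Path(path).read_text())
    props = doc.get("properties", {})
    return SceneGroundTruth(
        cells=geojson_to_cells(doc),
        canvas_width=int(props["canvas_width"]),
        canvas_height=int(props["canvas_height"]),
        magnification_tag=props.get("magnification", "40x"),
    )


def cells_to_frame(cells: list[CellRecord]) -> pd.DataFrame:
    """Cells as a table with columns class,x,y[,area,contour_wkt]."""
    rows = []
    for c in cells:
        row = {"class": c.cell_class, "x": c.x, "y": c.y, "area": c.area,
               "grade": c.grade}
        if c.contour is not None:
            row["contour_wkt"] = shapely_wkt.dumps(Polygon(c.contour))
        rows.append(row)
    return pd.DataFrame(rows)


def frame_to_cells(df: pd.DataFrame) -> list[CellRecord]:
    cells = []
    for _, row in df.iterrows():
        contour = None
        if "contour_wkt" in row and isinstance(row["contour_wkt"], str):
            poly = shapely_wkt.loads(row["contour_wkt"])
            contour = np.asarray(poly.exterior.coords[:-1], dtype=float)
        area = row.get("area")
        grade = row.get("grade")
        cells.append(CellRecord(
            cell_class=row["class"], x=float(row["x"]), y=float(row["y"]),
            contour=contour,
            area=None if pd.isna(area) else float(area),
            grade=None if pd.isna(grade) else int(grade),
        ))
    return cells


def write_model_json(model: LinearModel, path) -> None:
    Path(path).write_text(json.dumps(model.to_dict(), indent=2))


def read_model_json(path) -> LinearModel:
    return LinearModel.from_dict(json.loads(Path(path).read_text()))


_CONFIG_TYPES = {"scene": SceneConfig, "cohort": CohortConfig}


def read_config_yaml(path, kind: str):
    """Load a SceneConfig ("scene") or CohortConfig ("cohort") from YAML."""
    if kind not in _CONFIG_TYPES:
        raise ValueError(f"unknown config kind {kind!r}")
    data = yaml.safe_load(Path(path).read_text()) or {}
    cls = _CONFIG_TYPES[kind]
    valid = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - valid
    if unknown:
        raise ValueError(f"unknown {kind} config keys: {sorted(unknown)}")
    if "grade_mix" in data:
        data["grade_mix"] = tuple(data["grade_mix"])
    return cls(**data)
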