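"""File formats and run configuration.

Conventions used everywhere: coordinates are 0-based (x, y) = (column,
row) with the origin at the top-left pixel; patch intervals are half-open.

Native annotation schemas are JSON (versioned ``schema`` tag); readers are
also provided for two third-party dialects: the XML polygon format written
by common slide annotators (Annotation/Coordinates/Coordinate elements)
and labelme-style JSON point shapes.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import xml.etree.ElementTree as ET
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .density import TumorRegion
from .synthdata import COHORT_COLUMNS

__all__ = [
    "write_points",
    "read_points",
    "write_region",
    "read_region",
    "read_region_xml",
    "read_labelme_points",
    "write_cohort",
    "read_cohort",
    "RunConfig",
    "stage_seed",
]

POINTS_SCHEMA = "viadens/points-v1"
REGION_SCHEMA = "viadens/region-v1"
CONFIG_SCHEMA = "viadens/config-v1"


@dataclasses.dataclass(frozen=True)
class PointAnnotationFile:
    image_id: str
    width: int
    height: int
    points: np.ndarray  # (n, 2) float (x, y)
    label: str = "viable"


def _check_bounds(points: np.ndarray, width: int, height: int, where: str) -> None:
    if len(points) == 0:
        return
    if (
        points[:, 0].min() < 0
        or points[:, 1].min() < 0
        or points[:, 0].max() > width - 1
        or points[:, 1].max() > height - 1
    ):
        raise ValueError(f"{where}: point coordinates outside image bounds")


def write_points(path, points, image_id: str, width: int, height: int,
                 label: str = "viable") -> None:
    pts = np.asarray(points, dtype=float).reshape(-1, 2)
    _check_bounds(pts, width, height, str(path))
    payload = {
        "schema": POINTS_SCHEMA,
        "image": image_id,
        "width": int(width),
        "height": int(height),
        "points": [{"x": float(x), "y": float(y), "label": label} for x, y in pts],
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def read_points(path) -> PointAnnotationFile:
    try:
        payload = json.loads(Path(path).read_text())
    except json.JSONDecodeError as e:
        raise ValueError(f"{path}: malformed JSON at line {e.lineno}: {e.msg}") from e
    for key in ("schema", "image", "width", "height", "points"):
        if key not in payload:
            raise ValueError(f"{path}: missing required key {key!r}")
    if payload["schema"] != POINTS_SCHEMA:
        raise ValueError(f"{path}: unknown schema {payload['schema']!r}")
    pts = np.array(
        [[p["x"], p["y"]] for p in payload["points"]], dtype=float
    ).reshape(-1, 2)
    _check_bounds(pts, payload["width"], payload["height"], str(path))
    labels = {p.get("label", "viable") for p in payload["points"]}
    return PointAnnotationFile(
        image_id=payload["image"],
        width=int(payload["width"]),
        height=int(payload["height"]),
        points=pts,
        label=labels.pop() if len(labels) == 1 else "viable",
    )


def write_region(path, region: TumorRegion) -> None:
    payload = {
        "schema": REGION_SCHEMA,
        "mpp": region.mpp,
        "polygons": [
            [[float(x), float(y)] for x, y in p.exterior.coords[:-1]]
            for p in region.polygons
        ],
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def read_region(path) -> TumorRegion:
    payload = json.loads(Path(path).read_text())
    if payload.get("schema") != REGION_SCHEMA:
        raise ValueError(f"{path}: unknown region schema {payload.get('schema')!r}")
    return TumorRegion.from_vertices(payload["polygons"], mpp=float(payload["mpp"]))


def read_region_xml(path, mpp: float) -> TumorRegion:
    """Import an annotator XML polygon file (Annotation/Coordinate elements)."""
    try:
        root = ET.parse(str(path)).getroot()
    except ET.ParseError as e:
        raise ValueError(f"{path}: malformed XML: {e}") from e
    rings = []
    for ann in root.iter("Annotation"):
        coords = []
        for c in ann.iter("Coordinate"):
            try:
                order = int(float(c.attrib.get("Order", len(coords))))
                coords.append((order, float(c.attrib["X"]), float(c.attrib["Y"])))
            except (KeyError, ValueError) as e:
                raise ValueError(
                    f"{path}: bad Coordinate element in Annotation "
                    f"{ann.attrib.get('Name', '?')}: {e}"
                ) from e
        if coords:
            coords.sort()
            rings.append([(x, y) for _, x, y in coords])
    if not rings:
        raise ValueError(f"{path}: no Annotation/Coordinate polygons found")
    return TumorRegion.from_vertices(rings, mpp=mpp)


def read_labelme_points(path) -> np.ndarray:
    """Points from a labelme-style JSON file (shape_type == 'point')."""
    payload = json.loads(Path(path).read_text())
    if "shapes" not in payload:
        raise ValueError(f"{path}: not a labelme file (no 'shapes' key)")
    pts = [
        s["points"][0]
        for s in payload["shapes"]
        if s.get("shape_type") == "point"
    ]
    return np.asarray(pts, dtype=float).reshape(-1, 2)


def write_cohort(path, cohort: pd.DataFrame) -> None:
    missing = set(COHORT_COLUMNS) - set(cohort.columns)
    if missing:
        raise ValueError(f"cohort table missing columns: {sorted(missing)}")
    cohort.to_csv(path, index=False)


def read_cohort(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(COHORT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: cohort CSV missing columns: {sorted(missing)}")
    df["dss_event"] = df["dss_event"].astype(bool)
    df["mfs_event"] = df["mfs_event"].astype(bool)
    return df


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed derived from one global seed.

    Hashing the stage name avoids seed collisions between stages while
    keeping every stage reproducible from the single run seed.
    """
    digest = hashlib.blake2b(
        f"{int(global_seed)}:{stage}".encode(), digest_size=4
    ).digest()
    return int.from_bytes(digest, "big") & 0x7FFFFFFF


@dataclasses.dataclass
class RunConfig:
    """Serializable configuration for a full pipeline run."""

    seed: int = 0
    outdir: str = "viadens_run"
    # synthetic data
    patch_size_px: int = 256
    n_viable_per_patch: int = 12
    n_distractor_per_patch: int = 8
    nucleus_radius_px: float = 20.0
    min_separation_px: float = 45.0
    noise_sd: float = 0.03
    n_patients: int = 15
    patches_per_patient: int = 2
    slide_tiles: int = 3  # slide is tiles x tiles patches
    mpp: float = 1.0
    # detector
    epochs: int = 12
    learning_rate: float = 1e-3
    target_sigma_px: float = 6.0
    peak_threshold: float = 0.3
    peak_min_distance_px: float = 20.0
    # evaluation
    match_radius_px: float = 20.0
    n_folds: int = 5
    # density / survival
    density_patch_size_px: int = 256
    cohort_n_patients: int = 200
    cohort_true_cutoff: float = 400.0
    cohort_hazard_ratio: float = 4.5
    cutoff_step: float = 50.0
    min_group: int = 5
    alpha: float = 0.05

    def to_yaml(self, path) -> None:
        payload = {"schema": CONFIG_SCHEMA, **dataclasses.asdict(self)}
        Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        payload = yaml.safe_load(Path(path).read_text())
        schema = payload.pop("schema", None)
        if schema != CONFIG_SCHEMA:
            raise ValueError(f"{path}: unknown config schema {schema!r}")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(payload) - known
        if unknown:
            raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
        return cls(**payload)
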