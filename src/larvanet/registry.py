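"""Fixed study inputs: species life-history table and the MPA registry.

The packaged tables cover the 14 study species (pelagic larval duration 7-75
days, living depths 3-100 m, one spawning window each, threatened/economic
category) and the 21 national MPAs with their areas, a species-occurrence
matrix, and boundary polygons.

The published study does not print MPA center coordinates, boundary
geometries, or the MNR/SMPA split per site; the packaged centers and
designations are SYNTHETIC placeholders laid out along the synthetic
coastline (latitudes ordered Jiangsu north to Fujian south), and boundaries
default to area-preserving circles around each center.  User-supplied
GeoJSON polygons can override the circles.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from shapely.geometry import Point, Polygon, mapping, shape

from larvanet.errors import SchemaError
from larvanet.synthetic_ocean import M_PER_DEG

VALID_CATEGORIES = {"threatened", "economic"}
VALID_DESIGNATIONS = {"MNR", "SMPA"}


@dataclass(frozen=True)
class SpeciesParams:
    """Life-history parameters and MPA occurrence flags for one species."""

    name: str
    taxon_class: str
    category: str  # "threatened" | "economic"
    pld_days: int
    living_depth_m: float
    spawning_window: tuple[int, int]  # (start month, end month), may wrap
    occurrence: dict[str, bool]  # mpa_id -> occurs

    @property
    def occupied_mpas(self) -> list[str]:
        return [m for m, f in self.occurrence.items() if f]

    @property
    def n_release_points(self) -> int:
        return sum(self.occurrence.values())


@dataclass(frozen=True)
class MPASite:
    """One marine protected area: release source and arrival target."""

    mpa_id: str
    center: tuple[float, float]  # (lon, lat) degrees
    area_km2: float
    boundary: Polygon
    designation: str  # "MNR" | "SMPA"


def _packaged(name: str):
    return resources.files("larvanet.data").joinpath(name)


def _read_table(source, default_name):
    if source is None:
        with resources.as_file(_packaged(default_name)) as p:
            return pd.read_csv(p)
    if isinstance(source, pd.DataFrame):
        return source.copy()
    return pd.read_csv(source)


def make_boundary(center: tuple[float, float], area_km2: float,
                  n_vertices: int = 128) -> Polygon:
    """Circular boundary of the given area around ``center``.

    The radius is sqrt(area/pi); vertices are placed with the local
    meters-per-degree scaling (longitude scaled by cos(latitude)) so the
    enclosed area matches ``area_km2`` to well within 1% at >= 64 vertices.
    """
    if area_km2 <= 0:
        raise ValueError(f"area_km2 must be positive, got {area_km2}")
    lon_c, lat_c = center
    r_m = math.sqrt(area_km2 * 1e6 / math.pi)
    # inflate so the discretized polygon (inscribed) keeps the target area
    r_m /= math.sqrt(math.sin(2 * math.pi / n_vertices)
                     * n_vertices / (2 * math.pi))
    theta = np.linspace(0.0, 2 * math.pi, n_vertices, endpoint=False)
    dlat = r_m * np.sin(theta) / M_PER_DEG
    dlon = r_m * np.cos(theta) / (M_PER_DEG * math.cos(math.radians(lat_c)))
    return Polygon(zip(lon_c + dlon, lat_c + dlat))


def polygon_area_km2(poly: Polygon, lat_ref: float | None = None) -> float:
    """Polygon area in km² under the local equirectangular metric."""
    if lat_ref is None:
        lat_ref = poly.centroid.y
    deg2_to_km2 = (M_PER_DEG / 1000.0) ** 2 * math.cos(math.radians(lat_ref))
    return poly.area * deg2_to_km2


def load_species_table(source=None, mpa_source=None) -> list[SpeciesParams]:
    """Parse the species parameter table (packaged fixture by default).

    ``source`` and ``mpa_source`` may be paths, file-like objects, or
    DataFrames; occurrence flags come from the MPA table's species columns.
    An empty source yields an empty list.
    """
    df = _read_table(source, "species.csv")
    if df.empty:
        return []
    required = ["name", "taxon_class", "category", "pld_days",
                "living_depth_m", "spawn_start_month", "spawn_end_month"]
    for col in required:
        if col not in df.columns:
            raise SchemaError(f"species table missing column '{col}'")
    mpa_df = _read_table(mpa_source, "mpa_sites.csv")
    species = []
    for idx, row in df.iterrows():
        name = str(row["name"])
        where = f"species row {idx} ({name})"
        try:
            pld = int(row["pld_days"])
        except (TypeError, ValueError):
            raise SchemaError(f"{where}: column 'pld_days' is not an integer")
        if pd.isna(row["pld_days"]) or pld <= 0:
            raise SchemaError(f"{where}: column 'pld_days' must be positive")
        depth = float(row["living_depth_m"])
        if depth <= 0:
            raise SchemaError(f"{where}: column 'living_depth_m' must be positive")
        category = str(row["category"]).strip().lower()
        if category not in VALID_CATEGORIES:
            raise SchemaError(f"{where}: column 'category' unknown value "
                              f"'{row['category']}'")
        m0, m1 = int(row["spawn_start_month"]), int(row["spawn_end_month"])
        if not (1 <= m0 <= 12 and 1 <= m1 <= 12):
            raise SchemaError(f"{where}: spawning months must be in 1..12")
        if name in mpa_df.columns:
            occurrence = dict(zip(mpa_df["mpa_id"].astype(str),
                                  mpa_df[name].astype(bool)))
        else:
            occurrence = {}
        species.append(SpeciesParams(
            name=name, taxon_class=str(row["taxon_class"]), category=category,
            pld_days=pld, living_depth_m=depth, spawning_window=(m0, m1),
            occurrence=occurrence))
    return species


def load_mpa_registry(source=None, boundaries=None) -> list[MPASite]:
    """Parse the MPA registry (packaged fixture by default).

    ``boundaries`` optionally maps mpa_id to a shapely Polygon (e.g. from
    `load_boundaries_geojson`) overriding the default circular boundary.
    """
    df = _read_table(source, "mpa_sites.csv")
    required = ["mpa_id", "designation", "center_lon", "center_lat", "area_km2"]
    for col in required:
        if col not in df.columns:
            raise SchemaError(f"MPA table missing column '{col}'")
    ids = df["mpa_id"].astype(str)
    dup = ids[ids.duplicated()]
    if len(dup):
        raise SchemaError(f"duplicate mpa_id: {sorted(set(dup))}")
    boundaries = boundaries or {}
    sites = []
    for idx, row in df.iterrows():
        mpa_id = str(row["mpa_id"])
        area = float(row["area_km2"])
        if area <= 0:
            raise SchemaError(f"MPA row {idx} ({mpa_id}): column 'area_km2' "
                              "must be positive")
        desig = str(row["designation"])
        if desig not in VALID_DESIGNATIONS:
            raise SchemaError(f"MPA row {idx} ({mpa_id}): column 'designation' "
                              f"unknown value '{desig}'")
        center = (float(row["center_lon"]), float(row["center_lat"]))
        poly = boundaries.get(mpa_id) or make_boundary(center, area)
        if not poly.contains(Point(center)) and mpa_id not in boundaries:
            raise SchemaError(f"MPA row {idx} ({mpa_id}): boundary does not "
                              "contain the center")
        sites.append(MPASite(mpa_id=mpa_id, center=center, area_km2=area,
                             boundary=poly, designation=desig))
    return sites


def occurrence_matrix(species: list[SpeciesParams],
                      sites: list[MPASite]) -> pd.DataFrame:
    """Boolean (n_mpas x n_species) occurrence matrix."""
    return pd.DataFrame(
        {sp.name: [bool(sp.occurrence.get(s.mpa_id, False)) for s in sites]
         for sp in species},
        index=[s.mpa_id for s in sites])


def load_boundaries_geojson(path) -> dict[str, Polygon]:
    """Read boundary overrides from a GeoJSON FeatureCollection.

    Features must carry an ``mpa_id`` property and Polygon geometry
    (WGS84 lon/lat).
    """
    with open(path) as fh:
        gj = json.load(fh)
    out = {}
    for feat in gj.get("features", []):
        mpa_id = feat.get("properties", {}).get("mpa_id")
        if mpa_id is None:
            raise SchemaError("GeoJSON feature missing 'mpa_id' property")
        out[str(mpa_id)] = shape(feat["geometry"])
    return out


def registry_to_geojson(sites: list[MPASite], path) -> None:
    """Export the registry (boundaries + metadata) as GeoJSON for mapping."""
    features = [
        {
            "type": "Feature",
            "properties": {
                "mpa_id": s.mpa_id,
                "designation": s.designation,
                "area_km2": s.area_km2,
                "center_lon": s.center[0],
                "center_lat": s.center[1],
            },
            "geometry": mapping(s.boundary),
        }
        for s in sites
    ]
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)
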