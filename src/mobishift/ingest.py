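"""Data model and I/O for origin/destination partitions, visits, coverage and SES scores.

The analysis uses two planar partitions of a city: small *origin* regions
(census-block scale, with resident populations) and coarser *destination*
zones in which pass-through visits are tallied.  Two geometric rules drive
everything downstream:

* **Exclusion** — any origin/destination pair whose polygons share at least
  one point (overlapping interiors *or* touching boundaries) is excluded
  from visit aggregation, because visits recorded in a zone adjacent to the
  home region are dominated by GPS jitter and local movement rather than
  travel.
* **Coverage container** — the sample coverage of an origin is read from the
  single destination zone that *fully* contains it.  Origins not fully
  contained in any zone ("straddling" origins) have undefined coverage and
  drop out of the analysis.

Coordinates are planar (km or projected metres); no geodesic math is done
here.  Files are GeoJSON FeatureCollections for partitions and plain CSV
(comma-separated, UTF-8, header row, no index column) for tabular inputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import mapping, shape
from shapely.strtree import STRtree

from .errors import FormatError, InputError, ValidationError

_AREA_EPS = 1e-9  # interiors overlapping by less than this are treated as disjoint

VISIT_COLUMNS = ["origin_id", "destination_id", "period", "mean_daily_visits"]
COVERAGE_COLUMNS = ["origin_id", "period", "coverage"]
SES_COLUMNS = ["origin_id", "er_score", "eo_score"]


@dataclass
class PartitionSet:
    """Polygons for one role (origin or destination) tiling a city.

    ``table`` is indexed by ``region_id`` and holds a ``geometry`` column of
    shapely polygons plus optional properties (``population``, ``straddles``,
    SES scores written by the simulator, ...).
    """

    role: str
    table: pd.DataFrame

    def __post_init__(self) -> None:
        if self.role not in ("origin", "destination"):
            raise ValidationError(f"partition role must be origin/destination, got {self.role!r}")
        if "geometry" not in self.table.columns:
            raise ValidationError("partition table must have a 'geometry' column")
        self.table.index.name = "region_id"

    def __len__(self) -> int:
        return len(self.table)

    @property
    def ids(self) -> np.ndarray:
        return self.table.index.to_numpy()

    @property
    def geometries(self) -> np.ndarray:
        return self.table["geometry"].to_numpy()

    def centroids(self) -> pd.DataFrame:
        """Centroid coordinates, columns ``x``/``y``, indexed by region id."""
        cents = shapely.centroid(self.geometries)
        return pd.DataFrame(
            {"x": shapely.get_x(cents), "y": shapely.get_y(cents)}, index=self.table.index
        )

    def validate(self) -> None:
        """Enforce the partition invariants.

        Raises :class:`ValidationError` on duplicate ids, invalid polygons, or
        overlapping interiors within the role.
        """
        idx = self.table.index
        if idx.has_duplicates:
            dupes = idx[idx.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate region_id in {self.role} partitions: {dupes[:5]}")
        geoms = self.geometries
        valid = shapely.is_valid(geoms)
        if not valid.all():
            bad = idx[~valid].tolist()
            raise ValidationError(f"invalid polygon(s) in {self.role} partitions: {bad[:5]}")
        # pairwise interior disjointness: candidate pairs from the spatial index,
        # overlap iff the intersection has positive area
        tree = STRtree(geoms)
        left, right = tree.query(geoms, predicate="intersects")
        keep = left < right
        left, right = left[keep], right[keep]
        if len(left):
            areas = shapely.area(shapely.intersection(geoms[left], geoms[right]))
            bad = areas > _AREA_EPS
            if bad.any():
                i, j = left[bad][0], right[bad][0]
                raise ValidationError(
                    f"{self.role} partitions {idx[i]!r} and {idx[j]!r} have overlapping interiors"
                )


@dataclass(frozen=True)
class ExclusionSet:
    """Origin/destination pairs dropped from visit aggregation."""

    pairs: frozenset = field(default_factory=frozenset)

    def __contains__(self, pair) -> bool:
        return tuple(pair) in self.pairs

    def __len__(self) -> int:
        return len(self.pairs)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(sorted(self.pairs), columns=["origin_id", "destination_id"])


def write_partitions(partitions: PartitionSet, path) -> None:
    """Write a :class:`PartitionSet` as a GeoJSON FeatureCollection.

    All non-geometry columns become feature properties; NaN properties are
    dropped so that absent optional fields round-trip as absent.
    """
    features = []
    prop_cols = [c for c in partitions.table.columns if c != "geometry"]
    for region_id, row in partitions.table.iterrows():
        props = {"region_id": region_id}
        for c in prop_cols:
            v = row[c]
            if isinstance(v, float) and np.isnan(v):
                continue
            if isinstance(v, (np.integer,)):
                v = int(v)
            elif isinstance(v, (np.floating,)):
                v = float(v)
            elif isinstance(v, (np.bool_,)):
                v = bool(v)
            props[c] = v
        features.append(
            {"type": "Feature", "geometry": mapping(row["geometry"]), "properties": props}
        )
    doc = {"type": "FeatureCollection", "features": features}
    Path(path).write_text(json.dumps(doc), encoding="utf-8")


def read_partitions(path, role: str) -> PartitionSet:
    """Read a GeoJSON FeatureCollection into a validated :class:`PartitionSet`."""
    try:
        doc = json.loads(Path(path).read_text(encoding="utf-8"))
    except json.JSONDecodeError as exc:
        raise FormatError(f"{path}: not valid JSON: {exc}") from exc
    if doc.get("type") != "FeatureCollection":
        raise FormatError(f"{path}: expected a GeoJSON FeatureCollection")
    ids, geoms, props_rows = [], [], []
    for k, feat in enumerate(doc.get("features", [])):
        props = dict(feat.get("properties") or {})
        if "region_id" not in props:
            raise FormatError(f"{path}: feature {k} is missing the region_id property")
        rid = props.pop("region_id")
        try:
            geom = shape(feat["geometry"])
        except Exception as exc:
            raise FormatError(f"{path}: feature {rid!r} has unreadable geometry: {exc}") from exc
        if not geom.is_valid:
            raise FormatError(f"{path}: feature {rid!r} has an invalid polygon")
        ids.append(rid)
        geoms.append(geom)
        props_rows.append(props)
    if len(set(ids)) != len(ids):
        seen: set = set()
        dupes = [rid for rid in ids if rid in seen or seen.add(rid)]
        raise FormatError(f"{path}: duplicate region_id: {sorted(set(map(str, dupes)))[:5]}")
    table = pd.DataFrame(props_rows, index=pd.Index(ids, name="region_id"))
    table.insert(0, "geometry", geoms)
    ps = PartitionSet(role=role, table=table)
    ps.validate()
    return ps


def find_excluded_pairs(origins: PartitionSet, destinations: PartitionSet) -> ExclusionSet:
    """All (origin, destination) pairs whose polygons share at least one point.

    "Adjacent and intersecting" is read conservatively as share-any-point, so
    boundary-touching (including corner-touching) pairs are excluded along
    with genuinely overlapping ones.
    """
    tree = STRtree(destinations.geometries)
    o_idx, d_idx = tree.query(origins.geometries, predicate="intersects")
    oids = origins.ids
    dids = destinations.ids
    return ExclusionSet(frozenset(zip(oids[o_idx], dids[d_idx])))


def coverage_container(origins: PartitionSet, destinations: PartitionSet) -> dict:
    """Map each origin to the destination zone fully containing it, or ``None``.

    Containment allows shared boundary points (an origin on the edge of its
    zone is still fully inside it); disjoint destination interiors guarantee
    at most one container per origin.
    """
    tree = STRtree(destinations.geometries)
    o_idx, d_idx = tree.query(origins.geometries, predicate="covered_by")
    oids = origins.ids
    dids = destinations.ids
    out: dict = {rid: None for rid in oids}
    for oi, di in zip(o_idx, d_idx):
        if out[oids[oi]] is not None:
            raise ValidationError(
                f"origin {oids[oi]!r} is covered by more than one destination zone; "
                "destination interiors are not disjoint"
            )
        out[oids[oi]] = dids[di]
    return out


def _read_csv(path, required_columns) -> pd.DataFrame:
    try:
        df = pd.read_csv(path)
    except Exception as exc:
        raise FormatError(f"{path}: cannot read CSV: {exc}") from exc
    missing = [c for c in required_columns if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")
    return df


def _rows(mask: pd.Series) -> list:
    # 1-based data row numbers (header is row 0) for error messages
    return (np.flatnonzero(mask.to_numpy()) + 1).tolist()[:5]


def read_visits(path) -> pd.DataFrame:
    """Read a per-period origin->destination mean-daily visit edge list.

    Columns: origin_id, destination_id, period, mean_daily_visits.
    Rejects negative counts and duplicate (origin, destination, period) keys.
    """
    df = _read_csv(path, VISIT_COLUMNS)
    v = pd.to_numeric(df["mean_daily_visits"], errors="coerce")
    bad = v.isna() | (v < 0)
    if bad.any():
        raise FormatError(f"{path}: non-numeric or negative mean_daily_visits at rows {_rows(bad)}")
    df["mean_daily_visits"] = v.astype(float)
    dup = df.duplicated(subset=["origin_id", "destination_id", "period"], keep=False)
    if dup.any():
        raise FormatError(
            f"{path}: duplicate (origin_id, destination_id, period) at rows {_rows(dup)}"
        )
    return df[VISIT_COLUMNS].copy()


def read_coverage(path) -> pd.DataFrame:
    """Read per-origin per-period sample coverage; absent rows mean undefined coverage."""
    df = _read_csv(path, COVERAGE_COLUMNS)
    c = pd.to_numeric(df["coverage"], errors="coerce")
    bad = c.isna() | (c <= 0)
    if bad.any():
        raise FormatError(f"{path}: non-numeric or non-positive coverage at rows {_rows(bad)}")
    df["coverage"] = c.astype(float)
    dup = df.duplicated(subset=["origin_id", "period"], keep=False)
    if dup.any():
        raise FormatError(f"{path}: duplicate (origin_id, period) at rows {_rows(dup)}")
    return df[COVERAGE_COLUMNS].copy()


def read_ses(path) -> pd.DataFrame:
    """Read per-origin SES index scores (ER and EO), indexed by origin_id.

    An optional ``city`` column labels multi-city inputs; a single implicit
    city is assumed when absent.
    """
    df = _read_csv(path, SES_COLUMNS)
    for col in ("er_score", "eo_score"):
        v = pd.to_numeric(df[col], errors="coerce")
        bad = ~np.isfinite(v)
        if bad.any():
            raise FormatError(f"{path}: non-finite {col} at rows {_rows(pd.Series(bad))}")
        df[col] = v.astype(float)
    dup = df["origin_id"].duplicated(keep=False)
    if dup.any():
        raise FormatError(f"{path}: duplicate origin_id at rows {_rows(dup)}")
    if "city" not in df.columns:
        df["city"] = "city"
    out = df.set_index("origin_id")[["er_score", "eo_score", "city"]]
    return out


def seifa_from_partitions(origins: PartitionSet, city: str = "synthetic") -> pd.DataFrame:
    """Build a SES score table from partition properties (er_score/eo_score)."""
    for col in ("er_score", "eo_score"):
        if col not in origins.table.columns:
            raise InputError(f"origin partitions carry no {col} property")
    out = origins.table[["er_score", "eo_score"]].astype(float).copy()
    out["city"] = city
    return out
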