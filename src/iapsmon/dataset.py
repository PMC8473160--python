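"""Geotagged annotated survey images: data model, clustering, cleaning,
chi-square-balanced splitting and class balancing.

Images captured metres apart share field of view, so a naive random
train/validation/test split leaks information between sets.  The remedy used
here is spatial: images closer than a threshold (default 40 m, comfortably
above the worst-case 36.1 m gap between consecutive geotags at 130 km/h and
1 Hz GPS) are merged into clusters by single-linkage transitive closure, and
whole clusters — never individual images — are assigned to the three sets.

Cluster assignment is a greedy chi-square balancing pass: clusters are
shuffled once with a recorded seed and added one at a time to whichever set's
chi-square goodness-of-fit against its target class distribution decreases
the most; if no set improves, the cluster falls back to the training set
(the largest target).  Targets are ``E_c(s) = fraction(s) * N_c`` with
``N_c`` the dataset-wide image count of class ``c``, so the three targets
sum to the full dataset.
"""

from __future__ import annotations

import json
import math
import warnings
from collections import Counter
from dataclasses import dataclass, field
from datetime import date, datetime
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from shapely.geometry import Polygon as ShapelyPolygon

from .errors import (
    CannotBalanceError,
    InvalidAnnotationError,
    InvalidCoordinateError,
    UndefinedStatisticError,
)
from .labels import IAPS_SPECIES, MULTIPLE_SPECIES, NO_SPECIES, check_label

__all__ = [
    "Annotation",
    "GeoImage",
    "Cluster",
    "SplitAssignment",
    "RemovalReport",
    "haversine_distance",
    "image_class",
    "build_clusters",
    "polygon_iou",
    "clean_dataset",
    "chi2_statistic",
    "cluster_class_counts",
    "split_clusters",
    "balance_upsample",
    "summarize",
    "load_images",
    "write_images_csv",
    "write_annotations_json",
    "read_cvat_xml",
    "write_split_manifest",
    "read_split_manifest",
]

EARTH_RADIUS_M = 6_371_000.0

SPLIT_SETS = ("train", "validation", "test")


# ---------------------------------------------------------------------------
# data model
# ---------------------------------------------------------------------------

@dataclass
class Annotation:
    """A species-labelled pixel polygon.

    Vertices are ``(x, y)`` pixel coordinates with origin top-left, x
    rightward, y downward.  The polygon must be simple (non
    self-intersecting) with at least 3 vertices and positive area.
    """

    polygon: list[tuple[float, float]]
    species: str

    def __post_init__(self) -> None:
        check_label(self.species)
        if self.species not in IAPS_SPECIES:
            raise InvalidAnnotationError(
                f"annotations carry IAPS labels only, got {self.species!r}"
            )
        if len(self.polygon) < 3:
            raise InvalidAnnotationError("polygon needs >= 3 vertices")
        shp = ShapelyPolygon(self.polygon)
        if not shp.is_valid:
            raise InvalidAnnotationError("polygon is self-intersecting or invalid")
        if shp.area <= 0:
            raise InvalidAnnotationError("polygon has zero area")

    def shapely(self) -> ShapelyPolygon:
        return ShapelyPolygon(self.polygon)

    @property
    def area(self) -> float:
        """Polygon area in px^2 (shoelace, via shapely)."""
        return self.shapely().area

    def bbox(self) -> tuple[float, float, float, float]:
        """Axis-aligned (x_min, y_min, x_max, y_max)."""
        xs = [p[0] for p in self.polygon]
        ys = [p[1] for p in self.polygon]
        return min(xs), min(ys), max(xs), max(ys)


@dataclass
class GeoImage:
    """One geotagged survey image with its annotations."""

    image_id: str
    latitude: float
    longitude: float
    timestamp: datetime
    acquisition_date: date
    width: int
    height: int
    annotations: list[Annotation] = field(default_factory=list)

    def __post_init__(self) -> None:
        _check_coords(self.latitude, self.longitude)
        if self.width <= 0 or self.height <= 0:
            raise InvalidAnnotationError("image dimensions must be positive")
        for ann in self.annotations:
            self._clip(ann)

    def _clip(self, ann: Annotation) -> None:
        # Vertices outside the frame are clipped to the bounds with a warning
        # (annotation tools occasionally export a vertex a pixel outside).
        clipped = False
        poly = []
        for x, y in ann.polygon:
            cx = min(max(x, 0.0), float(self.width))
            cy = min(max(y, 0.0), float(self.height))
            clipped = clipped or (cx != x or cy != y)
            poly.append((cx, cy))
        if clipped:
            warnings.warn(
                f"image {self.image_id}: polygon vertex outside "
                f"[0,{self.width}]x[0,{self.height}] clipped to bounds",
                stacklevel=3,
            )
            ann.polygon = poly

    @property
    def relative_annotation_area(self) -> float:
        """Combined annotation area / image area, capped at 1."""
        total = sum(a.area for a in self.annotations)
        return min(total / (self.width * self.height), 1.0)


@dataclass
class Cluster:
    """A spatial group of images; the unit of train/val/test assignment."""

    cluster_id: str
    image_ids: set[str]

    def __post_init__(self) -> None:
        if not self.image_ids:
            raise InvalidAnnotationError("cluster must be non-empty")


@dataclass
class RemovalReport:
    """Per-rule counts of images dropped by :func:`clean_dataset`."""

    multiple_species: int = 0
    overlapping_annotations: int = 0
    rare_class: int = 0
    rare_classes_removed: list[str] = field(default_factory=list)
    removed_image_ids: dict[str, list[str]] = field(default_factory=dict)

    @property
    def total(self) -> int:
        return self.multiple_species + self.overlapping_annotations + self.rare_class

    def to_dict(self) -> dict:
        return {
            "multiple_species": self.multiple_species,
            "overlapping_annotations": self.overlapping_annotations,
            "rare_class": self.rare_class,
            "rare_classes_removed": list(self.rare_classes_removed),
            "removed_image_ids": {k: list(v) for k, v in self.removed_image_ids.items()},
        }


@dataclass
class SplitStep:
    """One greedy assignment, for replay/audit of the split."""

    cluster_id: str
    chosen_set: str
    chi2_before: float
    chi2_after: float
    fallback: bool


@dataclass
class SplitAssignment:
    """Cluster -> set mapping plus the provenance needed to reproduce it."""

    assignment: dict[str, str]
    fractions: tuple[float, float, float]
    seed: int
    log: list[SplitStep] = field(default_factory=list)

    def image_sets(self, clusters: Sequence[Cluster]) -> dict[str, set[str]]:
        """Expand the cluster-level assignment to image-id sets."""
        out: dict[str, set[str]] = {s: set() for s in SPLIT_SETS}
        for c in clusters:
            out[self.assignment[c.cluster_id]].update(c.image_ids)
        return out


# ---------------------------------------------------------------------------
# geometry on the sphere
# ---------------------------------------------------------------------------

def _check_coords(lat: float, lon: float) -> None:
    if not (math.isfinite(lat) and math.isfinite(lon)):
        raise InvalidCoordinateError("coordinates must be finite")
    if abs(lat) > 90.0 or abs(lon) > 180.0:
        raise InvalidCoordinateError(f"invalid WGS84 coordinates ({lat}, {lon})")


def haversine_distance(a: tuple[float, float], b: tuple[float, float]) -> float:
    """Great-circle distance in metres between two (lat, lon) points.

    Spherical earth of radius 6,371,000 m; the ~2.5 m GNSS error of a
    consumer receiver is far below the 40 m clustering threshold and is
    ignored throughout.
    """
    _check_coords(*a)
    _check_coords(*b)
    lat1, lon1, lat2, lon2 = map(math.radians, (*a, *b))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    h = math.sin(dlat / 2) ** 2 + math.cos(lat1) * math.cos(lat2) * math.sin(dlon / 2) ** 2
    return 2.0 * EARTH_RADIUS_M * math.asin(min(1.0, math.sqrt(h)))


def _local_xy(lats: np.ndarray, lons: np.ndarray) -> np.ndarray:
    """Equirectangular projection to metres about the mean latitude.

    Metre-accurate at survey scale (tens of km), which is all the 40 m
    threshold needs; candidate pairs are re-checked with haversine anyway.
    """
    lat0 = float(np.mean(lats))
    x = np.radians(lons) * EARTH_RADIUS_M * math.cos(math.radians(lat0))
    y = np.radians(lats) * EARTH_RADIUS_M
    return np.column_stack([x, y])


# ---------------------------------------------------------------------------
# image class and clustering
# ---------------------------------------------------------------------------

def image_class(image: GeoImage) -> str:
    """Image-level class label.

    ``No species`` without annotations, the unique species when all
    annotations agree, ``Multiple species`` when two or more taxa co-occur.
    """
    species = {a.species for a in image.annotations}
    if not species:
        return NO_SPECIES
    if len(species) == 1:
        return next(iter(species))
    return MULTIPLE_SPECIES


def build_clusters(
    images: Sequence[GeoImage], threshold: float = 40.0
) -> list[Cluster]:
    """Single-linkage spatial clustering of images.

    Two images share a cluster iff they are connected by a chain of pairwise
    great-circle distances strictly below *threshold* metres.  The result is
    independent of input order; cluster ids are ``c0001``... ordered by the
    first (lexicographically smallest) image id in each cluster.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    if not images:
        return []
    lats = np.array([im.latitude for im in images])
    lons = np.array([im.longitude for im in images])
    xy = _local_xy(lats, lons)
    tree = cKDTree(xy)
    # 1% slack on the projected radius, then exact haversine confirmation.
    pairs = tree.query_pairs(threshold * 1.01, output_type="ndarray")

    parent = list(range(len(images)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i, j in pairs:
        d = haversine_distance(
            (images[i].latitude, images[i].longitude),
            (images[j].latitude, images[j].longitude),
        )
        if d < threshold:
            ri, rj = find(int(i)), find(int(j))
            if ri != rj:
                parent[rj] = ri

    groups: dict[int, set[str]] = {}
    for idx, im in enumerate(images):
        groups.setdefault(find(idx), set()).add(im.image_id)
    ordered = sorted(groups.values(), key=lambda ids: min(ids))
    return [
        Cluster(cluster_id=f"c{k:04d}", image_ids=ids)
        for k, ids in enumerate(ordered, start=1)
    ]


def polygon_iou(p: Annotation, q: Annotation) -> float:
    """Intersection over union of two annotation polygons, in [0, 1]."""
    sp, sq = p.shapely(), q.shapely()
    if sp.area <= 0 or sq.area <= 0:
        raise InvalidAnnotationError("IoU undefined for zero-area polygon")
    inter = sp.intersection(sq).area
    union = sp.union(sq).area
    return inter / union


# ---------------------------------------------------------------------------
# cleaning
# ---------------------------------------------------------------------------

def clean_dataset(
    images: Sequence[GeoImage],
    min_class_images: int = 30,
    iou_threshold: float = 0.75,
) -> tuple[list[GeoImage], RemovalReport]:
    """Remove ambiguous and under-represented images before splitting.

    Three rules: (1) images whose annotations span multiple taxa, removed to
    keep the image-level classification target unambiguous; (2) images with
    any annotation pair overlapping above *iou_threshold* IoU, removed to
    keep the detection target unambiguous; (3) images of classes that, after
    rules 1-2, have fewer than *min_class_images* images dataset-wide.  The
    rare-class counts are taken on the survivors of rules 1-2, which makes
    the operation idempotent.  Each removed image is attributed to exactly
    one rule, in the order above.
    """
    report = RemovalReport()
    report.removed_image_ids = {
        "multiple_species": [],
        "overlapping_annotations": [],
        "rare_class": [],
    }
    survivors: list[GeoImage] = []
    for im in images:
        if image_class(im) == MULTIPLE_SPECIES:
            report.multiple_species += 1
            report.removed_image_ids["multiple_species"].append(im.image_id)
            continue
        if _has_overlap(im, iou_threshold):
            report.overlapping_annotations += 1
            report.removed_image_ids["overlapping_annotations"].append(im.image_id)
            continue
        survivors.append(im)

    counts = Counter(image_class(im) for im in survivors)
    rare = {c for c, n in counts.items() if n < min_class_images}
    report.rare_classes_removed = sorted(rare)
    kept: list[GeoImage] = []
    for im in survivors:
        if image_class(im) in rare:
            report.rare_class += 1
            report.removed_image_ids["rare_class"].append(im.image_id)
        else:
            kept.append(im)
    return kept, report


def _has_overlap(image: GeoImage, iou_threshold: float) -> bool:
    anns = image.annotations
    for i in range(len(anns)):
        for j in range(i + 1, len(anns)):
            if polygon_iou(anns[i], anns[j]) > iou_threshold:
                return True
    return False


# ---------------------------------------------------------------------------
# chi-square balanced splitting
# ---------------------------------------------------------------------------

def chi2_statistic(
    observed: Mapping[str, float], expected: Mapping[str, float]
) -> float:
    """Chi-square goodness-of-fit, ``sum_c (O_c - E_c)^2 / E_c``.

    Classes with zero expected count are excluded from the sum; if every
    expected count is zero the statistic is undefined.
    """
    included = [c for c, e in expected.items() if e > 0]
    if not included:
        raise UndefinedStatisticError("all expected counts are zero")
    return float(
        sum((observed.get(c, 0.0) - expected[c]) ** 2 / expected[c] for c in included)
    )


def cluster_class_counts(
    images: Sequence[GeoImage], clusters: Sequence[Cluster]
) -> dict[str, Counter]:
    """Per-cluster image-class counts (the weights driving the split)."""
    by_id = {im.image_id: im for im in images}
    out: dict[str, Counter] = {}
    for c in clusters:
        out[c.cluster_id] = Counter(
            image_class(by_id[i]) for i in c.image_ids if i in by_id
        )
    return out


def split_clusters(
    clusters: Sequence[Cluster],
    class_counts: Mapping[str, Mapping[str, int]],
    fractions: tuple[float, float, float] = (0.70, 0.15, 0.15),
    seed: int = 0,
) -> SplitAssignment:
    """Greedy chi-square-balanced assignment of clusters to train/val/test.

    Clusters are shuffled once with *seed*, then assigned in order: each goes
    to the set whose chi-square against its target distribution
    ``E_c(s) = fraction(s) * N_c`` decreases the most when the cluster's
    class counts are added.  Ties prefer train > validation > test; if no
    set's chi-square decreases, the cluster falls back to train (logged).
    Deterministic given *seed*; every step is recorded for audit.
    """
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    if not clusters:
        return SplitAssignment(assignment={}, fractions=tuple(fractions), seed=seed)

    totals: Counter = Counter()
    for cid in (c.cluster_id for c in clusters):
        totals.update(class_counts.get(cid, {}))
    expected = {
        s: {c: f * n for c, n in totals.items()}
        for s, f in zip(SPLIT_SETS, fractions)
    }

    rng = np.random.default_rng(seed)
    order = list(clusters)
    rng.shuffle(order)

    current: dict[str, Counter] = {s: Counter() for s in SPLIT_SETS}
    assignment: dict[str, str] = {}
    log: list[SplitStep] = []
    for cluster in order:
        counts = Counter(class_counts.get(cluster.cluster_id, {}))
        best_set, best_delta = None, 0.0
        deltas = {}
        for s in SPLIT_SETS:
            before = chi2_statistic(current[s], expected[s])
            after = chi2_statistic(current[s] + counts, expected[s])
            deltas[s] = (before, after)
            delta = after - before
            if delta < best_delta - 1e-12:
                best_set, best_delta = s, delta
        fallback = best_set is None
        chosen = "train" if fallback else best_set
        before, after = deltas[chosen]
        current[chosen] += counts
        assignment[cluster.cluster_id] = chosen
        log.append(
            SplitStep(
                cluster_id=cluster.cluster_id,
                chosen_set=chosen,
                chi2_before=before,
                chi2_after=after,
                fallback=fallback,
            )
        )
    return SplitAssignment(
        assignment=assignment, fractions=tuple(fractions), seed=seed, log=log
    )


# ---------------------------------------------------------------------------
# class balancing and summaries
# ---------------------------------------------------------------------------

def balance_upsample(images: Sequence[GeoImage]) -> list[GeoImage]:
    """Balance classes by cyclic repetition up to the majority-class count.

    Every class's images are repeated in their input order, cycling, until
    the class matches the most represented class (typically the background
    class).  The returned list is a multiset: distinct images are unchanged,
    only multiplicities grow.
    """
    if not images:
        return []
    by_class: dict[str, list[GeoImage]] = {}
    for im in images:
        by_class.setdefault(image_class(im), []).append(im)
    for cls, members in by_class.items():
        if not members:
            raise CannotBalanceError(f"class {cls!r} has no images")
    target = max(len(v) for v in by_class.values())
    out: list[GeoImage] = list(images)
    for members in by_class.values():
        deficit = target - len(members)
        for k in range(deficit):
            out.append(members[k % len(members)])
    return out


def summarize(
    images: Sequence[GeoImage],
    clusters: Sequence[Cluster] | None = None,
    split: SplitAssignment | None = None,
) -> pd.DataFrame:
    """Per-class bookkeeping table of clusters (C), images (I), polygons (P).

    Grouped by split set when *split* is given, by acquisition date
    otherwise.  ``I`` counts images by their image-level class; ``P`` counts
    that class's polygons in those images (for the multiple-species row,
    all polygons in its images).
    """
    cluster_of: dict[str, str] = {}
    if clusters:
        for c in clusters:
            for i in c.image_ids:
                cluster_of[i] = c.cluster_id

    if split is not None and clusters is not None:
        group_of = {
            i: split.assignment[cid]
            for c in clusters
            for cid, i in ((c.cluster_id, img) for img in c.image_ids)
        }
        groups = list(SPLIT_SETS)
    else:
        group_of = {im.image_id: im.acquisition_date.isoformat() for im in images}
        groups = sorted({v for v in group_of.values()})

    rows: dict[str, dict] = {}
    for im in images:
        g = group_of.get(im.image_id)
        if g is None:
            continue
        cls = image_class(im)
        rec = rows.setdefault(cls, {})
        cell = rec.setdefault(g, {"C": set(), "I": 0, "P": 0})
        cell["I"] += 1
        if im.image_id in cluster_of:
            cell["C"].add(cluster_of[im.image_id])
        if cls == MULTIPLE_SPECIES:
            cell["P"] += len(im.annotations)
        else:
            cell["P"] += sum(1 for a in im.annotations if a.species == cls)

    columns = pd.MultiIndex.from_product([groups, ["C", "I", "P"]])
    table = pd.DataFrame(0, index=sorted(rows), columns=columns)
    for cls, rec in rows.items():
        for g, cell in rec.items():
            table.loc[cls, (g, "C")] = len(cell["C"])
            table.loc[cls, (g, "I")] = cell["I"]
            table.loc[cls, (g, "P")] = cell["P"]
    return table


# ---------------------------------------------------------------------------
# I/O: CSV metadata + JSON annotations, CVAT XML, split manifest
# ---------------------------------------------------------------------------

_CSV_COLUMNS = ["image_id", "timestamp", "lat", "lon", "date", "width", "height"]


def write_images_csv(images: Sequence[GeoImage], path: str | Path) -> None:
    """Image metadata CSV: image_id, timestamp (ISO-8601), lat, lon, date, width, height."""
    rows = [
        {
            "image_id": im.image_id,
            "timestamp": im.timestamp.isoformat(),
            "lat": im.latitude,
            "lon": im.longitude,
            "date": im.acquisition_date.isoformat(),
            "width": im.width,
            "height": im.height,
        }
        for im in images
    ]
    pd.DataFrame(rows, columns=_CSV_COLUMNS).to_csv(path, index=False)


def write_annotations_json(images: Sequence[GeoImage], path: str | Path) -> None:
    """Annotations as a JSON list of {image_id, species, polygon}."""
    records = [
        {"image_id": im.image_id, "species": a.species, "polygon": [list(p) for p in a.polygon]}
        for im in images
        for a in im.annotations
    ]
    Path(path).write_text(json.dumps(records, indent=1))


def load_images(
    metadata_csv: str | Path, annotations_json: str | Path | None = None
) -> list[GeoImage]:
    """Load the documented CSV/JSON schema back into :class:`GeoImage`s."""
    meta = pd.read_csv(metadata_csv, dtype={"image_id": str})
    anns_by_image: dict[str, list[Annotation]] = {}
    if annotations_json is not None:
        for rec in json.loads(Path(annotations_json).read_text()):
            ann = Annotation(
                polygon=[tuple(p) for p in rec["polygon"]], species=rec["species"]
            )
            anns_by_image.setdefault(str(rec["image_id"]), []).append(ann)
    images = []
    for row in meta.itertuples(index=False):
        images.append(
            GeoImage(
                image_id=str(row.image_id),
                latitude=float(row.lat),
                longitude=float(row.lon),
                timestamp=datetime.fromisoformat(str(row.timestamp)),
                acquisition_date=date.fromisoformat(str(row.date)),
                width=int(row.width),
                height=int(row.height),
                annotations=anns_by_image.get(str(row.image_id), []),
            )
        )
    return images


def read_cvat_xml(path: str | Path) -> dict[str, list[Annotation]]:
    """Import polygon annotations from a CVAT images-export XML file.

    Returns a mapping image name -> annotations.  Only ``<polygon>`` elements
    are read; points are the semicolon-separated ``x,y`` pairs of the CVAT
    dialect.
    """
    import xml.etree.ElementTree as ET

    root = ET.parse(path).getroot()
    out: dict[str, list[Annotation]] = {}
    for image_el in root.iter("image"):
        name = image_el.get("name", "")
        anns = []
        for poly_el in image_el.iter("polygon"):
            pts = [
                (float(x), float(y))
                for x, y in (pair.split(",") for pair in poly_el.get("points", "").split(";"))
            ]
            anns.append(Annotation(polygon=pts, species=poly_el.get("label", "")))
        out[name] = anns
    return out


def write_split_manifest(
    split: SplitAssignment,
    path: str | Path,
    removal_report: RemovalReport | None = None,
) -> None:
    manifest = {
        "seed": split.seed,
        "fractions": list(split.fractions),
        "assignment": split.assignment,
        "log": [
            {
                "cluster_id": s.cluster_id,
                "set": s.chosen_set,
                "chi2_before": s.chi2_before,
                "chi2_after": s.chi2_after,
                "fallback": s.fallback,
            }
            for s in split.log
        ],
        "removal_report": removal_report.to_dict() if removal_report else None,
    }
    Path(path).write_text(json.dumps(manifest, indent=1))


def read_split_manifest(path: str | Path) -> SplitAssignment:
    data = json.loads(Path(path).read_text())
    return SplitAssignment(
        assignment=data["assignment"],
        fractions=tuple(data["fractions"]),
        seed=data["seed"],
        log=[
            SplitStep(
                cluster_id=s["cluster_id"],
                chosen_set=s["set"],
                chi2_before=s["chi2_before"],
                chi2_after=s["chi2_after"],
                fallback=s["fallback"],
            )
            for s in data.get("log", [])
        ],
    )
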