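"""Aggregate geotagged predictions into species occurrence map markers.

The camera frames faster than the GPS fixes, so several images (and their
predictions) share each fix; the map therefore has one marker per (GPS fix,
species) with at least one invasive prediction, carrying the number of
supporting images and the maximum confidence.  Background predictions never
produce markers.  At constant speed v (km/h) and fix rate r (Hz) consecutive
markers are v/(3.6 r) metres apart — 27.8 m at 100 km/h and 1 Hz.

GeoJSON (RFC 7946) is the canonical export; a CSV marker table is also
provided.  Rendering an HTML map is deliberately left to downstream tools —
the GeoJSON drops straight into any web map.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from datetime import date
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .dataset import GeoImage
from .detection import ImagePrediction
from .errors import VocabularyError
from .labels import is_iaps
from .synthetic import GpsFix

__all__ = [
    "MapMarker",
    "aggregate_markers",
    "filter_markers",
    "export_geojson",
    "load_geojson",
    "markers_to_csv",
]


@dataclass(frozen=True)
class MapMarker:
    latitude: float
    longitude: float
    species: str
    date: date
    count: int
    max_confidence: float

    def __post_init__(self) -> None:
        if not is_iaps(self.species):
            raise VocabularyError("markers are produced for invasive species only")
        if self.count < 1:
            raise ValueError("a marker needs at least one supporting prediction")


def aggregate_markers(
    predictions: Sequence[ImagePrediction],
    images: Mapping[str, GeoImage] | Sequence[GeoImage],
    fixes: Sequence[GpsFix],
) -> list[MapMarker]:
    """Group invasive predictions by their nearest GPS fix in time.

    Each prediction is located at the fix closest to its image's timestamp;
    one marker is emitted per (fix, species).  Predictions timestamped
    outside the track span (beyond half a fix interval past either end) are
    excluded with a warning.
    """
    if not fixes:
        return []
    if not isinstance(images, Mapping):
        images = {im.image_id: im for im in images}
    times = [f.timestamp for f in fixes]
    if len(times) > 1:
        half_gap = (times[1] - times[0]).total_seconds() / 2.0
    else:
        half_gap = 0.5
    groups: dict[tuple[int, str], list[tuple[ImagePrediction, GeoImage]]] = {}
    for pred in predictions:
        if not is_iaps(pred.label):
            continue
        im = images.get(pred.image_id)
        if im is None:
            warnings.warn(f"prediction for unknown image {pred.image_id!r} skipped")
            continue
        offsets = [(im.timestamp - t).total_seconds() for t in times]
        k = min(range(len(times)), key=lambda j: abs(offsets[j]))
        if abs(offsets[k]) > half_gap + 1e-9:
            warnings.warn(
                f"prediction for image {pred.image_id!r} falls outside the track "
                "span and was excluded"
            )
            continue
        groups.setdefault((k, pred.label), []).append((pred, im))

    markers = []
    for (k, species), members in sorted(groups.items()):
        fix = fixes[k]
        markers.append(
            MapMarker(
                latitude=fix.latitude,
                longitude=fix.longitude,
                species=species,
                date=members[0][1].acquisition_date,
                count=len(members),
                max_confidence=max(p.confidence for p, _ in members),
            )
        )
    return markers


def filter_markers(
    markers: Sequence[MapMarker],
    species: Sequence[str] | None = None,
    date_range: tuple[date, date] | None = None,
) -> list[MapMarker]:
    """Markers matching both a species subset and an inclusive date range."""
    out = []
    for m in markers:
        if species is not None and m.species not in species:
            continue
        if date_range is not None and not (date_range[0] <= m.date <= date_range[1]):
            continue
        out.append(m)
    return out


def export_geojson(markers: Sequence[MapMarker], path: str | Path) -> None:
    """RFC 7946 FeatureCollection of Point features, coordinates (lon, lat)."""
    collection = {
        "type": "FeatureCollection",
        "features": [
            {
                "type": "Feature",
                "geometry": {
                    "type": "Point",
                    "coordinates": [m.longitude, m.latitude],
                },
                "properties": {
                    "species": m.species,
                    "date": m.date.isoformat(),
                    "count": m.count,
                    "confidence": m.max_confidence,
                },
            }
            for m in markers
        ],
    }
    Path(path).write_text(json.dumps(collection, indent=1))


def load_geojson(path: str | Path) -> list[MapMarker]:
    """Inverse of :func:`export_geojson`."""
    collection = json.loads(Path(path).read_text())
    markers = []
    for feature in collection.get("features", []):
        lon, lat = feature["geometry"]["coordinates"]
        props = feature["properties"]
        markers.append(
            MapMarker(
                latitude=lat,
                longitude=lon,
                species=props["species"],
                date=date.fromisoformat(props["date"]),
                count=props["count"],
                max_confidence=props["confidence"],
            )
        )
    return markers


def markers_to_csv(markers: Sequence[MapMarker], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "lat": m.latitude,
                "lon": m.longitude,
                "species": m.species,
                "date": m.date.isoformat(),
                "count": m.count,
                "max_confidence": m.max_confidence,
            }
            for m in markers
        ]
    ).to_csv(path, index=False)
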