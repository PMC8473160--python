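"""Seeded generator of synthetic roadside surveys.

No public image archive exists for vehicle-mounted roadside IAPS surveys, so
every other module is exercised against scenarios generated here: a
road-following GPS track, plant patches clustered along the road, geotagged
images with single-species polygon annotations of controllable relative
size, label predictions drawn from a configurable confusion kernel, and
(optionally) rendered pixel rasters.

What the generator emulates, and how:

* the vehicle drives the road polyline at constant speed; GPS fixes fall
  every ``1/gps_rate`` seconds, i.e. every ``v/3.6/gps_rate`` metres;
* one image is captured per coverage interval (default 6.2 m of roadside per
  image); images are geotagged from the **nearest GPS fix** by default, so
  consecutive geotags jump in fix-sized steps exactly like a real logger
  (``geotag="exact"`` disables the quantisation);
* plants grow in patches: an image whose roadside interval overlaps a patch
  receives 1-3 polygons of the patch species, with combined relative area
  drawn from a Beta distribution centred on the patch mean (concentration
  10) and the polygons laid out in disjoint vertical slots so they never
  overlap each other;
* capture is either continuous (``capture_margin_m=None``) or triggered near
  patches only (a patch +/- margin window, emulating a driver-operated
  record button with a ring buffer), which keeps background images from
  chaining every patch into a single 40 m cluster;
* predictions are sampled per image from the row of a row-stochastic
  confusion kernel corresponding to the true class, with confidences from a
  Beta(5, 2).

All randomness flows from one seeded generator; identical scenario + seed
give identical outputs.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field, asdict
from datetime import date, datetime, timedelta, timezone
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml

from .dataset import Annotation, GeoImage
from .detection import ImagePrediction
from .errors import InvalidKernelError, InvalidScenarioError
from .geometry import KMH_TO_MS
from .labels import NO_SPECIES, RETAINED_SPECIES, check_label, is_iaps
from .dataset import EARTH_RADIUS_M

__all__ = [
    "Patch",
    "SurveyScenario",
    "GpsFix",
    "generate_track",
    "generate_images",
    "generate_predictions",
    "render_image",
    "RenderStyle",
    "example_scenario",
    "example_kernel",
    "identity_kernel",
]

_EPOCH = datetime(2020, 9, 15, 10, 0, 0, tzinfo=timezone.utc)


@dataclass(frozen=True)
class GpsFix:
    timestamp: datetime
    latitude: float
    longitude: float


@dataclass
class Patch:
    """A contiguous single-species stand along the road."""

    position_m: float          # start of patch, metres along the road
    species: str
    length_m: float = 30.0
    mean_relative_area: float = 0.25   # mean combined annotation area / image area

    def __post_init__(self) -> None:
        check_label(self.species)
        if not is_iaps(self.species):
            raise InvalidScenarioError("patches must carry an IAPS label")
        if self.length_m <= 0:
            raise InvalidScenarioError("patch length must be positive")
        if not 0.0 < self.mean_relative_area < 1.0:
            raise InvalidScenarioError("mean_relative_area must be in (0, 1)")


@dataclass
class SurveyScenario:
    """Complete description of one synthetic survey run."""

    road: list[tuple[float, float]]            # (lat, lon) polyline
    speed_kmh: float = 110.0
    gps_rate_hz: float = 1.0
    coverage_m: float = 6.2                    # roadside metres per image
    patches: list[Patch] = field(default_factory=list)
    kernel: dict[str, dict[str, float]] | None = None
    image_width: int = 4000
    image_height: int = 3000
    capture_margin_m: float | None = None      # None = continuous capture
    geotag: str = "gps"                        # "gps" (nearest fix) | "exact"
    acquisition_date: date = date(2020, 9, 15)
    beta_concentration: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.road) < 2:
            raise InvalidScenarioError("road polyline needs >= 2 vertices")
        if self.coverage_m <= 0:
            raise InvalidScenarioError("coverage must be positive")
        if self.gps_rate_hz <= 0:
            raise InvalidScenarioError("gps_rate must be positive")
        if self.speed_kmh < 0:
            raise InvalidScenarioError("speed must be non-negative")
        if self.geotag not in ("gps", "exact"):
            raise InvalidScenarioError("geotag must be 'gps' or 'exact'")
        length = _polyline_length(self.road)
        if length <= 0:
            raise InvalidScenarioError("road has zero length")
        for p in self.patches:
            if not 0 <= p.position_m <= length:
                raise InvalidScenarioError(
                    f"patch at {p.position_m} m outside the {length:.0f} m road"
                )

    # -- serialisation ----------------------------------------------------
    def to_yaml(self, path: str | Path) -> None:
        data = asdict(self)
        data["road"] = [list(p) for p in self.road]
        data["acquisition_date"] = self.acquisition_date.isoformat()
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SurveyScenario":
        data = yaml.safe_load(Path(path).read_text())
        data["road"] = [tuple(p) for p in data["road"]]
        data["patches"] = [Patch(**p) for p in data.get("patches", [])]
        if isinstance(data.get("acquisition_date"), str):
            data["acquisition_date"] = date.fromisoformat(data["acquisition_date"])
        return cls(**data)


# ---------------------------------------------------------------------------
# flat-earth road parameterisation
# ---------------------------------------------------------------------------

def _segment_lengths(road: Sequence[tuple[float, float]]) -> np.ndarray:
    lat0 = road[0][0]
    kx = EARTH_RADIUS_M * math.cos(math.radians(lat0)) * math.pi / 180.0
    ky = EARTH_RADIUS_M * math.pi / 180.0
    pts = np.array([(lon * kx, lat * ky) for lat, lon in road])
    return np.linalg.norm(np.diff(pts, axis=0), axis=1)


def _polyline_length(road: Sequence[tuple[float, float]]) -> float:
    return float(_segment_lengths(road).sum())


def _point_at(road: Sequence[tuple[float, float]], s: float) -> tuple[float, float]:
    """Linear interpolation of (lat, lon) at arc length *s* along the road."""
    seg = _segment_lengths(road)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    s = min(max(s, 0.0), float(cum[-1]))
    i = int(np.searchsorted(cum, s, side="right") - 1)
    i = min(i, len(seg) - 1)
    t = (s - cum[i]) / seg[i] if seg[i] > 0 else 0.0
    lat = road[i][0] + t * (road[i + 1][0] - road[i][0])
    lon = road[i][1] + t * (road[i + 1][1] - road[i][1])
    return lat, lon


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------

def generate_track(scenario: SurveyScenario) -> list[GpsFix]:
    """GPS fixes along the road, spaced by ``speed/3.6/gps_rate`` metres.

    A stationary vehicle produces a single fix at the road start.
    """
    length = _polyline_length(scenario.road)
    spacing = scenario.speed_kmh * KMH_TO_MS / scenario.gps_rate_hz
    if spacing == 0:
        times_positions = [(0.0, 0.0)]
    else:
        n = int(math.floor(length / spacing + 1e-9)) + 1
        times_positions = [(k / scenario.gps_rate_hz, k * spacing) for k in range(n)]
        # terminal fix where (and when) the vehicle reaches the road end, so
        # the track's time span covers the whole drive
        last = times_positions[-1][1]
        if length - last > 0.01 * spacing:
            v_ms = scenario.speed_kmh * KMH_TO_MS
            times_positions.append((length / v_ms, length))
    fixes = []
    for t, s in times_positions:
        lat, lon = _point_at(scenario.road, s)
        fixes.append(
            GpsFix(
                timestamp=_EPOCH + timedelta(seconds=t),
                latitude=lat,
                longitude=lon,
            )
        )
    return fixes


def _patch_for(scenario: SurveyScenario, s: float) -> Patch | None:
    for p in scenario.patches:
        if p.position_m <= s <= p.position_m + p.length_m:
            return p
    return None


def _near_patch(scenario: SurveyScenario, s: float) -> bool:
    m = scenario.capture_margin_m
    if m is None:
        return True
    return any(
        p.position_m - m <= s <= p.position_m + p.length_m + m
        for p in scenario.patches
    )


def generate_images(scenario: SurveyScenario) -> list[GeoImage]:
    """Geotagged annotated images, one per coverage interval.

    The road is divided into ``round(length / coverage)`` intervals; an
    image sits at each interval midpoint (subject to the capture window).
    Images overlapping a patch get 1-3 polygons of the patch species whose
    combined relative area is Beta-distributed around the patch mean;
    polygons occupy disjoint vertical slots, so annotations never overlap.
    """
    rng = np.random.default_rng(scenario.seed)
    length = _polyline_length(scenario.road)
    n = max(1, round(length / scenario.coverage_m))
    step = length / n
    track = generate_track(scenario)
    track_xy = None
    v_ms = scenario.speed_kmh * KMH_TO_MS

    images: list[GeoImage] = []
    for i in range(n):
        s = (i + 0.5) * step
        if not _near_patch(scenario, s):
            continue
        t = _EPOCH + timedelta(seconds=s / v_ms) if v_ms > 0 else _EPOCH
        if scenario.geotag == "gps" and len(track) > 1:
            k = min(
                range(len(track)),
                key=lambda j: abs((track[j].timestamp - t).total_seconds()),
            )
            lat, lon = track[k].latitude, track[k].longitude
        else:
            lat, lon = _point_at(scenario.road, s)
        patch = _patch_for(scenario, s)
        annotations = (
            _sample_annotations(scenario, patch, rng) if patch is not None else []
        )
        images.append(
            GeoImage(
                image_id=f"img{i:05d}",
                latitude=lat,
                longitude=lon,
                timestamp=t,
                acquisition_date=scenario.acquisition_date,
                width=scenario.image_width,
                height=scenario.image_height,
                annotations=annotations,
            )
        )
    return images


def _sample_annotations(
    scenario: SurveyScenario, patch: Patch, rng: np.random.Generator
) -> list[Annotation]:
    w, h = scenario.image_width, scenario.image_height
    k = int(rng.integers(1, 4))
    c = scenario.beta_concentration
    mu = patch.mean_relative_area
    total_rel = float(np.clip(rng.beta(mu * c, (1 - mu) * c), 0.005, 0.95))
    per_poly = total_rel / k
    slot_w = w / k
    anns = []
    for j in range(k):
        # rectangle of area per_poly*w*h inside slot j, aspect jitter 0.6-1.4
        area = per_poly * w * h
        aspect = float(rng.uniform(0.6, 1.4))
        pw = min(math.sqrt(area * aspect), slot_w * 0.95)
        ph = min(area / pw, h * 0.95)
        x0 = j * slot_w + float(rng.uniform(0, max(slot_w - pw, 1e-6)))
        y0 = float(rng.uniform(0, max(h - ph, 1e-6)))
        anns.append(
            Annotation(
                polygon=[(x0, y0), (x0 + pw, y0), (x0 + pw, y0 + ph), (x0, y0 + ph)],
                species=patch.species,
            )
        )
    return anns


def _validate_kernel(
    kernel: Mapping[str, Mapping[str, float]], labels: Sequence[str]
) -> None:
    for lab in labels:
        if lab not in kernel:
            raise InvalidKernelError(f"kernel missing row for {lab!r}")
        row = kernel[lab]
        total = sum(row.values())
        if abs(total - 1.0) > 1e-6 or any(v < 0 for v in row.values()):
            raise InvalidKernelError(f"kernel row {lab!r} is not a distribution")


def generate_predictions(
    images: Sequence[GeoImage],
    kernel: Mapping[str, Mapping[str, float]],
    seed: int = 0,
    confidence_beta: tuple[float, float] = (5.0, 2.0),
) -> list[ImagePrediction]:
    """Sample one label per image from the kernel row of its true class."""
    from .dataset import image_class

    truth = [image_class(im) for im in images]
    _validate_kernel(kernel, sorted(set(truth)))
    rng = np.random.default_rng(seed)
    out = []
    for im, cls in zip(images, truth):
        row = kernel[cls]
        labels = list(row)
        probs = np.array([row[l] for l in labels], dtype=float)
        probs /= probs.sum()
        label = labels[int(rng.choice(len(labels), p=probs))]
        conf = float(rng.beta(*confidence_beta))
        out.append(ImagePrediction(image_id=im.image_id, label=label, confidence=conf))
    return out


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

#: Per-species prototype colours for rendered blobs (well separated in RGB).
SPECIES_COLORS: dict[str, tuple[int, int, int]] = {
    "Cytisus scoparius": (220, 200, 40),   # yellow broom
    "Lupinus polyphyllus": (90, 60, 200),  # blue-violet lupine
    "Pastinaca sativa": (235, 235, 140),   # pale yellow umbels
    "Reynoutria": (200, 70, 60),           # reddish knotweed stems
    "Rosa rugosa": (210, 60, 160),         # pink rose
    "Solidago": (250, 170, 30),            # goldenrod orange
}

_BACKGROUND = (70, 110, 60)  # roadside green


@dataclass(frozen=True)
class RenderStyle:
    scale: float = 0.08          # raster size = image size * scale
    noise_sigma: float = 6.0
    seed: int = 0


def render_image(geo_image: GeoImage, style: RenderStyle = RenderStyle()) -> np.ndarray:
    """Render a small raster: textured background + one coloured blob per polygon.

    Deterministic given the image id and style seed.  Returns an
    (H, W, 3) uint8 array.
    """
    from PIL import Image, ImageDraw

    w = max(8, round(geo_image.width * style.scale))
    h = max(8, round(geo_image.height * style.scale))
    # stable across processes (built-in hash() is salted)
    digest = zlib.crc32(geo_image.image_id.encode())
    seed = (style.seed * 1_000_003 + digest) % (2**31)
    rng = np.random.default_rng(seed)
    raster = np.array(_BACKGROUND, dtype=float) + rng.normal(
        0.0, style.noise_sigma, size=(h, w, 3)
    )
    sx = w / geo_image.width
    sy = h / geo_image.height
    for ann in geo_image.annotations:
        mask_img = Image.new("L", (w, h), 0)
        pts = [(x * sx, y * sy) for x, y in ann.polygon]
        ImageDraw.Draw(mask_img).polygon(pts, fill=1)
        mask = np.asarray(mask_img, dtype=bool)
        color = np.array(SPECIES_COLORS[ann.species], dtype=float)
        noise = rng.normal(0.0, style.noise_sigma, size=(int(mask.sum()), 3))
        raster[mask] = color + noise
    return np.clip(raster, 0, 255).astype(np.uint8)


# ---------------------------------------------------------------------------
# bundled conditions
# ---------------------------------------------------------------------------

def identity_kernel(labels: Sequence[str]) -> dict[str, dict[str, float]]:
    """Error-free kernel: every class predicted as itself."""
    return {a: {b: 1.0 if a == b else 0.0 for b in labels} for a in labels}


def example_kernel(
    labels: Sequence[str] | None = None, accuracy: float = 0.7
) -> dict[str, dict[str, float]]:
    """Uniform-confusion kernel: *accuracy* on the diagonal, rest spread evenly."""
    labels = list(labels) if labels is not None else list(RETAINED_SPECIES) + [NO_SPECIES]
    off = (1.0 - accuracy) / (len(labels) - 1)
    return {a: {b: accuracy if a == b else off for b in labels} for a in labels}


def example_scenario(seed: int = 0) -> SurveyScenario:
    """The bundled survey conditions: a 12.2 km motorway stretch at 110 km/h.

    Sixty plant patches (ten per retained species) sit 200 m apart, 25-45 m
    long, with patch-triggered capture (+/- 30 m margin) so each patch and
    its background margin form one spatial cluster at the 40 m threshold —
    the regime the cluster-level split is designed for.  Patch order, sizes
    and annotation sizes are drawn from the given seed.
    """
    rng = np.random.default_rng(seed)
    lat0, lon0 = 56.0, 9.0
    length = 12_200.0
    dlon = length / (EARTH_RADIUS_M * math.cos(math.radians(lat0)) * math.pi / 180.0)
    road = [(lat0, lon0), (lat0, lon0 + dlon)]
    species = list(RETAINED_SPECIES) * 10
    rng.shuffle(species)
    patches = [
        Patch(
            position_m=100.0 + 200.0 * k,
            species=sp,
            length_m=float(rng.uniform(25.0, 45.0)),
            mean_relative_area=float(rng.uniform(0.1, 0.5)),
        )
        for k, sp in enumerate(species)
    ]
    return SurveyScenario(
        road=road,
        speed_kmh=110.0,
        gps_rate_hz=1.0,
        coverage_m=6.2,
        patches=patches,
        capture_margin_m=30.0,
        seed=seed,
    )
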