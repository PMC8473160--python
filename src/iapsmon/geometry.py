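"""Acquisition planning math for a sideways-looking vehicle-mounted camera.

A camera on a survey vehicle images the roadside at traffic speed.  Four
quantities decide whether the collected images are usable and the roadside is
fully covered:

* **GSD** (ground sampling distance) — metres of roadside per pixel; sets the
  level of detail available for recognising a plant.
* **Motion blur** — apparent horizontal displacement, in pixels, of a ground
  point during one exposure; blur beyond a few pixels destroys texture.
* **Coverage** — roadside metres per image, hence images/km and the minimum
  frame rate for gap-free coverage at a given speed.
* **GPS spacing** — distance driven between consecutive GPS fixes, which is
  the geotagging resolution of the images.

The camera yaw ``phi`` is measured from the perpendicular-to-driving
direction; ``phi = 0`` looks straight sideways, giving the finest GSD but the
largest blur.  The oblique-geometry model used here is: at yaw ``phi`` the
line of sight to the roadside plane lengthens to ``WD / cos(phi)`` and the
pixel footprint on that plane stretches by another ``1 / cos(phi)``, so

    GSD(phi) = GSD(0) / cos^2(phi),   GSD(0) = 2 WD tan(HFOV/2) / N_px

while the ground displacement ``v t`` during an exposure projects onto the
image with the two cosine factors in the opposite direction:

    blur(phi) = v t cos^2(phi) / GSD(0)   [pixels]

Both are model choices (slant range x obliquity); they reproduce the
qualitative behaviour of a perpendicular rig — finest GSD and worst blur at
``phi = 0`` — and the magnitude of blur observed in practice (a 46° HFOV,
4000 px camera at 110 km/h and 1/1000 s exposure blurs over ~20 px).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict

from .errors import InvalidArgumentError, InvalidGeometryError

__all__ = [
    "CameraModel",
    "SurveyGeometry",
    "PlanReport",
    "fov_width",
    "gsd_center",
    "motion_blur_px",
    "images_per_km",
    "min_frame_rate",
    "gps_gap",
    "plan",
]

KMH_TO_MS = 1.0 / 3.6


@dataclass(frozen=True)
class CameraModel:
    """Sensor width in pixels and horizontal field of view in degrees."""

    horizontal_pixels: int = 4000
    horizontal_fov: float = 46.0

    def __post_init__(self) -> None:
        if self.horizontal_pixels < 1:
            raise InvalidGeometryError("horizontal_pixels must be >= 1")
        if not 0.0 < self.horizontal_fov < 180.0:
            raise InvalidGeometryError("horizontal_fov must be in (0, 180) degrees")


@dataclass(frozen=True)
class SurveyGeometry:
    """How the camera is mounted and driven.

    Parameters
    ----------
    working_distance : float
        Perpendicular distance camera-to-roadside plane, metres.
    orientation_angle : float
        Camera yaw ``phi`` in degrees; 0 = perpendicular to driving direction.
    speed : float
        Vehicle speed in km/h.
    exposure_time : float
        Shutter time in seconds.
    gps_rate : float
        GPS fix rate in Hz.
    """

    working_distance: float = 7.0
    orientation_angle: float = 0.0
    speed: float = 110.0
    exposure_time: float = 1e-4
    gps_rate: float = 1.0

    def __post_init__(self) -> None:
        if self.working_distance <= 0:
            raise InvalidGeometryError("working_distance must be positive")
        if not -90.0 < self.orientation_angle < 90.0:
            raise InvalidGeometryError("orientation_angle must be in (-90, 90) degrees")
        if self.speed < 0:
            raise InvalidGeometryError("speed must be non-negative")
        if self.exposure_time < 0:
            raise InvalidGeometryError("exposure_time must be non-negative")
        if self.gps_rate <= 0:
            raise InvalidGeometryError("gps_rate must be positive")


@dataclass(frozen=True)
class PlanReport:
    """Derived planning quantities for one camera + survey configuration.

    Distances are reported to 0.1 m, frame rates to 0.01 FPS and images/km
    as an integer; the underlying functions return full precision.
    """

    fov_width: float          # m
    gsd_center: float         # m/px
    motion_blur: float        # px
    images_per_km: int
    min_frame_rate: float     # FPS
    gps_gap: float            # m

    def to_dict(self) -> dict:
        return asdict(self)

    def rounded(self) -> dict:
        """Display-rounded copy: 0.1 m distances, 0.01 FPS, mm/px GSD."""
        return {
            "fov_width_m": round(self.fov_width, 1),
            "gsd_center_mm_per_px": round(self.gsd_center * 1000.0, 3),
            "motion_blur_px": round(self.motion_blur, 1),
            "images_per_km": self.images_per_km,
            "min_frame_rate_fps": round(self.min_frame_rate, 2),
            "gps_gap_m": round(self.gps_gap, 1),
        }


def fov_width(geometry: SurveyGeometry, camera: CameraModel) -> float:
    """Width in metres of the camera footprint on the roadside plane.

    Measured at the working distance with the camera perpendicular
    (``phi = 0``): ``2 WD tan(HFOV / 2)``.
    """
    half = math.radians(camera.horizontal_fov / 2.0)
    return 2.0 * geometry.working_distance * math.tan(half)


def gsd_center(geometry: SurveyGeometry, camera: CameraModel) -> float:
    """Ground sampling distance at the image centre, metres per pixel.

    ``GSD(phi) = GSD(0) / cos^2(phi)`` — one cosine for the longer slant
    range ``WD / cos(phi)``, one for the oblique footprint on the roadside
    plane.  Even in ``phi`` and strictly increasing with ``|phi|``.
    """
    phi = math.radians(geometry.orientation_angle)
    gsd0 = fov_width(geometry, camera) / camera.horizontal_pixels
    return gsd0 / math.cos(phi) ** 2


def motion_blur_px(geometry: SurveyGeometry, camera: CameraModel) -> float:
    """Horizontal motion blur in pixels during one exposure.

    The ground displacement ``v t`` projects perpendicular to the line of
    sight (factor ``cos phi``) and is divided by the GSD at slant range
    (a second ``cos phi``): ``blur = v t cos^2(phi) / GSD(0)``.  Maximal at
    the perpendicular orientation and linear in both speed and exposure.
    """
    phi = math.radians(geometry.orientation_angle)
    gsd0 = fov_width(geometry, camera) / camera.horizontal_pixels
    displacement = geometry.speed * KMH_TO_MS * geometry.exposure_time
    return displacement * math.cos(phi) ** 2 / gsd0


def images_per_km(coverage_per_image: float) -> int:
    """Images needed for gap-free coverage of 1 km, rounded to nearest.

    Coverage per image is an independent input (hardware-measured footprint)
    rather than being derived from the FOV formula.
    """
    if coverage_per_image <= 0:
        raise InvalidArgumentError("coverage_per_image must be positive")
    return round(1000.0 / coverage_per_image)


def min_frame_rate(speed: float, coverage_per_image: float) -> float:
    """Minimum frame rate (FPS) for gap-free coverage at *speed* km/h.

    Satisfies ``min_frame_rate * coverage = speed / 3.6`` exactly.
    """
    if coverage_per_image <= 0:
        raise InvalidArgumentError("coverage_per_image must be positive")
    if speed < 0:
        raise InvalidArgumentError("speed must be non-negative")
    return speed * KMH_TO_MS / coverage_per_image


def gps_gap(speed: float, gps_rate: float) -> float:
    """Distance in metres driven between consecutive GPS fixes.

    This is the geotagging resolution of the survey: at 130 km/h and 1 Hz
    adjacent images can be up to 36.1 m apart.
    """
    if gps_rate <= 0:
        raise InvalidArgumentError("gps_rate must be positive")
    if speed < 0:
        raise InvalidArgumentError("speed must be non-negative")
    return speed * KMH_TO_MS / gps_rate


def plan(
    geometry: SurveyGeometry,
    camera: CameraModel,
    coverage_per_image: float | None = None,
) -> PlanReport:
    """Assemble the full planning report for one configuration.

    ``coverage_per_image`` defaults to the computed FOV width; pass the
    hardware-measured footprint instead when reproducing a specific rig
    (measured coverage can differ from the thin-lens formula).
    """
    width = fov_width(geometry, camera)
    coverage = width if coverage_per_image is None else float(coverage_per_image)
    if coverage <= 0:
        raise InvalidArgumentError("coverage_per_image must be positive")
    return PlanReport(
        fov_width=width,
        gsd_center=gsd_center(geometry, camera),
        motion_blur=motion_blur_px(geometry, camera),
        images_per_km=images_per_km(coverage),
        min_frame_rate=min_frame_rate(geometry.speed, coverage),
        gps_gap=gps_gap(geometry.speed, geometry.gps_rate),
    )
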