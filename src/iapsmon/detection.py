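"""Prediction exchange formats and detection-to-annotation matching.

Deep models live outside this package; they communicate through files.
Image-level classifiers exchange a CSV of (image_id, label, confidence);
object detectors exchange either darknet-style text files — one file per
image, one detection per line, ``class_index x_center y_center width height
confidence`` in coordinates relative to the image size — or a JSON list with
absolute pixel corners.  Class indices in darknet files map to an explicit
names list (by default the six retained IAPS in alphabetical order), stored
as a sidecar names file.

Building a detection confusion matrix requires pairing predicted boxes with
annotated polygons.  The rule here is greedy one-to-one matching in
descending confidence order against the annotations' bounding boxes (or full
polygons), accepting a pair when the IoU reaches a threshold (default 0.5).
Matched pairs count as (observed species, predicted label); unmatched
annotations are misses (observed species, background); unmatched detections
are background false positives (background row).

A deliberately simple colour-prototype classifier is included so the whole
pipeline can run end-to-end on rendered synthetic images without any
deep-learning dependency.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from shapely.geometry import box as shapely_box

from .dataset import Annotation
from .errors import CannotFitError, ParseError
from .labels import RETAINED_SPECIES, check_label

__all__ = [
    "ImagePrediction",
    "DetectionPrediction",
    "MatchResult",
    "read_detections",
    "write_detections",
    "read_names",
    "write_names",
    "read_image_predictions",
    "write_image_predictions",
    "match_detections",
    "confusion_from_matches",
    "ColorPrototypeClassifier",
]


@dataclass(frozen=True)
class ImagePrediction:
    """One model's class call for one image."""

    image_id: str
    label: str
    confidence: float = 1.0

    def __post_init__(self) -> None:
        check_label(self.label)
        if not 0.0 <= self.confidence <= 1.0:
            raise ValueError("confidence must be in [0, 1]")


@dataclass(frozen=True)
class DetectionPrediction:
    """One predicted bounding box: absolute pixel corners, label, confidence."""

    image_id: str
    x_min: float
    y_min: float
    x_max: float
    y_max: float
    label: str
    confidence: float

    def __post_init__(self) -> None:
        check_label(self.label)
        if not (self.x_min < self.x_max and self.y_min < self.y_max):
            raise ValueError("box corners must satisfy x_min < x_max, y_min < y_max")
        if not 0.0 <= self.confidence <= 1.0:
            raise ValueError("confidence must be in [0, 1]")

    def shapely(self):
        return shapely_box(self.x_min, self.y_min, self.x_max, self.y_max)


@dataclass
class MatchResult:
    """Outcome of pairing one image's detections with its annotations."""

    pairs: list[tuple[Annotation, DetectionPrediction]] = field(default_factory=list)
    missed_annotations: list[Annotation] = field(default_factory=list)
    background_false_positives: list[DetectionPrediction] = field(default_factory=list)


# ---------------------------------------------------------------------------
# file formats
# ---------------------------------------------------------------------------

DEFAULT_NAMES: tuple[str, ...] = RETAINED_SPECIES  # alphabetical six IAPS


def write_names(names: Sequence[str], path: str | Path) -> None:
    Path(path).write_text("\n".join(names) + "\n")


def read_names(path: str | Path) -> list[str]:
    return [line for line in Path(path).read_text().splitlines() if line.strip()]


def read_detections(
    path: str | Path,
    dialect: str = "darknet",
    image_id: str | None = None,
    image_size: tuple[int, int] | None = None,
    names: Sequence[str] = DEFAULT_NAMES,
) -> list[DetectionPrediction]:
    """Read one image's detections.

    darknet dialect: relative-coordinate lines converted to absolute pixel
    corners using *image_size* = (width, height); *image_id* defaults to the
    file stem.  JSON dialect: a list of records with absolute corners.
    """
    path = Path(path)
    if image_id is None:
        image_id = path.stem
    if dialect == "json":
        records = json.loads(path.read_text())
        return [
            DetectionPrediction(
                image_id=r.get("image_id", image_id),
                x_min=r["x_min"],
                y_min=r["y_min"],
                x_max=r["x_max"],
                y_max=r["y_max"],
                label=r["label"],
                confidence=r["confidence"],
            )
            for r in records
        ]
    if dialect != "darknet":
        raise ValueError(f"unknown dialect {dialect!r}")
    if image_size is None:
        raise ValueError("darknet dialect needs image_size=(width, height)")
    w, h = image_size
    out = []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        line = line.strip()
        if not line:
            continue
        parts = line.split()
        if len(parts) != 6:
            raise ParseError(f"expected 6 fields, got {len(parts)}", lineno)
        try:
            ci = int(parts[0])
            xc, yc, bw, bh, conf = map(float, parts[1:])
        except ValueError as exc:
            raise ParseError(str(exc), lineno) from exc
        if not 0 <= ci < len(names):
            raise ParseError(f"class index {ci} outside names list", lineno)
        out.append(
            DetectionPrediction(
                image_id=image_id,
                x_min=(xc - bw / 2) * w,
                y_min=(yc - bh / 2) * h,
                x_max=(xc + bw / 2) * w,
                y_max=(yc + bh / 2) * h,
                label=names[ci],
                confidence=conf,
            )
        )
    return out


def write_detections(
    detections: Sequence[DetectionPrediction],
    path: str | Path,
    dialect: str = "darknet",
    image_size: tuple[int, int] | None = None,
    names: Sequence[str] = DEFAULT_NAMES,
) -> None:
    """Write one image's detections; round-trips with :func:`read_detections`."""
    path = Path(path)
    if dialect == "json":
        path.write_text(
            json.dumps(
                [
                    {
                        "image_id": d.image_id,
                        "x_min": d.x_min,
                        "y_min": d.y_min,
                        "x_max": d.x_max,
                        "y_max": d.y_max,
                        "label": d.label,
                        "confidence": d.confidence,
                    }
                    for d in detections
                ],
                indent=1,
            )
        )
        return
    if dialect != "darknet":
        raise ValueError(f"unknown dialect {dialect!r}")
    if image_size is None:
        raise ValueError("darknet dialect needs image_size=(width, height)")
    w, h = image_size
    index = {n: i for i, n in enumerate(names)}
    lines = []
    for d in detections:
        xc = (d.x_min + d.x_max) / 2 / w
        yc = (d.y_min + d.y_max) / 2 / h
        bw = (d.x_max - d.x_min) / w
        bh = (d.y_max - d.y_min) / h
        lines.append(
            f"{index[d.label]} {xc:.6f} {yc:.6f} {bw:.6f} {bh:.6f} {d.confidence:.6f}"
        )
    path.write_text("\n".join(lines) + ("\n" if lines else ""))


def write_image_predictions(
    predictions: Sequence[ImagePrediction], path: str | Path
) -> None:
    pd.DataFrame(
        [{"image_id": p.image_id, "label": p.label, "confidence": p.confidence} for p in predictions]
    ).to_csv(path, index=False)


def read_image_predictions(path: str | Path) -> list[ImagePrediction]:
    frame = pd.read_csv(path, dtype={"image_id": str})
    return [
        ImagePrediction(
            image_id=str(r.image_id), label=r.label, confidence=float(r.confidence)
        )
        for r in frame.itertuples(index=False)
    ]


# ---------------------------------------------------------------------------
# matching
# ---------------------------------------------------------------------------

def _box_iou(det: DetectionPrediction, ann: Annotation, use_polygon: bool) -> float:
    b = det.shapely()
    target = ann.shapely() if use_polygon else shapely_box(*ann.bbox())
    inter = b.intersection(target).area
    if inter == 0:
        return 0.0
    return inter / b.union(target).area


def match_detections(
    annotations: Sequence[Annotation],
    detections: Sequence[DetectionPrediction],
    iou_threshold: float = 0.5,
    use_polygon: bool = False,
) -> MatchResult:
    """Greedy one-to-one pairing of detections with annotations.

    Detections are visited in descending confidence (ties keep input order);
    each takes the still-unmatched annotation of any species with the
    highest IoU, provided it reaches *iou_threshold*.  IoU is computed
    against the annotation's bounding box, or the polygon itself when
    *use_polygon* is set.
    """
    order = sorted(range(len(detections)), key=lambda i: (-detections[i].confidence, i))
    unmatched = list(range(len(annotations)))
    result = MatchResult()
    for di in order:
        det = detections[di]
        best_ai, best_iou = None, 0.0
        for ai in unmatched:
            iou = _box_iou(det, annotations[ai], use_polygon)
            if iou >= iou_threshold and iou > best_iou:
                best_ai, best_iou = ai, iou
        if best_ai is None:
            result.background_false_positives.append(det)
        else:
            unmatched.remove(best_ai)
            result.pairs.append((annotations[best_ai], det))
    result.missed_annotations = [annotations[ai] for ai in unmatched]
    return result


def confusion_from_matches(
    results: Iterable[MatchResult], vocabulary: Sequence[str]
):
    """Aggregate match results into a detection confusion matrix.

    Pairs feed (species, predicted label); misses the background column;
    background false positives the background row.  Total count equals
    #annotations + #background false positives.
    """
    from .evaluation import ConfusionMatrix
    from .labels import NO_SPECIES

    cm = ConfusionMatrix(vocabulary)
    for res in results:
        for ann, det in res.pairs:
            cm.add(ann.species, det.label)
        for ann in res.missed_annotations:
            cm.add(ann.species, NO_SPECIES)
        for det in res.background_false_positives:
            cm.add(NO_SPECIES, det.label)
    return cm


# ---------------------------------------------------------------------------
# baseline classifier
# ---------------------------------------------------------------------------

class ColorPrototypeClassifier:
    """Nearest-centroid classifier on the mean colour of the image centre.

    Fits one RGB prototype per class from labelled example images and
    predicts the nearest prototype (Euclidean in RGB).  Confidence is a
    softmax over negative distances.  Deterministic and order-independent —
    a pipeline smoke-test stand-alone model, not a serious classifier.
    """

    def __init__(self, central_fraction: float = 0.5, temperature: float = 25.0):
        self.central_fraction = central_fraction
        self.temperature = temperature
        self.prototypes: dict[str, np.ndarray] = {}

    def _feature(self, pixels: np.ndarray) -> np.ndarray:
        h, w = pixels.shape[:2]
        fh = max(1, int(h * self.central_fraction))
        fw = max(1, int(w * self.central_fraction))
        top, left = (h - fh) // 2, (w - fw) // 2
        crop = pixels[top : top + fh, left : left + fw]
        return crop.reshape(-1, pixels.shape[-1]).mean(axis=0).astype(float)

    def fit(self, examples: Sequence[tuple[np.ndarray, str]]) -> "ColorPrototypeClassifier":
        if not examples:
            raise CannotFitError("no labelled examples to fit on")
        feats: dict[str, list[np.ndarray]] = {}
        for pixels, label in examples:
            check_label(label)
            feats.setdefault(label, []).append(self._feature(pixels))
        self.prototypes = {lab: np.mean(f, axis=0) for lab, f in sorted(feats.items())}
        return self

    def predict(self, image_id: str, pixels: np.ndarray) -> ImagePrediction:
        if not self.prototypes:
            raise CannotFitError("classifier has not been fitted")
        feat = self._feature(pixels)
        labels = list(self.prototypes)
        dists = np.array([np.linalg.norm(feat - self.prototypes[lab]) for lab in labels])
        logits = -dists / self.temperature
        probs = np.exp(logits - logits.max())
        probs /= probs.sum()
        best = int(np.argmin(dists))
        return ImagePrediction(
            image_id=image_id, label=labels[best], confidence=float(probs[best])
        )
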