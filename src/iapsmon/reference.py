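"""Published benchmark confusion matrices bundled as package data.

Three confusion matrices from a vehicle-mounted roadside IAPS survey on
Danish motorways ship with the package, transcribed from the published
tables, so the metric conventions can be validated against printed results
without any survey data:

* ``resnet50v2_species`` — ResNet50V2 (ImageNet weights, max pooling,
  768x1024 px inputs) seven-class image classification on the test split
  (six IAPS + background; 2140 images).
* ``mobilenetv2_invasive`` — MobileNetV2 (ImageNet weights, average pooling,
  384x512 px inputs) invasive vs non-invasive classification on the same
  test split, already merged to 2x2.
* ``yolov3_detection`` — YOLOv3 object detection on the test split at a 25%
  confidence threshold, in the detection convention: the background row
  holds false detections on unannotated material, the background column
  holds missed annotations.
"""

from __future__ import annotations

from importlib import resources

from .evaluation import ConfusionMatrix

__all__ = ["REFERENCE_MATRICES", "load_reference_matrix"]

REFERENCE_MATRICES = (
    "resnet50v2_species",
    "mobilenetv2_invasive",
    "yolov3_detection",
)

_FILES = {
    "resnet50v2_species": "resnet50v2_species_confusion.csv",
    "mobilenetv2_invasive": "mobilenetv2_invasive_confusion.csv",
    "yolov3_detection": "yolov3_detection_confusion.csv",
}


def load_reference_matrix(name: str) -> ConfusionMatrix:
    """Load one of the bundled benchmark matrices by short name."""
    if name not in _FILES:
        raise KeyError(f"unknown reference matrix {name!r}; choose from {REFERENCE_MATRICES}")
    ref = resources.files("iapsmon.data") / _FILES[name]
    with resources.as_file(ref) as path:
        return ConfusionMatrix.from_csv(path)
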