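"""Classification and detection metrics with the two precision conventions
used for roadside IAPS monitoring.

Two confusion-matrix conventions coexist, selected by an explicit flag:

* ``classification`` — the standard convention: precision of class *c* is
  the diagonal over the predicted-*c* column, so cross-species confusions
  count as false positives; overall accuracy is trace/total.
* ``detection-background-fp`` — the object-detection convention in which a
  detection of the wrong species still found a plant: only detections on
  unannotated material (the background / "No species" row) count as false
  positives, ``P_c = TP_c / (TP_c + FP_bg,c)``.  Micro averages pool true
  positives over species: ``micro P = sum TP / (sum TP + sum background FP)``
  and ``micro R = sum TP / sum annotated``, with the summary F1 the harmonic
  mean of the two.

Macro averages are unweighted means over classes (optionally a subset);
classes with an empty row or column yield undefined (NaN) metrics and are
excluded from macro means with a warning.

Also here: merging all invasive species into one binary invasive vs
non-invasive matrix (inter-species confusion forgiven), recall binned by
relative annotation size with a Gaussian kernel-regression smoother, and
cluster-level detection statistics (a plant cluster counts as found when at
least one of its images is correctly flagged as invasive).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConventionError, UndefinedStatisticError, VocabularyError
from .labels import NO_SPECIES, is_iaps

__all__ = [
    "ConfusionMatrix",
    "MetricsReport",
    "SizeBinnedRecall",
    "ClusterDetectionReport",
    "confusion_from_predictions",
    "classification_metrics",
    "detection_metrics",
    "merge_invasive",
    "size_binned_recall",
    "cluster_detection",
    "threshold_sweep",
]


class ConfusionMatrix:
    """Square labelled count grid, rows = observed, columns = predicted."""

    def __init__(self, labels: Sequence[str], counts=None):
        self.labels = list(labels)
        n = len(self.labels)
        if counts is None:
            counts = np.zeros((n, n), dtype=np.int64)
        self.counts = np.asarray(counts, dtype=np.int64)
        if self.counts.shape != (n, n):
            raise ValueError("counts must be square over the label vocabulary")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")
        self._index = {lab: i for i, lab in enumerate(self.labels)}

    def __getitem__(self, key: tuple[str, str]) -> int:
        observed, predicted = key
        return int(self.counts[self._index[observed], self._index[predicted]])

    def add(self, observed: str, predicted: str, n: int = 1) -> None:
        if observed not in self._index or predicted not in self._index:
            raise VocabularyError(f"label not in vocabulary: {observed!r}/{predicted!r}")
        self.counts[self._index[observed], self._index[predicted]] += n

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def row_total(self, label: str) -> int:
        return int(self.counts[self._index[label]].sum())

    def column_total(self, label: str) -> int:
        return int(self.counts[:, self._index[label]].sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.labels, columns=self.labels)

    def to_csv(self, path) -> None:
        self.to_frame().rename_axis("observed").to_csv(path)

    @classmethod
    def from_csv(cls, path) -> "ConfusionMatrix":
        frame = pd.read_csv(path, index_col=0)
        if list(frame.index) != list(frame.columns):
            raise ValueError("confusion matrix CSV must have identical row/column labels")
        return cls(list(frame.index), frame.to_numpy())

    def __repr__(self) -> str:  # pragma: no cover
        return f"ConfusionMatrix(n={self.total}, labels={self.labels})"


@dataclass
class MetricsReport:
    """Per-class and averaged metrics for one convention."""

    convention: str                      # "classification" | "detection-background-fp"
    labels: list[str]
    precision: dict[str, float]
    recall: dict[str, float]
    f1: dict[str, float]
    accuracy: float | None = None        # classification convention only
    macro_precision: float | None = None
    macro_recall: float | None = None
    macro_f1: float | None = None
    micro_precision: float | None = None  # detection convention only
    micro_recall: float | None = None
    micro_f1: float | None = None

    def to_dict(self) -> dict:
        def clean(x):
            return None if x is None or (isinstance(x, float) and np.isnan(x)) else x

        return {
            "convention": self.convention,
            "per_class": {
                lab: {
                    "precision": clean(self.precision[lab]),
                    "recall": clean(self.recall[lab]),
                    "f1": clean(self.f1[lab]),
                }
                for lab in self.labels
            },
            "accuracy": clean(self.accuracy),
            "macro_precision": clean(self.macro_precision),
            "macro_recall": clean(self.macro_recall),
            "macro_f1": clean(self.macro_f1),
            "micro_precision": clean(self.micro_precision),
            "micro_recall": clean(self.micro_recall),
            "micro_f1": clean(self.micro_f1),
        }

    def to_text(self) -> str:
        """Aligned text table, ratios to 3 decimals."""
        lines = [f"{'class':<22}{'precision':>10}{'recall':>10}{'F1':>10}"]
        for lab in self.labels:
            p, r, f = self.precision[lab], self.recall[lab], self.f1[lab]
            lines.append(
                f"{lab:<22}"
                + "".join(f"{v:>10.3f}" if np.isfinite(v) else f"{'n/a':>10}" for v in (p, r, f))
            )
        if self.accuracy is not None:
            lines.append(f"accuracy: {self.accuracy:.3f}")
        if self.micro_precision is not None:
            lines.append(
                f"micro: P={self.micro_precision:.3f} R={self.micro_recall:.3f} "
                f"F1={self.micro_f1:.3f}"
            )
        return "\n".join(lines)


@dataclass
class SizeBinnedRecall:
    """Recall as a function of relative annotation size.

    ``recall`` holds NaN for empty bins; ``smoothed`` is a Nadaraya-Watson
    Gaussian kernel regression of the per-image correctness indicator on the
    relative area, evaluated on ``grid``.
    """

    bin_edges: np.ndarray
    counts: np.ndarray
    recall: np.ndarray
    grid: np.ndarray
    smoothed: np.ndarray
    bandwidth: float


@dataclass
class ClusterDetectionReport:
    detection_ratio: float
    average_cluster_precision: float
    n_iaps_clusters: int
    n_detected: int


# ---------------------------------------------------------------------------

def confusion_from_predictions(
    truth: Mapping[str, str],
    predictions: Mapping[str, str],
    vocabulary: Sequence[str],
) -> ConfusionMatrix:
    """Count (observed, predicted) pairs over the predicted images."""
    cm = ConfusionMatrix(vocabulary)
    for image_id, predicted in predictions.items():
        if image_id not in truth:
            raise VocabularyError(f"prediction for unknown image {image_id!r}")
        cm.add(truth[image_id], predicted)
    return cm


def _harmonic(p: float, r: float) -> float:
    if not (np.isfinite(p) and np.isfinite(r)) or p + r == 0:
        return np.nan
    return 2.0 * p * r / (p + r)


def _macro(values: Iterable[float], what: str) -> float:
    vals = np.array(list(values), dtype=float)
    if np.isnan(vals).any():
        warnings.warn(f"undefined per-class {what} excluded from macro mean", stacklevel=3)
        vals = vals[~np.isnan(vals)]
    return float(vals.mean()) if vals.size else np.nan


def classification_metrics(
    cm: ConfusionMatrix, macro_classes: Sequence[str] | None = None
) -> MetricsReport:
    """Standard per-class precision/recall/F1, accuracy, and macro means.

    *macro_classes* restricts the macro averages to a subset (e.g. dropping
    chronically under-represented species); per-class values always cover
    the full vocabulary.
    """
    if cm.total == 0:
        raise UndefinedStatisticError("empty confusion matrix")
    precision, recall, f1 = {}, {}, {}
    for lab in cm.labels:
        tp = cm[lab, lab]
        col, row = cm.column_total(lab), cm.row_total(lab)
        precision[lab] = tp / col if col else np.nan
        recall[lab] = tp / row if row else np.nan
        f1[lab] = _harmonic(precision[lab], recall[lab])
    subset = list(macro_classes) if macro_classes is not None else cm.labels
    return MetricsReport(
        convention="classification",
        labels=list(cm.labels),
        precision=precision,
        recall=recall,
        f1=f1,
        accuracy=float(np.trace(cm.counts)) / cm.total,
        macro_precision=_macro((precision[c] for c in subset), "precision"),
        macro_recall=_macro((recall[c] for c in subset), "recall"),
        macro_f1=_macro((f1[c] for c in subset), "F1"),
    )


def detection_metrics(
    cm: ConfusionMatrix, background: str = NO_SPECIES
) -> MetricsReport:
    """Detection-convention metrics: only background hits are false positives.

    Requires a *background* row (false detections on unannotated material)
    and column (missed annotations) in the matrix.  Cross-species cells do
    not count against precision.  The Average row of a detection table is a
    micro average: pooled TP over pooled (TP + background FP) and over pooled
    annotation counts, with F1 their harmonic mean.
    """
    if background not in cm.labels:
        raise ConventionError(
            f"detection convention requires a {background!r} row and column"
        )
    species = [lab for lab in cm.labels if lab != background]
    precision, recall, f1 = {}, {}, {}
    tp_sum = bg_fp_sum = annotated_sum = 0
    for lab in species:
        tp = cm[lab, lab]
        bg_fp = cm[background, lab]
        row = cm.row_total(lab)
        precision[lab] = tp / (tp + bg_fp) if (tp + bg_fp) else np.nan
        recall[lab] = tp / row if row else np.nan
        f1[lab] = _harmonic(precision[lab], recall[lab])
        tp_sum += tp
        bg_fp_sum += bg_fp
        annotated_sum += row
    precision[background] = np.nan
    recall[background] = np.nan
    f1[background] = np.nan
    micro_p = tp_sum / (tp_sum + bg_fp_sum) if (tp_sum + bg_fp_sum) else np.nan
    micro_r = tp_sum / annotated_sum if annotated_sum else np.nan
    return MetricsReport(
        convention="detection-background-fp",
        labels=list(cm.labels),
        precision=precision,
        recall=recall,
        f1=f1,
        macro_precision=_macro((precision[c] for c in species), "precision"),
        macro_recall=_macro((recall[c] for c in species), "recall"),
        macro_f1=_macro((f1[c] for c in species), "F1"),
        micro_precision=micro_p,
        micro_recall=micro_r,
        micro_f1=_harmonic(micro_p, micro_r),
    )


def merge_invasive(
    cm: ConfusionMatrix, background: str = NO_SPECIES
) -> ConfusionMatrix:
    """Collapse all invasive species into one class.

    The invasive-invasive cell sums every (species observed, species
    predicted) pair including cross-species confusions, which are thereby
    forgiven; the background class maps to "Non-invasive".  Total count is
    preserved.
    """
    if background not in cm.labels:
        raise ConventionError(f"vocabulary must include {background!r}")
    inv = [lab for lab in cm.labels if lab != background]
    merged = ConfusionMatrix(["Invasive", "Non-invasive"])
    bi = cm._index[background]
    inv_idx = [cm._index[lab] for lab in inv]
    merged.counts[0, 0] = cm.counts[np.ix_(inv_idx, inv_idx)].sum()
    merged.counts[0, 1] = cm.counts[inv_idx, bi].sum()
    merged.counts[1, 0] = cm.counts[bi, inv_idx].sum()
    merged.counts[1, 1] = cm.counts[bi, bi]
    return merged


def size_binned_recall(
    relative_areas: Sequence[float],
    correct: Sequence[bool],
    bins: int | Sequence[float] = 10,
    bandwidth: float = 0.05,
    grid_points: int = 101,
) -> SizeBinnedRecall:
    """Recall of a class binned by its images' relative annotation area.

    *relative_areas* are combined annotation areas divided by image area
    (in [0, 1]); *correct* flags whether each image was classified
    correctly.  Besides raw per-bin recall, a smoothed curve is computed by
    Nadaraya-Watson regression with a Gaussian kernel of the given
    *bandwidth* (relative-area units); grid points further than 4 bandwidths
    from every sample are NaN.
    """
    areas = np.asarray(relative_areas, dtype=float)
    hits = np.asarray(correct, dtype=float)
    if areas.shape != hits.shape:
        raise ValueError("relative_areas and correct must align")
    if areas.size and (areas.min() < 0 or areas.max() > 1):
        raise ValueError("relative areas must lie in [0, 1]")
    edges = (
        np.linspace(0.0, 1.0, bins + 1)
        if isinstance(bins, int)
        else np.asarray(bins, dtype=float)
    )
    nbins = len(edges) - 1
    idx = np.clip(np.digitize(areas, edges) - 1, 0, nbins - 1)
    counts = np.zeros(nbins, dtype=int)
    recall = np.full(nbins, np.nan)
    for b in range(nbins):
        mask = idx == b
        counts[b] = int(mask.sum())
        if counts[b]:
            recall[b] = float(hits[mask].mean())

    grid = np.linspace(0.0, 1.0, grid_points)
    smoothed = np.full(grid_points, np.nan)
    if areas.size:
        # Nadaraya-Watson: weighted mean of correctness under a Gaussian kernel
        z = (grid[:, None] - areas[None, :]) / bandwidth
        w = np.exp(-0.5 * z**2)
        wsum = w.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            est = (w @ hits) / wsum
        near = (np.abs(z) < 4.0).any(axis=1)
        smoothed[near] = est[near]
    return SizeBinnedRecall(
        bin_edges=edges,
        counts=counts,
        recall=recall,
        grid=grid,
        smoothed=smoothed,
        bandwidth=bandwidth,
    )


def cluster_detection(
    cluster_of: Mapping[str, str],
    truth: Mapping[str, str],
    predictions: Mapping[str, str],
) -> ClusterDetectionReport:
    """Cluster-level detection: a plant cluster is found if any of its
    invasive images is predicted as any invasive species.

    Over clusters containing at least one invasive image, reports the
    detected fraction and, within detected clusters, the mean precision of
    invasive calls ((# images correctly predicted invasive) / (# images
    predicted invasive)), averaged over detected clusters.
    """
    members: dict[str, list[str]] = {}
    for image_id, cid in cluster_of.items():
        members.setdefault(cid, []).append(image_id)
    iaps_clusters = [
        cid
        for cid, ids in members.items()
        if any(is_iaps(truth[i]) for i in ids if i in truth)
    ]
    if not iaps_clusters:
        raise UndefinedStatisticError("no clusters contain invasive images")
    detected, precisions = 0, []
    for cid in iaps_clusters:
        ids = [i for i in members[cid] if i in truth and i in predictions]
        hit = any(is_iaps(truth[i]) and is_iaps(predictions[i]) for i in ids)
        if not hit:
            continue
        detected += 1
        called = [i for i in ids if is_iaps(predictions[i])]
        correct = [i for i in called if is_iaps(truth[i])]
        precisions.append(len(correct) / len(called))
    return ClusterDetectionReport(
        detection_ratio=detected / len(iaps_clusters),
        average_cluster_precision=float(np.mean(precisions)) if precisions else np.nan,
        n_iaps_clusters=len(iaps_clusters),
        n_detected=detected,
    )


def threshold_sweep(
    annotations_by_image: Mapping[str, Sequence],
    detections: Sequence,
    vocabulary: Sequence[str],
    thresholds: Sequence[float] = (0.10, 0.25, 0.50),
    iou_threshold: float = 0.5,
) -> dict[float, MetricsReport]:
    """Detection metrics at several confidence thresholds.

    Detections below each threshold are discarded, the survivors are matched
    to annotations, and the detection-convention metrics are computed from
    the induced confusion matrix.  Raising the threshold trades recall for
    precision.
    """
    from .detection import confusion_from_matches, match_detections

    out: dict[float, MetricsReport] = {}
    for th in thresholds:
        kept = [d for d in detections if d.confidence >= th]
        by_image: dict[str, list] = {}
        for d in kept:
            by_image.setdefault(d.image_id, []).append(d)
        results = {}
        for image_id in set(annotations_by_image) | set(by_image):
            results[image_id] = match_detections(
                annotations_by_image.get(image_id, []),
                by_image.get(image_id, []),
                iou_threshold=iou_threshold,
            )
        cm = confusion_from_matches(results.values(), vocabulary)
        out[th] = detection_metrics(cm)
    return out
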