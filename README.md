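# iapsmon

A toolkit for **vehicle-mounted roadside monitoring of invasive alien plant
species (IAPS)** — plants such as *Rosa rugosa*, *Solidago* or *Reynoutria*
that spread along road verges and outcompete native vegetation. A sideways-
looking camera on a survey car photographs the roadside at traffic speed
(100–130 km/h); geotagged images are classified or searched for plants, and
the detections are aggregated into an occurrence map. This package
implements everything around the deep-learning models themselves: survey
planning, dataset construction, evaluation and mapping. It is aimed at
ecologists and engineers who run such surveys and at anyone benchmarking
plant classifiers/detectors on them.

## What it computes

**Acquisition planning** (`iapsmon.geometry`). For a camera with horizontal
field of view HFOV and N px horizontal pixels, mounted at yaw φ (0 =
perpendicular to driving) and working distance WD from the roadside:

    GSD(φ) = 2·WD·tan(HFOV/2) / (N · cos²φ)        [m/px]
    blur(φ) = v·t·cos²φ / GSD(0)                   [px]

plus roadside coverage per image, images/km, the minimum frame rate for
gap-free coverage (`v/3.6 / coverage`) and the geotag resolution
(`v/3.6 / gps_rate`).

**Dataset construction** (`iapsmon.dataset`). Images taken metres apart
overlap, so random splits leak. Images are clustered by single-linkage
transitive closure of the 40 m haversine-distance rule, cleaned (multi-
species images, annotation pairs with IoU > 0.75, under-represented
classes), and whole clusters are assigned to train/validation/test (70/15/15)
by a seeded greedy pass that minimises each set's χ² = Σc (Oc − Ec)²/Ec
against fraction-scaled class targets, with a fallback to the training set
when no set improves. Class balancing by cyclic upsampling is included.

**Evaluation** (`iapsmon.evaluation`). Confusion-matrix metrics under two
explicit conventions: standard classification (cross-species errors are
false positives) and the object-detection convention in which only
detections on unannotated background count against precision, with micro
averages pooled over species. Also: invasive vs non-invasive merging,
recall binned by relative annotation size with a Gaussian kernel-regression
smoother, cluster-level detection statistics, and confidence-threshold
sweeps. Three published benchmark confusion matrices (ResNet50V2,
MobileNetV2, YOLOv3 on a Danish motorway survey test set) ship as package
data for validation.

**Prediction exchange** (`iapsmon.detection`): darknet-style and JSON
detection files, image-prediction CSVs, greedy confidence-ordered box-to-
annotation matching, and a colour-prototype baseline classifier.

**Synthetic surveys** (`iapsmon.synthetic`): seeded generation of GPS
tracks, clustered plant patches, annotated images, kernel-driven
predictions and rendered rasters — a no-download test surface for the whole
pipeline. **Mapping** (`iapsmon.mapping`): per-GPS-fix species markers
exported as GeoJSON/CSV.

## Worked example

```sh
$ iapsmon plan --wd 7 --hfov 46 --pixels 4000 --speed 110 \
      --exposure 0.001 --gps-rate 1 --coverage 6.2
{
 "fov_width_m": 5.9,
 "gsd_center_mm_per_px": 1.486,
 "motion_blur_px": 20.6,
 "images_per_km": 161,
 "min_frame_rate_fps": 4.93,
 "gps_gap_m": 30.6
}
```

Reading: the rig resolves 1.49 mm of roadside per pixel at 7 m, needs 161
images (4.93 frames/s at 110 km/h) for gap-free kilometre coverage, smears
a ground point over ~21 px during a 1/1000 s exposure (hence the much
shorter exposures used in practice), and geotags images at 30.6 m
resolution from 1 Hz GPS.

Full pipeline on a synthetic survey:

```sh
$ iapsmon synth --seed 3 --out run/
wrote 929 images, 401 GPS fixes to run
$ iapsmon cluster --data run/
60 clusters from 929 images
$ iapsmon clean --data run/
kept 929 of 929 images (removed 0)
$ iapsmon split --data run/ --seed 5
train=639 (68.8%) validation=153 (16.5%) test=137 (14.7%)
$ iapsmon map --data run/      # after writing run/predictions.csv
```

Each cluster (a plant patch plus its background margin) lands in exactly
one set, and the greedy χ² balancing keeps the image shares within a few
points of 70/15/15.

```python
from iapsmon.reference import load_reference_matrix
from iapsmon.evaluation import detection_metrics

m = detection_metrics(load_reference_matrix("yolov3_detection"))
print(round(m.micro_precision, 3), round(m.micro_recall, 3))  # 0.771 0.263
```

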