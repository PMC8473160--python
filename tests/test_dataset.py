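"""Dataset model, clustering, cleaning, chi-square splitting and balancing."""

from collections import Counter

import numpy as np
import pytest

from conftest import make_image, square
from iapsmon.dataset import (
    Annotation,
    Cluster,
    balance_upsample,
    build_clusters,
    chi2_statistic,
    clean_dataset,
    cluster_class_counts,
    haversine_distance,
    image_class,
    load_images,
    polygon_iou,
    read_cvat_xml,
    split_clusters,
    summarize,
    write_annotations_json,
    write_images_csv,
)
from iapsmon.errors import (
    InvalidAnnotationError,
    InvalidCoordinateError,
    UndefinedStatisticError,
)
from iapsmon.labels import MULTIPLE_SPECIES, NO_SPECIES

M_PER_DEG_LAT = 111_194.9  # 6371 km sphere


def offset_lat(meters: float) -> float:
    return meters / M_PER_DEG_LAT


class TestHaversine:
    def test_identical_points(self):
        assert haversine_distance((55.0, 10.0), (55.0, 10.0)) == 0.0

    def test_meridian_arc(self):
        d = haversine_distance((55.0, 10.0), (55.001, 10.0))
        assert d == pytest.approx(111.2, abs=0.1)

    def test_symmetric(self):
        a, b = (55.5, 9.3), (56.1, 10.8)
        assert haversine_distance(a, b) == pytest.approx(haversine_distance(b, a))

    def test_invalid_coordinates(self):
        with pytest.raises(InvalidCoordinateError):
            haversine_distance((95.0, 0.0), (0.0, 0.0))


class TestImageClass:
    def test_single_species_multiple_polygons(self):
        im = make_image(species=("Solidago", "Solidago"))
        assert image_class(im) == "Solidago"

    def test_two_species(self):
        im = make_image(species=("Solidago", "Rosa rugosa"))
        assert image_class(im) == MULTIPLE_SPECIES

    def test_no_annotations(self):
        assert image_class(make_image()) == NO_SPECIES


def brute_force_clusters(images, threshold=40.0):
    """Transitive-closure oracle: BFS over the full pairwise distance matrix."""
    n = len(images)
    adj = [
        [
            haversine_distance(
                (images[i].latitude, images[i].longitude),
                (images[j].latitude, images[j].longitude),
            )
            < threshold
            for j in range(n)
        ]
        for i in range(n)
    ]
    seen, components = set(), []
    for start in range(n):
        if start in seen:
            continue
        queue, comp = [start], set()
        while queue:
            i = queue.pop()
            if i in comp:
                continue
            comp.add(i)
            queue.extend(j for j in range(n) if adj[i][j] and j not in comp)
        seen |= comp
        components.append(frozenset(images[i].image_id for i in comp))
    return set(components)


class TestBuildClusters:
    def test_chained_line(self):
        # 0, 30, 60 m along a meridian: ends are 60 m apart but chained via middle
        images = [
            make_image(image_id=f"i{k}", lat=56.0 + offset_lat(30.0 * k)) for k in range(3)
        ]
        clusters = build_clusters(images, threshold=40.0)
        assert len(clusters) == 1
        assert clusters[0].image_ids == {"i0", "i1", "i2"}

    def test_separated_singletons(self):
        images = [
            make_image(image_id="a"),
            make_image(image_id="b", lat=56.0 + offset_lat(50.0)),
        ]
        assert len(build_clusters(images, threshold=40.0)) == 2

    def test_empty_input(self):
        assert build_clusters([]) == []

    def test_matches_transitive_closure_oracle(self):
        rng = np.random.default_rng(8)
        for trial in range(5):
            n = int(rng.integers(20, 120))
            images = [
                make_image(
                    image_id=f"t{trial}i{k}",
                    lat=56.0 + offset_lat(float(rng.uniform(0, 600))),
                    lon=9.0 + float(rng.uniform(0, 0.01)),
                )
                for k in range(n)
            ]
            ours = {frozenset(c.image_ids) for c in build_clusters(images)}
            assert ours == brute_force_clusters(images)

    def test_order_independent(self):
        rng = np.random.default_rng(9)
        images = [
            make_image(image_id=f"i{k}", lat=56.0 + offset_lat(float(rng.uniform(0, 300))))
            for k in range(40)
        ]
        a = {frozenset(c.image_ids) for c in build_clusters(images)}
        b = {frozenset(c.image_ids) for c in build_clusters(images[::-1])}
        assert a == b


class TestPolygonIoU:
    def test_identical(self):
        p = Annotation(polygon=square(0, 0), species="Solidago")
        assert polygon_iou(p, p) == pytest.approx(1.0)

    def test_disjoint(self):
        p = Annotation(polygon=square(0, 0), species="Solidago")
        q = Annotation(polygon=square(500, 500), species="Solidago")
        assert polygon_iou(p, q) == 0.0

    def test_half_offset_unit_squares(self):
        p = Annotation(polygon=square(0, 0, side=1.0), species="Solidago")
        q = Annotation(polygon=square(0.5, 0, side=1.0), species="Solidago")
        assert polygon_iou(p, q) == pytest.approx(1 / 3)

    def test_symmetric_and_bounded(self):
        rng = np.random.default_rng(12)
        for _ in range(20):
            p = Annotation(polygon=square(*rng.uniform(0, 400, 2), side=150), species="Solidago")
            q = Annotation(polygon=square(*rng.uniform(0, 400, 2), side=150), species="Solidago")
            iou = polygon_iou(p, q)
            assert 0.0 <= iou <= 1.0
            assert iou == pytest.approx(polygon_iou(q, p))

    def test_degenerate_rejected_at_construction(self):
        with pytest.raises(InvalidAnnotationError):
            Annotation(polygon=[(0, 0), (1, 0), (2, 0)], species="Solidago")


class TestCleanDataset:
    def test_rare_class_removed(self):
        images = [make_image(image_id=f"s{k}", species=("Solidago",)) for k in range(12)]
        images += [make_image(image_id=f"h{k}", species=("Heracleum",)) for k in range(2)]
        kept, report = clean_dataset(images, min_class_images=10)
        assert report.rare_class == 2
        assert report.rare_classes_removed == ["Heracleum"]
        assert {image_class(im) for im in kept} == {"Solidago"}

    def test_overlapping_annotations_removed(self):
        bad = make_image(image_id="bad")
        bad.annotations = [
            Annotation(polygon=square(0, 0, side=100), species="Solidago"),
            Annotation(polygon=square(10, 0, side=100), species="Solidago"),  # IoU ~0.82
        ]
        kept, report = clean_dataset([bad], min_class_images=0)
        assert kept == [] and report.overlapping_annotations == 1

    def test_multiple_species_removed(self):
        images = [make_image(image_id="m", species=("Solidago", "Rosa rugosa"))]
        kept, report = clean_dataset(images, min_class_images=0)
        assert kept == [] and report.multiple_species == 1

    def test_clean_dataset_no_violations_unchanged(self):
        images = [make_image(image_id=f"i{k}", species=("Solidago",)) for k in range(5)]
        kept, report = clean_dataset(images, min_class_images=3)
        assert kept == images and report.total == 0

    def test_idempotent(self):
        rng = np.random.default_rng(13)
        images = []
        for k in range(40):
            sp = rng.choice(["Solidago", "Rosa rugosa", "Reynoutria"], size=rng.integers(0, 3))
            images.append(make_image(image_id=f"i{k}", species=tuple(sp)))
        once, _ = clean_dataset(images, min_class_images=8)
        twice, report2 = clean_dataset(once, min_class_images=8)
        assert [im.image_id for im in twice] == [im.image_id for im in once]
        assert report2.total == 0


class TestChi2:
    def test_perfect_fit(self):
        assert chi2_statistic({"a": 5, "b": 5}, {"a": 5, "b": 5}) == 0.0

    def test_hand_value(self):
        assert chi2_statistic({"a": 10, "b": 0}, {"a": 5, "b": 5}) == pytest.approx(10.0)

    def test_scaling_identity(self):
        o, e = {"a": 7, "b": 2}, {"a": 4, "b": 5}
        assert chi2_statistic(
            {k: 3 * v for k, v in o.items()}, {k: 3 * v for k, v in e.items()}
        ) == pytest.approx(3 * chi2_statistic(o, e))

    def test_zero_expected_excluded(self):
        assert chi2_statistic({"a": 3, "b": 9}, {"a": 3, "b": 0}) == 0.0

    def test_all_zero_expected(self):
        with pytest.raises(UndefinedStatisticError):
            chi2_statistic({"a": 1}, {"a": 0})


class TestSplitClusters:
    def singleton_clusters(self, n, species="Solidago"):
        clusters = [Cluster(cluster_id=f"c{k}", image_ids={f"i{k}"}) for k in range(n)]
        counts = {c.cluster_id: {species: 1} for c in clusters}
        return clusters, counts

    def test_singletons_hit_target_fractions(self):
        clusters, counts = self.singleton_clusters(100)
        split = split_clusters(clusters, counts, seed=3)
        shares = Counter(split.assignment.values())
        assert abs(shares["train"] - 70) <= 5
        assert abs(shares["validation"] - 15) <= 5
        assert abs(shares["test"] - 15) <= 5

    def test_deterministic_given_seed(self):
        clusters, counts = self.singleton_clusters(40)
        a = split_clusters(clusters, counts, seed=5)
        b = split_clusters(clusters, counts, seed=5)
        assert a.assignment == b.assignment

    def test_different_seed_shuffles(self):
        clusters, counts = self.singleton_clusters(40)
        a = split_clusters(clusters, counts, seed=5)
        b = split_clusters(clusters, counts, seed=6)
        # assignment as an ordered log differs even if shares agree
        assert [s.cluster_id for s in a.log] != [s.cluster_id for s in b.log]

    def test_fallback_to_train_when_nothing_improves(self):
        # Two identical 10-image clusters: the first fills train below its
        # 14-image target; the second would overshoot every set's chi2, so
        # the fallback rule sends it to train and is flagged in the log.
        clusters = [
            Cluster(cluster_id="a", image_ids={"i0"}),
            Cluster(cluster_id="b", image_ids={"i1"}),
        ]
        counts = {"a": {"Solidago": 10}, "b": {"Solidago": 10}}
        split = split_clusters(clusters, counts, seed=0)
        assert split.assignment == {"a": "train", "b": "train"}
        assert [s.fallback for s in split.log] == [False, True]

    def test_greedy_never_worsens_chosen_set_except_fallback(self):
        rng = np.random.default_rng(21)
        clusters, counts = [], {}
        for k in range(60):
            cid = f"c{k}"
            clusters.append(Cluster(cluster_id=cid, image_ids={f"i{k}"}))
            counts[cid] = {
                "Solidago": int(rng.integers(0, 6)),
                NO_SPECIES: int(rng.integers(1, 10)),
            }
        split = split_clusters(clusters, counts, seed=2)
        for step in split.log:
            if not step.fallback:
                assert step.chi2_after <= step.chi2_before + 1e-9

    def test_empty_cluster_list(self):
        split = split_clusters([], {}, seed=0)
        assert split.assignment == {}

    def test_invalid_fractions(self):
        with pytest.raises(ValueError):
            split_clusters([], {}, fractions=(0.5, 0.2, 0.2), seed=0)


class TestBalanceUpsample:
    def test_counts_equalized_cyclically(self):
        a = [make_image(image_id=f"a{k}", species=("Solidago",)) for k in range(3)]
        b = [make_image(image_id=f"b{k}", species=("Rosa rugosa",)) for k in range(5)]
        out = balance_upsample(a + b)
        counts = Counter(image_class(im) for im in out)
        assert counts["Solidago"] == counts["Rosa rugosa"] == 5
        extra = [im.image_id for im in out[8:]]
        assert extra == ["a0", "a1"]  # cyclic order

    def test_already_balanced_unchanged(self):
        images = [make_image(image_id=f"i{k}", species=("Solidago",)) for k in range(4)]
        assert balance_upsample(images) == images

    def test_single_class_unchanged(self):
        images = [make_image(image_id=f"i{k}") for k in range(3)]
        assert balance_upsample(images) == images

    def test_distinct_image_sets_preserved(self):
        a = [make_image(image_id=f"a{k}", species=("Solidago",)) for k in range(2)]
        b = [make_image(image_id=f"b{k}") for k in range(7)]
        out = balance_upsample(a + b)
        assert {im.image_id for im in out} == {im.image_id for im in a + b}


class TestSummarize:
    def test_bookkeeping_counts(self):
        images = [
            make_image(image_id="s1", species=("Solidago", "Solidago", "Solidago")),
            make_image(image_id="s2", species=("Solidago",)),
            make_image(image_id="n1"),
        ]
        clusters = [Cluster(cluster_id="c1", image_ids={"s1", "s2", "n1"})]
        table = summarize(images, clusters)
        day = images[0].acquisition_date.isoformat()
        assert table.loc["Solidago", (day, "I")] == 2
        assert table.loc["Solidago", (day, "P")] == 4  # 3 + 1 polygons
        assert table.loc[NO_SPECIES, (day, "I")] == 1
        assert int(table.xs("I", axis=1, level=1).to_numpy().sum()) == len(images)

    def test_empty(self):
        assert summarize([]).empty


class TestIO:
    def test_csv_json_round_trip(self, tmp_path):
        images = [
            make_image(image_id="r1", species=("Solidago",)),
            make_image(image_id="r2", lat=56.001),
        ]
        write_images_csv(images, tmp_path / "images.csv")
        write_annotations_json(images, tmp_path / "annotations.json")
        loaded = load_images(tmp_path / "images.csv", tmp_path / "annotations.json")
        assert [im.image_id for im in loaded] == ["r1", "r2"]
        assert loaded[0].annotations[0].species == "Solidago"
        assert loaded[0].annotations[0].polygon == images[0].annotations[0].polygon
        assert loaded[1].latitude == pytest.approx(56.001)

    def test_cvat_import(self, tmp_path):
        xml = (
            '<annotations><image name="frame1.jpg" width="1000" height="1000">'
            '<polygon label="Rosa rugosa" points="10,10;110,10;110,110;10,110"/>'
            "</image></annotations>"
        )
        (tmp_path / "cvat.xml").write_text(xml)
        anns = read_cvat_xml(tmp_path / "cvat.xml")
        assert list(anns) == ["frame1.jpg"]
        assert anns["frame1.jpg"][0].species == "Rosa rugosa"
        assert anns["frame1.jpg"][0].area == pytest.approx(10_000.0)

    def test_out_of_bounds_vertex_clipped_with_warning(self):
        with pytest.warns(UserWarning, match="clipped"):
            im = make_image(width=100, height=100, species=())
            im.annotations = []
            from iapsmon.dataset import GeoImage

            GeoImage(
                image_id="clip",
                latitude=56.0,
                longitude=9.0,
                timestamp=im.timestamp,
                acquisition_date=im.acquisition_date,
                width=100,
                height=100,
                annotations=[
                    Annotation(polygon=[(-5, 0), (50, 0), (50, 120), (-5, 120)], species="Solidago")
                ],
            )
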