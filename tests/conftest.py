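from datetime import date, datetime, timezone

import pytest

from iapsmon.dataset import Annotation, GeoImage

T0 = datetime(2020, 9, 15, 10, 0, 0, tzinfo=timezone.utc)
D0 = date(2020, 9, 15)


def square(x0: float, y0: float, side: float = 100.0) -> list[tuple[float, float]]:
    return [(x0, y0), (x0 + side, y0), (x0 + side, y0 + side), (x0, y0 + side)]


def make_image(
    image_id="img0",
    lat=56.0,
    lon=9.0,
    species=(),
    width=1000,
    height=1000,
    when=T0,
    day=D0,
):
    """A 1000x1000 px image with one 100x100 polygon per species listed."""
    anns = [
        Annotation(polygon=square(50 + 150 * i, 50), species=sp)
        for i, sp in enumerate(species)
    ]
    return GeoImage(
        image_id=image_id,
        latitude=lat,
        longitude=lon,
        timestamp=when,
        acquisition_date=day,
        width=width,
        height=height,
        annotations=anns,
    )


@pytest.fixture(scope="session")
def survey_run():
    """One full synthetic survey shared by the slower integration tests."""
    from iapsmon.dataset import build_clusters, clean_dataset
    from iapsmon.synthetic import example_scenario, generate_images, generate_track

    scenario = example_scenario(seed=11)
    images = generate_images(scenario)
    track = generate_track(scenario)
    clusters = build_clusters(images)
    kept, report = clean_dataset(images)
    return {
        "scenario": scenario,
        "images": images,
        "track": track,
        "clusters": clusters,
        "kept": kept,
        "report": report,
    }
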