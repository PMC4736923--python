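import numpy as np
import pytest

from iristex.annotation import Circle, IrisAnnotation, Point


@pytest.fixture
def concentric_annotation() -> IrisAnnotation:
    """Circles r = 50/100/200 all centred on (300, 300)."""
    c = Point(300.0, 300.0)
    return IrisAnnotation(
        id="concentric",
        iris_centre=c,
        pupil_centre=c,
        pupil_circle=Circle(c, 50.0),
        collarette_circle=Circle(c, 100.0),
        sclera_circle=Circle(c, 200.0),
    )


def make_offset_annotation(
    pupil_offset=(0.0, 0.0),
    collarette_offset=(0.0, 0.0),
    sclera_offset=(0.0, 0.0),
    radii=(50.0, 100.0, 200.0),
    centre=(300.0, 300.0),
    **kwargs,
) -> IrisAnnotation:
    cx, cy = centre
    rp, rc, rs = radii
    return IrisAnnotation(
        id=kwargs.pop("id", "offset"),
        iris_centre=Point(cx, cy),
        pupil_centre=Point(cx + pupil_offset[0], cy + pupil_offset[1]),
        pupil_circle=Circle(Point(cx + pupil_offset[0], cy + pupil_offset[1]), rp),
        collarette_circle=Circle(
            Point(cx + collarette_offset[0], cy + collarette_offset[1]), rc
        ),
        sclera_circle=Circle(Point(cx + sclera_offset[0], cy + sclera_offset[1]), rs),
        **kwargs,
    )


@pytest.fixture
def offset_annotation() -> IrisAnnotation:
    return make_offset_annotation(
        pupil_offset=(3.0, -2.0), collarette_offset=(15.0, -10.0), sclera_offset=(1.0, 1.0)
    )


def random_offset_annotation(rng: np.random.Generator) -> IrisAnnotation:
    """A valid, mildly non-concentric annotation with randomized layout."""
    rs = float(rng.uniform(150.0, 250.0))
    rc = float(rng.uniform(0.4, 0.6)) * rs
    rp = float(rng.uniform(0.4, 0.6)) * rc
    max_off = 0.05 * rs
    return make_offset_annotation(
        pupil_offset=tuple(rng.uniform(-0.3 * rp, 0.3 * rp, 2)),
        collarette_offset=tuple(rng.uniform(-max_off, max_off, 2)),
        sclera_offset=tuple(rng.uniform(-max_off, max_off, 2)),
        radii=(rp, rc, rs),
        centre=tuple(rng.uniform(290, 310, 2)),
    )
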