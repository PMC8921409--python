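import math

import numpy as np
import pytest

from spinealign.geometry import EndplateLine, KeyPointSet, Point2D


def random_keypointset(rng: np.random.Generator) -> KeyPointSet:
    """A geometrically plausible key-point set in canonical orientation
    (posterior toward +x), with endplate slopes within +/-60 degrees."""
    def plate(cy: float) -> EndplateLine:
        mid = Point2D(float(rng.uniform(100, 200)), cy)
        s = math.radians(float(rng.uniform(-60, 60)))
        half = float(rng.uniform(8, 25))
        return EndplateLine(
            Point2D(mid.x - half * math.cos(s), mid.y - half * math.sin(s)),
            Point2D(mid.x + half * math.cos(s), mid.y + half * math.sin(s)),
        )

    sacral = plate(600.0)
    m = sacral.midpoint
    pt = math.radians(float(rng.uniform(-40, 40)))
    length = float(rng.uniform(50, 120))
    f = Point2D(m.x - length * math.sin(pt), m.y + length * math.cos(pt))
    return KeyPointSet(
        c2_inf=plate(100.0), c7_inf=plate(170.0), t1_sup=plate(190.0),
        l1_sup=plate(480.0), s1_sup=sacral, femoral_center=f,
    )


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def phantom_pool():
    """A small shared pool of rendered phantoms (session-scoped: rendering
    is the slow part of many tests)."""
    from spinealign.phantom import PhantomSpec, generate_phantom

    specs = [
        PhantomSpec(seed=11, morphology="good_posture", posture="neutral"),
        PhantomSpec(seed=12, morphology="lumbar_lordosis", posture="flexion",
                    side="right_facing"),
        PhantomSpec(seed=13, morphology="thoracic_kyphosis", posture="extension"),
        PhantomSpec(seed=14, morphology="good_posture", posture="flexion",
                    occlusion=True),
    ]
    return [generate_phantom(s) for s in specs]
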