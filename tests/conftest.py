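import numpy as np
import pytest

import atlasanchor as aa


@pytest.fixture(scope="session")
def demo_xml() -> str:
    return aa.demo_descriptor_text("xml")


@pytest.fixture(scope="session")
def demo_json() -> str:
    return aa.demo_descriptor_text("json")


@pytest.fixture(scope="session")
def demo_series(demo_xml) -> aa.SeriesDescriptor:
    return aa.parse_xml(demo_xml)


@pytest.fixture(scope="session")
def slice2_anchoring(demo_series) -> aa.Anchoring:
    return demo_series.get(2).anchoring


@pytest.fixture(scope="session")
def synthetic_atlas():
    """64x80x56 synthetic atlas with 3 nested regions, seed 7."""
    return aa.make_synthetic_atlas((64, 80, 56), n_regions=3, seed=7)


def random_anchoring(rng: np.random.Generator, degenerate_ok: bool = False) -> aa.Anchoring:
    while True:
        o = rng.uniform(-100, 500, 3)
        u = rng.uniform(-300, 300, 3)
        v = rng.uniform(-300, 300, 3)
        a = aa.Anchoring(o, u, v)
        if degenerate_ok or np.linalg.norm(np.cross(u, v)) > 1e-6:
            return a
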