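import numpy as np
import pytest

from fidgetfusion import (
    Dataset,
    IMUSnippet,
    KeypointSnippet,
    PressureSnippet,
    SimConfig,
    SnippetMeta,
    SnippetTriple,
    generate_dataset,
)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def meta():
    return SnippetMeta(snippet_id="s000", infant_id="inf00", session="T5", label=1)


def make_triple(meta, rng, drop=()):
    """A random but structurally valid synchronized triple."""
    kp = KeypointSnippet(values=rng.normal(500, 30, (250, 15, 2)), meta=meta)
    pr = PressureSnippet(values=rng.uniform(0, 5, (500, 32, 32)), meta=meta)
    imu = IMUSnippet(values=rng.normal(0, 1, (300, 6, 6)), meta=meta)
    return SnippetTriple(
        meta=meta,
        keypoints=None if "VID" in drop else kp,
        pressure=None if "MAT" in drop else pr,
        imu=None if "IMU" in drop else imu,
    )


@pytest.fixture
def small_dataset(rng):
    """Ten complete triples from five infants, alternating labels."""
    triples = []
    for i in range(10):
        m = SnippetMeta(snippet_id=f"s{i:03d}", infant_id=f"inf{i % 5:02d}",
                        session="T5", label=i % 2)
        triples.append(make_triple(m, rng))
    return Dataset(triples=tuple(triples))


@pytest.fixture(scope="session")
def tiny_cohort():
    """A small simulated cohort with a clear class signal (session-scoped:
    simulation is the slow part of these tests)."""
    return generate_dataset(SimConfig(n_infants=6, snippets_per_infant=6, seed=42))


@pytest.fixture(scope="session")
def tiny_cohort_triple(tiny_cohort):
    return tiny_cohort.triples[0]
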