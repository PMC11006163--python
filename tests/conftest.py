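import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

import qtycode as q


@pytest.fixture(scope="session")
def reference_table():
    return q.load_reference_variants()


@pytest.fixture()
def tm_protein():
    """Tiny protein with one fully-annotated TM helix: positions 3-7."""
    rec = q.ProteinRecord(id="T1", sequence="GGLIVFKGDG")
    topo = q.Topology(
        protein_id="T1",
        segments=[q.TopologySegment(kind=q.SegmentKind.TM_HELIX, start=3, end=7, label="TM1")],
    )
    return rec, topo


@pytest.fixture(scope="session")
def synthetic_transporter():
    return q.generate_transporter(q.GeneratorConfig(seed=11))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
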