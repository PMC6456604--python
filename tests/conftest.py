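"""Shared fixtures: simulated studies reused across the suite.

The heavy simulations (a planted-signal PAR study at full desk scale and a
signal-free background study) are session-scoped so that pipeline, peak,
assignment and benchmark tests all run against the same data.
"""

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import clipseed as cs
from clipseed import workflows

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


def make_read(
    name="r1", umi="ACGTACGT", reference="tx", start=100, end=130,
    strand="+", blocks=None, sequence=None, mismatches=(), deletions=(),
    copy_number=1,
):
    """Hand-built read with a consistent default geometry."""
    if blocks is None:
        blocks = ((start, end),)
    if sequence is None:
        sequence = "A" * (sum(e - s for s, e in blocks) - len(deletions))
    return cs.AlignedRead(
        name=name, umi=umi, reference=reference, start=start, end=end,
        strand=strand, blocks=tuple(blocks), sequence=sequence,
        mismatches=tuple(mismatches), deletions=tuple(deletions),
        copy_number=copy_number,
    )


@pytest.fixture(scope="session")
def study():
    """Planted-signal PAR study: 300 transcripts, 30 miRNAs, 500 sites."""
    return workflows.run_planted_study(seed=1)


@pytest.fixture(scope="session")
def null_study():
    """Signal-free background study with tiling pseudo-clusters."""
    return workflows.run_null_study(seed=11)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
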