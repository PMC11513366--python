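"""Shared fixtures: seeded synthetic reference, completed design, transcript."""

import pytest
from hypothesis import HealthCheck, settings

from cas9tiling import (
    DesignConfig,
    FixtureSpec,
    GenomicRegion,
    TranscriptLayout,
    design_tiling,
    make_reference,
    make_transcript,
)

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def ref31k():
    """31,133 bp random reference at GC 0.4 (PAM-dense enough for tiling)."""
    return make_reference(FixtureSpec(seed=42, length=31133, gc_fraction=0.4))


@pytest.fixture(scope="session")
def locus31k(ref31k):
    return GenomicRegion(ref31k.name, 0, len(ref31k.sequence))


@pytest.fixture(scope="session")
def design31k(ref31k, locus31k):
    """Completed 4-pair tiling over the whole synthetic reference (no flanks)."""
    return design_tiling(ref31k, locus31k, DesignConfig(flank=0))


@pytest.fixture(scope="session")
def transcript31k(locus31k):
    return make_transcript(TranscriptLayout(), locus31k)
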