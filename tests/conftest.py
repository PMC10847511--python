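import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for oracles.py

from hrdscreen.genome import AlleleSpecificSegment, build_profile, toy_genome

MB = 1_000_000


@pytest.fixture(scope="session")
def arms():
    return toy_genome()


@pytest.fixture()
def rng():
    return np.random.default_rng(20240206)


@pytest.fixture()
def make_profile(arms):
    """Build a validated profile from (chrom, start, end, total, a, b) tuples."""

    def _make(*segs, sample_id="S1"):
        return build_profile(
            sample_id,
            [
                AlleleSpecificSegment(sample_id, chrom, start, end, total, a, b)
                for chrom, start, end, total, a, b in segs
            ],
            arms,
        )

    return _make


@pytest.fixture()
def balanced_profile(make_profile, arms):
    """Fully balanced diploid genome: one (2,1,1) segment per chromosome."""
    return make_profile(
        *[(c, 1, arms.length(c), 2, 1, 1) for c in arms.chromosomes]
    )
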