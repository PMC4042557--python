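import numpy as np
import pandas as pd
import pytest

from cnvsweep.calling import ProbeTrack
from cnvsweep.synthetic import Region, RegionSet, generate_probe_layout


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_track(ratios, sample_id="s1", population="pop1", region_ids=None, spacing=170):
    """Build a minimal single-chromosome track from a ratio vector."""
    n = len(ratios)
    if region_ids is None:
        region_ids = ["r1"] * n
    df = pd.DataFrame(
        {
            "chrom": ["chr1"] * n,
            "start": [i * spacing for i in range(n)],
            "end": [i * spacing + 60 for i in range(n)],
            "region_id": region_ids,
            "log2_ratio": list(ratios),
        }
    )
    return ProbeTrack(sample_id=sample_id, population=population, probes=df)


@pytest.fixture
def small_regions():
    return RegionSet(
        regions=[
            Region("chr1", 1000, 6000, "geneA"),
            Region("chr1", 20000, 28000, "geneB"),
            Region("chr2", 500, 4500, "geneC"),
        ],
        flank=1000,
    )


@pytest.fixture
def small_layout(small_regions):
    return generate_probe_layout(small_regions)
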