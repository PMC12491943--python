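import numpy as np
import pytest

from micromask import SequenceRecord, generate_host


@pytest.fixture
def tiny_target():
    return [
        SequenceRecord("c1", "ACGTACGTA"),
        SequenceRecord("c2", "GGGGCCCCAAAATTTT"),
    ]


@pytest.fixture
def random_contig():
    return generate_host(1, 1_000, seed=11)[0]


def base_coverage(regions, contigs):
    """Boolean per-base coverage masks, one per contig."""
    cov = {c.contig_id: np.zeros(c.length, dtype=bool) for c in contigs}
    for r in regions:
        cov[r.contig_id][r.start : r.end] = True
    return cov
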