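import numpy as np
import pytest

from tilechip.config import PipelineConfig
from tilechip.core_io import GeneModel, GenomeIndex, Interval, IntervalSet, ProbeTrack


@pytest.fixture
def cfg():
    return PipelineConfig()


@pytest.fixture
def small_genome():
    return GenomeIndex({"chr1": 100_000, "chr2": 80_000})


@pytest.fixture
def toy_genes():
    """Two plus and two minus genes, one divergent pair (g2-, g3+, gap 800)."""
    return [
        GeneModel("g1", "chr1", "+", 1000, 4000),
        GeneModel("g2", "chr1", "-", 10_000, 15_000),     # TSS 14999
        GeneModel("g3", "chr1", "+", 15_799, 19_000),     # TSS 15799
        GeneModel("g4", "chr2", "-", 2000, 6000),
    ]


def make_track(positions, values, probe_len=50, condition="control", n_reps=1):
    """Single-chromosome track helper: values may be 1-D (replicated) or 2-D."""
    positions = np.asarray(positions, dtype=np.int64)
    values = np.asarray(values, dtype=np.float64)
    if values.ndim == 1:
        values = np.repeat(values[:, None], n_reps, axis=1)
    samples = [(condition, r + 1) for r in range(values.shape[1])]
    return ProbeTrack(probe_len, samples, {"chr1": (positions, values)})


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
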