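import numpy as np
import pytest

from evotherm.simulate import SimulationConfig
from evotherm.variants import VariantRecord


@pytest.fixture
def small_config():
    """A fast pooled-seq config for pipeline tests."""
    return SimulationConfig(
        seed=11,
        n_treatments=2,
        n_replicates_per_treatment=2,
        n_sites=60,
        mean_depth=60.0,
        error_rate=0.0,
        n_het_sites=24,
        n_denovo_per_population=2,
        n_hetfix_per_population=6,
    )


@pytest.fixture
def record_factory():
    return make_record


def make_record(
    pos,
    *,
    chrom="chr1",
    ref="A",
    alt="G",
    qual=60.0,
    is_indel=False,
    depths=None,
    alt_depths=None,
    idv=None,
):
    depths = depths if depths is not None else {"s1": 20}
    alt_depths = alt_depths if alt_depths is not None else {"s1": 10}
    return VariantRecord(
        chrom=chrom,
        pos=pos,
        ref=ref,
        alt=alt,
        qual=qual,
        is_indel=is_indel,
        depths=depths,
        alt_depths=alt_depths,
        idv=idv,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
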