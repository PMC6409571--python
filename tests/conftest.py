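import numpy as np
import pytest
from hypothesis import settings

from trnaclusterscan.annotation_io import TrnaGene

settings.register_profile("default", derandomize=True, max_examples=50)
settings.load_profile("default")


def make_gene(start, end=None, isotype="M", anticodon="CAT", genome_id="g1", strand="+"):
    if end is None:
        end = start + 72
    return TrnaGene(
        genome_id=genome_id,
        start=start,
        end=end,
        strand=strand,
        isotype=isotype,
        anticodon=anticodon,
    )


def spaced_run(n, spacing, start=0, gene_len=72, genome_id="g1"):
    """n tRNA genes of gene_len bp whose starts are `spacing` bp apart."""
    return [
        make_gene(start + k * spacing, start + k * spacing + gene_len, genome_id=genome_id)
        for k in range(n)
    ]


def run_spanning(n, span_bp, start=0, gene_len=72, genome_id="g1"):
    """n genes laid out so the run spans exactly span_bp (first start to
    last end)."""
    assert n >= 2
    step = (span_bp - gene_len) / (n - 1)
    genes = []
    for k in range(n):
        s = start + round(k * step)
        genes.append(make_gene(s, s + gene_len, genome_id=genome_id))
    return genes


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
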