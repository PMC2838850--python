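import numpy as np
import pytest

from cgckit.cgc_scoring import GeneRecord
from cgckit.genome_partition import GeneLocus, GenomicInterval, QTLRegion
from cgckit.keyword_model import Keyword


@pytest.fixture
def basic_keywords():
    return (
        Keyword("arthritis", 100.0),
        Keyword("inflammation", 25.0),
        Keyword("joint pain", 7.5),
    )


@pytest.fixture
def small_corpus():
    return [
        GeneRecord("Ace", "chronic inflammation of joints"),
        GeneRecord("B2m", "inflammation, inflammation, arthritis"),
        GeneRecord("Tnf", "no relevant terms here"),
    ]


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


def make_locus(symbol, chrom, start, stop):
    return GeneLocus(symbol, GenomicInterval(chrom, start, stop))


def make_qtl(symbol, chrom, start, stop, cross="cross1"):
    return QTLRegion(symbol, GenomicInterval(chrom, start, stop), cross)
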