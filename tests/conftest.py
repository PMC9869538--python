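import pytest

from grhl2net.io_formats import Gene, GenomeAnnotation


@pytest.fixture
def toy_annotation() -> GenomeAnnotation:
    """Three hand-built genes: plus/minus strand multi-exon and single-exon."""
    genes = [
        Gene(
            "geneA", "chr1", 10000, 15000, "+",
            exons=((10000, 11000), (12000, 13000), (14000, 15000)),
            cds=(10200, 14800),
        ),
        Gene(
            "geneB", "chr1", 30000, 36000, "-",
            exons=((30000, 31500), (33000, 36000)),
            cds=(30500, 35500),
        ),
        Gene(
            "geneC", "chr2", 5000, 8000, "+",
            exons=((5000, 8000),),
            cds=(5100, 7900),
        ),
    ]
    return GenomeAnnotation(genes)
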