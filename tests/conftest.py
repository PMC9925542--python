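import io

import pytest

from fusionevo.genome import GeneAnnotation, GenomeAnnotation
from fusionevo import phylo


@pytest.fixture
def small_annotation() -> GenomeAnnotation:
    """Ten coding genes on one chromosome plus two on a second."""
    genes = [GeneAnnotation(f"A{i}", "chr1", 1000 * i, 1000 * i + 500)
             for i in range(1, 11)]
    genes += [GeneAnnotation("B1", "chr2", 1000, 1500),
              GeneAnnotation("B2", "chr2", 3000, 3500)]
    return GenomeAnnotation(genes)


@pytest.fixture(scope="session")
def primate_tree():
    return phylo.load_tree()


def tsv(text: str) -> io.StringIO:
    """Inline TSV fixture helper (strips leading spaces per line)."""
    lines = [l.strip() for l in text.strip().splitlines()]
    return io.StringIO("\n".join(lines))
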