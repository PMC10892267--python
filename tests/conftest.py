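import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))

from cubkit import (
    GeneratorConfig,
    count_codons,
    generate_cds_set,
    paper_worked_fixtures,
    standard_code,
)


@pytest.fixture(scope="session")
def code():
    return standard_code()


@pytest.fixture(scope="session")
def worked():
    """Deterministic fixtures mirroring published worked numbers."""
    return paper_worked_fixtures()


@pytest.fixture(scope="session")
def small_dataset():
    """A 60-gene synthetic family under default generator conditions."""
    return generate_cds_set(GeneratorConfig(seed=1, n_genes=60))


@pytest.fixture(scope="session")
def small_counts(small_dataset):
    return {c.gene_id: count_codons(c) for c in small_dataset.cds}


@pytest.fixture()
def toy_fasta(tmp_path):
    """Three tiny valid CDS records on disk."""
    path = tmp_path / "toy.fasta"
    path.write_text(
        ">geneA\nATGAAAAAGTTTTTCGGAGGCGGTGGGTGA\n"
        ">geneB\nATGAAAAAAAAGTTCCCACCGTAA\n"
        ">geneC\nATGGATGACGAAGAGCATCACTGTTGCTAG\n"
    )
    return path
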