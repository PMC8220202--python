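import pytest

from fishea.datasets import breakpoint_annotation, breakpoint_genes, replicate_karyotypes
from fishea.iscn import parse_karyotype


@pytest.fixture(scope="session")
def karyotype_table():
    """Replicate-well karyotype table (unexposed and exposed arms)."""
    return replicate_karyotypes()


@pytest.fixture(scope="session")
def exposed_karyotypes(karyotype_table):
    """The six exposed-arm karyotypes, parsed."""
    rows = karyotype_table[karyotype_table["condition"] == "exposed"]
    return [parse_karyotype(s) for s in rows["karyotype"]]


@pytest.fixture(scope="session")
def unexposed_karyotypes(karyotype_table):
    rows = karyotype_table[karyotype_table["condition"] == "unexposed"]
    return [parse_karyotype(s) for s in rows["karyotype"]]


@pytest.fixture(scope="session")
def annotation():
    """Hg19 annotation of the catalogued breakpoint-window genes."""
    return breakpoint_annotation()


@pytest.fixture(scope="session")
def gene_catalog():
    """Full catalog including observed signed fold changes."""
    return breakpoint_genes()
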