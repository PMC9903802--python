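import pytest

from svweave.config import Config
from svweave.genome_model import (
    Breakend,
    CopyNumberProfile,
    CopyNumberSegment,
    Junction,
    Karyotype,
    KnowledgeBase,
)
from svweave.simulate import toy_gene_model


@pytest.fixture(scope="session")
def karyotype():
    return Karyotype.toy()


@pytest.fixture(scope="session")
def gene_model():
    return toy_gene_model()


@pytest.fixture()
def config():
    return Config()


@pytest.fixture()
def uniform_profile(karyotype):
    """Flat diploid profile (cn 2, minor 1) over the toy karyotype."""
    def make(cn: float = 2.0, minor: float = 1.0) -> CopyNumberProfile:
        return CopyNumberProfile([
            CopyNumberSegment(c.name, 1, c.length, cn, minor)
            for c in karyotype.chromosomes.values()
        ])
    return make


def make_breakend(bid, chrom, pos, orient, **kw):
    return Breakend(bid, chrom, pos, orient, **kw)


def make_junction(jid, chrom1, pos1, o1, chrom2=None, pos2=None, o2=None,
                  jcn=1.0, **kw):
    b1 = Breakend(f"{jid}_a", chrom1, pos1, o1,
                  insert_sequence=kw.pop("insert", ""),
                  assembly_ids=kw.pop("asm1", []))
    b2 = None
    if chrom2 is not None:
        b2 = Breakend(f"{jid}_b", chrom2, pos2, o2,
                      assembly_ids=kw.pop("asm2", []))
    return Junction(jid, b1, b2, jcn, **kw)


@pytest.fixture()
def junction_factory():
    return make_junction
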