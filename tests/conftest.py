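import pytest

from ironmr.gwas_io import (AssociationRecord, load_als_fixture,
                            load_iron_table)
from ironmr.harmonize import HarmonizedInstrument, harmonize_set
from ironmr.instruments import conservative_set, liberal_set


@pytest.fixture(scope="session")
def iron_table():
    return load_iron_table()


@pytest.fixture(scope="session")
def als_records():
    return load_als_fixture()


@pytest.fixture(scope="session")
def conservative_instruments(iron_table, als_records):
    """Harmonized conservative (3-SNP) instruments, keyed by biomarker."""
    return {
        b: list(harmonize_set(conservative_set(iron_table, trait=b), als_records).instruments)
        for b in iron_table
    }


@pytest.fixture(scope="session")
def liberal_instruments(iron_table, als_records):
    """Harmonized liberal per-biomarker instruments."""
    return {
        b: list(harmonize_set(liberal_set(iron_table, b), als_records).instruments)
        for b in iron_table
    }


def make_inst(rsid="snp", bx=0.1, se_x=0.01, by=0.01, se_y=0.01, **kw) -> HarmonizedInstrument:
    return HarmonizedInstrument(rsid=rsid, effect_allele="A", bx=bx, se_x=se_x,
                                by=by, se_y=se_y, **kw)


def make_record(rsid="rs1", ea="A", oa="G", beta=0.1, se=0.01, eaf=0.3,
                pvalue=1e-9, **kw) -> AssociationRecord:
    return AssociationRecord(rsid=rsid, effect_allele=ea, other_allele=oa,
                             beta=beta, se=se, eaf=eaf, pvalue=pvalue, **kw)
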