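import pytest

from iopgenes import tables_io


@pytest.fixture(scope="session")
def fixtures():
    """All packaged printed-table transcriptions, loaded once."""
    return {name: tables_io.load_fixture(name) for name in tables_io.FIXTURE_ROW_COUNTS}


@pytest.fixture(scope="session")
def evidence_bundle(fixtures):
    from iopgenes.prioritization import EvidenceBundle

    return EvidenceBundle(
        de_tm=fixtures["table1"],
        de_sc=fixtures["table2"],
        cells_expr=fixtures["table3"],
        ocular_db=fixtures["table4"],
        tissue_expr=fixtures["table5"],
        variants=fixtures["table6"],
        stretch_de=fixtures["table7"],
    )
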