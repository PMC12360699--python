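import pytest

from bcrlik import (
    GermlineAnchoredProvider,
    SimulationConfig,
    simulate_repertoire,
)
from bcrlik.records import CellRecord, ChainRecord


def make_chain(
    cell_id,
    locus="heavy",
    sequence="ACDEFGHIKL",
    germline="ACDEFGHIKL",
    v_call="IGHV1-1*01",
    c_call="IGHM",
    cdr3_span=(3, 7),
    sample_id="s1",
):
    span = cdr3_span
    return ChainRecord(
        cell_id=cell_id,
        locus=locus,
        sequence_aa=sequence,
        germline_aa=germline,
        v_call=v_call,
        c_call=c_call,
        cdr3_aa=sequence[span[0]:span[1]] if span else "",
        cdr3_span=span,
        sample_id=sample_id,
    )


def make_cell(cell_id, heavy_seq="ACDEFGHIKL", germline="ACDEFGHIKL", c_call="IGHM"):
    return CellRecord(
        cell_id=cell_id,
        heavy=make_chain(cell_id, "heavy", heavy_seq, germline, c_call=c_call),
        light=make_chain(cell_id, "light", "LMNPQRSTVW", "LMNPQRSTVW",
                         v_call="IGKV1-1*01", c_call="IGKC"),
        sample_id="s1",
    )


@pytest.fixture(scope="session")
def small_sim():
    return simulate_repertoire(SimulationConfig(n_cells=150, seed=1))


@pytest.fixture(scope="session")
def small_rep(small_sim):
    return small_sim.to_repertoire()


@pytest.fixture(scope="session")
def germline_provider(small_rep):
    return GermlineAnchoredProvider.from_cells(small_rep.cells, q=0.7)
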