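import pytest

from concerted import GroupedAlignment, Record
from concerted.simulate import make_worked_fixtures


def make_aln(rows, populations=None, paralogs=None):
    """Build a GroupedAlignment from residue strings; default one group."""
    records = []
    for k, seq in enumerate(rows):
        pop = populations[k] if populations else "pop1"
        par = paralogs[k] if paralogs else "p1"
        records.append(Record(f"h{k + 1}", pop, par, seq))
    return GroupedAlignment(records)


@pytest.fixture(scope="session")
def fixtures():
    """The bundled deterministic worked fixtures (built once per session)."""
    return make_worked_fixtures()
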