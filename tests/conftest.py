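import pytest

import pamscan as ps
from pamscan.synthetic_data import SynthSpec, make_genome


@pytest.fixture(scope="session")
def marker_table():
    """Published fungal species marker targets (13 rows)."""
    return ps.load_marker_targets()


@pytest.fixture()
def tiny_genome():
    """A 5-kb seeded genome with a handful of spontaneous PAM sites."""
    return make_genome(SynthSpec(seed=11, length=5000, genome_id="tiny"))


@pytest.fixture()
def gl_target():
    """The Ganoderma lucidum marker as a Target anchored at position 0."""
    seq = "TTTGTAGGCTTGGACTTGGAGGCTT"
    return ps.Target(
        target_id="gl", genome_id="gl_genome", contig_name="c1",
        start=0, strand="+", sequence=seq,
    )
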