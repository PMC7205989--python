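import pytest

from metagenehunt.mgrast import SimilarityRecord
from metagenehunt.rat import RAT, DomainEnvelope


def make_record(
    query_id="read1",
    md5="abc123",
    s_start=10,
    s_end=49,
    bit_score=88.2,
    e_value=1e-12,
    **kw,
):
    defaults = dict(
        pct_identity=92.3,
        aln_length=s_end - s_start + 1,
        mismatches=3,
        gap_openings=0,
        q_start=1,
        q_end=120,
    )
    defaults.update(kw)
    return SimilarityRecord(
        query_id=query_id,
        subject_md5=md5,
        s_start=s_start,
        s_end=s_end,
        e_value=e_value,
        bit_score=bit_score,
        **defaults,
    )


@pytest.fixture
def tiny_rat():
    """Three proteins: single-domain, two-domain, and one with overlapping
    subdomain envelopes."""
    rat = RAT(lengths={"GH13": 450, "GH3": 600, "GH3C": 200, "CBM48": 100})
    rat.add(DomainEnvelope("prot1", "GH13", 100, 300))
    rat.add(DomainEnvelope("prot2", "GH3", 50, 500))
    rat.add(DomainEnvelope("prot2", "CBM48", 560, 640))
    rat.add(DomainEnvelope("prot3", "GH3", 10, 400))
    rat.add(DomainEnvelope("prot3", "GH3C", 250, 400))
    return rat
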