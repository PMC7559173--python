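import pytest

from famli.alignment_io import AlignmentRecord, AlignmentSet
from famli.benchmark import community_benchmark, multimapping_experiment


def make_set(rows, lengths, **kwargs):
    """AlignmentSet from (query, subject, pident, bitscore, sstart, send)."""
    records = [
        AlignmentRecord(
            query_id=q,
            subject_id=s,
            percent_identity=pid,
            align_length=send - sstart + 1,
            subject_start=sstart,
            subject_end=send,
            bitscore=bits,
        )
        for q, s, pid, bits, sstart, send in rows
    ]
    return AlignmentSet.from_records(records, lengths, **kwargs)


@pytest.fixture(scope="session")
def mm_exp():
    """The controlled multi-mapping design: 3 true CDS x 120 error-free read
    pairs against a reference set of the truths plus 30 decoy homologs."""
    return multimapping_experiment(seed=1)


@pytest.fixture(scope="session")
def bench():
    """One seeded 20-genome community run through the filter and the
    all-hits / unique-hits mapping baselines."""
    return community_benchmark(seed=1)
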