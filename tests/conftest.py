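import numpy as np
import pytest
from hypothesis import settings

from nerpeseq import ConstructSpec, ReadPair, TemplateProductPair

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")


@pytest.fixture(scope="session")
def spec() -> ConstructSpec:
    return ConstructSpec()


def make_pair(template: str, product: str, source_id: str = "") -> TemplateProductPair:
    return TemplateProductPair.from_sequences(template, product, source_id=source_id)


def reads_from_insert(
    insert: str,
    read_len: int = 70,
    q: int = 37,
    rid: str = "r1",
    fwd_qual=None,
    rev_qual=None,
) -> ReadPair:
    """Render one insert into an idealized read pair (no sequencing error)."""
    from nerpeseq import reverse_complement

    rl = min(read_len, len(insert))
    fwd = insert[:rl]
    rev = reverse_complement(insert[-rl:])
    return ReadPair(
        id=rid,
        fwd_seq=fwd,
        rev_seq=rev,
        fwd_qual=np.full(rl, q) if fwd_qual is None else np.asarray(fwd_qual),
        rev_qual=np.full(rl, q) if rev_qual is None else np.asarray(rev_qual),
    )
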