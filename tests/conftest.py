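import random

import pytest

from splicedose.gene_model import GeneModel, TranscriptModel, tyk2_like_fixture


@pytest.fixture(scope="session")
def tyk2_like():
    """(gene, forward primer, reverse primer) of the packaged cassette gene."""
    return tyk2_like_fixture()


def random_gene(rng: random.Random, max_tx: int = 6, max_exons: int = 10) -> GeneModel:
    """A random multi-isoform gene with sorted exons and intron gaps >= 1 nt
    within each transcript (abutting exons never occur in one isoform)."""
    transcripts = []
    for i in range(rng.randint(1, max_tx)):
        pos = rng.randint(0, 50)
        exons = []
        for _ in range(rng.randint(1, max_exons)):
            start = pos + rng.randint(1, 20)
            end = start + rng.randint(1, 30)
            exons.append((start, end))
            pos = end
        transcripts.append(TranscriptModel(f"T{i}", tuple(exons), "+"))
    return GeneModel("G", "chr1", "+", tuple(transcripts))
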