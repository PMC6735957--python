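import numpy as np
import pytest

from lncforge.genome_model_io import GenomicInterval, TranscriptModel


def make_transcript(
    tid="tx1",
    gene="g1",
    chrom="chr1",
    strand="+",
    exons=((100, 200), (300, 400)),
    source="assembled",
    biotype="other",
):
    return TranscriptModel(
        transcript_id=tid,
        gene_id=gene,
        exons=[GenomicInterval(chrom, s, e, strand) for s, e in exons],
        source=source,
        biotype=biotype,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def random_transcripts(rng):
    """50 random multi/single-exon transcripts on a toy chromosome."""
    out = []
    for i in range(50):
        n_exons = int(rng.integers(1, 5))
        strand = "+" if rng.random() < 0.5 else "-"
        pos = int(rng.integers(1, 100_000))
        exons = []
        for _ in range(n_exons):
            length = int(rng.integers(50, 500))
            exons.append((pos, pos + length - 1))
            pos += length + int(rng.integers(50, 2_000))
        out.append(
            make_transcript(
                tid=f"rand{i}", gene=f"gene{i}", strand=strand, exons=tuple(exons)
            )
        )
    return out
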