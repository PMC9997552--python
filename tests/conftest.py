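import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("suite", derandomize=True, deadline=None)
settings.load_profile("suite")

from psiseq.reference import GenomeRef, TranscriptModel
from psiseq.simulate import SyntheticConfig, PairSpec, simulate_dataset


@pytest.fixture
def tiny_genome():
    # chr1 carries a plus-strand two-exon gene; chr2 a minus-strand gene
    return GenomeRef(
        contigs={
            "chr1": "ACGTTTGATGCTGTAACCGGTTAACCGGATCGATCGTACGTACGTTTAAA",
            "chr2": "TTTTACGCGCGCGATATATATGCGCGCATATTTTTTGGGGCCCCAAAATT",
            "spike": "ACGT" * 10,
        },
        classes={"chr1": "nuclear", "chr2": "mitochondrial", "spike": "spikein"},
    )


@pytest.fixture
def plus_transcript():
    # exons 5..25 and 30..40 (0-based half-open): length 30, CDS 6..24
    return TranscriptModel(
        transcript_id="t1",
        gene_id="g1",
        biotype="mRNA",
        contig="chr1",
        strand="+",
        exons=((5, 25), (30, 40)),
        cds=(6, 24),
    )


@pytest.fixture
def minus_transcript():
    return TranscriptModel(
        transcript_id="t2",
        gene_id="g2",
        biotype="mRNA",
        contig="chr2",
        strand="-",
        exons=((10, 30), (35, 45)),
        cds=(3, 27),
    )


def small_config(**overrides):
    """Reduced-size generator config for fast tests (all rate parameters
    at their defaults)."""
    defaults = dict(
        n_transcripts=6,
        layout=(
            PairSpec("c1", "control", "Exp1"),
            PairSpec("c2", "control", "Exp2"),
            PairSpec("m1", "mutant", "Exp2", is_mutant=True),
        ),
        seed=11,
    )
    defaults.update(overrides)
    return SyntheticConfig(**defaults)


@pytest.fixture(scope="session")
def default_dataset():
    """Full default-condition dataset (7 control + 4 mutant pairs)."""
    return simulate_dataset(SyntheticConfig(seed=7))


@pytest.fixture(scope="session")
def small_dataset():
    return simulate_dataset(small_config())
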