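import pytest

from splicebench.gene_models import GeneModel, Transcript, synth_annotation


@pytest.fixture
def se_gene() -> GeneModel:
    """Two transcripts differing by one internal skipped exon."""
    return GeneModel(
        "gSE",
        "chr1",
        "+",
        [
            Transcript("gSE.1", ((1, 100), (201, 300), (401, 500))),
            Transcript("gSE.2", ((1, 100), (401, 500))),
        ],
    )


@pytest.fixture
def ir_gene() -> GeneModel:
    """Two transcripts differing by one retained intron."""
    return GeneModel(
        "gIR",
        "chr1",
        "+",
        [
            Transcript("gIR.1", ((1, 100), (201, 300))),
            Transcript("gIR.2", ((1, 300),)),
        ],
    )


@pytest.fixture(scope="session")
def mixed_genes():
    """A small deterministic synthetic annotation covering all classes."""
    mix = {
        "SE": 0.2,
        "IR": 0.2,
        "A3A5SS": 0.2,
        "MXE": 0.1,
        "complex": 0.1,
        "multi_event": 0.1,
        "single_isoform": 0.1,
    }
    return synth_annotation(60, mix, seed=7)
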