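import pytest

from tagdge import synthetic as syn
from tagdge.tag_library import build_reference_library


@pytest.fixture(scope="session")
def small_transcriptome():
    """200 genes, 10% untaggable — shared across read-only tests."""
    return syn.generate_transcriptome(
        syn.TranscriptomeParams(n_genes=200, fraction_untaggable=0.1, seed=42))


@pytest.fixture(scope="session")
def small_reference(small_transcriptome):
    return build_reference_library(small_transcriptome.records)
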