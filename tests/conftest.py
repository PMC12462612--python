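import pytest

from phenodefminer.corpus_io import SentenceRecord
from phenodefminer.lexicon import Lexicon, LexiconEntry, load_toy_lexicon
from phenodefminer.ner_features import load_default_schema

# A published methods sentence (PMID 12952547) in which "asthma" is
# mentioned three times alongside the definition keyword "defined as" —
# the canonical demonstration of the entity x definition co-occurrence.
WORKED_EXAMPLE_TEXT = (
    "Confirmed adult-onset asthma (AOA) cases were defined as those potential "
    "cases with either new-onset asthma or reactivated mild intermittent "
    "asthma that had been quiescent for at least one year"
)


@pytest.fixture(scope="session")
def toy_lexicon():
    return load_toy_lexicon()


@pytest.fixture(scope="session")
def default_schema():
    return load_default_schema()


@pytest.fixture()
def worked_example_sentence():
    return SentenceRecord(pmid="12952547", sentence_index=0, text=WORKED_EXAMPLE_TEXT)


@pytest.fixture()
def asthma_lexicon():
    """Minimal dictionary with 'asthma' as a clinical entity."""
    return Lexicon(
        [LexiconEntry("asthma", "asthma", "clinical", "SNOMED_CT", "SCT:195967001")]
    )
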