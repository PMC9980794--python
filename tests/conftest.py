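import pytest

from mitoscreen.literature_ranking import (
    CANDIDATE,
    TRAINING,
    Document,
    EntityCorpus,
    RankingConfig,
)


def make_corpus(entity_docs, training=()):
    """Build an EntityCorpus from {entity: [(year, text), ...]}."""
    entities = {
        eid: [Document(year=y, text=t) for y, t in docs]
        for eid, docs in entity_docs.items()
    }
    roles = {eid: TRAINING if eid in training else CANDIDATE for eid in entities}
    return EntityCorpus(entities, roles)


@pytest.fixture
def toy_corpus():
    """Three entities with tiny hand-checkable vocabularies."""
    return make_corpus(
        {
            "drugA": [(2010, "kinase inhibitor mitophagy"), (2011, "kinase assay")],
            "drugB": [(2012, "kinase inhibitor"), (2013, "receptor agonist")],
            "drugC": [(2014, "zebrafish larvae behaviour")],
        }
    )


@pytest.fixture
def permissive_config():
    return RankingConfig(min_abstracts=1)
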