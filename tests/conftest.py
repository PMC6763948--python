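import pytest

import evilit
from evilit.synthetic_corpus import CorpusSpec


@pytest.fixture(scope="session")
def genus_lex():
    return evilit.load_genus_lexicon()


@pytest.fixture(scope="session")
def disease_lex():
    return evilit.load_disease_lexicon()


@pytest.fixture(scope="session")
def tiny_articles():
    """Three hand-built abstracts: A1 Escherichia+ulcer (keyword 'immune'),
    A2 Escherichia & Lactobacillus, A3 no entities."""
    return [
        evilit.Article(
            pmid="A1",
            title="Escherichia and gastric disease",
            abstract="Escherichia coli was linked to ulcer formation and the "
                     "immune response of the host.",
        ),
        evilit.Article(
            pmid="A2",
            title="Gut community profiling",
            abstract="Escherichia and Lactobacillus were both detected in "
                     "stool samples.",
        ),
        evilit.Article(
            pmid="A3",
            title="An unrelated methods paper",
            abstract="This work describes laboratory procedures only.",
        ),
    ]


@pytest.fixture(scope="session")
def tiny_index(tiny_articles, genus_lex, disease_lex):
    return evilit.build_index(tiny_articles, genus_lex, disease_lex)


def make_random_spec(seed, n_articles=30, misspelling=0.0, abbreviation=0.0):
    """A small randomized corpus spec for property tests."""
    import numpy as np

    rng = np.random.default_rng(seed)
    genera = ["Escherichia", "Lactobacillus", "Bacteroides", "Prevotella",
              "Veillonella", "Staphylococcus", "Streptococcus", "Helicobacter"]
    diseases = ["ulcer", "asthma", "diarrhea", "obesity", "psoriasis"]
    k_g = int(rng.integers(2, len(genera) + 1))
    k_d = int(rng.integers(1, len(diseases) + 1))
    return CorpusSpec(
        n_articles=n_articles,
        seed=int(rng.integers(2**31)),
        genus_vocab=genera[:k_g],
        disease_vocab=diseases[:k_d],
        genus_baseline=float(rng.uniform(0.1, 0.4)),
        disease_baseline=float(rng.uniform(0.1, 0.4)),
        trend_injection_prob=float(rng.uniform(0, 1)),
        misspelling_rate=misspelling,
        abbreviation_rate=abbreviation,
    )


@pytest.fixture(scope="session")
def random_index_factory(genus_lex, disease_lex):
    def factory(seed, **kwargs):
        spec = make_random_spec(seed, **kwargs)
        articles, truth = evilit.generate_corpus(spec)
        index = evilit.build_index(articles, genus_lex, disease_lex)
        return index, truth, spec

    return factory
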