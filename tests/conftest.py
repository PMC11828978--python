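import pytest
from hypothesis import HealthCheck, settings

from echomap import (
    CascadeConfig,
    GeneratorConfig,
    MappingTriple,
    Ontology,
    OntologyTerm,
    generate_dictionary,
    generate_ontology,
    split_dictionary,
    train_cascade,
)

settings.register_profile(
    "ci", derandomize=True, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def toy_ontology() -> Ontology:
    """Two L1, two L2, two L3 terms; two licensed triples — enough to
    exercise licensed/novel/unknown triple logic by hand."""
    terms = [
        OntologyTerm("aortic valve", 1),
        OntologyTerm("left ventricle", 1, synonyms=("lv",)),
        OntologyTerm("function", 2),
        OntologyTerm("mass", 2),
        OntologyTerm("hyperdynamic", 3),
        OntologyTerm("none", 3),
    ]
    triples = [
        MappingTriple("left ventricle", "function", "hyperdynamic"),
        MappingTriple("aortic valve", "mass", "none"),
    ]
    return Ontology(terms, triples)


CLEAN_CFG = GeneratorConfig(seed=7, typo_rate=0.0, abbrev_rate=0.0)


@pytest.fixture(scope="session")
def clean_world():
    """Separable-by-construction synthetic study: 600 train / 200 held out,
    no typos or abbreviations."""
    o = generate_ontology(CLEAN_CFG)
    sentences = generate_dictionary(o, CLEAN_CFG)
    train, val = split_dictionary(sentences, 0.25, seed=7)
    return o, train, val


@pytest.fixture(scope="session")
def clean_model(clean_world):
    o, train, _ = clean_world
    return train_cascade(train, o, ccfg=CascadeConfig(seed=7))


@pytest.fixture(scope="session")
def noisy_world():
    """Default study conditions: 8% negation, abbreviations and typos on."""
    cfg = GeneratorConfig(seed=7)
    o = generate_ontology(cfg)
    sentences = generate_dictionary(o, cfg)
    train, val = split_dictionary(sentences, 0.25, seed=7)
    return o, cfg, train, val
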