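import numpy as np
import pytest

from kgwalk import (KnowledgeGraph, SyntheticSpec, generate,
                    generate_reasoning_benefit)


@pytest.fixture(scope="session")
def synthetic_kg():
    """Default planted two-community graph and its ground truth."""
    return generate(SyntheticSpec())


@pytest.fixture(scope="session")
def benefit_kg():
    """Reasoning-benefit fixture graph and ground truth."""
    return generate_reasoning_benefit(SyntheticSpec())


@pytest.fixture()
def small_spec():
    """A quick-to-generate scaled-down generator configuration."""
    return SyntheticSpec(entities={"drug": 12, "protein": 15, "disease": 8},
                         annotation_rate=1)


def make_chain_kg():
    """a -(r)-> b -(s)-> c with declared properties."""
    kg = KnowledgeGraph()
    for n in ("a", "b", "c"):
        kg.add_individual(n)
    kg.add_property("r")
    kg.add_property("s")
    kg.add_edge("a", "r", "b")
    kg.add_edge("b", "s", "c")
    return kg


@pytest.fixture()
def chain_kg():
    return make_chain_kg()
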