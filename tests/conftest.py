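import pytest

from foodweb_assembly import FoodWeb, Link, Species
from foodweb_assembly.generators import layered_web


@pytest.fixture
def chain_web():
    """basal → A → B over a shared nutrient."""
    return FoodWeb(
        (Species("basal", nutrient_id="N"), Species("A"), Species("B")),
        (Link("basal", "A"), Link("A", "B")),
        nutrient_mode="shared",
    )


@pytest.fixture
def pair_web():
    """Single basal species and its consumer."""
    return FoodWeb(
        (Species("b", nutrient_id="N"), Species("c")),
        (Link("b", "c"),),
        nutrient_mode="shared",
    )


@pytest.fixture
def two_basal_web():
    """Two basal species competing for one shared nutrient; one consumer of
    both; one top predator — the classic rule-violating (2,1,1) profile."""
    return FoodWeb(
        (
            Species("b1", nutrient_id="N"),
            Species("b2", nutrient_id="N"),
            Species("c"),
            Species("d"),
        ),
        (Link("b1", "c"), Link("b2", "c"), Link("c", "d")),
        nutrient_mode="shared",
    )


def full_layered(counts, nutrient_mode="shared", seed=0):
    """Layered web with complete adjacent-level connectivity."""
    max_links = sum(counts[i] * counts[i + 1] for i in range(len(counts) - 1))
    return layered_web(counts, max_links, seed=seed, nutrient_mode=nutrient_mode)


@pytest.fixture
def omnivore_rescue_web():
    """A rule-violating (2,2,2) shared-nutrient web rescued by a single
    generalist omnivore preying on one species of every level."""
    base = full_layered((2, 2, 2))
    return base.with_species(
        (Species("O"),),
        (Link("L1_1", "O"), Link("L2_1", "O"), Link("L3_1", "O")),
    )
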