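"""Synthetic web generators: trees, layered webs, niche/cascade models,
parasites and concomitant links."""

import numpy as np
import pytest

from foodweb_assembly import (
    LevelProfile,
    nullity,
    prey_averaged_levels,
    sharp_levels,
    validate_web,
)
from foodweb_assembly.generators import (
    GENERIC_LEVEL_COUNTS,
    add_concomitant_links,
    add_parasites,
    cascade_model,
    generic_web,
    layered_web,
    niche_model,
    tree_web,
)
from foodweb_assembly.web import (
    CONCOMITANT_ASYM,
    CONCOMITANT_SYM,
    PARASITIC,
    FoodWeb,
    Link,
    Species,
)


def test_tree_webs_are_coherent_and_full_rank():
    for seed in range(20):
        web = tree_web((2, 3, 2, 1), seed=seed)
        assert validate_web(web) == []
        levels = prey_averaged_levels(web)
        for link in web.links:
            assert levels[link.consumer] - levels[link.resource] == 1.0
        assert nullity(web, seed=seed) == 0


def test_tree_rejects_violating_profile():
    with pytest.raises(ValueError, match="assembly rules"):
        tree_web((2, 1, 1))


def test_trivial_tree_is_a_chain():
    web = tree_web((1, 1))
    assert [s.id for s in web.species] == ["L1_1", "L2_1"]
    assert len(web.links) == 1


def test_layered_web_structure():
    web = layered_web((2, 2), 4, seed=0)
    assert len(web.links) == 4  # complete bipartite
    for seed in range(5):
        web = layered_web((3, 4, 2), 13, seed=seed)
        assert validate_web(web) == []
        assert len(web.links) == 13
        levels = sharp_levels(prey_averaged_levels(web))
        for link in web.links:
            assert levels[link.consumer] - levels[link.resource] == 1
    # reproducibility
    a = layered_web((3, 4, 2), 13, seed=9)
    b = layered_web((3, 4, 2), 13, seed=9)
    assert a.links == b.links


def test_layered_web_link_bounds():
    with pytest.raises(ValueError, match="infeasible"):
        layered_web((2, 2), 1, seed=0)  # below spanning minimum
    with pytest.raises(ValueError, match="infeasible"):
        layered_web((2, 2), 5, seed=0)  # above complete bipartite


@pytest.mark.parametrize("model", [niche_model, cascade_model])
def test_model_webs_are_valid_and_reproducible(model):
    a = model(50, 0.12, seed=4)
    b = model(50, 0.12, seed=4)
    assert a.species == b.species and a.links == b.links
    assert a.S == 50
    assert validate_web(a) == []


@pytest.mark.parametrize("model", [niche_model, cascade_model])
def test_model_realized_connectance(model):
    """Mean realized L/S² within 3 standard errors of the target C."""
    S, C = 40, 0.15
    realized = [len(model(S, C, seed=s).links) / S**2 for s in range(100)]
    se = np.std(realized) / np.sqrt(len(realized))
    assert abs(np.mean(realized) - C) < 3 * se + 0.01


def test_model_parameter_validation():
    with pytest.raises(ValueError):
        niche_model(50, 0.6)
    with pytest.raises(ValueError):
        cascade_model(50, 0.0)


def test_parasite_counts_and_kinds():
    web = generic_web(seed=0)
    out = add_parasites(web, "c", parasite_count=47, links_per_parasite=2.0,
                        seed=1)
    assert len(out.parasite_ids) == 47
    assert out.S == web.S + 47
    n_links = sum(1 for l in out.links if l.link_type == PARASITIC)
    assert n_links == 94
    assert validate_web(out) == []


def test_case_d_confines_each_parasite_to_one_level():
    web = generic_web(seed=2)
    levels = sharp_levels(prey_averaged_levels(web))
    out = add_parasites(web, "d", parasite_count=10, links_per_parasite=4.0,
                        seed=3)
    hosts: dict[str, set[int]] = {}
    for link in out.links:
        if link.link_type == PARASITIC:
            hosts.setdefault(link.consumer, set()).add(levels[link.resource])
    for pid, host_levels in hosts.items():
        assert len(host_levels) == 1, pid


def test_case_f_adds_hyperparasitism():
    web = generic_web(seed=2)
    out = add_parasites(web, "f", parasite_count=47, links_per_parasite=8.0,
                        seed=3)
    parasites = set(out.parasite_ids)
    pp = [l for l in out.links
          if l.link_type == PARASITIC and l.resource in parasites]
    total = sum(1 for l in out.links if l.link_type == PARASITIC)
    assert 0 < len(pp) / total < 0.15  # ~5% of parasite links


def test_case_e_requires_high_levels():
    web = layered_web((2, 3), 6, seed=0)
    with pytest.raises(ValueError, match="level 3"):
        add_parasites(web, "e", parasite_count=3, seed=0)


def test_concomitant_links_definitional():
    """One parasite on a preyed-upon host → one link per host predator."""
    web = FoodWeb(
        (
            Species("b", nutrient_id="N"),
            Species("q1"),
            Species("q2"),
            Species("p", kind="parasite"),
        ),
        (
            Link("b", "q1"),
            Link("b", "q2"),
            Link("b", "p", PARASITIC),
        ),
        nutrient_mode="shared",
    )
    out = add_concomitant_links(web, sym_fraction=0.0, seed=0)
    conc = [l for l in out.links if l.link_type == CONCOMITANT_ASYM]
    assert {(l.resource, l.consumer) for l in conc} == {("p", "q1"), ("p", "q2")}
    # no triple → unchanged
    assert add_concomitant_links(web.subweb(["b", "p"]), seed=0).links == \
        web.subweb(["b", "p"]).links


def test_symmetric_concomitant_links_improve_rank_more():
    """With surplus parasites, symmetric concomitant links pair a parasite
    with a single free-living species; asymmetric ones need directed loops."""
    d_sym, d_asym = [], []
    for seed in range(5):
        base = generic_web(seed=seed, case="e", links_per_parasite=4.0)
        sym = add_concomitant_links(base, sym_fraction=1.0, seed=seed)
        asym = add_concomitant_links(base, sym_fraction=0.0, seed=seed)
        d_sym.append(nullity(sym, seed=seed))
        d_asym.append(nullity(asym, seed=seed))
    assert np.mean(d_sym) <= np.mean(d_asym)
    assert min(np.array(d_asym) - np.array(d_sym)) >= 0


def test_generic_web_totals():
    web = generic_web(seed=0)
    assert web.S == 110
    assert sum(GENERIC_LEVEL_COUNTS) == 110
    assert nullity(web, seed=0) > 0  # sharp levels leave niches missing
    full = generic_web(seed=0, case="c", links_per_parasite=1.0)
    assert full.S == 157
    assert len(full.parasite_ids) == 47


def test_chain_length_distributions_broader_for_models():
    """Niche/cascade webs spread chain lengths over a continuum, while a
    layered web of matched size concentrates them on L integers."""
    for model in (niche_model, cascade_model):
        for seed in range(3):
            mw = model(60, 0.12, seed=seed)
            distinct = len({round(v, 6)
                            for v in prey_averaged_levels(mw).values()})
            lw = layered_web((15, 20, 15, 10), len(mw.links), seed=seed)
            layered_distinct = len({round(v, 6)
                                    for v in prey_averaged_levels(lw).values()})
            assert layered_distinct == 4
            assert distinct > 3 * layered_distinct
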