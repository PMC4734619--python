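"""Pattern construction, pairing, structural rank, nullity and the exact
symbolic determinant oracle."""

import numpy as np
import pytest

from foodweb_assembly import (
    GENERICALLY_NONZERO,
    IDENTICALLY_ZERO,
    FoodWeb,
    Link,
    Species,
    assign_random_weights,
    build_pattern,
    exact_det_oracle,
    find_pairing,
    nullity,
    structural_rank,
)
from foodweb_assembly.matrix import UNIT, _augmented_matching
from foodweb_assembly.generators import layered_web

from conftest import full_layered


def brute_structural_rank(pattern):
    """Independent oracle: max matching of the nutrient-augmented graph by
    exhaustive recursion (tiny patterns only)."""
    nutrients = sorted(pattern.nutrient_groups)
    k = len(nutrients)
    n = pattern.S + k
    block = set(pattern.basal_block())
    adj = [[] for _ in range(n)]
    for (i, j) in pattern.entries:
        if (i, j) not in block:
            adj[i].append(j)
    for g, nutrient in enumerate(nutrients):
        aug = pattern.S + g
        for i in pattern.nutrient_groups[nutrient]:
            adj[i].append(aug)
            adj[aug].append(i)
        adj[aug].append(aug)

    def best(row, used):
        if row == n:
            return 0
        score = best(row + 1, used)  # leave this row unmatched
        for col in adj[row]:
            if not used & (1 << col):
                score = max(score, 1 + best(row + 1, used | (1 << col)))
        return score

    return best(0, 0) - k


def sympy_oracle(pattern):
    """Independent symbolic-determinant route (tied block symbols)."""
    import sympy

    group_of = pattern.group_of()
    m = sympy.zeros(pattern.S, pattern.S)
    for (i, j) in pattern.entries:
        if (i, j) in group_of:
            m[i, j] = sympy.Symbol(f"p_{group_of[(i, j)]}")
        else:
            m[i, j] = sympy.Symbol(f"e_{i}_{j}")
    det = sympy.expand(m.det(method="berkowitz"))
    return IDENTICALLY_ZERO if det == 0 else GENERICALLY_NONZERO


# ---------------------------------------------------------------------------
# pattern construction
# ---------------------------------------------------------------------------

def test_single_basal_pattern_is_unit():
    web = FoodWeb((Species("b", nutrient_id="N"),), (), nutrient_mode="shared")
    pattern = build_pattern(web)
    assert pattern.entries == {(0, 0): UNIT}


def test_pair_pattern_symmetric_offdiagonal(pair_web):
    pattern = build_pattern(pair_web)
    b, c = pattern.index.index("b"), pattern.index.index("c")
    assert pattern.entries[(b, b)] == UNIT
    assert (b, c) in pattern.entries and (c, b) in pattern.entries
    assert len(pattern.entries) == 3


def test_two_basal_chain_pattern_has_allones_block(two_basal_web):
    pattern = build_pattern(two_basal_web)
    idx = {sid: i for i, sid in enumerate(pattern.index)}
    block = pattern.basal_block()
    assert len(block) == 4  # 2×2 all-ones competition block
    # hand enumeration: every trophic link contributes a symmetric entry pair
    for resource, consumer in (("b1", "c"), ("b2", "c"), ("c", "d")):
        assert (idx[consumer], idx[resource]) in pattern.entries
        assert (idx[resource], idx[consumer]) in pattern.entries
    assert len(pattern.entries) == 4 + 6


def test_concomitant_asym_contributes_single_entry():
    web = FoodWeb(
        (
            Species("b", nutrient_id="N"),
            Species("q"),
            Species("p", kind="parasite"),
        ),
        (
            Link("b", "q"),
            Link("b", "p", "parasitic"),
            Link("p", "q", "concomitant_asym"),
        ),
        nutrient_mode="shared",
    )
    pattern = build_pattern(web)
    idx = {sid: i for i, sid in enumerate(pattern.index)}
    assert (idx["p"], idx["q"]) in pattern.entries
    assert (idx["q"], idx["p"]) not in pattern.entries


def test_grouped_mode_requires_assignments():
    web = FoodWeb(
        (Species("b", nutrient_id="N"), Species("c")),
        (Link("b", "c"),),
        nutrient_mode="shared",
    )
    pattern = build_pattern(web, nutrient_mode="grouped")
    assert pattern.nutrient_groups == {"N": (0,)}


# ---------------------------------------------------------------------------
# random weights
# ---------------------------------------------------------------------------

def test_random_weights_deterministic_and_patterned(two_basal_web):
    pattern = build_pattern(two_basal_web)
    a = assign_random_weights(pattern, seed=7)
    b = assign_random_weights(pattern, seed=7)
    c = assign_random_weights(pattern, seed=8)
    assert np.array_equal(a.matrix, b.matrix)
    assert np.array_equal(a.matrix != 0, c.matrix != 0)
    # tied competition entries stay exactly 1
    for (i, j) in pattern.basal_block():
        assert a.matrix[i, j] == 1.0
    off = [abs(a.matrix[e]) for e in pattern.entries if e not in set(pattern.basal_block())]
    assert all(0.5 <= v <= 1.5 for v in off)


def test_empty_pattern_rejected():
    from foodweb_assembly.matrix import InteractionPattern

    empty = InteractionPattern(index=(), entries={}, nutrient_groups={})
    with pytest.raises(ValueError):
        assign_random_weights(empty, seed=0)


# ---------------------------------------------------------------------------
# pairing and rank
# ---------------------------------------------------------------------------

def test_pair_web_has_symmetric_two_cycle(pair_web):
    pairing = find_pairing(build_pattern(pair_web))
    assert pairing.complete
    assert any(len(cycle) == 2 for cycle in pairing.cover)


def test_shared_block_limits_pairing(two_basal_web):
    """Only one basal species may pair through a shared nutrient pool."""
    pattern = build_pattern(two_basal_web)
    pairing = find_pairing(pattern)
    assert not pairing.complete
    assert pairing.size == 3
    assert nullity(two_basal_web) == 1
    assert exact_det_oracle(pattern) == IDENTICALLY_ZERO
    # individual pools lift the degeneracy entirely
    assert nullity(two_basal_web, nutrient_mode="individual") == 0


def test_generalist_omnivore_restores_pairing(omnivore_rescue_web):
    base = full_layered((2, 2, 2))
    assert not find_pairing(build_pattern(base)).complete
    pattern = build_pattern(omnivore_rescue_web)
    assert find_pairing(pattern).complete
    assert exact_det_oracle(pattern) == GENERICALLY_NONZERO


def test_cannibalism_enables_diagonal_one_cycle():
    web = FoodWeb(
        (Species("b", nutrient_id="N"), Species("c1"), Species("c2")),
        (Link("b", "c1"), Link("b", "c2"), Link("c2", "c2")),
        nutrient_mode="shared",
        allow_cannibalism=True,
    )
    pattern = build_pattern(web)
    pairing = find_pairing(pattern)
    assert pairing.complete
    idx = pattern.index.index("c2")
    assert ((idx, idx),) in pairing.cover  # the cannibal pairs with itself


def test_identical_rows_have_zero_determinant():
    two_shared = FoodWeb(
        (Species("b1", nutrient_id="N"), Species("b2", nutrient_id="N")),
        (),
        nutrient_mode="shared",
    )
    assert exact_det_oracle(build_pattern(two_shared)) == IDENTICALLY_ZERO
    assert (
        exact_det_oracle(build_pattern(two_shared, nutrient_mode="individual"))
        == GENERICALLY_NONZERO
    )


def test_oracle_rejects_large_patterns():
    web = full_layered((4, 4, 3), seed=0)
    with pytest.raises(ValueError, match="nullity"):
        exact_det_oracle(build_pattern(web))


def test_structural_rank_matches_brute_force_and_sympy():
    """Dual independent routes on assorted small webs, shared and individual
    nutrient pools."""
    webs = [
        full_layered((2, 1, 1)),
        full_layered((1, 2, 1)),
        full_layered((2, 2)),
        full_layered((1, 1, 1)),
        full_layered((3, 2)),
    ]
    for web in webs:
        for mode in ("shared", "individual"):
            pattern = build_pattern(web, nutrient_mode=mode)
            assert structural_rank(pattern) == brute_structural_rank(pattern)
            expected = sympy_oracle(pattern)
            assert exact_det_oracle(pattern) == expected
            assert (structural_rank(pattern) == pattern.S) == (
                expected == GENERICALLY_NONZERO
            )


def test_nullity_matches_exact_oracle_on_small_layered_webs():
    for seed in range(10):
        counts = tuple(np.random.default_rng(seed).integers(1, 3, size=3))
        web = full_layered(counts, seed=seed)
        pattern = build_pattern(web)
        d = nullity(web, seed=seed)
        assert (d == 0) == (exact_det_oracle(pattern) == GENERICALLY_NONZERO)


def test_nullity_invariant_under_ordering():
    web = layered_web((3, 4, 2), 12, seed=3)
    a = build_pattern(web, order="level")
    b = build_pattern(web, order="id")
    assert nullity(web, pattern=a) == nullity(web, pattern=b)


def test_adding_links_never_increases_nullity():
    rng = np.random.default_rng(1)
    for seed in range(5):
        web = layered_web((3, 4, 3), 12, seed=seed)
        d = nullity(web, seed=seed)
        names = [s.id for s in web.species]
        present = {(l.resource, l.consumer) for l in web.links}
        candidates = [
            (r, c)
            for r in names
            for c in names
            if r.startswith("L1") and c.startswith("L2")
            or r.startswith("L2") and c.startswith("L3")
        ]
        extras = [p for p in candidates if p not in present]
        rng.shuffle(extras)
        grown = web
        for resource, consumer in extras[:5]:
            grown = grown.with_links([Link(resource, consumer)])
            d_new = nullity(grown, seed=seed)
            assert d_new <= d
            d = d_new
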