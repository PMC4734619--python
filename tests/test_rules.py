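"""Assembly rules: Δ membership, nested inequalities, dominance, enumeration
and secondary-extinction predictions."""

import numpy as np
import pytest

from foodweb_assembly import (
    FoodWeb,
    LevelProfile,
    Link,
    Species,
    admissible_profiles,
    build_pattern,
    check_rules,
    check_web,
    find_pairing,
    intermediate_dominance,
    predict_secondary_extinctions,
)
from foodweb_assembly.generators import tree_web
from foodweb_assembly.rules import (
    CONSUMER_LIMITED,
    MIXED,
    NOT_APPLICABLE,
    RESOURCE_LIMITED,
)

from conftest import full_layered


@pytest.mark.parametrize(
    "counts, n_S, passed, delta, limitation",
    [
        ((2, 1, 1), 1, False, 2, NOT_APPLICABLE),
        ((1, 2, 1, 1), 1, False, -1, NOT_APPLICABLE),
        ((1, 1), 1, True, 0, CONSUMER_LIMITED),
        ((1,), 1, True, 1, RESOURCE_LIMITED),
        ((2, 1), 1, True, 1, RESOURCE_LIMITED),
        ((3, 4, 6, 5, 4, 3), 1, True, 1, RESOURCE_LIMITED),
        ((3, 1), 2, True, 2, RESOURCE_LIMITED),
        ((2, 1), 2, True, 1, MIXED),
        ((3, 1), 1, False, 2, NOT_APPLICABLE),
    ],
)
def test_delta_and_limitation(counts, n_S, passed, delta, limitation):
    verdict = check_rules(LevelProfile(counts, n_S=n_S))
    assert verdict.delta == delta
    assert verdict.passed is passed
    assert verdict.limitation == limitation


def test_nested_inequality_failure_reported():
    # Δ = 1 is fine but n2 ≥ n1 − Δ fails: 1 < 3 − 1
    verdict = check_rules(LevelProfile((3, 1, 2, 3)))
    assert verdict.delta_ok
    assert not verdict.passed
    assert (2, 2, 1) in verdict.inequality_failures
    # and the corresponding fully connected layered web has no pairing either
    pattern = build_pattern(full_layered((3, 1, 2, 3)))
    assert not find_pairing(pattern).complete


def test_rules_are_hall_conditions_of_the_layered_graph():
    """Independent re-derivation: evaluate the inequalities directly from
    their alternating-sum definition for every profile with S ≤ 9."""
    from itertools import combinations

    def direct(counts, delta):
        # n_l ≥ n_{l−1} − n_{l−2} + … ± n_1 ∓ Δ, written out term by term
        L = len(counts)
        for l in range(1, L):
            bound = sum(
                ((-1) ** (l - 1 - m)) * counts[m - 1] for m in range(l - 1, 0, -1)
            )
            bound += ((-1) ** (l - 1)) * delta
            if counts[l - 1] < bound:
                return False
        return True

    for total in range(1, 10):
        for L in range(1, total + 1):
            for cuts in combinations(range(1, total), L - 1):
                bounds = (0,) + cuts + (total,)
                counts = tuple(bounds[i + 1] - bounds[i] for i in range(L))
                profile = LevelProfile(counts)
                verdict = check_rules(profile)
                expected = profile.delta in (0, 1) and direct(counts, profile.delta)
                assert verdict.passed == expected, counts


def test_intermediate_dominance():
    assert intermediate_dominance(LevelProfile((1, 3, 1))) is True
    # consumer-limited, top-heavy: 2 + 2 > 1 + 1
    assert intermediate_dominance(LevelProfile((2, 1, 1, 2))) is False
    # resource-limited: the bound is shifted by one species, 3 ≤ 2 + 1
    assert intermediate_dominance(LevelProfile((2, 1, 1, 1))) is True
    with pytest.raises(ValueError):
        intermediate_dominance(LevelProfile((1, 1)))
    # every consumer-limited admissible profile satisfies the dominance bound
    for L in (3, 4, 5):
        for profile in admissible_profiles(10, L):
            if profile.delta == 0:
                assert intermediate_dominance(profile), profile.counts


def test_admissible_profiles_enumeration():
    two = admissible_profiles(2, 2)
    assert [p.counts for p in two] == [(1, 1)]
    one = admissible_profiles(3, 1)
    assert [p.counts for p in one] == [(1,)]
    # every admissible profile supports a complete pairing when fully wired
    for profile in admissible_profiles(8, 3):
        pattern = build_pattern(full_layered(profile.counts))
        assert find_pairing(pattern).complete, profile.counts


def test_check_web_defers_to_pairing_for_omnivores(omnivore_rescue_web):
    verdict = check_web(omnivore_rescue_web)
    assert verdict.passed
    assert verdict.limitation == MIXED
    assert verdict.topology_checked and verdict.pairing_complete


def test_check_web_rejects_sparse_web_that_counts_allow():
    """Counts alone are necessary, not sufficient: a sparse layered web with
    an admissible profile can still lack a pairing."""
    # (2,2): both consumers eat the same basal species
    web = FoodWeb(
        (
            Species("b1", nutrient_id="N"),
            Species("b2", nutrient_id="N"),
            Species("c1"),
            Species("c2"),
        ),
        (Link("b1", "c1"), Link("b1", "c2")),
        nutrient_mode="shared",
        allow_components=True,  # b2 hangs off the shared pool only
    )
    verdict = check_web(web)
    assert check_rules(LevelProfile((2, 2))).passed  # counts fine: Δ = 0
    assert not verdict.passed  # but both consumers share one prey
    assert verdict.pairing_complete is False


def test_removal_of_sole_basal_flagged(pair_web):
    report = predict_secondary_extinctions(pair_web)
    assert report.web_ok
    impact = {r.species: r for r in report.removals}
    assert impact["b"].violates  # consumer left without prey
    assert not impact["c"].violates  # single producer remains sustainable
    assert impact["b"].was_resource and not impact["b"].was_consumer


def test_removing_the_rescuing_omnivore_reintroduces_violation(omnivore_rescue_web):
    report = predict_secondary_extinctions(omnivore_rescue_web)
    impact = {r.species: r for r in report.removals}
    assert impact["O"].violates


def test_resource_removals_riskier_in_consumer_limited_webs():
    """Removal of a resource species breaks the rules more often than removal
    of a consumer species, across random consumer-limited layered webs."""
    resource_flags, consumer_flags = [], []
    for seed in range(12):
        web = tree_web((2, 3, 2, 1), seed=seed)  # Δ = 0, consumer-limited
        report = predict_secondary_extinctions(web)
        if not report.web_ok:
            continue
        for r in report.removals:
            if r.was_resource and not r.was_consumer:  # basal species
                resource_flags.append(r.violates)
            elif r.was_consumer and not r.was_resource:  # top consumers
                consumer_flags.append(r.violates)
    assert np.mean(resource_flags) > np.mean(consumer_flags)


def test_report_about_violating_web():
    web = full_layered((2, 1, 1))
    report = predict_secondary_extinctions(web)
    assert not report.web_ok
    assert report.removals == []
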