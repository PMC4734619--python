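"""The food-web assembly rules and their consequences.

For a community organised in sharp trophic levels with richness n_1..n_L and
n_S nutrient pools, sustainable coexistence (nonzero det R) requires

* Δ ≡ N_o − N_e ∈ {0, 1, …, n_S}, where N_o and N_e are the total richness of
  odd and even levels — Δ = 0 is the consumer-limited state and Δ = n_S the
  resource-limited one (for a single nutrient: Δ ∈ {0, 1});
* the nested inequalities n_1 ≥ Δ, n_2 ≥ n_1 − Δ, n_3 ≥ n_2 − n_1 + Δ, …
  evaluated here as alternating partial sums, the Hall condition of the
  layered pairing graph.

The rules are exact for fully connected adjacent levels and necessary for
sparse links, so verdicts carry a ``topology_checked`` flag: a sparse web is
never declared sustainable on counts alone, the pairing test has the last
word.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

from .levels import LevelProfile, level_profile, prey_averaged_levels
from .matrix import build_pattern, find_pairing
from .web import FoodWeb, validate_web

__all__ = [
    "CONSUMER_LIMITED",
    "RESOURCE_LIMITED",
    "MIXED",
    "NOT_APPLICABLE",
    "RuleVerdict",
    "check_rules",
    "check_web",
    "intermediate_dominance",
    "admissible_profiles",
    "predict_secondary_extinctions",
    "RemovalImpact",
    "SecondaryExtinctionReport",
]

CONSUMER_LIMITED = "consumer_limited"
RESOURCE_LIMITED = "resource_limited"
MIXED = "mixed"
NOT_APPLICABLE = "na"


@dataclass
class RuleVerdict:
    """Outcome of the assembly-rule check for one level profile."""

    delta: int
    allowed_deltas: frozenset[int]
    delta_ok: bool
    inequality_failures: list[tuple[int, int, int]]  # (level, required, actual)
    passed: bool
    limitation: str
    topology_checked: bool = False
    pairing_complete: bool | None = None

    def to_dict(self) -> dict:
        return {
            "delta": self.delta,
            "allowed_deltas": sorted(self.allowed_deltas),
            "delta_ok": self.delta_ok,
            "inequality_failures": [
                {"level": l, "required": r, "actual": a}
                for l, r, a in self.inequality_failures
            ],
            "pass": self.passed,
            "limitation": self.limitation,
            "topology_checked": self.topology_checked,
            "pairing_complete": self.pairing_complete,
        }


def check_rules(profile: LevelProfile) -> RuleVerdict:
    """Evaluate Δ membership and the nested richness inequalities.

    The inequality family is evaluated as partial alternating sums
    s_l = n_l − n_{l−1} + … ± n_1 ∓ Δ ≥ 0 for l = 1..L−1 (the closing sum at
    the top level vanishes identically for the profile's own Δ). For several
    nutrients the same family applies with the profile's Δ, any value in
    {0..n_S} being admissible.
    """
    counts = profile.counts
    delta = profile.delta
    allowed = frozenset(range(profile.n_S + 1))
    delta_ok = delta in allowed

    failures: list[tuple[int, int, int]] = []
    bound = delta  # required lower bound for n_1
    for l, n_l in enumerate(counts[:-1], start=1):
        if n_l < bound:
            failures.append((l, bound, n_l))
        bound = n_l - bound  # next bound: n_{l+1} >= n_l - bound_l

    passed = delta_ok and not failures
    if not delta_ok:
        limitation = NOT_APPLICABLE
    elif delta == 0:
        limitation = CONSUMER_LIMITED
    elif delta == profile.n_S:
        limitation = RESOURCE_LIMITED
    else:
        limitation = MIXED
    return RuleVerdict(
        delta=delta,
        allowed_deltas=allowed,
        delta_ok=delta_ok,
        inequality_failures=failures,
        passed=passed,
        limitation=limitation,
    )


def check_web(web: FoodWeb, nutrient_mode: str | None = None) -> RuleVerdict:
    """Rule check for an actual web, with the pairing test filled in.

    The counts-based verdict is necessary only on sparse link structure, so
    the returned verdict also runs :func:`find_pairing` on the interaction
    pattern; ``passed`` then requires a complete pairing as well. Webs whose
    species lack sharp levels (omnivores present) get a counts verdict of
    ``mixed/na`` limitation and defer entirely to the pairing test.
    """
    pattern = build_pattern(web, nutrient_mode=nutrient_mode)
    pairing = find_pairing(pattern)
    levels = prey_averaged_levels(web)
    # the counts rules bind only for genuinely layered webs: integral levels
    # and every diet link spanning exactly one level
    sharp_ok = all(abs(v - round(v)) < 1e-9 for v in levels.values()) and all(
        abs(levels[l.consumer] - levels[l.resource] - 1.0) < 1e-9
        for l in web.links
        if l.is_diet and l.resource in web
    )
    if sharp_ok:
        verdict = check_rules(level_profile(web, levels))
    else:
        verdict = RuleVerdict(
            delta=0,
            allowed_deltas=frozenset(range(max(web.n_S, 1) + 1)),
            delta_ok=True,
            inequality_failures=[],
            passed=True,  # counts place no constraint without sharp levels
            limitation=MIXED,
        )
    verdict.topology_checked = True
    verdict.pairing_complete = pairing.complete
    verdict.passed = verdict.passed and pairing.complete
    return verdict


def intermediate_dominance(profile: LevelProfile) -> bool:
    """Whether intermediate levels dominate: n_1 + n_L ≤ n_2 + n_{L−1}.

    In the resource-limited state the bound is shifted by one species.
    Requires at least three levels.
    """
    if profile.L < 3:
        raise ValueError("intermediate dominance needs at least 3 levels")
    counts = profile.counts
    slack = 1 if profile.delta == profile.n_S else 0
    return counts[0] + counts[-1] <= counts[1] + counts[-2] + slack


def admissible_profiles(S_max: int, L: int, n_S: int = 1) -> list[LevelProfile]:
    """All rule-satisfying profiles with L levels and at most S_max species.

    Enumeration harness for staircase plots and exhaustive cross-checks;
    deterministic lexicographic order.
    """
    if S_max > 15:
        raise ValueError("admissible_profiles is an enumeration tool; S_max <= 15")
    out = []
    for counts in _compositions(S_max, L):
        profile = LevelProfile(counts, n_S=n_S)
        if check_rules(profile).passed:
            out.append(profile)
    return out


def _compositions(s_max: int, length: int):
    """Positive integer vectors of given length with sum <= s_max, lex order."""
    for total in range(length, s_max + 1):
        # stars and bars in lexicographic order
        for cuts in combinations(range(1, total), length - 1):
            bounds = (0,) + cuts + (total,)
            yield tuple(bounds[i + 1] - bounds[i] for i in range(length))


# ---------------------------------------------------------------------------
# secondary extinctions
# ---------------------------------------------------------------------------

@dataclass
class RemovalImpact:
    species: str
    violates: bool
    reason: str
    was_resource: bool  # had consumers (predators or parasites)
    was_consumer: bool  # had prey


@dataclass
class SecondaryExtinctionReport:
    web_ok: bool
    base_verdict: RuleVerdict
    removals: list[RemovalImpact] = field(default_factory=list)


def predict_secondary_extinctions(
    web: FoodWeb, levels: dict[str, float] | None = None
) -> SecondaryExtinctionReport:
    """Flag single-species removals that break the assembly rules.

    For every species the reduced web is re-validated, re-profiled and
    re-paired; a flagged removal means secondary extinctions must follow
    before a sustainable state is regained. If the web itself violates the
    rules, the report is about the web and removals are not analysed.
    """
    base = check_web(web)
    if not base.passed:
        return SecondaryExtinctionReport(web_ok=False, base_verdict=base)

    removals = []
    for s in web.species:
        reduced = web.without_species(s.id)
        violates, reason = _reduced_web_violation(reduced)
        removals.append(
            RemovalImpact(
                species=s.id,
                violates=violates,
                reason=reason,
                was_resource=len(web.predators_of(s.id)) > 0,
                was_consumer=len(web.prey_of(s.id)) > 0,
            )
        )
    return SecondaryExtinctionReport(web_ok=True, base_verdict=base,
                                     removals=removals)


def _reduced_web_violation(reduced: FoodWeb) -> tuple[bool, str]:
    if reduced.S == 0:
        return False, "web empty after removal"
    problems = validate_web(reduced)
    if problems:
        # e.g. consumers left without any prey
        return True, "; ".join(problems)
    try:
        verdict = check_web(reduced)
    except ValueError as exc:
        return True, str(exc)
    if not verdict.passed:
        if not verdict.delta_ok:
            return True, f"delta {verdict.delta} not admissible"
        if verdict.inequality_failures:
            return True, "richness inequalities violated"
        return True, "no complete pairing"
    return False, "rules still satisfied"
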