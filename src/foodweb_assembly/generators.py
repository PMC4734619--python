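"""Synthetic food-web generators.

Covers every web class used by the analyses: maximally coherent tree webs
carrying a complete pairing by construction, sharp-level layered webs with
random adjacent-level links, the classical niche and cascade models, a
generic layered web emulating the averaged empirical profile (110
free-living species, optionally 47 parasites), parasite addition under four
linking protocols, hyperparasitism and concomitant links. All generators are
deterministic under their seed.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .levels import LevelProfile, prey_averaged_levels, sharp_levels
from .rules import check_rules
from .web import (
    CONCOMITANT_ASYM,
    CONCOMITANT_SYM,
    FREE_LIVING,
    PARASITE,
    PARASITIC,
    TROPHIC,
    FoodWeb,
    Link,
    Species,
)

__all__ = [
    "tree_web",
    "layered_web",
    "niche_model",
    "cascade_model",
    "add_parasites",
    "add_concomitant_links",
    "generic_web",
    "GENERIC_LEVEL_COUNTS",
    "GENERIC_LINK_COUNT",
    "GENERIC_PARASITE_COUNT",
]

#: Synthetic per-level species counts of the generic free-living web. The
#: published profile this emulates is only available as a bar chart, so these
#: counts are a reconstruction: consumer-dominated (even levels richer, as in
#: the empirical coastal webs, which are all consumer-limited), summing to
#: the printed total of 110 free-living species.
GENERIC_LEVEL_COUNTS = (20, 45, 30, 13, 2)

#: Adjacent-level link count of the generic web (~6.4 links per species, a
#: plausible empirical-like density; a packaged constant, not a fit).
GENERIC_LINK_COUNT = 700

#: Parasite count matching the empirical average.
GENERIC_PARASITE_COUNT = 47


def _species_names(counts: Sequence[int]) -> list[list[str]]:
    names = []
    n = 0
    for level, count in enumerate(counts, start=1):
        names.append([f"L{level}_{i + 1}" for i in range(count)])
        n += count
    return names


def tree_web(
    profile: LevelProfile | Sequence[int],
    seed: int = 0,
    n_S: int | None = None,
) -> FoodWeb:
    """A tree over species and nutrients containing a complete pairing.

    Works outward from the pairing the assembly rules guarantee: Δ basal
    species pair with (distinct) nutrient pools, the remaining species pair
    up as consumer–resource 2-cycles between adjacent levels, and every
    species paired only from above receives one extra diet link to a random
    species one level down, keeping the web a tree. Every consumer has
    exactly one prey, so all links span exactly one level — a maximally
    trophically coherent web with sharp levels and nullity zero.
    """
    if not isinstance(profile, LevelProfile):
        profile = LevelProfile.from_counts(profile, n_S=n_S or 1)
    verdict = check_rules(profile)
    if not verdict.passed:
        raise ValueError(
            f"profile {profile.counts} (n_S={profile.n_S}) violates the "
            f"assembly rules: {verdict.to_dict()}"
        )
    rng = np.random.default_rng(seed)
    counts = profile.counts
    names = _species_names(counts)
    delta = profile.delta

    if profile.n_S == 1:
        pools = ["N"]
        mode = "shared"
    else:
        pools = [f"N{i + 1}" for i in range(profile.n_S)]
        mode = "grouped"
    # every basal species draws on a pool; the Δ nutrient-paired ones must sit
    # on distinct pools, the rest are spread round-robin
    basal = list(names[0])
    rng.shuffle(basal)
    nutrient_of = {}
    for i, sid in enumerate(basal):
        nutrient_of[sid] = pools[i % len(pools)]

    species = [
        Species(sid, nutrient_id=nutrient_of[sid]) for sid in names[0]
    ]
    for level_names in names[1:]:
        species.extend(Species(sid) for sid in level_names)

    links: list[Link] = []
    # r_l species of level l pair upward with level l+1
    paired_up = basal[delta:]  # the first Δ basal species pair with nutrients
    for level in range(1, len(counts)):
        here = list(names[level])
        rng.shuffle(here)
        partners = here[: len(paired_up)]
        for resource, consumer in zip(paired_up, partners):
            links.append(Link(resource, consumer, TROPHIC))
        # species of this level pairing down already have their single prey;
        # the others pair upward and need a random prey one level below
        rest = here[len(paired_up):]
        below = names[level - 1]
        for consumer in rest:
            resource = below[rng.integers(len(below))]
            links.append(Link(resource, consumer, TROPHIC))
        paired_up = rest
    if paired_up:
        raise AssertionError("top level left unpaired despite rule check")
    return FoodWeb(tuple(species), tuple(links), nutrient_mode=mode)


def layered_web(
    counts: Sequence[int],
    n_links: int,
    seed: int = 0,
    nutrient_mode: str = "individual",
) -> FoodWeb:
    """Sharp-level web with ``n_links`` uniform adjacent-level links.

    Links connect only neighboring levels; every consumer keeps at least one
    prey one level down, so sharp integer levels hold by construction.
    Under ``nutrient_mode="individual"`` each basal species receives a
    private nutrient pool (the convention of the rank analyses).
    """
    counts = tuple(int(c) for c in counts)
    if any(c <= 0 for c in counts):
        raise ValueError(f"level counts must be positive: {counts}")
    names = _species_names(counts)
    min_links = sum(counts[1:])
    max_links = sum(counts[i] * counts[i + 1] for i in range(len(counts) - 1))
    if not (min_links <= n_links <= max_links):
        raise ValueError(
            f"n_links={n_links} infeasible for counts {counts}: needs "
            f"[{min_links}, {max_links}]"
        )
    rng = np.random.default_rng(seed)

    pairs: list[tuple[str, str]] = []
    chosen: set[tuple[str, str]] = set()
    for level in range(1, len(counts)):
        below = names[level - 1]
        for consumer in names[level]:
            resource = below[rng.integers(len(below))]
            chosen.add((resource, consumer))
    remaining = [
        (r, c)
        for level in range(1, len(counts))
        for c in names[level]
        for r in names[level - 1]
        if (r, c) not in chosen
    ]
    extra = n_links - len(chosen)
    if extra > 0:
        idx = rng.choice(len(remaining), size=extra, replace=False)
        chosen.update(remaining[i] for i in idx)

    if nutrient_mode == "shared":
        nutrient = {sid: "N" for sid in names[0]}
    else:
        nutrient = {sid: f"N_{sid}" for sid in names[0]}
    species = [Species(sid, nutrient_id=nutrient[sid]) for sid in names[0]]
    for level_names in names[1:]:
        species.extend(Species(sid) for sid in level_names)
    links = tuple(Link(r, c, TROPHIC) for r, c in sorted(chosen))
    mode = "shared" if nutrient_mode == "shared" else "individual"
    return FoodWeb(tuple(species), links, nutrient_mode=mode)


# ---------------------------------------------------------------------------
# classical structural models
# ---------------------------------------------------------------------------

def niche_model(S: int, C: float, seed: int = 0, max_attempts: int = 500) -> FoodWeb:
    """The niche model: uniform niche values, beta-distributed diet ranges.

    Each species i gets a niche value n_i ~ U(0,1), a feeding range
    r_i = x·n_i with x ~ Beta(1, 1/(2C) − 1) and a range centre uniform in
    [r_i/2, min(n_i, 1 − r_i/2)]; i consumes every species whose niche value
    falls inside the range. The species with the smallest niche value is
    forced basal. Draws with isolated species, no basal species, or species
    unreachable from the basal set are discarded and redrawn; cannibalistic
    self-links are allowed. Basal species get individual nutrient pools.
    """
    if not (0 < C < 0.5):
        raise ValueError("connectance must lie in (0, 0.5)")
    if S < 2:
        raise ValueError("need at least two species")
    rng = np.random.default_rng(seed)
    b = 1.0 / (2.0 * C) - 1.0
    for _ in range(max_attempts):
        n = rng.uniform(0.0, 1.0, size=S)
        x = rng.beta(1.0, b, size=S)
        r = x * n
        r[np.argmin(n)] = 0.0  # smallest-niche species is basal
        lo = r / 2.0
        hi = np.minimum(n, 1.0 - r / 2.0)
        c = rng.uniform(lo, np.maximum(lo, hi))
        prey_sets = [
            np.where((n >= c[i] - r[i] / 2.0) & (n <= c[i] + r[i] / 2.0))[0]
            if r[i] > 0 else np.array([], dtype=int)
            for i in range(S)
        ]
        web = _web_from_prey_sets(prey_sets, allow_cannibalism=True)
        if web is not None:
            return web
    raise RuntimeError(
        f"niche model failed to produce a connected web in {max_attempts} draws"
    )


def cascade_model(S: int, C: float, seed: int = 0, max_attempts: int = 500) -> FoodWeb:
    """The cascade model: a strict feeding hierarchy with random links.

    Species are strictly ordered; each ordered pair (i < j) is linked with
    probability 2CS/(S−1), the higher-ranked species consuming the lower.
    Disconnected draws are discarded. Basal species (those without prey) get
    individual nutrient pools.
    """
    if not (0 < C < 0.5):
        raise ValueError("connectance must lie in (0, 0.5)")
    if S < 2:
        raise ValueError("need at least two species")
    p = 2.0 * C * S / (S - 1.0)
    if p > 1.0:
        raise ValueError("2CS/(S-1) exceeds 1; lower C or raise S")
    rng = np.random.default_rng(seed)
    for _ in range(max_attempts):
        upper = rng.uniform(size=(S, S)) < p
        prey_sets = [np.where(upper[i, :i])[0] for i in range(S)]
        web = _web_from_prey_sets(prey_sets, allow_cannibalism=False)
        if web is not None:
            return web
    raise RuntimeError(
        f"cascade model failed to produce a connected web in {max_attempts} draws"
    )


def _web_from_prey_sets(prey_sets, allow_cannibalism: bool) -> FoodWeb | None:
    """Assemble a model web; None if isolated/unreachable/basal-free."""
    S = len(prey_sets)
    prey = [set(int(p) for p in ps) for ps in prey_sets]
    predators: list[set[int]] = [set() for _ in range(S)]
    for i, ps in enumerate(prey):
        for p in ps:
            predators[p].add(i)
    basal = [i for i in range(S) if not (prey[i] - {i})]
    if not basal:
        return None
    for i in range(S):
        if not prey[i] and not predators[i]:
            return None  # isolated species
    # every species must trace back to a basal species
    reachable = set(basal)
    frontier = list(basal)
    while frontier:
        current = frontier.pop()
        for q in predators[current]:
            if q not in reachable:
                reachable.add(q)
                frontier.append(q)
    if len(reachable) < S:
        return None

    width = len(str(S))
    ids = [f"sp{i + 1:0{width}d}" for i in range(S)]
    species = []
    for i in range(S):
        if i in set(basal):
            species.append(Species(ids[i], nutrient_id=f"N_{ids[i]}"))
        else:
            species.append(Species(ids[i]))
    links = []
    for i in range(S):
        for p in sorted(prey[i] - ({i} if i in set(basal) else set())):
            links.append(Link(ids[p], ids[i], TROPHIC))
    web = FoodWeb(tuple(species), tuple(links), nutrient_mode="individual",
                  allow_cannibalism=allow_cannibalism)
    from .web import validate_web

    return web if not validate_web(web) else None


# ---------------------------------------------------------------------------
# parasites, hyperparasitism and concomitant predation
# ---------------------------------------------------------------------------

PARASITE_CASES = ("c", "d", "e", "f")
HYPERPARASITE_SHARE = 0.05  # parasite→parasite share of links in case f


def add_parasites(
    web: FoodWeb,
    case: str,
    parasite_count: int = GENERIC_PARASITE_COUNT,
    links_per_parasite: float = 1.0,
    seed: int = 0,
) -> FoodWeb:
    """Add parasites to a sharp-level web under one of four link protocols.

    Every parasite first receives one host link — for cases ``c`` and ``d``
    to any free-living species, for ``e`` and ``f`` to a species at trophic
    level 3 or 4. Further links (a random parasite at a time, until the
    average of ``links_per_parasite`` is reached) are drawn per case:

    * ``c`` — to any free-living species;
    * ``d`` — only to species at the same level as that parasite's first host;
    * ``e`` — to free-living species at levels 3 or 4;
    * ``f`` — as ``e``, but ~5% of parasite links target another parasite
      (hyperparasitism).
    """
    if case not in PARASITE_CASES:
        raise ValueError(f"case must be one of {PARASITE_CASES}")
    if parasite_count < 1:
        raise ValueError("parasite_count must be positive")
    rng = np.random.default_rng(seed)
    levels = sharp_levels(prey_averaged_levels(web))
    free = [s.id for s in web.species if s.kind == FREE_LIVING]
    high = [sid for sid in free if levels[sid] in (3, 4)]
    if case in ("e", "f") and not high:
        raise ValueError(f"case {case!r} requires species at level 3 or 4")

    parasites = [f"P{i + 1}" for i in range(parasite_count)]
    host_links: set[tuple[str, str]] = set()
    first_level: dict[str, int] = {}
    for pid in parasites:
        pool = free if case in ("c", "d") else high
        host = pool[rng.integers(len(pool))]
        host_links.add((host, pid))
        first_level[pid] = levels[host]

    target = int(round(parasite_count * links_per_parasite))
    guard = 0
    while len(host_links) < target and guard < 100 * target:
        guard += 1
        pid = parasites[rng.integers(len(parasites))]
        if case == "c":
            pool = free
        elif case == "d":
            pool = [sid for sid in free if levels[sid] == first_level[pid]]
        elif case == "e":
            pool = high
        else:  # case f
            if rng.uniform() < HYPERPARASITE_SHARE and parasite_count > 1:
                pool = [q for q in parasites if q != pid]
            else:
                pool = high
        if not pool:
            continue
        host = pool[rng.integers(len(pool))]
        host_links.add((host, pid))

    new_species = tuple(Species(pid, kind=PARASITE) for pid in parasites)
    new_links = tuple(
        Link(host, pid, PARASITIC) for host, pid in sorted(host_links)
    )
    return web.with_species(new_species, new_links)


def add_concomitant_links(
    web: FoodWeb,
    sym_fraction: float = 0.2,
    seed: int = 0,
) -> FoodWeb:
    """Concomitant predation: parasites eaten along with their hosts.

    For every (parasite, host, host-predator) triple with a free-living
    predator, adds one parasite → predator link; a seeded ``sym_fraction``
    share of the links is symmetric (the predator benefits), the rest
    asymmetric. Adds nothing if the web has no such triple.
    """
    if not (0.0 <= sym_fraction <= 1.0):
        raise ValueError("sym_fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    pairs: set[tuple[str, str]] = set()
    for link in web.links:
        if link.link_type != PARASITIC or link.resource not in web:
            continue
        host, parasite = link.resource, link.consumer
        if web.species_by_id(parasite).kind != PARASITE:
            continue
        for predator in web.predators_of(host):
            if predator == parasite:
                continue
            if web.species_by_id(predator).kind == FREE_LIVING:
                pairs.add((parasite, predator))
    ordered = sorted(pairs)
    if not ordered:
        return web
    n_sym = int(round(sym_fraction * len(ordered)))
    sym_idx = set(
        rng.choice(len(ordered), size=n_sym, replace=False).tolist()
        if n_sym else []
    )
    new_links = tuple(
        Link(p, q, CONCOMITANT_SYM if i in sym_idx else CONCOMITANT_ASYM)
        for i, (p, q) in enumerate(ordered)
    )
    return web.with_links(new_links)


def generic_web(
    seed: int = 0,
    case: str | None = None,
    parasite_count: int = GENERIC_PARASITE_COUNT,
    links_per_parasite: float = 1.0,
    concomitant: bool = False,
    sym_fraction: float = 0.2,
) -> FoodWeb:
    """The generic layered web (110 free-living species, optional parasites).

    A sharp-level web with the packaged level profile and link count,
    individual nutrient pools per basal species; with ``case`` set, 47
    parasites (by default) are added under the corresponding protocol, and
    ``concomitant=True`` additionally wires concomitant links.
    """
    web = layered_web(GENERIC_LEVEL_COUNTS, GENERIC_LINK_COUNT, seed=seed,
                      nutrient_mode="individual")
    if case is not None:
        web = add_parasites(web, case, parasite_count=parasite_count,
                            links_per_parasite=links_per_parasite,
                            seed=seed + 1)
        if concomitant:
            web = add_concomitant_links(web, sym_fraction=sym_fraction,
                                        seed=seed + 2)
    return web
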