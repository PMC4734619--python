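"""Food-web representation: species, typed links and nutrient assignment.

A :class:`FoodWeb` is the single source of truth for topology. Species are
either free-living or parasitic; links are directed from resource to consumer
and carry one of four types:

``trophic``
    ordinary predator–prey (or producer–grazer) consumption.
``parasitic``
    a parasite consuming its host; mathematically the parasite is treated as
    an ordinary consumer of the host.
``concomitant_asym``
    concomitant predation — a parasite eaten incidentally when the predator of
    its host consumes the host. Only the parasite population is affected.
``concomitant_sym``
    concomitant predation from which the predator also draws benefit, so the
    interaction is mutual (symmetric matrix entries).

Basal species take up an abiotic nutrient instead of preying on other
species; the uptake is encoded by ``nutrient_id`` on the species, not by an
edge. Under a completely shared nutrient all basal species compete for the
same pool; under individual nutrients each basal species has a private pool.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Optional

__all__ = [
    "FREE_LIVING",
    "PARASITE",
    "TROPHIC",
    "PARASITIC",
    "CONCOMITANT_ASYM",
    "CONCOMITANT_SYM",
    "DIET_LINK_TYPES",
    "LINK_TYPES",
    "Species",
    "Link",
    "FoodWeb",
    "validate_web",
]

FREE_LIVING = "free_living"
PARASITE = "parasite"
SPECIES_KINDS = (FREE_LIVING, PARASITE)

TROPHIC = "trophic"
PARASITIC = "parasitic"
CONCOMITANT_ASYM = "concomitant_asym"
CONCOMITANT_SYM = "concomitant_sym"
LINK_TYPES = (TROPHIC, PARASITIC, CONCOMITANT_ASYM, CONCOMITANT_SYM)

#: link types that represent actual diet (energy intake) of the consumer;
#: concomitant links are mortality links for the parasite, not diet.
DIET_LINK_TYPES = (TROPHIC, PARASITIC)

SHARED = "shared"
INDIVIDUAL = "individual"
GROUPED = "grouped"


@dataclass(frozen=True, order=True)
class Species:
    """One node of the web.

    ``nutrient_id`` is set exactly for basal species (those with no prey among
    the species of the web); it names the nutrient pool the species draws on.
    """

    id: str
    kind: str = FREE_LIVING
    nutrient_id: Optional[str] = None

    @property
    def basal(self) -> bool:
        return self.nutrient_id is not None


@dataclass(frozen=True, order=True)
class Link:
    """Directed resource → consumer interaction."""

    resource: str
    consumer: str
    link_type: str = TROPHIC

    @property
    def is_diet(self) -> bool:
        return self.link_type in DIET_LINK_TYPES


@dataclass
class FoodWeb:
    """Species, typed links and the nutrient mode of the community.

    ``nutrient_mode`` is one of ``"shared"`` (a single pool used by every
    basal species, competition factors all equal), ``"individual"`` (a private
    pool per basal species) or ``"grouped"`` (several pools, each shared by
    the basal species assigned to it).
    """

    species: tuple[Species, ...]
    links: tuple[Link, ...]
    nutrient_mode: str = SHARED
    allow_cannibalism: bool = False
    allow_components: bool = False

    def __post_init__(self) -> None:
        self.species = tuple(sorted(self.species))
        self.links = tuple(sorted(set(self.links)))
        self._by_id = {s.id: s for s in self.species}
        self._prey: dict[str, list[str]] = {s.id: [] for s in self.species}
        self._predators: dict[str, list[str]] = {s.id: [] for s in self.species}
        nutrients = {s.nutrient_id for s in self.species if s.nutrient_id is not None}
        for link in self.links:
            if not link.is_diet:
                continue
            if link.resource in self._by_id and link.consumer in self._by_id:
                self._prey[link.consumer].append(link.resource)
                self._predators[link.resource].append(link.consumer)
        self._nutrients = tuple(sorted(nutrients))

    # -- basic accessors -------------------------------------------------

    @property
    def S(self) -> int:
        return len(self.species)

    @property
    def nutrients(self) -> tuple[str, ...]:
        return self._nutrients

    @property
    def n_S(self) -> int:
        return len(self._nutrients)

    def species_by_id(self, species_id: str) -> Species:
        return self._by_id[species_id]

    def __contains__(self, species_id: str) -> bool:
        return species_id in self._by_id

    @property
    def ids(self) -> tuple[str, ...]:
        return tuple(s.id for s in self.species)

    @property
    def basal_ids(self) -> tuple[str, ...]:
        return tuple(s.id for s in self.species if s.basal)

    @property
    def parasite_ids(self) -> tuple[str, ...]:
        return tuple(s.id for s in self.species if s.kind == PARASITE)

    def prey_of(self, species_id: str) -> tuple[str, ...]:
        """Species consumed by ``species_id`` through diet links."""
        return tuple(self._prey[species_id])

    def predators_of(self, species_id: str) -> tuple[str, ...]:
        """Species consuming ``species_id`` through diet links."""
        return tuple(self._predators[species_id])

    def nutrient_groups(self) -> dict[str, tuple[str, ...]]:
        """Map nutrient id → basal species drawing on that pool."""
        groups: dict[str, list[str]] = {n: [] for n in self._nutrients}
        for s in self.species:
            if s.nutrient_id is not None:
                groups[s.nutrient_id].append(s.id)
        return {n: tuple(members) for n, members in groups.items()}

    # -- derived webs ----------------------------------------------------

    def without_species(self, species_id: str) -> "FoodWeb":
        """Web with one species (and every link touching it) removed."""
        keep = tuple(s for s in self.species if s.id != species_id)
        links = tuple(
            l for l in self.links if species_id not in (l.resource, l.consumer)
        )
        return replace(self, species=keep, links=links)

    def with_links(self, new_links: Iterable[Link]) -> "FoodWeb":
        return replace(self, links=self.links + tuple(new_links))

    def with_species(self, new_species: Iterable[Species],
                     new_links: Iterable[Link] = ()) -> "FoodWeb":
        return replace(
            self,
            species=self.species + tuple(new_species),
            links=self.links + tuple(new_links),
        )

    def subweb(self, keep_ids: Iterable[str],
               link_types: Iterable[str] = LINK_TYPES) -> "FoodWeb":
        """Induced sub-web on ``keep_ids`` restricted to ``link_types``."""
        keep = set(keep_ids)
        types = set(link_types)
        species = tuple(s for s in self.species if s.id in keep)
        nutrients = {s.nutrient_id for s in species if s.nutrient_id}
        links = tuple(
            l
            for l in self.links
            if l.link_type in types
            and l.consumer in keep
            and (l.resource in keep or l.resource in nutrients)
        )
        return replace(self, species=species, links=links)

    def free_living_subweb(self) -> "FoodWeb":
        """Sub-web of free-living species and the trophic links among them."""
        free = [s.id for s in self.species if s.kind == FREE_LIVING]
        return self.subweb(free, link_types=(TROPHIC,))


def validate_web(web: FoodWeb) -> list[str]:
    """Check every structural invariant; return a list of violations.

    Reports rather than raises — an empty list means the web is consistent.
    """
    violations: list[str] = []
    ids = [s.id for s in web.species]
    if len(ids) != len(set(ids)):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        violations.append(f"duplicate species ids: {dupes}")
    if not web.species:
        violations.append("web has no species")
        return violations

    nutrients = set(web.nutrients)
    for s in web.species:
        if s.kind not in SPECIES_KINDS:
            violations.append(f"species {s.id!r}: unknown kind {s.kind!r}")
        if s.kind == PARASITE and s.nutrient_id is not None:
            violations.append(f"parasite {s.id!r} cannot be basal (has nutrient_id)")

    for link in web.links:
        if link.link_type not in LINK_TYPES:
            violations.append(
                f"link {link.resource}->{link.consumer}: unknown type {link.link_type!r}"
            )
            continue
        if link.consumer not in web:
            violations.append(f"link consumer {link.consumer!r} is not a species")
            continue
        if link.resource not in web:
            if link.resource in nutrients:
                consumer = web.species_by_id(link.consumer)
                if consumer.nutrient_id != link.resource:
                    violations.append(
                        f"nutrient link {link.resource}->{link.consumer}: consumer is "
                        f"not assigned to nutrient {link.resource!r}"
                    )
            else:
                violations.append(f"link resource {link.resource!r} is unknown")
            continue
        if link.resource == link.consumer and not web.allow_cannibalism:
            violations.append(
                f"self-link on {link.resource!r} without allow_cannibalism"
            )
        if link.link_type in (CONCOMITANT_ASYM, CONCOMITANT_SYM):
            res = web.species_by_id(link.resource)
            con = web.species_by_id(link.consumer)
            if res.kind != PARASITE:
                violations.append(
                    f"concomitant link {link.resource}->{link.consumer}: resource "
                    "must be a parasite"
                )
            if con.kind != FREE_LIVING:
                violations.append(
                    f"concomitant link {link.resource}->{link.consumer}: consumer "
                    "must be a free-living predator"
                )

    # basal status must match the diet topology
    for s in web.species:
        prey = [p for p in web.prey_of(s.id) if p != s.id]
        if s.basal and prey:
            violations.append(
                f"species {s.id!r} has nutrient_id but also prey {sorted(set(prey))}"
            )
        if not s.basal and not prey:
            violations.append(
                f"species {s.id!r} has neither nutrient_id nor any prey"
            )

    if web.nutrient_mode == SHARED and web.n_S > 1:
        violations.append(
            f"nutrient_mode=shared but {web.n_S} distinct nutrient ids present"
        )

    if not web.allow_components and web.S > 0:
        n_comp = _component_count(web)
        if n_comp > 1:
            violations.append(
                f"web is disconnected ({n_comp} components); pass "
                "allow_components=True to analyse components separately"
            )
    return violations


def _component_count(web: FoodWeb) -> int:
    """Connected components over species ∪ nutrients (links + uptake edges)."""
    import networkx as nx

    g = nx.Graph()
    g.add_nodes_from(s.id for s in web.species)
    for s in web.species:
        if s.nutrient_id is not None:
            g.add_edge(s.id, ("nutrient", s.nutrient_id))
    for link in web.links:
        if link.resource in web and link.consumer in web:
            g.add_edge(link.resource, link.consumer)
    return nx.number_connected_components(g)
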