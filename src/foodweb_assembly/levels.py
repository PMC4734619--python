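"""Trophic structure: prey-averaged levels, sharp levels and omnivory.

The trophic level of a species is its prey-averaged food chain length:
nutrients sit at level 0, basal species at level 1, and every consumer at one
plus the arithmetic mean of its prey's levels. Diet cycles (e.g. mutual
predation) are handled by solving the induced linear system rather than by
iterating in some order. Concomitant links never enter the prey set — they
are mortality links for the parasite, not diet.
"""

from __future__ import annotations

import math
from collections import deque
from dataclasses import dataclass

import numpy as np

from .web import FoodWeb

__all__ = [
    "prey_averaged_levels",
    "sharp_levels",
    "level_profile",
    "omnivory_index",
    "LevelProfile",
]


@dataclass(frozen=True)
class LevelProfile:
    """Species counts per sharp trophic level plus the nutrient count.

    ``counts[l-1]`` is the species richness n_l at level ``l``; ``n_S`` is the
    number of distinct nutrient pools. N_o and N_e sum the richness of odd and
    even levels and Δ = N_o − N_e is the balance the assembly rules constrain.
    """

    counts: tuple[int, ...]
    n_S: int = 1

    def __post_init__(self) -> None:
        if not self.counts:
            raise ValueError("a level profile needs at least one level")
        if any(c <= 0 for c in self.counts):
            raise ValueError(f"level counts must be positive, got {self.counts}")
        if self.n_S < 1:
            raise ValueError("n_S must be at least 1")

    @classmethod
    def from_counts(cls, counts, n_S: int = 1) -> "LevelProfile":
        return cls(tuple(int(c) for c in counts), n_S=int(n_S))

    @property
    def L(self) -> int:
        return len(self.counts)

    @property
    def S(self) -> int:
        return sum(self.counts)

    @property
    def N_o(self) -> int:
        return sum(self.counts[0::2])

    @property
    def N_e(self) -> int:
        return sum(self.counts[1::2])

    @property
    def delta(self) -> int:
        return self.N_o - self.N_e


def prey_averaged_levels(web: FoodWeb) -> dict[str, float]:
    """Solve the prey-averaged chain-length system for every species.

    Basal species are level 1; a consumer's level is 1 plus the mean level of
    its prey. The defining equations are linear, so webs whose diet graph
    contains cycles are solved exactly rather than approximated.

    Raises ``ValueError`` when a species cannot be reached from any basal
    species through diet links (its chain length would be undefined).
    """
    ids = list(web.ids)
    if not ids:
        raise ValueError("cannot compute levels of an empty web")
    pos = {sid: i for i, sid in enumerate(ids)}

    basal = [s.id for s in web.species if s.basal]
    reachable = set(basal)
    queue = deque(basal)
    while queue:
        current = queue.popleft()
        for pred in web.predators_of(current):
            if pred not in reachable:
                reachable.add(pred)
                queue.append(pred)
    unreachable = sorted(set(ids) - reachable)
    if unreachable:
        raise ValueError(
            "species not reachable from any basal species via diet links: "
            f"{unreachable}"
        )

    n = len(ids)
    a = np.zeros((n, n))
    b = np.ones(n)
    for sid in ids:
        i = pos[sid]
        a[i, i] = 1.0
        if web.species_by_id(sid).basal:
            continue  # level fixed to 1
        prey = web.prey_of(sid)
        w = 1.0 / len(prey)
        for p in prey:
            a[i, pos[p]] -= w
    try:
        x = np.linalg.solve(a, b)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - needs exotic cycles
        raise ValueError(f"singular trophic-level system: {exc}") from exc
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite trophic levels")
    return {sid: float(x[pos[sid]]) for sid in ids}


def sharp_levels(levels: dict[str, float]) -> dict[str, int]:
    """Round each chain length to the nearest integer; ties (x.5) round up."""
    out = {}
    for sid, value in levels.items():
        if not math.isfinite(value):
            raise ValueError(f"non-finite level for species {sid!r}")
        out[sid] = int(math.floor(value + 0.5))
    return out


def level_profile(web: FoodWeb, levels: dict[str, float] | None = None) -> LevelProfile:
    """Tally species per sharp level into a :class:`LevelProfile`.

    ``levels`` may be real-valued (rounded here) or already integral.
    An interior level with zero species is rejected — the assembly rules are
    stated for contiguous level structures.
    """
    if web.S == 0:
        raise ValueError("cannot profile an empty web")
    if levels is None:
        levels = prey_averaged_levels(web)
    sharp = sharp_levels(levels)
    top = max(sharp.values())
    counts = [0] * top
    for value in sharp.values():
        if value < 1:
            raise ValueError(f"species at level {value} < 1")
        counts[value - 1] += 1
    if any(c == 0 for c in counts):
        empty = [l + 1 for l, c in enumerate(counts) if c == 0]
        raise ValueError(f"no species at interior level(s) {empty}")
    return LevelProfile(tuple(counts), n_S=max(web.n_S, 1))


def omnivory_index(web: FoodWeb) -> tuple[dict[str, float], float]:
    """Per-species omnivory and its web-level mean.

    Omnivory of a consumer is the population standard deviation of its prey's
    prey-averaged chain lengths; species with at most one prey score 0. The
    web-level value is the mean over non-basal species (0 for a web of basal
    species only).
    """
    levels = prey_averaged_levels(web)
    per_species: dict[str, float] = {}
    consumer_values = []
    for s in web.species:
        prey = web.prey_of(s.id)
        if s.basal or len(prey) == 0:
            per_species[s.id] = 0.0
            continue
        prey_levels = np.array([levels[p] for p in prey])
        value = float(np.std(prey_levels))  # population SD over the prey set
        per_species[s.id] = value
        consumer_values.append(value)
    mean = float(np.mean(consumer_values)) if consumer_values else 0.0
    return per_species, mean
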