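"""Steady-state interaction matrix R: pattern, pairing, rank and nullity.

At steady state the generalized Lotka–Volterra equations reduce to the linear
system R·S = k. The zero pattern of R encodes the topology: a trophic link
between resource m and consumer c contributes the symmetric entry pair
(row c, col m) and (row m, col c); basal species carry an additional block of
competition entries p_ji which is all-ones within each shared nutrient pool
(and the identity under individual nutrients); asymmetric concomitant links
contribute a single directed entry (the parasite's loss term).

Coexistence requires det(R) ≠ 0, which holds generically exactly when the
pattern supports a permutation — a cover of all species by vertex-disjoint
cycles of nonzero entries (2-cycles are consumer–resource pairs, 1-cycles are
diagonal self-pairings). The one subtlety is the shared-nutrient block: its
entries are all equal, so it is a rank-one block and at most one pairing may
pass through each nutrient pool. :func:`find_pairing` enforces this with a
nutrient-augmented matching, and :func:`exact_det_oracle` verifies the same
cancellation symbolically on small patterns.

The nullity d ≡ S − rank(R), computed with random weights on the nonzero
entries, counts the species left without a private niche (unpaired species).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import maximum_bipartite_matching

from .levels import prey_averaged_levels, sharp_levels
from .web import (
    CONCOMITANT_ASYM,
    CONCOMITANT_SYM,
    FoodWeb,
    GROUPED,
    INDIVIDUAL,
    SHARED,
)
from . import web as _web

__all__ = [
    "InteractionPattern",
    "WeightedMatrix",
    "Pairing",
    "build_pattern",
    "assign_random_weights",
    "numeric_rank",
    "generic_rank",
    "nullity",
    "structural_rank",
    "find_pairing",
    "exact_det_oracle",
    "IDENTICALLY_ZERO",
    "GENERICALLY_NONZERO",
]

GAIN = "+"
LOSS = "-"
UNIT = "unit"

IDENTICALLY_ZERO = "identically_zero"
GENERICALLY_NONZERO = "generically_nonzero"


@dataclass
class InteractionPattern:
    """Sign/zero pattern of R with species indexing.

    ``entries`` maps (row, col) positions to a sign tag in {``+``, ``-``,
    ``unit``}; row i holds the steady-state equation of species ``index[i]``
    and column j the density of species ``index[j]``. ``nutrient_groups``
    records, per nutrient pool, the indices of the basal species whose
    competition entries are tied to the common value 1 — the source of the
    rank-one basal blocks.
    """

    index: tuple[str, ...]
    entries: dict[tuple[int, int], str]
    nutrient_groups: dict[str, tuple[int, ...]]
    diagonal_allowed: bool = False

    @property
    def S(self) -> int:
        return len(self.index)

    def basal_block(self) -> tuple[tuple[int, int], ...]:
        """Positions of the competition (p) entries."""
        positions = []
        for members in self.nutrient_groups.values():
            for i in members:
                for j in members:
                    positions.append((i, j))
        return tuple(sorted(positions))

    def group_of(self) -> dict[tuple[int, int], str]:
        """Map each basal-block position to its nutrient id."""
        out = {}
        for nutrient, members in self.nutrient_groups.items():
            for i in members:
                for j in members:
                    out[(i, j)] = nutrient
        return out


@dataclass
class WeightedMatrix:
    """A random realisation of a pattern: tied unit entries, random others."""

    pattern: InteractionPattern
    matrix: np.ndarray
    seed: int


@dataclass
class Pairing:
    """A (possibly partial) non-overlapping pairing.

    ``cover`` is a tuple of cycles, each a tuple of (row, col) entry
    positions; 2-cycles are symmetric consumer–resource pairs and 1-cycles
    diagonal self-pairings. ``size`` is the number of species covered
    (the structural rank of the pattern under tied nutrient blocks).
    """

    cover: tuple[tuple[tuple[int, int], ...], ...]
    complete: bool
    size: int


def build_pattern(
    web: FoodWeb,
    nutrient_mode: str | None = None,
    order: str = "level",
) -> InteractionPattern:
    """Construct the zero/sign pattern of R from a food web.

    ``nutrient_mode`` overrides the web's own mode (e.g. to re-analyse a
    shared-nutrient web with an individual pool per basal species). Rows and
    columns are ordered by ascending sharp trophic level, then id; det(R) is
    invariant under the ordering, which is purely presentational. ``order``
    may be set to ``"id"`` for webs whose levels are not computable.
    """
    if web.S == 0:
        raise ValueError("cannot build a pattern for an empty web")
    mode = nutrient_mode or web.nutrient_mode

    ids = _ordered_ids(web, order)
    pos = {sid: i for i, sid in enumerate(ids)}

    # competition (p) blocks: grouping depends on the nutrient mode
    if mode == SHARED:
        groups = {"shared": tuple(pos[b] for b in web.basal_ids)}
    elif mode == INDIVIDUAL:
        groups = {f"ind:{b}": (pos[b],) for b in web.basal_ids}
    elif mode == GROUPED:
        raw = web.nutrient_groups()
        unassigned = [b for b in web.basal_ids
                      if web.species_by_id(b).nutrient_id is None]
        if unassigned:
            raise ValueError(f"grouped nutrient mode with unassigned basal "
                             f"species: {unassigned}")
        groups = {n: tuple(pos[b] for b in members)
                  for n, members in raw.items()}
    else:
        raise ValueError(f"unknown nutrient mode {mode!r}")

    entries: dict[tuple[int, int], str] = {}
    for nutrient, members in groups.items():
        for i in members:
            for j in members:
                entries[(i, j)] = UNIT

    diagonal = False
    for link in web.links:
        if link.resource not in web:  # nutrient uptake rows carry no entry
            continue
        r, c = pos[link.resource], pos[link.consumer]
        if link.link_type in _web.DIET_LINK_TYPES:
            if r == c:
                entries.setdefault((r, r), LOSS)  # cannibalistic self-pairing
                diagonal = True
                continue
            # consumer's equation gains from the resource ...
            entries.setdefault((c, r), GAIN)
            # ... and the resource's equation records the consumer
            tag = GAIN if web.species_by_id(link.resource).basal else LOSS
            entries.setdefault((r, c), tag)
        elif link.link_type == CONCOMITANT_ASYM:
            entries.setdefault((r, c), LOSS)  # parasite loss only
        elif link.link_type == CONCOMITANT_SYM:
            entries.setdefault((r, c), LOSS)
            entries.setdefault((c, r), GAIN)
        else:
            raise ValueError(f"unknown link type {link.link_type!r}")

    return InteractionPattern(
        index=tuple(ids),
        entries=entries,
        nutrient_groups=groups,
        diagonal_allowed=diagonal,
    )


def _ordered_ids(web: FoodWeb, order: str) -> list[str]:
    if order == "id":
        return sorted(web.ids)
    if order != "level":
        raise ValueError(f"unknown ordering {order!r}")
    levels = sharp_levels(prey_averaged_levels(web))
    return sorted(web.ids, key=lambda sid: (levels[sid], sid))


def assign_random_weights(
    pattern: InteractionPattern,
    seed: int,
    magnitude_range: tuple[float, float] = (0.5, 1.5),
) -> WeightedMatrix:
    """Fill the pattern with independent random magnitudes.

    Unit (competition) entries stay exactly 1 — they are tied by the shared
    nutrient pool, and this is the one place independent random values would
    be wrong. All other entries get independent uniform magnitudes with the
    tag's sign. Identical seeds give identical matrices.
    """
    if pattern.S == 0:
        raise ValueError("cannot weight an empty pattern")
    lo, hi = magnitude_range
    if not (0 < lo <= hi):
        raise ValueError(f"invalid magnitude range {magnitude_range}")
    rng = np.random.default_rng(seed)
    m = np.zeros((pattern.S, pattern.S))
    for (i, j), tag in sorted(pattern.entries.items()):
        if tag == UNIT:
            m[i, j] = 1.0
        else:
            value = rng.uniform(lo, hi)
            m[i, j] = value if tag == GAIN else -value
    return WeightedMatrix(pattern=pattern, matrix=m, seed=seed)


def numeric_rank(matrix: np.ndarray) -> int:
    """Rank from singular values with relative tolerance S·ε·σ_max."""
    s = np.linalg.svd(matrix, compute_uv=False)
    if s.size == 0 or s[0] == 0.0:
        return 0
    tol = max(matrix.shape) * np.finfo(matrix.dtype).eps * s[0]
    return int(np.sum(s > tol))


def generic_rank(
    web: FoodWeb,
    trials: int = 3,
    seed: int = 0,
    nutrient_mode: str | None = None,
    pattern: InteractionPattern | None = None,
) -> int:
    """Generic rank of R estimated as the max numeric rank over random draws.

    Random weights achieve the generic rank with probability one; several
    trials guard against an unlucky near-singular draw.
    """
    if trials < 1:
        raise ValueError("trials must be >= 1")
    if pattern is None:
        pattern = build_pattern(web, nutrient_mode=nutrient_mode)
    best = 0
    for t in range(trials):
        weighted = assign_random_weights(pattern, seed=seed + t)
        best = max(best, numeric_rank(weighted.matrix))
    return best


def nullity(
    web: FoodWeb,
    trials: int = 3,
    seed: int = 0,
    nutrient_mode: str | None = None,
    pattern: InteractionPattern | None = None,
) -> int:
    """Lack of niches d ≡ S − rank(R) under random weights."""
    if pattern is None:
        pattern = build_pattern(web, nutrient_mode=nutrient_mode)
    return pattern.S - generic_rank(web, trials=trials, seed=seed, pattern=pattern)


# ---------------------------------------------------------------------------
# structural (term) rank with tied nutrient blocks, and pairing witnesses
# ---------------------------------------------------------------------------

def _augmented_matching(pattern: InteractionPattern) -> tuple[int, np.ndarray, list[str]]:
    """Maximum matching of the nutrient-augmented row–column graph.

    The all-ones block of nutrient pool g is the rank-one outer product
    e_g·e_gᵀ, and rank(A + Σ_g u_g v_gᵀ) = rank([[A, U], [Vᵀ, −I]]) − k.
    Structurally, the augmentation replaces the tied block by a nutrient node
    that at most one pairing can pass through. Returns the raw matching size
    of the augmented graph, scipy's column-for-row assignment, and the
    nutrient ordering used for the extra indices.
    """
    nutrients = sorted(pattern.nutrient_groups)
    k = len(nutrients)
    n = pattern.S + k
    block = set(pattern.basal_block())
    rows, cols = [], []
    for (i, j) in pattern.entries:
        if (i, j) not in block:
            rows.append(i)
            cols.append(j)
    for g, nutrient in enumerate(nutrients):
        aug = pattern.S + g
        for i in pattern.nutrient_groups[nutrient]:
            rows.extend((i, aug))
            cols.extend((aug, i))
        rows.append(aug)
        cols.append(aug)
    graph = csr_matrix((np.ones(len(rows), dtype=np.int8), (rows, cols)),
                       shape=(n, n))
    match = maximum_bipartite_matching(graph, perm_type="column")
    size = int(np.sum(match >= 0))
    return size, match, nutrients


def structural_rank(pattern: InteractionPattern) -> int:
    """Generic rank implied by the pattern alone (term rank with tied blocks)."""
    size, _, nutrients = _augmented_matching(pattern)
    return size - len(nutrients)


def find_pairing(pattern: InteractionPattern) -> Pairing:
    """Search for a complete non-overlapping pairing (cycle cover).

    A permutation supported on the pattern is exactly a cover of all species
    by vertex-disjoint cycles of directed pairings; for bipartite patterns
    (sharp levels, no omnivory) it reduces to a perfect matching between
    neighboring levels. The row–column matching runs on the
    nutrient-augmented graph so that each (shared) nutrient pool pairs with
    at most one basal species. When complete, a witness cover is returned.
    """
    size, match, nutrients = _augmented_matching(pattern)
    covered = size - len(nutrients)
    complete = covered == pattern.S
    if not complete:
        return Pairing(cover=(), complete=False, size=covered)

    # contract nutrient nodes: row i -> nutrient g -> col j becomes the block
    # entry (i, j); a self-matched nutrient drops out.
    perm: dict[int, int] = {}
    row_for_col = {int(c): r for r, c in enumerate(match) if c >= 0}
    for r in range(pattern.S):
        c = int(match[r])
        if c < pattern.S:
            perm[r] = c
    for g in range(len(nutrients)):
        aug = pattern.S + g
        c = int(match[aug])
        if c == aug:
            continue
        r = row_for_col[aug]  # species row matched into the nutrient column
        perm[r] = c  # uses block entry (r, c), both basal in pool g

    cycles = []
    seen: set[int] = set()
    for start in range(pattern.S):
        if start in seen:
            continue
        cycle = []
        node = start
        while node not in seen:
            seen.add(node)
            nxt = perm[node]
            cycle.append((node, nxt))
            node = nxt
        if cycle:
            cycles.append(tuple(cycle))
    return Pairing(cover=tuple(cycles), complete=True, size=pattern.S)


# ---------------------------------------------------------------------------
# exact symbolic determinant oracle for small patterns
# ---------------------------------------------------------------------------

def exact_det_oracle(pattern: InteractionPattern, max_size: int = 10) -> str:
    """Decide whether det(R) is the zero polynomial for a small pattern.

    Every entry is treated as an independent symbol except the competition
    entries of one nutrient pool, which share a single symbol — exactly the
    tie that makes permutations using two or more entries of the same pool
    cancel pairwise. The determinant is expanded permutation by permutation
    over the support and monomial coefficients are collected; the pattern is
    generically nonzero iff some coefficient survives.

    Factorial cost: refuses patterns with more than ``max_size`` species
    (use :func:`nullity` there).
    """
    n = pattern.S
    if n > max_size:
        raise ValueError(
            f"exact_det_oracle is limited to S <= {max_size} (got {n}); "
            "use nullity() for larger webs"
        )
    group_of = pattern.group_of()
    symbol: dict[tuple[int, int], object] = {}
    for (i, j) in pattern.entries:
        if (i, j) in group_of:
            symbol[(i, j)] = ("p", group_of[(i, j)])
        else:
            symbol[(i, j)] = ("e", i, j)

    row_entries: list[list[int]] = [[] for _ in range(n)]
    for (i, j) in pattern.entries:
        row_entries[i].append(j)
    # visit sparse rows first for early pruning
    row_order = sorted(range(n), key=lambda i: len(row_entries[i]))
    row_masks = [sum(1 << j for j in row_entries[i]) for i in row_order]

    coeffs: dict[tuple, int] = {}
    assignment: list[tuple[int, int]] = []  # (row, col) in processing order

    def recurse(depth: int, used: int, sign: int) -> None:
        if depth == n:
            monomial = tuple(sorted(
                symbol[(r, c)] for r, c in assignment
            ))
            coeffs[monomial] = coeffs.get(monomial, 0) + sign
            return
        # prune: some later row with no free column
        free = ~used
        for later in range(depth, n):
            if row_masks[later] & free == 0:
                return
        row = row_order[depth]
        for col in row_entries[row]:
            bit = 1 << col
            if used & bit:
                continue
            inversions = sum(
                1 for (r2, c2) in assignment if (r2 - row) * (c2 - col) < 0
            )
            assignment.append((row, col))
            recurse(depth + 1, used | bit, sign * (-1) ** inversions)
            assignment.pop()

    recurse(0, 0, 1)
    nonzero = any(c != 0 for c in coeffs.values())
    return GENERICALLY_NONZERO if nonzero else IDENTICALLY_ZERO
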