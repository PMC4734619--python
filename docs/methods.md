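# Methods

## Model

The package works with generalized Lotka–Volterra (GLV) dynamics for a
community of S species organised by who eats whom. Primary producers
(basal species) draw on one or more abiotic nutrient pools and obey

    Ṡ_i / S_i = k_i (1 − Σ_j p_ji S_j) − α_i − Σ_c η_ci S_c ,

where k_i is the maximal growth rate (time⁻¹), α_i the decay rate, p_ji the
competition factor between producers j and i (1 within a shared pool, 0
across pools), and η_ci the interaction coefficient with consumer c. Every
other species balances conversion gain against predation loss and decay,

    Ṡ_c / S_c = Σ_m β_cm η_cm S_m − Σ_q η_qc S_q − α_c ,

with conversion efficiencies β ∈ (0, 1]. Interactions are linear (type-I
response); consumers are not self-limiting. Setting the derivatives to zero
gives the linear steady state **R·S = k**: row i of R holds the coefficients
of species i's equation (producers additionally carry the p-block of
competition entries, all equal within a shared pool), and k collects
k̃_i ≡ (k_i − α_i)/k_i for producers and α_c for consumers.

## The pairing criterion and the lack of niches

Sustainable coexistence needs a unique, perturbation-robust steady state,
hence det(R) ≠ 0. Generically this holds exactly when the zero pattern of R
supports a permutation — a cover of all species by vertex-disjoint cycles of
nonzero entries. A 2-cycle is a consumer–resource pair (the mutual entries
either side of the diagonal), a 1-cycle a diagonal entry (a producer
"paired with the nutrient", or a cannibal), and longer directed cycles
appear once omnivory, parasitism or concomitant links make the pattern
non-bipartite. We call such a cover a non-overlapping pairing.

One subtlety makes naive term rank wrong: within a shared nutrient pool the
competition entries are all equal, so the p-block has rank one and at most
one pairing may pass through each pool. `find_pairing` therefore runs the
row–column matching on a nutrient-augmented graph: the identity
rank(A + Σ_g u_g v_gᵀ) = rank([[A, U], [Vᵀ, −I]]) − n_S turns each tied
rank-one block into an explicit nutrient node that a single cycle can use.
`exact_det_oracle` verifies the same cancellation symbolically on patterns
with S ≤ 10 by expanding the determinant over support permutations with one
shared symbol per pool: any term using two or more entries of the same pool
cancels against its transposition partner.

The *lack of niches* is d ≡ S − rank(R). `nullity` estimates the generic
rank by filling the pattern with independent uniform magnitudes on
[0.5, 1.5] (signs from the pattern, tied competition entries kept at exactly
1), taking the numeric rank from singular values at relative tolerance
S·ε·σ_max, and maximising over 3 seeds. The trial count and tolerance are
this package's declared defaults — random weights achieve the generic rank
with probability one, and the extra trials only guard against a near-
singular draw. Tests verify d equals the deficit of the augmented matching
wherever entries are untied.

## Assembly rules

For webs whose species occupy sharp integer trophic levels (every diet link
spanning exactly one level) the pattern is layered-bipartite and the pairing
criterion reduces to counting. With n_l species at level l, N_o and N_e the
odd- and even-level totals and n_S nutrient pools, coexistence requires

* Δ ≡ N_o − N_e ∈ {0, 1, …, n_S} (Δ = 0 consumer-limited, Δ = n_S
  resource-limited, intermediate values mixed), and
* the nested inequalities n_1 ≥ Δ, n_2 ≥ n_1 − Δ, n_3 ≥ n_2 − n_1 + Δ, …
  up to level L−1, evaluated here as alternating partial sums (the closing
  sum at level L vanishes identically for the profile's own Δ). These are
  the Hall conditions of the layered pairing graph: for fully connected
  adjacent levels they are exact, for sparse links necessary only, so
  `check_web` always also runs the pairing test and never declares a sparse
  web sustainable on counts alone.

A direct corollary is intermediate dominance, n_1 + n_L ≤ n_2 + n_{L−1},
shifted by one species in the resource-limited state. Webs with omnivores
have no binding counts rule; the verdict defers to the pairing test.
Removing (or adding) a species can break the rules; `predict_secondary_
extinctions` re-profiles and re-pairs the web after each single removal and
flags the removals that force further losses.

## Dynamics, feasibility, stability

`steady_state_solve` solves R·S = k and reports feasibility (all densities
strictly positive). `simulate` integrates the ODEs with LSODA and an
analytic Jacobian over geometrically growing windows, stopping when
max |Ṡ_i/S_i| < 10⁻⁹ over surviving species; species falling below 10⁻¹²
are set to zero and stay there (the flow leaves the boundary invariant).
The horizon is 10⁶ time units. The integration tolerance is rtol = 10⁻¹²:
the steady detector reads the derivative off the integrated state, so the
noise floor of the integrator must sit below the steady threshold —
at rtol 10⁻⁸ the residual plateaus near 10⁻⁸ and the detector can never
fire. Weakly damped webs (slowest relaxation modes scale with the smallest
decay rates) may still reach the horizon before the threshold; such stages
are flagged, not errors.

Global stability of feasible tree webs is monitored with the classical
weighted Lyapunov function V(S) = Σ_i c_i (S_i − S*_i − S*_i ln(S_i/S*_i)),
with c = 1 for producers and c_consumer = c_resource/β along each tree
link; the consumer–resource cross terms then cancel and V̇ reduces to the
negative-semidefinite producer competition term. The weights are well
defined when each consumer has one prey (the tree backbone); for other webs
the package falls back to unit weights and validates monotonicity
numerically rather than claiming it.

For any rule-satisfying profile, parameters always exist that make the tree
web feasible. `feasible_tree_params` realises this constructively: draw
target densities shrinking geometrically with level (default factor 0.2),
rescale so every producer stays within carrying capacity, and read α off
the steady-state equations at unit k, η, β.

## The packaged assembly demonstration

`tree_assembly_demo` grows a two-branch tree over a single shared nutrient
through the stage profiles (1), (1,1), (2,1), (2,2), (2,2,1), (2,2,1,1),
(2,2,2,1), (2,2,2,2) — alternating between resource- and consumer-limited
states, every stage passing the rules. Rates are unit except the decay list
α = (.1, .1, .16, .1, .12, .15, .1, .1) in introduction order; each species
enters at density 10⁻⁴. The topology is a reconstruction: the diagram it
emulates is published only as a figure, so the packaged tree is any
assembly sequence consistent with the stage profiles and the decay list
(all eight stage steady states were hand-solved and are strictly positive;
the final state is (.25, .45, .20, .39, .15, .33, .10, .29)). A weak extra
link present in the original diagram was zeroed in the original simulations
and is simply omitted here.

## Synthetic webs

* `tree_web` builds the pairing first — Δ producers anchored on distinct
  pools, the rest as adjacent-level 2-cycles — then gives every
  upward-paired species one random prey a level down. Each consumer has
  exactly one prey: the web is maximally trophically coherent and has d = 0
  by construction.
* `layered_web` assigns a requested number of uniform adjacent-level links,
  each consumer keeping at least one prey. Individual nutrient pools per
  producer are the default, matching the convention of the rank analyses.
* `niche_model` / `cascade_model` follow the canonical constructions
  (uniform niche values with beta-distributed diet ranges; a strict
  hierarchy with link probability 2CS/(S−1)). Draws with isolated species,
  no producer, or species unreachable from a producer are discarded and
  redrawn; the niche model allows cannibalistic self-links (diagonal
  entries, hence 1-cycles).
* `generic_web` emulates the averaged empirical coastal web: 110
  free-living species on the packaged profile (20, 45, 30, 13, 2) with 700
  adjacent-level links (~6.4 links/species). The profile is a
  reconstruction — only the totals (110 free-living, 47 parasites) are
  published as numbers — and is deliberately even-dominated (N_e − N_o = 6),
  because the empirical free-living webs are all consumer-limited; that
  imbalance, plus link sparsity, is what leaves d > 0 for sharp-level webs.
* `add_parasites` wires 47 parasites (the empirical average) under four
  protocols: first link to any free-living species (cases c, d) or to a
  species at level 3–4 (cases e, f); subsequent links to any free-living
  species (c), only to the level of the parasite's first host (d), to
  levels 3–4 (e), or to levels 3–4 with ~5% of links to another parasite
  (f, hyperparasitism). The links-per-parasite sweep grid used in tests
  (1–10, 20 seeds) is this package's choice — the empirical average is not
  published as a number, so the sweep treats it as the independent
  variable.
* `add_concomitant_links` adds one parasite → host-predator link per
  (parasite, host, predator) triple; 20% are symmetric by default.
  Asymmetric concomitant links are single directed entries and help only
  through closed directed loops; symmetric ones are ordinary pairs and can
  anchor one parasite each, which is why only they reliably improve rank
  when parasites are in surplus.

## What the generators do and do not emulate

The synthetic webs reproduce the *structural* conditions of the analyses —
level profiles, link densities, parasite wiring protocols — but not
body-mass scaling, sampling intensity, spatial structure or the
species-specific biology of real webs. Passing tests therefore demonstrate
the combinatorial and dynamical claims (rules ⟺ pairing ⟺ rank; parasite
links restore rank; tree assembly is feasible and stable), not agreement
with any particular empirical dataset; re-analysis of published empirical
webs is out of scope.

## Numerical choices and edge cases

* Sharp levels round half-up (2.5 → 3), fixed so profiles are
  deterministic.
* Prey-averaged levels solve the induced linear system, so diet cycles are
  handled exactly; species unreachable from a producer are an error naming
  the species.
* Concomitant links never enter the prey set of the level computation —
  they are mortality, not diet.
* Matrix row/column order is ascending sharp level then id; det(R) and d
  are invariant under the ordering (tested).
* Disconnected webs are rejected by default; `allow_components` permits
  per-component analysis.
* `exact_det_oracle` refuses S > 10 (factorial cost) and points to
  `nullity`.
* The multi-nutrient rule family is implemented as the same Hall conditions
  at the profile's own Δ with Δ ∈ {0..n_S} admissible — the published
  account only summarises the several-nutrient case, and this is the
  package's documented reading of it.

## Known limitations

No type-II/Holling responses, frequency-dependent predation, multi-host
parasite life cycles, eigenvalue-based local stability screening, or
structural-stability volume estimation. The Lyapunov construction is exact
only on tree backbones. `nullity` is a numeric-rank protocol: for matrices
far larger than those used here (S of a few hundred), tolerance tuning
would deserve re-examination.
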