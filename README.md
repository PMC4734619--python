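# foodweb-assembly

Assembly rules, pairing/rank diagnostics and generalized Lotka–Volterra
(GLV) dynamics for food webs.

## The problem

In a GLV community the steady state solves the linear system **R·S = k**,
where R is the interaction matrix of consumer–resource couplings.
Coexistence of all S species requires det(R) ≠ 0 — each species must occupy
its own niche. That algebraic condition has a combinatorial face: the zero
pattern of R must admit a **non-overlapping pairing**, a cover of all
species by vertex-disjoint cycles of nonzero entries (consumer–resource
pairs, producers paired with a nutrient pool, or longer directed loops once
omnivores or parasites are present). When no complete pairing exists, the
**lack of niches** d ≡ S − rank(R) counts the species left unpaired.

For webs organised in sharp trophic levels with richness n_1 … n_L over n_S
nutrient pools, the pairing condition reduces to the **food web assembly
rules**:

    Δ ≡ N_o − N_e ∈ {0, 1, …, n_S}
    n_1 ≥ Δ,  n_2 ≥ n_1 − Δ,  n_3 ≥ n_2 − n_1 + Δ,  …

with N_o, N_e the total richness of odd and even levels. Δ = 0 is the
consumer-limited state, Δ = n_S the resource-limited one; a corollary is
that intermediate levels dominate sustainable communities
(n_1 + n_L ≤ n_2 + n_{L−1}). The package is for ecologists and modellers
who want to check these rules on a web, quantify its missing niches,
predict which removals force secondary extinctions, and simulate community
assembly species by species.

## What's inside

| module | contents |
| --- | --- |
| `web` | typed food webs: species, trophic/parasitic/concomitant links, nutrient pools, validation |
| `levels` | prey-averaged trophic levels (exact on diet cycles), sharp rounding, level profiles, omnivory index |
| `matrix` | interaction-matrix pattern, random-weight nullity d, pairing search (nutrient-aware matching), exact symbolic determinant oracle |
| `rules` | assembly-rule verdicts, intermediate dominance, profile enumeration, secondary-extinction prediction |
| `dynamics` | steady states, stiff ODE integration, Lyapunov traces, sequential assembly, constructive feasible parameters for trees |
| `generators` | tree webs, layered webs, niche/cascade models, the generic 110+47 web, parasite addition (4 protocols), hyperparasitism, concomitant links |
| `analysis`, `io`, `cli` | rank-drop tables, TSV/MTX/JSON I/O, the `foodweb` command line |

## Worked example

Grow an eight-species tree community one species at a time — every
introduction at density 10⁻⁴, unit growth/coupling constants, decay
coefficients (.1, .1, .16, .1, .12, .15, .1, .1):

```sh
python examples/03_sequential_assembly.py
```

```
stage  introduced  steady  min density  V trend
    1  s1          True           0.9  non-increasing
    2  s2          True           0.1  non-increasing
    3  s3          True          0.06  non-increasing
    4  s4          True           0.1  non-increasing
    5  s5          True          0.06  non-increasing
    6  s6          True           0.1  non-increasing
    7  s7          True          0.04  non-increasing
    8  s8          True           0.1  non-increasing

final densities:
  s1: 0.250
  s2: 0.450
  s3: 0.200
  s4: 0.390
  s5: 0.150
  s6: 0.330
  s7: 0.100
  s8: 0.290
```

Every stage settles into a feasible steady state (all densities positive)
and the weighted Lyapunov function decreases monotonically within each
stage — each addition is a stable transition, and the final community of
eight species coexists at the densities listed.

The other examples are equally short: `01` evaluates the assembly rules on
level profiles, `02` shows the pairing criterion and how an omnivore
repairs a violating web, `04` contrasts the full-rank niche/cascade models
(modal d = 0 at S = 110) with a sharp-level web (d = 6), and `05` sweeps
the four parasite-linking protocols — random linking recovers full rank,
level-confined linking plateaus at d > 0, hyperparasitism breaks the
plateau — and prints a Free/Par/ParCon rank-drop table.

A thin CLI wraps the same functions:

```sh
foodweb generate --kind generic --case c --links-per-parasite 4 --seed 3 --out-dir web/
foodweb check web/species.tsv web/edges.tsv       # exit 0 pass / 1 fail / 2 invalid
foodweb rankdrop web/species.tsv web/edges.tsv
```

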