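"""Parasites as rank rescuers: the four linking protocols and concomitant links.

Starting from the generic sharp-level web (110 free-living species, d > 0),
47 parasites are wired in under four protocols. Parasites that reach hosts
at many trophic levels (case c) recover full rank as links accumulate;
level-confined parasites (cases d, e) leave a plateau d > 0; parasite–
parasite links (case f, hyperparasitism) break that plateau. Concomitant
links (a predator incidentally eating its prey's parasites) drop d further,
especially the symmetric ones.
"""

import numpy as np

from foodweb_assembly import nullity, rank_drop_table
from foodweb_assembly.generators import add_concomitant_links, generic_web

seeds = range(5)
print("mean d over 5 seeds     links/parasite:  1     4     10")
for case in "cdef":
    row = []
    for lpp in (1, 4, 10):
        row.append(np.mean([
            nullity(generic_web(seed=s, case=case, links_per_parasite=lpp),
                    seed=s)
            for s in seeds
        ]))
    print(f"  case {case}:                          "
          + "  ".join(f"{v:5.1f}" for v in row))

web = add_concomitant_links(
    generic_web(seed=1, case="e", links_per_parasite=4.0), sym_fraction=0.2,
    seed=1,
)
print("\nrank-drop table (case e web + 20% symmetric concomitant links):")
print(rank_drop_table(web, seed=1).to_string(index=False))
print("Reading down the rows: each category of parasite link recovers part "
      "of the missing rank of the free-living web.")
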