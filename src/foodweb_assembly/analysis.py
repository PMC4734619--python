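"""Composite analyses: the link-category rank-drop table.

Mirrors the standard presentation of parasite effects on niche availability:
the lack of niches d is computed on the free-living sub-web, then with
parasite links added, then with concomitant links treated as purely
asymmetric, and finally with the symmetric subset honoured. Parasite links
generally lower d; symmetric concomitant links can lower it further because
each lets a surplus parasite pair with a single free-living species, while
asymmetric ones only help through closed directed loops.
"""

from __future__ import annotations

import logging
from dataclasses import replace

import pandas as pd

from .matrix import nullity
from .web import (
    CONCOMITANT_ASYM,
    CONCOMITANT_SYM,
    PARASITIC,
    TROPHIC,
    FoodWeb,
    Link,
)

__all__ = ["rank_drop_table", "RANK_DROP_CATEGORIES"]

logger = logging.getLogger(__name__)

RANK_DROP_CATEGORIES = ("Free", "Par", "ParCon asym", "ParCon sym")


def _coerce_asym(web: FoodWeb) -> FoodWeb:
    links = tuple(
        Link(l.resource, l.consumer, CONCOMITANT_ASYM)
        if l.link_type == CONCOMITANT_SYM
        else l
        for l in web.links
    )
    return replace(web, links=links)


def rank_drop_table(
    web: FoodWeb,
    trials: int = 3,
    seed: int = 0,
    nutrient_mode: str = "individual",
) -> pd.DataFrame:
    """d per link category, one row per category.

    Categories are cumulative: ``Free`` (free-living species and trophic
    links only), ``Par`` (plus parasites and parasite links), ``ParCon
    asym`` (plus every concomitant link downgraded to asymmetric) and
    ``ParCon sym`` (link types as annotated). Webs without parasites yield a
    single ``Free`` row with a logged warning. Basal species are given
    individual nutrient pools, the convention of the rank analyses.
    """
    rows = []

    def record(label: str, subweb: FoodWeb) -> None:
        d = nullity(subweb, trials=trials, seed=seed, nutrient_mode=nutrient_mode)
        rows.append({"category": label, "S": subweb.S, "d": d})

    record("Free", web.free_living_subweb())
    if not web.parasite_ids:
        logger.warning("rank_drop_table: web has no parasites; single row")
        return pd.DataFrame(rows)

    with_parasites = web.subweb(web.ids, link_types=(TROPHIC, PARASITIC))
    record("Par", with_parasites)
    record("ParCon asym", _coerce_asym(web))
    record("ParCon sym", web)
    return pd.DataFrame(rows)
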