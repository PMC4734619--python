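"""Plain-text I/O: species/edge TSV tables, MTX pattern export, param configs.

Species table columns: ``id``, ``kind``, ``nutrient_id`` (empty for
non-basal species). Edge table columns: ``resource``, ``consumer``,
``link_type``. Both are UTF-8 TSV with a header row; ids are opaque strings.
The nutrient mode is inferred on read: one nutrient id → shared, one id per
basal species → individual, anything else → grouped.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml
from scipy.io import mmwrite
from scipy.sparse import coo_matrix

from .dynamics import GLVParams
from .matrix import GAIN, UNIT, InteractionPattern
from .web import FREE_LIVING, LINK_TYPES, FoodWeb, Link, Species

__all__ = [
    "read_web",
    "write_web",
    "write_pattern_mtx",
    "load_params",
    "params_from_dict",
    "write_trajectory_csv",
]

SPECIES_COLUMNS = ["id", "kind", "nutrient_id"]
EDGE_COLUMNS = ["resource", "consumer", "link_type"]


def read_web(
    species_path: str | Path,
    edges_path: str | Path,
    allow_cannibalism: bool = False,
    allow_components: bool = False,
) -> FoodWeb:
    """Read a web from species and edge TSV tables."""
    sp = pd.read_csv(species_path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in SPECIES_COLUMNS if c not in sp.columns]
    if missing:
        raise ValueError(f"{species_path}: missing column(s) {missing}")
    if sp.empty:
        raise ValueError(f"{species_path}: no species rows")
    dupes = sp["id"][sp["id"].duplicated()].tolist()
    if dupes:
        raise ValueError(f"{species_path}: duplicate species ids {sorted(set(dupes))}")

    species = []
    for row_number, row in enumerate(sp.itertuples(index=False), start=2):
        if not row.id:
            raise ValueError(f"{species_path}: empty id on line {row_number}")
        species.append(
            Species(
                id=row.id,
                kind=row.kind or FREE_LIVING,
                nutrient_id=row.nutrient_id or None,
            )
        )

    ed = pd.read_csv(edges_path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in EDGE_COLUMNS if c not in ed.columns]
    if missing:
        raise ValueError(f"{edges_path}: missing column(s) {missing}")
    links = []
    for row_number, row in enumerate(ed.itertuples(index=False), start=2):
        if row.link_type not in LINK_TYPES:
            raise ValueError(
                f"{edges_path} line {row_number}: unknown link_type "
                f"{row.link_type!r}"
            )
        links.append(Link(row.resource, row.consumer, row.link_type))

    nutrients = {s.nutrient_id for s in species if s.nutrient_id}
    basal = [s for s in species if s.nutrient_id]
    if len(nutrients) <= 1:
        mode = "shared"
    elif len(nutrients) == len(basal):
        mode = "individual"
    else:
        mode = "grouped"
    return FoodWeb(
        tuple(species),
        tuple(links),
        nutrient_mode=mode,
        allow_cannibalism=allow_cannibalism,
        allow_components=allow_components,
    )


def write_web(web: FoodWeb, species_path: str | Path, edges_path: str | Path) -> None:
    """Write a web to species and edge TSV tables (round-trips with read)."""
    sp = pd.DataFrame(
        {
            "id": [s.id for s in web.species],
            "kind": [s.kind for s in web.species],
            "nutrient_id": [s.nutrient_id or "" for s in web.species],
        }
    )
    sp.to_csv(species_path, sep="\t", index=False)
    ed = pd.DataFrame(
        {
            "resource": [l.resource for l in web.links],
            "consumer": [l.consumer for l in web.links],
            "link_type": [l.link_type for l in web.links],
        }
    )
    ed.to_csv(edges_path, sep="\t", index=False)


def write_pattern_mtx(
    pattern: InteractionPattern,
    mtx_path: str | Path,
    sidecar_path: str | Path,
) -> None:
    """Export a pattern in Matrix Market coordinate form plus an index map.

    Entries carry their sign (+1/−1, competition entries +1); the sidecar
    JSON maps matrix indices to species ids and lists the tied competition
    positions per nutrient pool.
    """
    rows, cols, data = [], [], []
    for (i, j), tag in sorted(pattern.entries.items()):
        rows.append(i)
        cols.append(j)
        data.append(1.0 if tag in (GAIN, UNIT) else -1.0)
    m = coo_matrix((data, (rows, cols)), shape=(pattern.S, pattern.S))
    mmwrite(str(mtx_path), m)
    sidecar = {
        "index": list(pattern.index),
        "nutrient_groups": {
            n: list(members) for n, members in pattern.nutrient_groups.items()
        },
    }
    Path(sidecar_path).write_text(json.dumps(sidecar, indent=2))


def _pair_keys(table: Mapping) -> dict:
    """Convert 'resource->consumer' string keys to tuple keys."""
    out = {}
    for key, value in table.items():
        if isinstance(key, str) and "->" in key:
            resource, consumer = key.split("->", 1)
            out[(resource.strip(), consumer.strip())] = float(value)
        else:
            out[key] = float(value)
    return out


def params_from_dict(config: Mapping) -> GLVParams:
    kwargs = {}
    for name in ("k", "alpha"):
        if name in config:
            value = config[name]
            kwargs[name] = (
                {k: float(v) for k, v in value.items()}
                if isinstance(value, Mapping)
                else float(value)
            )
    for name in ("eta", "beta"):
        if name in config:
            value = config[name]
            kwargs[name] = (
                _pair_keys(value) if isinstance(value, Mapping) else float(value)
            )
    if "p" in config and config["p"] is not None:
        kwargs["p"] = _pair_keys(config["p"])
    return GLVParams(**kwargs)


def load_params(path: str | Path) -> GLVParams:
    """Load GLV parameters from a YAML or JSON config file."""
    text = Path(path).read_text()
    config = yaml.safe_load(text)
    if not isinstance(config, Mapping):
        raise ValueError(f"{path}: expected a mapping of parameter names")
    return params_from_dict(config)


def write_trajectory_csv(result, path: str | Path) -> None:
    """Time column plus one density column per species id."""
    frame = pd.DataFrame(result.densities, columns=list(result.ids))
    frame.insert(0, "time", result.times)
    frame.to_csv(path, index=False)
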