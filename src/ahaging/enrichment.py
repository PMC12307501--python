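"""Hypergeometric over-representation analysis against GMT gene-set files.

Generic replacement for database-specific enrichment: the user supplies any
gene-set collection in GMT format (set name, description, tab-separated
members) and a query protein set is tested per gene set with the upper-tail
hypergeometric probability, BH-adjusted across tested sets. The universe
defaults to all quantified proteins, matching the sampling frame of a
proteomics experiment rather than the whole genome.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd

from ._stats import bh_adjust, hypergeom_upper_tail
from .errors import ParseError, ValidationError

__all__ = ["GeneSetCollection", "read_gmt", "write_gmt", "enrich"]


@dataclass
class GeneSetCollection:
    """Named gene sets with free-text provenance."""

    sets: dict[str, tuple[str, ...]]
    source: str = ""
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        for name, members in self.sets.items():
            if not members:
                raise ValidationError(f"gene set {name!r} has no members")

    def __len__(self) -> int:
        return len(self.sets)


def read_gmt(path) -> GeneSetCollection:
    """Parse a GMT file: one set per line, name TAB description TAB members."""
    sets: dict[str, tuple[str, ...]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}: line {lineno} has fewer than 3 fields")
            name, description, *members = fields
            members = [m for m in members if m]
            if name in sets:
                raise ValidationError(f"{path}: gene set {name!r} listed twice")
            unique = list(dict.fromkeys(members))
            if len(unique) < len(members):
                warnings.warn(f"gene set {name!r}: duplicate members deduplicated",
                              stacklevel=2)
            sets[name] = tuple(unique)
            descriptions[name] = description
    return GeneSetCollection(sets=sets, source=str(path), descriptions=descriptions)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for name, members in collection.sets.items():
            description = collection.descriptions.get(name, "")
            fh.write("\t".join([name, description, *members]) + "\n")


def enrich(
    query: Iterable[str],
    collection: GeneSetCollection,
    universe: Iterable[str],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Upper-tail hypergeometric over-representation of ``query`` per gene set.

    Set members are intersected with the universe before testing; sets with
    zero universe overlap are skipped (reported with NaN p). BH adjustment
    spans the tested sets.
    """
    query_set = set(query)
    uni = set(universe)
    offenders = sorted(query_set - uni)
    if offenders:
        raise ValidationError(f"query proteins outside universe: {offenders[:5]}")
    rows = []
    for name, members in collection.sets.items():
        in_universe = set(members) & uni
        overlap = query_set & in_universe
        rows.append({
            "set": name,
            "set_size": len(in_universe),
            "overlap": len(overlap),
            "members_in_overlap": ",".join(sorted(overlap)),
            "p": (hypergeom_upper_tail(len(overlap), len(in_universe),
                                       len(query_set), len(uni))
                  if in_universe else float("nan")),
        })
    out = pd.DataFrame(rows).set_index("set")
    tested = out["p"].notna()
    out["padj"] = float("nan")
    if tested.any():
        out.loc[tested, "padj"] = bh_adjust(out.loc[tested, "p"].to_numpy())
    out["enriched"] = out["padj"] < alpha
    return out
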