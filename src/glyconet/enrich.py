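"""Over-representation analysis (ORA) of marker lists against set collections.

For a query of ``n`` ids drawn from a universe of ``N``, a set of ``K``
members overlapping the query in ``k`` ids is scored with the upper-tail
hypergeometric probability P(X >= k). Multiple testing is handled with
Benjamini-Hochberg across the collection; results are filtered at a per-run
p cutoff (0.05 for gene queries, 0.01 for metabolite queries by default).

Collections are read from GMT files (set_id TAB description TAB members...).
The universe defaults to the union of all set members; callers analysing
expression-derived queries should pass the measured-gene universe instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .diffexpr import bh_fdr

__all__ = [
    "GeneSetCollection",
    "load_gmt",
    "write_gmt",
    "ora",
    "metabolite_ora",
]


@dataclass
class GeneSetCollection:
    """Named id sets over a universe.

    ``sets`` maps set_id -> (name, frozenset of member ids). Every set is
    non-empty and contained in the universe.
    """

    sets: dict[str, tuple[str, frozenset[str]]]
    universe: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if not self.universe:
            self.universe = frozenset().union(*(m for _, m in self.sets.values())) if self.sets else frozenset()
        for sid, (_, members) in self.sets.items():
            if not members:
                raise ValueError(f"set {sid!r} is empty")
            extra = members - self.universe
            if extra:
                raise ValueError(f"set {sid!r} has members outside the universe: {sorted(extra)[:5]}")

    def __len__(self) -> int:
        return len(self.sets)


def load_gmt(path: str | Path, universe: Iterable[str] | None = None) -> GeneSetCollection:
    """Read a GMT file. Duplicate members within a line are dropped with a note.

    Raises on lines with fewer than 3 fields (naming the line number) and on
    duplicate set ids.
    """
    sets: dict[str, tuple[str, frozenset[str]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"line {lineno}: GMT line needs >= 3 tab-separated fields")
            sid, name, *members = fields
            members = [m for m in members if m.strip()]
            if not members:
                raise ValueError(f"line {lineno}: set {sid!r} has no members")
            if sid in sets:
                raise ValueError(f"line {lineno}: duplicate set id {sid!r}")
            uniq = frozenset(members)
            if len(uniq) < len(members):
                import logging

                logging.getLogger(__name__).warning(
                    "set %s: %d duplicate member(s) dropped", sid, len(members) - len(uniq)
                )
            sets[sid] = (name, uniq)
    uni = frozenset(universe) if universe is not None else frozenset()
    return GeneSetCollection(sets, uni)


def write_gmt(coll: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for sid in sorted(coll.sets):
            name, members = coll.sets[sid]
            fh.write("\t".join([sid, name, *sorted(members)]) + "\n")


def ora(
    query: Sequence[str],
    coll: GeneSetCollection,
    p_cutoff: float = 0.05,
) -> pd.DataFrame:
    """Hypergeometric over-representation test of ``query`` against every set.

    Returns rows (set_id, name, set_size, overlap, overlap_ids, p, q) for
    sets with p <= p_cutoff, sorted by p then set_id. q is BH across the
    whole collection (computed before the cutoff filter).
    """
    universe = coll.universe
    q_in = frozenset(query) & universe
    if not q_in:
        raise ValueError("no mappable query ids (query disjoint from universe)")
    N, n = len(universe), len(q_in)
    rows = []
    for sid in sorted(coll.sets):
        name, members = coll.sets[sid]
        K = len(members)
        overlap = members & q_in
        k = len(overlap)
        # P(X >= k) with X ~ Hypergeom(N, K, n)
        p = float(hypergeom.sf(k - 1, N, K, n)) if k > 0 else 1.0
        p = min(max(p, np.nextafter(0, 1)), 1.0)
        rows.append(
            {
                "set_id": sid,
                "name": name,
                "set_size": K,
                "overlap": k,
                "overlap_ids": ";".join(sorted(overlap)),
                "p": p,
            }
        )
    df = pd.DataFrame(rows, columns=["set_id", "name", "set_size", "overlap", "overlap_ids", "p"])
    df["q"] = bh_fdr(df["p"]) if len(df) else []
    df = df[df["p"] <= p_cutoff].sort_values(["p", "set_id"], kind="mergesort")
    return df.reset_index(drop=True)


def metabolite_ora(
    kegg_ids: Sequence[str],
    coll: GeneSetCollection,
    p_cutoff: float = 0.01,
) -> pd.DataFrame:
    """ORA over metabolite-set collections; same kernel, default cutoff 0.01."""
    return ora(kegg_ids, coll, p_cutoff=p_cutoff)
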