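"""Glycogene registry and reaction-code -> glycan-epitope inference.

The registry mirrors a curated glycobiology knowledge base: glycogene
records (lectins, enzymes, transporters, other glyco-pathway proteins, and
proteoglycans), enzymatic glycosylation reactions identified by reaction
codes and grouped into substrate-product reaction patterns, and glycan
epitopes (e.g. sialyl-Lewis^x) each encoded by the set of reaction codes
required for its synthesis.

Epitope inference automates the manual lookup: the reaction codes reachable
from a query enzyme list are collected and each epitope is scored by the
fraction of its required codes covered; full coverage (the default
criterion) predicts the epitope as a possible structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "CATEGORIES",
    "GlycogeneRecord",
    "GlycoReaction",
    "GlycanEpitope",
    "GlycoRegistry",
    "load_registry",
    "write_registry",
    "registry_stats",
    "reactions_for_enzymes",
    "infer_epitopes",
    "glyco_subset",
]

CATEGORIES = frozenset({"lectin", "enzyme", "transporter", "other", "proteoglycan"})


@dataclass(frozen=True)
class GlycogeneRecord:
    symbol: str
    category: str

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r} for {self.symbol}")


@dataclass(frozen=True)
class GlycoReaction:
    reaction_code: str
    enzyme_symbols: frozenset[str]
    substrate: str
    product: str
    pattern_id: str

    def __post_init__(self) -> None:
        if not self.enzyme_symbols:
            raise ValueError(f"reaction {self.reaction_code}: empty enzyme set")


@dataclass(frozen=True)
class GlycanEpitope:
    epitope_id: str
    name: str
    required_codes: frozenset[str]

    def __post_init__(self) -> None:
        if not self.required_codes:
            raise ValueError(f"epitope {self.epitope_id}: empty required-code set")


@dataclass
class GlycoRegistry:
    """Validated container for records, reactions and epitopes.

    Referential integrity is enforced at construction: reaction enzymes must
    be registry records and epitope required codes must be known reactions.
    """

    records: dict[str, GlycogeneRecord] = field(default_factory=dict)
    reactions: dict[str, GlycoReaction] = field(default_factory=dict)
    epitopes: dict[str, GlycanEpitope] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for code, rxn in self.reactions.items():
            unknown = rxn.enzyme_symbols - self.records.keys()
            if unknown:
                raise ValueError(
                    f"reaction {code}: unknown enzyme(s) {sorted(unknown)}"
                )
        for eid, epi in self.epitopes.items():
            unknown = epi.required_codes - self.reactions.keys()
            if unknown:
                raise ValueError(
                    f"epitope {eid}: unknown reaction code(s) {sorted(unknown)}"
                )

    @property
    def pattern_ids(self) -> set[str]:
        return {r.pattern_id for r in self.reactions.values()}


# ---------------------------------------------------------------------------
# Loading / writing (TSV dialects documented in the README)
# ---------------------------------------------------------------------------

def load_registry(
    genes_path: str | Path, reactions_path: str | Path, epitopes_path: str | Path
) -> GlycoRegistry:
    """Load and validate a registry from its three TSV tables.

    genes: (symbol, category); reactions: (code, enzymes ';'-joined,
    substrate, product, pattern); epitopes: (id, name, required codes
    ';'-joined). All referential-integrity violations and duplicate ids are
    errors naming the offending row.
    """
    genes = pd.read_csv(
        genes_path, sep="\t", header=None, names=["symbol", "category"], dtype=str
    )
    records: dict[str, GlycogeneRecord] = {}
    for i, r in genes.iterrows():
        if r["symbol"] in records:
            raise ValueError(f"genes row {i + 1}: duplicate gene {r['symbol']!r}")
        records[r["symbol"]] = GlycogeneRecord(r["symbol"], r["category"])

    rxns = pd.read_csv(
        reactions_path, sep="\t", header=None,
        names=["code", "enzymes", "substrate", "product", "pattern"], dtype=str,
    )
    reactions: dict[str, GlycoReaction] = {}
    for i, r in rxns.iterrows():
        if r["code"] in reactions:
            raise ValueError(f"reactions row {i + 1}: duplicate code {r['code']!r}")
        reactions[r["code"]] = GlycoReaction(
            r["code"],
            frozenset(e.strip() for e in r["enzymes"].split(";") if e.strip()),
            r["substrate"], r["product"], r["pattern"],
        )

    epis = pd.read_csv(
        epitopes_path, sep="\t", header=None, names=["id", "name", "codes"], dtype=str
    )
    epitopes: dict[str, GlycanEpitope] = {}
    for i, r in epis.iterrows():
        if r["id"] in epitopes:
            raise ValueError(f"epitopes row {i + 1}: duplicate epitope {r['id']!r}")
        epitopes[r["id"]] = GlycanEpitope(
            r["id"], r["name"],
            frozenset(c.strip() for c in r["codes"].split(";") if c.strip()),
        )
    return GlycoRegistry(records, reactions, epitopes)


def write_registry(reg: GlycoRegistry, out_dir: str | Path) -> dict[str, Path]:
    """Write the three TSV tables into ``out_dir``; inverse of load_registry."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "genes": out / "glyco_genes.tsv",
        "reactions": out / "glyco_reactions.tsv",
        "epitopes": out / "glyco_epitopes.tsv",
    }
    with open(paths["genes"], "w") as fh:
        for sym in sorted(reg.records):
            fh.write(f"{sym}\t{reg.records[sym].category}\n")
    with open(paths["reactions"], "w") as fh:
        for code in sorted(reg.reactions):
            r = reg.reactions[code]
            fh.write(
                f"{code}\t{';'.join(sorted(r.enzyme_symbols))}\t{r.substrate}\t{r.product}\t{r.pattern_id}\n"
            )
    with open(paths["epitopes"], "w") as fh:
        for eid in sorted(reg.epitopes):
            e = reg.epitopes[eid]
            fh.write(f"{eid}\t{e.name}\t{';'.join(sorted(e.required_codes))}\n")
    return paths


# ---------------------------------------------------------------------------
# Queries
# ---------------------------------------------------------------------------

def registry_stats(reg: GlycoRegistry) -> dict[str, int]:
    """Counts: glyco proteins (excl. proteoglycans), proteoglycans, reactions,
    reaction patterns, epitopes."""
    syms = set(reg.records)
    pg = {s for s in syms if reg.records[s].category == "proteoglycan"}
    return {
        "glyco_proteins": len(syms - pg),
        "proteoglycans": len(pg),
        "reactions": len(reg.reactions),
        "patterns": len(reg.pattern_ids),
        "epitopes": len(reg.epitopes),
    }


def reactions_for_enzymes(
    reg: GlycoRegistry, enzymes: Iterable[str]
) -> tuple[set[str], list[str]]:
    """Union of reaction codes catalysed by any of the query enzymes.

    Returns ``(codes, unknown_symbols)``; unknown symbols are reported, not
    fatal, and an empty result is allowed.
    """
    query = {e.strip() for e in enzymes if e.strip()}
    unknown = sorted(query - reg.records.keys())
    codes = {
        code
        for code, rxn in reg.reactions.items()
        if rxn.enzyme_symbols & query
    }
    return codes, unknown


def infer_epitopes(
    reg: GlycoRegistry, enzymes: Sequence[str], min_coverage: float = 1.0
) -> pd.DataFrame:
    """Score every epitope by required-reaction-code coverage from the enzymes.

    coverage = |required codes covered| / |required codes|; epitopes with
    coverage >= min_coverage are returned, sorted by coverage descending then
    epitope name then id. ``min_coverage=1`` demands every required reaction,
    i.e. the epitope is fully synthesisable with the query enzymes.
    """
    if not 0.0 <= min_coverage <= 1.0:
        raise ValueError("min_coverage must lie in [0, 1]")
    available, _ = reactions_for_enzymes(reg, enzymes)
    rows = []
    for eid in sorted(reg.epitopes):
        epi = reg.epitopes[eid]
        covered = epi.required_codes & available
        coverage = len(covered) / len(epi.required_codes)
        if coverage >= min_coverage and (coverage > 0 or min_coverage == 0):
            rows.append(
                {
                    "epitope_id": eid,
                    "name": epi.name,
                    "n_required": len(epi.required_codes),
                    "covered_codes": ";".join(sorted(covered)),
                    "coverage": coverage,
                    "fully_covered": coverage == 1.0,
                }
            )
    df = pd.DataFrame(
        rows,
        columns=["epitope_id", "name", "n_required", "covered_codes", "coverage", "fully_covered"],
    )
    if len(df):
        df = df.sort_values(
            ["coverage", "name", "epitope_id"], ascending=[False, True, True], kind="mergesort"
        ).reset_index(drop=True)
    return df


def glyco_subset(reg: GlycoRegistry, degs: pd.DataFrame) -> pd.DataFrame:
    """Selected DEGs that are registry glycogenes (proteoglycans included),
    with their direction."""
    sel = degs.loc[degs["selected"]]
    mask = [str(g) in reg.records for g in sel.index]
    out = sel.loc[mask, ["direction"]].copy()
    out.index.name = "gene"
    return out.sort_index()
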