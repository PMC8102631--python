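"""Nomenclature harmonization and gene-family dimensionality reduction.

Marker lists arriving from heterogeneous sources are first resolved to
approved gene symbols (alias table lookup; case-insensitive after whitespace
stripping), metabolite names to their KEGG/PubChem/HMDB identifiers, and the
resulting gene lists are collapsed onto gene families. Families are ranked by
member count (Excel RANK "min" semantics for ties) and those with at least
``cutoff`` members (default 5) are selected; the union of their members forms
the reduced marker list carried into enrichment and network analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "IdMap",
    "GeneFamilyTable",
    "normalize_symbols",
    "map_metabolite_ids",
    "assign_gene_families",
    "rank_families",
    "select_top_family_genes",
    "read_alias_tsv",
    "read_family_tsv",
    "read_crosswalk_tsv",
]


def _norm(token: str) -> str:
    return token.strip().upper()


@dataclass
class IdMap:
    """Alias -> approved-symbol map plus a metabolite-name -> id crosswalk.

    Approved symbols always map to themselves; lookups are case-insensitive
    after whitespace stripping.
    """

    alias_to_symbol: dict[str, str] = field(default_factory=dict)
    metabolite_ids: dict[str, dict[str, str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        normalized: dict[str, str] = {}
        for alias, symbol in self.alias_to_symbol.items():
            key = _norm(alias)
            if key in normalized and normalized[key] != symbol:
                raise ValueError(f"alias {alias!r} maps to two approved symbols")
            normalized[key] = symbol
        for symbol in list(normalized.values()):
            normalized.setdefault(_norm(symbol), symbol)
        self.alias_to_symbol = normalized
        self.metabolite_ids = {_norm(k): dict(v) for k, v in self.metabolite_ids.items()}

    def resolve(self, symbol: str) -> str | None:
        return self.alias_to_symbol.get(_norm(symbol))


@dataclass
class GeneFamilyTable:
    """Gene symbol -> set of family identifiers (multi-membership allowed)."""

    families: dict[str, set[str]]

    def __post_init__(self) -> None:
        cleaned: dict[str, set[str]] = {}
        for gene, fams in self.families.items():
            fams = {f.strip() for f in fams if f and f.strip()}
            if any(not f for f in fams):
                raise ValueError(f"empty family id for gene {gene!r}")
            cleaned[_norm(gene)] = fams
        self.families = cleaned

    def of(self, gene: str) -> set[str]:
        return self.families.get(_norm(gene), set())


def normalize_symbols(
    symbols: Sequence[str], idmap: IdMap
) -> tuple[list[str], list[str], dict[str, list[str]]]:
    """Resolve each input to its approved symbol.

    Returns ``(mapped, unmapped, duplicates)`` where ``mapped`` preserves the
    input order with post-mapping duplicates collapsed to their first
    occurrence, ``unmapped`` lists inputs absent from the map, and
    ``duplicates`` reports approved symbols that absorbed more than one input.
    """
    mapped: list[str] = []
    unmapped: list[str] = []
    sources: dict[str, list[str]] = {}
    for s in symbols:
        approved = idmap.resolve(s)
        if approved is None:
            unmapped.append(s)
            continue
        sources.setdefault(approved, []).append(s)
        if len(sources[approved]) == 1:
            mapped.append(approved)
    duplicates = {sym: srcs for sym, srcs in sources.items() if len(srcs) > 1}
    return mapped, unmapped, duplicates


def map_metabolite_ids(
    names: Sequence[str], idmap: IdMap
) -> tuple[pd.DataFrame, list[str]]:
    """Look up KEGG/PubChem/HMDB identifiers for metabolite names.

    Returns a table (name, kegg, pubchem, hmdb; missing ids empty) for names
    with at least one identifier, and the list of unmapped names.
    """
    rows, unmapped = [], []
    for name in names:
        rec = idmap.metabolite_ids.get(_norm(name))
        if rec is None or not any(rec.get(k) for k in ("kegg", "pubchem", "hmdb")):
            unmapped.append(name)
            continue
        rows.append(
            {
                "name": name,
                "kegg": rec.get("kegg", "") or "",
                "pubchem": rec.get("pubchem", "") or "",
                "hmdb": rec.get("hmdb", "") or "",
            }
        )
    cols = ["name", "kegg", "pubchem", "hmdb"]
    return pd.DataFrame(rows, columns=cols), unmapped


def assign_gene_families(
    genes: Sequence[str], fam: GeneFamilyTable
) -> tuple[dict[str, list[str]], list[str]]:
    """Group genes by family; a gene in several families is counted in each.

    Returns ``(family -> member list, genes with no family)``. Member lists
    preserve input order.
    """
    members: dict[str, list[str]] = {}
    orphans: list[str] = []
    for g in genes:
        fams = fam.of(g)
        if not fams:
            orphans.append(g)
            continue
        for f in sorted(fams):
            members.setdefault(f, []).append(g)
    return members, orphans


def rank_families(members: Mapping[str, Sequence[str]], cutoff: int = 5) -> pd.DataFrame:
    """Rank families by descending member count; select those with count >= cutoff.

    Ties share the minimum rank (Excel RANK semantics): rank = 1 + number of
    families with a strictly greater count.
    """
    if cutoff < 1:
        raise ValueError("cutoff must be >= 1")
    counts = {f: len(ms) for f, ms in members.items()}
    rows = []
    for f in sorted(counts, key=lambda f: (-counts[f], f)):
        c = counts[f]
        rank = 1 + sum(1 for other in counts.values() if other > c)
        rows.append({"family": f, "member_count": c, "rank": rank, "selected": c >= cutoff})
    return pd.DataFrame(rows, columns=["family", "member_count", "rank", "selected"])


def select_top_family_genes(
    degs: pd.DataFrame,
    ranking: pd.DataFrame,
    members: Mapping[str, Sequence[str]],
    extra_genes: Iterable[str] = (),
) -> dict[str, object]:
    """Union of members of selected families, split by DEG direction.

    ``extra_genes`` (typically the glycogene subset of the DEGs) are always
    appended to the selection regardless of family rank. Returns a dict with
    ``up``, ``down`` gene lists and the ``coverage`` fraction
    |selected genes| / |selected DEGs|.
    """
    direction = degs.loc[degs["selected"], "direction"]
    dir_of = {str(g): d for g, d in direction.items()}
    chosen: list[str] = []
    seen: set[str] = set()
    selected_fams = ranking.loc[ranking["selected"], "family"]
    for f in selected_fams:
        for g in members.get(f, []):
            if g not in seen:
                seen.add(g)
                chosen.append(g)
    for g in extra_genes:
        if g in dir_of and g not in seen:
            seen.add(g)
            chosen.append(g)
    up = [g for g in chosen if dir_of.get(g) == "up"]
    down = [g for g in chosen if dir_of.get(g) == "down"]
    n_degs = len(dir_of)
    coverage = (len(up) + len(down)) / n_degs if n_degs else 0.0
    return {"up": up, "down": down, "coverage": coverage}


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_alias_tsv(path: str | Path) -> IdMap:
    """Alias map TSV: columns (alias, approved), no header."""
    df = pd.read_csv(path, sep="\t", header=None, names=["alias", "approved"], dtype=str)
    return IdMap(alias_to_symbol=dict(zip(df["alias"], df["approved"])))


def read_crosswalk_tsv(path: str | Path, idmap: IdMap | None = None) -> IdMap:
    """Metabolite crosswalk TSV: columns (name, kegg, pubchem, hmdb), no header."""
    df = pd.read_csv(
        path, sep="\t", header=None, names=["name", "kegg", "pubchem", "hmdb"],
        dtype=str, keep_default_na=False,
    )
    xwalk = {
        r["name"]: {"kegg": r["kegg"], "pubchem": r["pubchem"], "hmdb": r["hmdb"]}
        for _, r in df.iterrows()
    }
    base = idmap.alias_to_symbol if idmap else {}
    return IdMap(alias_to_symbol=dict(base), metabolite_ids=xwalk)


def read_family_tsv(path: str | Path) -> GeneFamilyTable:
    """Family table TSV: columns (gene, family), no header; one row per pair."""
    df = pd.read_csv(path, sep="\t", header=None, names=["gene", "family"], dtype=str)
    fams: dict[str, set[str]] = {}
    for _, r in df.iterrows():
        fams.setdefault(r["gene"], set()).add(r["family"])
    return GeneFamilyTable(fams)
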