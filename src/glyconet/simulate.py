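"""Seeded synthetic-data generators with planted, recoverable structure.

Every pipeline input has a generator here: negative-binomial count matrices
with planted differentially expressed genes, gene-set collections with one
planted enriched set, preferential-attachment interaction networks with a
planted connector node, and toy glyco registries with planted recoverable
epitopes (plus one-extra-code decoys). Each generator returns the data
together with a :class:`SyntheticTruth` recording what was planted, so every
downstream stage can be tested for recovery without any external download.

Defaults emulate a small bulk RNA-seq two-group comparison: gene-wise
baseline means drawn log-normally (meanlog 4, sdlog 1.5 on the natural log
scale), constant NB dispersion 0.1, five replicates per class, 10% of genes
differentially expressed at 4-fold.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .diffexpr import ExpressionMatrix, SampleDesign
from .enrich import GeneSetCollection
from .glyco import (
    GlycanEpitope,
    GlycoReaction,
    GlycogeneRecord,
    GlycoRegistry,
    write_registry,
)

__all__ = [
    "SyntheticTruth",
    "simulate_counts",
    "simulate_genesets",
    "simulate_network",
    "simulate_glyco_registry",
    "simulate_bundle",
]


@dataclass
class SyntheticTruth:
    """What was planted, and with which generator parameters."""

    seed: int
    params: dict = field(default_factory=dict)
    planted_de_genes: dict[str, float] = field(default_factory=dict)
    planted_enriched_set_id: str | None = None
    planted_connector_ids: list[str] = field(default_factory=list)
    planted_epitope_ids: list[str] = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticTruth":
        with open(path) as fh:
            return cls(**json.load(fh))


def simulate_counts(
    n_genes: int = 2000,
    n_per_class: int = 5,
    de_fraction: float = 0.10,
    lfc: float = 2.0,
    dispersion: float = 0.1,
    seed: int = 0,
    mean_log: float = 4.0,
    sd_log: float = 1.5,
) -> tuple[ExpressionMatrix, SampleDesign, SyntheticTruth]:
    """Negative-binomial counts for a two-class design with planted DE genes.

    Baseline means are log-normal; a ``de_fraction`` of genes is shifted by
    ``lfc`` (log2 units, alternating sign) in the case class. The NB is
    parameterised by mean mu and dispersion phi with variance mu + phi*mu^2.
    """
    if n_genes < 1 or n_per_class < 1:
        raise ValueError("n_genes and n_per_class must be positive")
    if not 0.0 <= de_fraction <= 1.0:
        raise ValueError("de_fraction must lie in [0, 1]")
    if dispersion <= 0 or lfc <= 0:
        raise ValueError("dispersion and lfc must be positive")
    rng = np.random.default_rng(seed)
    genes = [f"g{i:05d}" for i in range(1, n_genes + 1)]
    base = rng.lognormal(mean_log, sd_log, size=n_genes)
    n_de = int(round(de_fraction * n_genes))
    de_idx = rng.choice(n_genes, size=n_de, replace=False)
    effects = np.zeros(n_genes)
    # alternate up/down so both directions are represented
    signs = np.where(np.arange(n_de) % 2 == 0, 1.0, -1.0)
    effects[de_idx] = signs * lfc

    mu_ctrl = np.tile(base[:, None], (1, n_per_class))
    mu_case = np.tile((base * 2.0**effects)[:, None], (1, n_per_class))
    mu = np.concatenate([mu_case, mu_ctrl], axis=1)
    # NB(mean mu, dispersion phi): r = 1/phi, p = r/(r+mu)
    r = 1.0 / dispersion
    counts = rng.negative_binomial(r, r / (r + mu))
    samples = [f"case_{i+1}" for i in range(n_per_class)] + [
        f"ctrl_{i+1}" for i in range(n_per_class)
    ]
    m = ExpressionMatrix(pd.DataFrame(counts, index=genes, columns=samples), scale="counts")
    design = SampleDesign(
        {s: ("case" if s.startswith("case") else "control") for s in samples},
        reference="control",
    )
    truth = SyntheticTruth(
        seed=seed,
        params={
            "n_genes": n_genes, "n_per_class": n_per_class, "de_fraction": de_fraction,
            "lfc": lfc, "dispersion": dispersion, "mean_log": mean_log, "sd_log": sd_log,
        },
        planted_de_genes={genes[i]: float(effects[i]) for i in sorted(de_idx)},
    )
    return m, design, truth


def simulate_genesets(
    n_sets: int = 50,
    set_size: int = 20,
    universe_size: int = 1000,
    query_size: int = 30,
    planted_overlap: int = 15,
    seed: int = 0,
) -> tuple[GeneSetCollection, list[str], SyntheticTruth]:
    """Random gene sets plus one planted set heavily overlapping a query.

    Returns ``(collection, query, truth)``. The planted set shares
    ``planted_overlap`` members with the query; the remaining query ids are
    drawn from outside the planted set so decoy overlaps stay at chance
    level.
    """
    if planted_overlap > min(set_size, query_size):
        raise ValueError("planted_overlap cannot exceed set or query size")
    rng = np.random.default_rng(seed)
    universe = [f"u{i:05d}" for i in range(1, universe_size + 1)]
    sets: dict[str, tuple[str, frozenset[str]]] = {}
    for j in range(1, n_sets + 1):
        members = rng.choice(universe_size, size=set_size, replace=False)
        sid = f"S{j:03d}"
        sets[sid] = (f"random set {j}", frozenset(universe[i] for i in members))
    planted_id = "S_planted"
    planted_members = rng.choice(universe_size, size=set_size, replace=False)
    planted = frozenset(universe[i] for i in planted_members)
    sets[planted_id] = ("planted enriched set", planted)
    in_set = rng.choice(sorted(planted), size=planted_overlap, replace=False).tolist()
    outside = sorted(set(universe) - planted)
    out_set = rng.choice(outside, size=query_size - planted_overlap, replace=False).tolist()
    query = sorted(in_set + out_set)
    coll = GeneSetCollection(sets, frozenset(universe))
    truth = SyntheticTruth(
        seed=seed,
        params={
            "n_sets": n_sets, "set_size": set_size, "universe_size": universe_size,
            "query_size": query_size, "planted_overlap": planted_overlap,
        },
        planted_enriched_set_id=planted_id,
    )
    return coll, query, truth


def simulate_network(
    n_nodes: int = 200,
    attachment: int = 3,
    seeds_k: int = 10,
    connector_fraction: float = 0.8,
    edge_type_probs: dict[str, float] | None = None,
    seed: int = 0,
) -> tuple[nx.Graph, list[str], SyntheticTruth]:
    """Preferential-attachment network with a planted connector node.

    A Barabasi-Albert graph on ``n_nodes - 1`` nodes is grown, ``seeds_k``
    seed nodes are drawn at random, and one extra node (the planted
    connector) is wired to ``round(connector_fraction * seeds_k)`` of them.
    Edge types are sampled at the stated proportions (default 70%
    protein-protein, 20% gene-regulatory, 10% biochemical).
    """
    if seeds_k < 1 or n_nodes < seeds_k + attachment + 2:
        raise ValueError("network too small for the requested seeds")
    probs = edge_type_probs or {
        "protein-protein": 0.7, "gene-regulatory": 0.2, "biochemical": 0.1,
    }
    if abs(sum(probs.values()) - 1.0) > 1e-9:
        raise ValueError("edge type proportions must sum to 1")
    rng = np.random.default_rng(seed)
    base = nx.barabasi_albert_graph(n_nodes - 1, attachment, seed=int(rng.integers(2**31)))
    mapping = {i: f"n{i:04d}" for i in base.nodes}
    g = nx.relabel_nodes(base, mapping)
    seed_nodes = sorted(
        mapping[i] for i in rng.choice(n_nodes - 1, size=seeds_k, replace=False)
    )
    connector = "connector"
    wired = sorted(
        rng.choice(seed_nodes, size=int(round(connector_fraction * seeds_k)), replace=False)
    )
    g.add_node(connector)
    g.add_edges_from((connector, s) for s in wired)
    types = list(probs)
    draw = rng.choice(len(types), size=g.number_of_edges(), p=[probs[t] for t in types])
    for (u, v), ti in zip(sorted(g.edges), draw):
        g.edges[u, v]["edge_type"] = types[ti]
    truth = SyntheticTruth(
        seed=seed,
        params={
            "n_nodes": n_nodes, "attachment": attachment, "seeds_k": seeds_k,
            "connector_fraction": connector_fraction, "edge_type_probs": probs,
        },
        planted_connector_ids=[connector],
    )
    return g, seed_nodes, truth


def simulate_glyco_registry(
    n_genes: int = 30,
    n_reactions: int = 40,
    n_epitopes: int = 12,
    n_patterns: int | None = None,
    planted_enzymes: Sequence[str] | None = None,
    n_planted_epitopes: int = 3,
    n_decoys: int = 3,
    proteoglycan_fraction: float = 0.1,
    symbols: Sequence[str] | None = None,
    seed: int = 0,
) -> tuple[GlycoRegistry, SyntheticTruth]:
    """Toy registry in which planted epitopes are exactly recoverable.

    The planted enzymes (default the first three generated enzyme symbols)
    catalyse a dedicated block of reactions; planted epitopes require exactly
    that code set, decoy epitopes require it plus one code catalysed only by
    non-planted enzymes, so at full coverage the planted epitopes are always
    predicted and the decoys never are. ``n_genes`` counts all records,
    proteoglycans included; ``n_patterns`` defaults to n_reactions // 6
    (min 2) and every pattern id is instantiated by at least one reaction.
    """
    if n_genes < 6 or n_reactions < 6:
        raise ValueError("registry too small")
    n_patterns = n_patterns or max(2, n_reactions // 6)
    if n_patterns > n_reactions:
        raise ValueError("n_patterns cannot exceed n_reactions")
    rng = np.random.default_rng(seed)
    symbols = list(symbols) if symbols is not None else [
        f"GT{i:03d}" for i in range(1, n_genes + 1)
    ]
    if len(symbols) != n_genes:
        raise ValueError("symbols list must have length n_genes")
    n_pg = int(round(proteoglycan_fraction * n_genes))
    n_enz = max(4, (n_genes - n_pg) // 2)
    records: dict[str, GlycogeneRecord] = {}
    for i, sym in enumerate(symbols):
        if i < n_enz:
            cat = "enzyme"
        elif i < n_enz + n_pg:
            cat = "proteoglycan"
        else:
            cat = ["lectin", "transporter", "other"][(i - n_enz - n_pg) % 3]
        records[sym] = GlycogeneRecord(sym, cat)
    enzyme_syms = [s for s, r in records.items() if r.category == "enzyme"]
    planted = list(planted_enzymes) if planted_enzymes else enzyme_syms[:3]
    if not set(planted) <= set(records):
        raise ValueError("planted enzymes must be registry genes")
    others = [s for s in enzyme_syms if s not in planted]
    if not others:
        raise ValueError("at least one non-planted enzyme is required")

    n_planted_rxn = max(2, n_reactions // 8)
    reactions: dict[str, GlycoReaction] = {}
    sugars = ["Gal", "GlcNAc", "Fuc", "Neu5Ac", "GalNAc", "Man", "Xyl", "GlcA"]
    for i in range(1, n_reactions + 1):
        code = f"r{i:03d}"
        if i <= n_planted_rxn:
            enz = frozenset([planted[(i - 1) % len(planted)]])
        else:
            enz = frozenset([others[int(rng.integers(len(others)))]])
        sub = sugars[int(rng.integers(len(sugars)))]
        prod = sugars[int(rng.integers(len(sugars)))]
        pattern = f"p{1 + (i - 1) % n_patterns:03d}"
        reactions[code] = GlycoReaction(code, enz, sub, prod, pattern)
    planted_codes = frozenset(f"r{i:03d}" for i in range(1, n_planted_rxn + 1))
    decoy_pool = sorted(set(reactions) - planted_codes)

    epitopes: dict[str, GlycanEpitope] = {}
    truth_epitopes: list[str] = []
    for j in range(1, n_epitopes + 1):
        eid = f"E{j:03d}"
        if j <= n_planted_epitopes:
            req = planted_codes
            truth_epitopes.append(eid)
            name = f"planted epitope {j}"
        elif j <= n_planted_epitopes + n_decoys:
            extra = decoy_pool[int(rng.integers(len(decoy_pool)))]
            req = planted_codes | {extra}
            name = f"decoy epitope {j}"
        else:
            size = int(rng.integers(2, 5))
            req = frozenset(
                decoy_pool[i] for i in rng.choice(len(decoy_pool), size=size, replace=False)
            )
            name = f"random epitope {j}"
        epitopes[eid] = GlycanEpitope(eid, name, req)

    reg = GlycoRegistry(records, reactions, epitopes)
    truth = SyntheticTruth(
        seed=seed,
        params={
            "n_genes": n_genes, "n_reactions": n_reactions, "n_epitopes": n_epitopes,
            "n_patterns": n_patterns, "planted_enzymes": list(planted),
            "n_planted_epitopes": n_planted_epitopes, "n_decoys": n_decoys,
        },
        planted_epitope_ids=truth_epitopes,
    )
    return reg, truth


def simulate_bundle(
    out_dir: str | Path,
    seed: int = 0,
    n_genes: int = 2000,
    n_per_class: int = 5,
    de_fraction: float = 0.10,
    lfc: float = 2.0,
    dispersion: float = 0.1,
    family_size: int = 16,
    n_network_nodes: int = 200,
    seeds_k: int = 10,
    connector_fraction: float = 0.8,
) -> dict:
    """Write a coherent synthetic input bundle sharing one gene namespace.

    All planted structure is cross-linked so the full pipeline can recover
    it: a planted gene family of strongly expressed planted DE genes per
    direction, a gene-set collection (universe = the measured genes) with one
    set enriched in the planted family, an interaction network over genes
    containing a planted connector wired to most planted-family genes, and a
    glyco registry whose planted enzymes are strongly expressed planted
    up-regulated genes.

    Returns ``{"paths": {...}, "truth": SyntheticTruth}``. Files: counts.tsv,
    design.tsv, families.tsv, sets.gmt, network.tsv, registry/ and
    truth.json.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    m, design, t_counts = simulate_counts(
        n_genes, n_per_class, de_fraction, lfc, dispersion, seed=seed
    )
    genes = m.gene_ids
    base_mean = m.values.mean(axis=1)
    planted_up = [g for g, e in t_counts.planted_de_genes.items() if e > 0]
    planted_dn = [g for g, e in t_counts.planted_de_genes.items() if e < 0]
    # strongly expressed planted genes: reliably detectable at these settings
    top_up = sorted(planted_up, key=lambda g: -base_mean[g])[:family_size]
    top_dn = sorted(planted_dn, key=lambda g: -base_mean[g])[:family_size]
    if len(top_up) < 5 or len(top_dn) < 5:
        raise ValueError("too few planted genes to build family structure")

    m.values.to_csv(out / "counts.tsv", sep="\t")
    with open(out / "design.tsv", "w") as fh:
        for s in m.sample_ids:
            fh.write(f"{s}\t{design.labels[s]}\n")

    # --- family table: one planted family per direction, 3-member decoys ----
    fam_rows: list[tuple[str, str]] = []
    for g in top_up:
        fam_rows.append((g, "FAM_PLANTED_UP"))
    for g in top_dn:
        fam_rows.append((g, "FAM_PLANTED_DOWN"))
    in_planted = set(top_up) | set(top_dn)
    rest = [g for g in genes if g not in in_planted]
    for j, i in enumerate(range(0, len(rest) - 2, 3)):
        if j >= 40:
            break
        for g in rest[i : i + 3]:
            fam_rows.append((g, f"FAM{j:03d}"))
    with open(out / "families.tsv", "w") as fh:
        for g, f in fam_rows:
            fh.write(f"{g}\t{f}\n")

    # --- gene sets: universe = measured genes, planted set over the family --
    sets: dict[str, tuple[str, frozenset[str]]] = {}
    for j in range(1, 40):
        idx = rng.choice(len(genes), size=20, replace=False)
        sets[f"S{j:03d}"] = (f"random set {j}", frozenset(genes[i] for i in idx))
    filler = rng.choice(rest, size=4, replace=False).tolist()
    planted_set = frozenset(top_up[:8] + top_dn[:8] + filler)
    sets["S_planted"] = ("planted enriched set", planted_set)
    coll = GeneSetCollection(sets, frozenset(genes))
    from .enrich import write_gmt

    write_gmt(coll, out / "sets.gmt")

    # --- network over genes with planted connector --------------------------
    net_extra = [g for g in rest if g not in planted_set]
    n_bg = n_network_nodes - len(in_planted) - 1
    bg = rng.choice(net_extra, size=n_bg, replace=False).tolist()
    node_pool = sorted(in_planted) + bg
    base = nx.barabasi_albert_graph(len(node_pool), 3, seed=int(rng.integers(2**31)))
    g_net = nx.relabel_nodes(base, dict(enumerate(node_pool)))
    connector = "CONNECT1"
    wired_k = int(round(connector_fraction * seeds_k))
    wired = sorted(rng.choice(sorted(in_planted), size=wired_k, replace=False))
    g_net.add_node(connector)
    g_net.add_edges_from((connector, s) for s in wired)
    probs = {"protein-protein": 0.7, "gene-regulatory": 0.2, "biochemical": 0.1}
    types = list(probs)
    draw = rng.choice(len(types), size=g_net.number_of_edges(), p=[probs[t] for t in types])
    with open(out / "network.tsv", "w") as fh:
        for (u, v), ti in zip(sorted(g_net.edges), draw):
            fh.write(f"{u}\t{v}\t{types[ti]}\n")

    # --- glyco registry: planted enzymes are strong planted up genes --------
    planted_enzymes = top_up[:3]
    other_syms = [g for g in rest if g not in planted_set][-27:]
    reg, t_reg = simulate_glyco_registry(
        n_genes=30,
        symbols=planted_enzymes + other_syms,
        planted_enzymes=planted_enzymes,
        seed=seed,
    )
    write_registry(reg, out / "registry")

    truth = SyntheticTruth(
        seed=seed,
        params={
            "n_genes": n_genes, "n_per_class": n_per_class,
            "de_fraction": de_fraction, "lfc": lfc, "dispersion": dispersion,
            "family_size": family_size, "planted_families": [
                "FAM_PLANTED_UP", "FAM_PLANTED_DOWN",
            ],
            "planted_family_up": top_up, "planted_family_down": top_dn,
            "planted_enzymes": planted_enzymes,
        },
        planted_de_genes=t_counts.planted_de_genes,
        planted_enriched_set_id="S_planted",
        planted_connector_ids=[connector],
        planted_epitope_ids=t_reg.planted_epitope_ids,
    )
    truth.to_json(out / "truth.json")
    paths = {
        "counts": out / "counts.tsv", "design": out / "design.tsv",
        "families": out / "families.tsv", "gmt": out / "sets.gmt",
        "network": out / "network.tsv", "registry": out / "registry",
        "truth": out / "truth.json",
    }
    return {"paths": paths, "truth": truth}
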