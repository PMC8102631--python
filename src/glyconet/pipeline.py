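"""End-to-end orchestration: config -> report bundle.

The pipeline chains the stages in their analysis order: differential
expression (or ingestion of a pre-made marker list), symbol normalization,
gene-family ranking and reduction (with glycogenes always appended),
over-representation analysis, induced network-module extraction, and
glycogene-to-epitope inference. All outputs are plain text (TSV / GraphML /
XGMML / JSON) and a manifest records versions, seeds and thresholds so a
bundle is reproducible byte-for-byte from its config.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .diffexpr import (
    DEThresholds,
    read_counts_tsv,
    read_design_tsv,
    run_de,
    write_deg_tsv,
)
from .enrich import load_gmt, metabolite_ora, ora
from .glyco import glyco_subset, infer_epitopes, load_registry, registry_stats
from .markers import (
    assign_gene_families,
    map_metabolite_ids,
    normalize_symbols,
    rank_families,
    read_alias_tsv,
    read_crosswalk_tsv,
    read_family_tsv,
    select_top_family_genes,
)
from .netmod import annotate_and_export, induce_module, load_network

__all__ = ["PipelineConfig", "run_pipeline", "run_marker_enrichment"]

log = logging.getLogger("glyconet.pipeline")


@dataclass
class PipelineConfig:
    """Paths and thresholds for a full run; defaults follow the study design
    (p 0.05 / FDR 0.1 / twofold, family cutoff 5, gene ORA 0.05, z 20)."""

    out_dir: str
    counts: str | None = None
    design: str | None = None
    design_reference: str | None = None
    marker_list: str | None = None
    alias_map: str | None = None
    family_table: str | None = None
    gmt: str | None = None
    network: str | None = None
    registry_dir: str | None = None
    scale: str = "counts"
    thresholds: DEThresholds = field(default_factory=DEThresholds)
    family_cutoff: int = 5
    family_per_direction: bool = True
    ora_p_cutoff: float = 0.05
    metabolite_p_cutoff: float = 0.01
    z_threshold: float = 20.0
    permutations: int = 999
    seed: int = 0
    export_format: str = "graphml"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        thr = raw.pop("thresholds", None)
        cfg = cls(**raw)
        if thr:
            cfg.thresholds = DEThresholds(**thr)
        return cfg

    def validate(self) -> None:
        if self.counts is None and self.marker_list is None:
            raise ValueError("config needs either counts+design or a marker_list")
        for name in (
            "counts", "design", "marker_list", "alias_map", "family_table",
            "gmt", "network",
        ):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise ValueError(f"{name} path does not exist: {p}")
        if self.registry_dir is not None and not Path(self.registry_dir).is_dir():
            raise ValueError(f"registry_dir does not exist: {self.registry_dir}")

    def manifest(self) -> dict:
        from dataclasses import asdict

        d = asdict(self)
        d["glyconet_version"] = __version__
        return d


def _stage(name: str):
    """Log a stage and convert its failures into stage-named errors."""

    class _Ctx:
        def __enter__(self):
            self.t0 = time.perf_counter()
            log.info("stage %s: start", name)
            return self

        def __exit__(self, exc_type, exc, tb):
            dt = time.perf_counter() - self.t0
            if exc is not None:
                log.error("stage %s: failed after %.2fs", name, dt)
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
            log.info("stage %s: done in %.2fs", name, dt)
            return False

    return _Ctx()


def _load_registry_dir(registry_dir: str) -> "object":
    d = Path(registry_dir)
    return load_registry(
        d / "glyco_genes.tsv", d / "glyco_reactions.tsv", d / "glyco_epitopes.tsv"
    )


def run_pipeline(cfg: PipelineConfig) -> dict[str, Path]:
    """Execute the configured stages and write the report bundle.

    Returns a mapping of artifact name -> written path. Re-running with the
    same config and seeds reproduces identical files.
    """
    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    idmap = read_alias_tsv(cfg.alias_map) if cfg.alias_map else None
    registry = _load_registry_dir(cfg.registry_dir) if cfg.registry_dir else None

    # --- stage 1: markers (DE selection or pre-made list) ------------------
    if cfg.counts is not None:
        with _stage("differential-expression"):
            m = read_counts_tsv(cfg.counts, scale=cfg.scale)
            design = read_design_tsv(cfg.design, reference=cfg.design_reference)
            degs = run_de(m, design, cfg.thresholds, B=cfg.permutations, seed=cfg.seed)
            write_deg_tsv(degs, out / "degs.tsv")
            written["degs"] = out / "degs.tsv"
    else:
        with _stage("marker-ingestion"):
            markers = [
                ln.strip() for ln in Path(cfg.marker_list).read_text().splitlines()
                if ln.strip()
            ]
            degs = pd.DataFrame(
                {
                    "log2fc": 0.0, "stat": 0.0, "p": 1.0, "fdr": 1.0,
                    "direction": "up", "selected": True,
                },
                index=pd.Index(markers, name="gene"),
            )
            degs.to_csv(out / "markers_ingested.tsv", sep="\t")
            written["degs"] = out / "markers_ingested.tsv"

    # --- stage 2: symbol normalization --------------------------------------
    selected = [str(g) for g in degs.index[degs["selected"]]]
    if idmap is not None:
        with _stage("symbol-normalization"):
            mapped, unmapped, dups = normalize_symbols(selected, idmap)
            rename = {}
            for g in selected:
                r = idmap.resolve(g)
                if r is not None:
                    rename[g] = r
            degs = degs.rename(index=rename)
            degs = degs[~degs.index.duplicated(keep="first")]
            report = pd.DataFrame(
                {"input": unmapped, "status": ["unmapped"] * len(unmapped)}
            )
            report.to_csv(out / "normalization_report.tsv", sep="\t", index=False)
            written["normalization_report"] = out / "normalization_report.tsv"
            selected = [str(g) for g in degs.index[degs["selected"]]]

    # --- stage 3: family reduction ------------------------------------------
    glyco_genes: list[str] = []
    if registry is not None:
        glyco_genes = list(glyco_subset(registry, degs).index)
    if cfg.family_table is not None:
        with _stage("family-reduction"):
            fam = read_family_tsv(cfg.family_table)
            if cfg.family_per_direction:
                parts = []
                pools: dict[str, list[str]] = {"up": [], "down": []}
                for direction in ("up", "down"):
                    genes = [
                        str(g)
                        for g in degs.index[
                            degs["selected"] & (degs["direction"] == direction)
                        ]
                    ]
                    members, _ = assign_gene_families(genes, fam)
                    ranking = rank_families(members, cfg.family_cutoff)
                    ranking.insert(0, "direction", direction)
                    parts.append(ranking)
                    picked = select_top_family_genes(degs, ranking, members, glyco_genes)
                    pools[direction] = picked[direction]
                ranking_all = pd.concat(parts, ignore_index=True)
                reduced = {"up": pools["up"], "down": pools["down"]}
            else:
                members, _ = assign_gene_families(selected, fam)
                ranking_all = rank_families(members, cfg.family_cutoff)
                reduced = select_top_family_genes(degs, ranking_all, members, glyco_genes)
            ranking_all.to_csv(out / "family_ranking.tsv", sep="\t", index=False)
            written["family_ranking"] = out / "family_ranking.tsv"
            seed_genes = sorted(set(reduced["up"]) | set(reduced["down"]) | set(glyco_genes))
            pd.Series(seed_genes, name="gene").to_csv(
                out / "reduced_genes.tsv", sep="\t", index=False
            )
            written["reduced_genes"] = out / "reduced_genes.tsv"
    else:
        seed_genes = sorted(set(selected) | set(glyco_genes))

    # --- stage 4: over-representation ---------------------------------------
    if cfg.gmt is not None:
        with _stage("over-representation"):
            coll = load_gmt(cfg.gmt)
            res = ora(seed_genes, coll, p_cutoff=cfg.ora_p_cutoff)
            res.to_csv(out / "enrichment.tsv", sep="\t", index=False, float_format="%.6g")
            written["enrichment"] = out / "enrichment.tsv"

    # --- stage 5: induced network module ------------------------------------
    if cfg.network is not None:
        with _stage("induced-module"):
            net = load_network(cfg.network)
            module = induce_module(net, seed_genes, z_threshold=cfg.z_threshold)
            ext = "graphml" if cfg.export_format == "graphml" else "xgmml"
            path = out / f"module.{ext}"
            annotate_and_export(module, degs, path, fmt=cfg.export_format)
            written["module"] = path

    # --- stage 6: epitope inference ------------------------------------------
    if registry is not None:
        with _stage("epitope-inference"):
            up_glyco = [
                g for g in glyco_genes if str(degs.loc[g, "direction"]) == "up"
            ]
            preds = infer_epitopes(registry, up_glyco or glyco_genes)
            preds.to_csv(out / "epitopes.tsv", sep="\t", index=False, float_format="%.6g")
            written["epitopes"] = out / "epitopes.tsv"
            stats = registry_stats(registry)
            with open(out / "registry_stats.json", "w") as fh:
                json.dump(stats, fh, indent=2, sort_keys=True)
                fh.write("\n")
            written["registry_stats"] = out / "registry_stats.json"

    # --- manifest -------------------------------------------------------------
    with open(out / "manifest.json", "w") as fh:
        json.dump(cfg.manifest(), fh, indent=2, sort_keys=True)
        fh.write("\n")
    written["manifest"] = out / "manifest.json"
    return written


def run_marker_enrichment(
    markers: list[str],
    kind: str,
    cfg: PipelineConfig,
) -> pd.DataFrame:
    """Normalize a marker list and run the kind-specific ORA.

    ``kind`` is "protein" (gene symbols, cutoff ``cfg.ora_p_cutoff``) or
    "metabolite" (names resolved to KEGG ids, cutoff
    ``cfg.metabolite_p_cutoff``). Raises if every marker is unmapped.
    """
    if kind not in ("protein", "metabolite"):
        raise ValueError(f"unknown marker kind {kind!r}")
    if cfg.gmt is None:
        raise ValueError("config must point to a GMT collection")
    coll = load_gmt(cfg.gmt)
    if kind == "protein":
        if cfg.alias_map:
            idmap = read_alias_tsv(cfg.alias_map)
            query, unmapped, _ = normalize_symbols(markers, idmap)
        else:
            query, unmapped = list(dict.fromkeys(markers)), []
        if not query:
            raise ValueError("all markers unmapped")
        res = ora(query, coll, p_cutoff=cfg.ora_p_cutoff)
    else:
        if not cfg.alias_map:
            raise ValueError("metabolite runs need a crosswalk table (alias_map)")
        idmap = read_crosswalk_tsv(cfg.alias_map)
        table, unmapped = map_metabolite_ids(markers, idmap)
        query = [k for k in table["kegg"] if k]
        if not query:
            raise ValueError("all markers unmapped")
        res = metabolite_ora(query, coll, p_cutoff=cfg.metabolite_p_cutoff)
    res.attrs["unmapped"] = unmapped
    return res
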