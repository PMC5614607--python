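"""End-to-end orchestration: read -> map -> build -> induce -> detect ->
filter -> validate -> integrate -> enrich -> write -> report.

The whole run is reproducible bit-for-bit given ``rng_seed``; each random
stage draws from a single seeded generator in a fixed order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from . import io as hio
from .core import (BioNetwork, GeneScoreTable, Subnetwork,
                   induce_scored_subgraph, transform_scores)
from .detection import detect_subnetworks, filter_redundant
from .enrichment import AnnotationTable, enrich_gene_set
from .integration import MetaSubnetwork, build_meta_subnetworks, meta_threshold_profile
from .report import render_report
from .validation import (ValidationConfig, null_type1, null_type2, null_type3,
                         validate_subnetworks)

__all__ = ["RunConfig", "RunResult", "run", "run_in_memory", "sweep"]

log = logging.getLogger("htsnet")


@dataclass
class RunConfig:
    """All parameters of one analysis run.

    th is the minimum mean-score improvement a neighbor must contribute to
    be aggregated (default 0.05, a compromise between subnetwork count and
    stringency); overlap_rate is the redundancy-filter threshold (default
    0.8); min_common_n the interactome/regulome shared-gene threshold for
    meta-subnetworks; alpha_int / alpha_reg the per-network significance
    levels applied to all three p-values.
    """

    scores: Optional[Path] = None
    interactome: Optional[Path] = None
    regulome: Optional[Path] = None
    mapping: Optional[Path] = None
    annotations: Optional[Path] = None
    out_dir: Optional[Path] = None

    th: float = 0.05
    overlap_rate: float = 0.8
    min_common_n: int = 4
    alpha_int: float = 5e-3
    alpha_reg: float = 1e-2
    bonferroni: bool = True
    score_transform: str = "identity"
    score_mode: str = "mean"
    min_size: int = 2
    n_reps: int = 20
    m_samples: int = 10_000
    n_swaps_factor: int = 10
    max_components: int = 3
    rng_seed: int = 42
    average_duplicates: bool = False
    enrichment_scope: str = "per-set"  # or "pooled"
    enrichment_fdr: float = 0.05
    write_report: bool = True

    def validation_config(self) -> ValidationConfig:
        return ValidationConfig(
            n_reps=self.n_reps, m_samples=self.m_samples,
            alpha_int=self.alpha_int, alpha_reg=self.alpha_reg,
            bonferroni=self.bonferroni, max_components=self.max_components,
            n_swaps_factor=self.n_swaps_factor, th=self.th,
            overlap_rate=self.overlap_rate, min_size=self.min_size,
            score_mode=self.score_mode,
        )

    def echo(self) -> dict:
        d = {k: v for k, v in asdict(self).items()
             if not isinstance(v, (Path, type(None)))}
        for key in ("scores", "interactome", "regulome", "mapping",
                    "annotations", "out_dir"):
            val = getattr(self, key)
            if val is not None:
                d[key] = str(val)
        return d


@dataclass
class RunResult:
    subnetworks: List[Subnetwork]
    metas: List[MetaSubnetwork]
    unlinked: List[Subnetwork]
    networks: Dict[str, BioNetwork]
    scores: GeneScoreTable
    enrichment: Dict[str, list]
    summary: dict
    manifest: List[str] = field(default_factory=list)

    @property
    def retained(self) -> List[Subnetwork]:
        return [sn for sn in self.subnetworks if sn.retained]


def run_in_memory(
    config: RunConfig,
    scores: GeneScoreTable,
    interactome: BioNetwork,
    regulome: BioNetwork,
    annotations: Optional[AnnotationTable] = None,
) -> RunResult:
    """Run detection + validation + integration + enrichment on in-memory
    inputs. The on-disk stages (reading, writing, report) live in
    :func:`run`."""
    rng = np.random.default_rng(config.rng_seed)
    vcfg = config.validation_config()
    summary: dict = {"config": config.echo()}

    all_validated: List[Subnetwork] = []
    per_kind_retained: Dict[str, List[Subnetwork]] = {}
    for net in (interactome, regulome):
        induced, n_mapped = induce_scored_subgraph(net, scores)
        log.info("%s: %d scored genes, %d edges", net.kind, n_mapped,
                 induced.n_edges())
        subs = detect_subnetworks(induced, scores, th=config.th,
                                  min_size=config.min_size,
                                  score_mode=config.score_mode)
        subs = filter_redundant(subs, rate=config.overlap_rate)
        log.info("%s: %d candidate subnetworks after redundancy filter",
                 net.kind, len(subs))
        n1 = null_type1(induced, scores, vcfg, rng)
        n2 = null_type2(induced, scores, vcfg, rng)
        n3 = null_type3(scores, [sn.size for sn in subs] or [2], vcfg, rng)
        validated = validate_subnetworks(subs, n1, n2, n3, vcfg,
                                         scores=scores, rng=rng)
        kept = [sn for sn in validated if sn.retained]
        log.info("%s: %d retained at alpha=%g", net.kind, len(kept),
                 vcfg.alpha_for(net.kind))
        summary[net.kind] = {
            "genes_mapped": n_mapped,
            "edges": induced.n_edges(),
            "candidates": len(subs),
            "retained": len(kept),
        }
        all_validated.extend(validated)
        per_kind_retained[net.kind] = kept

    metas, unlinked = build_meta_subnetworks(
        per_kind_retained.get("interactome", []),
        per_kind_retained.get("regulome", []),
        n=config.min_common_n,
        scores=scores,
    )
    log.info("%d meta-subnetworks at n=%d (%d unlinked subnetworks)",
             len(metas), config.min_common_n, len(unlinked))
    summary["meta_subnetworks"] = len(metas)
    summary["unlinked_subnetworks"] = len(unlinked)

    enrichment: Dict[str, list] = {}
    if annotations is not None:
        universes = {
            kind: (induce_scored_subgraph(net, scores)[0].nodes)
            for kind, net in (("interactome", interactome), ("regulome", regulome))
        }
        retained = [sn for sn in all_validated if sn.retained]
        if config.enrichment_scope == "pooled":
            pooled = set()
            for sn in retained:
                pooled |= sn.members
            if pooled:
                universe = universes["interactome"] | universes["regulome"]
                enrichment["pooled"] = enrich_gene_set(
                    pooled, universe, annotations, fdr=config.enrichment_fdr)
        else:
            for sn in retained:
                enrichment[sn.id] = enrich_gene_set(
                    sn.members, universes[sn.network_kind], annotations,
                    fdr=config.enrichment_fdr)
            universe = universes["interactome"] | universes["regulome"]
            for m in metas:
                enrichment[m.id] = enrich_gene_set(
                    m.union_genes & universe, universe, annotations,
                    fdr=config.enrichment_fdr)
        n_sig = sum(sum(1 for r in v if r.significant) for v in enrichment.values())
        summary["significant_terms"] = n_sig

    return RunResult(
        subnetworks=all_validated,
        metas=metas,
        unlinked=unlinked,
        networks={"interactome": interactome, "regulome": regulome},
        scores=scores,
        enrichment=enrichment,
        summary=summary,
    )


def run(config: RunConfig) -> RunResult:
    """Full on-disk run: parse inputs, analyze, write outputs and report."""
    for name in ("scores", "interactome", "regulome"):
        p = getattr(config, name)
        if p is None or not Path(p).exists():
            raise FileNotFoundError(f"required input {name!r} missing: {p}")
    if config.out_dir is None:
        raise ValueError("out_dir is required")

    raw = hio.read_score_file(config.scores,
                              average_duplicates=config.average_duplicates)
    scores = transform_scores(raw, config.score_transform,
                              source_label=str(config.scores))

    records = hio.read_edge_list(config.interactome, default_class="ppi")
    records += hio.read_edge_list(config.regulome, default_class="tf-target")
    if config.mapping is not None:
        mapping = hio.read_id_mapping(config.mapping)
        records, n_unmapped = hio.apply_id_mapping(records, mapping)
        log.info("id mapping: %d unmapped identifiers kept verbatim", n_unmapped)
        mapped_scores = {}
        for g, z in scores.entries.items():
            mapped_scores[mapping.get(g, g)] = z
        scores = GeneScoreTable(entries=mapped_scores,
                                transform=scores.transform,
                                source_label=scores.source_label)
    interactome, regulome = hio.build_networks(records)

    annotations = (hio.read_annotations(config.annotations)
                   if config.annotations is not None else None)

    result = run_in_memory(config, scores, interactome, regulome, annotations)

    result.manifest = hio.write_outputs(
        config.out_dir, result.subnetworks, result.metas, result.networks,
        result.scores, enrichment=result.enrichment, summary=result.summary,
    )
    if config.write_report:
        result.manifest += render_report(
            config.out_dir, result.subnetworks, result.metas, result.networks,
            result.scores, enrichment=result.enrichment,
            config_echo=config.echo(),
        )
    result.manifest.sort()
    return result


def sweep(
    config: RunConfig,
    scores: GeneScoreTable,
    interactome: BioNetwork,
    regulome: BioNetwork,
    parameter: str,
    values: Sequence,
) -> List[Tuple[object, int, int, int]]:
    """Profile a parameter: rows of (value, subnetwork count, gene count,
    meta count). For ``min_common_n`` only the integration stage is rerun;
    for ``th`` and ``alpha`` the affected stages are recomputed."""
    if parameter not in ("th", "min_common_n", "alpha"):
        raise ValueError(f"unknown sweep parameter {parameter!r}")
    rows: List[Tuple[object, int, int, int]] = []
    if parameter == "min_common_n":
        result = run_in_memory(config, scores, interactome, regulome)
        int_subs = [s for s in result.retained if s.network_kind == "interactome"]
        reg_subs = [s for s in result.retained if s.network_kind == "regulome"]
        genes = set()
        for s in result.retained:
            genes |= s.members
        for n, count in meta_threshold_profile(int_subs, reg_subs,
                                               [int(v) for v in values], scores):
            rows.append((n, len(result.retained), len(genes), count))
        return rows
    for v in values:
        cfg = RunConfig(**{**asdict(config)})
        if parameter == "th":
            cfg.th = float(v)
        else:
            cfg.alpha_int = cfg.alpha_reg = float(v)
        result = run_in_memory(cfg, scores, interactome, regulome)
        genes = set()
        for s in result.retained:
            genes |= s.members
        rows.append((v, len(result.retained), len(genes), len(result.metas)))
    return rows
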