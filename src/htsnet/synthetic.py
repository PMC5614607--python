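"""Synthetic screen generator: networks, scores, annotations, planted modules.

Produces inputs in exactly the on-disk formats the pipeline reads, so the
whole tool can be exercised end to end without any database download. The
interactome is grown by preferential attachment, giving the heavy-tailed
degree distribution characteristic of real protein-interaction networks
(which is what stresses degree-preserving rewiring); the regulome wires a
designated TF fraction to random target sets. A "planted module" is a
random connected subgraph whose genes receive elevated z-scores
(Normal(effect_mean, noise_sd)) against a Normal(0, 1) background,
emulating a true hit neighborhood in an RNAi screen.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Optional, Set, Tuple

import networkx as nx
import numpy as np

from .core import BioNetwork, GeneScoreTable
from .enrichment import AnnotationTable

__all__ = [
    "PlantedTruth",
    "generate_network",
    "plant_module",
    "generate_scores",
    "generate_annotations",
    "write_fixture_files",
]


@dataclass
class PlantedTruth:
    """Ground truth of a synthetic screen for recovery benchmarks."""

    module_genes: Set[str]
    effect_mean: float
    noise_sd: float
    n_nodes: int
    tf_fraction: float
    rng_seed: int


def _gene_name(i: int) -> str:
    return f"G{i:04d}"


def generate_network(
    n_nodes: int = 300,
    mean_degree: float = 4.0,
    tf_fraction: float = 0.1,
    rng: Optional[np.random.Generator] = None,
    targets_per_tf: int = 8,
) -> Tuple[BioNetwork, BioNetwork]:
    """Generate an (interactome, regulome) pair over a shared gene universe.

    Interactome: Barabási–Albert preferential attachment with
    m = mean_degree / 2 edges per incoming node. Regulome:
    ceil(tf_fraction * n) TFs, each wired to ``targets_per_tf`` distinct
    random targets. TF flags are shared by both networks.
    """
    if n_nodes < 10:
        raise ValueError("need at least 10 nodes")
    rng = rng or np.random.default_rng()
    m = max(1, int(round(mean_degree / 2)))
    seed = int(rng.integers(0, 2**31 - 1))
    g = nx.barabasi_albert_graph(n_nodes, m, seed=seed)
    relabel = {i: _gene_name(i) for i in g.nodes}
    g = nx.relabel_nodes(g, relabel)

    genes = sorted(relabel.values())
    n_tfs = math.ceil(tf_fraction * n_nodes)
    tf_idx = rng.choice(n_nodes, size=n_tfs, replace=False)
    tfs = {genes[i] for i in tf_idx}

    interactome = BioNetwork(kind="interactome", graph=g, tf_genes=set(tfs))

    reg = nx.Graph()
    directed: Set[Tuple[str, str]] = set()
    for tf in sorted(tfs):
        candidates = [x for x in genes if x != tf]
        chosen = rng.choice(len(candidates), size=min(targets_per_tf, len(candidates)),
                            replace=False)
        for c in chosen:
            target = candidates[c]
            reg.add_edge(tf, target)
            directed.add((tf, target))
    regulome = BioNetwork(kind="regulome", graph=reg, tf_genes=set(tfs),
                          directed_edges=directed)
    return interactome, regulome


def plant_module(
    net: BioNetwork, size: int, rng: Optional[np.random.Generator] = None
) -> Set[str]:
    """Pick a random connected subgraph of ``size`` genes by random-walk
    induction from a random start node."""
    rng = rng or np.random.default_rng()
    nodes = sorted(net.nodes)
    if size < 1 or size > len(nodes):
        raise ValueError(f"module size {size} infeasible on {len(nodes)} nodes")
    components = [c for c in nx.connected_components(net.graph) if len(c) >= size]
    if not components:
        raise ValueError(f"no connected component of size >= {size}")
    comp = sorted(components[int(rng.integers(0, len(components)))])
    start = comp[int(rng.integers(0, len(comp)))]
    module = {start}
    frontier = net.neighbors(start)
    while len(module) < size:
        frontier -= module
        if not frontier:  # pragma: no cover - component size checked above
            raise ValueError("random walk exhausted before reaching size")
        pick = sorted(frontier)[int(rng.integers(0, len(frontier)))]
        module.add(pick)
        frontier |= net.neighbors(pick)
    return module


def generate_scores(
    net: BioNetwork,
    module: Set[str],
    effect_mean: float = 3.0,
    noise_sd: float = 0.5,
    rng: Optional[np.random.Generator] = None,
) -> GeneScoreTable:
    """Background z ~ N(0, 1); planted-module z ~ N(effect_mean, noise_sd)."""
    rng = rng or np.random.default_rng()
    if not module <= net.nodes:
        raise ValueError("module genes must be network nodes")
    entries: Dict[str, float] = {}
    for g in sorted(net.nodes):
        if g in module:
            entries[g] = float(rng.normal(effect_mean, noise_sd))
        else:
            entries[g] = float(rng.normal(0.0, 1.0))
    return GeneScoreTable(entries=entries, transform="identity",
                          source_label="synthetic screen")


def generate_annotations(
    net: BioNetwork,
    n_terms: int = 20,
    term_size_range: Tuple[int, int] = (5, 30),
    enriched_module: Optional[Set[str]] = None,
    rng: Optional[np.random.Generator] = None,
) -> AnnotationTable:
    """Random term memberships, plus (optionally) one term set to exactly
    the planted module as a positive control for enrichment."""
    rng = rng or np.random.default_rng()
    genes = sorted(net.nodes)
    lo, hi = term_size_range
    if hi > len(genes):
        raise ValueError("term size exceeds gene universe")
    gene_terms: Dict[str, Set[str]] = {}
    term_names: Dict[str, str] = {}
    for t in range(n_terms):
        term = f"T{t:04d}"
        term_names[term] = f"random process {t}"
        size = int(rng.integers(lo, hi + 1))
        members = rng.choice(len(genes), size=size, replace=False)
        for i in members:
            gene_terms.setdefault(genes[i], set()).add(term)
    if enriched_module:
        term = "T_MODULE"
        term_names[term] = "planted module process"
        for g in enriched_module:
            gene_terms.setdefault(g, set()).add(term)
    return AnnotationTable(gene_terms=gene_terms, term_names=term_names)


def write_fixture_files(
    out_dir: Path,
    n_nodes: int = 300,
    module_size: int = 8,
    effect_mean: float = 3.0,
    noise_sd: float = 0.5,
    tf_fraction: float = 0.1,
    mean_degree: float = 4.0,
    seed: int = 42,
) -> PlantedTruth:
    """Write a complete synthetic input set (scores.tsv, interactome.tsv,
    regulome.tsv, annotations.tsv, truth.tsv) in the pipeline's formats."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    interactome, regulome = generate_network(n_nodes, mean_degree, tf_fraction, rng)
    module = plant_module(interactome, module_size, rng)
    scores = generate_scores(interactome, module, effect_mean, noise_sd, rng)
    annotations = generate_annotations(interactome, enriched_module=module, rng=rng)

    with open(out_dir / "scores.tsv", "w") as fh:
        fh.write("gene\tzscore\n")
        for g in sorted(scores.entries):
            fh.write(f"{g}\t{scores.entries[g]:.6f}\n")
    with open(out_dir / "interactome.tsv", "w") as fh:
        for u, v in sorted(tuple(sorted(e)) for e in interactome.graph.edges()):
            fh.write(f"{u}\t{v}\tppi\n")
    with open(out_dir / "regulome.tsv", "w") as fh:
        for u, v in sorted(regulome.directed_edges):
            fh.write(f"{u}\t{v}\ttf-target\n")
    with open(out_dir / "annotations.tsv", "w") as fh:
        for g in sorted(annotations.gene_terms):
            for t in sorted(annotations.gene_terms[g]):
                fh.write(f"{g}\t{t}\t{annotations.term_names[t]}\n")
    with open(out_dir / "truth.tsv", "w") as fh:
        fh.write("module_gene\n")
        for g in sorted(module):
            fh.write(f"{g}\n")
    return PlantedTruth(
        module_genes=module,
        effect_mean=effect_mean,
        noise_sd=noise_sd,
        n_nodes=n_nodes,
        tf_fraction=tf_fraction,
        rng_seed=seed,
    )
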